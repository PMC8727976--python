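"""Consequences of 3D-print dimensional error for restrictor performance.

For each microscopy row of the printed 2 mm restrictors (true mean bore,
ridge feature size, layer thickness) this driver generates a synthetic wall
profile with those parameters, re-measures it with the profile analyser
(closing the generator/analyser loop), and propagates the undersizing
through the fourth-power law to the multiplicative pressure-drop error.

Usage: python analysis/05_print_tolerance.py [--seed N]
"""

import argparse
from pathlib import Path

import pandas as pd

import ventsplit as v
from ventsplit import reference as ref

RESULTS = Path(__file__).resolve().parents[1] / "results"
NOMINAL = 2.0


def main(seed: int = 0) -> pd.DataFrame:
    rows = []
    for i, (printer, (layer, true_id, _, feature)) in enumerate(
            ref.MICROSCOPY_2MM.items()):
        profile = v.gen_wall_profile(
            nominal=NOMINAL, mean_undersize=NOMINAL - true_id,
            ridge_amplitude=feature, layer_thickness=layer,
            length=max(5.0, 8 * layer), noise_sd=0.002, seed=seed + i)
        summary = v.summarize_profile(profile)
        rows.append({
            "printer": printer,
            "layer_mm": layer,
            "true_id_mm": true_id,
            "measured_id_mm": summary.mean_internal_diameter,
            "feature_size_mm": summary.mean_feature_size,
            "id_error_to_layer": summary.id_error_to_layer_ratio,
            "dp_inflation_undersizing": summary.pressure_inflation_factor,
            "dp_inflation_with_ridges": v.pressure_deviation_from_undersizing(
                NOMINAL, summary.mean_internal_diameter,
                ridge_amplitude=summary.mean_feature_size / 2.0),
        })
    df = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "05_print_tolerance.csv", index=False)
    return df


if __name__ == "__main__":
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    df = main(parser.parse_args().seed)
    print(df.round(3).to_string(index=False))
    print("\nEvery printed 2 mm bore is undersized; the D^-4 sensitivity "
          "turns 0.06-0.62 mm of undersizing into 1.1x-4.4x pressure-drop "
          "inflation before ridge roughness is even counted — why printed "
          "restrictors need individual calibration.")
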