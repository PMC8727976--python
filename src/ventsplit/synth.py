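"""Synthetic bench data and wall profiles.

Everything the analysis consumes can be generated here with the stated
statistical structure, so every stage is testable without instruments:

* bench measurements of pressure drop vs flow with multiplicative Gaussian
  noise at the instrument accuracies (0.6% of reading for the mass flow
  meter, 0.5% for the pressure transducers, both read as 1-sigma relative),
* internal-wall radius profiles with systematic undersizing, layer-periodic
  sinusoidal ridges, and additive measurement noise.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError
from .fitting import MeasurementSet
from .hydraulics import RestrictorLaw, quadratic_pressure_drop
from .tolerance import WallProfile


@dataclass(frozen=True)
class BenchNoiseModel:
    """Relative 1-sigma instrument noise for the bench rig."""

    flow_relative_sd: float = 0.006  # mass flow meter, fraction of reading
    pressure_relative_sd: float = 0.005  # pressure transducers
    seed: int = 0

    def __post_init__(self) -> None:
        if self.flow_relative_sd < 0 or self.pressure_relative_sd < 0:
            raise DomainError("noise standard deviations must be non-negative")


def gen_bench_measurements(law: RestrictorLaw, flows, n_reps: int,
                           noise: BenchNoiseModel | None = None) -> MeasurementSet:
    """Simulate repeated steady pressure-drop/flow measurements.

    For each commanded flow and replicate the observed flow is
    ``true * (1 + eps_f)`` and the observed drop ``dp(true) * (1 + eps_p)``
    with independent Gaussian relative errors — percent-of-reading
    instrument specs read as multiplicative noise.
    """
    noise = noise or BenchNoiseModel()
    flows = np.asarray(flows, dtype=float)
    if np.any(flows <= 0):
        raise DomainError("commanded flows must be positive")
    if n_reps < 1:
        raise DomainError("n_reps must be >= 1")
    rng = np.random.default_rng(noise.seed)
    true_flows = np.repeat(flows, n_reps)
    true_drops = np.array([quadratic_pressure_drop(law, f) for f in true_flows])
    obs_flows = true_flows * (1.0 + noise.flow_relative_sd
                              * rng.standard_normal(true_flows.size))
    obs_drops = true_drops * (1.0 + noise.pressure_relative_sd
                              * rng.standard_normal(true_flows.size))
    return MeasurementSet(flows=obs_flows, pressure_drops=obs_drops,
                          diameter=law.diameter, replicate_count=n_reps)


def gen_wall_profile(nominal: float, mean_undersize: float,
                     ridge_amplitude: float, layer_thickness: float,
                     length: float, noise_sd: float = 0.0, seed: int = 0,
                     samples_per_layer: int = 16) -> WallProfile:
    """Generate a sectioned bore profile with undersizing and layer ridges.

    radius(z) = (nominal - mean_undersize)/2
                + (ridge_amplitude/2) * sin(2 pi z / layer_thickness)
                + N(0, noise_sd)

    ``ridge_amplitude`` is on the diameter scale, matching the feature-size
    convention of the tolerance analyser (a generator amplitude of 0.05 mm
    reads back as a 0.05 mm feature).
    """
    if not (nominal > 0 and layer_thickness > 0 and length > 0):
        raise DomainError("nominal, layer_thickness and length must be positive")
    if not nominal - mean_undersize > 0:
        raise DomainError("mean_undersize leaves a non-physical bore")
    if ridge_amplitude < 0 or noise_sd < 0:
        raise DomainError("ridge_amplitude and noise_sd must be non-negative")
    if samples_per_layer < 8:
        raise DomainError("need at least 8 samples per layer period")
    dz = layer_thickness / samples_per_layer
    n = max(int(round(length / dz)) + 1, 16)
    z = np.arange(n) * dz
    rng = np.random.default_rng(seed)
    radius = ((nominal - mean_undersize) / 2.0
              + (ridge_amplitude / 2.0) * np.sin(2.0 * np.pi * z / layer_thickness)
              + noise_sd * rng.standard_normal(n))
    if np.any(radius <= 0):
        raise DomainError("generated radii are non-physical; reduce noise or "
                          "undersize")
    return WallProfile(axial_positions=z, internal_radii=radius,
                       layer_thickness=layer_thickness,
                       nominal_diameter=nominal)
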