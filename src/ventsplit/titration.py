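"""Tidal-volume titration by inspiratory time.

With a fixed restrictor, the delivered end-inspiratory volume can only be
controlled at the ventilator, by extending the inspiratory window.  This
module sweeps the window length T, simulating each case and recording the
end volume per branch (the titration curve), and inverts the monotone
curve by bisection to find the shortest T achieving a target volume.

In the unrestricted linear limit the curve is exactly
``C * dp * (1 - exp(-T / tau))``, which bounds what any window can
deliver: targets above the plateau ``C * dp`` are unreachable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .config import Scenario
from .errors import ConfigurationError, DomainError, UnreachableTargetError
from .simulation import simulate_branch
from .waveform import build_waveform


@dataclass(frozen=True)
class TitrationCurve:
    """End-inspiratory volume (L) per branch over a grid of windows (s)."""

    inspiratory_times: np.ndarray
    end_volumes: dict[str, np.ndarray]

    def to_frame(self):
        import pandas as pd
        data = {"T_s": self.inspiratory_times}
        for label, vols in self.end_volumes.items():
            data[f"V_end_L_{label}"] = vols
        return pd.DataFrame(data)


def _end_volume(scenario: Scenario, label: str, window: float) -> float:
    """Simulate one branch with the inspiratory window set to ``window``."""
    if window == 0.0:
        return 0.0
    vent = scenario.ventilator
    if window <= vent.rise_time:
        raise ConfigurationError(
            f"inspiratory window {window} s does not exceed the rise time "
            f"{vent.rise_time} s")
    vent = replace(vent, pressure_max_time=window - vent.rise_time)
    dt = min(scenario.solver.dt, vent.pressure_max_time / 20.0)
    waveform = build_waveform(vent, dt)
    solver = replace(scenario.solver, dt=dt)
    result = simulate_branch(waveform, scenario.branch(label),
                             scenario.gas, solver)
    return result.end_inspiratory_volume


def titration_curve(scenario: Scenario, t_grid,
                    branch_labels=None) -> TitrationCurve:
    """End-inspiratory volume vs inspiratory window for each branch.

    ``t_grid`` must be increasing; each entry is either 0 (no breath, zero
    volume) or a window longer than the configured rise time.  A breath
    period longer than the scenario's respiratory rate allows is permitted
    here — the sweep deliberately explores windows up to several seconds —
    so the rate constraint is relaxed by construction of the waveform per
    point.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size == 0 or np.any(np.diff(t_grid) <= 0):
        raise DomainError("t_grid must be a non-empty increasing 1-D grid")
    if np.any(t_grid < 0):
        raise DomainError("inspiratory times must be non-negative")
    labels = branch_labels or [b.label for b in scenario.branches]
    scenario = _without_rate_limit(scenario, float(t_grid[-1]))
    curves = {
        label: np.array([_end_volume(scenario, label, t) for t in t_grid])
        for label in labels}
    return TitrationCurve(inspiratory_times=t_grid, end_volumes=curves)


def _without_rate_limit(scenario: Scenario, t_max: float) -> Scenario:
    """Lower the respiratory rate so long sweep windows stay valid."""
    vent = scenario.ventilator
    slow_rate = 60.0 / (t_max + vent.rise_time + 1.0)
    vent = replace(vent, respiratory_rate=min(vent.respiratory_rate,
                                              slow_rate))
    return replace(scenario, ventilator=vent)


def required_inspiratory_time(scenario: Scenario, branch_label: str,
                              target_volume: float, t_max: float = 5.0,
                              tolerance: float = 1e-3) -> float:
    """Shortest inspiratory window delivering at least ``target_volume`` L.

    Bisects the monotone end-volume function to the given time tolerance
    (1 ms by default).  Raises :class:`UnreachableTargetError` if the
    target exceeds what ``t_max`` (or the infinite-time plateau C * dp)
    allows, reporting the plateau volume.
    """
    if not target_volume > 0:
        raise DomainError("target_volume must be positive")
    if not t_max > 0:
        raise DomainError("t_max must be positive")
    scenario = _without_rate_limit(scenario, t_max)
    branch = scenario.branch(branch_label)
    vent = scenario.ventilator
    plateau = branch.patient.compliance * (vent.peak_pressure - vent.peep)
    v_max = _end_volume(scenario, branch_label, t_max)
    if v_max < target_volume:
        raise UnreachableTargetError(
            f"target {target_volume} L unreachable within {t_max} s "
            f"(volume at t_max {v_max:.4f} L, asymptote {plateau:.4f} L)",
            asymptotic_volume=plateau)
    lo, hi = 0.0, t_max  # end volume < target at lo, >= target at hi
    while hi - lo > tolerance:
        mid = 0.5 * (lo + hi)
        if mid <= vent.rise_time:
            lo = mid
            continue
        if _end_volume(scenario, branch_label, mid) >= target_volume:
            hi = mid
        else:
            lo = mid
    return hi
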