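"""Two-patient inspiratory simulation of a ventilator splitter.

Each branch couples the ventilator waveform, an optional restrictor law and
the lumped RC patient model through the implicit scalar balance

    p_vent(t) - dp_restrictor(Vdot) = (tau / C) Vdot + V / C,

with driving pressures referenced to PEEP and the state V starting at 0
(so the end-of-window value is the tidal volume).  At each time step the
balance is solved for the flow by a safeguarded Newton iteration (the left
side minus the right is strictly monotone in Vdot, so a bracket always
exists and bisection is a guaranteed fallback), and the volume is advanced
with Heun's explicit trapezoidal rule.

The Y-splitter body's own loss is negligible at circuit scale, so by
default the two branches decouple and are integrated independently.  An
optional common series resistance re-couples them through the shared
splitter-node pressure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, SolverError
from .hydraulics import GasProperties, RestrictorLaw, quadratic_pressure_drop
from .patient import CircuitParams, PatientParams, time_constant
from .waveform import PressureWaveform


@dataclass(frozen=True)
class SolverOptions:
    """Integrator controls: step size, Newton tolerance and iteration cap."""

    dt: float = 1e-3  # s
    flow_tolerance: float = 1e-9  # L/s
    max_iterations: int = 60

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ConfigurationError("dt must be positive")
        if not self.flow_tolerance > 0:
            raise ConfigurationError("flow_tolerance must be positive")
        if self.max_iterations < 1:
            raise ConfigurationError("max_iterations must be >= 1")


@dataclass(frozen=True)
class BranchConfig:
    """One splitter branch: a labelled patient + circuit + restrictor."""

    label: str
    patient: PatientParams
    circuit: CircuitParams
    restrictor: RestrictorLaw = field(default_factory=RestrictorLaw.identity)

    def __post_init__(self) -> None:
        if not self.label:
            raise ConfigurationError("branch label must be non-empty")


@dataclass(frozen=True)
class BranchResult:
    """Simulated time series and summary scalars for one branch.

    ``flows`` are in L/min, ``volumes`` in L above the PEEP equilibrium,
    ``port_pressures`` are the stagnation pressures at the splitter outlet
    (gauge, cmH2O) and ``restrictor_drops`` the instantaneous restrictor
    pressure losses.
    """

    label: str
    times: np.ndarray
    flows: np.ndarray
    volumes: np.ndarray
    port_pressures: np.ndarray
    restrictor_drops: np.ndarray
    peak_pressure_drop: float
    peak_flow: float
    end_inspiratory_volume: float

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "time_s": self.times,
            "flow_Lmin": self.flows,
            "volume_L": self.volumes,
            "port_pressure_cmH2O": self.port_pressures,
            "restrictor_drop_cmH2O": self.restrictor_drops,
        })


def _solve_branch_flow(rhs: float, stiffness: float, law: RestrictorLaw,
                       tol: float, max_iter: int,
                       t: float = float("nan")) -> float:
    """Solve stiffness*q + dp_law(60 q) = rhs for the flow q (L/s).

    ``stiffness`` is tau/C > 0.  The residual is strictly increasing in q,
    so the root lies in [0, rhs/stiffness] (or its mirror for rhs < 0) and
    Newton steps are safeguarded by bisection on that shrinking bracket.
    """
    if rhs == 0.0:
        return 0.0
    lo, hi = sorted((0.0, rhs / stiffness))
    q = rhs / (stiffness + 60.0 * law.b)  # exact when a == 0
    g = float("nan")
    for _ in range(max_iter):
        g = stiffness * q + quadratic_pressure_drop(law, 60.0 * q) - rhs
        if g > 0.0:
            hi = q
        else:
            lo = q
        dg = stiffness + 60.0 * (2.0 * law.a * abs(60.0 * q) + law.b)
        q_new = q - g / dg
        if not (lo < q_new < hi):
            q_new = 0.5 * (lo + hi)
        if abs(q_new - q) < tol:
            return q_new
        q = q_new
    raise SolverError(
        f"flow solve did not converge at t={t:.4f} s (residual {g:.3e})",
        time=t, residual=g)


def simulate_branch(waveform: PressureWaveform, branch: BranchConfig,
                    gas: GasProperties | None = None,
                    solver: SolverOptions | None = None) -> BranchResult:
    """Integrate one branch over the waveform's inspiratory window.

    Driving pressure is ``p_vent(t) - waveform.baseline`` (i.e. referenced
    to PEEP); the reported port pressure is the absolute gauge stagnation
    pressure downstream of the restrictor.
    """
    solver = solver or SolverOptions()
    if not branch.patient.compliance > 0:
        raise ConfigurationError("compliance must be positive")
    dt = solver.dt
    t_end = float(waveform.times[-1] - waveform.times[0])
    n = max(int(round(t_end / dt)), 1)
    times = waveform.times[0] + np.linspace(0.0, t_end, n + 1)
    p_vent = np.interp(times, waveform.times, waveform.pressures)
    drive = p_vent - waveform.baseline

    tau = time_constant(branch.patient, branch.circuit)
    c = branch.patient.compliance
    stiffness = tau / c
    law = branch.restrictor
    tol, maxit = solver.flow_tolerance, solver.max_iterations

    volumes = np.empty(n + 1)
    flows_ls = np.empty(n + 1)
    v = 0.0
    for k in range(n + 1):
        q = _solve_branch_flow(drive[k] - v / c, stiffness, law, tol, maxit,
                               t=float(times[k]))
        volumes[k] = v
        flows_ls[k] = q
        if k < n:
            h = times[k + 1] - times[k]
            v_pred = v + h * q
            q_pred = _solve_branch_flow(drive[k + 1] - v_pred / c, stiffness,
                                        law, tol, maxit, t=float(times[k + 1]))
            v = v + 0.5 * h * (q + q_pred)

    flows = 60.0 * flows_ls
    drops = np.array([quadratic_pressure_drop(law, f) for f in flows])
    port_pressures = p_vent - drops
    return BranchResult(
        label=branch.label, times=times, flows=flows, volumes=volumes,
        port_pressures=port_pressures, restrictor_drops=drops,
        peak_pressure_drop=float(np.max(drops)),
        peak_flow=float(np.max(flows)),
        end_inspiratory_volume=float(volumes[-1]))


def _summary_frame(results) -> "object":
    import pandas as pd
    return pd.DataFrame({
        "branch": [r.label for r in results],
        "peak_drop_cmH2O": [r.peak_pressure_drop for r in results],
        "peak_flow_Lmin": [r.peak_flow for r in results],
        "end_inspiratory_volume_L": [r.end_inspiratory_volume for r in results],
    })


def simulate_splitter(waveform: PressureWaveform,
                      branches: tuple[BranchConfig, BranchConfig],
                      gas: GasProperties | None = None,
                      solver: SolverOptions | None = None,
                      common_resistance: float = 0.0):
    """Simulate both splitter branches; returns (results, summary table).

    With the default zero common resistance the branches decouple (the
    splitter body's loss is negligible) and are simulated independently.
    A positive ``common_resistance`` (cmH2O/(L/s)) re-couples them through
    the shared splitter-node pressure, solved per step by root bracketing.
    """
    if len(branches) != 2:
        raise ConfigurationError("exactly two branches are required")
    if branches[0].label == branches[1].label:
        raise ConfigurationError("branch labels must be unique")
    if common_resistance == 0.0:
        results = tuple(simulate_branch(waveform, b, gas, solver)
                        for b in branches)
    else:
        results = _simulate_coupled(waveform, branches, solver,
                                    common_resistance)
    return results, _summary_frame(results)


def _simulate_coupled(waveform, branches, solver, common_resistance):
    """Coupled integration with a common series resistance upstream."""
    from scipy.optimize import brentq

    solver = solver or SolverOptions()
    dt = solver.dt
    t_end = float(waveform.times[-1] - waveform.times[0])
    n = max(int(round(t_end / dt)), 1)
    times = waveform.times[0] + np.linspace(0.0, t_end, n + 1)
    p_vent = np.interp(times, waveform.times, waveform.pressures)
    drive = p_vent - waveform.baseline

    cs = [b.patient.compliance for b in branches]
    stiff = [time_constant(b.patient, b.circuit) / b.patient.compliance
             for b in branches]
    laws = [b.restrictor for b in branches]
    tol, maxit = solver.flow_tolerance, solver.max_iterations

    def branch_flows(node_drive, vols, t):
        return [
            _solve_branch_flow(node_drive - v / c, s, law, tol, maxit, t=t)
            for v, c, s, law in zip(vols, cs, stiff, laws)]

    def node_flows(p_drive, vols, t):
        """Flows and node pressure at a given inlet driving pressure."""
        def h(p_node):
            q = branch_flows(p_node, vols, t)
            return p_drive - p_node - common_resistance * sum(q)
        lo = min(p_drive, min(v / c for v, c in zip(vols, cs)), 0.0) - 1.0
        p_node = brentq(h, lo, p_drive + 1.0, xtol=1e-10)
        return branch_flows(p_node, vols, t), p_node

    vols = [0.0, 0.0]
    volumes = np.empty((2, n + 1))
    flows_ls = np.empty((2, n + 1))
    node_pressures = np.empty(n + 1)
    for k in range(n + 1):
        q, p_node = node_flows(drive[k], vols, float(times[k]))
        node_pressures[k] = p_node + waveform.baseline
        for i in range(2):
            volumes[i, k] = vols[i]
            flows_ls[i, k] = q[i]
        if k < n:
            h_step = times[k + 1] - times[k]
            v_pred = [vols[i] + h_step * q[i] for i in range(2)]
            q_pred, _ = node_flows(drive[k + 1], v_pred, float(times[k + 1]))
            vols = [vols[i] + 0.5 * h_step * (q[i] + q_pred[i])
                    for i in range(2)]

    results = []
    for i, b in enumerate(branches):
        flows = 60.0 * flows_ls[i]
        drops = np.array([quadratic_pressure_drop(laws[i], f) for f in flows])
        results.append(BranchResult(
            label=b.label, times=times, flows=flows, volumes=volumes[i],
            port_pressures=node_pressures - drops, restrictor_drops=drops,
            peak_pressure_drop=float(np.max(drops)),
            peak_flow=float(np.max(flows)),
            end_inspiratory_volume=float(volumes[i, -1])))
    return tuple(results)
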