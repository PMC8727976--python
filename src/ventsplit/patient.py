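"""Lumped RC model of one patient's airway/lungs and breathing circuit.

The patient branch is a single-compartment resistance-compliance network:
airway resistance R in series with lung compliance C, plus the endotracheal
tube and breathing-circuit compliance C_bc and resistance R_bc.  Because
the air's inertia is negligible, the stagnation pressure p0 at the splitter
outlet relates to the inspired volume V(t) by the first-order law

    p0 = (tau / C) dV/dt + V / C,      tau = R C + R_bc (C_bc + C).

Under a constant driving pressure this has the familiar exponential step
response V(t) = C p0 + (V0 - C p0) exp(-t / tau), used throughout as the
analytic oracle for the numerical integrator in the unrestricted limit.

Volumes are referenced to the end-expiratory equilibrium at PEEP, so the
state starts at V = 0 and the end-of-window value is the tidal volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DegenerateModelError, DomainError
from .hydraulics import CMH2O_PA, LMIN_TO_M3S, GasProperties


@dataclass(frozen=True)
class PatientParams:
    """Airway/lung constants: C in L/cmH2O, resistances in cmH2O/(L/s).

    Only the inspiratory resistance drives the simulation (expiration is
    out of scope); the expiratory value is carried for completeness.
    """

    compliance: float
    resistance_inspiration: float = 13.0
    resistance_expiration: float = 12.0

    def __post_init__(self) -> None:
        if not self.compliance > 0:
            raise DomainError("compliance must be positive")
        if self.resistance_inspiration < 0 or self.resistance_expiration < 0:
            raise DomainError("resistances must be non-negative")


@dataclass(frozen=True)
class CircuitParams:
    """Endotracheal tube + breathing-circuit constants."""

    compliance_bc: float = 0.004  # L/cmH2O
    resistance_bc: float = 22.0  # cmH2O/(L/s)

    def __post_init__(self) -> None:
        if self.compliance_bc < 0 or self.resistance_bc < 0:
            raise DomainError("circuit parameters must be non-negative")


def time_constant(patient: PatientParams, circuit: CircuitParams) -> float:
    """tau = R C + R_bc (C_bc + C), seconds, using inspiratory R."""
    return (patient.resistance_inspiration * patient.compliance
            + circuit.resistance_bc * (circuit.compliance_bc
                                       + patient.compliance))


def inspiratory_flow_rate(p0: float, volume: float, patient: PatientParams,
                          circuit: CircuitParams) -> float:
    """dV/dt = (p0 - V/C) * C / tau in L/s, the RC law solved for flow."""
    tau = time_constant(patient, circuit)
    if tau == 0:
        raise DegenerateModelError(
            "time constant is zero: instantaneous equilibration is not "
            "representable")
    return (p0 - volume / patient.compliance) * patient.compliance / tau


def step_response_volume(p0_step: float, t: float, patient: PatientParams,
                         circuit: CircuitParams, v0: float = 0.0) -> float:
    """Closed-form volume under a constant driving pressure p0_step.

    V(t) = C p0 + (v0 - C p0) exp(-t / tau).  Serves as the analytic
    oracle for the numerical branch integrator when no restrictor is
    present.
    """
    if t < 0:
        raise DomainError("t must be non-negative")
    tau = time_constant(patient, circuit)
    v_inf = patient.compliance * p0_step
    if tau == 0:
        return v_inf
    return v_inf + (v0 - v_inf) * math.exp(-t / tau)


def stagnation_to_static(p0: float, flow: float, port_diameter: float,
                         gas: GasProperties | None = None) -> float:
    """Convert stagnation to static pressure: p = p0 - rho U^2 / 2 (cmH2O).

    U is the bulk velocity of the given flow (L/min) through a circular
    port of the given diameter (mm).  At the 22 mm circuit ports the
    dynamic term is ~0.01 cmH2O and negligible; inside a 2 mm restrictor
    throat it reaches several cmH2O.
    """
    if not port_diameter > 0:
        raise DomainError("port_diameter must be positive")
    gas = gas or GasProperties()
    area = math.pi * (port_diameter * 1e-3 / 2.0) ** 2
    u = flow * LMIN_TO_M3S / area
    return p0 - 0.5 * gas.density() * u * abs(u) / CMH2O_PA
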