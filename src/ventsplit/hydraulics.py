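"""Pointwise hydraulic relations for flow restrictors.

A restrictor is a small-bore orifice placed in series with one port of a
ventilator Y-splitter so that the more compliant patient receives a reduced
inspiratory pressure.  This module collects the algebraic relations that
describe a restrictor in isolation:

* pipe Reynolds number ``Re = 4*Vdot / (pi * D * nu)``,
* the ideal orifice pressure drop ``dp = 8 rho Vdot^2 / (pi^2 c_D^2 D^4)``
  with discharge coefficient ``c_D``,
* the empirical signed quadratic law ``dp = a*Vdot*|Vdot| + b*Vdot`` fitted
  to resolved-flow simulations of the splitter+restrictor assembly,
* its cross-diameter power-law generalisation
  ``dp = k_a D^{m_a} Vdot^2 + k_b D^{m_b} Vdot``,
* the fourth-power diameter-sensitivity ratio and the secant mean
  resistance.

Interface units are the clinical ones: cmH2O for pressures, L/min for
volumetric flow, mm for diameters.  SI conversion happens only inside the
functions that need gas properties.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

from .errors import DomainError

#: Pascals per centimetre of water column.
CMH2O_PA = 98.0665

#: Cubic metres per second per (litre per minute).
LMIN_TO_M3S = 1.0 / 60000.0

#: Validity range (mm) of the cross-diameter power-law model.
POWERLAW_DIAMETER_RANGE = (2.0, 4.0)


@dataclass(frozen=True)
class GasProperties:
    """Thermophysical properties of the ventilated gas mixture.

    Defaults describe an 80% O2 / 20% dry-air blend at ambient conditions:
    specific gas constant 265 J/(kg K), specific heat capacity 936 J/(kg K),
    kinematic viscosity 2.02e-5 m^2/s.
    """

    specific_gas_constant: float = 265.0  # J/(kg K)
    specific_heat_capacity: float = 936.0  # J/(kg K)
    kinematic_viscosity: float = 2.02e-5  # m^2/s
    ambient_pressure: float = 101325.0  # Pa
    ambient_temperature: float = 293.0  # K

    def __post_init__(self) -> None:
        for name in ("specific_gas_constant", "specific_heat_capacity",
                     "kinematic_viscosity", "ambient_pressure",
                     "ambient_temperature"):
            if not getattr(self, name) > 0:
                raise DomainError(f"GasProperties.{name} must be positive")

    def density(self) -> float:
        """Ideal-gas density rho = p / (R T) in kg/m^3."""
        return self.ambient_pressure / (
            self.specific_gas_constant * self.ambient_temperature)


@dataclass(frozen=True)
class RestrictorLaw:
    """Signed quadratic pressure-flow law of one restrictor.

    ``dp(Vdot) = a * Vdot * |Vdot| + b * Vdot`` with ``a`` in
    cmH2O/(L/min)^2 and ``b`` in cmH2O/(L/min).  ``a = b = 0`` is the
    identity law (an unrestricted port).  The odd extension in flow keeps
    the law dissipative under flow reversal.
    """

    diameter: float | None  # nominal bore, mm; None for "no restrictor"
    a: float  # cmH2O/(L/min)^2
    b: float  # cmH2O/(L/min)
    discharge_coefficient: float | None = None

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0:
            raise DomainError("RestrictorLaw coefficients must be non-negative")
        if self.diameter is not None and not self.diameter > 0:
            raise DomainError("RestrictorLaw.diameter must be positive")
        if self.discharge_coefficient is not None and not (
                0 < self.discharge_coefficient <= 1):
            raise DomainError(
                "RestrictorLaw.discharge_coefficient must lie in (0, 1]")

    @classmethod
    def identity(cls) -> "RestrictorLaw":
        """The no-restrictor law: zero pressure drop at any flow."""
        return cls(diameter=None, a=0.0, b=0.0)

    @property
    def is_identity(self) -> bool:
        return self.a == 0.0 and self.b == 0.0

    def to_json(self) -> str:
        return json.dumps({
            "diameter_mm": self.diameter,
            "a_cmH2O_per_Lmin2": self.a,
            "b_cmH2O_per_Lmin": self.b,
            "discharge_coefficient": self.discharge_coefficient,
        })

    @classmethod
    def from_json(cls, text: str) -> "RestrictorLaw":
        d = json.loads(text)
        return cls(diameter=d.get("diameter_mm"),
                   a=d["a_cmH2O_per_Lmin2"], b=d["b_cmH2O_per_Lmin"],
                   discharge_coefficient=d.get("discharge_coefficient"))


@dataclass(frozen=True)
class PowerLawModel:
    """Cross-diameter generalisation of the quadratic restrictor law.

    ``dp(D, Vdot) = k_a * D^{m_a} * Vdot^2 + k_b * D^{m_b} * Vdot`` with D
    in mm, Vdot in L/min and dp in cmH2O.  Exponents are negative: wider
    bores drop less pressure.
    """

    k_a: float
    m_a: float
    k_b: float
    m_b: float

    def __post_init__(self) -> None:
        if not (self.k_a > 0 and self.k_b > 0):
            raise DomainError("PowerLawModel prefactors must be positive")
        if not (self.m_a < 0 and self.m_b < 0):
            raise DomainError("PowerLawModel exponents must be negative")

    def to_json(self) -> str:
        return json.dumps({
            "k_a_cmH2O_per_Lmin2": self.k_a, "m_a": self.m_a,
            "k_b_cmH2O_per_Lmin": self.k_b, "m_b": self.m_b,
        })

    @classmethod
    def from_json(cls, text: str) -> "PowerLawModel":
        d = json.loads(text)
        return cls(k_a=d["k_a_cmH2O_per_Lmin2"], m_a=d["m_a"],
                   k_b=d["k_b_cmH2O_per_Lmin"], m_b=d["m_b"])


def reynolds_number(flow: float, diameter: float,
                    gas: GasProperties | None = None) -> float:
    """Pipe Reynolds number 4*Vdot/(pi D nu) for flow in L/min, D in mm.

    Returns 0 at zero flow.  Transition to fully turbulent pipe flow occurs
    around Re ~ 4000; bench conditions for 2-4 mm restrictors sit in the
    5000-8000 band.
    """
    if not diameter > 0:
        raise DomainError("diameter must be positive")
    gas = gas or GasProperties()
    if flow == 0:
        return 0.0
    v_si = flow * LMIN_TO_M3S
    return 4.0 * v_si / (math.pi * (diameter * 1e-3) * gas.kinematic_viscosity)


def orifice_pressure_drop(flow: float, diameter: float,
                          discharge_coefficient: float,
                          gas: GasProperties | None = None) -> float:
    """Ideal sharp-orifice pressure drop, cmH2O, antisymmetric in flow.

    dp = 8 rho Vdot^2 / (pi^2 c_D^2 D^4) in SI, then converted to cmH2O.
    The drop scales as D^-4, which is what makes printed restrictors so
    sensitive to bore undersizing.
    """
    if not diameter > 0:
        raise DomainError("diameter must be positive")
    if not (0 < discharge_coefficient <= 1):
        raise DomainError("discharge_coefficient must lie in (0, 1]")
    gas = gas or GasProperties()
    v_si = flow * LMIN_TO_M3S
    d_m = diameter * 1e-3
    dp_pa = (8.0 * gas.density() * v_si * abs(v_si)
             / (math.pi ** 2 * discharge_coefficient ** 2 * d_m ** 4))
    return dp_pa / CMH2O_PA


def quadratic_pressure_drop(law: RestrictorLaw, flow: float) -> float:
    """Evaluate the signed quadratic law a*V|V| + b*V (flow in L/min)."""
    return law.a * flow * abs(flow) + law.b * flow


def powerlaw_pressure_drop(diameter: float, flow: float,
                           model: PowerLawModel) -> float:
    """Evaluate the cross-diameter power-law pressure drop, cmH2O.

    Warns (does not raise) outside the fitted 2-4 mm diameter range.
    """
    if not diameter > 0:
        raise DomainError("diameter must be positive")
    lo, hi = POWERLAW_DIAMETER_RANGE
    if not (lo <= diameter <= hi):
        warnings.warn(
            f"diameter {diameter} mm is outside the fitted range "
            f"{lo}-{hi} mm; extrapolating", stacklevel=2)
    return (model.k_a * diameter ** model.m_a * flow * abs(flow)
            + model.k_b * diameter ** model.m_b * flow)


def diameter_sensitivity(nominal_diameter: float, true_diameter: float) -> float:
    """(nominal/true)^4: the dp multiplier at fixed flow for an undersized bore."""
    if not (nominal_diameter > 0 and true_diameter > 0):
        raise DomainError("diameters must be positive")
    return (nominal_diameter / true_diameter) ** 4


def mean_resistance(law: RestrictorLaw, flow: float) -> float:
    """Secant resistance dp/Vdot in cmH2O/(L/s) at a given flow (L/min).

    Equals 60*(a*flow + b); at zero flow this is the small-signal value 60*b.
    """
    if flow < 0:
        raise DomainError("flow must be non-negative")
    return 60.0 * (law.a * flow + law.b)
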