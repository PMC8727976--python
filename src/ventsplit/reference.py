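"""Reference study conditions and CFD-fitted coefficients.

These constants are the published operating point of the splitter-restrictor
assessment this package reimplements at desk scale: pressure-control
ventilator settings, gas properties, patient/circuit RC constants, the
quadratic pressure-flow coefficients fitted to resolved-flow simulations of
each restrictor diameter, the cross-diameter power-law model, and the
microscopy measurements of printed 2 mm restrictors.  They serve as default
scenario inputs and as fixtures for the analysis drivers.
"""

from __future__ import annotations

from .hydraulics import GasProperties, PowerLawModel, RestrictorLaw
from .patient import CircuitParams, PatientParams
from .waveform import VentilatorSettings

#: Default pressure-control settings (PIP 30 / PEEP 5 cmH2O, 16 breaths/min,
#: 1.25 s at peak pressure, 0.480 L target tidal volume per patient).
DEFAULT_VENTILATOR = VentilatorSettings()

#: 80% O2 / 20% dry air blend at ambient conditions.
DEFAULT_GAS = GasProperties()

#: Endotracheal tube + breathing circuit: C_bc = 0.004 L/cmH2O, R_bc = 22.
DEFAULT_CIRCUIT = CircuitParams()

#: Patient compliances considered, L/cmH2O.  The restricted port serves the
#: more compliant lung, whose inspiratory pressure the restrictor lowers.
RESTRICTED_COMPLIANCES = (0.04, 0.08, 0.20)
UNRESTRICTED_COMPLIANCES = (0.02, 0.04, 0.10)

#: CFD-fitted quadratic pressure-flow laws, dp = a V|V| + b V, per nominal
#: restrictor diameter (mm).  None = bare splitter port (no restrictor).
RESTRICTOR_LAWS: dict[float | None, RestrictorLaw] = {
    2.0: RestrictorLaw(diameter=2.0, a=0.22444, b=0.88262),
    3.0: RestrictorLaw(diameter=3.0, a=0.03961, b=0.26081),
    4.0: RestrictorLaw(diameter=4.0, a=0.01394, b=0.07828),
    None: RestrictorLaw(diameter=None, a=0.0, b=0.00361),
}

#: Cross-diameter power law dp ~ 3.55 D^-4.03 V^2 + 10.27 D^-3.46 V,
#: valid for D in 2-4 mm and flows up to 60 L/min.
POWER_LAW = PowerLawModel(k_a=3.55, m_a=-4.03, k_b=10.27, m_b=-3.46)

#: Peak pressure drops (cmH2O) and peak flows (L/min) from the resolved-flow
#: simulations, keyed like RESTRICTOR_LAWS.
PEAK_PRESSURE_DROPS = {2.0: 15.22, 3.0: 11.21, 4.0: 7.40, None: 0.11}
PEAK_FLOWS = {2.0: 6.6, 3.0: 14.0, 4.0: 20.4, None: 30.4}

#: Equivalent mean resistances at the time-average flow, cmH2O/(L/s).
MEAN_RESISTANCES = {2.0: 156.0, 3.0: 51.0, 4.0: 25.0, None: 0.22}

#: Microscopy of printed 2 mm restrictors: printer label ->
#: (layer thickness mm, true mean I.D. mm, I.D. peak-peak variation mm,
#:  mean ridge feature size mm).
MICROSCOPY_2MM = {
    "consumer_sla_50um": (0.050, 1.69, 0.06, 0.05),
    "consumer_fdm_50um": (0.050, 1.87, 0.04, 0.05),
    "consumer_fdm_100um": (0.100, 1.94, 0.12, 0.10),
    "consumer_fdm_200um": (0.200, 1.92, 0.15, 0.20),
    "professional_fdm_254um": (0.254, 1.38, 0.14, 0.23),
    "professional_polyjet_32um": (0.032, 1.74, 0.27, 0.43),
    "professional_fdm_100um": (0.100, 1.78, 0.28, 0.10),
    "prosumer_sla_50um": (0.050, 1.73, 0.06, 0.05),
}

#: Microscopy measurement uncertainty, mm.
MICROSCOPY_UNCERTAINTY = 0.01


def default_patient(compliance: float) -> PatientParams:
    """Patient with the standard airway resistances and a given compliance."""
    return PatientParams(compliance=compliance)
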