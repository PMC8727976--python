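"""Scenario configuration: YAML in, validated domain objects out.

A scenario bundles everything one splitter simulation needs — ventilator
settings, gas properties, exactly two patient branches with their
restrictors, and solver options.  Units are embedded in every YAML key so
a config file cannot be silently misread.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .hydraulics import GasProperties, RestrictorLaw
from .patient import CircuitParams, PatientParams
from .simulation import BranchConfig, SolverOptions
from .waveform import VentilatorSettings


@dataclass(frozen=True)
class Scenario:
    """A complete, validated simulation scenario."""

    ventilator: VentilatorSettings
    gas: GasProperties
    branches: tuple[BranchConfig, BranchConfig]
    solver: SolverOptions = field(default_factory=SolverOptions)

    def __post_init__(self) -> None:
        if len(self.branches) != 2:
            raise ConfigurationError("a scenario needs exactly two branches")
        if self.branches[0].label == self.branches[1].label:
            raise ConfigurationError("branch labels must be unique")

    def branch(self, label: str) -> BranchConfig:
        for b in self.branches:
            if b.label == label:
                return b
        raise ConfigurationError(
            f"no branch labelled {label!r}; have "
            f"{[b.label for b in self.branches]}")


def _require(mapping: dict, key: str, where: str):
    if key not in mapping:
        raise ConfigurationError(f"missing key {key!r} in {where}")
    return mapping[key]


def _ventilator_from_dict(d: dict) -> VentilatorSettings:
    return VentilatorSettings(
        peak_pressure=_require(d, "peak_pressure_cmH2O", "ventilator"),
        peep=_require(d, "peep_cmH2O", "ventilator"),
        respiratory_rate=d.get("respiratory_rate_per_min", 16.0),
        pressure_max_time=_require(d, "pressure_max_time_s", "ventilator"),
        rise_time=d.get("rise_time_s", 0.0),
        target_end_inspiratory_volume=d.get(
            "target_end_inspiratory_volume_L", 0.480))


def _gas_from_dict(d: dict | None) -> GasProperties:
    d = d or {}
    return GasProperties(
        specific_gas_constant=d.get("specific_gas_constant_J_kgK", 265.0),
        specific_heat_capacity=d.get("specific_heat_capacity_J_kgK", 936.0),
        kinematic_viscosity=d.get("kinematic_viscosity_m2_s", 2.02e-5),
        ambient_pressure=d.get("ambient_pressure_Pa", 101325.0),
        ambient_temperature=d.get("ambient_temperature_K", 293.0))


def _restrictor_from_dict(d: dict | None) -> RestrictorLaw:
    if d is None:
        return RestrictorLaw.identity()
    return RestrictorLaw(
        diameter=d.get("diameter_mm"),
        a=d.get("a_cmH2O_per_Lmin2", 0.0),
        b=d.get("b_cmH2O_per_Lmin", 0.0),
        discharge_coefficient=d.get("discharge_coefficient"))


def _branch_from_dict(d: dict) -> BranchConfig:
    circuit = d.get("circuit") or {}
    return BranchConfig(
        label=_require(d, "label", "patients entry"),
        patient=PatientParams(
            compliance=_require(d, "compliance_L_cmH2O", "patients entry"),
            resistance_inspiration=d.get(
                "resistance_inspiration_cmH2O_Ls", 13.0),
            resistance_expiration=d.get(
                "resistance_expiration_cmH2O_Ls", 12.0)),
        circuit=CircuitParams(
            compliance_bc=circuit.get("compliance_L_cmH2O", 0.004),
            resistance_bc=circuit.get("resistance_cmH2O_Ls", 22.0)),
        restrictor=_restrictor_from_dict(d.get("restrictor")))


def _solver_from_dict(d: dict | None) -> SolverOptions:
    d = d or {}
    return SolverOptions(
        dt=d.get("dt_s", 1e-3),
        flow_tolerance=d.get("flow_tolerance_Ls", 1e-9),
        max_iterations=d.get("max_iterations", 60))


def scenario_from_dict(doc: dict) -> Scenario:
    if not isinstance(doc, dict):
        raise ConfigurationError("scenario document must be a mapping")
    patients = _require(doc, "patients", "scenario")
    if not isinstance(patients, list) or len(patients) != 2:
        raise ConfigurationError("patients: must list exactly two branches")
    return Scenario(
        ventilator=_ventilator_from_dict(_require(doc, "ventilator", "scenario")),
        gas=_gas_from_dict(doc.get("gas")),
        branches=tuple(_branch_from_dict(p) for p in patients),
        solver=_solver_from_dict(doc.get("solver")))


def load_scenario(path) -> Scenario:
    """Parse and validate a scenario YAML file."""
    try:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"could not parse {path}: {exc}") from exc
    return scenario_from_dict(doc)


def default_scenario() -> Scenario:
    """The packaged default: 4 mm restrictor, C=0.1/0.2 patient pair."""
    text = resources.files("ventsplit.data").joinpath(
        "default_scenario.yaml").read_text()
    return scenario_from_dict(yaml.safe_load(text))


def default_scenario_path() -> Path:
    return Path(str(resources.files("ventsplit.data")
                    .joinpath("default_scenario.yaml")))
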