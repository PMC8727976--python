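"""Regression of restrictor pressure-flow laws.

Two levels of fitting:

1. Per-restrictor: least squares of measured pressure drop on (Vdot^2,
   Vdot) with zero intercept — the quadratic law has no constant term
   because dp(0) = 0 physically.
2. Cross-diameter: ordinary least squares of ln(a) and ln(b) on ln(D),
   yielding the power-law model dp = k_a D^{m_a} Vdot^2 + k_b D^{m_b} Vdot.

The closed-form inversion of the quadratic prefactor through the power-law
model, D = (a / k_a)^{1/m_a}, estimates the hydraulically effective bore of
a printed part from bench data alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import DomainError, FitError
from .hydraulics import PowerLawModel


@dataclass(frozen=True)
class MeasurementSet:
    """Bench measurements of one restrictor: paired flow (L/min) and dp (cmH2O)."""

    flows: np.ndarray
    pressure_drops: np.ndarray
    diameter: float | None = None  # nominal bore, mm
    replicate_count: int = 1

    def __post_init__(self) -> None:
        flows = np.asarray(self.flows, dtype=float)
        drops = np.asarray(self.pressure_drops, dtype=float)
        object.__setattr__(self, "flows", flows)
        object.__setattr__(self, "pressure_drops", drops)
        if flows.shape != drops.shape or flows.ndim != 1:
            raise DomainError("flows and pressure_drops must be 1-D and equal length")
        if np.any(flows < 0):
            raise DomainError("flows must be non-negative")

    def __len__(self) -> int:
        return self.flows.size

    def to_csv(self, path) -> None:
        import pandas as pd
        with open(path, "w") as fh:
            if self.diameter is not None:
                fh.write(f"# diameter_mm: {self.diameter}\n")
            fh.write(f"# replicate_count: {self.replicate_count}\n")
            pd.DataFrame({"flow_Lmin": self.flows,
                          "dp_cmH2O": self.pressure_drops}).to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "MeasurementSet":
        import pandas as pd
        diameter = None
        replicate_count = 1
        with open(path) as fh:
            pos = fh.tell()
            while True:
                line = fh.readline()
                if not line.startswith("#"):
                    fh.seek(pos)
                    break
                key, _, value = line[1:].partition(":")
                key = key.strip()
                if key == "diameter_mm":
                    diameter = float(value)
                elif key == "replicate_count":
                    replicate_count = int(value)
                pos = fh.tell()
            df = pd.read_csv(fh)
        return cls(flows=df["flow_Lmin"].to_numpy(),
                   pressure_drops=df["dp_cmH2O"].to_numpy(),
                   diameter=diameter, replicate_count=replicate_count)


@dataclass(frozen=True)
class QuadraticFit:
    """Fitted dp = a Vdot^2 + b Vdot with fit diagnostics.

    ``r_squared`` uses the zero-intercept convention (1 - SS_res / sum y^2);
    ``r_squared_centered`` is the mean-centred alternative, reported for
    comparison since conventions differ between tools.
    """

    a: float
    b: float
    r_squared: float
    standard_errors: tuple[float, float]
    r_squared_centered: float = float("nan")
    diameter: float | None = None

    def to_json_dict(self) -> dict:
        return {
            "diameter_mm": self.diameter,
            "a_cmH2O_per_Lmin2": self.a,
            "b_cmH2O_per_Lmin": self.b,
            "se_a": self.standard_errors[0],
            "se_b": self.standard_errors[1],
            "r_squared_zero_intercept": self.r_squared,
            "r_squared_centered": self.r_squared_centered,
        }


def _zero_intercept_lstsq(x: np.ndarray, y: np.ndarray):
    coef, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    if rank < x.shape[1]:
        raise FitError("design matrix is rank deficient "
                       "(need at least 3 distinct non-zero flows)")
    return coef


def fit_quadratic_law(data: MeasurementSet,
                      constrain_nonnegative: bool = False) -> QuadraticFit:
    """Zero-intercept least squares of dp on (Vdot^2, Vdot).

    With ``constrain_nonnegative`` a negative coefficient is clipped to
    zero and the other refit alone (noise on a nearly-linear law can push
    the tiny quadratic term below zero).
    """
    if np.unique(data.flows).size < 3:
        raise FitError("need at least 3 distinct flows for a quadratic fit")
    v = data.flows
    y = data.pressure_drops
    design = np.column_stack([v ** 2, v])
    a, b = _zero_intercept_lstsq(design, y)
    if constrain_nonnegative and (a < 0 or b < 0):
        if a < 0:
            a = 0.0
            b = float(np.dot(v, y) / np.dot(v, v))
            if b < 0:
                b = 0.0
        else:
            b = 0.0
            a = float(np.dot(v ** 2, y) / np.dot(v ** 2, v ** 2))
            if a < 0:
                a = 0.0

    resid = y - (a * v ** 2 + b * v)
    ss_res = float(np.dot(resid, resid))
    ss_tot_zero = float(np.dot(y, y))
    ss_tot_cent = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot_zero if ss_tot_zero > 0 else 1.0
    r2c = 1.0 - ss_res / ss_tot_cent if ss_tot_cent > 0 else float("nan")

    dof = max(len(data) - 2, 1)
    sigma2 = ss_res / dof
    cov = sigma2 * np.linalg.inv(design.T @ design)
    se = (float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1])))
    return QuadraticFit(a=float(a), b=float(b), r_squared=r2,
                        standard_errors=se, r_squared_centered=r2c,
                        diameter=data.diameter)


def bootstrap_standard_errors(data: MeasurementSet, n_boot: int = 200,
                              seed: int = 0) -> tuple[float, float]:
    """Residual-bootstrap standard errors of (a, b) for the quadratic fit."""
    fit = fit_quadratic_law(data)
    v = data.flows
    fitted = fit.a * v ** 2 + fit.b * v
    resid = data.pressure_drops - fitted
    rng = np.random.default_rng(seed)
    coefs = np.empty((n_boot, 2))
    design = np.column_stack([v ** 2, v])
    for i in range(n_boot):
        y_star = fitted + rng.choice(resid, size=resid.size, replace=True)
        coefs[i] = np.linalg.lstsq(design, y_star, rcond=None)[0]
    sd = coefs.std(axis=0, ddof=1)
    return float(sd[0]), float(sd[1])


def fit_power_laws(
        coefficients: Iterable[tuple[float, float, float]]) -> PowerLawModel:
    """Log-log OLS of per-diameter (a, b) coefficients against diameter.

    Input triples are (diameter_mm, a, b); the slope of ln(coef) on ln(D)
    is the exponent and exp(intercept) the prefactor, independently for a
    and b.
    """
    triples = list(coefficients)
    diams = np.array([t[0] for t in triples], dtype=float)
    a_vals = np.array([t[1] for t in triples], dtype=float)
    b_vals = np.array([t[2] for t in triples], dtype=float)
    if np.unique(diams).size < 2:
        raise FitError("need at least 2 distinct diameters")
    if np.any(a_vals <= 0) or np.any(b_vals <= 0) or np.any(diams <= 0):
        raise DomainError("power-law fitting requires positive diameters "
                          "and coefficients")
    ln_d = np.log(diams)
    m_a, ln_k_a = np.polyfit(ln_d, np.log(a_vals), 1)
    m_b, ln_k_b = np.polyfit(ln_d, np.log(b_vals), 1)
    return PowerLawModel(k_a=float(np.exp(ln_k_a)), m_a=float(m_a),
                         k_b=float(np.exp(ln_k_b)), m_b=float(m_b))


def effective_diameter(a: float, model: PowerLawModel) -> float:
    """Hydraulically effective bore (mm) from a quadratic prefactor a."""
    if not a > 0:
        raise DomainError("quadratic coefficient a must be positive")
    return (a / model.k_a) ** (1.0 / model.m_a)


def effective_diameter_from_fit(fit: QuadraticFit,
                                model: PowerLawModel) -> float:
    """Invert the power-law model to estimate the true bore from a fit.

    Solves k_a D^{m_a} = a in closed form; useful for diagnosing print
    undersizing from bench measurements alone.
    """
    return effective_diameter(fit.a, model)
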