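"""Parametric pressure-control ventilator waveform.

A pressure-control ventilator holds the airway at PEEP between breaths and
drives it to the peak inspiratory pressure (PIP) for a set time during each
breath.  Only the inspiratory window is generated here — expiration is out
of scope for the splitter analysis — so a waveform runs from t = 0 to
``rise_time + pressure_max_time``.

The rise is an exponential approach to PIP with time constant
``rise_time / 3`` (so the waveform reaches ~95% of the PIP-PEEP span by the
end of the rise), followed by a hold at PIP.  The default ``rise_time = 0``
produces a pure step already at PIP at t = 0, for which the lumped patient
model has a closed-form solution used as the solver oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DomainError


@dataclass(frozen=True)
class VentilatorSettings:
    """Pressure-control settings of the driving ventilator.

    Pressures are gauge, in cmH2O; the inspiratory window is
    ``rise_time + pressure_max_time`` and must fit inside one breath period
    ``60 / respiratory_rate``.
    """

    peak_pressure: float = 30.0  # cmH2O (PIP)
    peep: float = 5.0  # cmH2O
    respiratory_rate: float = 16.0  # breaths/min
    pressure_max_time: float = 1.25  # s at PIP
    rise_time: float = 0.0  # s, 0 = step
    target_end_inspiratory_volume: float = 0.480  # L per patient

    def __post_init__(self) -> None:
        if not self.peep >= 0:
            raise ConfigurationError("peep must be non-negative")
        if not self.peak_pressure > self.peep:
            raise ConfigurationError("peak_pressure must exceed peep")
        if not self.respiratory_rate > 0:
            raise ConfigurationError("respiratory_rate must be positive")
        if not self.rise_time >= 0:
            raise ConfigurationError("rise_time must be non-negative")
        window = self.rise_time + self.pressure_max_time
        if not 0 < window < 60.0 / self.respiratory_rate:
            raise ConfigurationError(
                "pressure_max_time: inspiratory window "
                f"{window:.3f} s must lie in (0, {60.0 / self.respiratory_rate:.3f}) s")

    @property
    def inspiratory_window(self) -> float:
        """Total inspiratory duration, s."""
        return self.rise_time + self.pressure_max_time


@dataclass(frozen=True)
class PressureWaveform:
    """Sampled gauge-pressure waveform (cmH2O) on a strictly increasing grid.

    ``baseline`` records the PEEP of the generating settings so simulators
    can reference driving pressure to the end-expiratory equilibrium.
    """

    times: np.ndarray
    pressures: np.ndarray
    baseline: float = 0.0

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        pressures = np.asarray(self.pressures, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "pressures", pressures)
        if times.shape != pressures.shape or times.ndim != 1:
            raise ConfigurationError(
                "times and pressures must be 1-D arrays of equal length")
        if times.size < 2 or not np.all(np.diff(times) > 0):
            raise ConfigurationError("times must be strictly increasing")
        if np.min(pressures) < 0:
            raise ConfigurationError("pressures must be non-negative (gauge)")

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame({"time_s": self.times,
                      "pressure_cmH2O": self.pressures}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, baseline: float = 0.0) -> "PressureWaveform":
        import pandas as pd
        df = pd.read_csv(path)
        return cls(times=df["time_s"].to_numpy(),
                   pressures=df["pressure_cmH2O"].to_numpy(),
                   baseline=baseline)


def build_waveform(settings: VentilatorSettings, dt: float) -> PressureWaveform:
    """Sample the inspiratory pressure waveform on a uniform grid of step dt.

    With ``rise_time = 0`` every sample equals PIP (the step happens at
    t = 0-, so the window is entirely at peak pressure).  With a positive
    rise time the waveform starts at PEEP and approaches PIP exponentially
    with time constant ``rise_time / 3`` before the hold.
    """
    if not dt > 0:
        raise ConfigurationError("dt must be positive")
    if not dt < settings.pressure_max_time / 10.0:
        raise ConfigurationError(
            "dt must be smaller than pressure_max_time / 10")
    total = settings.inspiratory_window
    n = int(round(total / dt))
    times = np.linspace(0.0, n * dt, n + 1)
    if times[-1] < total - 1e-12:
        times = np.append(times, total)
    elif times[-1] > total:
        times[-1] = total
    if settings.rise_time == 0.0:
        pressures = np.full_like(times, settings.peak_pressure)
    else:
        tau_rise = settings.rise_time / 3.0
        span = settings.peak_pressure - settings.peep
        rising = settings.peep + span * (1.0 - np.exp(-times / tau_rise))
        pressures = np.where(times < settings.rise_time,
                             rising, settings.peak_pressure)
    return PressureWaveform(times=times, pressures=pressures,
                            baseline=settings.peep)


def sample_pressure(waveform: PressureWaveform, t: float) -> float:
    """Linearly interpolate the waveform at time t (exact at sample nodes)."""
    if t < waveform.times[0] or t > waveform.times[-1]:
        raise DomainError(
            f"t={t} outside waveform domain "
            f"[{waveform.times[0]}, {waveform.times[-1]}]")
    return float(np.interp(t, waveform.times, waveform.pressures))
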