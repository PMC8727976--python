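"""Exception hierarchy for ventsplit.

All package errors derive from :class:`VentsplitError` so callers can catch
one base class; subclasses distinguish configuration mistakes from numerical
failures and physically out-of-domain inputs.
"""


class VentsplitError(Exception):
    """Base class for all ventsplit errors."""


class ConfigurationError(VentsplitError, ValueError):
    """A settings object or scenario file violates an invariant.

    The message names the offending field.
    """


class DomainError(VentsplitError, ValueError):
    """An argument is outside the physical domain of an operation."""


class DegenerateModelError(VentsplitError):
    """The lumped model has a zero time constant (instantaneous equilibration)."""


class SolverError(VentsplitError, RuntimeError):
    """The per-step implicit flow solve failed to converge."""

    def __init__(self, message: str, time: float | None = None,
                 residual: float | None = None):
        super().__init__(message)
        self.time = time
        self.residual = residual


class FitError(VentsplitError):
    """A regression problem is rank-deficient or otherwise unsolvable."""


class UnreachableTargetError(VentsplitError):
    """A titration target volume cannot be reached within the allowed window.

    Carries ``asymptotic_volume``, the branch's infinite-time volume C*dp.
    """

    def __init__(self, message: str, asymptotic_volume: float):
        super().__init__(message)
        self.asymptotic_volume = asymptotic_volume
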