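"""Exception hierarchy for kurafit."""


class KurafitError(Exception):
    """Base class for all kurafit errors."""


class ValidationError(KurafitError, ValueError):
    """Input data violates a documented contract (shape, finiteness, ...)."""


class InvalidBandError(ValidationError):
    """Requested frequency band is empty or outside (0, Nyquist)."""


class UndefinedPhaseError(KurafitError):
    """Instantaneous phase is undefined (e.g. an all-zero region series)."""


class UnderdeterminedSystemError(KurafitError):
    """Fewer phase-increment equations than unknown couplings (T < r + 2)."""


class SingularSystemError(KurafitError):
    """Normal-equation matrix is numerically singular for a target region."""


class IntegrationError(KurafitError):
    """Numerical integration produced a non-finite state."""


class PatternError(KurafitError):
    """Score-dependence pattern cannot be realised as requested."""
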