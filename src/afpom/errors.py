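"""Exception hierarchy shared across the pipeline."""


class AfpomError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(AfpomError, ValueError):
    """A model parameter violates its physical invariant (e.g. non-positive conductance)."""


class RangeError(AfpomError, ValueError):
    """A value lies outside its documented admissible range."""


class NumericalStateError(AfpomError, ValueError):
    """A state vector contains NaN/Inf; the message names the offending variable."""


class StabilityError(AfpomError, ValueError):
    """An explicit integration step violates the stability bound; the message suggests a dt."""


class PropagationError(AfpomError, RuntimeError):
    """A planar wave failed to reach a measurement probe."""


class NoAPError(AfpomError, ValueError):
    """No action-potential upstroke was detected where one was required."""


class ConfigurationError(AfpomError, ValueError):
    """A configuration entry is unknown or inconsistent."""


class DegenerateLabelError(AfpomError, ValueError):
    """A training table contains a single outcome class."""


class SchemaError(AfpomError, ValueError):
    """A feature table does not match the schema a fitted model expects."""


class MissingStageError(AfpomError, RuntimeError):
    """A pipeline stage was requested before its upstream outputs exist."""
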