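"""Exception hierarchy.

All package errors derive from :class:`AECError` so callers can catch a
single type; the subclasses mirror the kinds of failure a calibration or
compensation run can hit (bad arguments, ill-posed estimation, quality
vetoes, state misuse, file parsing).
"""


class AECError(Exception):
    """Base class for all errors raised by this package."""


class InvalidArgumentError(AECError, ValueError):
    """An argument violates a documented precondition."""


class EstimationError(AECError):
    """Kernel least-squares estimation is ill-posed (e.g. constant probe)."""


class SeparationError(AECError):
    """Electrode/membrane kernel separation cannot proceed."""


class QualityError(AECError):
    """A measurement failed a quality check (drift, negative resistance...)."""


class InstabilityError(QualityError):
    """Across-repeat scatter too high; the preparation is not stationary."""


class RecalibrationAdvised(QualityError):
    """Too much evoked activity during probing; repeat the calibration."""


class StateError(AECError, RuntimeError):
    """An operation was called on an object in the wrong state."""


class ParseError(AECError, ValueError):
    """A trace/kernel/config file could not be parsed."""
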