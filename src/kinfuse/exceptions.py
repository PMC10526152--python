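"""Exception hierarchy.

Everything raised on purpose derives from :class:`KinfuseError`, so callers
(and the CLI) can distinguish modelling errors from genuine bugs.
"""


class KinfuseError(Exception):
    """Base class for all package errors."""


class ConfigurationError(KinfuseError):
    """Inconsistent dimensions, non-stochastic tensors, bad class counts."""


class StepSizeError(KinfuseError):
    """A discrete step pushed a probability outside [0, 1]: Δt too large."""


class ValidationError(KinfuseError):
    """Malformed user input (files, specs, evidence records)."""


class InsufficientDataError(KinfuseError):
    """Too few observations for the requested statistic."""


class CalibrationError(KinfuseError):
    """A calibration step cannot be carried out on the given cohort."""


class AdmissibilityError(CalibrationError):
    """A (lambda, mu) choice violates its algebraic bounds."""


class CoverageError(CalibrationError):
    """A feature value falls outside every interval of a partition."""


class FeatureLookupError(KinfuseError):
    """Evidence refers to a feature with no calibrated matrices."""
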