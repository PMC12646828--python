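"""Exception hierarchy shared across the package.

Validation-type errors (bad parameters, bad config, missing columns) are
distinguished from computation-type errors (detection failures, degenerate
inputs, non-convergence) so the CLI can map them to distinct exit codes.
"""


class SonomyoError(Exception):
    """Base class for all package errors."""


class ValidationError(SonomyoError):
    """Invalid configuration, schema or file-level input."""


class InvalidParameterError(ValidationError):
    """A numeric parameter violates its documented constraints."""


class InvalidSpecError(ValidationError):
    """A cohort/scene specification is internally inconsistent."""


class MissingDataError(ValidationError):
    """Required fields or columns are absent; names the offenders."""


class InsufficientDataError(ValidationError):
    """Too few observations for the requested statistic."""


class ComputationError(SonomyoError):
    """The computation itself failed on otherwise valid inputs."""


class EmptyRoiError(ComputationError):
    """A region-of-interest mask contains no pixels."""


class DegenerateHistogramError(ComputationError):
    """Histogram has fewer distinct populated levels than classes."""


class DetectionFailureError(ComputationError):
    """An image-landmark detector found no usable structure."""


class ConvergenceError(ComputationError):
    """A model fit did not converge (e.g. perfect separation)."""


class UndefinedCorrelationError(ComputationError):
    """Correlation undefined because one variable has zero variance."""
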