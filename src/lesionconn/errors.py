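"""Exception types raised across the pipeline.

All inherit from :class:`LesionConnError` so callers can catch the package's
failures in one clause; parameter problems additionally inherit ``ValueError``.
"""


class LesionConnError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(LesionConnError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateSeriesError(LesionConnError):
    """A node time series (or residual) has zero variance."""


class DegenerateInputError(LesionConnError):
    """A statistical input has no variance or too few values."""


class IncompatibleInputError(LesionConnError):
    """Inputs that must align (node sets, subjects, lengths) do not."""


class InvalidNodeError(LesionConnError, KeyError):
    """A node id is absent from the object it was looked up in."""


class EmptyResultError(LesionConnError):
    """An operation would return an empty object (e.g. empty hemisphere)."""


class CoverageError(LesionConnError):
    """A voxel grid does not cover a node's sphere."""


class UndefinedMetricError(LesionConnError):
    """A graph metric is undefined for this input (e.g. edgeless graph)."""
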