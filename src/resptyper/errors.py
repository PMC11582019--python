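"""Typed error hierarchy.

Every validation failure in the package raises exactly one of these, all
rooted at :class:`RespTyperError` so callers (and the CLI) can catch the
whole family and map it to a non-zero exit status.
"""


class RespTyperError(Exception):
    """Base class for all errors raised by resptyper."""


class ParseError(RespTyperError):
    """A file could not be parsed in the expected dialect."""


class SchemaError(RespTyperError):
    """A table is missing required columns or holds out-of-design values."""


class DuplicateIdError(SchemaError):
    """Repeated ASV or sample identifier on a table axis."""


class MissingMetadataError(SchemaError):
    """A sample present in the count table lacks metadata or a qPCR total."""


class ExistsError(RespTyperError):
    """Output files already present and overwrite not requested."""


class ConfigError(RespTyperError):
    """Inconsistent simulation or pipeline configuration."""


class UnknownTypeError(ConfigError):
    """Unrecognised response-archetype label."""


class DesignError(RespTyperError):
    """The factorial design is incomplete (e.g. an empty treatment x day cell)."""


class UnitError(RespTyperError):
    """Physically impossible quantity (non-positive soil mass or interval)."""


class DegenerateSeriesError(RespTyperError):
    """A rate series is constant (or too short) to locate a peak."""


class ZeroDepthError(RespTyperError):
    """A sample has zero total reads; proportions are undefined."""


class NormalizationError(RespTyperError):
    """A vector that must be a composition does not sum to one."""


class NonPositiveError(RespTyperError):
    """Log-ratio input contains zero or negative entries."""


class ConstantTrajectoryError(RespTyperError):
    """Cannot z-score a constant trajectory."""


class TooFewItemsError(RespTyperError):
    """Not enough trajectories for the requested cluster-number scan."""


class KTooLargeError(RespTyperError):
    """Requested more clusters than distinct points."""


class IncompleteAssignmentError(RespTyperError):
    """An ASV lacks a response-type assignment in one or more treatments."""


class SingularDesignError(RespTyperError):
    """Collinear or degenerate explanatory factors in variance partitioning."""


class LabelConflictWarning(UserWarning):
    """A merged cluster centroid correlates poorly (<0.5) with every archetype."""
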