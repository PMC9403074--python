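"""Typed exceptions for the reference-chart pipeline.

Every failure mode named in the module contracts maps to one class here so
callers (and the CLI) can report errors without string matching.
"""


class AortaRefError(Exception):
    """Base class for all package errors."""


class InvalidMeasurementError(AortaRefError):
    """A diameter is non-positive or otherwise physically impossible."""


class InconsistentFramesError(AortaRefError):
    """End-systolic diameter smaller than end-diastolic (Dmax < Dmin)."""


class MalformedModelError(AortaRefError):
    """A polynomial model with no terms or duplicated powers."""


class ChartDomainError(AortaRefError):
    """Predicted SD non-positive at the requested predictor value."""


class InvalidSDError(AortaRefError):
    """A z-score was requested with a non-positive SD."""


class UnknownChartError(AortaRefError, KeyError):
    """No chart registered for the requested (response, predictor)."""


class IncompleteRecordError(AortaRefError):
    """The record lacks the predictor or response the chart needs."""


class EmptyInputError(AortaRefError):
    """An operation received an empty grid or table."""


class InsufficientDataError(AortaRefError):
    """Too few observations for the requested fit or test."""


class SingularFitError(AortaRefError):
    """Rank-deficient design matrix."""


class NoModelError(AortaRefError):
    """Every candidate term set failed to fit."""


class InsufficientBinsError(AortaRefError):
    """Too few predictor bins meet the minimum count for SD estimation."""


class NonPositiveSDError(AortaRefError):
    """A fitted SD model dips to zero or below over the data range."""


class DegenerateInputError(AortaRefError):
    """Constant or zero-variance input where variation is required."""


class DegenerateTableError(DegenerateInputError):
    """A repeatability table with zero total variance."""


class SchemaError(AortaRefError):
    """An input file is missing required columns or is empty."""


class ConfigError(AortaRefError):
    """An invalid generator or fit configuration."""


class ExtrapolationWarning(UserWarning):
    """Predictor value outside the chart's validated range."""
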