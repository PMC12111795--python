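"""Exception types shared across the package."""


class GraincastError(Exception):
    """Base class for all package errors."""


class DesignError(GraincastError):
    """Invalid factorial design (empty factor list, replicates < 1, ...)."""


class SchemaError(GraincastError):
    """A panel file/table does not match the expected column schema."""


class ParseError(GraincastError):
    """A cell in a panel file could not be parsed as a number."""


class InvalidRateError(GraincastError):
    """Missingness rate outside [0, 1)."""


class DegenerateScaleError(GraincastError):
    """A column is constant and cannot be standardized."""


class InsufficientDataError(GraincastError):
    """A series has too few observed points for the requested operation."""


class DegenerateSeriesError(GraincastError):
    """A series has zero variance; a correlation edge is undefined."""


class ShapeError(GraincastError):
    """Array dimensions inconsistent with the declared configuration."""


class ConfigError(GraincastError):
    """Invalid model or pipeline configuration."""


class DataSizeError(GraincastError):
    """Not enough time points to form a single training window."""


class UndefinedMetricError(GraincastError):
    """A metric is undefined for the given input (e.g. all-zero truths)."""


class InfeasibleKError(GraincastError):
    """Requested number of clusters exceeds the number of distinct points."""


class NotFittedError(GraincastError):
    """Operation requires a fitted model."""
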