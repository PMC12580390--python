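"""Exception types shared across the package."""


class SpatialTmeError(Exception):
    """Base class for all package errors."""


class SchemaError(SpatialTmeError):
    """A required column is missing or has the wrong type."""


class ValidationError(SpatialTmeError):
    """A row or value violates the data contract (carries line context)."""


class ConfigError(SpatialTmeError):
    """A configuration object is internally inconsistent."""


class UndefinedMetricError(SpatialTmeError):
    """A metric is undefined on the given input (e.g. no target cells).

    Undefined is deliberately distinct from zero: a core with no endothelial
    cells has no nearest-neighbor distance, not a distance of 0.
    """

    def __init__(self, message: str, *, reason: str = ""):
        super().__init__(message)
        self.reason = reason or message
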