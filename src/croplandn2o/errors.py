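"""Exception hierarchy shared across the pipeline stages."""


class CroplandN2OError(Exception):
    """Base class for all package errors."""


class InputError(CroplandN2OError, ValueError):
    """An input table, grid or argument violates a precondition."""


class ConfigError(CroplandN2OError, ValueError):
    """A configuration object violates one of its invariants."""


class SchemaError(CroplandN2OError, ValueError):
    """A table or grid is missing required columns/layers."""


class AlignmentError(CroplandN2OError, ValueError):
    """Two grids that must share shape and coordinates do not."""


class DependencyError(CroplandN2OError, RuntimeError):
    """A pipeline stage was requested without its upstream artifact."""


class NotFittedError(CroplandN2OError, RuntimeError):
    """A model operation was called before fitting."""


class InfeasibleScenarioError(CroplandN2OError, ValueError):
    """A nitrogen budget would require negative chemical-N input."""
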