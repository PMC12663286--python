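"""Exception hierarchy shared across the pipeline."""


class ThermacupError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(ThermacupError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateGeometryError(ThermacupError, ValueError):
    """Fiducials are collinear / a transform is singular."""


class EmptyRegionError(ThermacupError, ValueError):
    """A rasterized region contains no pixels."""


class DegenerateSampleError(ThermacupError, ValueError):
    """A statistical routine received a sample it cannot handle (zero variance, too few points)."""


class ConfigurationError(ThermacupError, ValueError):
    """A configuration value (thresholds, group parameters, run config) is invalid."""


class DatasetError(ThermacupError, ValueError):
    """An on-disk dataset is malformed; the message names the offending file."""
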