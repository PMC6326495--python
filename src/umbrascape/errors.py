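"""Exception hierarchy shared across the package."""


class UmbrascapeError(Exception):
    """Base class for all package errors."""


class GridMismatchError(UmbrascapeError):
    """Layers or masks do not share an identical grid."""


class InvalidParameterError(UmbrascapeError, ValueError):
    """A parameter is outside its documented domain."""


class EmptyFeatureError(UmbrascapeError):
    """A feature has no mass over the analysis mask and must be dropped."""


class EmptyLandscapeError(UmbrascapeError):
    """The analysis mask contains no cells."""


class InvalidCellError(UmbrascapeError):
    """A cell index is not in the remaining set."""


class StateCorruptionError(UmbrascapeError):
    """Internal prioritizer bookkeeping violated an invariant."""


class UnsupportedFormatError(UmbrascapeError):
    """A raster file is not a single-band north-up GeoTIFF."""


class InvalidComparisonError(UmbrascapeError):
    """Equal-area comparison requested at a fraction that does not match the region."""


class DegenerateTestError(UmbrascapeError):
    """A paired t-test with zero variance and non-zero mean difference."""


class InvalidClassError(UmbrascapeError):
    """A classed raster contains an unknown class code."""


class MissingLabelError(UmbrascapeError):
    """A feature lacks a group label required for a grouped summary."""


class ConfigError(UmbrascapeError):
    """A run configuration is invalid (unknown scenario, bad paths, ...)."""
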