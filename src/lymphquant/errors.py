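"""Exception hierarchy for the lymphquant pipeline."""


class LymphquantError(Exception):
    """Base class for all lymphquant errors."""


class FormatError(LymphquantError):
    """An input file decodes but violates the format contract (bit depth, channels)."""


class DegenerateHistogramError(LymphquantError):
    """A grey-level histogram has too little structure to threshold."""


class EstimationError(LymphquantError):
    """A data-driven parameter (e.g. background luminance) cannot be estimated."""


class RegistrationError(LymphquantError):
    """Rasters that must share a pixel grid do not."""


class NoTumorError(LymphquantError):
    """An operation requiring a tumor mask received an empty one."""


class ZeroAreaError(LymphquantError):
    """A region mask with zero surface cannot carry a density."""


class UndefinedAngleError(LymphquantError):
    """Angle of a point coincident with the reference centre is undefined."""


class PlacementError(LymphquantError):
    """Synthetic-slide rejection sampling could not satisfy the layout constraints."""


class ConfigError(LymphquantError):
    """A configuration file or value is invalid."""
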