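"""Exception hierarchy for the pmtraffic pipeline."""


class PMTrafficError(Exception):
    """Base class for all pmtraffic errors."""


class ParameterError(PMTrafficError, ValueError):
    """A simulation or analysis parameter is invalid (non-finite, out of range)."""


class ConfigurationError(PMTrafficError, ValueError):
    """A configuration object violates its invariants (e.g. no negative control)."""


class ShapeMismatchError(PMTrafficError, ValueError):
    """Rasters that must share a shape do not."""


class ChannelMismatchError(PMTrafficError, ValueError):
    """An image and an illumination profile belong to different channel roles."""


class OverConfluentError(PMTrafficError, ValueError):
    """A field has too few cell-free pixels to estimate residual background."""


class GateUndefinedError(PMTrafficError, ValueError):
    """Too few images on the plate to derive an adaptive QC gate."""


class ContractViolationError(PMTrafficError, RuntimeError):
    """An internal invariant was violated (e.g. zero-total cell reached scoring)."""


class DegenerateControlError(PMTrafficError, ValueError):
    """The negative control has zero or undefined SEM; deviation scores undefined."""


class FilenameParseError(PMTrafficError, ValueError):
    """A filename does not match the configured schema."""


class LayoutError(PMTrafficError, ValueError):
    """A plate layout table is malformed or incomplete."""
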