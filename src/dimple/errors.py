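"""Exception hierarchy for the pipeline."""


class DimpleError(Exception):
    """Base class for all pipeline errors."""


class FormatError(DimpleError):
    """A file could not be parsed in the expected format."""


class UnsupportedModeError(FormatError):
    """Profile-mode (non-centroided) spectra are not supported."""


class ShapeError(DimpleError):
    """Inconsistent raster shapes between inputs."""


class MaskError(DimpleError):
    """A mask violates its invariants (wrong shape, no foreground, ...)."""


class ParameterError(DimpleError, ValueError):
    """An out-of-range or inconsistent parameter value."""


class ChannelNotFoundError(DimpleError, KeyError):
    """No hyperspectral channel within the requested m/z tolerance."""
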