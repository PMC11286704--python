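"""Exception hierarchy for the quantification pipeline."""


class PFTQuantError(Exception):
    """Base class for all package-specific errors."""


class ParseError(PFTQuantError):
    """A DICOM file or config file could not be read."""


class GeometryError(PFTQuantError):
    """Series geometry is missing, inconsistent, or mismatched."""


class DegenerateInputError(PFTQuantError):
    """Input has no usable signal (constant volume, single-bin histogram, ...)."""


class PlacementError(PFTQuantError):
    """Phantom objects could not be placed without overlap."""


class ConfigError(PFTQuantError):
    """A rule table or run configuration is invalid."""


class StageError(PFTQuantError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
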