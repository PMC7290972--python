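"""Exception hierarchy for the FGR screening pipeline."""


class FgrScreenError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(FgrScreenError, ValueError):
    """A configuration field failed validation; the message names the field."""


class FormatError(FgrScreenError, ValueError):
    """A spectrum file could not be parsed or violates spectrum invariants."""


class CalibrationError(FgrScreenError):
    """Internal recalibration failed: a calibrant ion signal is missing or
    the fitted mass-axis correction is implausibly large. Spectra raising
    this are excluded from the analysis."""


class MarkerMissingError(FgrScreenError):
    """A panel marker ion signal could not be quantified.

    Attributes
    ----------
    marker_mz : float
        Nominal m/z of the missing marker.
    """

    def __init__(self, marker_mz: float, message: str | None = None):
        self.marker_mz = marker_mz
        super().__init__(message or f"marker ion signal at m/z {marker_mz:g} not found")


class DegenerateCutoffError(FgrScreenError, ValueError):
    """Two cut-off sets coincide on a quotient, so no dual (three-regime)
    scoring is possible for it."""


class StageError(FgrScreenError):
    """A pipeline stage failed; carries the stage name and offending record."""

    def __init__(self, stage: str, record_id: str, cause: Exception):
        self.stage = stage
        self.record_id = record_id
        self.cause = cause
        super().__init__(f"stage '{stage}' failed on record '{record_id}': {cause}")
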