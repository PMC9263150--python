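"""Exception hierarchy for the pipeline."""


class MangroveSlrError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(MangroveSlrError):
    """A configuration object violates its invariants."""


class AlignmentError(MangroveSlrError):
    """Rasters do not share shape, transform, or CRS."""


class NoExcessError(MangroveSlrError):
    """A Pb-210 core has no positive-excess interval to fit."""


class InsufficientDataError(MangroveSlrError):
    """Fewer positive-excess intervals than the fitting minimum."""


class NonDecayingProfileError(MangroveSlrError):
    """Fitted excess-activity slope is non-negative: no decay with depth."""


class OutOfRangeError(MangroveSlrError):
    """Requested year outside the tabulated scenario range."""


class InvalidSpanError(MangroveSlrError):
    """Rate denominator span is non-positive."""


class NoContourError(MangroveSlrError):
    """No elevation contour intersects the region of interest."""


class StageError(MangroveSlrError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
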