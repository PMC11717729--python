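"""Exception hierarchy for the pipeline.

All failures that a caller can act on derive from :class:`ACHRFError`, so a
batch driver can distinguish a bad scan (segmentation failure) from a bad
invocation (parameter error).
"""


class ACHRFError(Exception):
    """Base class for all package errors."""


class InputError(ACHRFError):
    """An input file or table is missing, unreadable or malformed."""


class ParameterError(ACHRFError, ValueError):
    """A parameter is outside its documented domain."""


class InvariantError(ACHRFError):
    """A domain-type invariant is violated (e.g. mismatched image shapes)."""


class SegmentationError(ACHRFError):
    """A scan could not be segmented; carries the pipeline stage that failed."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


class PlacementError(ACHRFError):
    """Focus placement failed; reports how many foci were actually placed."""

    def __init__(self, requested: int, achieved: int):
        self.requested = requested
        self.achieved = achieved
        super().__init__(
            f"could only place {achieved} of {requested} foci with the "
            f"required minimum separation"
        )


class EstimationError(ACHRFError):
    """A statistical model could not be estimated on the given data."""
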