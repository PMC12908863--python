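"""Exception hierarchy for the wfoi package."""


class WfoiError(Exception):
    """Base class for all wfoi errors."""


class InvalidArgumentError(WfoiError, ValueError):
    """An argument violates a documented precondition."""


class OutOfRangeError(WfoiError, ValueError):
    """A wavelength or window falls outside the supported range."""


class DegenerateSpectraError(WfoiError, ValueError):
    """Extinction curves are identical over the queried range."""


class NearSingularMatrixError(WfoiError, ValueError):
    """The two-wavelength extinction matrix is too ill-conditioned to invert."""


class FormatError(WfoiError, ValueError):
    """An input file or array has an inconsistent shape or layout."""


class DegenerateLandmarksError(WfoiError, ValueError):
    """Bregma and lambda coincide; no orientation can be derived."""


class EmptyMaskError(WfoiError, ValueError):
    """A brain mask contains no pixels."""


class StageError(WfoiError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
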