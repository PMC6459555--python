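"""Exception hierarchy for the autoflux pipeline.

Every stage raises a subclass of :class:`AutofluxError` so callers (and the
CLI) can distinguish bad inputs from internal failures.
"""


class AutofluxError(Exception):
    """Base class for all autoflux errors."""


class InvalidSpecError(AutofluxError, ValueError):
    """A simulation spec violates its invariants."""


class InvalidParameterError(AutofluxError, ValueError):
    """An analysis parameter is out of its documented range."""


class InvalidInputError(AutofluxError, ValueError):
    """Input data violate a precondition (non-finite intensities, shape mismatch...)."""


class PlacementError(AutofluxError, RuntimeError):
    """Cells could not be placed without overlap within the retry budget."""


class DegenerateModelError(AutofluxError, ValueError):
    """A background model cannot be fit (e.g. zero-variance calibration field)."""


class NotReadyError(AutofluxError, RuntimeError):
    """A component that requires training/configuration was used before it."""


class NoSeedsError(AutofluxError, ValueError):
    """Seeded watershed invoked with an empty seed volume."""


class EmptyPopulationError(AutofluxError, ValueError):
    """All flow events were excluded; no ratios to summarize."""


class InsufficientEventsError(AutofluxError, ValueError):
    """Fewer events than the configured floor for summary statistics."""


class UndefinedScoreError(AutofluxError, ZeroDivisionError):
    """Fold repression undefined: control and reference medians coincide."""


class InvalidLibraryError(AutofluxError, ValueError):
    """sgRNA library malformed (duplicate sequences, multi-gene guides...)."""


class UnknownGeneError(AutofluxError, KeyError):
    """A hit table references a gene absent from the simulated library."""


class DegenerateSampleError(AutofluxError, ValueError):
    """A count sample is all zeros; size factors are undefined."""


class PipelineStageError(AutofluxError, RuntimeError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
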