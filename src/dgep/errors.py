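"""Error taxonomy for the pipeline.

Every stage raises a named subclass of :class:`DgepError` so that callers
(and the CLI) can map failures to stable exit diagnostics.
"""


class DgepError(Exception):
    """Base class for all pipeline errors."""


# --- synthetic generators -------------------------------------------------
class UnknownIntensity(DgepError):
    """Requested stimulation intensity is not on the simulated grid."""


class IncompleteDesign(DgepError):
    """A required recording session is missing from the study design."""


class InvalidDuration(DgepError):
    """Non-positive recording duration."""


class InvalidDamage(DgepError):
    """Damaged area exceeds the total slice area."""


# --- evoked-potential analysis -------------------------------------------
class NoResponseDetected(DgepError):
    """Post-stimulus response amplitude below the configured minimum."""


class InsufficientRise(DgepError):
    """Too few samples in the rising-phase window for a slope fit."""


class MalformedLandmarks(DgepError):
    """Population-spike landmarks are not properly ordered."""


class EmptySession(DgepError):
    """No sweeps available for a recording session."""


class NoSpikingResponse(DgepError):
    """All population-spike areas are zero; no reference intensity exists."""


class UndefinedRatio(DgepError):
    """Denominator of a normalization or paired-pulse ratio is zero."""


# --- unit activity --------------------------------------------------------
class NyquistViolation(DgepError):
    """Sample rate too low for the requested filter band."""


class DegenerateSignal(DgepError):
    """Signal has zero median absolute deviation (e.g. constant)."""


class TooShort(DgepError):
    """Recording shorter than two rate bins."""


class UndefinedChange(DgepError):
    """Baseline firing rate is zero; relative change undefined."""


# --- morphometry ----------------------------------------------------------
class UndefinedPercent(DgepError):
    """Reference volume is zero; percent difference undefined."""


class InvalidROI(DgepError):
    """Mask extent exceeds the region of interest."""


# --- statistics -----------------------------------------------------------
class DegenerateDifferences(DgepError):
    """Paired differences carry no information (all zero / zero variance)."""


class InvalidP(DgepError):
    """A p-value outside [0, 1] was supplied."""


# --- orchestration --------------------------------------------------------
class MissingInput(DgepError):
    """A required stage output is absent."""


class IOFailure(DgepError):
    """Output location is not writable."""


class SchemaError(DgepError):
    """A dataset file violates the expected schema."""

    def __init__(self, message: str, file: str | None = None,
                 field: str | None = None):
        self.file = file
        self.field = field
        loc = " ".join(p for p in (file, field) if p)
        super().__init__(f"{message}" + (f" [{loc}]" if loc else ""))
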