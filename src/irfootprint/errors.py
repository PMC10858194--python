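"""Exception hierarchy.

Every data-shaped failure is a distinct, catchable subclass of
:class:`FootprintError`; the pipeline converts them into report diagnostics
rather than crashing.
"""


class FootprintError(Exception):
    """Base class for all irfootprint errors."""


# -- context -----------------------------------------------------------------

class MalformedRecordError(FootprintError):
    """The annotated-sequence record could not be interpreted."""


class NoFeaturesError(MalformedRecordError):
    """The record carries no gene/CDS features."""


class RegulatorNotFoundError(FootprintError):
    """The query regulator id does not match exactly one feature."""


class RegionTooShortError(FootprintError):
    """The extracted inter-operon region is shorter than the minimum length.

    Carries the arrangement and the (possibly empty) coordinates so callers
    can report the failure mode precisely.
    """

    def __init__(self, message, *, arrangement=None, start=None, end=None):
        super().__init__(message)
        self.arrangement = arrangement
        self.start = start
        self.end = end


# -- irscan ------------------------------------------------------------------

class SpacerTooLargeError(FootprintError):
    """Spacer exceeds the gap table under the 'forbid' overflow policy."""


class UnequalArmLengthError(FootprintError):
    """Inverted-repeat arms must have equal length."""


class NoRepeatFoundError(FootprintError):
    """No inverted repeat reached the score floor."""


# -- homology ----------------------------------------------------------------

class BackendUnavailableError(FootprintError):
    """Systemic backend failure (network down, archive missing)."""


class ZeroHitsError(FootprintError):
    """No homolog hits survive the filters."""


# -- footprint ---------------------------------------------------------------

class TooFewInstancesError(FootprintError):
    """Fewer operator instances than required to build a consensus."""


class EmptyMotifError(FootprintError):
    """Conservation score requested for a zero-length motif."""


# -- benchmark ---------------------------------------------------------------

class SequenceTooShortError(FootprintError):
    """Operator comparison needs both sequences to be at least 8 bp."""


# -- simfix ------------------------------------------------------------------

class InfeasibleParamsError(FootprintError):
    """Simulation parameters are inconsistent (operator longer than region)."""
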