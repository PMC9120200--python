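"""Exception hierarchy shared across the analysis stages."""


class PursuitError(Exception):
    """Base class for all analysis errors."""


class TraceFormatError(PursuitError):
    """The on-disk file does not follow the trace CSV dialect."""


class TraceValidationError(PursuitError):
    """A trace violates a structural invariant (e.g. non-monotone time)."""


class UnrecoverableTraceError(PursuitError):
    """Every sample of a trace is missing; interpolation has no anchors."""


class SegmentTooShortError(PursuitError):
    """An excursion's trimmed interval is empty."""

    def __init__(self, ordinal: int, message: str | None = None):
        self.ordinal = ordinal
        super().__init__(message or f"excursion {ordinal}: trimmed interval is empty")


class ClassificationDegeneracyError(PursuitError):
    """Rank grouping failed to produce a bijection onto the eight directions."""

    def __init__(self, ordinals, message: str | None = None):
        self.ordinals = list(ordinals)
        super().__init__(
            message or f"ambiguous direction assignment for excursions {sorted(self.ordinals)}"
        )


class ExcursionCountError(PursuitError):
    """The number of segmented excursions differs from the protocol's count."""


class DegenerateSegmentError(PursuitError):
    """A position-vector segment carries no usable shape (e.g. constant)."""


class WindowNotFoundError(PursuitError):
    """The rising limb never reaches the requested amplitude fraction."""


class InsufficientSamplesError(PursuitError):
    """Fewer than the minimum usable samples remain inside a regression window."""


class DegenerateTargetError(PursuitError):
    """The target's regression slope is (numerically) zero; gain is undefined."""
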