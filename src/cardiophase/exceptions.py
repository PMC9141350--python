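"""Exception hierarchy for cardiophase.

All package errors derive from :class:`CardioPhaseError`; validation-type
errors additionally derive from :class:`ValueError` so callers that only
know the standard library still catch them.
"""


class CardioPhaseError(Exception):
    """Base class for all cardiophase errors."""


class ValidationError(CardioPhaseError, ValueError):
    """Input violates a documented precondition or schema."""


class SeriesTooShortError(ValidationError):
    """A beat series is shorter than the smoothing window admits."""


class InsufficientDataError(CardioPhaseError, ValueError):
    """Too few observations for the requested statistical operation."""


class DegenerateFitError(CardioPhaseError, ValueError):
    """A regression or distribution fit has no usable solution."""


class ClassifierError(CardioPhaseError, ValueError):
    """The cohort model cannot support the requested classification."""
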