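"""Exception types raised across the pipeline."""

from __future__ import annotations


class AdeprevError(Exception):
    """Base class for all package-specific errors."""


class FormValidationError(AdeprevError, ValueError):
    """A criterion-response form is malformed (missing or unknown criteria,
    out-of-scale responses)."""


class RecordValidationError(AdeprevError, ValueError):
    """An assessment/consensus record set violates its preconditions
    (mismatched keys, duplicated or missing ratings)."""


class UnresolvedCaseError(AdeprevError):
    """Discordant rater pair with neither a discussion nor an adjudication
    outcome available."""

    def __init__(self, events: list):
        self.events = list(events)
        super().__init__(
            f"{len(self.events)} discordant case(s) without a discussion or "
            f"adjudication outcome: {self.events[:10]}"
        )


class UndefinedKappaError(AdeprevError, ZeroDivisionError):
    """Chance agreement is 1 while observed agreement is below 1; kappa has
    no defined value."""


class EmptySubsetError(AdeprevError, ValueError):
    """An agreement computation was requested on an empty event subset."""
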