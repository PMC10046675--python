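"""Exception hierarchy for the brevis package."""


class BrevisError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(BrevisError, ValueError):
    """Raised when input data violate a structural constraint."""


class ScoringError(BrevisError):
    """Raised when a card cannot be scored (e.g. all 25 targets omitted)."""

    def __init__(self, message: str, card_id: int | None = None,
                 participant_id: str | None = None):
        super().__init__(message)
        self.card_id = card_id
        self.participant_id = participant_id


class NormDomainError(BrevisError, ValueError):
    """Raised when demographics fall outside a correction model's hard domain."""


class PipelineError(BrevisError):
    """Raised when a norming-pipeline step cannot be carried out."""


class CohortFormatError(BrevisError, ValueError):
    """Raised for malformed cohort files; message lists offending rows."""


class SimulationError(BrevisError):
    """Raised when the synthetic generator receives an infeasible request."""
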