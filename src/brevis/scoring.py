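"""Raw scoring of the BReViS four-card cancellation task.

Each of the four cards (1: linear layout/low crowding, 2: linear/high,
3: random/low, 4: random/high) contains 25 targets among Landolt-ring
distractors. Execution time is inflated for missed targets into a
*performance time*::

    performance time = 25 * execution_time / (25 - omissions)

and the four performance times P1..P4 are combined into the indexes

* ``SA``  (Selective Attention)      = P1
* ``OA``  (Orientation of Attention) = (P3 + P4)/2 - (P1 + P2)/2
* ``FA``  (Focal Attention)          = (P2 + P4)/2 - (P1 + P3)/2
* ``Err`` (Total Errors)             = sum of omissions + substitutions

Higher values always mean worse performance. Autocorrections (targets the
examinee crossed, then corrected despite the "do not go back" instruction)
are recorded and reported but do not enter ``Err``: they are procedure
deviations rather than search failures.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ScoringError, ValidationError

#: number of targets on every card
N_TARGETS = 25

CARD_IDS = (1, 2, 3, 4)

CARD_LABELS = {
    1: "linear layout, low crowding",
    2: "linear layout, high crowding",
    3: "random layout, low crowding",
    4: "random layout, high crowding",
}


@dataclass(frozen=True)
class CardObservation:
    """Raw timing and error counts for a single card."""

    card_id: int
    execution_time: float  # seconds
    omissions: int
    substitutions: int = 0
    autocorrections: int = 0

    def __post_init__(self) -> None:
        if self.card_id not in CARD_IDS:
            raise ValidationError(f"card_id must be 1-4, got {self.card_id}")
        if not self.execution_time > 0:
            raise ValidationError(
                f"card {self.card_id}: execution_time must be > 0, "
                f"got {self.execution_time}"
            )
        if not 0 <= self.omissions <= N_TARGETS:
            raise ValidationError(
                f"card {self.card_id}: omissions must be within 0-{N_TARGETS}, "
                f"got {self.omissions}"
            )
        if self.substitutions < 0 or self.autocorrections < 0:
            raise ValidationError(
                f"card {self.card_id}: error counts must be non-negative"
            )


@dataclass(frozen=True)
class ParticipantRecord:
    """Demographics plus one observation per card, keyed by card_id."""

    participant_id: str
    age: int
    education: int  # years of formal schooling
    gender: str     # "F" or "M"
    cards: tuple[CardObservation, ...]

    def __post_init__(self) -> None:
        if self.gender not in ("F", "M"):
            raise ValidationError(
                f"participant {self.participant_id}: gender must be 'F' or "
                f"'M', got {self.gender!r}"
            )
        if self.education < 1:
            raise ValidationError(
                f"participant {self.participant_id}: education must be >= 1"
            )
        ids = sorted(c.card_id for c in self.cards)
        if ids != list(CARD_IDS):
            if len(set(ids)) < len(ids):
                raise ValidationError(
                    f"participant {self.participant_id}: duplicate card "
                    f"ids {ids}"
                )
            raise ValidationError(
                f"participant {self.participant_id}: missing card(s) "
                f"{sorted(set(CARD_IDS) - set(ids))}"
            )
        # store in administration order 1-4 regardless of input order
        object.__setattr__(
            self, "cards", tuple(sorted(self.cards, key=lambda c: c.card_id))
        )

    @property
    def gender_code(self) -> int:
        """0 = female, 1 = male (the coding of the correction equations)."""
        return 0 if self.gender == "F" else 1

    def card(self, card_id: int) -> CardObservation:
        return self.cards[card_id - 1]


@dataclass(frozen=True)
class IndexSet:
    """The four raw indexes plus the per-card performance times."""

    sa: float
    oa: float
    fa: float
    err: int
    card_performance_times: dict[int, float] = field(default_factory=dict)
    autocorrections: int = 0

    def as_dict(self) -> dict[str, float]:
        return {"SA": self.sa, "OA": self.oa, "FA": self.fa,
                "Err": float(self.err)}


def performance_time(execution_time: float, omissions: int, *,
                     card_id: int | None = None) -> float:
    """Execution time inflated for missed targets.

    Equals the execution time when nothing was omitted and grows without
    bound as omissions approach 25; a card with all 25 targets omitted has
    no defined performance time.
    """
    if not 0 <= omissions <= N_TARGETS:
        raise ValidationError(
            f"omissions must be within 0-{N_TARGETS}, got {omissions}"
        )
    if not execution_time > 0:
        raise ValidationError(
            f"execution_time must be > 0, got {execution_time}"
        )
    if omissions == N_TARGETS:
        where = f" on card {card_id}" if card_id is not None else ""
        raise ScoringError(
            f"all {N_TARGETS} targets omitted{where}: performance time "
            "undefined", card_id=card_id,
        )
    if omissions == 0:
        return float(execution_time)
    return N_TARGETS * execution_time / (N_TARGETS - omissions)


def compute_indexes(record: ParticipantRecord) -> IndexSet:
    """Score one participant: performance times and the four indexes."""
    times: dict[int, float] = {}
    for card in record.cards:
        try:
            times[card.card_id] = performance_time(
                card.execution_time, card.omissions, card_id=card.card_id
            )
        except ScoringError as exc:
            raise ScoringError(
                f"participant {record.participant_id}: {exc}",
                card_id=exc.card_id, participant_id=record.participant_id,
            ) from exc
    p1, p2, p3, p4 = (times[i] for i in CARD_IDS)
    err = sum(c.omissions + c.substitutions for c in record.cards)
    autoc = sum(c.autocorrections for c in record.cards)
    return IndexSet(
        sa=p1,
        oa=(p3 + p4) / 2.0 - (p1 + p2) / 2.0,
        fa=(p2 + p4) / 2.0 - (p1 + p3) / 2.0,
        err=err,
        card_performance_times=times,
        autocorrections=autoc,
    )
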