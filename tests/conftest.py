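import numpy as np
import pytest

from brevis import (
    CardObservation, ParticipantRecord, SyntheticCohortSpec, generate_cohort,
    published_norms,
)


@pytest.fixture(scope="session")
def published():
    return published_norms()


@pytest.fixture
def make_record():
    """Factory for records with given per-card (time, omissions) pairs."""

    def _make(times, omissions=(0, 0, 0, 0), substitutions=(0, 0, 0, 0),
              pid="P1", age=40, education=13, gender="F"):
        cards = tuple(
            CardObservation(card_id=i + 1, execution_time=float(t),
                            omissions=int(o), substitutions=int(s))
            for i, (t, o, s) in enumerate(zip(times, omissions, substitutions))
        )
        return ParticipantRecord(participant_id=pid, age=age,
                                 education=education, gender=gender,
                                 cards=cards)

    return _make


@pytest.fixture(scope="session")
def small_cohort():
    """A 120-participant synthetic cohort shared by read-only tests."""
    return generate_cohort(SyntheticCohortSpec(n=120, seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
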