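"""Raw scoring: performance times, index contrasts, validation."""
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brevis import (
    CardObservation, ParticipantRecord, ScoringError, ValidationError,
    compute_indexes, performance_time,
)


def _record(times):
    cards = tuple(
        CardObservation(card_id=i + 1, execution_time=float(t), omissions=0)
        for i, t in enumerate(times)
    )
    return ParticipantRecord("H1", 40, 13, "F", cards)


@pytest.mark.parametrize("t, om, expected", [
    (50.0, 0, 50.0),    # no omissions: time unchanged
    (48.0, 1, 50.0),    # 25*48/24
    (60.0, 5, 75.0),    # 25*60/20
])
def test_performance_time_values(t, om, expected):
    assert performance_time(t, om) == pytest.approx(expected)


def test_performance_time_all_omitted_is_scoring_error():
    with pytest.raises(ScoringError) as exc:
        performance_time(30.0, 25, card_id=3)
    assert exc.value.card_id == 3
    assert "card 3" in str(exc.value)


@pytest.mark.parametrize("t, om", [(30.0, 26), (30.0, -1), (0.0, 0),
                                   (-5.0, 2)])
def test_performance_time_invalid_inputs(t, om):
    with pytest.raises(ValidationError):
        performance_time(t, om)


@settings(max_examples=50, derandomize=True)
@given(t=st.floats(1.0, 500.0), lo=st.integers(0, 23))
def test_performance_time_increasing_in_omissions(t, lo):
    assert performance_time(t, lo + 1) > performance_time(t, lo)
    assert performance_time(t, 0) == t


@pytest.mark.parametrize("times, sa, oa, fa", [
    ((50, 60, 70, 80), 50.0, 20.0, 10.0),
    ((60, 60, 60, 60), 60.0, 0.0, 0.0),   # identical cards null the contrasts
])
def test_compute_indexes_contrasts(make_record, times, sa, oa, fa):
    s = compute_indexes(make_record(times))
    assert (s.sa, s.oa, s.fa) == pytest.approx((sa, oa, fa))
    assert s.err == 0


def test_compute_indexes_with_omissions_chain(make_record):
    # performance times (1 d.p.): 50.0, 58.7, 75.0, 85.7
    rec = make_record((48, 54, 66, 72), omissions=(1, 2, 3, 4))
    s = compute_indexes(rec)
    p = [25 * t / (25 - o) for t, o in zip((48, 54, 66, 72), (1, 2, 3, 4))]
    assert [round(v, 1) for v in p] == [50.0, 58.7, 75.0, 85.7]
    assert s.sa == pytest.approx(50.0)
    assert s.oa == pytest.approx((p[2] + p[3]) / 2 - (p[0] + p[1]) / 2)
    assert round(s.oa, 1) == 26.0
    assert round(s.fa, 1) == 9.7
    assert s.err == 10


def test_err_counts_omissions_and_substitutions_not_autocorrections():
    cards = tuple(
        CardObservation(card_id=i, execution_time=50.0, omissions=1,
                        substitutions=2, autocorrections=3)
        for i in range(1, 5)
    )
    rec = ParticipantRecord("P1", 40, 13, "M", cards)
    s = compute_indexes(rec)
    assert s.err == 4 * (1 + 2)
    assert s.autocorrections == 12


def test_compute_indexes_propagates_card_identity(make_record):
    rec = make_record((50, 50, 50, 50), omissions=(0, 0, 25, 0))
    with pytest.raises(ScoringError) as exc:
        compute_indexes(rec)
    assert exc.value.card_id == 3
    assert "P1" in str(exc.value)


def test_record_requires_all_four_distinct_cards():
    def card(cid):
        return CardObservation(card_id=cid, execution_time=50.0, omissions=0)

    with pytest.raises(ValidationError, match="missing card"):
        ParticipantRecord("P1", 40, 13, "F",
                          (card(1), card(2), card(3)))
    with pytest.raises(ValidationError, match="duplicate"):
        ParticipantRecord("P1", 40, 13, "F",
                          (card(1), card(2), card(3), card(3)))


def test_cards_stored_in_administration_order():
    def card(cid):
        return CardObservation(card_id=cid, execution_time=float(cid),
                               omissions=0)

    rec = ParticipantRecord("P1", 40, 13, "F",
                            (card(3), card(1), card(4), card(2)))
    assert [c.card_id for c in rec.cards] == [1, 2, 3, 4]
    assert rec.card(2).execution_time == 2.0


@settings(max_examples=50, derandomize=True)
@given(
    times=st.tuples(*[st.floats(5.0, 300.0)] * 4),
    shift=st.floats(-4.0, 50.0),
)
def test_contrast_shift_invariance(times, shift):
    """OA and FA are invariant under adding a constant to all four card
    times; SA shifts by exactly that constant."""
    base = compute_indexes(_record(times))
    moved = compute_indexes(_record(tuple(t + shift for t in times)))
    assert moved.sa - base.sa == pytest.approx(shift, abs=1e-9)
    assert moved.oa == pytest.approx(base.oa, abs=1e-9)
    assert moved.fa == pytest.approx(base.fa, abs=1e-9)


@settings(max_examples=50, derandomize=True)
@given(times=st.tuples(*[st.floats(5.0, 300.0)] * 4))
def test_card4_decomposition_identity(times):
    """Card 4's performance time decomposes exactly as SA + OA + FA: the
    two half-difference contrasts and the card-1 baseline always sum back
    to the hardest card's time."""
    s = compute_indexes(_record(times))
    p = s.card_performance_times
    assert p[4] == pytest.approx(s.sa + s.oa + s.fa, abs=1e-9)
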