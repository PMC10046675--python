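"""Synthetic cohort generator: structure, determinism, round-trips."""
import numpy as np
import pytest

from brevis import (
    ParticipantRecord, SyntheticCohortSpec, ValidationError, compute_indexes,
    filter_outliers, generate_cohort, indices_to_cards, published_norms,
    sample_demographics,
)
from brevis.simulate import (
    DECADES, DEMOGRAPHIC_COUNTS, EDUCATION_BANDS, default_baselines,
)


def test_default_baselines_are_sample_weighted():
    b = default_baselines()
    assert b["SA"] == pytest.approx(63.39, abs=0.01)
    assert b["Err"] == pytest.approx(16.08, abs=0.01)


def test_sample_demographics_single_record(rng):
    d = sample_demographics(1, rng)
    assert len(d) == 1
    assert 20 <= d["age"].item() <= 79
    assert 5 <= d["education"].item() <= 21
    assert d["gender"].item() in (0, 1)


def test_sample_demographics_margins(rng):
    """Decade and gender proportions track the normative cell counts."""
    n = 10_000
    d = sample_demographics(n, rng)
    counts = np.array([DEMOGRAPHIC_COUNTS[b] for b in EDUCATION_BANDS])
    male_expected = counts[:, :, 1].sum() / counts.sum()
    assert d["gender"].mean() == pytest.approx(male_expected, abs=0.02)
    decade_expected = counts.sum(axis=(0, 2)) / counts.sum()
    for i, (lo, hi) in enumerate(DECADES):
        frac = ((d["age"] >= lo) & (d["age"] <= hi)).mean()
        assert frac == pytest.approx(decade_expected[i], abs=0.02)


def test_generate_cohort_deterministic():
    a = generate_cohort(SyntheticCohortSpec(n=60, seed=42))
    b = generate_cohort(SyntheticCohortSpec(n=60, seed=42))
    assert a.records == b.records
    assert a.truth.equals(b.truth)
    c = generate_cohort(SyntheticCohortSpec(n=60, seed=43))
    assert c.records != a.records


def test_cards_index_round_trip(small_cohort):
    """Scoring the generated cards reproduces the generated indexes exactly
    (continuous indexes to numerical precision, Err identically)."""
    for rec, row in zip(small_cohort.records,
                        small_cohort.truth.itertuples()):
        s = compute_indexes(rec)
        assert s.sa == pytest.approx(row.true_SA, abs=1e-9)
        assert s.oa == pytest.approx(row.true_OA, abs=1e-9)
        assert s.fa == pytest.approx(row.true_FA, abs=1e-9)
        assert s.err == row.true_Err


def test_indices_to_cards_inversion(rng):
    cards = indices_to_cards(50.0, 20.0, 10.0, 8, omission_rate=0.0, rng=rng)
    assert [c.execution_time for c in cards] == [50.0, 60.0, 70.0, 80.0]
    assert all(c.omissions == 0 for c in cards)
    assert sum(c.substitutions for c in cards) == 8
    # with omissions, execution time is deflated by the omission factor
    cards2 = indices_to_cards(75.0, 10.0, 5.0, 30, omission_rate=5.0,
                              rng=rng)
    s = compute_indexes(ParticipantRecord("X", 40, 13, "F", cards2))
    assert s.sa == pytest.approx(75.0, abs=1e-9)
    assert s.err == 30
    om1 = cards2[0].omissions
    assert cards2[0].execution_time == pytest.approx(75.0 * (25 - om1) / 25)


def test_interaction_breaks_card4_only(rng):
    cards = indices_to_cards(50.0, 20.0, 10.0, 0, interaction=6.0,
                             omission_rate=0.0, rng=rng)
    s = compute_indexes(ParticipantRecord("X", 40, 13, "F", cards))
    p = s.card_performance_times
    assert p[4] == pytest.approx(86.0)
    assert (p[4] - p[3]) - (p[2] - p[1]) == pytest.approx(6.0)


def test_age_effect_direction():
    """Raw selective-attention times increase with age by construction."""
    res = generate_cohort(SyntheticCohortSpec(n=550, seed=2))
    ages = np.array([r.age for r in res.records])
    sa = np.array([compute_indexes(r).sa for r in res.records])
    assert sa[ages >= 60].mean() > sa[ages <= 29].mean()


def test_published_correction_cancels_age_gradient():
    """Adding the published correction removes the demographic gradient the
    generator put in (construction inverts the same model)."""
    res = generate_cohort(SyntheticCohortSpec(n=2000, seed=9))
    pub = published_norms()
    rows = [(r.age, compute_indexes(r).sa
             + pub.models["SA"].correction(r.age, r.education, r.gender_code))
            for r in res.records]
    ages, adj = map(np.array, zip(*rows))
    slope = np.polyfit(ages, adj, 1)[0]
    assert abs(slope) < 0.09  # ~3 sigma of the fit at this n and noise


def test_outlier_injection_and_filter():
    res = generate_cohort(SyntheticCohortSpec(n=120, seed=21, n_outliers=5))
    flagged = set(res.truth.loc[res.truth.is_outlier, "participant_id"])
    assert len(flagged) == 5
    filt = filter_outliers(list(res.records))
    assert set(filt.removed_ids) == flagged


def test_spec_validation():
    with pytest.raises(ValidationError):
        SyntheticCohortSpec(n=0)
    with pytest.raises(ValidationError):
        SyntheticCohortSpec(n=10, n_outliers=10)
    with pytest.raises(ValidationError):
        SyntheticCohortSpec(noise="weibull")


def test_normal_noise_option_gives_parametric_branch():
    from brevis import tolerance_limits

    res = generate_cohort(SyntheticCohortSpec(n=800, seed=3, noise="normal"))
    pub = published_norms()
    adj = np.array([
        compute_indexes(r).sa
        + pub.models["SA"].correction(r.age, r.education, r.gender_code)
        for r in res.records
    ])
    limits = tolerance_limits(adj)
    assert limits.method == "parametric"
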