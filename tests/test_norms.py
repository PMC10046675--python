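"""Published correction models, classification tables, norm files."""
import math

import numpy as np
import pytest

from brevis import (
    IndexSet, NormDomainError, ValidationError, adjust_indexes,
    correction_score, load_norms, round_half_away, save_norms,
)
from brevis.norms import (
    BORDERLINE, INDEXES, PATHOLOGICAL, WITHIN, gender_code, is_extrapolated,
)


def indexset(sa=60.0, oa=40.0, fa=10.0, err=10):
    return IndexSet(sa=sa, oa=oa, fa=fa, err=err,
                    card_performance_times={1: sa, 2: sa + fa, 3: sa + oa,
                                            4: sa + oa + fa})


@pytest.mark.parametrize("x, expected", [
    (2.254, 2.3), (-0.4525, -0.5), (0.25, 0.3), (-0.25, -0.3),
    (1.04, 1.0), (-13.09, -13.1), (0.0, 0.0),
])
def test_round_half_away(x, expected):
    assert round_half_away(x, 1) == expected


@pytest.mark.parametrize("index, age, edu, g, expected", [
    ("SA", 22, 8, 0, 1.8),
    ("SA", 77, 21, 0, -14.1),
    ("SA", 47, 13, 0, 1.3),
    ("OA", 77, 13, 0, -13.1),
    ("OA", 47, 13, 0, 1.0),
    ("FA", 22, 13, 0, 2.3),
    ("Err", 22, 8, 1, 3.7),
    ("Err", 77, 21, 0, -2.3),
    ("Err", 42, 13, 0, -1.3),
])
def test_published_correction_cells(published, index, age, edu, g, expected):
    v = correction_score(published.models[index], age, edu, g)
    assert round_half_away(v, 1) == expected


def test_sa_correction_zero_at_centering_point(published):
    age = 86.9 - math.exp(3.628)
    edu = 1.0 / 0.081
    v = published.models["SA"].correction(age, edu, 0)
    assert v == pytest.approx(0.0, abs=1e-9)


def test_sa_correction_domain_errors(published):
    model = published.models["SA"]
    with pytest.raises(NormDomainError, match="86.9"):
        model.correction(87.0, 13, 0)
    with pytest.raises(NormDomainError):
        model.correction(40, 0, 0)


def test_correction_monotonicity(published):
    """Directions of the demographic gradients over the normative ranges."""
    ages = np.arange(20, 80)
    sa = [published.models["SA"].correction(a, 13, 0) for a in ages]
    oa = [published.models["OA"].correction(a, 13, 0) for a in ages]
    fa = [published.models["FA"].correction(a, 13, 0) for a in ages]
    er = [published.models["Err"].correction(a, 13, 0) for a in ages]
    for seq in (sa, oa, fa, er):
        assert all(b < a for a, b in zip(seq, seq[1:]))  # decreasing in age
    edus = np.arange(1, 22)
    sa_e = [published.models["SA"].correction(47, e, 0) for e in edus]
    er_e = [published.models["Err"].correction(47, e, 0) for e in edus]
    for seq in (sa_e, er_e):
        assert all(b > a for a, b in zip(seq, seq[1:]))  # increasing in edu
    assert (published.models["Err"].correction(47, 13, 1)
            > published.models["Err"].correction(47, 13, 0))


def test_adjust_indexes_values_and_warnings(published):
    adj = adjust_indexes(indexset(sa=60.0), 22, 8, "F", published)
    assert adj["SA"].adjusted == pytest.approx(60.0
                                               + adj["SA"].correction)
    assert round_half_away(adj["SA"].adjusted, 1) == 61.8
    assert adj.warnings == ()
    # Err raw 10, female, 47/13 -> correction -1.805 -> adjusted 8.2
    adj2 = adjust_indexes(indexset(err=10), 47, 13, "F", published)
    assert round_half_away(adj2["Err"].adjusted, 1) == 8.2
    # out-of-norm age flagged, not refused
    adj3 = adjust_indexes(indexset(), 85, 13, "F", published)
    assert any("extrapolation" in w for w in adj3.warnings)


def test_is_extrapolated_ranges():
    assert not is_extrapolated(20, 1) and not is_extrapolated(79, 21)
    assert is_extrapolated(19, 13) and is_extrapolated(40, 22)


@pytest.mark.parametrize("value, expected", [
    (90.0, WITHIN), (97.4, PATHOLOGICAL), (93.0, BORDERLINE),
    (90.1, BORDERLINE), (97.3, BORDERLINE), (50.0, WITHIN),
])
def test_classify_tolerance_sa(published, value, expected):
    assert published.tables.classify_tolerance("SA", value) == expected


@pytest.mark.parametrize("index, value, expected", [
    ("SA", 98.0, 0), ("SA", 61.4, 4), ("SA", 61.5, 3), ("SA", 67.0, 3),
    ("SA", 67.1, 2), ("FA", 20.0, 2), ("OA", 98.8, 0), ("Err", 35.2, 0),
    ("Err", 10.0, 4),
])
def test_equivalent_score_bins(published, index, value, expected):
    assert published.tables.equivalent_score(index, value) == expected


def test_unknown_index_rejected(published):
    with pytest.raises(ValidationError):
        published.tables.equivalent_score("XX", 10.0)


def test_es_zero_iff_pathological(published):
    """ES 0 and the pathological tolerance class are the same region."""
    for index in INDEXES:
        for v in np.arange(-35.0, 130.0, 0.05):
            es = published.tables.equivalent_score(index, v)
            cls = published.tables.classify_tolerance(index, v)
            assert (es == 0) == (cls == PATHOLOGICAL), (index, v)


@pytest.mark.parametrize("index, value, label", [
    ("SA", 61.5, "50"), ("SA", 30.0, ">99"), ("Err", 45.0, "1"),
    ("Err", 50.0, "<1"), ("SA", 38.4, "99"), ("FA", -1.0, "75"),
])
def test_percentile_band_lookup(published, index, value, label):
    assert published.tables.percentile_band(index, value).label == label


def test_percentile_band_brackets(published):
    band = published.tables.percentile_band("SA", 61.5)
    assert (band.lower, band.upper) == (50, 55)


def test_classifications_are_step_functions(published):
    """Moving a score by less than the table resolution inside a band never
    changes any classification."""
    for index in INDEXES:
        for v in np.arange(0.0, 120.0, 1.0):
            center = v + 0.13  # strictly interior at 1 d.p. resolution
            for eps in (-0.01, 0.0, 0.01):
                assert (published.tables.equivalent_score(index, center + eps)
                        == published.tables.equivalent_score(index, center))
                assert (published.tables.classify_tolerance(index,
                                                            center + eps)
                        == published.tables.classify_tolerance(index, center))


def test_gender_coding():
    assert gender_code("F") == gender_code("female") == 0
    assert gender_code("M") == gender_code(1) == 1
    with pytest.raises(ValidationError):
        gender_code("X")


def test_norm_file_round_trip(published, tmp_path):
    path = tmp_path / "norms.json"
    save_norms(published, path)
    loaded = load_norms(path)
    assert loaded.version == published.version
    for index in INDEXES:
        assert loaded.models[index] == published.models[index]
        assert (loaded.tables.per_index[index]
                == published.tables.per_index[index])
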