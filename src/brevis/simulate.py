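"""Synthetic normative cohorts for testing the scoring and norming pipeline.

The generator emulates the published normative sample: demographics are
drawn from the study's gender x age-decade x education-band cell counts
(550 adults, ages 20-79), and each index is generated by *inverting* the
published correction equations::

    raw index = baseline - correction(age, education, gender) + noise

so that applying the published correction to a generated cohort re-centres
every demographic cell on the baseline. Residual noise is right-skewed
(shifted gamma) by default, matching the study's observation that adjusted
scores are not normally distributed; a normal option exercises the
parametric tolerance-limit branch. Total errors are generated as an
overdispersed count (gamma-Poisson) with demographic-dependent mean.

Index sets are folded back into four plausible card observations by
inverting the index formulas (P1 = SA, P2 = SA + FA, P3 = SA + OA,
P4 = SA + OA + FA + I), drawing omissions, and setting
``execution_time = P * (25 - omissions) / 25``; scoring the produced cards
reproduces the generated indexes exactly when the layout x crowding
interaction I is zero.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SimulationError, ValidationError
from .norms import CorrectionModel, published_correction_models
from .scoring import CardObservation, ParticipantRecord

#: normative-sample cell counts: education band x age decade x gender (F, M)
DECADES = ((20, 29), (30, 39), (40, 49), (50, 59), (60, 69), (70, 79))
EDUCATION_BANDS = ("0-5", "6-8", "9-13", ">13")
DEMOGRAPHIC_COUNTS: dict[str, tuple[tuple[int, int], ...]] = {
    "0-5": ((0, 0), (0, 0), (0, 1), (0, 0), (0, 3), (6, 2)),
    "6-8": ((0, 0), (2, 5), (3, 5), (3, 9), (9, 6), (10, 10)),
    "9-13": ((11, 12), (16, 20), (25, 21), (34, 22), (19, 20), (4, 10)),
    ">13": ((55, 30), (34, 32), (33, 19), (22, 15), (5, 9), (3, 5)),
}

#: published per-decade mean performance of each index, used to set the
#: generator's baseline (decade-size weighted grand mean)
DECADE_MEANS = {
    "SA": (54.5, 57.7, 59.6, 66.7, 74.8, 79.9),
    "OA": (46.5, 48.6, 46.7, 44.6, 54.5, 61.2),
    "FA": (9.0, 10.1, 7.2, 12.7, 13.1, 16.4),
    "Err": (11.8, 14.9, 17.8, 17.3, 17.9, 19.1),
}

#: residual standard errors of the published correction fits - the cleanest
#: printed residual-scale quantity, used as the default noise scale
PUBLISHED_RSE = {"SA": 16.01, "OA": 23.38, "FA": 18.11, "Err": 8.83}

#: education-band -> years-of-schooling rule
_BAND_YEARS = {"0-5": (5, 5), "6-8": (8, 8), "9-13": (9, 13), ">13": (14, 21)}


def _decade_totals() -> np.ndarray:
    counts = np.array([DEMOGRAPHIC_COUNTS[b] for b in EDUCATION_BANDS])
    return counts.sum(axis=(0, 2))


def default_baselines() -> dict[str, float]:
    """Grand means of the normative sample, weighting decades by size."""
    weights = _decade_totals()
    return {
        name: float(np.average(DECADE_MEANS[name], weights=weights))
        for name in DECADE_MEANS
    }


@dataclass
class SyntheticCohortSpec:
    """Conditions of a simulated normative study."""

    n: int = 550
    seed: int = 0
    noise: str = "gamma"                      # "gamma" or "normal"
    noise_scale: dict[str, float] = field(
        default_factory=lambda: dict(PUBLISHED_RSE))
    baselines: dict[str, float] = field(default_factory=default_baselines)
    index_models: dict[str, CorrectionModel] = field(
        default_factory=published_correction_models)
    omission_rate: float = 1.0                # mean omissions per card
    interaction: float = 0.0                  # layout x crowding term I
    n_outliers: int = 0                       # injected extreme outliers

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("n must be >= 1")
        if not 0 <= self.n_outliers < self.n:
            raise ValidationError("n_outliers must be within [0, n)")
        if self.noise not in ("gamma", "normal"):
            raise ValidationError("noise must be 'gamma' or 'normal'")
        if any(s <= 0 for s in self.noise_scale.values()):
            raise ValidationError("noise scales must be positive")


def sample_demographics(n: int, rng: np.random.Generator,
                        counts: dict | None = None) -> pd.DataFrame:
    """Draw (age, education, gender) from the normative cell structure.

    Cell membership is proportional to the normative counts; age is uniform
    within the decade; education years are mapped from the band (0-5 -> 5,
    6-8 -> 8, 9-13 -> uniform 9..13, >13 -> uniform 14..21).
    """
    counts = counts or DEMOGRAPHIC_COUNTS
    cells = []
    weights = []
    for band in EDUCATION_BANDS:
        for d, decade in enumerate(DECADES):
            for g, cnt in enumerate(counts[band][d]):
                if cnt > 0:
                    cells.append((band, decade, g))
                    weights.append(cnt)
    probs = np.asarray(weights, dtype=float)
    probs /= probs.sum()
    draws = rng.choice(len(cells), size=n, p=probs)
    ages = np.empty(n, dtype=int)
    edus = np.empty(n, dtype=int)
    genders = np.empty(n, dtype=int)
    for i, c in enumerate(draws):
        band, (lo, hi), g = cells[c]
        ages[i] = rng.integers(lo, hi + 1)
        ylo, yhi = _BAND_YEARS[band]
        edus[i] = ylo if ylo == yhi else rng.integers(ylo, yhi + 1)
        genders[i] = g
    return pd.DataFrame({"age": ages, "education": edus, "gender": genders})


def _noise(rng: np.random.Generator, sd: float, size: int,
           kind: str) -> np.ndarray:
    if kind == "normal":
        return rng.normal(0.0, sd, size)
    # shifted gamma with shape 4: zero mean, standard deviation sd,
    # skewness 1 (right tail, like real time scores)
    shape = 4.0
    scale = sd / np.sqrt(shape)
    return rng.gamma(shape, scale, size) - shape * scale


def generate_indices(demographics: pd.DataFrame, spec: SyntheticCohortSpec,
                     rng: np.random.Generator) -> pd.DataFrame:
    """Generate true index values for each demographic row.

    Rows whose implied card performance times would be non-positive (deep
    negative OA/FA draws against a small SA) have their noise redrawn.
    """
    n = len(demographics)
    corr = {
        name: np.array([
            model.correction(a, e, g) for a, e, g in zip(
                demographics["age"], demographics["education"],
                demographics["gender"])
        ])
        for name, model in spec.index_models.items()
    }
    out = {}
    for name in ("SA", "OA", "FA"):
        out[name] = (spec.baselines[name] - corr[name]
                     + _noise(rng, spec.noise_scale[name], n, spec.noise))
    # redraw noise where any implied performance time would be <= 1 s
    for _ in range(200):
        p2 = out["SA"] + out["FA"]
        p3 = out["SA"] + out["OA"]
        p4 = out["SA"] + out["OA"] + out["FA"] + spec.interaction
        bad = (out["SA"] <= 1.0) | (p2 <= 1.0) | (p3 <= 1.0) | (p4 <= 1.0)
        if not bad.any():
            break
        m = int(bad.sum())
        for name in ("SA", "OA", "FA"):
            out[name][bad] = (spec.baselines[name] - corr[name][bad]
                              + _noise(rng, spec.noise_scale[name], m,
                                       spec.noise))
    else:
        raise SimulationError(
            "could not generate positive card times; noise scale too large "
            "relative to the baselines"
        )
    # overdispersed error counts: gamma-Poisson with mean from the inverted
    # model and variance matching the published residual scale
    mu = np.clip(spec.baselines["Err"] - corr["Err"], 0.1, None)
    var = spec.noise_scale["Err"] ** 2
    errs = np.empty(n, dtype=int)
    for i, m_i in enumerate(mu):
        if var > m_i:
            shape = m_i ** 2 / (var - m_i)
            lam = rng.gamma(shape, (var - m_i) / m_i)
        else:
            lam = m_i
        errs[i] = rng.poisson(lam)
    frame = pd.DataFrame(out)
    frame["Err"] = errs
    for name in ("SA", "OA", "FA", "Err"):
        frame[f"correction_{name}"] = corr[name]
    return frame


def _cards_from_times(times, err: int, omission_rate: float,
                      rng: np.random.Generator,
                      max_retries: int = 10) -> tuple[CardObservation, ...]:
    """Fold four performance times and an error total into card records."""
    times = [float(t) for t in times]
    if any(t <= 0 for t in times):
        raise SimulationError(f"non-positive performance time in {times}")
    if err < 0:
        raise SimulationError("Err must be non-negative")
    for _ in range(max_retries):
        oms = np.minimum(rng.poisson(omission_rate, 4), 24)
        if oms.sum() <= err:
            break
    else:
        # truncate the draw to fit the error total instead of failing:
        # drop excess omissions card by card
        excess = int(oms.sum()) - err
        for j in range(4):
            take = min(excess, int(oms[j]))
            oms[j] -= take
            excess -= take
    remaining = err - int(oms.sum())
    subs = rng.multinomial(remaining, [0.25] * 4)
    autoc = rng.poisson(0.3, 4)
    return tuple(
        CardObservation(
            card_id=i + 1,
            execution_time=times[i] * (25 - int(oms[i])) / 25.0,
            omissions=int(oms[i]),
            substitutions=int(subs[i]),
            autocorrections=int(autoc[i]),
        )
        for i in range(4)
    )


def indices_to_cards(sa: float, oa: float, fa: float, err: int, *,
                     interaction: float = 0.0, omission_rate: float = 1.0,
                     rng: np.random.Generator | None = None
                     ) -> tuple[CardObservation, ...]:
    """Invert the index formulas into four card observations.

    With ``interaction`` = 0, scoring the returned cards reproduces
    (sa, oa, fa, err) exactly.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    times = (sa, sa + fa, sa + oa, sa + oa + fa + interaction)
    return _cards_from_times(times, int(err), omission_rate, rng)


@dataclass(frozen=True)
class CohortResult:
    records: tuple[ParticipantRecord, ...]
    #: ground-truth sidecar: demographics, true indexes, corrections applied
    #: by the generator, and the injected-outlier flag
    truth: pd.DataFrame


def generate_cohort(spec: SyntheticCohortSpec) -> CohortResult:
    """Generate a full synthetic cohort (deterministic given the seed).

    When ``spec.n_outliers`` > 0 the last ``n_outliers`` participants are
    turned into extreme slow outliers on card 1 (performance time at
    Q3 + 12*IQR of the clean participants) while the clean participants'
    card times are winsorised at Q3 + 2*IQR, so a 3*IQR casewise filter on
    the combined cohort removes exactly the injected records.
    """
    rng = np.random.default_rng(spec.seed)
    demo = sample_demographics(spec.n, rng)
    idx = generate_indices(demo, spec, rng)
    p = np.column_stack([
        idx["SA"],
        idx["SA"] + idx["FA"],
        idx["SA"] + idx["OA"],
        idx["SA"] + idx["OA"] + idx["FA"] + spec.interaction,
    ])
    errs = idx["Err"].to_numpy(dtype=int)
    is_outlier = np.zeros(spec.n, dtype=bool)
    if spec.n_outliers:
        k = spec.n_outliers
        is_outlier[-k:] = True
        clean = p[:-k]
        q1 = np.percentile(clean, 25, axis=0)
        q3 = np.percentile(clean, 75, axis=0)
        iqr = q3 - q1
        p[:-k] = np.minimum(clean, q3 + 2.0 * iqr)
        med = np.median(clean, axis=0)
        p[-k:] = med
        p[-k:, 0] = q3[0] + 12.0 * iqr[0]
        errs[-k:] = int(np.median(errs[:-k]))
        # keep the sidecar's index truth consistent with the final times
        idx.loc[:, "SA"] = p[:, 0]
        idx.loc[:, "OA"] = ((p[:, 2] + p[:, 3]) - (p[:, 0] + p[:, 1])) / 2.0
        idx.loc[:, "FA"] = ((p[:, 1] + p[:, 3]) - (p[:, 0] + p[:, 2])) / 2.0
        idx.loc[:, "Err"] = errs
    records = []
    for i in range(spec.n):
        cards = _cards_from_times(p[i], int(errs[i]), spec.omission_rate, rng)
        records.append(ParticipantRecord(
            participant_id=f"S{i + 1:04d}",
            age=int(demo["age"][i]),
            education=int(demo["education"][i]),
            gender="F" if demo["gender"][i] == 0 else "M",
            cards=cards,
        ))
    truth = pd.DataFrame({
        "participant_id": [r.participant_id for r in records],
        "age": demo["age"], "education": demo["education"],
        "gender": ["F" if g == 0 else "M" for g in demo["gender"]],
        "true_SA": idx["SA"], "true_OA": idx["OA"], "true_FA": idx["FA"],
        "true_Err": errs,
        "correction_SA": idx["correction_SA"],
        "correction_OA": idx["correction_OA"],
        "correction_FA": idx["correction_FA"],
        "correction_Err": idx["correction_Err"],
        "is_outlier": is_outlier,
    })
    return CohortResult(tuple(records), truth)
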