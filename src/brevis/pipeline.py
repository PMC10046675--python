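"""Regression-based norming pipeline.

Turns a normative cohort (real or synthetic) into a :class:`~brevis.norms.NormSet`
by the same sequence of steps that produced the published norms:

1. casewise removal of extreme outliers (any card performance time at or
   above Q3 + 3*IQR of that card over the cohort);
2. per predictor, choice of the transformation (identity / square / cube /
   inverse / log / reflected log) whose bivariate regression on the raw
   index has the lowest small-sample-corrected AIC (AICc);
3. choice among the seven non-empty subsets of {age, education, gender} by
   AICc, with a parsimony rule (a model nested in the AICc-best model within
   2 AICc units wins) and an overall F-test gate at alpha = 0.05;
4. refit on mean-centred transformed predictors and mean-centred index;
   the sign-reversed slopes and the predictor means form the correction
   equation;
5. one-sided 95%-content / 95%-confidence tolerance limits on the adjusted
   scores - nonparametric order statistics when normality is rejected
   (Shapiro-Wilk, alpha = 0.05), otherwise a normal-theory one-sided
   tolerance factor;
6. equivalent-score boundaries (outer tolerance limit, order statistics at
   cumulative 0.80 and 0.65, and the median) and a percentile grid.

Quantiles for the outlier filter and the percentile grid use linear
interpolation between order statistics; the choice is recorded in the
output metadata.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import PipelineError, ValidationError
from .norms import (
    INDEXES, CorrectionModel, CorrectionTerm, IndexNorms, NormSet,
    NormativeTables, ToleranceBand, round_half_away,
)
from .scoring import CARD_IDS, ParticipantRecord, compute_indexes
from .transforms import TransformSpec

#: candidate transformation families per predictor (gender enters as 0/1)
AGE_FAMILIES = ("identity", "square", "cube", "inverse", "log",
                "reflected_log")
EDUCATION_FAMILIES = ("identity", "inverse", "log")

#: printed percentile ranks of the normative tables
PERCENTILE_RANKS = (99, 95, 90, 85, 80, 75, 70, 65, 60, 55, 50,
                    45, 40, 35, 30, 25, 20, 15, 10, 5, 4, 3, 2, 1)

#: default grid levels of the printed correction grids
GRID_AGES = tuple(range(22, 78, 5))
GRID_EDUCATIONS = (8, 13, 16, 18, 21)

MODEL_SUBSETS = tuple(
    subset
    for size in (1, 2, 3)
    for subset in itertools.combinations(("age", "education", "gender"), size)
)


# ---------------------------------------------------------------------------
# outlier filtering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OutlierFilterResult:
    retained: tuple[ParticipantRecord, ...]
    removed_ids: tuple[str, ...]
    thresholds: dict[int, float]   # per card; NaN when the IQR is degenerate
    warnings: tuple[str, ...] = ()


def filter_outliers(cohort: list[ParticipantRecord], *,
                    iqr_multiplier: float = 3.0) -> OutlierFilterResult:
    """Casewise removal of extreme slow outliers.

    Thresholds are computed once on the full input cohort (single pass):
    per card, Q3 + ``iqr_multiplier``*IQR of the performance times, with
    linearly interpolated quartiles. A participant is dropped entirely if
    any card's performance time is at or above its card threshold. A card
    with zero IQR cannot discriminate outliers and is skipped with a
    warning.
    """
    if not cohort:
        raise ValidationError("cohort is empty")
    times = np.array(
        [[compute_indexes(r).card_performance_times[c] for c in CARD_IDS]
         for r in cohort]
    )
    thresholds: dict[int, float] = {}
    warnings: list[str] = []
    active: list[int] = []
    for j, card in enumerate(CARD_IDS):
        q1, q3 = np.percentile(times[:, j], [25, 75])
        iqr = q3 - q1
        if iqr == 0:
            warnings.append(
                f"card {card}: degenerate distribution (IQR = 0); "
                "no outlier screening on this card"
            )
            thresholds[card] = float("nan")
            continue
        thresholds[card] = float(q3 + iqr_multiplier * iqr)
        active.append(j)
    if active:
        exceed = np.zeros(len(cohort), dtype=bool)
        for j in active:
            exceed |= times[:, j] >= thresholds[CARD_IDS[j]]
    else:
        exceed = np.zeros(len(cohort), dtype=bool)
    retained = tuple(r for r, bad in zip(cohort, exceed) if not bad)
    removed = tuple(r.participant_id for r, bad in zip(cohort, exceed) if bad)
    return OutlierFilterResult(retained, removed, thresholds, tuple(warnings))


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------

def aicc(log_likelihood: float, k: int, n: int) -> float:
    """Small-sample-corrected Akaike information criterion.

    ``k`` counts every estimated parameter - intercept, slopes and the
    residual variance - so a one-predictor linear model has k = 3.
    """
    if n <= k + 1:
        raise PipelineError(
            f"AICc undefined: need n > k + 1 (n = {n}, k = {k})"
        )
    return -2.0 * log_likelihood + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _gaussian_ll(rss: float, n: int) -> float:
    # profile log-likelihood of an OLS fit with sigma^2 = RSS/n
    rss = max(rss, 1e-300)
    return -0.5 * n * (math.log(2.0 * math.pi * rss / n) + 1.0)


def _ols_aicc(y: np.ndarray, x_cols: list[np.ndarray]) -> tuple[float, float]:
    """(AICc, log-likelihood) of an OLS fit with intercept."""
    n = len(y)
    design = np.column_stack([np.ones(n), *x_cols])
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        raise np.linalg.LinAlgError("singular design")
    resid = y - design @ beta
    ll = _gaussian_ll(float(resid @ resid), n)
    k = design.shape[1] + 1
    return aicc(ll, k, n), ll


@dataclass(frozen=True)
class TransformSelection:
    spec: TransformSpec
    candidates: pd.DataFrame    # family, offset, AICc, log-likelihood
    warnings: tuple[str, ...] = ()


def select_transform(x, y, predictor: str = "age") -> TransformSelection:
    """Pick the predictor transformation whose bivariate fit minimises AICc.

    For the reflected log the offset is profiled over a grid from
    ``max(x) + 0.1`` to ``max(x) + 25`` in steps of 0.1, and the best-offset
    fit represents the family.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 10:
        raise ValidationError("need matched x/y with at least 10 records")
    families = AGE_FAMILIES if predictor == "age" else EDUCATION_FAMILIES
    warnings: list[str] = []
    if np.ptp(x) == 0:
        warnings.append(
            f"{predictor} is constant across the cohort; all candidate "
            "transforms are equivalent - identity returned"
        )
        table = pd.DataFrame(
            {"family": ["identity"], "offset": [np.nan],
             "aicc": [np.nan], "ll": [np.nan]}
        )
        return TransformSelection(TransformSpec("identity"), table,
                                  tuple(warnings))
    rows = []
    for family in families:
        offset = np.nan
        try:
            if family == "reflected_log":
                offsets = np.arange(x.max() + 0.1, x.max() + 25.0 + 1e-9, 0.1)
                best = None
                for c in offsets:
                    crit, ll = _ols_aicc(y, [np.log(c - x)])
                    if best is None or crit < best[0]:
                        best = (crit, ll, c)
                crit, ll, offset = best
            else:
                tx = TransformSpec(family)(x)
                crit, ll = _ols_aicc(y, [tx])
        except (np.linalg.LinAlgError, ValueError, ValidationError,
                ArithmeticError) as exc:
            warnings.append(f"transform {family} excluded: {exc}")
            continue
        rows.append({"family": family, "offset": offset,
                     "aicc": crit, "ll": ll})
    if not rows:
        raise PipelineError(
            f"no candidate transform could be fitted for {predictor}"
        )
    table = pd.DataFrame(rows).sort_values("aicc").reset_index(drop=True)
    best_row = table.iloc[0]
    if best_row["family"] == "reflected_log":
        spec = TransformSpec("reflected_log",
                             offset=round(float(best_row["offset"]), 1))
    else:
        spec = TransformSpec(best_row["family"])
    return TransformSelection(spec, table, tuple(warnings))


@dataclass(frozen=True)
class ModelSelectionResult:
    """AICc comparison of the seven demographic models for one index."""

    table: pd.DataFrame          # Models, K, AICc, Delta_AICc, ModelLik,
                                 # AICcWt, LL, Cum.Wt (sorted by AICc)
    chosen: tuple[str, ...]      # () means "no correction"
    best: tuple[str, ...]        # AICc-best model before the parsimony rule
    p_value: float               # overall F-test of the chosen model
    significant: bool
    warnings: tuple[str, ...] = ()


def _apply_parsimony(rows: list[dict], delta_threshold: float = 2.0
                     ) -> tuple[str, ...]:
    """Prefer a model nested in the AICc-best one when its delta is small.

    ``rows`` must carry ``predictors`` (tuple) and ``aicc``; the best model
    itself always qualifies. Among qualifying models the one with the fewest
    predictors wins (AICc breaks ties).
    """
    rows = sorted(rows, key=lambda r: r["aicc"])
    best = rows[0]
    candidates = [best]
    for r in rows[1:]:
        nested = set(r["predictors"]) < set(best["predictors"])
        if nested and r["aicc"] - best["aicc"] < delta_threshold:
            candidates.append(r)
    chosen = min(candidates, key=lambda r: (len(r["predictors"]), r["aicc"]))
    return tuple(chosen["predictors"])


def select_model(demographics: pd.DataFrame, y, index_name: str,
                 transforms: dict[str, TransformSpec], *,
                 alpha: float = 0.05) -> ModelSelectionResult:
    """Rank the seven demographic models by AICc and choose one.

    ``demographics`` needs columns ``age``, ``education`` and ``gender``
    (0/1). Age and education enter through their chosen transforms; gender
    enters untransformed. If the chosen model's overall F-test is not
    significant at ``alpha``, the empty "no correction" model is returned.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    cols = {
        "age": transforms["age"](demographics["age"].to_numpy(dtype=float)),
        "education": transforms["education"](
            demographics["education"].to_numpy(dtype=float)),
        "gender": demographics["gender"].to_numpy(dtype=float),
    }
    warnings: list[str] = []
    rows = []
    for subset in MODEL_SUBSETS:
        design = sm.add_constant(np.column_stack([cols[p] for p in subset]))
        if np.linalg.matrix_rank(design) < design.shape[1]:
            warnings.append(f"model {'+'.join(subset)}: collinear design")
        fit = sm.OLS(y, design).fit()
        k = design.shape[1] + 1
        rows.append({
            "predictors": subset, "k": k, "ll": float(fit.llf),
            "aicc": aicc(float(fit.llf), k, n),
            "f_pvalue": float(fit.f_pvalue),
        })
    chosen = _apply_parsimony(rows)
    rows = sorted(rows, key=lambda r: r["aicc"])
    best = rows[0]["predictors"]
    deltas = [r["aicc"] - rows[0]["aicc"] for r in rows]
    liks = [math.exp(-0.5 * d) for d in deltas]
    total = sum(liks)
    weights = [lik / total for lik in liks]
    table = pd.DataFrame({
        "Models": [" + ".join(r["predictors"]).replace("gender", "sex")
                   for r in rows],
        "K": [r["k"] for r in rows],
        "AICc": [r["aicc"] for r in rows],
        "Delta_AICc": deltas,
        "ModelLik": liks,
        "AICcWt": weights,
        "LL": [r["ll"] for r in rows],
        "Cum.Wt": np.cumsum(weights),
    })
    chosen_row = next(r for r in rows if r["predictors"] == chosen)
    significant = chosen_row["f_pvalue"] < alpha
    if not significant:
        warnings.append(
            f"{index_name}: best model not significant "
            f"(p = {chosen_row['f_pvalue']:.3g}); no correction applied"
        )
        chosen = ()
    return ModelSelectionResult(
        table=table, chosen=chosen, best=best,
        p_value=chosen_row["f_pvalue"], significant=significant,
        warnings=tuple(warnings),
    )


def fit_correction_regression(demographics: pd.DataFrame, y, index_name: str,
                              predictors: tuple[str, ...],
                              transforms: dict[str, TransformSpec]
                              ) -> CorrectionModel:
    """Fit the mean-centred regression and reverse its coefficients.

    Each transformed predictor is centred at its cohort mean (these means
    become the centering constants of the correction equation) and the index
    at its mean; the correction coefficients are the sign-reversed OLS
    slopes, so that adding the correction to a raw score removes the fitted
    demographic effect.
    """
    if not predictors:
        raise PipelineError("cannot fit a correction with no predictors")
    y = np.asarray(y, dtype=float)
    n = len(y)
    cols, centers = [], []
    for p in predictors:
        t = transforms[p] if p != "gender" else TransformSpec("identity")
        z = t(demographics[p if p != "gender" else "gender"]
              .to_numpy(dtype=float))
        centers.append(float(np.mean(z)))
        cols.append(z - np.mean(z))
    yc = y - y.mean()
    design = np.column_stack(cols)
    fit = sm.OLS(yc, design).fit()
    slopes = np.asarray(fit.params, dtype=float)
    conf = np.asarray(fit.conf_int(alpha=0.05), dtype=float)
    rss = float(fit.ssr)
    tss = float(yc @ yc)
    p = len(predictors)
    r2 = 1.0 - rss / tss
    metadata = {
        "r2": r2,
        "adj_r2": 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1),
        "rse": math.sqrt(rss / (n - p - 1)),
        "n": n,
        "index_mean": float(y.mean()),
        # 95% CI of each reversed coefficient, keyed by predictor
        "conf_int": {
            pred: [float(-conf[i, 1]), float(-conf[i, 0])]
            for i, pred in enumerate(predictors)
        },
    }
    terms = tuple(
        CorrectionTerm(
            predictor=pred,
            transform=(transforms[pred] if pred != "gender"
                       else TransformSpec("identity")),
            coefficient=float(-slopes[i]),
            center=centers[i],
        )
        for i, pred in enumerate(predictors)
    )
    return CorrectionModel(index_name, terms, metadata)


# ---------------------------------------------------------------------------
# tolerance limits, equivalent scores, percentiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToleranceRanks:
    """1-based order-statistic ranks of the inner and outer limits.

    With scores sorted ascending (lower = better), the outer rank is the
    smallest m with BinomialCDF(m - 1; n, content) >= confidence, and the
    inner rank the smallest m with BinomialCDF(m - 1; n, content) >=
    1 - confidence. ``outer`` is None when no rank up to n satisfies the
    inequality (the limit is not computable at this sample size).
    """

    inner: int | None
    outer: int | None
    n: int
    content: float = 0.95
    confidence: float = 0.95

    @property
    def computable(self) -> bool:
        return self.inner is not None and self.outer is not None


def tolerance_ranks(n: int, content: float = 0.95,
                    confidence: float = 0.95) -> ToleranceRanks:
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    cdf = stats.binom.cdf(np.arange(n), n, content)  # cdf[m-1] at index m-1
    def smallest(level: float) -> int | None:
        idx = np.nonzero(cdf >= level)[0]
        return int(idx[0]) + 1 if idx.size else None
    return ToleranceRanks(inner=smallest(1.0 - confidence),
                          outer=smallest(confidence),
                          n=n, content=content, confidence=confidence)


@dataclass(frozen=True)
class ToleranceLimits:
    itl: float | None
    otl: float | None
    method: str               # "nonparametric" or "parametric"
    normality_p: float
    ranks: ToleranceRanks | None = None
    warnings: tuple[str, ...] = ()

    @property
    def borderline(self) -> tuple[float, float] | None:
        """Open interval between the limits (borderline band)."""
        if self.itl is None or self.otl is None:
            return None
        return (self.itl, self.otl)


def tolerance_limits(scores, content: float = 0.95,
                     confidence: float = 0.95, *,
                     method: str = "auto") -> ToleranceLimits:
    """One-sided upper tolerance limits of a (lower-is-better) score.

    ``method='auto'`` tests normality (Shapiro-Wilk, alpha = 0.05) and takes
    the nonparametric order-statistic path when it is rejected - the usual
    case for right-skewed time scores - and the normal-theory one-sided
    tolerance factor otherwise.
    """
    x = np.sort(np.asarray(scores, dtype=float))
    n = len(x)
    if n < 4:
        raise ValidationError("need at least 4 scores for tolerance limits")
    if n <= 5000:
        normality_p = float(stats.shapiro(x).pvalue)
    else:
        normality_p = float(stats.normaltest(x).pvalue)
    if method == "auto":
        method = "nonparametric" if normality_p < 0.05 else "parametric"
    if method == "nonparametric":
        ranks = tolerance_ranks(n, content, confidence)
        warnings = ()
        itl = x[ranks.inner - 1] if ranks.inner is not None else None
        otl = x[ranks.outer - 1] if ranks.outer is not None else None
        if otl is None:
            warnings = (
                f"outer tolerance limit not computable at n = {n} "
                f"(needs rank > n)",
            )
        return ToleranceLimits(itl, otl, "nonparametric", normality_p,
                               ranks, warnings)
    mean, sd = float(x.mean()), float(x.std(ddof=1))
    nc = stats.norm.ppf(content) * math.sqrt(n)
    k_outer = stats.nct.ppf(confidence, n - 1, nc) / math.sqrt(n)
    k_inner = stats.nct.ppf(1.0 - confidence, n - 1, nc) / math.sqrt(n)
    return ToleranceLimits(mean + k_inner * sd, mean + k_outer * sd,
                           "parametric", normality_p, None)


def derive_equivalent_scores(scores, otl: float
                             ) -> tuple[float, float, float, float]:
    """Equivalent-score boundaries from adjusted scores and the outer limit.

    ES 0 begins at the outer tolerance limit; ES 4 at the median; the
    ES 1/2 and ES 2/3 edges are the order statistics at cumulative
    proportions 0.80 and 0.65 of the ascending scores - three equal
    15%-probability bands between the 5% worse tail and the median.
    """
    x = np.sort(np.asarray(scores, dtype=float))
    n = len(x)
    if n < 20:
        raise ValidationError("need at least 20 scores to derive ES bands")
    b1 = float(x[math.ceil(0.80 * n) - 1])
    b2 = float(x[math.ceil(0.65 * n) - 1])
    b3 = float(np.median(x))
    return (float(otl), b1, b2, b3)


def derive_percentiles(scores, ranks: tuple[int, ...] = PERCENTILE_RANKS
                       ) -> dict[int, float]:
    """Percentile grid: value at rank p is the empirical quantile at
    cumulative proportion 1 - p/100 (p = % of the sample performing worse),
    with linear interpolation between order statistics."""
    x = np.asarray(scores, dtype=float)
    return {int(p): float(np.quantile(x, 1.0 - p / 100.0)) for p in ranks}


# ---------------------------------------------------------------------------
# correction grids and the end-to-end pipeline
# ---------------------------------------------------------------------------

def build_correction_grid(model: CorrectionModel,
                          ages: tuple[int, ...] = GRID_AGES,
                          educations: tuple[int, ...] = GRID_EDUCATIONS,
                          genders: tuple[int, ...] | None = None
                          ) -> pd.DataFrame:
    """Evaluate a correction model over a clinician-facing grid.

    Returns a long-format frame (age [, education] [, gender], correction)
    with corrections rounded half away from zero to one decimal; cells whose
    demographics fall outside the model's hard domain are flagged instead of
    aborting the grid.
    """
    uses_edu = "education" in model.predictors
    uses_gender = "gender" in model.predictors
    if genders is None:
        genders = (0, 1) if uses_gender else (0,)
    edu_levels = educations if uses_edu else (GRID_EDUCATIONS[1],)
    rows = []
    for g in genders:
        for age in ages:
            for edu in edu_levels:
                row: dict = {"age": age}
                if uses_edu:
                    row["education"] = edu
                if uses_gender:
                    row["gender"] = "F" if g == 0 else "M"
                try:
                    row["correction"] = round_half_away(
                        model.correction(age, edu, g), 1)
                    row["flag"] = ""
                except Exception as exc:  # domain error for this cell only
                    row["correction"] = float("nan")
                    row["flag"] = str(exc)
                rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class NormingResult:
    norms: NormSet
    selection: dict[str, ModelSelectionResult]
    transform_choices: dict[str, dict[str, TransformSelection]]
    filter_result: OutlierFilterResult
    adjusted: pd.DataFrame
    warnings: tuple[str, ...] = ()


def build_norms(cohort: list[ParticipantRecord], *, content: float = 0.95,
                confidence: float = 0.95) -> NormingResult:
    """Run the full norming pipeline on a cohort.

    Requires at least 50 scoreable records. Indexes whose selected model is
    not significant receive the empty (zero) correction.
    """
    if len(cohort) < 50:
        raise ValidationError(
            f"norming needs at least 50 records, got {len(cohort)}"
        )
    filt = filter_outliers(cohort)
    records = list(filt.retained)
    idx = [compute_indexes(r) for r in records]
    demo = pd.DataFrame({
        "participant_id": [r.participant_id for r in records],
        "age": [r.age for r in records],
        "education": [r.education for r in records],
        "gender": [r.gender_code for r in records],
    })
    raw = pd.DataFrame({name: [s.as_dict()[name] for s in idx]
                        for name in INDEXES})
    warnings: list[str] = list(filt.warnings)
    models: dict[str, CorrectionModel] = {}
    tables: dict[str, IndexNorms] = {}
    selection: dict[str, ModelSelectionResult] = {}
    choices: dict[str, dict[str, TransformSelection]] = {}
    adjusted = demo.copy()
    for name in INDEXES:
        y = raw[name].to_numpy(dtype=float)
        age_sel = select_transform(demo["age"], y, "age")
        edu_sel = select_transform(demo["education"], y, "education")
        choices[name] = {"age": age_sel, "education": edu_sel}
        warnings += [f"{name}/age: {w}" for w in age_sel.warnings]
        warnings += [f"{name}/education: {w}" for w in edu_sel.warnings]
        transforms = {"age": age_sel.spec, "education": edu_sel.spec}
        sel = select_model(demo, y, name, transforms)
        selection[name] = sel
        warnings += list(sel.warnings)
        if sel.chosen:
            model = fit_correction_regression(demo, y, name, sel.chosen,
                                              transforms)
        else:
            model = CorrectionModel(name, (), {"note": "no correction"})
        models[name] = model
        corr = np.array([
            model.correction(a, e, g)
            for a, e, g in zip(demo["age"], demo["education"], demo["gender"])
        ])
        adj = y + corr
        adjusted[name] = adj
        limits = tolerance_limits(adj, content, confidence)
        warnings += list(limits.warnings)
        if limits.otl is None:
            raise PipelineError(
                f"{name}: outer tolerance limit not computable at "
                f"n = {len(adj)}"
            )
        es = derive_equivalent_scores(adj, limits.otl)
        tables[name] = IndexNorms(
            tolerance=ToleranceBand(float(limits.itl), float(limits.otl)),
            es_boundaries=tuple(round_half_away(b, 1) for b in es),
            percentiles={p: round_half_away(v, 1)
                         for p, v in derive_percentiles(adj).items()},
        )
    normset = NormSet(
        models=models, tables=NormativeTables(tables), version="custom",
        metadata={
            "n_input": len(cohort),
            "n_retained": len(records),
            "outlier_thresholds": {str(k): v
                                   for k, v in filt.thresholds.items()},
            "quantile_convention": "linear interpolation between order "
                                   "statistics",
            "content": content,
            "confidence": confidence,
        },
    )
    return NormingResult(normset, selection, choices, filt, adjusted,
                         tuple(warnings))


def selection_tables(result: NormingResult) -> pd.DataFrame:
    """Concatenate the per-index AICc model-comparison tables."""
    frames = []
    for name, sel in result.selection.items():
        frame = sel.table.copy()
        frame.insert(0, "Index", name)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
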