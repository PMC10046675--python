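"""Published demographic-correction norms and classification tables.

The normative study (550 healthy Italian adults aged 20-79) expressed the
demographic dependence of each index as a *correction regression*: a sum of
``coefficient * (transform(predictor) - centering_constant)`` terms whose
coefficients are the sign-reversed slopes of the fitted model, so that

    adjusted score = raw score + correction(age, education, gender)

re-centres every demographic cell on the normative sample's mean. Adjusted
scores are then classified three ways:

* against nonparametric one-sided 95%/95% tolerance limits (within limits /
  borderline / pathological),
* into five equivalent-score bands (ES 4 = at or better than the median,
  ES 0 = beyond the outer tolerance limit, i.e. pathological),
* against a printed percentile grid (step-function lookup, no
  interpolation; the rank is the percentage of the normative sample that
  performed worse).

All published constants are embedded below and can also be round-tripped
through a JSON norm file so alternative norm sets can be loaded.
"""
from __future__ import annotations

import decimal
import json
from dataclasses import dataclass, field
from pathlib import Path

from .errors import NormDomainError, ValidationError
from .scoring import IndexSet
from .transforms import TransformSpec

INDEXES = ("SA", "OA", "FA", "Err")

#: demographic ranges covered by the normative sample; outside them the
#: correction is an extrapolation and is flagged as such.
NORM_AGE_RANGE = (20, 79)
NORM_EDUCATION_RANGE = (1, 21)

WITHIN = "within_limits"
BORDERLINE = "borderline"
PATHOLOGICAL = "pathological"


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round to ``ndigits`` decimals with ties going away from zero.

    This is the convention of the printed correction grids (e.g. -0.45
    rounds to -0.5, not -0.4 as under round-half-to-even).
    """
    q = decimal.Decimal(1).scaleb(-ndigits)
    d = decimal.Decimal(repr(float(x))).quantize(
        q, rounding=decimal.ROUND_HALF_UP
    )
    return float(d)


def gender_code(gender) -> int:
    """Normalise a gender value to the 0 = female / 1 = male coding."""
    if gender in (0, 1):
        return int(gender)
    if isinstance(gender, str):
        g = gender.strip().upper()
        if g in ("F", "FEMALE"):
            return 0
        if g in ("M", "MALE"):
            return 1
    raise ValidationError(f"gender must be F/M or 0/1, got {gender!r}")


# ---------------------------------------------------------------------------
# correction models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrectionTerm:
    predictor: str          # "age", "education" or "gender"
    transform: TransformSpec
    coefficient: float      # sign-reversed slope of the fitted regression
    center: float           # normative-sample mean of the transformed predictor


@dataclass(frozen=True)
class CorrectionModel:
    """Correction regression for one index.

    An empty ``terms`` tuple is the "no correction" model (no demographic
    predictor reached significance): the correction is identically zero.
    """

    index: str
    terms: tuple[CorrectionTerm, ...] = ()
    metadata: dict = field(default_factory=dict)

    @property
    def predictors(self) -> tuple[str, ...]:
        return tuple(t.predictor for t in self.terms)

    def correction(self, age: float, education: float, gender) -> float:
        """Correction score to be *added* to the raw index."""
        if age <= 0:
            raise NormDomainError(f"age must be positive, got {age}")
        if education < 1:
            raise NormDomainError(
                f"education must be at least 1 year, got {education}"
            )
        values = {"age": float(age), "education": float(education),
                  "gender": float(gender_code(gender))}
        total = 0.0
        for term in self.terms:
            try:
                z = term.transform(values[term.predictor])
            except NormDomainError as exc:
                raise NormDomainError(
                    f"{self.index} correction: {term.predictor} "
                    f"{term.transform.label()}: {exc}"
                ) from exc
            total += term.coefficient * (z - term.center)
        return total


def is_extrapolated(age: float, education: float) -> bool:
    """True when demographics fall outside the normative-sample ranges."""
    return not (NORM_AGE_RANGE[0] <= age <= NORM_AGE_RANGE[1]
                and NORM_EDUCATION_RANGE[0] <= education
                <= NORM_EDUCATION_RANGE[1])


def correction_score(model: CorrectionModel, age: float, education: float,
                     gender) -> float:
    """Functional wrapper around :meth:`CorrectionModel.correction`."""
    return model.correction(age, education, gender)


# ---------------------------------------------------------------------------
# normative tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToleranceBand:
    itl: float  # inner tolerance limit: at or below -> within limits
    otl: float  # outer tolerance limit: at or above -> pathological


@dataclass(frozen=True)
class PercentileBand:
    """Half-open band of printed percentile ranks bracketing a score."""

    lower: int | None   # worse (smaller) printed rank, None for "<1"
    upper: int | None   # next better printed rank, None at the grid edge
    label: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


@dataclass(frozen=True)
class IndexNorms:
    tolerance: ToleranceBand
    #: lower-inclusive boundaries of ES 0..3 (ES 4 lies below the last one);
    #: the first equals the outer tolerance limit by construction.
    es_boundaries: tuple[float, float, float, float]
    #: printed percentile grid, rank -> adjusted score
    percentiles: dict[int, float]


@dataclass(frozen=True)
class NormativeTables:
    per_index: dict[str, IndexNorms]

    def _norms(self, index_name: str) -> IndexNorms:
        try:
            return self.per_index[index_name]
        except KeyError:
            raise ValidationError(f"unknown index {index_name!r}") from None

    def classify_tolerance(self, index_name: str, adjusted: float) -> str:
        """Tolerance-limit classification of an adjusted score.

        The printed bands have one-decimal resolution, so the score is
        rounded to one decimal first; boundaries then behave exactly as
        printed (e.g. SA: 90.0 within, 90.1-97.3 borderline, 97.4 and above
        pathological).
        """
        nm = self._norms(index_name)
        v = round_half_away(adjusted, 1)
        if v <= nm.tolerance.itl:
            return WITHIN
        if v >= nm.tolerance.otl:
            return PATHOLOGICAL
        return BORDERLINE

    def equivalent_score(self, index_name: str, adjusted: float) -> int:
        """Five-level equivalent score; 0 is pathological, 4 at/better than
        the normative median."""
        nm = self._norms(index_name)
        v = round_half_away(adjusted, 1)
        for es, bound in enumerate(nm.es_boundaries):
            if v >= bound:
                return es
        return 4

    def percentile_band(self, index_name: str, adjusted: float
                        ) -> PercentileBand:
        """Step-function lookup in the printed percentile grid.

        Returns the band of printed ranks bracketing the score; scores
        better than the 99th-percentile entry report ">99", worse than the
        1st report "<1".
        """
        nm = self._norms(index_name)
        v = round_half_away(adjusted, 1)
        ranks = sorted(nm.percentiles, reverse=True)  # 99 first, best scores
        if v < nm.percentiles[ranks[0]]:
            return PercentileBand(ranks[0], None, f">{ranks[0]}")
        if v > nm.percentiles[ranks[-1]]:
            return PercentileBand(None, ranks[-1], f"<{ranks[-1]}")
        matching = [p for p in ranks if nm.percentiles[p] >= v]
        p = max(matching)
        better = [q for q in ranks if q > p]
        upper = min(better) if better else None
        return PercentileBand(p, upper, str(p))


# ---------------------------------------------------------------------------
# adjusted scores
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AdjustedIndex:
    index: str
    raw: float
    correction: float
    adjusted: float            # raw + correction, full precision
    equivalent_score: int
    percentile: PercentileBand
    tolerance_class: str


@dataclass(frozen=True)
class AdjustedIndexSet:
    per_index: dict[str, AdjustedIndex]
    warnings: tuple[str, ...] = ()

    def __getitem__(self, index_name: str) -> AdjustedIndex:
        return self.per_index[index_name]


@dataclass(frozen=True)
class NormSet:
    """A complete, versioned norm package: models plus classification tables."""

    models: dict[str, CorrectionModel]
    tables: NormativeTables
    version: str = "custom"
    metadata: dict = field(default_factory=dict)


def adjust_indexes(indexes: IndexSet, age: float, education: float, gender,
                   norms: NormSet) -> AdjustedIndexSet:
    """Correct the four raw indexes for demographics and classify them."""
    raw = indexes.as_dict()
    warnings: list[str] = []
    if is_extrapolated(age, education):
        warnings.append(
            f"demographics (age {age}, education {education}) outside the "
            f"normative ranges {NORM_AGE_RANGE}/{NORM_EDUCATION_RANGE}: "
            "corrections are extrapolations"
        )
    out: dict[str, AdjustedIndex] = {}
    for name in INDEXES:
        model = norms.models[name]
        corr = model.correction(age, education, gender)
        adj = raw[name] + corr
        out[name] = AdjustedIndex(
            index=name, raw=raw[name], correction=corr, adjusted=adj,
            equivalent_score=norms.tables.equivalent_score(name, adj),
            percentile=norms.tables.percentile_band(name, adj),
            tolerance_class=norms.tables.classify_tolerance(name, adj),
        )
    return AdjustedIndexSet(per_index=out, warnings=tuple(warnings))


# ---------------------------------------------------------------------------
# embedded published constants
# ---------------------------------------------------------------------------

def published_correction_models() -> dict[str, CorrectionModel]:
    """The four published correction regressions.

    Gender is coded 0 = female, 1 = male; logarithms are natural. The
    R^2 / adjusted R^2 / residual standard error of the underlying fits are
    carried as metadata only.
    """
    age_rlog = TransformSpec("reflected_log", offset=86.9)
    inv = TransformSpec("inverse")
    cube = TransformSpec("cube")
    ident = TransformSpec("identity")
    return {
        "SA": CorrectionModel("SA", (
            CorrectionTerm("age", age_rlog, 13.796, 3.628),
            CorrectionTerm("education", inv, -129.5, 0.081),
        ), {"r2": 0.238, "adj_r2": 0.236, "rse": 16.01}),
        "OA": CorrectionModel("OA", (
            CorrectionTerm("age", cube, -0.00004, 129295.0),
        ), {"r2": 0.041, "adj_r2": 0.039, "rse": 23.38}),
        "FA": CorrectionModel("FA", (
            CorrectionTerm("age", cube, -0.000019, 129295.0),
        ), {"r2": 0.017, "adj_r2": 0.015, "rse": 18.11}),
        "Err": CorrectionModel("Err", (
            CorrectionTerm("age", inv, 195.11, 0.0251),
            CorrectionTerm("education", inv, -38.13, 0.0812),
            CorrectionTerm("gender", ident, 2.6, 0.47),
        ), {"r2": 0.091, "adj_r2": 0.086, "rse": 8.83}),
    }


#: Published percentile grids (rank -> adjusted score; rank = % of the
#: normative sample performing worse).
PUBLISHED_PERCENTILES: dict[str, dict[int, float]] = {
    "SA": {99: 38.4, 95: 42.2, 90: 45.5, 85: 47.6, 80: 50.7, 75: 52.5,
           70: 54.0, 65: 55.8, 60: 57.4, 55: 59.9, 50: 61.5, 45: 63.1,
           40: 65.0, 35: 67.1, 30: 69.7, 25: 71.6, 20: 74.0, 15: 77.8,
           10: 83.7, 5: 92.5, 4: 96.9, 3: 98.0, 2: 102.1, 1: 114.1},
    "OA": {99: 4.5, 95: 12.9, 90: 22.2, 85: 27.2, 80: 30.2, 75: 34.1,
           70: 36.4, 65: 38.2, 60: 41.3, 55: 44.0, 50: 46.2, 45: 48.6,
           40: 51.5, 35: 55.1, 30: 58.4, 25: 61.0, 20: 66.7, 15: 72.9,
           10: 78.9, 5: 88.5, 4: 95.1, 3: 100.8, 2: 107.7, 1: 120.3},
    "FA": {99: -29.3, 95: -13.7, 90: -8.8, 85: -4.9, 80: -2.7, 75: -0.5,
           70: 1.4, 65: 2.9, 60: 4.9, 55: 6.4, 50: 8.4, 45: 10.7,
           40: 13.5, 35: 15.4, 30: 17.3, 25: 19.6, 20: 23.6, 15: 27.4,
           10: 32.8, 5: 44.1, 4: 45.6, 3: 50.9, 2: 56.5, 1: 60.5},
    "Err": {99: 1.0, 95: 4.3, 90: 6.1, 85: 7.4, 80: 8.3, 75: 9.9,
            70: 10.9, 65: 11.9, 60: 12.9, 55: 13.7, 50: 14.7, 45: 15.9,
            40: 16.7, 35: 18.0, 30: 19.2, 25: 20.3, 20: 22.6, 15: 24.3,
            10: 27.5, 5: 31.3, 4: 33.5, 3: 35.5, 2: 38.1, 1: 45.0},
}

#: Published tolerance limits (inner, outer) per index.
PUBLISHED_TOLERANCE: dict[str, tuple[float, float]] = {
    "SA": (90.0, 97.4),
    "OA": (86.1, 98.8),
    "FA": (41.0, 49.2),
    "Err": (29.9, 35.2),
}

#: Published equivalent-score boundaries (lower-inclusive edges of ES 0..3).
#: The ES-0 edge is the outer tolerance limit: pathological and ES 0 are the
#: same region by definition. (The published ES table prints the OA ES-0 edge
#: as 98.9, one resolution step above the published OTL 98.8; the OTL is
#: authoritative here so that ES 0 and the pathological class coincide.)
PUBLISHED_ES_BOUNDARIES: dict[str, tuple[float, float, float, float]] = {
    "SA": (97.4, 74.8, 67.1, 61.5),
    "OA": (98.8, 67.9, 55.6, 46.3),
    "FA": (49.2, 24.8, 15.5, 8.4),
    "Err": (35.2, 23.1, 18.1, 14.7),
}


def published_tables() -> NormativeTables:
    per_index = {}
    for name in INDEXES:
        itl, otl = PUBLISHED_TOLERANCE[name]
        per_index[name] = IndexNorms(
            tolerance=ToleranceBand(itl, otl),
            es_boundaries=PUBLISHED_ES_BOUNDARIES[name],
            percentiles=dict(PUBLISHED_PERCENTILES[name]),
        )
    return NormativeTables(per_index)


def published_norms() -> NormSet:
    """The embedded norm set of the published normative study."""
    return NormSet(
        models=published_correction_models(),
        tables=published_tables(),
        version="brevis-published-1.0",
        metadata={
            "sample": "550 healthy Italian adults, ages 20-79",
            "gender_coding": "0 = female, 1 = male",
            "tolerance": "one-sided nonparametric 95% content / "
                         "95% confidence",
        },
    )


# ---------------------------------------------------------------------------
# norm-file (de)serialisation
# ---------------------------------------------------------------------------

def _term_to_json(term: CorrectionTerm) -> dict:
    d = {"predictor": term.predictor, "family": term.transform.family,
         "coefficient": term.coefficient, "center": term.center}
    if term.transform.offset is not None:
        d["offset"] = term.transform.offset
    return d


def _term_from_json(d: dict) -> CorrectionTerm:
    return CorrectionTerm(
        predictor=d["predictor"],
        transform=TransformSpec(d["family"], d.get("offset")),
        coefficient=float(d["coefficient"]),
        center=float(d["center"]),
    )


def save_norms(norms: NormSet, path) -> None:
    """Write a norm set as a human-readable JSON norm file."""
    doc = {"format": "brevis-norms", "version": norms.version,
           "metadata": norms.metadata, "indexes": {}}
    for name in INDEXES:
        model = norms.models[name]
        nm = norms.tables.per_index[name]
        doc["indexes"][name] = {
            "correction_terms": [_term_to_json(t) for t in model.terms],
            "model_metadata": model.metadata,
            "tolerance": {"inner": nm.tolerance.itl, "outer": nm.tolerance.otl},
            "equivalent_score_boundaries": list(nm.es_boundaries),
            "percentiles": {str(k): v for k, v in nm.percentiles.items()},
        }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def load_norms(path) -> NormSet:
    """Load a norm set previously written by :func:`save_norms`."""
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "brevis-norms":
        raise ValidationError(f"{path}: not a brevis norm file")
    models: dict[str, CorrectionModel] = {}
    tables: dict[str, IndexNorms] = {}
    for name in INDEXES:
        entry = doc["indexes"][name]
        models[name] = CorrectionModel(
            name,
            tuple(_term_from_json(t) for t in entry["correction_terms"]),
            dict(entry.get("model_metadata", {})),
        )
        tables[name] = IndexNorms(
            tolerance=ToleranceBand(entry["tolerance"]["inner"],
                                    entry["tolerance"]["outer"]),
            es_boundaries=tuple(entry["equivalent_score_boundaries"]),
            percentiles={int(k): float(v)
                         for k, v in entry["percentiles"].items()},
        )
    return NormSet(models=models, tables=NormativeTables(tables),
                   version=doc.get("version", "custom"),
                   metadata=doc.get("metadata", {}))
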