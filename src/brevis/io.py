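"""Cohort file formats and the clinician-facing score report.

Cohorts travel as comma-separated UTF-8 text with a header row. The long
format has one row per participant x card::

    participant_id,age_years,education_years,gender,card,
    execution_time_s,omissions,substitutions,autocorrections

A wide variant (one row per participant, columns ``execution_time_1`` ..
``autocorrections_4``) is auto-detected. The decimal separator is always
".". Reports are written as JSON or CSV with seconds-valued quantities
rounded to one decimal and counts kept as integers.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import CohortFormatError
from .norms import INDEXES, NormSet, adjust_indexes, round_half_away
from .scoring import (
    CARD_IDS, CardObservation, ParticipantRecord, compute_indexes,
)

LONG_COLUMNS = ("participant_id", "age_years", "education_years", "gender",
                "card", "execution_time_s", "omissions", "substitutions",
                "autocorrections")

_CARD_FIELDS = ("execution_time", "omissions", "substitutions",
                "autocorrections")


def _parse_gender(value, where: str) -> str:
    g = str(value).strip().upper()
    if g in ("F", "FEMALE"):
        return "F"
    if g in ("M", "MALE"):
        return "M"
    raise CohortFormatError(f"{where}: gender must be F or M, got {value!r}")


def write_cohort(records, path) -> None:
    """Write records in the long format (lossless float round-trip)."""
    rows = []
    for r in records:
        for c in r.cards:
            rows.append({
                "participant_id": r.participant_id, "age_years": r.age,
                "education_years": r.education, "gender": r.gender,
                "card": c.card_id, "execution_time_s": c.execution_time,
                "omissions": c.omissions, "substitutions": c.substitutions,
                "autocorrections": c.autocorrections,
            })
    pd.DataFrame(rows, columns=LONG_COLUMNS).to_csv(path, index=False)


def _records_from_long(df: pd.DataFrame) -> tuple[list[ParticipantRecord],
                                                  list[str]]:
    issues: list[str] = []
    records: list[ParticipantRecord] = []
    df = df.copy()
    df["_line"] = df.index + 2  # header is line 1
    for pid, group in df.groupby("participant_id", sort=False):
        where = f"participant {pid}"
        try:
            cards = []
            seen = set()
            for _, row in group.iterrows():
                card_id = int(row["card"])
                if card_id in seen:
                    raise CohortFormatError(
                        f"line {row['_line']}: duplicate card {card_id} "
                        f"for {where}"
                    )
                seen.add(card_id)
                cards.append(CardObservation(
                    card_id=card_id,
                    execution_time=float(row["execution_time_s"]),
                    omissions=int(row["omissions"]),
                    substitutions=int(row["substitutions"]),
                    autocorrections=int(row["autocorrections"]),
                ))
            missing = sorted(set(CARD_IDS) - seen)
            if missing:
                raise CohortFormatError(
                    f"{where}: missing card {', '.join(map(str, missing))}"
                )
            first = group.iloc[0]
            records.append(ParticipantRecord(
                participant_id=str(pid),
                age=int(first["age_years"]),
                education=int(first["education_years"]),
                gender=_parse_gender(first["gender"], where),
                cards=tuple(cards),
            ))
        except (CohortFormatError, ValueError) as exc:
            issues.append(f"{where} (lines {group['_line'].min()}-"
                          f"{group['_line'].max()}): {exc}")
    return records, issues


def _records_from_wide(df: pd.DataFrame) -> tuple[list[ParticipantRecord],
                                                  list[str]]:
    issues: list[str] = []
    records: list[ParticipantRecord] = []
    for i, row in df.iterrows():
        pid = str(row["participant_id"])
        try:
            cards = tuple(
                CardObservation(
                    card_id=c,
                    execution_time=float(row[f"execution_time_{c}"]),
                    omissions=int(row[f"omissions_{c}"]),
                    substitutions=int(row.get(f"substitutions_{c}", 0)),
                    autocorrections=int(row.get(f"autocorrections_{c}", 0)),
                )
                for c in CARD_IDS
            )
            records.append(ParticipantRecord(
                participant_id=pid,
                age=int(row["age_years"]),
                education=int(row["education_years"]),
                gender=_parse_gender(row["gender"], f"participant {pid}"),
                cards=cards,
            ))
        except (KeyError, ValueError) as exc:
            issues.append(f"participant {pid} (line {i + 2}): {exc}")
    return records, issues


def read_cohort(path, *, strict: bool = True
                ) -> tuple[list[ParticipantRecord], list[str]]:
    """Read a cohort file; returns (records, issues).

    With ``strict`` (the default) any malformed or incomplete participant
    raises :class:`CohortFormatError` listing every problem with line
    numbers; otherwise offending participants are dropped and reported in
    ``issues``.
    """
    path = Path(path)
    if not path.exists():
        raise CohortFormatError(f"{path}: file not found")
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise CohortFormatError(f"{path}: cannot parse as CSV: {exc}")
    if "execution_time_1" in df.columns:
        records, issues = _records_from_wide(df)
    else:
        missing = [c for c in LONG_COLUMNS if c not in df.columns]
        if missing:
            raise CohortFormatError(
                f"{path}: missing required column(s) {', '.join(missing)}"
            )
        records, issues = _records_from_long(df)
    if strict and issues:
        raise CohortFormatError(f"{path}:\n" + "\n".join(issues))
    return records, issues


# ---------------------------------------------------------------------------
# score report
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoreReport:
    """Per-participant adjusted scores plus cohort-level ES counts."""

    table: pd.DataFrame
    summary: pd.DataFrame
    norm_version: str

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self, path) -> None:
        doc = {
            "norm_version": self.norm_version,
            "participants": self.table.to_dict(orient="records"),
            "es_counts": self.summary.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def score_cohort(records, norms: NormSet) -> ScoreReport:
    """Score every participant against a norm set.

    Seconds-valued quantities are rounded to one decimal in the report;
    adjusted = raw + correction holds at the stored precision. Scoring
    errors (a card with all targets omitted) propagate with the participant
    and card identity.
    """
    rows = []
    counts = {name: {es: 0 for es in range(5)} for name in INDEXES}
    for r in records:
        idx = compute_indexes(r)
        adj = adjust_indexes(idx, r.age, r.education, r.gender, norms)
        row: dict = {
            "participant_id": r.participant_id, "age": r.age,
            "education": r.education, "gender": r.gender,
        }
        for name in INDEXES:
            a = adj[name]
            digits = 0 if name == "Err" else 1
            row[f"{name}_raw"] = round_half_away(a.raw, digits)
            row[f"{name}_correction"] = round_half_away(a.correction, 1)
            row[f"{name}_adjusted"] = round_half_away(a.adjusted, 1)
            row[f"{name}_es"] = a.equivalent_score
            row[f"{name}_percentile"] = a.percentile.label
            row[f"{name}_class"] = a.tolerance_class
            counts[name][a.equivalent_score] += 1
        row["autocorrections"] = idx.autocorrections
        row["warnings"] = "; ".join(adj.warnings)
        rows.append(row)
    summary = pd.DataFrame(
        [{"index": name, **{f"ES{es}": counts[name][es] for es in range(5)}}
         for name in INDEXES]
    )
    return ScoreReport(pd.DataFrame(rows), summary, norms.version)
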