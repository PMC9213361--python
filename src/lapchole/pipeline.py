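"""End-to-end pipeline: cohort CSV in, study report out.

The chain mirrors the study's analysis: apply the eligibility filter, score
every included patient, dichotomise the intraoperative grade, then compute
the bivariate comparisons, the per-cutoff accuracy table, the stratified
outcome rates and the ROC summary.  The report validates against its model
on construction and serialises to JSON with full-precision values alongside
the truncated publication-style renderings.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
from pydantic import BaseModel, model_validator

from . import bivariate as bv
from . import diagnostics as dx
from .cohort import (
    OutcomeFlags,
    OUTCOME_FIELDS,
    PatientRecord,
    apply_eligibility_filter,
    dichotomize_difficulty,
    preoperative_score,
)
from .formatting import pct2, trunc2

logger = logging.getLogger("lapchole")

__all__ = [
    "COHORT_COLUMNS",
    "SCORED_COLUMNS",
    "SchemaError",
    "ParseError",
    "PipelineConfig",
    "StudyReport",
    "read_cohort_csv",
    "write_cohort_csv",
    "records_to_frame",
    "frame_to_records",
    "score_records",
    "write_scored_csv",
    "run_pipeline",
    "outcome_rates_by_stratum",
    "cutoff_table_frame",
    "report_json_schema",
]

COHORT_COLUMNS = [
    "id", "age", "sex", "asa", "diagnosis", "wall_thickness_mm",
    "cbd_diameter_mm", "preop_ercp", "admission", "planned_open", "malignancy",
    "intraop_grade", "conversion", "subtotal", "cvs_failed", "bleeding",
    "bile_leak", "cbd_injury",
]
SCORED_COLUMNS = COHORT_COLUMNS + ["score_total", "risk_category", "difficulty"]


class SchemaError(ValueError):
    """The CSV header does not match the cohort schema."""


class ParseError(ValueError):
    """A CSV row could not be interpreted; the message carries its line."""


def _opt_int(v):
    return None if pd.isna(v) else int(v)


def _opt_float(v):
    return None if pd.isna(v) else float(v)


def _opt_bool(v):
    return None if pd.isna(v) else bool(int(v))


def read_cohort_csv(path: Union[str, Path]) -> list[PatientRecord]:
    """Read a cohort CSV (one row per patient, booleans as 0/1, absent grade
    or outcomes as empty cells) into validated records."""
    try:
        df = pd.read_csv(path, dtype={"id": str})
    except pd.errors.EmptyDataError:
        return []
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort CSV is missing columns: {missing}")
    return frame_to_records(df)


def frame_to_records(df: pd.DataFrame) -> list[PatientRecord]:
    records = []
    for i, row in enumerate(df.to_dict("records")):
        try:
            has_outcomes = not all(pd.isna(row[k]) for k in OUTCOME_FIELDS)
            outcomes = (
                OutcomeFlags(**{k: bool(int(row[k])) if not pd.isna(row[k]) else False
                                for k in OUTCOME_FIELDS})
                if has_outcomes else None
            )
            records.append(PatientRecord(
                id=str(row["id"]),
                age=_opt_int(row["age"]),
                sex=None if pd.isna(row["sex"]) else str(row["sex"]),
                asa=_opt_int(row["asa"]),
                diagnosis=None if pd.isna(row["diagnosis"]) else str(row["diagnosis"]),
                wall_thickness_mm=_opt_float(row["wall_thickness_mm"]),
                cbd_diameter_mm=_opt_float(row["cbd_diameter_mm"]),
                preop_ercp=_opt_bool(row["preop_ercp"]),
                admission=None if pd.isna(row["admission"]) else str(row["admission"]),
                planned_open=bool(int(row["planned_open"])) if not pd.isna(row["planned_open"]) else False,
                malignancy=bool(int(row["malignancy"])) if not pd.isna(row["malignancy"]) else False,
                intraop_grade=_opt_int(row["intraop_grade"]),
                outcomes=outcomes,
            ))
        except (ValueError, KeyError) as exc:
            # +2: header line plus 1-based numbering
            raise ParseError(f"line {i + 2}: {exc}") from exc
    return records


def records_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "id": r.id,
            "age": r.age,
            "sex": r.sex.value if r.sex else None,
            "asa": r.asa,
            "diagnosis": r.diagnosis.value if r.diagnosis else None,
            "wall_thickness_mm": r.wall_thickness_mm,
            "cbd_diameter_mm": r.cbd_diameter_mm,
            "preop_ercp": None if r.preop_ercp is None else int(r.preop_ercp),
            "admission": r.admission.value if r.admission else None,
            "planned_open": int(r.planned_open),
            "malignancy": int(r.malignancy),
            "intraop_grade": r.intraop_grade,
        }
        for k in OUTCOME_FIELDS:
            row[k] = None if r.outcomes is None else int(getattr(r.outcomes, k))
        rows.append(row)
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def write_cohort_csv(records: Sequence[PatientRecord], path: Union[str, Path]) -> None:
    records_to_frame(records).to_csv(path, index=False)


def score_records(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Score eligible records into a frame with ``score_total``,
    ``risk_category`` and (where a grade exists) ``difficulty``."""
    df = records_to_frame(records)
    totals, cats, diffs = [], [], []
    for r in records:
        b = preoperative_score(r)
        totals.append(b.total)
        cats.append(b.category.value)
        diffs.append(
            dichotomize_difficulty(r.intraop_grade).value
            if r.intraop_grade is not None else None
        )
    df["score_total"] = totals
    df["risk_category"] = cats
    df["difficulty"] = diffs
    return df


def write_scored_csv(df: pd.DataFrame, path: Union[str, Path]) -> None:
    df.to_csv(path, index=False, columns=[c for c in SCORED_COLUMNS if c in df.columns])


# --------------------------------------------------------------------------
# report model


class RocSummary(BaseModel):
    thresholds: list[int]
    points: list[tuple[float, float]]
    auc: float
    auc_ci: tuple[float, float]
    confidence_level: float
    ci_method: str


class CohortSummary(BaseModel):
    n_assessed: int
    exclusions: dict[str, int]
    n: int
    n_easy: int
    n_difficult: int
    prevalence_difficult: Optional[float] = None
    prevalence_difficult_pct: Optional[float] = None

    @model_validator(mode="after")
    def _consistent(self):
        if self.n != self.n_assessed - sum(self.exclusions.values()):
            raise ValueError("included n must equal assessed minus exclusions")
        if self.n_easy + self.n_difficult > self.n:
            raise ValueError("graded cases cannot exceed included n")
        return self


class StudyReport(BaseModel):
    """Validated container for one full analysis run."""

    summary: CohortSummary
    bivariate: Optional[list[dict]] = None
    cutoff_table: Optional[list[dict]] = None
    optimal_cutoff: Optional[int] = None
    outcomes_by_stratum: Optional[dict[str, Optional[dict]]] = None
    roc: Optional[RocSummary] = None

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(self.model_dump_json(indent=2), encoding="utf-8")


def report_json_schema() -> dict:
    """JSON Schema document for the report (exportable for consumers)."""
    return StudyReport.model_json_schema()


class PipelineConfig(BaseModel):
    cutoffs: list[int] = list(range(1, 14))
    confidence_level: float = 0.95
    ci_method: str = "hanley-mcneil"
    diagnosis_ordered: bool = True

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True).encode()
        ).hexdigest()[:12]


def cutoff_table_frame(rows: Sequence[dx.CutoffRow]) -> pd.DataFrame:
    """Publication-style rendering of a cutoff table (values truncated to two
    decimals, column order sensitivity/specificity/PPV/NPV/Youden)."""
    out = []
    for r in rows:
        m = r.metrics
        out.append({
            "cutoff": r.cutoff,
            "sensitivity": None if m.sensitivity is None else trunc2(m.sensitivity),
            "specificity": None if m.specificity is None else trunc2(m.specificity),
            "ppv": None if m.ppv is None else trunc2(m.ppv),
            "npv": None if m.npv is None else trunc2(m.npv),
            "youden": None if m.youden is None else trunc2(m.youden),
        })
    return pd.DataFrame(out)


def outcome_rates_by_stratum(df: pd.DataFrame) -> dict[str, Optional[dict]]:
    """Count and percentage of each surgical outcome per risk stratum.

    Percentages are 100*count/stratum_n truncated to two decimals; an empty
    stratum yields None rather than rates with a zero denominator.
    """
    out: dict[str, Optional[dict]] = {}
    for stratum in ("low", "intermediate", "high"):
        sub = df[df["risk_category"] == stratum]
        n = len(sub)
        if n == 0:
            out[stratum] = None
            continue
        entry: dict = {"n": n, "outcomes": {}}
        for oc in OUTCOME_FIELDS:
            if oc in sub:
                count = int(pd.to_numeric(sub[oc], errors="coerce").fillna(0).sum())
            else:
                count = 0
            entry["outcomes"][oc] = {
                "count": count,
                "pct": pct2(count, n),
                "pct_exact": 100.0 * count / n,
            }
        out[stratum] = entry
    return out


def run_pipeline(
    cohort: Union[str, Path, Sequence[PatientRecord]],
    config: Optional[PipelineConfig] = None,
) -> StudyReport:
    """Filter, score and evaluate a cohort; deterministic for fixed input."""
    config = config or PipelineConfig()
    records = (
        read_cohort_csv(cohort)
        if isinstance(cohort, (str, Path))
        else list(cohort)
    )
    included, tally = apply_eligibility_filter(records)
    logger.info(
        "pipeline config=%s assessed=%d exclusions=%s included=%d",
        config.digest(), len(records), dict(tally), len(included),
    )

    if not included:
        return StudyReport(summary=CohortSummary(
            n_assessed=len(records), exclusions=dict(tally),
            n=0, n_easy=0, n_difficult=0,
        ))

    df = score_records(included)
    graded = df[df["difficulty"].notna()]
    n_easy = int((graded["difficulty"] == "easy").sum())
    n_difficult = int((graded["difficulty"] == "difficult").sum())
    prev = n_difficult / (n_easy + n_difficult) if n_easy + n_difficult else None
    summary = CohortSummary(
        n_assessed=len(records), exclusions=dict(tally), n=len(included),
        n_easy=n_easy, n_difficult=n_difficult,
        prevalence_difficult=prev,
        prevalence_difficult_pct=None if prev is None else pct2(n_difficult, n_easy + n_difficult),
    )

    report = StudyReport(summary=summary,
                         outcomes_by_stratum=outcome_rates_by_stratum(df))

    if n_easy > 0 and n_difficult > 0:
        scores = graded["score_total"].astype(int).tolist()
        labels = graded["difficulty"].tolist()
        rows = dx.cutoff_table(scores, labels, config.cutoffs)

        def _t(v):
            return None if v is None else trunc2(v)

        report.cutoff_table = [
            {"cutoff": r.cutoff,
             "sensitivity": r.metrics.sensitivity,
             "specificity": r.metrics.specificity,
             "ppv": r.metrics.ppv, "npv": r.metrics.npv,
             "youden": r.metrics.youden,
             "tp": r.counts.tp, "fp": r.counts.fp,
             "tn": r.counts.tn, "fn": r.counts.fn,
             "rendered": {
                 "sensitivity": _t(r.metrics.sensitivity),
                 "specificity": _t(r.metrics.specificity),
                 "ppv": _t(r.metrics.ppv), "npv": _t(r.metrics.npv),
                 "youden": _t(r.metrics.youden),
             }}
            for r in rows
        ]
        report.optimal_cutoff = dx.youden_optimal_cutoff(rows)
        roc = dx.roc_curve(scores, labels, config.confidence_level, config.ci_method)
        report.roc = RocSummary(
            thresholds=list(roc.thresholds), points=[tuple(p) for p in roc.points],
            auc=roc.auc, auc_ci=roc.auc_ci,
            confidence_level=roc.confidence_level, ci_method=roc.ci_method,
        )
        comparisons = bv.bivariate_report(graded, config.diagnosis_ordered)
        report.bivariate = bv.report_frame(comparisons, len(graded)).to_dict("records")

    return report
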