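"""Published aggregate counts of the source study and their expansion into a
synthetic per-patient cohort.

Patient-level data were never released; what the study prints are stratum
totals (easy/difficult per risk stratum), outcome counts per stratum, and the
selection flowchart.  This module holds those aggregates and expands them
into a synthetic cohort of minimal-score patients that reproduces every
aggregate exactly — each low/intermediate/high patient gets the smallest
covariate pattern attaining its stratum (scores 0, 2 and 7), a grade of 1 or
3 matching its easy/difficult label, and outcome flags assigned
deterministically within the stratum.  Such a cohort is sufficient for any
statistic that depends on the data only through stratum membership and the
dichotomised grade.
"""

from __future__ import annotations

from .cohort import Difficulty, OutcomeFlags, PatientRecord
from .diagnostics import GroupedCounts

__all__ = [
    "STRATA",
    "TABLE_STRATA_COUNTS",
    "STRATUM_SIZES",
    "OUTCOME_COUNTS",
    "FLOWCHART",
    "STRATUM_MIN_SCORE",
    "grouped_counts",
    "expand_scores_labels",
    "reference_cohort",
    "eligibility_fixture",
]

STRATA = ("low", "intermediate", "high")

#: (easy, difficult) counts per risk stratum as published.
TABLE_STRATA_COUNTS = {
    "low": (32, 2),
    "intermediate": (94, 29),
    "high": (28, 134),
}

STRATUM_SIZES = {s: sum(TABLE_STRATA_COUNTS[s]) for s in STRATA}  # 34, 123, 162

#: Outcome counts per stratum as published (conversion, subtotal
#: cholecystectomy, critical-view-of-safety failure, bleeding, bile leak,
#: common-bile-duct injury).
OUTCOME_COUNTS = {
    "low": {"conversion": 0, "subtotal": 0, "cvs_failed": 1,
            "bleeding": 0, "bile_leak": 0, "cbd_injury": 0},
    "intermediate": {"conversion": 2, "subtotal": 4, "cvs_failed": 7,
                     "bleeding": 2, "bile_leak": 0, "cbd_injury": 0},
    "high": {"conversion": 13, "subtotal": 14, "cvs_failed": 24,
             "bleeding": 4, "bile_leak": 2, "cbd_injury": 1},
}

#: Selection flowchart: patients assessed and exclusions by reason.
FLOWCHART = {
    "assessed": 334,
    "planned_open": 2,
    "missing_variables": 12,
    "malignancy": 1,
    "included": 319,
}

#: Smallest score inside each stratum; the expansion assigns it to every
#: patient of the stratum.
STRATUM_MIN_SCORE = {"low": 0, "intermediate": 2, "high": 7}


def grouped_counts() -> GroupedCounts:
    """The published stratum x difficulty counts as a GroupedCounts."""
    return GroupedCounts(
        categories=STRATA,
        easy=tuple(TABLE_STRATA_COUNTS[s][0] for s in STRATA),
        difficult=tuple(TABLE_STRATA_COUNTS[s][1] for s in STRATA),
    )


def expand_scores_labels() -> tuple[list[int], list[str]]:
    """Per-patient (score, label) lists using the minimal stratum scores."""
    scores: list[int] = []
    labels: list[str] = []
    for s in STRATA:
        easy, difficult = TABLE_STRATA_COUNTS[s]
        scores += [STRATUM_MIN_SCORE[s]] * (easy + difficult)
        labels += [Difficulty.EASY.value] * easy + [Difficulty.DIFFICULT.value] * difficult
    return scores, labels


# covariate patterns attaining each stratum's minimal score
_BASE = dict(age=35, sex="female", asa=1, diagnosis="biliary_colic",
             wall_thickness_mm=2.0, cbd_diameter_mm=4.0, preop_ercp=False,
             admission="elective")
_STRATUM_PATTERN = {
    "low": _BASE,                                        # total 0
    "intermediate": {**_BASE, "wall_thickness_mm": 4.0},  # thick wall -> 2
    "high": {**_BASE, "asa": 4},                          # ASA 4 -> 7
}


def reference_cohort() -> list[PatientRecord]:
    """Synthetic 319-patient expansion of the published aggregates.

    Within each stratum, easy patients come first (grade 1) then difficult
    ones (grade 3); each outcome's k flagged patients are the first k of the
    stratum, independently per outcome.
    """
    records: list[PatientRecord] = []
    for s in STRATA:
        easy, difficult = TABLE_STRATA_COUNTS[s]
        pat = _STRATUM_PATTERN[s]
        oc = OUTCOME_COUNTS[s]
        for i in range(easy + difficult):
            grade = 1 if i < easy else 3
            flags = OutcomeFlags(**{k: i < v for k, v in oc.items()})
            records.append(PatientRecord(
                id=f"{s}-{i:03d}", intraop_grade=grade, outcomes=flags, **pat
            ))
    return records


def eligibility_fixture() -> list[PatientRecord]:
    """Synthetic 334-record fixture reproducing the selection flowchart:
    the 319 eligible patients plus 2 planned-open, 12 missing-variable and
    1 malignancy records."""
    records = reference_cohort()
    for i in range(FLOWCHART["planned_open"]):
        records.append(PatientRecord(id=f"excl-open-{i}", planned_open=True, **_BASE))
    for i in range(FLOWCHART["missing_variables"]):
        rec = PatientRecord(id=f"excl-miss-{i}", **_BASE)
        rec.wall_thickness_mm = None
        records.append(rec)
    for i in range(FLOWCHART["malignancy"]):
        records.append(PatientRecord(id=f"excl-cancer-{i}", malignancy=True, **_BASE))
    return records
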