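"""Bivariate comparisons of preoperative factors between easy and difficult
procedures.

Binary factors are compared with Pearson's chi-square test on the 2x2 table
(no continuity correction by default); ordered multi-level factors (ASA
class, primary diagnosis, admission type, risk stratum) with the
Mann-Whitney test on their natural order.  Cell percentages are rendered as
shares of the whole cohort, truncated to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import AGE_CUTOFF, CBD_CUTOFF_MM, WALL_CUTOFF_MM, ValidationError
from .diagnostics import DegenerateInputError
from .formatting import pct2

__all__ = [
    "ContingencyTable",
    "TestResult",
    "VariableComparison",
    "DegenerateTableError",
    "chi_square_test",
    "mann_whitney_test",
    "bivariate_report",
    "ORDERED_VARIABLES",
]


class DegenerateTableError(ValueError):
    """Contingency table has a zero marginal; the test is undefined."""


@dataclass(frozen=True)
class ContingencyTable:
    """Counts of easy and difficult cases per level of one variable."""

    levels: tuple[str, ...]
    easy: tuple[int, ...]
    difficult: tuple[int, ...]

    def __post_init__(self):
        if len(self.levels) < 2:
            raise ValidationError("a contingency table needs at least 2 rows")
        if not (len(self.levels) == len(self.easy) == len(self.difficult)):
            raise ValidationError("rows and counts must align")
        if min(self.easy) < 0 or min(self.difficult) < 0:
            raise ValidationError("counts must be nonnegative")

    @property
    def observed(self) -> np.ndarray:
        return np.column_stack([self.easy, self.difficult]).astype(np.float64)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str  # "chi_square" | "mann_whitney"
    df: Optional[int] = None


def chi_square_test(t: ContingencyTable, correction: bool = False) -> TestResult:
    """Pearson chi-square test of independence on the levels x outcome table.

    No Yates continuity correction by default; pass ``correction=True`` for
    the corrected 2x2 statistic.
    """
    obs = t.observed
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise DegenerateTableError("zero row or column marginal")
    res = stats.chi2_contingency(obs, correction=correction)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="chi_square",
        df=int(res.dof),
    )


def mann_whitney_test(
    values_easy: Sequence[float], values_difficult: Sequence[float]
) -> TestResult:
    """Mann-Whitney U test on ordinal values, two-sided.

    Midranks handle ties; the p-value comes from the normal approximation
    with tie-corrected variance (no continuity correction).  When every
    observation is tied the statistic carries no information and p = 1.
    """
    x = np.asarray(values_easy, dtype=np.float64)
    y = np.asarray(values_difficult, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise DegenerateInputError("both groups must be non-empty")
    if np.unique(np.concatenate([x, y])).size == 1:
        return TestResult(statistic=x.size * y.size / 2.0, p_value=1.0,
                          method="mann_whitney")
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      method="mann_whitney")


# ordered level sets, in their natural (point-table) order
_ASA_LEVELS = ["1", "2", "3", "4-5"]
_DIAGNOSIS_LEVELS = ["pancreatitis", "biliary_colic", "choledocholithiasis", "cholecystitis"]
_ADMISSION_LEVELS = ["elective", "delayed", "emergency"]
_RISK_LEVELS = ["low", "intermediate", "high"]

#: Variables tested with Mann-Whitney on their natural order; the rest use
#: chi-square.  Primary diagnosis is treated as ordered by default (its point
#: order: pancreatitis < biliary colic < choledocholithiasis < cholecystitis)
#: but can be analysed as nominal.
ORDERED_VARIABLES = ("asa", "diagnosis", "admission", "risk_category")


@dataclass(frozen=True)
class VariableComparison:
    variable: str
    table: ContingencyTable
    result: Optional[TestResult]
    error: Optional[str] = None


def _level_series(df: pd.DataFrame) -> dict[str, tuple[pd.Series, list[str]]]:
    age_lvl = np.where(df["age"] >= AGE_CUTOFF, "40+", "<40")
    wall_lvl = np.where(df["wall_thickness_mm"] >= WALL_CUTOFF_MM, "yes", "no")
    cbd_lvl = np.where(df["cbd_diameter_mm"] > CBD_CUTOFF_MM, "yes", "no")
    ercp_lvl = np.where(df["preop_ercp"].astype(float) > 0, "yes", "no")
    asa_lvl = np.where(df["asa"].astype(float) >= 4, "4-5",
                       df["asa"].astype(float).astype(int).astype(str))
    return {
        "age": (pd.Series(age_lvl, index=df.index), ["<40", "40+"]),
        "sex": (df["sex"].astype(str), ["female", "male"]),
        "asa": (pd.Series(asa_lvl, index=df.index), _ASA_LEVELS),
        "diagnosis": (df["diagnosis"].astype(str), _DIAGNOSIS_LEVELS),
        "thick_wall": (pd.Series(wall_lvl, index=df.index), ["no", "yes"]),
        "cbd_dilated": (pd.Series(cbd_lvl, index=df.index), ["no", "yes"]),
        "preop_ercp": (pd.Series(ercp_lvl, index=df.index), ["no", "yes"]),
        "admission": (df["admission"].astype(str), _ADMISSION_LEVELS),
        "risk_category": (df["risk_category"].astype(str), _RISK_LEVELS),
    }

# which raw variable feeds each report row-group's ordering
_ORDER_KEY = {"asa": "asa", "diagnosis": "diagnosis",
              "admission": "admission", "risk_category": "risk_category"}


def bivariate_report(
    df: pd.DataFrame, diagnosis_ordered: bool = True
) -> list[VariableComparison]:
    """Per-variable easy/difficult contingency tables with the matching test.

    ``df`` is a scored cohort frame with a ``difficulty`` column; counts are
    always produced, while a degenerate table records its error instead of a
    test result.
    """
    if "difficulty" not in df:
        raise ValidationError("cohort frame must carry a 'difficulty' column")
    sub = df[df["difficulty"].isin(["easy", "difficult"])]
    is_diff = (sub["difficulty"] == "difficult").to_numpy()

    comparisons = []
    for name, (series, levels) in _level_series(sub).items():
        vals = series.to_numpy()
        easy_counts = tuple(int(np.sum((vals == lv) & ~is_diff)) for lv in levels)
        diff_counts = tuple(int(np.sum((vals == lv) & is_diff)) for lv in levels)
        table = ContingencyTable(tuple(levels), easy_counts, diff_counts)
        ordered = name in ORDERED_VARIABLES and (name != "diagnosis" or diagnosis_ordered)
        try:
            if ordered:
                rank = {lv: i for i, lv in enumerate(levels)}
                coded = np.array([rank[v] for v in vals], dtype=np.float64)
                result = mann_whitney_test(coded[~is_diff], coded[is_diff])
            else:
                result = chi_square_test(table)
            comparisons.append(VariableComparison(name, table, result))
        except (DegenerateTableError, DegenerateInputError) as exc:
            comparisons.append(VariableComparison(name, table, None, error=str(exc)))
    return comparisons


def report_frame(comparisons: Sequence[VariableComparison], n_total: int) -> pd.DataFrame:
    """Flatten a bivariate report into the export table layout
    (variable, level, counts, grand-total percentages, test, p)."""
    from .formatting import format_p

    rows = []
    for comp in comparisons:
        for lv, e, d in zip(comp.table.levels, comp.table.easy, comp.table.difficult):
            rows.append({
                "variable": comp.variable,
                "level": lv,
                "easy_n": e,
                "easy_pct": pct2(e, n_total) if n_total else np.nan,
                "difficult_n": d,
                "difficult_pct": pct2(d, n_total) if n_total else np.nan,
                "test": comp.result.method if comp.result else "none",
                "p_value": format_p(comp.result.p_value) if comp.result else "",
            })
    return pd.DataFrame(rows)
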