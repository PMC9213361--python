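"""Seeded synthetic cohort generator.

The generator emulates the statistical structure the analysis assumes, not
any individual patient: covariates are drawn from the published cohort
marginals (age as a normal truncated at 18; wall thickness and duct diameter
as moment-matched gammas, which keeps them positive given only mean +/- SD;
categorical variables from their observed proportions), the preoperative
score is computed from the drawn covariates, and operative difficulty is
then drawn from a logistic link

    P(difficult | score) = 1 / (1 + exp(-(alpha + beta * score))).

The link is an artifact of the generator — the study fit no such model — and
its default parameters are calibrated so the synthetic pipeline reproduces
the published discrimination (AUC 0.88) at the published prevalence of
difficult procedures.  Difficult cases receive grade 3 or 4 with equal odds,
easy ones grade 1 or 2; surgical outcomes are drawn per risk stratum from
the published stratum rates; optional exclusion injection adds planned-open,
missing-variable and malignancy records at given rates.

All draws flow from a single seeded ``numpy.random.Generator``.
"""

from __future__ import annotations

from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy import optimize, stats
from scipy.special import expit

from .cohort import (
    Difficulty,
    OutcomeFlags,
    PatientRecord,
    SCORED_FIELDS,
    OUTCOME_FIELDS,
    score_frame,
)
from .reference import OUTCOME_COUNTS, STRATUM_SIZES
from .diagnostics import DegenerateInputError

__all__ = [
    "CohortSpec",
    "CalibrationResult",
    "LogisticFit",
    "CalibrationError",
    "SeparationError",
    "generate_frame",
    "generate_cohort",
    "calibrate_link",
    "recover_link",
    "empirical_auc",
]

_N_STUDY = 319  # published cohort size; denominators of the default marginals

#: Default stratum outcome probabilities, from the published counts.
_DEFAULT_OUTCOME_RATES = {
    s: {k: v / STRATUM_SIZES[s] for k, v in OUTCOME_COUNTS[s].items()}
    for s in OUTCOME_COUNTS
}


class CalibrationError(RuntimeError):
    """The link calibration could not bracket the target."""


class SeparationError(RuntimeError):
    """Logistic fit did not converge (likely complete separation)."""


class CohortSpec(BaseModel):
    """Generative model of the study cohort; defaults are the published
    marginals and stratified outcome rates."""

    n: int = Field(default=_N_STUDY, ge=1)
    seed: int = 0

    age_mean: float = 55.4
    age_sd: float = Field(default=18.2, gt=0)
    age_min: float = 18.0

    p_female: float = Field(default=185 / _N_STUDY, ge=0, le=1)

    # probabilities over ASA 1, 2, 3, 4 (the "4-5" mass sits entirely on 4)
    asa_probs: tuple[float, float, float, float] = (
        109 / _N_STUDY, 138 / _N_STUDY, 71 / _N_STUDY, 1 / _N_STUDY)
    # pancreatitis, biliary colic, choledocholithiasis, cholecystitis
    diagnosis_probs: tuple[float, float, float, float] = (
        8 / _N_STUDY, 132 / _N_STUDY, 37 / _N_STUDY, 142 / _N_STUDY)
    # elective, delayed, emergency
    admission_probs: tuple[float, float, float] = (
        58 / _N_STUDY, 252 / _N_STUDY, 9 / _N_STUDY)

    wall_mean: float = 3.3
    wall_sd: float = Field(default=1.7, gt=0)
    cbd_mean: float = 4.9
    cbd_sd: float = Field(default=2.1, gt=0)
    p_ercp: float = Field(default=63 / _N_STUDY, ge=0, le=1)

    # difficulty link; defaults calibrated to AUC 0.88 at the published
    # prevalence (see calibrate_link)
    alpha: float = -5.197334122442908
    beta: float = 0.84375
    target_prevalence: float = Field(default=165 / _N_STUDY, gt=0, lt=1)

    # stylised dependence: cholecystitis shifts the wall-thickness mean up
    # and tilts admission away from elective; off by default (independent
    # marginals)
    couple_covariates: bool = False
    cholecystitis_wall_shift: float = 1.5

    outcome_rates: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {s: dict(r) for s, r in _DEFAULT_OUTCOME_RATES.items()}
    )
    # planned_open, missing_variables, malignancy — fractions of n
    exclusion_rates: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @field_validator("asa_probs", "diagnosis_probs", "admission_probs")
    @classmethod
    def _sums_to_one(cls, v):
        if abs(sum(v) - 1.0) > 1e-9:
            raise ValueError(f"probabilities must sum to 1, got {sum(v)}")
        if min(v) < 0:
            raise ValueError("probabilities must be nonnegative")
        return v

    @model_validator(mode="after")
    def _check_rates(self):
        for s, rates in self.outcome_rates.items():
            for k, p in rates.items():
                if not 0 <= p <= 1:
                    raise ValueError(f"outcome rate {s}.{k}={p} outside [0,1]")
        if min(self.exclusion_rates) < 0 or sum(self.exclusion_rates) > 1:
            raise ValueError("exclusion rates must be >= 0 and sum to <= 1")
        return self

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)


def _gamma_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-matched gamma (shape, scale)."""
    return (mean / sd) ** 2, sd * sd / mean


def _draw_covariates(spec: CohortSpec, n: int, rng: np.random.Generator) -> pd.DataFrame:
    a = (spec.age_min - spec.age_mean) / spec.age_sd
    age = stats.truncnorm.rvs(a, np.inf, loc=spec.age_mean, scale=spec.age_sd,
                              size=n, random_state=rng)
    sex = np.where(rng.random(n) < spec.p_female, "female", "male")
    asa = rng.choice([1, 2, 3, 4], size=n, p=spec.asa_probs)
    diagnosis = rng.choice(
        ["pancreatitis", "biliary_colic", "choledocholithiasis", "cholecystitis"],
        size=n, p=spec.diagnosis_probs)

    shape_w, scale_w = _gamma_params(spec.wall_mean, spec.wall_sd)
    wall = rng.gamma(shape_w, scale_w, size=n)
    if spec.couple_covariates:
        chole = diagnosis == "cholecystitis"
        shape_c, scale_c = _gamma_params(
            spec.wall_mean + spec.cholecystitis_wall_shift, spec.wall_sd)
        wall = np.where(chole, rng.gamma(shape_c, scale_c, size=n), wall)

    shape_c, scale_c = _gamma_params(spec.cbd_mean, spec.cbd_sd)
    cbd = rng.gamma(shape_c, scale_c, size=n)
    ercp = rng.random(n) < spec.p_ercp

    adm_levels = np.array(["elective", "delayed", "emergency"])
    if spec.couple_covariates:
        p = np.tile(np.asarray(spec.admission_probs), (n, 1))
        chole = diagnosis == "cholecystitis"
        # move half of the elective mass to delayed for cholecystitis
        p[chole, 1] += p[chole, 0] / 2.0
        p[chole, 0] /= 2.0
        u = rng.random(n)
        cum = np.cumsum(p, axis=1)
        admission = adm_levels[(u[:, None] > cum).sum(axis=1)]
    else:
        admission = rng.choice(adm_levels, size=n, p=spec.admission_probs)

    return pd.DataFrame({
        "age": np.floor(age).astype(int),
        "sex": sex,
        "asa": asa,
        "diagnosis": diagnosis,
        "wall_thickness_mm": np.round(wall, 1),
        "cbd_diameter_mm": np.round(cbd, 1),
        "preop_ercp": ercp.astype(int),
        "admission": admission,
    })


def generate_frame(spec: CohortSpec, rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Columnar cohort draw: the fast path behind :func:`generate_cohort`.

    Returns one row per patient with the cohort-CSV columns plus
    ``score_total``, ``risk_category`` and ``difficulty``.  Excluded records
    (when exclusion injection is on) carry their exclusion flags and no
    grade.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    n = spec.n
    df = _draw_covariates(spec, n, rng)
    df.insert(0, "id", [f"sim-{i:06d}" for i in range(n)])

    p_open, p_miss, p_mal = spec.exclusion_rates
    reason = rng.choice(4, size=n, p=[1 - p_open - p_miss - p_mal, p_open, p_miss, p_mal])
    df["planned_open"] = (reason == 1).astype(int)
    df["malignancy"] = (reason == 3).astype(int)
    miss_idx = np.flatnonzero(reason == 2)
    if miss_idx.size:
        which = rng.integers(0, len(SCORED_FIELDS), size=miss_idx.size)
        for j, col in enumerate(SCORED_FIELDS):
            rows = miss_idx[which == j]
            if rows.size:
                df.loc[df.index[rows], col] = np.nan

    df = score_frame(df)
    eligible = (reason == 0) & df["score_total"].notna()

    p_diff = expit(spec.alpha + spec.beta * df["score_total"].to_numpy(dtype=float))
    difficult = rng.random(n) < p_diff
    grade = np.where(difficult, rng.integers(3, 5, size=n), rng.integers(1, 3, size=n))
    df["intraop_grade"] = np.where(eligible, grade, np.nan)
    df["difficulty"] = np.where(
        eligible,
        np.where(difficult, Difficulty.DIFFICULT.value, Difficulty.EASY.value),
        None,
    )

    for oc in OUTCOME_FIELDS:
        rate = df["risk_category"].map(
            {s: spec.outcome_rates.get(s, {}).get(oc, 0.0) for s in spec.outcome_rates}
        ).fillna(0.0).to_numpy(dtype=float)
        drawn = rng.random(n) < rate
        df[oc] = np.where(eligible, drawn.astype(float), np.nan)
    return df


def generate_cohort(spec: CohortSpec) -> list[PatientRecord]:
    """Draw a cohort as :class:`PatientRecord` objects (deterministic given
    ``spec.seed``)."""
    df = generate_frame(spec)
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        has_grade = d["intraop_grade"] == d["intraop_grade"]  # not NaN
        outcomes = None
        if has_grade:
            outcomes = OutcomeFlags(**{k: bool(d[k]) for k in OUTCOME_FIELDS})
        records.append(PatientRecord(
            id=d["id"],
            age=None if d["age"] != d["age"] else int(d["age"]),
            sex=None if pd.isna(d["sex"]) else d["sex"],
            asa=None if d["asa"] != d["asa"] else int(d["asa"]),
            diagnosis=None if pd.isna(d["diagnosis"]) else d["diagnosis"],
            wall_thickness_mm=None if d["wall_thickness_mm"] != d["wall_thickness_mm"] else float(d["wall_thickness_mm"]),
            cbd_diameter_mm=None if d["cbd_diameter_mm"] != d["cbd_diameter_mm"] else float(d["cbd_diameter_mm"]),
            preop_ercp=None if d["preop_ercp"] != d["preop_ercp"] else bool(d["preop_ercp"]),
            admission=None if pd.isna(d["admission"]) else d["admission"],
            planned_open=bool(d["planned_open"]),
            malignancy=bool(d["malignancy"]),
            intraop_grade=int(d["intraop_grade"]) if has_grade else None,
            outcomes=outcomes,
        ))
    return records


def empirical_auc(scores: Sequence[float], labels: Sequence) -> float:
    """Tie-aware concordance AUC of a score against easy/difficult labels,
    computed from the per-score histogram (exact, O(#distinct scores^2))."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray([1 if Difficulty(l) is Difficulty.DIFFICULT else 0 for l in labels])
    vals = np.unique(s)
    d = np.array([np.sum((s == v) & (y == 1)) for v in vals], dtype=float)
    e = np.array([np.sum((s == v) & (y == 0)) for v in vals], dtype=float)
    if d.sum() == 0 or e.sum() == 0:
        raise DegenerateInputError("both classes must be present")
    conc = sum(d[i] * e[:i].sum() for i in range(len(vals)))
    ties = float(np.dot(d, e))
    return float((conc + 0.5 * ties) / (d.sum() * e.sum()))


class CalibrationResult(NamedTuple):
    alpha: float
    beta: float
    achieved_auc: float


def _expected_auc_for_link(score_counts: np.ndarray, score_vals: np.ndarray,
                           alpha: float, beta: float) -> float:
    p = expit(alpha + beta * score_vals)
    d = score_counts * p
    e = score_counts * (1.0 - p)
    conc = sum(d[i] * e[:i].sum() for i in range(len(score_vals)))
    ties = float(np.dot(d, e))
    return float((conc + 0.5 * ties) / (d.sum() * e.sum()))


def _solve_alpha(score_counts, score_vals, beta, prevalence):
    def mean_p(alpha):
        p = expit(alpha + beta * score_vals)
        return float(np.dot(score_counts, p) / score_counts.sum()) - prevalence
    # the lower bracket scales with beta so a root always exists
    lo = -60.0 - abs(beta) * (float(score_vals.max()) + 1.0)
    return float(optimize.brentq(mean_p, lo, 60.0, xtol=1e-12))


def calibrate_link(
    spec: CohortSpec,
    target_auc: float,
    tolerance: float = 0.005,
    n_eval: int = 50_000,
) -> CalibrationResult:
    """Calibrate (alpha, beta) so that difficulty drawn from the logistic
    link attains a target AUC while holding prevalence at
    ``spec.target_prevalence``.

    A score sample of size ``n_eval`` is drawn once from the covariate
    model; for each candidate beta, alpha is re-solved to hold the expected
    prevalence, and the expected tie-aware AUC over the Bernoulli mechanism
    is evaluated in closed form on the score histogram.  Bisection on beta
    runs until that AUC is within ``tolerance`` of the target.
    """
    if not 0.5 < target_auc < 1.0:
        raise CalibrationError(f"target_auc must be in (0.5, 1), got {target_auc}")
    rng = np.random.default_rng(spec.seed)
    df = _draw_covariates(spec, n_eval, rng)
    df = score_frame(df)
    scores = df["score_total"].to_numpy(dtype=float)
    vals, counts = np.unique(scores, return_counts=True)
    counts = counts.astype(float)

    def auc_at(beta: float) -> tuple[float, float]:
        alpha = _solve_alpha(counts, vals, beta, spec.target_prevalence)
        return alpha, _expected_auc_for_link(counts, vals, alpha, beta)

    lo, hi = 0.0, 0.5
    _, auc_hi = auc_at(hi)
    while auc_hi < target_auc:
        hi *= 2.0
        if hi > 64.0:
            raise CalibrationError(
                f"cannot reach AUC {target_auc}: score spread too small "
                f"(max attainable ~{auc_hi:.3f})"
            )
        _, auc_hi = auc_at(hi)

    for _ in range(200):
        mid = 0.5 * (lo + hi)
        alpha, auc_mid = auc_at(mid)
        if abs(auc_mid - target_auc) <= tolerance or hi - lo < 1e-10:
            return CalibrationResult(alpha, mid, auc_mid)
        if auc_mid < target_auc:
            lo = mid
        else:
            hi = mid
    raise CalibrationError("bisection failed to converge")


class LogisticFit(NamedTuple):
    alpha: float
    beta: float
    se_alpha: float
    se_beta: float
    n_iter: int


def recover_link(
    scores: Sequence[float],
    labels: Sequence,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> LogisticFit:
    """Maximum-likelihood logistic fit of difficulty on score by iteratively
    reweighted least squares.

    Standard errors come from the inverse Fisher information.  Raises
    :class:`SeparationError` when the fit diverges (complete separation) or
    fails to converge.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray([1 if Difficulty(l) is Difficulty.DIFFICULT else 0 for l in labels],
                   dtype=float)
    if y.sum() == 0 or y.sum() == y.size:
        raise DegenerateInputError("both classes must be present")
    X = np.column_stack([np.ones_like(s), s])
    b = np.zeros(2)
    for it in range(1, max_iter + 1):
        eta = X @ b
        if np.max(np.abs(eta)) > 40.0:
            raise SeparationError("diverging linear predictor: complete separation?")
        p = expit(eta)
        w = p * (1.0 - p)
        info = X.T @ (X * w[:, None])
        grad = X.T @ (y - p)
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            raise SeparationError("singular information matrix") from None
        b = b + step
        if np.max(np.abs(step)) < tol:
            cov = np.linalg.inv(info)
            return LogisticFit(float(b[0]), float(b[1]),
                               float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1])),
                               it)
    raise SeparationError(f"IRLS did not converge in {max_iter} iterations")
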