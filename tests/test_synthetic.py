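"""Synthetic cohort generator: marginal fidelity, link calibration and
parameter recovery."""

import numpy as np
import pytest

from lapchole.synthetic import (
    CalibrationError,
    CohortSpec,
    SeparationError,
    calibrate_link,
    empirical_auc,
    generate_cohort,
    generate_frame,
    recover_link,
)

N_BIG = 100_000


@pytest.fixture(scope="module")
def big_frame():
    return generate_frame(CohortSpec(n=N_BIG, seed=123))


def _within_3se(p_hat, p, n):
    return abs(p_hat - p) <= 3 * np.sqrt(p * (1 - p) / n) + 1e-12


class TestGeneration:
    def test_determinism(self):
        spec = CohortSpec(n=300, seed=9)
        assert generate_cohort(spec) == generate_cohort(spec)

    def test_categorical_marginals_within_3se(self, big_frame):
        df, n = big_frame, N_BIG
        spec = CohortSpec()
        assert _within_3se((df["sex"] == "female").mean(), spec.p_female, n)
        for level, p in zip([1, 2, 3, 4], spec.asa_probs):
            assert _within_3se((df["asa"] == level).mean(), p, n)
        for level, p in zip(
            ["pancreatitis", "biliary_colic", "choledocholithiasis", "cholecystitis"],
            spec.diagnosis_probs,
        ):
            assert _within_3se((df["diagnosis"] == level).mean(), p, n)
        for level, p in zip(["elective", "delayed", "emergency"], spec.admission_probs):
            assert _within_3se((df["admission"] == level).mean(), p, n)
        assert _within_3se((df["preop_ercp"] == 1).mean(), spec.p_ercp, n)

    def test_continuous_marginals(self, big_frame):
        df = big_frame
        assert df["wall_thickness_mm"].mean() == pytest.approx(3.3, abs=0.05)
        assert df["cbd_diameter_mm"].mean() == pytest.approx(4.9, abs=0.05)
        assert df["age"].min() >= 18
        assert (df["wall_thickness_mm"] >= 0).all()

    def test_score_support(self, big_frame):
        scores = big_frame["score_total"]
        assert scores.min() >= 0
        assert scores.max() <= 19

    def test_prevalence_near_target(self, big_frame):
        g = big_frame[big_frame["difficulty"].notna()]
        prev = (g["difficulty"] == "difficult").mean()
        assert prev == pytest.approx(CohortSpec().target_prevalence, abs=0.01)

    def test_difficult_cases_get_high_grades(self, big_frame):
        g = big_frame[big_frame["difficulty"].notna()]
        assert set(g.loc[g["difficulty"] == "difficult", "intraop_grade"]) <= {3, 4}
        assert set(g.loc[g["difficulty"] == "easy", "intraop_grade"]) <= {1, 2}

    def test_null_link_gives_auc_half(self):
        spec = CohortSpec(n=20_000, seed=21, alpha=0.0, beta=0.0)
        df = generate_frame(spec)
        g = df[df["difficulty"].notna()]
        auc = empirical_auc(g["score_total"], g["difficulty"])
        assert auc == pytest.approx(0.5, abs=0.02)

    def test_exclusion_injection_rates(self):
        rates = (0.02, 0.04, 0.01)
        spec = CohortSpec(n=50_000, seed=33, exclusion_rates=rates)
        df = generate_frame(spec)
        assert _within_3se(df["planned_open"].mean(), rates[0], spec.n)
        assert _within_3se(df["malignancy"].mean(), rates[2], spec.n)
        missing = df["score_total"].isna() & (df["planned_open"] == 0)
        assert _within_3se(missing.mean(), rates[1], spec.n)

    def test_coupled_covariates_shift_wall(self):
        spec = CohortSpec(n=30_000, seed=4, couple_covariates=True)
        df = generate_frame(spec)
        chole = df["diagnosis"] == "cholecystitis"
        shift = df.loc[chole, "wall_thickness_mm"].mean() - \
            df.loc[~chole, "wall_thickness_mm"].mean()
        assert shift == pytest.approx(spec.cholecystitis_wall_shift, abs=0.1)


class TestCalibration:
    def test_target_auc_reached(self):
        spec = CohortSpec(seed=0)
        res = calibrate_link(spec, 0.88, tolerance=0.002, n_eval=50_000)
        assert res.achieved_auc == pytest.approx(0.88, abs=0.002)
        # round trip: generate with the calibrated link at a fresh seed
        spec2 = spec.model_copy(update={
            "alpha": res.alpha, "beta": res.beta, "n": 50_000, "seed": 77})
        df = generate_frame(spec2)
        g = df[df["difficulty"].notna()]
        assert empirical_auc(g["score_total"], g["difficulty"]) == pytest.approx(
            0.88, abs=0.01)

    def test_monotone_in_target(self):
        spec = CohortSpec(seed=0)
        betas = [calibrate_link(spec, t, tolerance=0.005, n_eval=20_000).beta
                 for t in (0.7, 0.8, 0.9)]
        assert betas == sorted(betas)

    def test_unreachable_target_raises(self):
        with pytest.raises(CalibrationError):
            calibrate_link(CohortSpec(seed=0), 0.9999, tolerance=1e-4, n_eval=5_000)

    def test_invalid_target_rejected(self):
        with pytest.raises(CalibrationError):
            calibrate_link(CohortSpec(), 0.4)


class TestRecovery:
    def test_recovers_truth_within_3se(self, big_frame):
        g = big_frame[big_frame["difficulty"].notna()]
        fit = recover_link(g["score_total"].to_numpy(), g["difficulty"].tolist())
        spec = CohortSpec()
        assert abs(fit.alpha - spec.alpha) <= 3 * fit.se_alpha
        assert abs(fit.beta - spec.beta) <= 3 * fit.se_beta

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        df = generate_frame(CohortSpec(n=5_000, seed=8))
        g = df[df["difficulty"].notna()]
        s = g["score_total"].to_numpy(dtype=float)
        y = (g["difficulty"] == "difficult").astype(float).to_numpy()
        fit = recover_link(s, g["difficulty"].tolist())
        X = np.column_stack([np.ones_like(s), s])
        ref = sm.Logit(y, X).fit(disp=0)
        assert fit.alpha == pytest.approx(ref.params[0], abs=1e-6)
        assert fit.beta == pytest.approx(ref.params[1], abs=1e-6)
        assert fit.se_beta == pytest.approx(ref.bse[1], rel=1e-4)

    def test_null_truth_ci_covers_zero(self):
        spec = CohortSpec(n=20_000, seed=13, alpha=0.0, beta=0.0)
        df = generate_frame(spec)
        g = df[df["difficulty"].notna()]
        fit = recover_link(g["score_total"].to_numpy(), g["difficulty"].tolist())
        assert abs(fit.beta) <= 3 * fit.se_beta

    def test_tiny_or_separated_input_never_crashes(self):
        # separated: every difficult case outscores every easy one
        scores = [0, 1, 2, 8, 9, 10]
        labels = ["easy"] * 3 + ["difficult"] * 3
        try:
            fit = recover_link(scores, labels)
            assert np.isfinite(fit.beta)
        except SeparationError:
            pass
        # tiny but overlapping input returns finite estimates
        scores = [2, 4, 6, 3, 5, 3, 5, 7, 4, 6]
        labels = ["easy"] * 5 + ["difficult"] * 5
        fit = recover_link(scores, labels)
        assert np.isfinite(fit.alpha) and np.isfinite(fit.beta)
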