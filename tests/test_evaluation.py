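import numpy as np
import pandas as pd
import pytest
from scipy import stats

from prfr.evaluation import (
    auc,
    balanced_split,
    calibration_bins,
    clinical_covariate_screen,
    final_model_eval,
    repeated_cv_performance,
    subsample_validation,
)
from prfr.models import PreconditionedRandomForest, fit_prfr, ForestConfig


def pairwise_auc(scores, outcome):
    """Exhaustive concordance oracle: fraction of case/control pairs
    where the case outscores the control, ties counting one half."""
    scores = np.asarray(scores, float)
    outcome = np.asarray(outcome)
    cases = scores[outcome == 1]
    controls = scores[outcome == 0]
    total = conc = 0.0
    for c in cases:
        for k in controls:
            total += 1
            conc += 1.0 if c > k else (0.5 if c == k else 0.0)
    return conc / total


class TestAuc:
    def test_hand_example(self):
        assert auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert auc([0, 0, 1, 1], [0, 0, 1, 1]) == 1.0

    def test_all_tied_scores(self):
        assert auc([0.3] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [1, 1])

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = rng.integers(6, 50)
            scores = rng.choice([0.1, 0.2, 0.5, 0.7], size=n)
            outcome = rng.binomial(1, 0.5, n)
            if outcome.min() == outcome.max():
                continue
            assert auc(scores, outcome) == pytest.approx(
                pairwise_auc(scores, outcome), abs=1e-12
            )


class TestBalancedSplit:
    def test_two_thirds_of_365(self):
        # 74 cases / 291 controls: training gets floor(365 * 2/3) = 243
        y = np.r_[np.ones(74), np.zeros(291)]
        spec = balanced_split(y, seed=1)
        assert len(spec.train_idx) == 243
        assert len(spec.val_idx) == 122
        assert abs(spec.event_rate_train - spec.event_rate_val) < 0.01

    def test_loose_tolerance_accepts_first_draw(self):
        y = np.r_[np.ones(30), np.zeros(70)]
        spec = balanced_split(y, tolerance=1.0, seed=2)
        assert spec.n_attempts == 1

    def test_deterministic_given_seed(self):
        y = np.r_[np.ones(40), np.zeros(60)]
        a = balanced_split(y, seed=3)
        b = balanced_split(y, seed=3)
        np.testing.assert_array_equal(a.train_idx, b.train_idx)

    def test_partition_is_disjoint_and_covering(self):
        y = np.r_[np.ones(25), np.zeros(75)]
        spec = balanced_split(y, seed=4)
        both = np.concatenate([spec.train_idx, spec.val_idx])
        assert sorted(both) == list(range(100))

    def test_too_few_cases_rejected(self):
        with pytest.raises(ValueError):
            balanced_split(np.r_[np.ones(1), np.zeros(20)])


class TestRepeatedCv:
    def test_repeat_and_fold_counts(self, small_cohort):
        g, _, pheno, _ = small_cohort
        y = pheno["outcome"].to_numpy()
        X = g.to_frame()
        est = PreconditionedRandomForest(alpha=0.05, n_trees=30, random_state=0)
        cv = repeated_cv_performance(est, X.iloc[:200], y[:200],
                                     X.iloc[200:], y[200:],
                                     folds=5, repeats=1, seed=0)
        assert len(cv.aucs) + cv.n_failed == 5
        assert ((cv.aucs >= 0) & (cv.aucs <= 1)).all()


class TestCalibrationBins:
    def test_scores_equal_outcomes_perfectly_calibrated(self):
        y = np.array([0, 1] * 6)
        report = calibration_bins(y.astype(float), y, n_bins=6)
        assert report.attrs["chi2"] == pytest.approx(0.0, abs=1e-6)
        assert report.attrs["p"] == pytest.approx(1.0, abs=1e-6)

    def test_hand_computed_chi_square(self):
        # 2 bins of 4: scores give E_events (1.0, 3.0); observed (2, 2)
        scores = np.array([0.2, 0.2, 0.3, 0.3, 0.7, 0.7, 0.8, 0.8])
        outcome = np.array([1, 1, 0, 0, 1, 0, 0, 1])
        report = calibration_bins(scores, outcome, n_bins=2)
        exp = ((2 - 1.0) ** 2 / 1.0 + (2 - 3.0) ** 2 / 3.0
               + (2 - 3.0) ** 2 / 3.0 + (2 - 1.0) ** 2 / 1.0)
        assert report.attrs["chi2"] == pytest.approx(exp, abs=1e-10)
        assert report.attrs["df"] == 2
        np.testing.assert_allclose(report["predicted"], [0.25, 0.75])
        np.testing.assert_allclose(report["observed"], [0.5, 0.5])

    def test_uniform_scores_match_event_rate(self):
        rng = np.random.default_rng(7)
        y = rng.binomial(1, 0.5, 600)
        report = calibration_bins(np.full(600, 0.5), y, n_bins=6)
        assert np.allclose(report["predicted"], 0.5)
        # each bin of 100: binomial 4-sigma band around 0.5
        assert (np.abs(report["observed"] - 0.5) < 0.2).all()
        assert report.attrs["p"] > 0.05

    def test_bins_partition_and_risk_nondecreasing(self):
        rng = np.random.default_rng(8)
        s = rng.uniform(size=100)
        y = rng.binomial(1, s)
        report = calibration_bins(s, y, n_bins=6)
        assert report["n"].sum() == 100
        assert (np.diff(report["predicted"]) >= 0).all()

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="bins"):
            calibration_bins(np.arange(5) / 5, np.array([0, 1, 0, 1, 0]), n_bins=6)


class TestFinalModelEval:
    def test_anti_calibrated_scores_invert(self, small_cohort):
        """Scoring with 1 - risk flips the AUC below one half and makes
        observed incidence fall across bins."""
        g, _, pheno, truth = small_cohort
        y = pheno["outcome"].to_numpy()
        eta = truth["linear_predictor"]
        good = 1 / (1 + np.exp(-eta))
        a_good = auc(good, y)
        a_bad = auc(1 - good, y)
        assert a_good > 0.5 > a_bad
        report = calibration_bins(1 - good, y, n_bins=6)
        obs = report["observed"].to_numpy()
        slope = np.polyfit(np.arange(6), obs, 1)[0]
        assert slope < 0

    def test_small_validation_rejected(self, small_cohort):
        g, _, pheno, _ = small_cohort
        y = pheno["outcome"].to_numpy()
        X = g.to_frame()
        est = PreconditionedRandomForest(alpha=0.05, n_trees=10, random_state=0)
        with pytest.raises(ValueError, match="bins"):
            final_model_eval(est, X.iloc[:200], y[:200], X.iloc[:4], y[:4])


@pytest.fixture(scope="module")
def fixed_model(small_cohort):
    g, _, pheno, _ = small_cohort
    X = g.to_frame()
    rng = np.random.default_rng(0)
    target = np.clip(0.5 + 0.2 * rng.normal(size=200), 0.01, 0.99)
    return fit_prfr(X.iloc[:200, :30], target, ForestConfig(n_trees=30))


class TestSubsampleValidation:

    def test_full_fraction_reproduces_full_auc(self, small_cohort, fixed_model):
        g, _, pheno, _ = small_cohort
        y = pheno["outcome"].to_numpy()
        X_val = g.to_frame().iloc[200:, :30]
        aucs = subsample_validation(fixed_model, X_val, y[200:], frac=1.0, repeats=5)
        full = auc(fixed_model.predict(X_val), y[200:])
        np.testing.assert_allclose(aucs, full)

    def test_deterministic_and_near_full_auc(self, small_cohort, fixed_model):
        g, _, pheno, _ = small_cohort
        y = pheno["outcome"].to_numpy()
        X_val = g.to_frame().iloc[200:, :30]
        a = subsample_validation(fixed_model, X_val, y[200:], frac=0.6,
                                 repeats=50, seed=3)
        b = subsample_validation(fixed_model, X_val, y[200:], frac=0.6,
                                 repeats=50, seed=3)
        np.testing.assert_array_equal(a, b)
        full = auc(fixed_model.predict(X_val), y[200:])
        assert abs(a.mean() - full) < 0.02


class TestClinicalCovariateScreen:
    def test_null_covariate_or_near_one_not_retained(self):
        rng = np.random.default_rng(9)
        hits = 0
        ors = []
        for _ in range(50):
            x = rng.normal(size=400)
            y = rng.binomial(1, 0.5, 400)
            t = clinical_covariate_screen(pd.DataFrame({"c": x}), y)
            hits += int(t["retained"].iloc[0])
            ors.append(t["odds_ratio"].iloc[0])
        assert hits == 0  # alpha = 0.001 on null data
        assert np.median(ors) == pytest.approx(1.0, abs=0.1)

    def test_strong_covariate_power(self):
        """An OR-3.5 covariate at n=157 passes the alpha=0.001 screen in
        the majority of replicates (its Wald power there is ~0.67)."""
        rng = np.random.default_rng(10)
        beta = np.log(3.5)
        hits, betas_pos = 0, 0
        n_rep = 30
        for _ in range(n_rep):
            x = rng.binomial(1, 0.5, 157).astype(float)
            eta = -0.4 + beta * x
            y = rng.binomial(1, 1 / (1 + np.exp(-eta)))
            t = clinical_covariate_screen(pd.DataFrame({"adt": x}), y)
            hits += int(t["retained"].iloc[0])
            betas_pos += int(t["odds_ratio"].iloc[0] > 1)
        assert hits >= n_rep // 2
        assert betas_pos >= n_rep - 2

    def test_constant_covariate_skipped(self):
        y = np.array([0, 1] * 10)
        with pytest.warns(UserWarning, match="constant"):
            t = clinical_covariate_screen(
                pd.DataFrame({"flat": np.ones(20), "ok": np.arange(20.0)}), y
            )
        assert list(t["covariate"]) == ["ok"]
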