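import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from prfr.models import (
    BinaryRandomForest,
    ForestConfig,
    LassoLogistic,
    PreconditionedLasso,
    PreconditionedRandomForest,
    fit_ols,
    fit_pl,
    fit_prfr,
    fit_rfc,
    oob_permutation_importance,
)


@pytest.fixture(scope="module")
def noisy_panel():
    """One strongly predictive dosage column among noise columns."""
    rng = np.random.default_rng(10)
    n = 120
    signal = rng.binomial(2, 0.4, n).astype(float)
    target = (0.4 * signal + 0.05 * rng.normal(size=n) + 0.2).clip(0.01, 0.99)
    noise = rng.binomial(2, 0.3, size=(n, 6)).astype(float)
    X = pd.DataFrame(np.column_stack([signal, noise]),
                     columns=[f"rs{j}" for j in range(7)])
    return X, target


def test_mtry_is_floor_sqrt():
    assert ForestConfig().resolve_mtry(749) == 27
    assert ForestConfig().resolve_mtry(367) == 19
    assert ForestConfig(mtry=5).resolve_mtry(749) == 5
    assert ForestConfig().resolve_mtry(1) == 1


def test_constant_target_predicts_constant(noisy_panel):
    X, _ = noisy_panel
    m = fit_prfr(X, np.full(len(X), 0.37), ForestConfig(n_trees=50))
    np.testing.assert_allclose(m.predict(X), 0.37)


def test_forest_prediction_is_mean_of_trees(noisy_panel):
    X, target = noisy_panel
    m = fit_prfr(X.iloc[:50], target[:50], ForestConfig(n_trees=40, seed=2))
    x = m._align(X.iloc[50:60])
    per_tree = np.stack([t.predict(x) for t in m.estimator.estimators_])
    np.testing.assert_allclose(m.predict(X.iloc[50:60]), per_tree.mean(axis=0),
                               atol=1e-12)


class TestPredictContract:
    def test_column_permutation_invariant(self, noisy_panel):
        X, target = noisy_panel
        m = fit_prfr(X, target, ForestConfig(n_trees=30, seed=1))
        shuffled = X.iloc[:, ::-1]
        np.testing.assert_allclose(m.predict(X), m.predict(shuffled))

    def test_unknown_feature_rejected(self, noisy_panel):
        X, target = noisy_panel
        m = fit_prfr(X, target, ForestConfig(n_trees=10))
        with pytest.raises(KeyError, match="absent"):
            m.predict(X.drop(columns=["rs0"]))

    def test_empty_sample_set(self, noisy_panel):
        X, target = noisy_panel
        m = fit_prfr(X, target, ForestConfig(n_trees=10))
        assert m.predict(X.iloc[:0]).shape == (0,)

    def test_missing_dosages_imputed_with_training_means(self, noisy_panel):
        X, target = noisy_panel
        m = fit_prfr(X, target, ForestConfig(n_trees=30, seed=1))
        X_holes = X.copy()
        X_holes.iloc[0, 0] = np.nan
        filled = X.copy()
        filled.iloc[0, 0] = m.impute_means[0]
        np.testing.assert_allclose(m.predict(X_holes), m.predict(filled))


class TestComparators:
    def test_ols_limit_matches_least_squares(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.binomial(2, 0.4, size=(60, 4)).astype(float),
                         columns=list("abcd"))
        y = rng.uniform(0.2, 0.8, 60)
        m = fit_ols(X, y)
        beta, *_ = np.linalg.lstsq(np.column_stack([np.ones(60), X.values]),
                                   y, rcond=None)
        pred = np.column_stack([np.ones(60), X.values]) @ beta
        np.testing.assert_allclose(m.predict(X), pred, atol=1e-6)

    def test_pl_deterministic_given_seed(self, noisy_panel):
        X, target = noisy_panel
        a = fit_pl(X, target, seed=5)
        b = fit_pl(X, target, seed=5)
        np.testing.assert_array_equal(a.predict(X), b.predict(X))

    def test_rfc_rejects_single_class(self, noisy_panel):
        X, _ = noisy_panel
        with pytest.raises(ValueError, match="both classes"):
            fit_rfc(X, np.zeros(len(X)))

    def test_rfc_vote_fractions_separate_classes(self):
        rng = np.random.default_rng(4)
        n = 80
        y = np.r_[np.zeros(40), np.ones(40)]
        sep = np.r_[np.zeros(40), np.full(40, 2.0)]
        X = pd.DataFrame({"sep": sep,
                          "noise": rng.binomial(2, 0.3, n).astype(float)})
        m = fit_rfc(X, y, ForestConfig(n_trees=50, seed=1))
        scores = m.predict(X)
        assert scores[y == 1].mean() > 0.9
        assert scores[y == 0].mean() < 0.1

    def test_llr_probabilities_in_unit_interval(self, noisy_panel):
        X, target = noisy_panel
        y = (target > np.median(target)).astype(int)
        from prfr.models import fit_llr

        m = fit_llr(X, y, seed=2)
        p = m.predict(X)
        assert ((p >= 0) & (p <= 1)).all()


class TestOobImportance:
    def test_predictive_snp_outranks_noise(self, noisy_panel):
        X, target = noisy_panel
        m = fit_prfr(X, target, ForestConfig(n_trees=300, seed=7))
        imp = oob_permutation_importance(m, X)
        assert imp.loc[imp["snp_id"] == "rs0", "rank"].iloc[0] == 1
        top = imp.sort_values("rank")["delta_mse"].to_numpy()
        assert top[0] > top[1]

    def test_independent_snp_near_zero(self, noisy_panel):
        X, target = noisy_panel
        m = fit_prfr(X, target, ForestConfig(n_trees=300, seed=7))
        imp = oob_permutation_importance(m, X)
        signal = imp.loc[imp["snp_id"] == "rs0", "delta_mse"].iloc[0]
        noise = imp.loc[imp["snp_id"] != "rs0", "delta_mse"]
        assert noise.abs().max() < 0.2 * signal

    def test_permutation_seed_stability(self, noisy_panel):
        """Re-permuting with a different seed moves scores by less than
        the gap that separates signal from noise."""
        X, target = noisy_panel
        m = fit_prfr(X, target, ForestConfig(n_trees=300, seed=7))
        a = oob_permutation_importance(m, X, seed=1)
        b = oob_permutation_importance(m, X, seed=2)
        assert a.loc[a["rank"] == 1, "snp_id"].iloc[0] == \
            b.loc[b["rank"] == 1, "snp_id"].iloc[0]
        np.testing.assert_allclose(a["delta_mse"], b["delta_mse"], atol=5e-3)

    def test_rfc_importance_supported(self):
        rng = np.random.default_rng(8)
        n = 100
        y = rng.binomial(1, 0.5, n).astype(float)
        sig = np.clip(2 * y + rng.binomial(1, 0.2, n) - rng.binomial(1, 0.2, n), 0, 2)
        X = pd.DataFrame({"sig": sig,
                          "noise": rng.binomial(2, 0.3, n).astype(float)})
        m = fit_rfc(X, y, ForestConfig(n_trees=100, seed=3))
        imp = oob_permutation_importance(m, X)
        assert imp.loc[imp["snp_id"] == "sig", "rank"].iloc[0] == 1

    def test_non_forest_model_rejected(self, noisy_panel):
        X, target = noisy_panel
        m = fit_pl(X, target)
        with pytest.raises(ValueError, match="forest"):
            oob_permutation_importance(m, X)


class TestScreenedEstimators:
    @pytest.mark.parametrize("cls", [PreconditionedRandomForest, PreconditionedLasso,
                                     BinaryRandomForest, LassoLogistic])
    def test_sklearn_clone_roundtrip(self, cls):
        est = cls(alpha=0.01, random_state=3)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()

    def test_fit_screens_and_predicts(self, small_cohort):
        g, _, pheno, truth = small_cohort
        y = pheno["outcome"].to_numpy()
        est = PreconditionedRandomForest(alpha=0.01, n_trees=100, random_state=0)
        est.fit(g.to_frame(), y)
        assert len(est.support_) >= 1
        scores = est.predict(g.to_frame())
        assert scores.shape == (g.n_samples,)
        assert ((scores > 0) & (scores < 1)).all()
        # screened-in SNPs are enriched for the planted causal set
        causal = set(truth["causal_snp_ids"])
        assert len(causal & set(est.support_)) >= 1

    def test_training_artifacts_ignore_validation_data(self, small_cohort):
        """No leakage: the fitted state depends only on training rows."""
        g, _, pheno, _ = small_cohort
        y = pheno["outcome"].to_numpy()
        X = g.to_frame()
        est1 = PreconditionedRandomForest(alpha=0.01, n_trees=50, random_state=1)
        est1.fit(X.iloc[:200], y[:200])
        est2 = PreconditionedRandomForest(alpha=0.01, n_trees=50, random_state=1)
        est2.fit(X.iloc[:200], y[:200])
        _ = est2.predict(X.iloc[200:])  # touching other rows changes nothing
        assert est1.support_ == est2.support_
        np.testing.assert_array_equal(est1.pseudo_outcomes_, est2.pseudo_outcomes_)
        np.testing.assert_array_equal(est1.predict(X.iloc[:10]),
                                      est2.predict(X.iloc[:10]))

    def test_covariate_columns_bypass_screen(self, small_cohort):
        g, _, pheno, _ = small_cohort
        y = pheno["outcome"].to_numpy()
        X = g.to_frame().copy()
        rng = np.random.default_rng(9)
        X["age"] = rng.normal(63, 7, g.n_samples)
        est = PreconditionedRandomForest(alpha=0.01, n_trees=50, random_state=1,
                                         covariates=["age"])
        est.fit(X, y)
        assert est.support_[-1] == "age"
        assert est.n_snp_features_ == len(est.support_) - 1
        est.predict(X)
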