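"""PRFR and comparator models, plus out-of-bag permutation importance.

The headline estimator, :class:`PreconditionedRandomForest`, wraps the
full model-building recipe behind a scikit-learn ``fit``/``predict``
surface:

1. screen SNPs on the 3x2 genotype-by-outcome chi-square (p <= alpha),
2. rank survivors by univariate logistic CV AUC,
3. pre-condition the binary outcome into continuous pseudo-outcomes
   (PCA panel + logistic fit, saturating panel size),
4. regress the pseudo-outcomes on *all* screened SNPs with a random
   forest (1000 trees, mtry = floor(sqrt(p)), nodes with fewer than 5
   samples left unsplit).

Because screening and ranking live inside ``fit``, cross-validating the
estimator re-derives everything from each fold's training portion —
no information leaks from held-out samples.

Comparators share the same screen: :class:`PreconditionedLasso` (PL,
lasso on pseudo-outcomes), :class:`BinaryRandomForest` (RFC, forest
classifier on the raw outcome, scores = case-vote fractions) and
:class:`LassoLogistic` (LLR, L1 logistic on the raw outcome).

Importance of a SNP is the mean over trees of MSEp - MSE: each tree's
out-of-bag MSE before and after permuting that SNP's values within the
tree's out-of-bag samples.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, clone
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import LassoCV, LinearRegression, LogisticRegressionCV
from sklearn.utils import check_random_state

from .association import univariate_filter
from .io import GenotypeMatrix
from .preconditioning import PCLogisticPreconditioner

def _bootstrap_indices(random_state, n_samples, n_samples_bootstrap):
    """Recreate a tree's bootstrap sample from its stored seed.

    Matches scikit-learn's unweighted draw (RandomState.randint), so the
    complement is exactly the tree's out-of-bag set.
    """
    return check_random_state(random_state).randint(0, n_samples, n_samples_bootstrap)


@dataclass
class ForestConfig:
    """Forest hyperparameters: 1000 trees, sqrt feature subsampling,
    and no split of nodes holding fewer than 5 samples."""

    n_trees: int = 1000
    mtry: int | str = "sqrt"
    min_node_samples: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.min_node_samples < 1:
            raise ValueError("min_node_samples must be >= 1")

    def resolve_mtry(self, p: int) -> int:
        if self.mtry == "sqrt":
            return max(1, math.floor(math.sqrt(p)))
        return int(self.mtry)


def _as_matrix(g, feature_ids=None):
    """Coerce genotype input to (float matrix, feature id list)."""
    if isinstance(g, GenotypeMatrix):
        return g.values.astype(float), list(g.snp_ids)
    if isinstance(g, pd.DataFrame):
        return g.to_numpy(dtype=float), [str(c) for c in g.columns]
    arr = np.asarray(g, dtype=float)
    if feature_ids is None:
        feature_ids = [f"x{j}" for j in range(arr.shape[1])]
    return arr, list(feature_ids)


def _impute(x: np.ndarray, means: np.ndarray) -> np.ndarray:
    if np.isnan(x).any():
        x = np.where(np.isnan(x), means[None, :], x)
    return x


@dataclass
class FittedModel:
    """A fitted risk model: kind, feature ids, imputation means, state.

    ``predict`` accepts a GenotypeMatrix, a DataFrame (columns matched
    by id, any order), or a bare array laid out like the training
    features. Missing dosages are filled with the stored training
    means. Scores are continuous risk — ordinal, not necessarily
    calibrated probabilities (PL's linear predictions may leave [0, 1]).
    """

    kind: str
    feature_ids: list[str]
    impute_means: np.ndarray
    estimator: object
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def _align(self, g_new) -> np.ndarray:
        if isinstance(g_new, GenotypeMatrix):
            g_new = g_new.to_frame()
        if isinstance(g_new, pd.DataFrame):
            missing = [f for f in self.feature_ids if f not in g_new.columns]
            if missing:
                raise KeyError(f"features absent from input: {missing[:5]}")
            x = g_new.loc[:, self.feature_ids].to_numpy(dtype=float)
        else:
            x = np.asarray(g_new, dtype=float)
            if x.ndim != 2 or x.shape[1] != len(self.feature_ids):
                raise ValueError(
                    f"expected {len(self.feature_ids)} feature columns, got {x.shape}"
                )
        return _impute(x, self.impute_means)

    def predict(self, g_new) -> np.ndarray:
        x = self._align(g_new)
        if x.shape[0] == 0:
            return np.empty(0)
        if self.kind in ("RFC", "LLR"):
            return self.estimator.predict_proba(x)[:, 1]
        return self.estimator.predict(x)


def _forest_regressor(cfg: ForestConfig, p: int) -> RandomForestRegressor:
    return RandomForestRegressor(
        n_estimators=cfg.n_trees,
        max_features=cfg.resolve_mtry(p),
        min_samples_split=cfg.min_node_samples,
        min_samples_leaf=1,
        bootstrap=True,
        random_state=cfg.seed,
        n_jobs=1,
    )


def fit_prfr(g_train, pseudo, cfg: ForestConfig | None = None) -> FittedModel:
    """Random-forest regression of pseudo-outcomes on screened SNPs."""
    cfg = cfg or ForestConfig()
    x, ids = _as_matrix(g_train)
    if x.shape[1] == 0:
        raise ValueError("no features to fit")
    if isinstance(pseudo, pd.DataFrame):
        pseudo = pseudo["value"].to_numpy()
    y = np.asarray(pseudo, dtype=float)
    means = np.nanmean(x, axis=0)
    x = _impute(x, means)
    forest = _forest_regressor(cfg, x.shape[1]).fit(x, y)
    return FittedModel("PRFR", ids, means, forest, cfg.seed,
                       {"mtry": cfg.resolve_mtry(x.shape[1]), "target": y})


def fit_pl(g_train, pseudo, cv: int = 5, n_alphas: int = 100,
           seed: int = 0) -> FittedModel:
    """Lasso regression of pseudo-outcomes; penalty picked by internal CV.

    A penalty of ``numpy.inf`` short-circuits to the intercept-only
    model; otherwise a 100-value log-spaced path is cross-validated.
    """
    x, ids = _as_matrix(g_train)
    if isinstance(pseudo, pd.DataFrame):
        pseudo = pseudo["value"].to_numpy()
    y = np.asarray(pseudo, dtype=float)
    means = np.nanmean(x, axis=0)
    x = _impute(x, means)
    model = LassoCV(alphas=n_alphas, cv=cv, random_state=seed, max_iter=5000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(x, y)
    if np.all(model.coef_ == 0):
        warnings.warn("lasso selected the all-zero solution; intercept-only model")
    return FittedModel("PL", ids, means, model, seed)


def fit_ols(g_train, pseudo) -> FittedModel:
    """Unpenalized least squares (the lasso path's penalty-0 limit)."""
    x, ids = _as_matrix(g_train)
    if isinstance(pseudo, pd.DataFrame):
        pseudo = pseudo["value"].to_numpy()
    means = np.nanmean(x, axis=0)
    x = _impute(x, means)
    return FittedModel("PL", ids, means, LinearRegression().fit(x, np.asarray(pseudo, float)))


def fit_rfc(g_train, outcome_binary, cfg: ForestConfig | None = None) -> FittedModel:
    """Random-forest classifier on the raw binary outcome.

    Scores are case-vote fractions (mean per-tree class-1 probability).
    """
    cfg = cfg or ForestConfig()
    x, ids = _as_matrix(g_train)
    y = np.asarray(outcome_binary)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    means = np.nanmean(x, axis=0)
    x = _impute(x, means)
    forest = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        max_features=cfg.resolve_mtry(x.shape[1]),
        min_samples_split=cfg.min_node_samples,
        min_samples_leaf=1,
        bootstrap=True,
        random_state=cfg.seed,
        n_jobs=1,
    ).fit(x, y)
    return FittedModel("RFC", ids, means, forest, cfg.seed, {"target": y.astype(float)})


def fit_llr(g_train, outcome_binary, cv: int = 5, n_alphas: int = 100,
            seed: int = 0) -> FittedModel:
    """L1-penalized logistic regression on the raw binary outcome."""
    x, ids = _as_matrix(g_train)
    y = np.asarray(outcome_binary)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    means = np.nanmean(x, axis=0)
    x = _impute(x, means)
    model = LogisticRegressionCV(
        Cs=n_alphas, cv=cv, penalty="l1", solver="liblinear",
        random_state=seed, max_iter=1000,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(x, y)
    return FittedModel("LLR", ids, means, model, seed)


def predict(m: FittedModel, g_new) -> np.ndarray:
    """Risk scores for new samples (wrapper over ``m.predict``)."""
    return m.predict(g_new)


def oob_permutation_importance(m: FittedModel, g_train, target=None,
                               seed: int | None = None) -> pd.DataFrame:
    """Per-SNP mean out-of-bag MSE increase under permutation.

    For every tree: compute the MSE of its predictions on its
    out-of-bag samples, then for each SNP permute that SNP's values
    within the out-of-bag rows and recompute (MSEp). The importance is
    the average of MSEp - MSE across trees with at least two
    out-of-bag samples; larger means the forest leaned on the SNP.

    ``target`` defaults to the training target stored at fit time
    (pseudo-outcomes for PRFR, the 0/1 outcome for RFC).
    """
    if m.kind not in ("PRFR", "RFC"):
        raise ValueError(f"importance requires a forest model, got {m.kind}")
    forest = m.estimator
    x = m._align(g_train)
    if target is None:
        target = m.meta.get("target")
        if target is None:
            raise ValueError("no stored training target; pass `target`")
    y = np.asarray(target, dtype=float)
    n, p = x.shape
    rng_root = np.random.SeedSequence(m.seed if seed is None else seed)
    tree_seeds = rng_root.generate_state(len(forest.estimators_))

    delta_sum = np.zeros(p)
    delta_n = np.zeros(p, dtype=int)
    n_boot = forest._n_samples_bootstrap if hasattr(forest, "_n_samples_bootstrap") else n
    for tree, ts in zip(forest.estimators_, tree_seeds):
        sampled = _bootstrap_indices(tree.random_state, n, n_boot)
        oob_mask = np.ones(n, dtype=bool)
        oob_mask[sampled] = False
        oob_idx = np.flatnonzero(oob_mask)
        if oob_idx.size < 2:
            continue
        x_oob = x[oob_idx]
        y_oob = y[oob_idx]
        rng = np.random.default_rng(ts)
        # one batched predict per tree: base block + one permuted block per SNP
        blocks = np.tile(x_oob, (p + 1, 1))
        m_oob = oob_idx.size
        for j in range(p):
            blk = blocks[(j + 1) * m_oob:(j + 2) * m_oob]
            blk[:, j] = rng.permutation(x_oob[:, j])
        if m.kind == "RFC":
            proba = tree.predict_proba(blocks)[:, 1]
            preds = proba
        else:
            preds = tree.predict(blocks)
        preds = preds.reshape(p + 1, m_oob)
        mse = np.mean((preds[0] - y_oob) ** 2)
        mse_p = np.mean((preds[1:] - y_oob[None, :]) ** 2, axis=1)
        delta_sum += mse_p - mse
        delta_n += 1
    if (delta_n == 0).all():
        raise ValueError("every tree had a trivial out-of-bag set")
    delta = np.where(delta_n > 0, delta_sum / np.maximum(delta_n, 1), 0.0)
    out = pd.DataFrame({"snp_id": m.feature_ids, "delta_mse": delta})
    order = out["delta_mse"].to_numpy()
    # rank 1 = largest importance; ties broken by snp_id for determinism
    out = out.sort_values(["delta_mse", "snp_id"], ascending=[False, True])
    out["rank"] = np.arange(1, p + 1)
    return out.sort_index()


class _ScreenedModel(BaseEstimator):
    """Shared base: chi-square screening (and optional AUC ranking)
    happen inside ``fit``, so cross-validation re-screens per fold.

    Columns named in ``covariates`` (clinical variables such as age or
    a hormone-therapy flag) bypass the genotype screen and are appended
    unscreened after the ranked SNPs; screen them first with
    :func:`prfr.evaluation.clinical_covariate_screen`.
    """

    _needs_ranking = False

    def __init__(self, alpha=0.001, rank_cv_folds=5, random_state=0,
                 covariates=None):
        self.alpha = alpha
        self.rank_cv_folds = rank_cv_folds
        self.random_state = random_state
        self.covariates = covariates

    def _split_covariates(self, X):
        cov = list(self.covariates or [])
        if not cov:
            return X, None
        if isinstance(X, GenotypeMatrix):
            X = X.to_frame()
        if not isinstance(X, pd.DataFrame):
            raise ValueError("covariate columns require a DataFrame input")
        missing = [c for c in cov if c not in X.columns]
        if missing:
            raise KeyError(f"covariates absent from input: {missing}")
        return X.drop(columns=cov), X.loc[:, cov]

    def _screen(self, X, y):
        x, ids = _as_matrix(X)
        g = GenotypeMatrix(x, [f"S{i}" for i in range(x.shape[0])], ids)
        retained, assoc = univariate_filter(
            g, y, alpha=self.alpha, rank=self._needs_ranking,
            cv_folds=self.rank_cv_folds, seed=self.random_state,
        )
        cols = [ids.index(s) for s in retained]
        x_sel = x[:, cols]
        means = np.nanmean(x_sel, axis=0)
        return _impute(x_sel, means), retained, means, assoc

    def fit(self, X, y):
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("outcome must contain both classes")
        X_snp, X_cov = self._split_covariates(X)
        x_sel, retained, means, assoc = self._screen(X_snp, y)
        self.n_snp_features_ = len(retained)
        if X_cov is not None:
            cov_vals = X_cov.to_numpy(dtype=float)
            cov_means = np.nanmean(cov_vals, axis=0)
            x_sel = np.hstack([x_sel, _impute(cov_vals, cov_means)])
            retained = retained + list(X_cov.columns)
            means = np.concatenate([means, cov_means])
        self.support_ = retained
        self.assoc_ = assoc
        self.impute_means_ = means
        self.model_ = self._fit_core(x_sel, retained, means, y)
        return self

    def predict(self, X) -> np.ndarray:
        if isinstance(X, (GenotypeMatrix,)):
            X = X.to_frame()
        if not isinstance(X, pd.DataFrame):
            # bare array: assume the same column layout as the fit input
            x, ids = _as_matrix(X)
            X = pd.DataFrame(x, columns=self._fit_feature_ids_)
        return self.model_.predict(X)

    def _fit_core(self, x_sel, retained, means, y) -> FittedModel:
        raise NotImplementedError

    def fit_predict_auc(self, X, y, X_val, y_val) -> float:
        from .evaluation import auc as _auc

        self.fit(X, y)
        return _auc(self.predict(X_val), y_val)

    # remember raw feature ids so bare-array predict can be aligned
    def _screen_with_names(self, X):
        _, ids = _as_matrix(X)
        self._fit_feature_ids_ = ids


class PreconditionedRandomForest(_ScreenedModel):
    """Pre-conditioned random forest regression (PRFR).

    Screens SNPs at ``alpha``, ranks them by univariate CV AUC, builds
    continuous pseudo-outcomes from a logistic fit on the leading
    principal components of the saturating top-k panel, and regresses
    the pseudo-outcomes on all screened SNPs with a random forest.
    ``predict`` returns continuous risk scores on the probability scale.

    Fitted attributes: ``support_`` (screened SNP ids, rank order),
    ``preconditioner_``, ``pseudo_outcomes_``, ``model_``.
    """

    _needs_ranking = True

    def __init__(self, alpha=0.001, n_components=2, k_grid=None,
                 saturation_auc=0.99, n_trees=1000, mtry="sqrt",
                 min_node_samples=5, rank_cv_folds=5, random_state=0,
                 covariates=None):
        super().__init__(alpha, rank_cv_folds, random_state, covariates)
        self.n_components = n_components
        self.k_grid = k_grid
        self.saturation_auc = saturation_auc
        self.n_trees = n_trees
        self.mtry = mtry
        self.min_node_samples = min_node_samples

    def fit(self, X, y):
        self._screen_with_names(X)
        return super().fit(X, y)

    def _fit_core(self, x_sel, retained, means, y):
        pre = PCLogisticPreconditioner(
            self.n_components, self.k_grid, self.saturation_auc, self.random_state
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pre.fit(x_sel[:, : self.n_snp_features_], y)  # panel: ranked SNPs only
        self.preconditioner_ = pre
        self.pseudo_outcomes_ = pre.pseudo_outcomes_
        cfg = ForestConfig(self.n_trees, self.mtry, self.min_node_samples,
                           self.random_state)
        fm = fit_prfr(pd.DataFrame(x_sel, columns=retained),
                      pre.pseudo_outcomes_, cfg)
        fm.impute_means = means
        return fm


class PreconditionedLasso(_ScreenedModel):
    """PL: lasso regression on pre-conditioned outcomes."""

    _needs_ranking = True

    def __init__(self, alpha=0.001, n_components=2, k_grid=None,
                 saturation_auc=0.99, cv=5, n_alphas=100,
                 rank_cv_folds=5, random_state=0, covariates=None):
        super().__init__(alpha, rank_cv_folds, random_state, covariates)
        self.n_components = n_components
        self.k_grid = k_grid
        self.saturation_auc = saturation_auc
        self.cv = cv
        self.n_alphas = n_alphas

    def fit(self, X, y):
        self._screen_with_names(X)
        return super().fit(X, y)

    def _fit_core(self, x_sel, retained, means, y):
        pre = PCLogisticPreconditioner(
            self.n_components, self.k_grid, self.saturation_auc, self.random_state
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pre.fit(x_sel[:, : self.n_snp_features_], y)
        self.preconditioner_ = pre
        self.pseudo_outcomes_ = pre.pseudo_outcomes_
        fm = fit_pl(pd.DataFrame(x_sel, columns=retained),
                    pre.pseudo_outcomes_, cv=self.cv, n_alphas=self.n_alphas,
                    seed=self.random_state)
        fm.impute_means = means
        return fm


class BinaryRandomForest(_ScreenedModel):
    """RFC: random-forest classifier on the raw binary outcome."""

    def __init__(self, alpha=0.001, n_trees=1000, mtry="sqrt",
                 min_node_samples=5, random_state=0, covariates=None):
        super().__init__(alpha, 5, random_state, covariates)
        self.n_trees = n_trees
        self.mtry = mtry
        self.min_node_samples = min_node_samples

    def fit(self, X, y):
        self._screen_with_names(X)
        return super().fit(X, y)

    def _fit_core(self, x_sel, retained, means, y):
        cfg = ForestConfig(self.n_trees, self.mtry, self.min_node_samples,
                           self.random_state)
        fm = fit_rfc(pd.DataFrame(x_sel, columns=retained), y, cfg)
        fm.impute_means = means
        return fm


class LassoLogistic(_ScreenedModel):
    """LLR: L1-penalized logistic regression on the raw binary outcome."""

    def __init__(self, alpha=0.001, cv=5, n_alphas=100, random_state=0,
                 covariates=None):
        super().__init__(alpha, 5, random_state, covariates)
        self.cv = cv
        self.n_alphas = n_alphas

    def fit(self, X, y):
        self._screen_with_names(X)
        return super().fit(X, y)

    def _fit_core(self, x_sel, retained, means, y):
        fm = fit_llr(pd.DataFrame(x_sel, columns=retained), y,
                     cv=self.cv, n_alphas=self.n_alphas, seed=self.random_state)
        fm.impute_means = means
        return fm


MODEL_REGISTRY = {
    "prfr": PreconditionedRandomForest,
    "pl": PreconditionedLasso,
    "rfc": BinaryRandomForest,
    "llr": LassoLogistic,
}
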