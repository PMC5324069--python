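"""Pre-conditioning: binary outcomes -> continuous pseudo-outcomes.

The binary endpoint is replaced by the fitted probabilities of a
logistic regression on the leading principal components of the top-k
univariately-ranked SNPs. The panel size k is grown along a grid until
the training AUC of that logistic fit saturates (>= 0.99 by default) —
the smallest saturating k wins, else the k with the best AUC. The
resulting pseudo-outcomes are continuous preliminary estimates of
complication probability, correlated both with the outcome and with the
informative SNPs, and feed the downstream random-forest regression.

Numerical conventions: dosage columns are mean-imputed and standardized
to unit variance before PCA (zero-variance columns dropped); the
logistic fit is unpenalized, falling back to a light ridge under
separation or non-convergence; pseudo-outcomes are clamped to
[1e-6, 1 - 1e-6].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

CLAMP_EPS = 1e-6


def default_k_grid(n_snps: int) -> list[int]:
    """Panel-size grid: 10, 20, 50, 100, 200, then all retained SNPs."""
    grid = [k for k in (10, 20, 50, 100, 200) if k < n_snps]
    grid.append(n_snps)
    return grid


@dataclass
class PreconditioningConfig:
    n_components: int = 2
    k_grid: list[int] | None = None
    saturation_auc: float = 0.99
    seed: int = 0

    def __post_init__(self):
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.k_grid is not None:
            grid = list(self.k_grid)
            if grid != sorted(set(grid)):
                raise ValueError("k_grid must be strictly increasing")
            self.k_grid = grid

    def resolve_grid(self, n_snps: int) -> list[int]:
        grid = self.k_grid if self.k_grid is not None else default_k_grid(n_snps)
        grid = [k for k in grid if k <= n_snps]
        if not grid:
            raise ValueError(f"k_grid has no entry <= {n_snps} retained SNPs")
        return grid


def _impute_and_standardize(x: np.ndarray):
    """Mean-impute NaNs, center, scale to unit variance; drop flat columns."""
    x = np.asarray(x, dtype=float)
    col_mean = np.nanmean(x, axis=0)
    x = np.where(np.isnan(x), col_mean[None, :], x)
    mean = x.mean(axis=0)
    std = x.std(axis=0)
    keep = std > 0
    if not keep.all():
        warnings.warn(f"dropped {int((~keep).sum())} zero-variance column(s) before PCA")
    z = (x[:, keep] - mean[keep]) / std[keep]
    return z, mean, std, keep


def pca_panel(g_sub: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Principal-component scores of a standardized top-k dosage panel."""
    z, *_ = _impute_and_standardize(g_sub)
    if z.shape[1] < n_components:
        raise ValueError(
            f"panel has {z.shape[1]} usable columns < {n_components} components"
        )
    return PCA(n_components=n_components, svd_solver="full").fit_transform(z)


def fit_pc_logistic(scores: np.ndarray, outcome) -> tuple[np.ndarray, float]:
    """Logistic regression of the outcome on PC scores.

    Returns the fitted (training) probabilities and the training AUC.
    Perfect separation / non-convergence triggers a lightly ridge-
    penalized refit.
    """
    y = np.asarray(outcome)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    model = LogisticRegression(C=np.inf, max_iter=1000, tol=1e-10)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        model.fit(scores, y)
        diverged = any(issubclass(w.category, ConvergenceWarning) for w in caught)
    # a huge per-SD log-odds flags (quasi-)separation even when the
    # optimizer reports convergence
    per_sd = np.abs(model.coef_[0]) * scores.std(axis=0)
    if diverged or per_sd.max() > 10:
        warnings.warn("logistic fit unstable (separation?); light ridge refit")
        model = LogisticRegression(C=100.0, max_iter=2000, tol=1e-10)
        model.fit(scores, y)
    prob = model.predict_proba(scores)[:, 1]
    return prob, float(roc_auc_score(y, prob))


class PCLogisticPreconditioner(BaseEstimator):
    """Supervised-PCA + logistic pre-conditioner for binary outcomes.

    ``fit(X, y)`` expects the SNP columns of ``X`` already ordered by
    univariate rank (best first). The estimator selects the saturating
    panel size ``chosen_k_``, and exposes ``pseudo_outcomes_`` — the
    clamped fitted probabilities — as the continuous training target
    for the downstream regressor.

    Parameters
    ----------
    n_components : int, default 2
        Number of leading principal components fed to the logistic fit.
    k_grid : list of int, optional
        Increasing panel sizes to scan; defaults to 10, 20, 50, 100,
        200, all.
    saturation_auc : float, default 0.99
        Training AUC at which the panel size is considered saturated.
    """

    def __init__(self, n_components: int = 2, k_grid=None,
                 saturation_auc: float = 0.99, random_state: int = 0):
        self.n_components = n_components
        self.k_grid = k_grid
        self.saturation_auc = saturation_auc
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        cfg = PreconditioningConfig(self.n_components, self.k_grid,
                                    self.saturation_auc, self.random_state)
        grid = cfg.resolve_grid(X.shape[1])
        aucs, probs = [], []
        for k in grid:
            scores = pca_panel(X[:, :k], cfg.n_components)
            prob, train_auc = fit_pc_logistic(scores, y)
            aucs.append(train_auc)
            probs.append(prob)
        saturated = [i for i, a in enumerate(aucs) if a >= cfg.saturation_auc]
        if saturated:
            best = saturated[0]
        else:
            best = int(np.argmax(aucs))
            warnings.warn(
                f"training AUC never reached {cfg.saturation_auc:.2f}; "
                f"using k={grid[best]} (AUC {aucs[best]:.3f})"
            )
        self.k_grid_ = grid
        self.auc_path_ = np.array(aucs)
        self.chosen_k_ = grid[best]
        self.training_auc_ = aucs[best]
        self.pseudo_outcomes_ = np.clip(probs[best], CLAMP_EPS, 1 - CLAMP_EPS)
        return self

    def fit_transform(self, X, y):
        return self.fit(X, y).pseudo_outcomes_


def find_saturation_k(g_ranked: np.ndarray, outcome,
                      cfg: PreconditioningConfig | None = None) -> int:
    """Smallest grid k whose training AUC saturates (else the argmax k)."""
    cfg = cfg or PreconditioningConfig()
    pre = PCLogisticPreconditioner(cfg.n_components, cfg.k_grid,
                                   cfg.saturation_auc, cfg.seed)
    pre.fit(g_ranked, outcome)
    return pre.chosen_k_


def make_pseudo_outcomes(g_train, outcome_train,
                         cfg: PreconditioningConfig | None = None,
                         sample_ids=None) -> pd.DataFrame:
    """Pre-conditioned outcomes for a ranked training matrix.

    ``g_train`` holds the univariate-screened SNPs with columns ordered
    by rank (best first); accepts a GenotypeMatrix or an array.
    """
    from .io import GenotypeMatrix

    cfg = cfg or PreconditioningConfig()
    if isinstance(g_train, GenotypeMatrix):
        X = g_train.values
        sample_ids = sample_ids or g_train.sample_ids
    else:
        X = np.asarray(g_train, dtype=float)
        if sample_ids is None:
            sample_ids = [f"S{i + 1}" for i in range(X.shape[0])]
    pre = PCLogisticPreconditioner(cfg.n_components, cfg.k_grid,
                                   cfg.saturation_auc, cfg.seed)
    pre.fit(X, outcome_train)
    return pd.DataFrame({
        "sample_id": sample_ids,
        "value": pre.pseudo_outcomes_,
        "chosen_k": pre.chosen_k_,
        "training_auc_at_k": pre.training_auc_,
    })
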