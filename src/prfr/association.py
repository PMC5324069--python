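"""Per-SNP univariate screening and ranking on training data.

Screening is a chi-square test on the 3 x 2 table of genotype
(0/1/2 minor-allele copies) by outcome; SNPs with p > alpha (default
0.001) are dropped. Retained SNPs are ranked by the mean held-out AUC
of a univariate logistic regression over stratified 5-fold CV — the
ranking that drives the pre-conditioning panel.

Association tests must only ever see training samples; the caller owns
that contract (the evaluation module re-screens inside every CV fold).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .io import GenotypeMatrix


def chisq_3x2(g_column, outcome) -> tuple[float, float, int]:
    """Chi-square test of a genotype-by-outcome contingency table.

    Rows are the genotype classes {0, 1, 2} present in the data (empty
    classes are dropped, reducing the degrees of freedom), columns are
    controls/cases. Missing dosages are excluded pairwise. No
    continuity correction. With fewer than two non-empty genotype rows
    the test is uninformative and returns (0.0, 1.0, 0).
    """
    g_column = np.asarray(g_column, dtype=float)
    outcome = np.asarray(outcome)
    keep = ~np.isnan(g_column)
    g_column, outcome = g_column[keep], outcome[keep]
    table = np.array([
        [((g_column == d) & (outcome == 0)).sum(), ((g_column == d) & (outcome == 1)).sum()]
        for d in (0.0, 1.0, 2.0)
    ])
    table = table[table.sum(axis=1) > 0]
    if table.shape[0] < 2 or (table.sum(axis=0) == 0).any():
        return 0.0, 1.0, 0
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p), int(df)


def chisq_3x2_bulk(g: GenotypeMatrix | np.ndarray, outcome) -> pd.DataFrame:
    """Vectorized :func:`chisq_3x2` over every SNP column.

    Returns a DataFrame with ``snp_id`` (when a GenotypeMatrix is
    given), ``chi2``, ``p`` and ``df``.
    """
    if isinstance(g, GenotypeMatrix):
        values, snp_ids = g.values, g.snp_ids
    else:
        values = np.asarray(g, dtype=float)
        snp_ids = [str(j) for j in range(values.shape[1])]
    outcome = np.asarray(outcome)
    counts = np.empty((3, 2, values.shape[1]))
    for d in (0, 1, 2):
        is_d = values == float(d)
        counts[d, 0] = (is_d & (outcome == 0)[:, None]).sum(axis=0)
        counts[d, 1] = (is_d & (outcome == 1)[:, None]).sum(axis=0)
    row_tot = counts.sum(axis=1)                      # 3 x p
    col_tot = counts.sum(axis=0)                      # 2 x p
    n = col_tot.sum(axis=0)                           # p
    nonempty = row_tot > 0
    n_rows = nonempty.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = row_tot[:, None, :] * col_tot[None, :, :] / n
        cell = np.where(row_tot[:, None, :] > 0,
                        (counts - expected) ** 2 / expected, 0.0)
    chi2 = np.nan_to_num(cell.sum(axis=(0, 1)))
    df = np.maximum(n_rows - 1, 0)
    valid = (n_rows >= 2) & (col_tot > 0).all(axis=0)
    chi2 = np.where(valid, chi2, 0.0)
    df = np.where(valid, df, 0)
    p = np.ones(values.shape[1])
    p[valid] = stats.chi2.sf(chi2[valid], df[valid])
    return pd.DataFrame({"snp_id": snp_ids, "chi2": chi2, "p": p, "df": df})


class EmptyPanelError(ValueError):
    """No SNP survived the univariate screen."""


def univariate_filter(g: GenotypeMatrix, outcome, alpha: float = 0.001,
                      rank: bool = True, cv_folds: int = 5,
                      seed: int = 0):
    """Screen SNPs at ``p <= alpha`` and rank survivors by CV AUC.

    Returns
    -------
    (retained snp ids, association table)
        The association table has one row per input SNP with the 3x2
        chi-square results; retained SNPs additionally carry
        ``cv_auc_mean`` and ``rank`` (1 = best). Ties in AUC break by
        smaller chi-square p, then lexicographic SNP id.
    """
    assoc = chisq_3x2_bulk(g, outcome)
    retained_mask = assoc["p"].to_numpy() <= alpha
    retained = [s for s, keep in zip(g.snp_ids, retained_mask) if keep]
    assoc["retained"] = retained_mask
    assoc["cv_auc_mean"] = np.nan
    assoc["rank"] = pd.array([pd.NA] * len(assoc), dtype="Int64")
    if not retained:
        raise EmptyPanelError(
            f"no SNP passed the univariate screen at alpha={alpha}"
        )
    if rank:
        outcome = np.asarray(outcome)
        aucs = np.array([
            univariate_cv_auc(g.values[:, g.snp_ids.index(s)], outcome,
                              folds=cv_folds, seed=seed)
            for s in retained
        ])
        sub = assoc.loc[retained_mask].copy()
        sub["cv_auc_mean"] = aucs
        order = sub.sort_values(
            by=["cv_auc_mean", "p", "snp_id"], ascending=[False, True, True]
        ).index
        assoc.loc[retained_mask, "cv_auc_mean"] = aucs
        assoc.loc[order, "rank"] = np.arange(1, len(order) + 1)
        retained = list(assoc.loc[order, "snp_id"])
    return retained, assoc


def univariate_cv_auc(g_column, outcome, folds: int = 5, seed: int = 0,
                      max_refolds: int = 10) -> float:
    """Mean held-out AUC of a single-SNP logistic model over k folds.

    Folds are stratified by outcome; should a training fold still end up
    single-class (tiny inputs), folding is retried with a fresh seed.
    A SNP with no variance in a training fold contributes AUC 0.5.
    """
    x = np.asarray(g_column, dtype=float).reshape(-1, 1)
    if np.isnan(x).any():
        col_mean = np.nanmean(x)
        x = np.where(np.isnan(x), col_mean, x)
    y = np.asarray(outcome)
    for attempt in range(max_refolds):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=seed + attempt)
        aucs = []
        try:
            for train_idx, test_idx in skf.split(x, y):
                y_tr, y_te = y[train_idx], y[test_idx]
                if len(np.unique(y_tr)) < 2 or len(np.unique(y_te)) < 2:
                    raise _RefoldNeeded
                if np.ptp(x[train_idx]) == 0:
                    aucs.append(0.5)
                    continue
                model = LogisticRegression(max_iter=200)
                model.fit(x[train_idx], y_tr)
                scores = model.predict_proba(x[test_idx])[:, 1]
                aucs.append(roc_auc_score(y_te, scores))
            return float(np.mean(aucs))
        except _RefoldNeeded:
            warnings.warn(f"single-class fold; refolding with seed {seed + attempt + 1}")
            continue
    raise ValueError("could not form folds with both classes present")


class _RefoldNeeded(Exception):
    pass


def qq_points(pvals) -> pd.DataFrame:
    """Expected vs observed -log10 p-values for a Q-Q plot.

    Expected quantiles use the (i - 0.5)/n rule over the sorted
    p-values. Zero p-values are clamped to the smallest positive float.
    """
    p = np.asarray(pvals, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if (p == 0).any():
        warnings.warn("p-value of 0 clamped to the machine floor")
        p = np.maximum(p, np.finfo(float).tiny)
    p_sorted = np.sort(p)
    n = len(p_sorted)
    expected = (np.arange(1, n + 1) - 0.5) / n
    return pd.DataFrame({
        "expected_neglog10": -np.log10(expected),
        "observed_neglog10": -np.log10(p_sorted),
    })
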