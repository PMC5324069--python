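"""Splitting, repeated cross-validated AUC, calibration, covariate screen.

The evaluation protocol mirrors a hold-out design: the cohort is split
once into ~2/3 training and ~1/3 validation with near-equal event
rates (redrawing until the rates match); model variability is
estimated by rebuilding the entire pipeline on each fold of repeated
stratified 5-fold CV over the training set and scoring every rebuilt
model on the untouched validation set (5 x 100 = 500 AUCs by default);
the final model uses all training data once and is assessed by a
single validation AUC plus a 6-bin risk calibration table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

import statsmodels.api as sm

from .association import EmptyPanelError
from .io import GenotypeMatrix


def auc(scores, outcome) -> float:
    """Probability a random case outscores a random control (ties = 1/2)."""
    y = np.asarray(outcome)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


@dataclass
class SplitSpec:
    train_idx: np.ndarray
    val_idx: np.ndarray
    event_rate_train: float
    event_rate_val: float
    seed: int
    n_attempts: int


def balanced_split(outcome, frac_train: float = 2 / 3, tolerance: float = 0.0,
                   max_attempts: int = 1000, seed: int = 0) -> SplitSpec:
    """Random train/validation split redrawn until event rates match.

    ``tolerance=0`` means "best achievable": all attempts are drawn and
    the split with the smallest event-rate difference wins (ties to the
    earliest draw). The training set holds ``floor(n * frac_train)``
    samples.
    """
    y = np.asarray(outcome)
    n = len(y)
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("need at least two cases and two controls")
    n_train = int(np.floor(n * frac_train))
    rng = np.random.default_rng(seed)
    best = None
    for attempt in range(1, max_attempts + 1):
        perm = rng.permutation(n)
        tr, va = perm[:n_train], perm[n_train:]
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[va])) < 2:
            continue
        r_tr, r_va = y[tr].mean(), y[va].mean()
        diff = abs(r_tr - r_va)
        if best is None or diff < best[0]:
            best = (diff, tr, va, r_tr, r_va, attempt)
        if diff <= tolerance:
            break
    if best is None:
        raise ValueError("could not form a split with both classes on each side")
    diff, tr, va, r_tr, r_va, attempt = best
    if diff > tolerance:
        warnings.warn(
            f"event-rate difference {diff:.4f} exceeds tolerance {tolerance}; "
            f"keeping the best of {max_attempts} draws"
        )
    tr.sort()
    va.sort()
    return SplitSpec(tr, va, float(r_tr), float(r_va), seed, attempt)


@dataclass
class CvResult:
    aucs: np.ndarray
    n_failed: int = 0

    @property
    def mean(self) -> float:
        return float(np.mean(self.aucs))

    @property
    def std(self) -> float:
        return float(np.std(self.aucs, ddof=1)) if len(self.aucs) > 1 else 0.0


def _values_of(g):
    if isinstance(g, GenotypeMatrix):
        return g.to_frame()
    return g


def repeated_cv_performance(estimator, g_train, outcome_train, g_val, outcome_val,
                            folds: int = 5, repeats: int = 100,
                            seed: int = 0) -> CvResult:
    """Hold-out AUCs from pipelines rebuilt on repeated CV training folds.

    For each of ``repeats`` shuffles, the training set is split into
    ``folds`` stratified folds; the full pipeline (screening, ranking,
    pre-conditioning, model fit) is re-estimated on each fold's
    training portion via ``clone(estimator).fit`` and scored on the
    fixed validation set. Fold failures (e.g. an empty SNP panel) are
    excluded and counted.
    """
    X = _values_of(g_train)
    X_val = _values_of(g_val)
    y_tr = np.asarray(outcome_train)
    y_val = np.asarray(outcome_val)
    aucs, n_failed = [], 0
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + r)
        for fold_train, _ in skf.split(np.zeros(len(y_tr)), y_tr):
            try:
                model = clone(estimator)
                if hasattr(model, "random_state"):
                    model.set_params(random_state=seed + r)
                Xf = X.iloc[fold_train] if isinstance(X, pd.DataFrame) else X[fold_train]
                model.fit(Xf, y_tr[fold_train])
                aucs.append(auc(model.predict(X_val), y_val))
            except (EmptyPanelError, ValueError) as exc:
                n_failed += 1
                warnings.warn(f"CV fold failed and was excluded: {exc}")
    if not aucs:
        raise ValueError("every CV fold failed")
    return CvResult(np.asarray(aucs), n_failed)


def calibration_bins(scores, outcome, n_bins: int = 6) -> pd.DataFrame:
    """Risk-bin calibration table with a goodness-of-fit chi-square.

    Samples are sorted by score and split into ``n_bins`` near-equal
    groups (remainder spread over the lowest bins); bin 1 is lowest
    risk. Predicted incidence is the bin's mean score (scores are on
    the probability scale for PRFR), observed incidence the event
    fraction, SE the binomial standard error. The goodness-of-fit
    statistic sums (O - E)^2 / E over the event and non-event cells of
    every bin, df = ``n_bins``.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcome)
    n = len(s)
    if n < n_bins:
        raise ValueError(f"cannot form {n_bins} bins from {n} samples")
    order = np.argsort(s, kind="stable")
    base, extra = divmod(n, n_bins)
    sizes = [base + (1 if b < extra else 0) for b in range(n_bins)]
    rows, chi2 = [], 0.0
    start = 0
    eps = 1e-10
    for b, size in enumerate(sizes, start=1):
        idx = order[start:start + size]
        start += size
        pred = float(s[idx].mean())
        obs_events = int(y[idx].sum())
        obs = obs_events / size
        se = float(np.sqrt(obs * (1 - obs) / size))
        e_events = max(float(s[idx].sum()), eps)
        e_non = max(size - float(s[idx].sum()), eps)
        chi2 += (obs_events - e_events) ** 2 / e_events
        chi2 += ((size - obs_events) - e_non) ** 2 / e_non
        rows.append({"bin": b, "n": size, "predicted": pred,
                     "observed": obs, "se": se})
    report = pd.DataFrame(rows)
    report.attrs["chi2"] = float(chi2)
    report.attrs["df"] = n_bins
    report.attrs["p"] = float(stats.chi2.sf(chi2, df=n_bins))
    return report


def final_model_eval(estimator, g_train, outcome_train, g_val, outcome_val,
                     n_bins: int = 6):
    """Fit on all training data once; validation AUC + calibration table."""
    y_val = np.asarray(outcome_val)
    if len(y_val) < n_bins:
        raise ValueError(f"validation set of {len(y_val)} cannot form {n_bins} bins")
    model = clone(estimator)
    model.fit(_values_of(g_train), np.asarray(outcome_train))
    scores = model.predict(_values_of(g_val))
    return auc(scores, y_val), calibration_bins(scores, y_val, n_bins), model


def subsample_validation(model, g_val, outcome_val, frac: float = 0.6,
                         repeats: int = 100, seed: int = 0) -> np.ndarray:
    """AUCs of a fixed model on repeated random validation subsets.

    Subsets with a single outcome class are redrawn. ``frac=1.0``
    reduces every repeat to the full-validation AUC.
    """
    X = _values_of(g_val)
    y = np.asarray(outcome_val)
    scores = model.predict(X)
    n_sub = max(1, int(round(frac * len(y))))
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(repeats):
        for _attempt in range(100):
            idx = rng.choice(len(y), size=n_sub, replace=False)
            if len(np.unique(y[idx])) == 2:
                break
        else:
            raise ValueError("could not draw a subset with both classes")
        out.append(auc(scores[idx], y[idx]))
    return np.asarray(out)


def clinical_covariate_screen(covariates: pd.DataFrame, outcome,
                              alpha: float = 0.001) -> pd.DataFrame:
    """Univariate logistic screen of clinical covariates on training data.

    Each covariate is fit alone (with intercept); the table reports the
    Wald p-value and odds ratio exp(coef), and ``retained`` marks
    p <= alpha — the same threshold used for SNP screening. Retained
    covariates are meant to be appended to the SNP feature matrix for a
    model refit. Constant covariates are skipped with a warning.
    """
    y = np.asarray(outcome)
    rows = []
    for name in covariates.columns:
        x = covariates[name].to_numpy(dtype=float)
        if np.nanstd(x) == 0:
            warnings.warn(f"covariate {name!r} is constant; skipped")
            continue
        x = np.where(np.isnan(x), np.nanmean(x), x)
        design = sm.add_constant(x)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, design).fit(disp=0)
            p = float(fit.pvalues[1])
            or_ = float(np.exp(fit.params[1]))
        except Exception as exc:  # separation etc.
            warnings.warn(f"logistic fit failed for {name!r}: {exc}")
            p, or_ = np.nan, np.nan
        rows.append({"covariate": name, "p": p, "odds_ratio": or_,
                     "retained": bool(p <= alpha) if np.isfinite(p) else False})
    return pd.DataFrame(rows, columns=["covariate", "p", "odds_ratio", "retained"])
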