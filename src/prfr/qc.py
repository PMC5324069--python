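"""SNP quality control and cohort-level diagnostics.

A SNP passes QC when its missing rate is at most 5%, its minor allele
frequency is at least 5%, and its Hardy-Weinberg equilibrium p-value is
at least 1e-5 (defaults; all configurable). Cohort-level diagnostics
are the genomic inflation factor lambda (median observed association
statistic over the null median, ~1 in the absence of population
stratification) and a chi-square homogeneity test of event rates across
population groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypeMatrix


@dataclass
class QcThresholds:
    max_missing_rate: float = 0.05
    min_maf: float = 0.05
    min_hwe_p: float = 1e-5

    def __post_init__(self):
        for name in ("max_missing_rate", "min_maf", "min_hwe_p"):
            val = getattr(self, name)
            if not (0 < val < 1):
                raise ValueError(f"{name}={val} outside (0, 1)")


def snp_missing_rate(g: GenotypeMatrix) -> np.ndarray:
    """Fraction of missing calls per SNP."""
    if g.n_samples < 1:
        raise ValueError("need at least one sample")
    return np.isnan(g.values).mean(axis=0)


def minor_allele_frequency(g: GenotypeMatrix) -> np.ndarray:
    """Folded allele frequency min(f, 1-f) per SNP, missing calls excluded.

    All-missing SNPs get NaN (they are flagged as QC failures, not errors).
    """
    n_nonmiss = (~np.isnan(g.values)).sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        dosage_sum = np.nansum(g.values, axis=0)
        f = np.where(n_nonmiss > 0, dosage_sum / (2.0 * np.maximum(n_nonmiss, 1)), np.nan)
    return np.minimum(f, 1.0 - f)


def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> tuple[float, float]:
    """1-df chi-square test of Hardy-Weinberg equilibrium.

    Genotype counts are compared with the p^2 / 2pq / q^2 expectation at
    the estimated allele frequency. Monomorphic SNPs carry no
    information and return (0.0, 1.0).
    """
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("need at least one genotyped sample")
    p_hat = (2 * n_AA + n_Aa) / (2.0 * n)
    q_hat = 1.0 - p_hat
    if p_hat == 0.0 or q_hat == 0.0:
        return 0.0, 1.0
    expected = np.array([n * p_hat**2, 2 * n * p_hat * q_hat, n * q_hat**2])
    observed = np.array([n_AA, n_Aa, n_aa], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def hwe_test_vectorized(g: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP HWE chi-square and p-value over all samples."""
    vals = g.values
    n_aa = (vals == 2.0).sum(axis=0)   # minor homozygote
    n_Aa = (vals == 1.0).sum(axis=0)
    n_AA = (vals == 0.0).sum(axis=0)
    n = n_AA + n_Aa + n_aa
    n_safe = np.maximum(n, 1)
    p_hat = (2 * n_AA + n_Aa) / (2.0 * n_safe)
    q_hat = 1.0 - p_hat
    poly = (p_hat > 0) & (q_hat > 0) & (n > 0)
    chi2 = np.zeros(g.n_snps)
    with np.errstate(divide="ignore", invalid="ignore"):
        exp_AA = n_safe * p_hat**2
        exp_Aa = 2 * n_safe * p_hat * q_hat
        exp_aa = n_safe * q_hat**2
        raw = ((n_AA - exp_AA) ** 2 / exp_AA
               + (n_Aa - exp_Aa) ** 2 / exp_Aa
               + (n_aa - exp_aa) ** 2 / exp_aa)
    chi2[poly] = raw[poly]
    p = np.ones(g.n_snps)
    p[poly] = stats.chi2.sf(chi2[poly], df=1)
    return chi2, p


def apply_qc(g: GenotypeMatrix, v: pd.DataFrame,
             thresholds: QcThresholds | None = None):
    """Filter SNPs on missing rate, MAF and HWE.

    Returns
    -------
    (GenotypeMatrix, variant table, QC report)
        The report is a DataFrame with per-SNP ``missing_rate``, ``maf``,
        ``hwe_chi2``, ``hwe_p``, per-criterion failure flags and the
        overall ``pass`` flag; summary counts live in ``report.attrs``
        (per-criterion failures, uniquely-failing counts, n retained).
    """
    thresholds = thresholds or QcThresholds()
    miss = snp_missing_rate(g)
    maf = minor_allele_frequency(g)
    hwe_chi2, hwe_p = hwe_test_vectorized(g)

    fail_missing = miss > thresholds.max_missing_rate
    fail_maf = ~(maf >= thresholds.min_maf)  # NaN MAF (all-missing) fails
    fail_hwe = hwe_p < thresholds.min_hwe_p
    ok = ~(fail_missing | fail_maf | fail_hwe)

    report = pd.DataFrame({
        "snp_id": g.snp_ids,
        "missing_rate": miss,
        "maf": maf,
        "hwe_chi2": hwe_chi2,
        "hwe_p": hwe_p,
        "fail_missing": fail_missing,
        "fail_maf": fail_maf,
        "fail_hwe": fail_hwe,
        "pass": ok,
    })
    n_fail = int((~ok).sum())
    only = {
        "missing": int((fail_missing & ~fail_maf & ~fail_hwe).sum()),
        "maf": int((fail_maf & ~fail_missing & ~fail_hwe).sum()),
        "hwe": int((fail_hwe & ~fail_missing & ~fail_maf).sum()),
    }
    report.attrs.update({
        "n_snps": g.n_snps,
        "n_retained": int(ok.sum()),
        "n_removed": n_fail,
        "n_fail_missing": int(fail_missing.sum()),
        "n_fail_maf": int(fail_maf.sum()),
        "n_fail_hwe": int(fail_hwe.sum()),
        "n_fail_only": only,
    })
    if not ok.any():
        raise ValueError("QC removed every SNP; check thresholds and input coding")
    kept = [s for s, k in zip(g.snp_ids, ok) if k]
    g_f = g.subset_snps(kept)
    v_f = v[v["snp_id"].isin(kept)].reset_index(drop=True)
    return g_f, v_f, report


def inflation_factor(chi2_stats: np.ndarray, df: int = 1) -> float:
    """Genomic inflation factor: median statistic over the null median.

    lambda ~ 1 indicates no systematic inflation (e.g. from population
    stratification); the df must match the association statistic that
    produced the values (df=2 for the 3x2 genotype table test).
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    arr = np.asarray(chi2_stats, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("no finite statistics supplied")
    return float(np.median(arr) / stats.chi2.ppf(0.5, df=df))


def event_rate_homogeneity(outcome, group) -> tuple[float, float]:
    """R x 2 chi-square test of equal event rates across groups.

    No continuity correction; each group must have at least one sample.
    """
    outcome = np.asarray(outcome)
    group = np.asarray(group)
    levels = pd.unique(group)
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    table = np.array([
        [(outcome[group == lev] == 1).sum(), (outcome[group == lev] == 0).sum()]
        for lev in levels
    ])
    if (table.sum(axis=1) == 0).any():
        raise ValueError("a group has zero samples")
    if (table.sum(axis=0) == 0).any():  # all-case or all-control cohort
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)
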