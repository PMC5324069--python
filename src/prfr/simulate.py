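"""Synthetic GWAS cohorts for exercising the modelling pipeline.

The generator emulates the structure the method assumes: a few hundred
samples genotyped at many biallelic SNPs coded as minor-allele dosage,
a binary endpoint driven by a sparse additive logistic model with many
small per-allele effects, optional clinical covariates, and
missing-completely-at-random genotype calls. SNPs are drawn
independently (no linkage disequilibrium) so that analytic expectations
— event rates, null test-statistic distributions, screening counts —
are exact. Pure-null "phoney" SNPs can be appended to a cohort to probe
how many statistical artifacts survive univariate screening and where
they land in the importance ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, make_variant_table


@dataclass
class CovariateSpec:
    """A clinical covariate: name, sampling distribution, log-odds effect.

    ``distribution`` is ``("normal", mean, sd)`` or ``("bernoulli", p)``.
    """

    name: str
    distribution: tuple
    log_odds: float = 0.0

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        kind = self.distribution[0]
        if kind == "normal":
            _, mean, sd = self.distribution
            return rng.normal(mean, sd, n)
        if kind == "bernoulli":
            _, p = self.distribution
            return rng.binomial(1, p, n).astype(float)
        raise ValueError(f"unknown covariate distribution {kind!r}")


@dataclass
class SimConfig:
    """Configuration of a synthetic cohort.

    Defaults mirror a radiogenomics toxicity cohort: several hundred
    patients, an event rate near one half, age (years) and a binary
    hormone-therapy flag as covariates, and a sparse set of causal SNPs
    with small additive per-allele log-odds effects.
    """

    n_samples: int = 900
    n_snps: int = 5000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal: int = 20
    effect_log_odds: float | np.ndarray = 0.25
    intercept: float | None = None
    covariate_specs: list[CovariateSpec] = field(default_factory=list)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        low, high = self.maf_range
        if not (0 < low <= high <= 0.5):
            raise ValueError(f"maf_range {self.maf_range} outside (0, 0.5]")
        if self.n_causal > self.n_snps:
            raise ValueError(f"n_causal {self.n_causal} > n_snps {self.n_snps}")
        if not (0 <= self.missing_rate < 1):
            raise ValueError(f"missing_rate {self.missing_rate} outside [0, 1)")


def default_covariates() -> list[CovariateSpec]:
    """Age (years) and a binary androgen-deprivation-therapy flag.

    Effects are oriented the way they act on radiotherapy toxicity:
    older age and hormone therapy both increase risk.
    """
    return [
        CovariateSpec("age", ("normal", 63.0, 7.0), log_odds=0.0),
        CovariateSpec("adt", ("bernoulli", 0.5), log_odds=0.0),
    ]


def _draw_genotypes(rng, n_samples, n_snps, maf_range):
    mafs = rng.uniform(maf_range[0], maf_range[1], n_snps)
    dosages = rng.binomial(2, mafs[None, :], size=(n_samples, n_snps)).astype(float)
    return dosages, mafs


def simulate_cohort(cfg: SimConfig):
    """Draw one synthetic cohort.

    Genotypes are Binomial(2, MAF) per sample and SNP, MAFs uniform on
    ``cfg.maf_range``. The outcome is Bernoulli with log-odds
    ``intercept + sum(effect * dosage) + sum(covariate effects)``.
    An ``intercept`` of ``None`` (the default) centers the liability at
    its expected genetic and covariate contribution, giving an event
    rate near one half — inside the range of typical toxicity cohorts.

    Returns
    -------
    (GenotypeMatrix, variant table, phenotype table, truth)
        ``truth`` is a dict with ``causal_snp_ids``, ``effects`` (aligned
        per-causal-SNP log-odds), ``mafs`` (all SNPs), and
        ``linear_predictor`` (per-sample true log-odds).
    """
    rng = np.random.default_rng(cfg.seed)
    dosages, mafs = _draw_genotypes(rng, cfg.n_samples, cfg.n_snps, cfg.maf_range)
    snp_ids = [f"rs{j + 1}" for j in range(cfg.n_snps)]
    sample_ids = [f"S{i + 1}" for i in range(cfg.n_samples)]

    causal_idx = rng.choice(cfg.n_snps, size=cfg.n_causal, replace=False)
    causal_idx.sort()
    effects = np.broadcast_to(
        np.asarray(cfg.effect_log_odds, dtype=float), (cfg.n_causal,)
    ).copy()

    if cfg.intercept is None:
        # center the liability so the event rate sits near one half
        intercept = -float(effects @ (2.0 * mafs[causal_idx])) if cfg.n_causal else 0.0
        for spec in cfg.covariate_specs:
            # distribution[1] is the mean for both normal and bernoulli
            intercept -= spec.log_odds * spec.distribution[1]
    else:
        intercept = float(cfg.intercept)
    eta = np.full(cfg.n_samples, intercept)
    if cfg.n_causal:
        eta += dosages[:, causal_idx] @ effects

    pheno = pd.DataFrame({"sample_id": sample_ids})
    for spec in cfg.covariate_specs:
        x = spec.draw(rng, cfg.n_samples)
        pheno[spec.name] = x
        eta += spec.log_odds * x

    prob = 1.0 / (1.0 + np.exp(-eta))
    outcome = rng.binomial(1, prob)
    pheno.insert(1, "outcome", outcome)

    if cfg.missing_rate > 0:
        mask = rng.random(dosages.shape) < cfg.missing_rate
        dosages[mask] = np.nan

    # spread SNPs 5 kb apart across one synthetic chromosome
    positions = 1 + 5000 * np.arange(cfg.n_snps)
    g = GenotypeMatrix(dosages, sample_ids, snp_ids)
    v = make_variant_table(snp_ids, chrom="1", pos=positions)
    truth = {
        "causal_snp_ids": [snp_ids[j] for j in causal_idx],
        "effects": effects,
        "mafs": mafs,
        "linear_predictor": eta,
    }
    return g, v, pheno, truth


def inject_null_snps(g: GenotypeMatrix, v: pd.DataFrame, n_null: int,
                     maf_range=(0.05, 0.5), seed: int = 0):
    """Append ``n_null`` SNPs simulated independently of everything.

    The injected columns are drawn exactly as :func:`simulate_cohort`
    draws genotypes but share no dependence with the outcome, so any of
    them surviving association screening is a false positive by
    construction.

    Returns the widened matrix, widened variant table, and the list of
    injected SNP ids (``null1`` ... ``null<n>``).
    """
    if n_null < 0:
        raise ValueError("n_null must be >= 0")
    if n_null == 0:
        return g, v, []
    rng = np.random.default_rng(seed)
    dosages, _ = _draw_genotypes(rng, g.n_samples, n_null, maf_range)
    null_ids = [f"null{j + 1}" for j in range(n_null)]
    clash = set(null_ids) & set(g.snp_ids)
    if clash:
        raise ValueError(f"null SNP ids collide with existing ids: {sorted(clash)[:5]}")
    values = np.hstack([g.values, dosages])
    g2 = GenotypeMatrix(values, list(g.sample_ids), list(g.snp_ids) + null_ids)
    last_pos = int(v["pos"].max()) if len(v) else 0
    v_null = make_variant_table(null_ids, chrom="1",
                                pos=last_pos + 5000 * np.arange(1, n_null + 1))
    v2 = pd.concat([v, v_null], ignore_index=True)
    return g2, v2, null_ids


def make_gene_fixture(v: pd.DataFrame, n_genes: int = 10, seed: int = 0,
                      window_bp: int = 10_000):
    """Place genes near a known subset of SNPs and return the truth map.

    Genes are laid out so that each one captures its anchor SNP within
    the ±``window_bp`` rule (some spanning the SNP, some ending exactly
    at the window boundary) while staying outside the window of every
    other SNP whenever spacing allows.

    Returns
    -------
    (gene table, truth)
        ``truth`` maps gene name -> set of SNP ids within the window.
    """
    rng = np.random.default_rng(seed)
    n_genes = min(n_genes, len(v))
    anchors = rng.choice(len(v), size=n_genes, replace=False)
    records, truth = [], {}
    for k, a in enumerate(sorted(anchors)):
        row = v.iloc[a]
        pos = int(row["pos"])
        name = f"GENE{k + 1}"
        if k % 2 == 0:
            start, end = max(1, pos - 500), pos + 500          # spans the SNP
        else:
            end = max(1, pos - window_bp)                      # boundary case
            start = max(1, end - 1000)
        records.append({"gene": name, "chrom": str(row["chrom"]),
                        "start": start, "end": end})
    genes = pd.DataFrame(records)
    pos_arr = v["pos"].to_numpy()
    for rec in records:
        hit = (v["chrom"].astype(str) == rec["chrom"]) & \
              (pos_arr >= rec["start"] - window_bp) & (pos_arr <= rec["end"] + window_bp)
        truth[rec["gene"]] = set(v.loc[hit, "snp_id"])
    return genes, truth
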