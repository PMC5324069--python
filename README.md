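# prfr — pre-conditioned random forest regression for SNP risk models

`prfr` builds polygenic predictive models of binary clinical endpoints
from genome-wide SNP genotypes. The motivating setting is
radiogenomics: predicting which patients will develop late
radiotherapy toxicities (rectal bleeding, erectile dysfunction) from
germline variation, where the signal is spread over many markers of
individually small effect and cohorts number a few hundred patients.
It is aimed at statistical geneticists and biostatisticians who want
the whole workflow — QC, screening, model, evaluation, annotation —
reproducible from one seed.

## The method

Genotypes are additively coded (x ∈ {0,1,2} minor-allele copies). On
training data only:

1. screen SNPs with a χ² test on the 3×2 genotype-by-outcome table,
   keeping p ≤ 0.001;
2. rank survivors by the held-out AUC of univariate logistic
   regression over stratified 5-fold CV;
3. **pre-condition**: for growing panels of the top-k ranked SNPs,
   take the first two principal components of the standardized dosage
   matrix and fit logistic regression
   `logit P(y=1) = β₀ + β₁PC₁ + β₂PC₂`, growing k until the training
   AUC saturates (≥ 0.99); the fitted probabilities ŷ ∈ (0,1) are the
   continuous *pseudo-outcomes*;
4. fit random forest regression of ŷ on all screened SNPs
   (1000 trees, mtry = ⌊√p⌋, minimum node size 5).

Validation scores are forest means; SNP importance is the out-of-bag
permutation score, mean over trees of MSEᵖ − MSE. Comparators PL
(lasso on ŷ), RFC (classification forest on y) and LLR (L1 logistic
on y) share the screen. Top-importance SNP fractions map to genes
within ±10 kb for downstream enrichment tools.

## Worked example

```python
import numpy as np
from prfr import (SimConfig, simulate_cohort, apply_qc, balanced_split,
                  PreconditionedRandomForest, oob_permutation_importance,
                  auc, calibration_bins)

cfg = SimConfig(n_samples=900, n_snps=5000, n_causal=10,
                effect_log_odds=1.0, seed=42)
g, variants, pheno, truth = simulate_cohort(cfg)
y = pheno["outcome"].to_numpy()
g, variants, report = apply_qc(g, variants)
print(f"QC retained {report.attrs['n_retained']} / {report.attrs['n_snps']} SNPs")

split = balanced_split(y, seed=42)          # 2/3 train, event-rate balanced
X = g.to_frame()
model = PreconditionedRandomForest(random_state=42)
model.fit(X.iloc[split.train_idx], y[split.train_idx])
print(f"screened panel: {len(model.support_)} SNPs, "
      f"pre-conditioning k = {model.preconditioner_.chosen_k_}")

scores = model.predict(X.iloc[split.val_idx])
print(f"validation AUC = {auc(scores, y[split.val_idx]):.3f}")

imp = oob_permutation_importance(model.model_,
                                 X.iloc[split.train_idx].loc[:, model.support_])
rep = calibration_bins(scores, y[split.val_idx], n_bins=6)
print(f"calibration GOF chi2 = {rep.attrs['chi2']:.2f}, p = {rep.attrs['p']:.2f}")
```

prints

```
QC retained 4978 / 5000 SNPs
screened panel: 12 SNPs, pre-conditioning k = 12
validation AUC = 0.637
calibration GOF chi2 = 3.27, p = 0.77
```

Of 5,000 simulated SNPs, 4,978 pass QC and 12 survive the univariate
screen on the 600 training samples (the 10 planted causal SNPs have
per-allele OR e¹·⁰ ≈ 2.7, so most are caught, plus a couple of nulls).
The model scores the untouched 300-sample validation set at AUC 0.637
— well above chance for a purely genetic model — and the 6-bin
calibration table shows no significant disagreement between predicted
and observed incidence (p = 0.77). The importance ranking put planted
causal SNPs in ranks 1 and 3.

The same workflow runs from the shell:

```sh
prfr simulate --n-samples 900 --n-snps 5000 --seed 42 --out-prefix cohort
prfr qc cohort.genotypes.tsv --out-prefix qc
prfr assoc qc.genotypes.tsv cohort.phenotypes.tsv
prfr fit qc.genotypes.tsv cohort.phenotypes.tsv --model prfr
prfr run config.yaml        # the whole pipeline from one YAML config
```

`prfr run` writes a manifest with per-stage seeds and SHA-256 hashes
of every artifact; identical configs reproduce identical outputs.

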