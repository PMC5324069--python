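# Methods

## The model

The package builds polygenic predictive models of a binary clinical
endpoint (the motivating application is late radiotherapy toxicity —
e.g. rectal bleeding or erectile dysfunction after prostate
irradiation) from a sample × SNP matrix of additively coded genotypes:
each SNP is the count of minor alleles, 0/1/2, so a per-allele effect
acts linearly on the log-odds scale.

The core estimator is **pre-conditioned random forest regression
(PRFR)**. A random forest classifier fed a binary outcome receives one
noisy bit per sample; pre-conditioning replaces the outcome with a
continuous pseudo-outcome that is correlated both with the outcome and
with the informative SNPs, giving the regression forest a richer
target. The fitting recipe, entirely re-estimated on whatever training
set `fit` receives:

1. **Screen.** Each SNP is tested with a chi-square on the 3 × 2 table
   of genotype class (0/1/2) by outcome; SNPs with p > α (default
   0.001) are dropped. Empty genotype rows are removed, reducing the
   degrees of freedom; no continuity correction.
2. **Rank.** Survivors are ranked by the mean held-out AUC of a
   univariate logistic regression over stratified 5-fold CV (ties:
   smaller chi-square p, then SNP id).
3. **Pre-condition.** For panel sizes k on a grid (10, 20, 50, 100,
   200, all), the top-k ranked SNPs are mean-imputed, standardized to
   unit variance, reduced to their first two principal components, and
   a logistic regression of the outcome on those components is fitted.
   The smallest k whose in-sample AUC reaches 0.99 wins (otherwise the
   argmax, with a warning). The winning model's fitted probabilities,
   clamped to [1e-6, 1 − 1e-6], are the pseudo-outcomes.
4. **Regress.** A random forest regression of the pseudo-outcomes on
   *all* screened SNPs: 1000 trees, bootstrap of n samples with
   replacement per tree, `floor(sqrt(p))` candidate features per
   split, and nodes with fewer than 5 samples left unsplit.

Predictions are forest means — continuous risk scores on the
probability scale (ordinal; calibration is assessed separately).

Three comparators share the same screen: **PL** (lasso regression on
the pseudo-outcomes, penalty by internal 5-fold CV over a 100-value
path), **RFC** (random forest classifier on the raw outcome, scores =
case-vote fractions, same tree hyperparameters), and **LLR**
(L1-penalized logistic regression on the raw outcome).

**Importance.** For each tree, the mean squared error of its
predictions on its out-of-bag samples (MSE) is compared with the MSE
after permuting one SNP's values within those out-of-bag rows (MSEp);
the importance of a SNP is the average of MSEp − MSE over trees
(trees with fewer than two out-of-bag samples are skipped). Because
the pseudo-outcome is constructed from the full training set, the
out-of-bag rows are internal to training; importance measures the
forest's reliance on a SNP, not external validity.

## Quality control and diagnostics

SNPs are removed when missing rate > 5%, minor allele frequency < 5%,
or the 1-df Hardy–Weinberg chi-square p < 1e-5 (all thresholds
configurable). HWE uses the asymptotic chi-square rather than the
exact test — the classical default, fast at 10^5–10^6 SNPs — computed
on all samples; MAF and HWE denominators exclude missing calls, and
MAF is folded (min(f, 1−f)) so a mis-oriented column cannot report a
frequency above one half. The genomic inflation factor λ is the median
observed association statistic over the null-distribution median at
the caller-stated df (df = 2 for the 3 × 2 screen); λ ≈ 1 on null
cohorts is verified by simulation. An R × 2 chi-square checks that
event rates do not differ across population groups.

## Evaluation protocol

The cohort is split once into ~2/3 training and ~1/3 validation
(`floor(n·2/3)` training samples), redrawing until the two event rates
agree; `tolerance=0` means "best achievable over the attempt budget".
Variability is estimated by repeated stratified 5-fold CV on the
training set: each fold's training portion rebuilds the entire
pipeline — screen, ranking, pre-conditioning, forest — and is scored
on the untouched validation set, yielding folds × repeats AUCs (500 in
the full protocol). Screening inside the fold is what prevents
selection leakage; the no-leakage property is tested directly.

The final model uses all training data once and reports a validation
AUC plus a calibration table: samples sorted by score are cut into 6
near-equal-count bins (remainder to the lowest bins), and each bin
compares predicted incidence (mean score) with observed incidence. The
goodness-of-fit statistic sums (O−E)²/E over the event and non-event
cells of every bin; df = number of bins, since no parameter is
re-estimated on validation data. Quantile bins avoid empty bins at any
score distribution; expected counts are floored at 1e-10.

Clinical covariates (age in years, hormone-therapy flag, …) are
screened by univariate logistic regression at the same α = 0.001
(Wald p; odds ratio = exp(coef)); retained covariates can be appended
unscreened to the SNP feature matrix via the estimators' `covariates`
parameter, entering the forest but not the PCA panel.

## The synthetic cohort generator

`simulate_cohort` emulates the statistical structure the method
assumes: n_samples × n_snps dosages drawn Binomial(2, MAF) with MAFs
uniform on (0.05, 0.5], a sparse causal subset with additive per-allele
log-odds effects, optional covariates, and MCAR missingness. The
default intercept centers the liability at its expectation, putting
the event rate near one half — inside the 20–56% range typical of
toxicity cohorts. The reference conditions used throughout the test
suite are 900 samples (600 train / 300 validation), 5,000 SNPs, and
20 causal SNPs at per-allele log-OR 0.25 — many small effects, the
regime the method targets.

SNPs are **independent** (no linkage disequilibrium): the method never
models LD, and independence makes analytic expectations exact — the
per-SNP screen at α retains Binomial(n, α) null SNPs, null p-values
are uniform (verified by Kolmogorov–Smirnov at n = 600; at much
smaller n the discreteness of the 3 × 2 statistic is detectable), and
λ concentrates at 1. What passing tests therefore do *not* show: LD
aggregation of signal across correlated SNPs, which in real cohorts
substantially raises the information carried by a screened panel, and
population structure. Results on this generator are a lower bound on
what the method achieves when LD lets many markers tag each causal
variant.

`inject_null_snps` appends outcome-independent "phoney" SNPs for the
false-positive probe. The probe's cohort plants 10 biomarkers at
per-allele log-OR 1.5, chosen so their attenuated association z (~6)
sits clearly above the expected maximum of 60,000 null draws (~4.6):
the qualitative claim under test — no phoney SNP outranks every real
biomarker in the importance list — presupposes a screened panel
dominated by genuinely detectable markers, and with independent SNPs
that regime requires strong per-SNP effects (in real data LD
aggregation supplies it at weaker per-SNP effects).

## Numerical choices

- Missing dosages are mean-imputed per SNP with training means stored
  and reused at prediction time; 0 is a valid dosage, so missingness
  is NaN, never 0.
- Dosage columns are standardized before PCA (variances differ by MAF
  and would otherwise dominate loadings); zero-variance columns are
  dropped with a warning.
- The pre-conditioning logistic fit is unpenalized (intercept
  unpenalized too, so mean fitted probability equals the event rate to
  solver precision, tol = 1e-10). (Quasi-)separation — detected as a
  per-SD log-odds above 10 or a convergence failure — triggers a light
  ridge refit (C = 100).
- `mtry = floor(sqrt(p))`, e.g. 27 for a 749-SNP panel; the
  minimum-node-size rule is implemented as "do not split nodes with
  fewer than 5 samples".
- All stochastic stages derive per-stage seeds deterministically from
  one run seed (CRC-mixed SeedSequence, < 2^31), so identical configs
  reproduce identical artifacts; the pipeline manifest records SHA-256
  hashes of every output to audit exactly that.
- Coordinates are 1-based closed intervals internally; BED input is
  converted on read. The ±10 kb gene window is inclusive at both
  boundaries and strand-agnostic, and top-fraction SNP counts use
  floor(fraction · n).

## Known limitations

- No LD, no population structure, no imputation-aware dosages in the
  generator; sample-level QC (call rate, relatedness) is out of scope.
- At the reference conditions the α = 0.001 screen has only ~10%
  per-SNP power, so screened panels hold a handful of SNPs and
  validation AUCs sit close to 0.5: the reference simulation
  exercises the machinery end-to-end but is signal-poor compared with
  a real LD-structured cohort, and per-seed method orderings
  (PRFR vs RFC) are within noise there even though the across-seed
  means order correctly.
- The calibration GOF uses df = bins; with model-estimated scores the
  statistic is only approximately chi-square (the classical
  Hosmer–Lemeshow caveat).
- The importance score shares the known permutation-importance bias
  toward high-variance features; with 0/1/2 dosages of comparable MAF
  this is mild.
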