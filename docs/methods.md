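# Methods

This note documents the models, estimators and design choices in pwaskit,
what the synthetic-data generator does and does not emulate, and the
numerical conventions that matter when reproducing results.

## Synthetic cohorts

**Genotypes.** Dosages are generated from a latent multivariate Gaussian
with block-wise AR(1) correlation (adjacent variants at correlation ρ,
variants k apart at ρᵏ; blocks independent), thresholded at each variant's
Hardy–Weinberg genotype quantiles. This preserves MAF and HWE exactly in
expectation while giving tunable, seedable LD without any external
reference panel. Imputation uncertainty is emulated by adding Gaussian
dosage noise with variance (1−INFO)·2p(1−p), clipped to [0, 2] — an
approximation consistent with the INFO score's definition as the ratio of
observed to expected dosage variance. Missing calls are masked uniformly at
random at a per-variant rate.

What this does **not** emulate: recombination-map realism, allele-frequency
spectra from demography, population structure or relatedness, and the
haplotype-level composition of genotypes (the latent threshold acts on one
Gaussian per genotype, not two per haplotype, so third-order LD moments
differ from coalescent data). Passing tests therefore demonstrate
correctness of the statistical machinery under idealized LD, not robustness
to structure or cryptic relatedness.

**Proteins.** Levels = genetic value + covariate term + Gaussian noise.
Causal variants are drawn uniformly inside (cis) or outside (trans) a 1 Mb
TSS window; raw effects are N(0, 1) and the genetic value is rescaled so it
contributes exactly the target fraction h² of the genetic-plus-noise
variance in-sample. Covariate effects sit on top of that unit-variance
core, which is what the covariate-adjustment stage removes. A truth record
(causal ids, standardized effects, per-sample genetic values) accompanies
every simulated protein so recovery can be scored; the same truth can be
replayed in an independent cohort (`simulate_levels_from_truth`) to emulate
a validation subcohort.

**GWAS summaries.** Z ~ MVN(√N_eff · γ · Σb, Σ), where b are the protein's
standardized effects mapped onto the reference panel, γ the standardized
effect of the protein on disease liability, and N_eff = 4/(1/n_cases +
1/n_controls) the usual effective sample size for case-control z-scores.
γ = 0 gives an exact null with the panel's correlation structure. Default
case/control counts (8,275 / 6,723) match a large pancreatic-cancer GWAS.
Σ is eigenvalue-floored before factorization so rank-deficient panels
remain drawable.

## Variant QC and phenotypes

Filters run in a fixed order — INFO ≥ 0.7, MAF ≥ 0.05 (or minor allele
count ≥ 5 with `maf_mode="count"`; the frequency reading is the default
because a 5-allele floor is vacuous at biobank scale), exact HWE P ≥
5×10⁻⁶, missing rate < 5% (strict), LD-panel presence, and removal of
strand-ambiguous A/T and C/G variants — and the QC report records the first
failing rule per dropped variant. The HWE test is the exact conditional
test (enumeration over heterozygote counts given allele counts, summing
tables no more probable than the observed one, no mid-p), chosen over the
chi-square for its validity at low counts; boundary equality keeps a
variant.

Phenotype preparation: optional log of raw positive levels, OLS residuals
on covariates plus intercept (collinear columns dropped via pivoted QR,
missing rows excluded and returned as NaN), then the Blom rank-inverse
normal transform Φ⁻¹((rank − 3/8)/(n + ¼)) with average ranks for ties.

## Prediction models

Candidate selection is seed-and-expand: cis seeds at BH-FDR < 0.05
(computed per protein, over that protein's cis variants — the proteome-wide
alternative would couple unrelated proteins' model building), trans seeds
at P ≤ 5×10⁻⁸ (alternates 5×10⁻⁷/10⁻⁹/10⁻¹⁰ for robustness runs), each
expanded ±100 kb. Trans seeds are not LD-clumped in the main mode; pruning
(greedy left-to-right, r² ≤ 0.1 within 250 kb) is a separate robustness
strategy.

All methods emit weights on the standardized-genotype scale:

* **top1** — the variant with the smallest marginal p keeps its marginal
  slope; ties break to the lowest genomic position for determinism.
* **LASSO / elastic net** — scikit-learn coordinate descent; the penalty
  strength minimizes 5-fold CV error along the path (mixing fixed at 0.5
  for the elastic net, the glmnet/FUSION convention); an all-zero solution
  discards the method for that protein.
* **BLUP** — ridge with λ = m(1−ĥ²)/ĥ², ĥ² from REML on the candidate-set
  GRM, floored at 0.01 (maximal shrinkage when no genetic signal is
  detectable). ĥ² is estimated once per protein and shared across CV folds.
* **bslmm_approx** — a spike-and-slab (point-normal) Gibbs sampler:
  coefficients are zero with probability 1−π or N(0, σ²b); σ²e carries a
  scaled-inverse-χ² update, σ²b a scaled-inverse-χ² with ν₀ = 4 and scale
  σ²e, and π a Beta(1+k, 1+4(m−k)) update leaning toward sparsity. The
  first half of the chain is burn-in; posterior-mean weights are returned
  and a split-chain cosine check warns on apparent non-convergence. This is
  a deliberate simplification of BSLMM (no dense polygenic component, fixed
  iteration budget).

**Cross-validation.** Folds come from a seeded permutation (k = 5); each
sample is predicted once by a model trained without it. The phenotype is
centered globally and predictions carry no per-fold intercept: training-
fold means are anti-correlated with the held-out fold's mean, and per-fold
intercepts would bias the pooled correlation negative under the null.
cv_r2 is the signed squared Pearson correlation of pooled predictions with
the phenotype, and cv_p its t-transform p-value with n−2 df. Note this
pooled statistic is a quadratic form in y whose null variance exceeds the
nominal t's (roughly twofold, more with method selection), so cv_p ranks
models rather than providing calibrated inference; the test suite validates
its null distribution against an independent simulation of the same
construction.

Model choice: smallest cv_p, ties to larger cv_r2, then the fixed order
top1 < lasso < enet < blup < bslmm_approx. Winners below CV R² = 0.01 are
rejected; external validation passes at Pearson r ≥ 0.1 (inclusive) with
allele-orientation-aware prediction.

## Heritability

`estimate_h2` maximizes the restricted likelihood of the one-GRM model by
average-information updates on (σ²g, σ²e), falling back to EM whenever an
AI step leaves the positive orthant or the AI matrix is singular
(max 100 iterations, likelihood tolerance 10⁻⁶; the convergence flag is
honest). A single eigendecomposition of the GRM makes every iteration O(n).
Estimates are invariant to positive phenotype rescaling, clamped to [0, 1]
(GCTA's default behavior), with a delta-method SE from the inverse AI
matrix. The cis+trans vs cis-only comparison classifies Δĥ² as
higher/same/lower with a "same" tolerance of 10⁻⁶ — tight because exact
ties are the meaningful category (identical SNP sets when a protein has no
trans candidates); the tolerance is configurable.

## Association testing

Harmonization matches SNPs by id across model, GWAS and LD reference;
swapped effect/other alleles flip the GWAS z sign and the reference row
signs; records whose alleles neither match nor swap are dropped with a
reason code. Missing SNPs are dropped rather than LD-imputed — simpler and
honestly flagged — with a coverage gate: below 50% retained |w| mass the
protein is reported missing, not scored. Σ's eigenvalues are floored at
10⁻⁸ (no blanket shrinkage by default), preserving the quoted statistic
while preventing division blow-ups; a quadratic form under 10⁻⁸ yields NA.
P-values go through the normal survival function (accurate deep into the
tail) and are floored at the smallest positive float. The BH-FDR family is
all proteins with a computable z.

Replication rule for robustness modes: alternative-strategy p < 0.05
(strict) and a z of the same sign as the main analysis.

## Enrichment

Primary output is the pooled-variance two-proportion z without continuity
correction — the formula used by common online two-proportion calculators —
with Fisher's exact test reported alongside for small counts. A pooled
proportion of exactly 0 or 1 leaves z undefined (NaN) while the Fisher p is
still returned.

## Validation experiment sizes

The experiment drivers (`pwaskit.experiments`) use: 10,000 replicate null
GWAS draws for type-I error (binomial SE ≈ 0.002); 300 replicates of a
1,000-protein global-null proteome sharing one 200-SNP panel (the shared
GWAS induces the positive dependence a real scan has); 20 cohorts of
2,000 × 200 for REML recovery at h² = 0.4 plus 50 single-causal cohorts of
500 × 60 for weight recovery; and one end-to-end cohort of 500 samples ×
2,000 variants × 30 proteins with 6 disease-mediated proteins (γ = 0.12
each, h² = 0.3, age/sex covariate effects). These sizes keep Monte-Carlo
error well inside the margins being tested while completing in minutes on
one CPU.

## Known limitations

* The LD emulator's genotypes are marginally HWE but not haplotype-derived;
  methods sensitive to haplotype structure would need a coalescent
  simulator.
* cv_p is a ranking device, not calibrated inference (see above).
* The bslmm approximation omits BSLMM's polygenic background component and
  will under-shrink relative to GEMMA's sampler on highly polygenic
  architectures.
* Single-GRM REML only; no multi-component or bivariate models.
* The association test assumes the LD reference matches the GWAS
  population; mismatch inflates or deflates the quadratic form and is not
  detected beyond the coverage diagnostic.
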