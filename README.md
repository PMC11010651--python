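# pwaskit

A toolkit for proteome-wide association studies (PWAS): building genetic
prediction models of plasma protein levels from **cis and trans** variants,
testing genetically predicted protein levels against disease GWAS summary
statistics, and the supporting machinery — variant QC, phenotype
preparation, GREML heritability, and gene-set enrichment — all validated
offline through a first-class synthetic-data generator.

## Who this is for

Statistical geneticists and cancer epidemiologists who want to ask: *does a
plasma protein's genetically regulated component associate with disease
risk?* Directly measured protein biomarkers suffer from confounding and
reverse causation; using germline variants as instruments sidesteps both.
The design instantiated here mirrors studies that train protein prediction
weights in a genotyped, SOMAscan-profiled cohort and test them against a
large case-control GWAS (e.g. pancreatic ductal adenocarcinoma, with
8,275 cases and 6,723 controls).

## The statistics at the core

**Prediction models.** For each protein, candidate predictors are seeded by
a marginal scan: cis variants (within 1 Mb of the encoding gene's TSS) at
BH-FDR < 0.05, trans variants at P ≤ 5×10⁻⁸, each seed expanded to all
QC-passing variants within 100 kb. Weights **w** on the
standardized-genotype scale are fit by `top1`, LASSO, elastic net
(mixing 0.5) and BLUP (ridge with penalty λ = m(1−ĥ²)/ĥ²); the method with
the most significant 5-fold cross-validation P wins, models with CV R² <
0.01 are discarded, and external validation passes at Pearson r ≥ 0.1.
A spike-and-slab Gibbs sampler (a BSLMM-style point-normal model) and
LD pruning (r² = 0.1, 250 kb) provide robustness modes.

**Association test.** With GWAS Wald z-scores **Z** and an LD reference
correlation matrix Σ,

```
z = wᵀZ / √(wᵀ Σ w)
```

is asymptotically standard normal under the null; two-sided p-values are
BH-FDR corrected across the tested proteome (significance at q ≤ 0.05).
Alleles are harmonized between model, GWAS and reference before testing,
and proteins retaining less than half their |w| mass are flagged untestable
rather than scored.

**Heritability.** Single-component GREML: y ~ N(μ, σ²g·A + σ²e·I) with A
the GRM from standardized dosages, fit by AI-REML with an EM fallback;
ĥ² = σ²g/(σ²g+σ²e) clamped to [0, 1]. Comparing cis+trans with cis-only
candidate sets quantifies how much heritability trans variants add.

**Enrichment.** The pooled two-proportion z test (with Fisher's exact
companion) compares the fraction of associated-protein genes carrying
qualifying somatic mutations against the background gene set.

## Worked example

`examples/03_pwas_association.py` simulates five proteins, one of which
(PROT2) causally raises disease liability, trains prediction models, and
tests them against a simulated case-control GWAS:

```
GWAS: 300 SNPs, N = 14998 (8,275 cases + 6,723 controls)
protein         z            p            q  n_snps_used  significant
  PROT2 10.159552 3.004532e-24 1.502266e-23           13         True
  PROT3 -1.519789 1.285639e-01 3.072077e-01           14        False
  PROT0  1.327557 1.843246e-01 3.072077e-01            1        False
  PROT1 -0.258181 7.962672e-01 7.974225e-01            8        False
  PROT4 -0.256684 7.974225e-01 7.974225e-01            6        False
```

The mediated protein surfaces with |z| ≈ 10 and survives FDR control; the
null proteins' z-scores behave like standard normal draws. The other
examples cover cohort simulation (`01`), model training and external
validation (`02`), cis+trans vs cis-only heritability (`04`), and the
somatic-mutation enrichment test (`05`), each printing the quantities it
computes and a line on what they mean.

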