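"""Synthetic cohort generation for the protein-prediction / PWAS pipeline.

Generates LD-structured genotype dosages, plasma-protein phenotypes with a
specified cis/trans causal architecture and heritability, covariate effects,
LD reference panels, and case-control GWAS summary z-scores with or without a
protein-mediated disease effect.  Everything is seeded and bit-reproducible,
so every downstream stage (QC, model training, heritability, association
testing) can be validated offline against known truth.

Linkage disequilibrium is emulated by a latent multivariate Gaussian with
block-wise AR(1) correlation, thresholded at the Hardy-Weinberg genotype
quantiles of each variant's minor allele frequency.  This preserves MAF and
HWE exactly in expectation while giving a tunable, seedable correlation
structure; it makes no attempt at recombination-map realism, coalescent
genealogies, or population structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VariantSpec",
    "ArchitectureSpec",
    "DiseaseModel",
    "GenotypeMatrix",
    "LDReference",
    "ProteinTruth",
    "make_variants",
    "simulate_genotypes",
    "simulate_proteome",
    "simulate_levels_from_truth",
    "simulate_gwas_summary",
    "make_reference_panel",
]

_NUCLEOTIDES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class VariantSpec:
    """Metadata for a single biallelic variant.

    ``maf`` is the frequency of the effect (minor) allele, in (0, 0.5].
    ``info`` is the imputation-quality score in [0, 1]; values below 1 make
    simulated dosages fractional (noisy).  ``missing_rate`` is the fraction
    of sample calls set missing, for exercising QC filters.
    """

    chrom: str
    pos: int
    id: str
    ref_allele: str
    effect_allele: str
    maf: float
    info: float = 1.0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.maf <= 0.5):
            raise ValueError(f"maf must be in (0, 0.5], got {self.maf}")
        if not (0.0 <= self.info <= 1.0):
            raise ValueError(f"info must be in [0, 1], got {self.info}")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.ref_allele == self.effect_allele:
            raise ValueError(f"alleles must differ for {self.id}")

    @property
    def is_strand_ambiguous(self) -> bool:
        """A/T and C/G pairs cannot be strand-resolved from alleles alone."""
        return {self.ref_allele, self.effect_allele} in ({"A", "T"}, {"C", "G"})


@dataclass(frozen=True)
class ArchitectureSpec:
    """Causal architecture of one simulated protein.

    ``h2`` is the narrow-sense heritability: the fraction of the
    (genetic + noise) phenotypic variance explained by the causal variants.
    Cis causal variants are drawn within ``cis_window_bp`` of ``tss`` on
    ``tss_chrom``; trans causal variants from everywhere else.
    """

    n_cis_causal: int
    n_trans_causal: int
    h2: float
    tss: int
    tss_chrom: str = "1"
    cis_window_bp: int = 1_000_000
    covariate_effects: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_cis_causal < 0 or self.n_trans_causal < 0:
            raise ValueError("causal counts must be nonnegative")
        if not (0.0 <= self.h2 < 1.0):
            raise ValueError(f"h2 must be in [0, 1), got {self.h2}")


@dataclass(frozen=True)
class DiseaseModel:
    """Liability-scale disease model for GWAS summary generation.

    ``gamma`` is the standardized effect of the (standardized) protein level
    on disease liability; gamma = 0 gives an exact null.  Default case and
    control counts mirror a large pancreatic-cancer case-control GWAS.
    """

    gamma: float
    n_case: int = 8275
    n_control: int = 6723

    def __post_init__(self) -> None:
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("n_case and n_control must be >= 1")

    @property
    def n_eff(self) -> float:
        """Effective sample size 4 / (1/n_case + 1/n_control)."""
        return 4.0 / (1.0 / self.n_case + 1.0 / self.n_control)


@dataclass
class GenotypeMatrix:
    """Sample x variant dosage matrix with per-variant metadata.

    Dosages count copies of the effect (minor) allele; missing calls are NaN.
    """

    dosages: np.ndarray
    variants: list[VariantSpec]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        n, m = self.dosages.shape
        if m != len(self.variants):
            raise ValueError("variant metadata does not match dosage columns")
        if n != len(self.sample_ids):
            raise ValueError("sample ids do not match dosage rows")
        ids = [v.id for v in self.variants]
        if len(set(ids)) != len(ids):
            raise ValueError("variant ids must be unique")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def variant_index(self) -> dict:
        return {v.id: j for j, v in enumerate(self.variants)}

    def empirical_maf(self) -> np.ndarray:
        """Minor-allele frequency from observed (non-missing) dosages."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            freq = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def standardized(self, ddof: int = 0) -> np.ndarray:
        """Mean-imputed, column-standardized dosages (mean 0, variance 1).

        Monomorphic columns come back as all-zero rather than NaN.
        """
        X = self.dosages.copy()
        col_mean = np.nanmean(X, axis=0)
        nan_r, nan_c = np.where(np.isnan(X))
        X[nan_r, nan_c] = col_mean[nan_c]
        X -= X.mean(axis=0)
        sd = X.std(axis=0, ddof=ddof)
        keep = sd > 0
        X[:, keep] /= sd[keep]
        X[:, ~keep] = 0.0
        return X

    def subset(self, snp_ids) -> "GenotypeMatrix":
        idx = self.variant_index()
        cols = [idx[s] for s in snp_ids]
        return GenotypeMatrix(
            self.dosages[:, cols],
            [self.variants[j] for j in cols],
            list(self.sample_ids),
        )


@dataclass
class LDReference:
    """Variant correlation structure estimated from reference genotypes."""

    snp_ids: list[str]
    effect_alleles: list[str]
    other_alleles: list[str]
    corr: np.ndarray

    def __post_init__(self) -> None:
        self.corr = np.asarray(self.corr, dtype=float)
        k = len(self.snp_ids)
        if self.corr.shape != (k, k):
            raise ValueError("corr shape does not match snp ids")

    def index(self) -> dict:
        return {s: j for j, s in enumerate(self.snp_ids)}


@dataclass
class ProteinTruth:
    """Ground truth for one simulated protein: causal ids and effects on the
    standardized-genotype scale, plus each sample's true genetic value."""

    protein_id: str
    causal_ids: list[str]
    effects: np.ndarray  # standardized-genotype scale, variance-normalized
    genetic_values: np.ndarray
    h2: float


def make_variants(
    n_variants: int,
    chrom: str = "1",
    start: int = 1_000_000,
    spacing: int = 5_000,
    maf_range: tuple = (0.05, 0.5),
    info: float = 1.0,
    missing_rate: float = 0.0,
    seed: int = 0,
    prefix: str = "rs",
) -> list[VariantSpec]:
    """Convenience grid of variant specs with uniformly drawn MAFs."""
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(maf_range[0], maf_range[1], size=n_variants)
    out = []
    for j in range(n_variants):
        ref, eff = rng.choice(_NUCLEOTIDES, size=2, replace=False)
        out.append(
            VariantSpec(
                chrom=chrom,
                pos=start + j * spacing,
                id=f"{prefix}{chrom}_{j}",
                ref_allele=str(ref),
                effect_allele=str(eff),
                maf=float(mafs[j]),
                info=info,
                missing_rate=missing_rate,
            )
        )
    return out


def _check_blocks(n_variants: int, block_sizes) -> list[int]:
    if block_sizes is None:
        return [n_variants]
    block_sizes = [int(b) for b in block_sizes]
    if any(b < 1 for b in block_sizes):
        raise ValueError("block sizes must be positive")
    if sum(block_sizes) != n_variants:
        raise ValueError(
            f"block sizes sum to {sum(block_sizes)}, expected {n_variants}"
        )
    return block_sizes


def simulate_genotypes(
    n_samples: int,
    variants: list[VariantSpec],
    ld_rho: float = 0.0,
    block_sizes=None,
    seed: int = 0,
) -> GenotypeMatrix:
    """Draw HWE genotype dosages with block-AR(1) latent LD.

    Within a block, adjacent variants' latent Gaussians have correlation
    ``ld_rho``; variants k apart have ld_rho**k.  Blocks are independent.
    The latent normal is cut at the HWE genotype quantiles of each variant's
    MAF, so genotype margins are Hardy-Weinberg by construction.  Variants
    with ``info`` < 1 get Gaussian dosage noise of variance
    (1 - info) * 2 * maf * (1 - maf), clipped to [0, 2], mimicking imputation
    uncertainty; ``missing_rate`` > 0 masks calls at random.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if not (0.0 <= ld_rho < 1.0):
        raise ValueError(f"ld_rho must be in [0, 1), got {ld_rho}")
    ids = [v.id for v in variants]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate variant ids")
    for chrom in {v.chrom for v in variants}:
        pos = [v.pos for v in variants if v.chrom == chrom]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError(f"positions must be strictly increasing on chr{chrom}")
    blocks = _check_blocks(len(variants), block_sizes)

    rng = np.random.default_rng(seed)
    m = len(variants)
    latent = np.empty((n_samples, m))
    j = 0
    for b in blocks:
        eps = rng.standard_normal((n_samples, b))
        block = np.empty((n_samples, b))
        block[:, 0] = eps[:, 0]
        scale = np.sqrt(1.0 - ld_rho**2)
        for k in range(1, b):
            block[:, k] = ld_rho * block[:, k - 1] + scale * eps[:, k]
        latent[:, j : j + b] = block
        j += b

    u = stats.norm.cdf(latent)
    dos = np.zeros((n_samples, m))
    for j, v in enumerate(variants):
        p = v.maf
        c0 = (1.0 - p) ** 2          # P(genotype 0) under HWE
        c1 = c0 + 2.0 * p * (1.0 - p)  # P(genotype <= 1)
        dos[:, j] = (u[:, j] >= c0).astype(float) + (u[:, j] >= c1)
        if v.info < 1.0:
            noise_var = (1.0 - v.info) * 2.0 * p * (1.0 - p)
            dos[:, j] = np.clip(
                dos[:, j] + rng.normal(0.0, np.sqrt(noise_var), n_samples), 0.0, 2.0
            )
        if v.missing_rate > 0.0:
            mask = rng.random(n_samples) < v.missing_rate
            dos[mask, j] = np.nan

    samples = [f"S{i:06d}" for i in range(n_samples)]
    return GenotypeMatrix(dos, list(variants), samples)


def _pick_causals(
    genotypes: GenotypeMatrix, arch: ArchitectureSpec, rng: np.random.Generator
) -> list[int]:
    cis_idx, trans_idx = [], []
    for j, v in enumerate(genotypes.variants):
        if v.chrom == arch.tss_chrom and abs(v.pos - arch.tss) <= arch.cis_window_bp:
            cis_idx.append(j)
        else:
            trans_idx.append(j)
    if arch.n_cis_causal > len(cis_idx):
        raise ValueError(
            f"requested {arch.n_cis_causal} cis causal variants, only "
            f"{len(cis_idx)} available within the cis window"
        )
    if arch.n_trans_causal > len(trans_idx):
        raise ValueError(
            f"requested {arch.n_trans_causal} trans causal variants, only "
            f"{len(trans_idx)} available"
        )
    chosen = []
    if arch.n_cis_causal:
        chosen += list(rng.choice(cis_idx, size=arch.n_cis_causal, replace=False))
    if arch.n_trans_causal:
        chosen += list(rng.choice(trans_idx, size=arch.n_trans_causal, replace=False))
    return sorted(int(j) for j in chosen)


def simulate_proteome(
    genotypes: GenotypeMatrix,
    arch: ArchitectureSpec,
    covariates: pd.DataFrame | None = None,
    seed: int = 0,
    protein_id: str = "P0",
) -> tuple[np.ndarray, ProteinTruth]:
    """Simulate one protein's plasma levels from a causal architecture.

    levels = genetic value + covariate term + Gaussian noise, with the
    genetic value rescaled so that it contributes exactly the fraction
    ``arch.h2`` of the genetic-plus-noise variance (covariate effects sit on
    top of that).  Returns the levels and a :class:`ProteinTruth` record for
    recovery testing.
    """
    rng = np.random.default_rng(seed)
    n = genotypes.n_samples
    idx = _pick_causals(genotypes, arch, rng)
    X = genotypes.standardized()

    g = np.zeros(n)
    effects = np.zeros(len(idx))
    if idx and arch.h2 > 0:
        raw = rng.standard_normal(len(idx))
        g_raw = X[:, idx] @ raw
        sd = g_raw.std()
        if sd > 0:
            scale = np.sqrt(arch.h2) / sd
            effects = raw * scale
            g = g_raw * scale
    noise = rng.standard_normal(n) * np.sqrt(1.0 - arch.h2)

    cov_term = np.zeros(n)
    for name, coef in arch.covariate_effects.items():
        if covariates is None or name not in covariates.columns:
            raise ValueError(f"covariate '{name}' not provided")
        cov_term = cov_term + coef * covariates[name].to_numpy(dtype=float)

    levels = g + cov_term + noise
    truth = ProteinTruth(
        protein_id=protein_id,
        causal_ids=[genotypes.variants[j].id for j in idx],
        effects=effects,
        genetic_values=g,
        h2=arch.h2,
    )
    return levels, truth


def simulate_levels_from_truth(
    genotypes: GenotypeMatrix,
    truth: ProteinTruth,
    covariates: pd.DataFrame | None = None,
    covariate_effects: dict | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Protein levels for a new cohort under an existing causal truth.

    Emulates measuring the same protein in an independent validation
    subcohort: the causal variants and their standardized effects are those
    of ``truth``; only the environmental noise (and optional covariate
    term) is redrawn.
    """
    rng = np.random.default_rng(seed)
    idx = genotypes.variant_index()
    missing = [s for s in truth.causal_ids if s not in idx]
    if missing:
        raise ValueError(f"causal variants absent from cohort: {missing[:5]}")
    X = genotypes.standardized()
    g = (
        X[:, [idx[s] for s in truth.causal_ids]] @ np.asarray(truth.effects)
        if truth.causal_ids
        else np.zeros(genotypes.n_samples)
    )
    noise = rng.standard_normal(genotypes.n_samples) * np.sqrt(1.0 - truth.h2)
    cov_term = np.zeros(genotypes.n_samples)
    for name, coef in (covariate_effects or {}).items():
        if covariates is None or name not in covariates.columns:
            raise ValueError(f"covariate '{name}' not provided")
        cov_term = cov_term + coef * covariates[name].to_numpy(dtype=float)
    return g + cov_term + noise


def make_reference_panel(
    genotypes: GenotypeMatrix, snp_ids=None
) -> LDReference:
    """Pearson correlation of standardized dosages over a reference cohort.

    Monomorphic variants have undefined correlations; they are excluded with
    a warning.
    """
    if genotypes.n_samples < 2:
        raise ValueError("need >= 2 reference samples")
    g = genotypes if snp_ids is None else genotypes.subset(snp_ids)
    sd = np.nanstd(g.dosages, axis=0)
    mono = np.where(~(sd > 0))[0]
    if mono.size:
        bad = [g.variants[j].id for j in mono]
        warnings.warn(
            f"excluding {len(bad)} monomorphic variant(s) from LD panel: {bad[:5]}"
        )
        keep = [v.id for j, v in enumerate(g.variants) if j not in set(mono)]
        g = g.subset(keep)
    X = g.standardized()
    n = X.shape[0]
    corr = (X.T @ X) / n
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return LDReference(
        snp_ids=g.variant_ids,
        effect_alleles=[v.effect_allele for v in g.variants],
        other_alleles=[v.ref_allele for v in g.variants],
        corr=corr,
    )


def _floored_sqrt_factor(sigma: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Symmetric square root of sigma with eigenvalues floored at `floor`."""
    w, V = np.linalg.eigh((sigma + sigma.T) / 2.0)
    w = np.maximum(w, floor)
    return V * np.sqrt(w)


def simulate_gwas_summary(
    ld: LDReference,
    protein_truth: ProteinTruth,
    disease: DiseaseModel,
    seed: int = 0,
) -> pd.DataFrame:
    """Case-control GWAS z-scores consistent with an LD reference and a
    protein-mediated disease effect.

    Z ~ MVN(sqrt(N_eff) * gamma * (Sigma @ b_std), Sigma) where b_std are the
    protein's standardized causal effects mapped onto the panel's variants and
    N_eff = 4 / (1/n_case + 1/n_control).  gamma = 0 yields an exact null
    with the panel's correlation structure.  Returns a frame with columns
    snp, a1 (effect allele), a2, z, n.
    """
    pos = ld.index()
    missing = [s for s in protein_truth.causal_ids if s not in pos]
    if missing:
        raise ValueError(f"causal variants absent from LD reference: {missing[:5]}")
    k = len(ld.snp_ids)
    b = np.zeros(k)
    for s, e in zip(protein_truth.causal_ids, protein_truth.effects):
        b[pos[s]] = e

    mean = np.sqrt(disease.n_eff) * disease.gamma * (ld.corr @ b)
    rng = np.random.default_rng(seed)
    A = _floored_sqrt_factor(ld.corr)
    z = mean + A @ rng.standard_normal(k)
    return pd.DataFrame(
        {
            "snp": ld.snp_ids,
            "a1": ld.effect_alleles,
            "a2": ld.other_alleles,
            "z": z,
            "n": int(round(disease.n_case + disease.n_control)),
        }
    )
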