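"""Variant QC and protein phenotype preparation.

Variant filters mirror standard imputed-genotype QC for pQTL model building:
imputation INFO >= 0.7, minor allele frequency >= 0.05 (or minor allele
count >= 5 in ``maf_mode="count"``), exact Hardy-Weinberg P >= 5e-6,
missing rate < 5%, presence in the LD reference panel, and exclusion of
strand-ambiguous (A/T, C/G) variants.  Phenotypes are prepared as
rank-inverse-normal transformed residuals after ordinary-least-squares
covariate adjustment, the conventional pipeline for SOMAscan-style plasma
proteomics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .simulate import GenotypeMatrix

__all__ = [
    "QCThresholds",
    "PhenotypeResiduals",
    "hwe_exact_test",
    "filter_variants",
    "adjust_covariates",
    "rank_inverse_normal",
    "prepare_phenotype",
]


@dataclass(frozen=True)
class QCThresholds:
    """Variant QC thresholds.

    ``maf_mode`` selects between a frequency floor (``"freq"``: MAF >=
    min_maf) and an absolute minor-allele-count floor (``"count"``: MAC >=
    min_mac).
    """

    min_info: float = 0.7
    min_maf: float = 0.05
    min_mac: int = 5
    maf_mode: str = "freq"
    hwe_p_floor: float = 5e-6
    max_missing: float = 0.05
    require_panel_presence: bool = True
    exclude_strand_ambiguous: bool = True

    def __post_init__(self) -> None:
        for v in (self.min_info, self.min_maf, self.max_missing):
            if not (0.0 <= v <= 1.0):
                raise ValueError("thresholds must lie in [0, 1]")
        if not (0.0 < self.hwe_p_floor < 1.0):
            raise ValueError("hwe_p_floor must be in (0, 1)")
        if self.maf_mode not in ("freq", "count"):
            raise ValueError("maf_mode must be 'freq' or 'count'")


@dataclass
class PhenotypeResiduals:
    """Covariate-adjusted, rank-inverse-normalized protein levels."""

    values: np.ndarray
    protein_id: str
    covariates_used: list[str] = field(default_factory=list)


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and enumerates all heterozygote
    counts of matching parity; p is the probability mass of tables no more
    probable than the observed one (no mid-p correction).  Symmetric under
    allele relabeling; monomorphic input returns 1.0.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("at least one genotyped sample required")
    n_rare = 2 * min(n_AA, n_aa) + n_Aa
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0

    # log-probability of each heterozygote count given allele counts
    het_values = list(range(n_rare % 2, n_rare + 1, 2))
    lgamma = math.lgamma
    log_probs = []
    for het in het_values:
        rare_hom = (n_rare - het) // 2
        common_hom = n - het - rare_hom
        lp = (
            het * math.log(2.0)
            + lgamma(n + 1) - lgamma(het + 1) - lgamma(rare_hom + 1)
            - lgamma(common_hom + 1)
            + lgamma(n_rare + 1) + lgamma(2 * n - n_rare + 1) - lgamma(2 * n + 1)
        )
        log_probs.append(lp)
    log_probs = np.array(log_probs)
    probs = np.exp(log_probs - log_probs.max())
    probs /= probs.sum()
    obs = het_values.index(n_Aa)
    p = float(probs[probs <= probs[obs] * (1.0 + 1e-12)].sum())
    return min(p, 1.0)


def _hard_call_counts(col: np.ndarray) -> tuple[int, int, int]:
    """Round dosages to hard calls and count genotype classes (effect-allele
    dosage 2 / 1 / 0), ignoring missing."""
    obs = col[~np.isnan(col)]
    calls = np.clip(np.round(obs), 0, 2).astype(int)
    return (
        int(np.sum(calls == 2)),
        int(np.sum(calls == 1)),
        int(np.sum(calls == 0)),
    )


def filter_variants(
    g: GenotypeMatrix,
    t: QCThresholds = QCThresholds(),
    panel_ids: set | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply variant QC; return filtered genotypes and a per-variant report.

    Rules are evaluated in a fixed order (info, maf, hwe, missing, panel,
    strand-ambiguity) and the report records the first failing rule for each
    dropped variant.  Boundary conventions: info >= min_info kept, MAF >=
    min_maf kept, HWE p >= hwe_p_floor kept, missing rate < max_missing kept
    (equality dropped).
    """
    if t.require_panel_presence and panel_ids is None:
        raise ValueError("panel_ids required when require_panel_presence is set")
    maf = g.empirical_maf()
    miss = g.missing_rate()
    n_obs = (~np.isnan(g.dosages)).sum(axis=0)

    rows = []
    for j, v in enumerate(g.variants):
        reason = ""
        if v.info < t.min_info:
            reason = "low_info"
        elif t.maf_mode == "freq" and not (maf[j] >= t.min_maf):
            reason = "low_maf"
        elif t.maf_mode == "count" and not (maf[j] * 2 * n_obs[j] >= t.min_mac):
            reason = "low_mac"
        else:
            hwe_p = hwe_exact_test(*_hard_call_counts(g.dosages[:, j]))
            if not (hwe_p >= t.hwe_p_floor):
                reason = "hwe_fail"
            elif not (miss[j] < t.max_missing):
                reason = "high_missing"
            elif t.require_panel_presence and v.id not in panel_ids:
                reason = "not_in_panel"
            elif t.exclude_strand_ambiguous and v.is_strand_ambiguous:
                reason = "strand_ambiguous"
        rows.append(
            {
                "variant_id": v.id,
                "kept": reason == "",
                "reason": reason or "pass",
                "maf": maf[j],
                "info": v.info,
                "missing_rate": miss[j],
            }
        )
    report = pd.DataFrame(rows)
    keep_ids = report.loc[report["kept"], "variant_id"].tolist()
    if not keep_ids:
        warnings.warn("all variants removed by QC filters")
        filtered = GenotypeMatrix(
            np.empty((g.n_samples, 0)), [], list(g.sample_ids)
        )
    else:
        filtered = g.subset(keep_ids)
    return filtered, report


def adjust_covariates(
    levels: np.ndarray, covariates: pd.DataFrame
) -> np.ndarray:
    """OLS residuals of protein levels on covariates plus an intercept.

    Rows with missing values (in levels or any covariate) are dropped from
    the fit and returned as NaN.  Collinear covariate columns are removed
    with a warning via pivoted QR.  Residuals are orthogonal to every
    retained covariate column.
    """
    y = np.asarray(levels, dtype=float)
    C = covariates.to_numpy(dtype=float)
    if C.shape[0] != y.shape[0]:
        raise ValueError("levels and covariates have different lengths")
    ok = np.isfinite(y) & np.all(np.isfinite(C), axis=1)
    if not ok.all():
        warnings.warn(f"dropping {int((~ok).sum())} row(s) with missing values")

    X = np.column_stack([np.ones(int(ok.sum())), C[ok]])
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int(np.sum(diag > tol))
    if rank < X.shape[1]:
        dropped = sorted(piv[rank:])
        names = ["(intercept)"] + list(covariates.columns)
        warnings.warn(
            "dropping collinear covariate column(s): "
            + ", ".join(names[j] for j in dropped)
        )
        X = X[:, sorted(piv[:rank])]

    beta, *_ = np.linalg.lstsq(X, y[ok], rcond=None)
    resid = np.full_like(y, np.nan)
    resid[ok] = y[ok] - X @ beta
    return resid


def rank_inverse_normal(values: np.ndarray) -> np.ndarray:
    """Blom rank-inverse-normal transform Phi^-1((rank - 3/8) / (n + 1/4)).

    Ties take average ranks; the map is monotone in the input and invariant
    to any strictly increasing transform of it.  All-identical input carries
    no ordering information and is rejected.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-D vector with n >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    if np.ptp(x) == 0:
        raise ValueError("all values identical; rank transform undefined")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.375) / (x.size + 0.25))


def prepare_phenotype(
    levels: np.ndarray,
    covariates: pd.DataFrame | None,
    protein_id: str = "P0",
    log_transform: bool = False,
) -> PhenotypeResiduals:
    """Full phenotype pipeline: optional log of raw positive levels,
    covariate adjustment, then rank-inverse-normal transform."""
    y = np.asarray(levels, dtype=float)
    if log_transform:
        if np.any(y <= 0):
            raise ValueError("log transform requires strictly positive levels")
        y = np.log(y)
    used: list[str] = []
    if covariates is not None and covariates.shape[1] > 0:
        y = adjust_covariates(y, covariates)
        used = list(covariates.columns)
    if np.isnan(y).any():
        raise ValueError("missing values remain after covariate adjustment")
    return PhenotypeResiduals(
        values=rank_inverse_normal(y), protein_id=protein_id, covariates_used=used
    )
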