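"""Summary-statistics association test for genetically predicted proteins.

For each protein with trained SNP weights w, GWAS Wald z-scores Z, and an
LD reference correlation matrix Sigma, the weighted-burden statistic is

    z = w' Z / sqrt(w' Sigma w)

with a two-sided standard-normal p-value, and Benjamini-Hochberg FDR control
across the family of proteins with a computable statistic.  Before testing,
model, GWAS and reference are harmonized by SNP id and allele orientation:
swapped effect/other alleles flip the GWAS z sign (and the reference row
signs); SNPs missing from either source are dropped, and a protein whose
retained |w| mass falls below half is flagged untestable rather than scored
on a remnant of its model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import PredictionModel
from .simulate import LDReference

__all__ = [
    "Harmonized",
    "harmonize",
    "pwas_z",
    "bh_fdr",
    "run_pwas",
    "replication_flags",
]

_P_FLOOR = np.finfo(float).tiny


@dataclass
class Harmonized:
    """Aligned (w, Z, Sigma) triple plus the coverage diagnostic."""

    snp_ids: list
    w: np.ndarray
    z: np.ndarray
    sigma: np.ndarray
    coverage: float
    dropped: list = field(default_factory=list)  # (snp, reason)
    untestable: bool = False


def harmonize(
    model: PredictionModel,
    gwas: pd.DataFrame,
    ref: LDReference,
    min_coverage: float = 0.5,
) -> Harmonized:
    """Match model SNPs to GWAS and reference by id, aligning alleles.

    A GWAS (or reference) record whose effect/other alleles are swapped
    relative to the model contributes with flipped sign; records whose
    alleles neither match nor swap are dropped with reason
    ``allele_mismatch``.  ``coverage`` is the |w| mass retained; below
    ``min_coverage`` the result is flagged untestable.
    """
    if len(model.snp_ids) == 0:
        raise ValueError("empty prediction model")
    gw = gwas.set_index("snp")
    ref_idx = ref.index()

    keep, w_list, z_list, ref_sign = [], [], [], []
    dropped = []
    for k, snp in enumerate(model.snp_ids):
        if snp not in gw.index:
            dropped.append((snp, "missing_from_gwas"))
            continue
        if snp not in ref_idx:
            dropped.append((snp, "missing_from_reference"))
            continue
        ea, oa = model.effect_alleles[k], model.other_alleles[k]
        row = gw.loc[snp]
        if (row["a1"], row["a2"]) == (ea, oa):
            z_sign = 1.0
        elif (row["a2"], row["a1"]) == (ea, oa):
            z_sign = -1.0
        else:
            dropped.append((snp, "allele_mismatch"))
            continue
        j = ref_idx[snp]
        ra, ro = ref.effect_alleles[j], ref.other_alleles[j]
        if (ra, ro) == (ea, oa):
            s_ref = 1.0
        elif (ro, ra) == (ea, oa):
            s_ref = -1.0
        else:
            dropped.append((snp, "allele_mismatch"))
            continue
        keep.append((snp, j))
        w_list.append(model.weights[k])
        z_list.append(z_sign * float(row["z"]))
        ref_sign.append(s_ref)

    total_mass = float(np.sum(np.abs(model.weights)))
    kept_mass = float(np.sum(np.abs(w_list))) if w_list else 0.0
    coverage = kept_mass / total_mass if total_mass > 0 else 0.0

    if keep:
        cols = [j for _, j in keep]
        s = np.asarray(ref_sign)
        sigma = ref.corr[np.ix_(cols, cols)] * np.outer(s, s)
    else:
        sigma = np.empty((0, 0))
    return Harmonized(
        snp_ids=[snp for snp, _ in keep],
        w=np.asarray(w_list, dtype=float),
        z=np.asarray(z_list, dtype=float),
        sigma=sigma,
        coverage=coverage,
        dropped=dropped,
        untestable=coverage < min_coverage,
    )


def pwas_z(
    w: np.ndarray, Z: np.ndarray, Sigma: np.ndarray, eig_floor: float = 1e-8
) -> tuple[float, float]:
    """The weighted-burden statistic z = w'Z / sqrt(w' Sigma w) and its
    two-sided normal p-value.

    Sigma must be symmetric; its eigenvalues are floored at ``eig_floor`` to
    keep the quadratic form positive on rank-deficient panels.  A quadratic
    form below 1e-8 (weights annihilated by the floor) yields (nan, nan).
    The p-value is evaluated through the survival function, which stays
    accurate far into the tail (|z| well beyond 6), and floored at the
    smallest positive float so it remains in (0, 1].
    """
    w = np.asarray(w, dtype=float)
    Z = np.asarray(Z, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    if not (w.shape == Z.shape and Sigma.shape == (w.size, w.size)):
        raise ValueError("dimension mismatch between w, Z and Sigma")
    if w.size == 0 or not np.any(w != 0):
        raise ValueError("weights must be nonempty and not all zero")
    if not np.allclose(Sigma, Sigma.T, atol=1e-10):
        raise ValueError("Sigma must be symmetric")

    evals, V = np.linalg.eigh(Sigma)
    evals = np.maximum(evals, eig_floor)
    q = float((V.T @ w) ** 2 @ evals)
    if q < 1e-8:
        return float("nan"), float("nan")
    z = float(w @ Z) / np.sqrt(q)
    p = float(np.clip(2.0 * stats.norm.sf(abs(z)), _P_FLOOR, 1.0))
    return z, p


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (running-minimum adjusted)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def run_pwas(
    models,
    gwas: pd.DataFrame,
    ref: LDReference,
    min_coverage: float = 0.5,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Harmonize and test every protein model against one GWAS.

    Proteins flagged untestable (coverage below ``min_coverage``) or with a
    degenerate quadratic form are reported with NaN statistics and excluded
    from the FDR family.  Output is sorted by p then protein id, with
    columns protein, gene, z, p, q, n_snps_used, coverage, direction,
    significant.
    """
    rows = []
    for model in models:
        h = harmonize(model, gwas, ref, min_coverage=min_coverage)
        if h.untestable or h.w.size == 0:
            z, p = float("nan"), float("nan")
        else:
            z, p = pwas_z(h.w, h.z, h.sigma)
        rows.append(
            {
                "protein": model.protein_id,
                "gene": model.gene,
                "z": z,
                "p": p,
                "n_snps_used": len(h.snp_ids),
                "coverage": h.coverage,
                "direction": int(np.sign(z)) if np.isfinite(z) else 0,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["protein", "gene", "z", "p", "n_snps_used", "coverage", "direction"],
    )
    out["q"] = np.nan
    testable = out["p"].notna()
    if testable.any():
        out.loc[testable, "q"] = bh_fdr(out.loc[testable, "p"].to_numpy())
    out["significant"] = out["q"] <= fdr_threshold
    out = out.sort_values(
        ["p", "protein"], na_position="last", kind="mergesort"
    ).reset_index(drop=True)
    if (~testable).any():
        warnings.warn(
            f"{int((~testable).sum())} protein(s) untestable (low coverage or "
            "degenerate LD); reported as missing"
        )
    return out[
        ["protein", "gene", "z", "p", "q", "n_snps_used", "coverage",
         "direction", "significant"]
    ]


def replication_flags(main: pd.DataFrame, alt: pd.DataFrame) -> pd.Series:
    """Robustness replication rule: an association replicates under an
    alternative strategy iff the alternative's nominal p < 0.05 (strict) and
    its z has the same sign as the main analysis."""
    m = main.set_index("protein")
    a = alt.set_index("protein")
    flags = {}
    for protein in m.index:
        if protein not in a.index:
            flags[protein] = False
            continue
        pz, az = m.loc[protein, "z"], a.loc[protein, "z"]
        ap = a.loc[protein, "p"]
        flags[protein] = bool(
            np.isfinite(az) and np.isfinite(ap)
            and ap < 0.05 and np.sign(az) == np.sign(pz)
        )
    return pd.Series(flags, name="replicated")
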