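"""Readers and writers for the pipeline's on-disk formats.

PLINK .bed/.bim/.fam (SNP-major 2-bit codec, hard calls), a TSV dosage
dialect (samples x variants, header row of variant ids, first column sample
id), GWAS summary TSV (snp, chr, pos, a1, a2, z, n), per-protein weight
files with a JSON manifest, and GCTA-style GRM output (plain TSV and the
binary grm.bin / grm.N.bin / grm.id triple).
"""

from __future__ import annotations

import json
import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import GenotypeMatrix, VariantSpec

__all__ = [
    "write_plink",
    "read_plink",
    "write_dosage_tsv",
    "read_dosage_tsv",
    "write_gwas_tsv",
    "read_gwas_tsv",
    "write_weights",
    "read_weights",
    "write_grm_tsv",
    "write_grm_gcta",
    "write_truth_manifest",
]

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major mode

# 2-bit PLINK codes, indexed by effect-allele (A1) dosage; 0b01 is missing
_CODE_FOR_DOSAGE = {2: 0b00, 1: 0b10, 0: 0b11}
_DOSAGE_FOR_CODE = {0b00: 2.0, 0b10: 1.0, 0b11: 0.0, 0b01: np.nan}


def write_plink(genotypes: GenotypeMatrix, prefix: str | Path) -> None:
    """Write hard-call genotypes as .bed/.bim/.fam.

    Fractional dosages are rounded to the nearest hard call; NaN becomes the
    PLINK missing code.  The effect allele is written as A1.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = genotypes.dosages.shape

    with open(prefix.with_suffix(".fam"), "w") as fh:
        for s in genotypes.sample_ids:
            fh.write(f"{s} {s} 0 0 0 -9\n")

    with open(prefix.with_suffix(".bim"), "w") as fh:
        for v in genotypes.variants:
            fh.write(f"{v.chrom}\t{v.id}\t0\t{v.pos}\t{v.effect_allele}\t{v.ref_allele}\n")

    stride = (n + 3) // 4
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        for j in range(m):
            col = genotypes.dosages[:, j]
            buf = bytearray(stride)
            for i in range(n):
                d = col[i]
                code = 0b01 if np.isnan(d) else _CODE_FOR_DOSAGE[int(round(d))]
                buf[i >> 2] |= code << ((i & 3) * 2)
            fh.write(bytes(buf))


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a .bed/.bim/.fam triple back into a :class:`GenotypeMatrix`."""
    prefix = Path(prefix)
    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"], dtype={"iid": str},
    )
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep="\t", header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "id": str, "a1": str, "a2": str},
    )
    n, m = len(fam), len(bim)
    stride = (n + 3) // 4
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed is not a SNP-major PLINK bed file")
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != stride * m:
        raise ValueError("bed payload size does not match fam/bim dimensions")
    body = body.reshape(m, stride)

    codes = np.empty((m, stride * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (body >> (2 * k)) & 0b11
    codes = codes[:, :n]
    lut = np.array([2.0, np.nan, 1.0, 0.0])
    dosages = lut[codes].T  # samples x variants

    variants = [
        VariantSpec(
            chrom=str(r.chrom), pos=int(r.pos), id=str(r.id),
            ref_allele=str(r.a2), effect_allele=str(r.a1),
            maf=_maf_or_default(dosages[:, j]),
        )
        for j, r in enumerate(bim.itertuples())
    ]
    return GenotypeMatrix(dosages, variants, fam["iid"].tolist())


def _maf_or_default(col: np.ndarray) -> float:
    f = float(np.nanmean(col)) / 2.0 if np.isfinite(np.nanmean(col)) else 0.5
    f = min(f, 1.0 - f)
    return f if 0.0 < f <= 0.5 else 0.5


def write_dosage_tsv(genotypes: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        genotypes.dosages, index=genotypes.sample_ids, columns=genotypes.variant_ids
    )
    df.index.name = "sample"
    df.to_csv(path, sep="\t", float_format="%.6g")


def read_dosage_tsv(
    path: str | Path, variants: list[VariantSpec] | None = None
) -> GenotypeMatrix:
    """Read the TSV dosage dialect; variant metadata can be supplied or is
    reconstructed minimally (positions by column order) when absent."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if variants is None:
        variants = [
            VariantSpec(
                chrom="1", pos=j + 1, id=str(c), ref_allele="A", effect_allele="G",
                maf=_maf_or_default(df[c].to_numpy(dtype=float)),
            )
            for j, c in enumerate(df.columns)
        ]
    else:
        if [v.id for v in variants] != list(df.columns):
            raise ValueError("provided variant metadata does not match columns")
    return GenotypeMatrix(df.to_numpy(dtype=float), variants, [str(s) for s in df.index])


def write_gwas_tsv(gwas: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ("snp", "chr", "pos", "a1", "a2", "z", "n") if c in gwas.columns]
    gwas[cols].to_csv(path, sep="\t", index=False)


def read_gwas_tsv(path: str | Path) -> pd.DataFrame:
    """GWAS summary TSV: requires snp, a1, a2, z; a1 is the allele whose
    dosage increase corresponds to a positive z."""
    df = pd.read_csv(path, sep="\t", dtype={"snp": str, "a1": str, "a2": str})
    required = {"snp", "a1", "a2", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"GWAS summary must have columns {sorted(required)}")
    return df


def write_weights(model, directory: str | Path) -> Path:
    """One TSV per protein (snp, chr, pos, effect_allele, other_allele,
    weight) plus a JSON manifest of method and fit metrics."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tsv = directory / f"{model.protein_id}.weights.tsv"
    pd.DataFrame(
        {
            "snp": model.snp_ids,
            "chr": model.chroms,
            "pos": model.positions,
            "effect_allele": model.effect_alleles,
            "other_allele": model.other_alleles,
            "weight": model.weights,
        }
    ).to_csv(tsv, sep="\t", index=False)
    manifest = {
        "protein_id": model.protein_id,
        "gene": model.gene,
        "method": model.method,
        "cv_r2": model.cv_r2,
        "cv_p": model.cv_p,
        "n_cis": model.n_cis,
        "n_trans": model.n_trans,
    }
    with open(directory / f"{model.protein_id}.manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return tsv


def read_weights(directory: str | Path, protein_id: str):
    from .models import PredictionModel

    directory = Path(directory)
    df = pd.read_csv(directory / f"{protein_id}.weights.tsv", sep="\t",
                     dtype={"snp": str, "chr": str})
    with open(directory / f"{protein_id}.manifest.json") as fh:
        man = json.load(fh)
    return PredictionModel(
        protein_id=man["protein_id"],
        gene=man.get("gene", man["protein_id"]),
        method=man["method"],
        snp_ids=df["snp"].tolist(),
        chroms=df["chr"].astype(str).tolist(),
        positions=df["pos"].astype(int).tolist(),
        effect_alleles=df["effect_allele"].tolist(),
        other_alleles=df["other_allele"].tolist(),
        weights=df["weight"].to_numpy(dtype=float),
        cv_r2=float(man["cv_r2"]),
        cv_p=float(man["cv_p"]),
        n_cis=int(man["n_cis"]),
        n_trans=int(man["n_trans"]),
    )


def write_grm_tsv(grm, sample_ids, path: str | Path) -> None:
    pd.DataFrame(grm.matrix, index=sample_ids, columns=sample_ids).to_csv(
        path, sep="\t", float_format="%.8g"
    )


def write_grm_gcta(grm, sample_ids, prefix: str | Path) -> None:
    """GCTA binary GRM triple: float32 lower triangle (row-major, diagonal
    included), per-pair variant counts, and a two-column id file."""
    prefix = Path(prefix)
    n = grm.matrix.shape[0]
    with open(f"{prefix}.grm.bin", "wb") as fh:
        for i in range(n):
            fh.write(struct.pack(f"<{i + 1}f", *grm.matrix[i, : i + 1]))
    with open(f"{prefix}.grm.N.bin", "wb") as fh:
        count = struct.pack("<f", float(grm.m))
        fh.write(count * (n * (n + 1) // 2))
    with open(f"{prefix}.grm.id", "w") as fh:
        for s in sample_ids:
            fh.write(f"{s}\t{s}\n")


def write_truth_manifest(truths, path: str | Path) -> None:
    payload = [
        {
            "protein_id": t.protein_id,
            "h2": t.h2,
            "causal_ids": list(t.causal_ids),
            "effects": [float(e) for e in np.asarray(t.effects)],
        }
        for t in truths
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
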