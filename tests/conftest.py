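import numpy as np
import pytest

from pwaskit import GenotypeMatrix, VariantSpec, make_variants, simulate_genotypes


@pytest.fixture(scope="session")
def small_cohort():
    """300 samples x 60 LD-structured variants, one chromosome."""
    variants = make_variants(60, spacing=20_000, seed=11)
    return simulate_genotypes(300, variants, ld_rho=0.4, block_sizes=[10] * 6, seed=12)


@pytest.fixture
def toy_variants():
    def make(cols, chrom="1", spacing=10_000, alleles=("A", "G")):
        return [
            VariantSpec(
                chrom=chrom, pos=1_000_000 + j * spacing, id=f"v{j}",
                ref_allele=alleles[0], effect_allele=alleles[1], maf=0.3,
            )
            for j in range(cols)
        ]

    return make


def orthonormal_design(n: int, m: int, seed: int = 0) -> np.ndarray:
    """Columns with empirical mean 0 and (1/n) X'X = I exactly."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, m + 1))
    X[:, 0] = 1.0
    Q, _ = np.linalg.qr(X)
    return Q[:, 1:] * np.sqrt(n)


def genotypes_from_matrix(dosages, positions=None, chrom="1") -> GenotypeMatrix:
    """Wrap an arbitrary numeric matrix as a GenotypeMatrix for algebraic
    tests (dosage values need not be 0/1/2)."""
    dosages = np.asarray(dosages, dtype=float)
    m = dosages.shape[1]
    if positions is None:
        positions = [1_000_000 + 10_000 * j for j in range(m)]
    variants = [
        VariantSpec(chrom=chrom, pos=int(positions[j]), id=f"v{j}",
                    ref_allele="A", effect_allele="G", maf=0.3)
        for j in range(m)
    ]
    return GenotypeMatrix(dosages, variants, [f"s{i}" for i in range(dosages.shape[0])])
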