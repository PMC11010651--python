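"""Simulate a genotype cohort with LD structure and a heritable protein.

Builds 1,000 samples x 100 variants with block-AR(1) linkage
disequilibrium, simulates a plasma protein with two cis and two trans
causal variants at heritability 0.4, and verifies the generated structure.
"""

import numpy as np

from pwaskit import (
    ArchitectureSpec,
    make_variants,
    simulate_genotypes,
    simulate_proteome,
)

variants = make_variants(100, chrom="1", spacing=30_000, seed=1)
cohort = simulate_genotypes(1000, variants, ld_rho=0.5,
                            block_sizes=[20] * 5, seed=2)
print(f"cohort: {cohort.n_samples} samples x {cohort.n_variants} variants")
print(f"empirical MAF range: {cohort.empirical_maf().min():.3f}"
      f" - {cohort.empirical_maf().max():.3f}")

arch = ArchitectureSpec(n_cis_causal=2, n_trans_causal=2, h2=0.4,
                        tss=1_500_000)
levels, truth = simulate_proteome(cohort, arch, seed=3)
r2 = np.corrcoef(levels, truth.genetic_values)[0, 1] ** 2
print(f"causal variants: {truth.causal_ids}")
print(f"variance explained by the true genetic score: {r2:.3f} "
      f"(target h2 = {arch.h2})")
# The R^2 of protein levels on the latent genetic value should sit at the
# simulated heritability; that is the ceiling any prediction model can reach.
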