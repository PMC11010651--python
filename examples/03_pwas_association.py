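"""Run the summary-statistics association test for a small proteome.

Simulates one case-control GWAS in which a single protein causally raises
disease liability, trains prediction models for five proteins, and tests
each with the weighted-burden statistic z = w'Z / sqrt(w' Sigma w) under
BH-FDR control.  The mediated protein should surface with a large |z|.
"""

import warnings

import numpy as np

from pwaskit import (
    ArchitectureSpec,
    DiseaseModel,
    build_model,
    make_reference_panel,
    make_variants,
    prepare_phenotype,
    run_pwas,
    simulate_genotypes,
    simulate_gwas_summary,
    simulate_proteome,
)

warnings.simplefilter("ignore")

variants = make_variants(300, chrom="1", spacing=30_000, seed=20)
train = simulate_genotypes(1000, variants, ld_rho=0.5,
                           block_sizes=[20] * 15, seed=21)
ref = make_reference_panel(
    simulate_genotypes(800, variants, ld_rho=0.5, block_sizes=[20] * 15,
                       seed=22)
)

models, truths = [], {}
for i in range(5):
    tss = 1_500_000 + i * 1_500_000
    arch = ArchitectureSpec(n_cis_causal=3, n_trans_causal=0, h2=0.35,
                            tss=tss)
    pid = f"PROT{i}"
    levels, truth = simulate_proteome(train, arch, seed=30 + i,
                                      protein_id=pid)
    truths[pid] = truth
    m = build_model(train, prepare_phenotype(levels, None, pid), tss=tss)
    if m is not None:
        models.append(m)

# protein PROT2 mediates disease risk (gamma = 0.15 per SD of protein)
gwas = simulate_gwas_summary(ref, truths["PROT2"],
                             DiseaseModel(gamma=0.15), seed=40)
print(f"GWAS: {len(gwas)} SNPs, N = {gwas['n'].iloc[0]} "
      "(8,275 cases + 6,723 controls)")

results = run_pwas(models, gwas, ref)
print(results[["protein", "z", "p", "q", "n_snps_used", "significant"]]
      .to_string(index=False))
# PROT2 should carry a large |z| and survive FDR <= 0.05; the other
# proteins' z-scores behave like standard normal draws.
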