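"""Somatic-mutation enrichment: two-proportion comparison of gene sets.

Given k1 of n1 disease-associated genes carrying qualifying somatic variants
versus k2 of n2 background genes, the primary statistic is the pooled
two-proportion z test (no continuity correction),

    z = (p1 - p2) / sqrt(pbar (1 - pbar) (1/n1 + 1/n2)),

with pbar = (k1 + k2) / (n1 + n2), alongside Fisher's exact p as a
small-count companion.  Counts are inputs here; calling and classifying the
somatic variants is upstream of this module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["EnrichmentInput", "EnrichmentResult", "two_proportion_test"]


@dataclass(frozen=True)
class EnrichmentInput:
    """Qualifying/total counts for the associated set (k1/n1) and the
    background set (k2/n2)."""

    k1: int
    n1: int
    k2: int
    n2: int

    def __post_init__(self) -> None:
        for k, n in ((self.k1, self.n1), (self.k2, self.n2)):
            if n < 1:
                raise ValueError("set sizes must be >= 1")
            if not (0 <= k <= n):
                raise ValueError("qualifying counts must satisfy 0 <= k <= n")


@dataclass(frozen=True)
class EnrichmentResult:
    p1: float
    p2: float
    z: float
    p_two_sided: float
    p_fisher: float


def two_proportion_test(inp: EnrichmentInput) -> EnrichmentResult:
    """Pooled-variance two-proportion z test plus Fisher's exact p.

    When the pooled proportion is 0 or 1 the z statistic is undefined
    (returned as NaN with p NaN); the Fisher p is still reported.
    Antisymmetric: swapping the two groups negates z and leaves both
    p-values unchanged.
    """
    p1 = inp.k1 / inp.n1
    p2 = inp.k2 / inp.n2
    pooled = (inp.k1 + inp.k2) / (inp.n1 + inp.n2)

    table = [[inp.k1, inp.n1 - inp.k1], [inp.k2, inp.n2 - inp.k2]]
    _, p_fisher = stats.fisher_exact(table, alternative="two-sided")

    if pooled in (0.0, 1.0):
        z, p_norm = float("nan"), float("nan")
    else:
        se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / inp.n1 + 1.0 / inp.n2))
        z = float((p1 - p2) / se)
        p_norm = float(np.clip(2.0 * stats.norm.sf(abs(z)),
                               np.finfo(float).tiny, 1.0))
    return EnrichmentResult(
        p1=p1, p2=p2, z=z, p_two_sided=p_norm, p_fisher=float(p_fisher)
    )
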