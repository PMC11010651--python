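"""Independent reference implementations used to check the package.

Everything here is deliberately written by a different route than the
library code it validates: exact rational enumeration for the HWE and Fisher
tests, dense-matrix likelihood evaluation for REML, closed-form algebra for
OLS and the weighted-burden statistic.
"""

from fractions import Fraction
from math import comb, factorial

import numpy as np


def hwe_exact_enumeration(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact-rational conditional HWE p-value by full enumeration.

    P(het = h | allele counts) = C(n; nAA, nAa, naa) 2^h / C(2n; nA) terms,
    summed over all tables with probability <= the observed table's.
    """
    n = n_AA + n_Aa + n_aa
    na = 2 * n_AA + n_Aa  # A allele count
    nb = 2 * n_aa + n_Aa
    if na == 0 or nb == 0:
        return 1.0
    rare = min(na, nb)

    def table_prob(h: int) -> Fraction:
        r_hom = (rare - h) // 2
        c_hom = n - h - r_hom
        num = (
            Fraction(factorial(n), factorial(h) * factorial(r_hom) * factorial(c_hom))
            * 2**h
        )
        den = Fraction(comb(2 * n, rare))
        return num / den

    probs = {h: table_prob(h) for h in range(rare % 2, rare + 1, 2)}
    obs = probs[n_Aa]
    return float(sum(p for p in probs.values() if p <= obs))


def fisher_two_sided_enumeration(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided Fisher exact p via hypergeometric enumeration with exact
    rationals: sum of P(x) over all x with P(x) <= P(observed)."""
    total = n1 + n2
    successes = k1 + k2

    def prob(x: int) -> Fraction:
        if x < 0 or x > n1 or successes - x > n2 or successes - x < 0:
            return Fraction(0)
        return Fraction(comb(n1, x) * comb(n2, successes - x), comb(total, successes))

    p_obs = prob(k1)
    lo = max(0, successes - n2)
    hi = min(n1, successes)
    return float(sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs))


def ols_slope_se(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Closed-form simple-regression slope and SE (with intercept)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    xc = x - x.mean()
    yc = y - y.mean()
    beta = float(xc @ yc) / float(xc @ xc)
    resid = yc - beta * xc
    se = np.sqrt(float(resid @ resid) / (n - 2) / float(xc @ xc))
    return beta, se


def bh_stepup(pvals) -> np.ndarray:
    """Step-up BH q-values with explicit running-minimum enforcement."""
    p = np.asarray(pvals, float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        q[i] = running
    return q


def pwas_z_dense(w, Z, Sigma) -> tuple[float, float]:
    """Direct algebraic evaluation of the weighted-burden statistic on a
    positive-definite Sigma (no eigenvalue flooring)."""
    from math import erfc, sqrt

    w = np.asarray(w, float)
    Z = np.asarray(Z, float)
    Sigma = np.asarray(Sigma, float)
    z = float(np.dot(w, Z)) / sqrt(float(w @ Sigma @ w))
    p = erfc(abs(z) / sqrt(2.0))
    return z, p


def reml_loglik_dense(h2: float, A: np.ndarray, y: np.ndarray) -> float:
    """Dense REML log-likelihood at heritability h2 with the total variance
    profiled out; fixed effect = intercept only."""
    n = y.size
    X = np.ones((n, 1))
    K = h2 * A + (1.0 - h2) * np.eye(n)
    sign, logdetK = np.linalg.slogdet(K)
    Ki = np.linalg.inv(K)
    XtKiX = X.T @ Ki @ X
    beta = np.linalg.solve(XtKiX, X.T @ Ki @ y)
    r = y - X @ beta
    ypy = float(r @ Ki @ r)
    nr = n - 1
    s2 = ypy / nr
    return -0.5 * (
        nr * np.log(s2) + logdetK + np.linalg.slogdet(XtKiX)[1] + nr
    )


def reml_h2_grid(A: np.ndarray, y: np.ndarray, step: float = 0.0025) -> float:
    """Grid-search maximizer of the dense REML log-likelihood over h2.

    The grid stops short of h2 = 1: a rank-deficient GRM makes V singular
    there and the restricted likelihood undefined."""
    y = (y - y.mean()) / y.std()
    grid = np.arange(0.0, 0.995 + 1e-9, step)
    vals = [reml_loglik_dense(float(h), A, y) for h in grid]
    vals = np.where(np.isfinite(vals), vals, -np.inf)
    return float(grid[int(np.argmax(vals))])
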