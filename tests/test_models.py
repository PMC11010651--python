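"""Candidate selection, the four weight-training methods, cross-validation,
LD pruning and external validation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import pwaskit.models as mod
from pwaskit import (
    ModelConfig,
    PredictionModel,
    SelectionThresholds,
    cross_validate,
    external_validate,
    fit_blup,
    fit_bslmm_approx,
    fit_penalized,
    fit_top1,
    marginal_scan,
    prepare_phenotype,
    prune_ld,
    select_candidates,
)
from pwaskit.models import MethodFit, select_best
from pwaskit.preprocess import PhenotypeResiduals

from conftest import genotypes_from_matrix, orthonormal_design
from oracles import ols_slope_se


def _phen(values, pid="P0"):
    return PhenotypeResiduals(values=np.asarray(values, float), protein_id=pid)


class TestMarginalScan:
    def test_toy_matches_closed_form_ols(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, size=(4, 2)).astype(float)
        d[:, 0] = [0, 1, 2, 1]
        d[:, 1] = [2, 0, 1, 1]
        g = genotypes_from_matrix(d)
        y = np.array([0.3, -1.2, 0.8, 0.1])
        scan = marginal_scan(g, _phen(y), tss=1_000_000)
        X = g.standardized()
        for j in range(2):
            beta, se = ols_slope_se(X[:, j], y)
            assert scan["beta"][j] == pytest.approx(beta, rel=1e-10)
            assert scan["se"][j] == pytest.approx(se, rel=1e-10)

    def test_self_phenotype_gives_unit_slope_floored_p(self, small_cohort):
        X = small_cohort.standardized()
        scan = marginal_scan(small_cohort, _phen(X[:, 5]), tss=1_000_000)
        assert scan["beta"][5] == pytest.approx(1.0, rel=1e-10)
        assert 0 < scan["p"][5] <= 1e-200

    def test_null_pvalues_uniform(self):
        from pwaskit import make_variants, simulate_genotypes

        v = make_variants(1000, spacing=1000, seed=1)
        g = simulate_genotypes(300, v, ld_rho=0.0, seed=2)
        y = np.random.default_rng(3).standard_normal(300)
        scan = marginal_scan(g, _phen(y), tss=1_000_000)
        assert stats.kstest(scan["p"], "uniform").pvalue > 0.01

    def test_zero_variance_variant_excluded(self):
        d = np.column_stack([np.array([0, 1, 2, 1, 0.0]), np.ones(5)])
        g = genotypes_from_matrix(d)
        with pytest.warns(UserWarning, match="zero-variance"):
            scan = marginal_scan(g, _phen(np.arange(5.0)), tss=1_000_000)
        assert scan["id"].tolist() == ["v0"]

    def test_distance_to_tss_signed(self):
        d = np.random.default_rng(0).integers(0, 3, (50, 2)).astype(float)
        g = genotypes_from_matrix(d, positions=[900_000, 1_100_000])
        scan = marginal_scan(g, _phen(np.random.default_rng(1).standard_normal(50)),
                             tss=1_000_000)
        assert scan["distance_to_tss"].tolist() == [-100_000, 100_000]


def _scan_frame(pvals, positions, tss=0, chrom="1"):
    pos = np.asarray(positions)
    return pd.DataFrame(
        {
            "id": [f"v{j}" for j in range(len(pvals))],
            "chrom": chrom,
            "pos": pos,
            "beta": 0.1,
            "se": 0.05,
            "p": np.asarray(pvals, float),
            "distance_to_tss": pos - tss,
        }
    )


class TestSelectCandidates:
    def test_bh_hand_case_keeps_first_two_cis(self):
        # positions far apart so the expansion window adds nothing
        scan = _scan_frame(
            [0.001, 0.002, 0.2, 0.5, 0.9],
            positions=[0, 300_000, 600_000, 900_000, 999_000],
        )
        got = select_candidates(scan, SelectionThresholds())
        assert got == ["v0", "v1"]

    def test_trans_p_boundary_inclusive(self):
        scan = _scan_frame(
            [5e-8, 6e-8], positions=[5_000_000, 9_000_000], tss=0
        )
        got = select_candidates(scan, SelectionThresholds())
        assert got == ["v0"]

    def test_expansion_window_boundary(self):
        # seed at 5,000,000 (trans); neighbors at 99,999 and 100,001 bp
        scan = _scan_frame(
            [1e-9, 0.5, 0.5],
            positions=[5_000_000, 5_099_999, 5_100_001],
            tss=0,
        )
        got = select_candidates(scan, SelectionThresholds())
        assert got == ["v0", "v1"]

    def test_no_seeds_returns_empty(self):
        scan = _scan_frame([0.5, 0.9], positions=[0, 5_000_000])
        assert select_candidates(scan, SelectionThresholds()) == []

    def test_alternate_trans_thresholds(self):
        scan = _scan_frame([2e-9], positions=[5_000_000], tss=0)
        assert select_candidates(scan, SelectionThresholds(trans_p=5e-9))
        assert not select_candidates(scan, SelectionThresholds(trans_p=5e-10))


class TestFitters:
    def test_top1_exact_column(self):
        X = orthonormal_design(40, 3, seed=0)
        w = fit_top1(X, X[:, 1].copy())
        assert w[1] == pytest.approx(1.0, rel=1e-9)
        assert w[0] == w[2] == 0.0

    def test_top1_tie_breaks_to_lowest_position(self):
        X = orthonormal_design(40, 1, seed=1)
        Xdup = np.column_stack([X[:, 0], X[:, 0]])
        y = Xdup[:, 0] * 0.5
        w = fit_top1(Xdup, y, positions=[200, 100])
        assert w[1] != 0.0 and w[0] == 0.0

    def test_top1_toy_equals_ols(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((4, 2))
        X -= X.mean(axis=0)
        X /= X.std(axis=0)
        y = np.array([1.0, -0.5, 0.3, 0.2])
        w = fit_top1(X, y)
        j = int(np.nonzero(w)[0][0])
        beta, _ = ols_slope_se(X[:, j], y)
        assert w[j] == pytest.approx(beta, rel=1e-9)

    def test_lasso_soft_threshold_closed_form(self):
        X = orthonormal_design(200, 2, seed=3)
        y = 2.0 * X[:, 0] + 0.5 * X[:, 1]
        w = fit_penalized(X, y, alpha=1.0, penalty=1.0)
        assert w[0] == pytest.approx(1.0, abs=1e-6)
        assert w[1] == pytest.approx(0.0, abs=1e-9)

    def test_huge_penalty_zeroes_everything(self):
        X = orthonormal_design(100, 3, seed=4)
        y = X @ np.array([1.0, -2.0, 0.5])
        assert not np.any(fit_penalized(X, y, alpha=1.0, penalty=1e6))

    def test_ridge_matches_matrix_inverse(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((30, 2))
        X -= X.mean(axis=0)
        y = X @ np.array([0.7, -0.3]) + rng.standard_normal(30) * 0.1
        lam = 3.0
        w = fit_penalized(X, y, alpha=0.0, penalty=lam)
        yc = y - y.mean()
        expected = np.linalg.solve(X.T @ X + lam * np.eye(2), X.T @ yc)
        np.testing.assert_allclose(w, expected, rtol=1e-8)

    def test_blup_single_variant_closed_form(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(100)
        x = (x - x.mean()) / x.std()  # sum of squares = 100
        q = rng.standard_normal(100)
        q -= x * (q @ x) / (x @ x)  # orthogonal noise
        y = 0.5 * x + q              # marginal slope exactly 0.5
        w = fit_blup(x[:, None], y, lam=100.0)
        assert w[0] == pytest.approx(100 * 0.5 / (100 + 100), rel=1e-9)

    def test_blup_heritability_floor_is_maximal_shrinkage(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((50, 3))
        y = rng.standard_normal(50)
        np.testing.assert_allclose(
            fit_blup(X, y, h2=0.005), fit_blup(X, y, h2=0.01)
        )

    def test_blup_vanishes_as_h2_floors_to_zero_shrinkage_limit(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((50, 2))
        y = rng.standard_normal(50)
        w_tiny = fit_blup(X, y, h2=1e-9)
        # lambda = m(1-h2)/h2 -> enormous, weights -> 0... but floored at 0.01
        lam = 2 * (1 - 0.01) / 0.01
        expected = np.linalg.solve(X.T @ X + lam * np.eye(2),
                                   X.T @ (y - y.mean()))
        np.testing.assert_allclose(w_tiny, expected)


class TestBSLMMApprox:
    def test_null_posterior_means_small(self):
        rng = np.random.default_rng(0)
        hits = 0
        for rep in range(50):
            X = rng.standard_normal((300, 10))
            y = rng.standard_normal(300)
            w = fit_bslmm_approx(X, y, iters=2000, seed=rep)
            hits += np.all(np.abs(w) < 0.05)
        assert hits >= 45  # >= 95% of replicates

    def test_single_causal_recovery(self):
        rng = np.random.default_rng(1)
        good = 0
        reps = 20
        for rep in range(reps):
            X = rng.standard_normal((2000, 10))
            X -= X.mean(axis=0)
            X /= X.std(axis=0)
            y = X[:, 4] * np.sqrt(0.5) + rng.standard_normal(2000) * np.sqrt(0.5)
            w = fit_bslmm_approx(X, y, iters=400, seed=100 + rep)
            if w[4] ** 2 / max(np.sum(w**2), 1e-30) >= 0.8:
                good += 1
        assert good >= int(0.9 * reps)

    def test_same_seed_identical_weights(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((100, 5))
        y = rng.standard_normal(100)
        np.testing.assert_array_equal(
            fit_bslmm_approx(X, y, iters=200, seed=7),
            fit_bslmm_approx(X, y, iters=200, seed=7),
        )


class TestCrossValidate:
    def test_noiseless_linear_signal(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((200, 3))
        y = X @ np.array([1.0, -0.5, 0.25])
        cv_r2, cv_p = cross_validate(
            X, y, lambda Xt, yt: fit_penalized(Xt, yt, alpha=0.0, penalty=1e-6)
        )
        assert cv_r2 > 0.99 and cv_p < 1e-20

    def test_null_distribution_matches_independent_oracle(self):
        # Pooled-CV correlation is a quadratic form in y and its null
        # distribution is wider than the nominal t; validate the package
        # against a standalone re-simulation of the same construction.
        rng = np.random.default_rng(1)
        n, lam = 100, 50.0

        def oracle_stat(X, y, folds):
            yc = y - y.mean()
            pred = np.empty(n)
            for te in folds:
                tr = np.setdiff1d(np.arange(n), te)
                w = np.linalg.solve(
                    X[tr].T @ X[tr] + lam * np.eye(X.shape[1]), X[tr].T @ yc[tr]
                )
                pred[te] = X[te] @ w
            return np.corrcoef(pred, yc)[0, 1]

        X = rng.standard_normal((n, 3))
        pkg_r, oracle_r = [], []
        for rep in range(400):
            y = rng.standard_normal(n)
            cv_r2, _ = cross_validate(
                X, y, lambda Xt, yt: fit_blup(Xt, yt, lam=lam), k=5, seed=rep
            )
            pkg_r.append(np.sign(cv_r2) * np.sqrt(abs(cv_r2)))
            perm = np.random.default_rng(10_000 + rep).permutation(n)
            y2 = rng.standard_normal(n)
            oracle_r.append(oracle_stat(X, y2, np.array_split(perm, 5)))
        assert stats.ks_2samp(pkg_r, oracle_r).pvalue > 0.01

    def test_cv_p_decreases_with_signal(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((150, 3))
        ps = []
        for effect in (0.0, 0.3, 0.8):
            y = effect * X[:, 0] + rng.standard_normal(150)
            _, p = cross_validate(
                X, y, lambda Xt, yt: fit_blup(Xt, yt, lam=10.0), k=5, seed=0
            )
            ps.append(p)
        assert ps[2] < ps[1] < ps[0]

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((80, 4))
        y = rng.standard_normal(80)
        a = cross_validate(X, y, fit_top1, seed=3)
        b = cross_validate(X, y, fit_top1, seed=3)
        assert a == b


class TestModelSelectionAndGate:
    def _fit(self, method, cv_r2, cv_p):
        return MethodFit(method=method, weights=np.array([1.0]),
                         cv_r2=cv_r2, cv_p=cv_p)

    def test_smallest_cv_p_wins(self):
        best = select_best([self._fit("top1", 0.1, 0.01),
                            self._fit("lasso", 0.2, 0.001)])
        assert best.method == "lasso"

    def test_tie_breaks_on_r2_then_method_order(self):
        best = select_best([self._fit("enet", 0.3, 0.01),
                            self._fit("blup", 0.2, 0.01)])
        assert best.method == "enet"
        best = select_best([self._fit("blup", 0.2, 0.01),
                            self._fit("lasso", 0.2, 0.01)])
        assert best.method == "lasso"

    def test_all_zero_fits_discarded(self):
        zero = MethodFit("lasso", np.zeros(3), 0.5, 1e-5)
        assert select_best([zero]) is None

    def test_build_model_r2_gate_boundary(self, small_cohort, monkeypatch):
        y = np.random.default_rng(0).standard_normal(small_cohort.n_samples)
        phen = _phen(small_cohort.standardized()[:, 0] * 0.8 + y * 0.6, "P1")

        for gate_r2, expect_model in [(0.009, False), (0.011, True)]:
            monkeypatch.setattr(
                mod, "cross_validate", lambda *a, **k: (gate_r2, 1e-4)
            )
            m = mod.build_model(small_cohort, phen, tss=1_000_000,
                                config=ModelConfig(methods=("top1",)))
            assert (m is not None) == expect_model

    def test_cis_only_architecture_yields_no_trans(self):
        from pwaskit import ArchitectureSpec, make_variants, simulate_genotypes, simulate_proteome

        v = make_variants(80, spacing=20_000, seed=3)
        g = simulate_genotypes(600, v, ld_rho=0.3, seed=4)
        arch = ArchitectureSpec(n_cis_causal=3, n_trans_causal=0, h2=0.4,
                                tss=1_400_000)
        levels, _ = simulate_proteome(g, arch, seed=5)
        phen = prepare_phenotype(levels, None, "P2")
        m = mod.build_model(g, phen, tss=1_400_000)
        assert m is not None and m.n_trans == 0 and m.n_cis == len(m.snp_ids)

    def test_weight_scale_contract_doubled_dosages(self, small_cohort):
        doubled = genotypes_from_matrix(
            small_cohort.dosages * 2.0,
            positions=[v.pos for v in small_cohort.variants],
        )
        np.testing.assert_allclose(
            small_cohort.standardized(), doubled.standardized(), atol=1e-12
        )


class TestPruneLD:
    def test_duplicated_pair_keeps_one(self):
        rng = np.random.default_rng(0)
        col = rng.integers(0, 3, 100).astype(float)
        g = genotypes_from_matrix(np.column_stack([col, col]))
        assert prune_ld(g) == ["v0"]

    def test_independent_variants_all_retained(self):
        rng = np.random.default_rng(1)
        d = rng.integers(0, 3, (2000, 5)).astype(float)
        g = genotypes_from_matrix(d)
        assert prune_ld(g) == [f"v{j}" for j in range(5)]

    def test_three_variant_chain(self):
        # target r^2: (1,2)=0.5, (2,3)=0.5, (1,3)=0.05 -> greedy keeps {1,3}
        n = 400
        rng = np.random.default_rng(2)
        Ztmp = rng.standard_normal((n, 3))
        Ztmp -= Ztmp.mean(axis=0)
        # empirical whitening, then imprint the exact target correlation
        cov = Ztmp.T @ Ztmp / n
        W = np.linalg.cholesky(np.linalg.inv(cov))
        iid = Ztmp @ W
        r12 = r23 = np.sqrt(0.5)
        r13 = np.sqrt(0.05)
        R = np.array([[1, r12, r13], [r12, 1, r23], [r13, r23, 1]])
        Xc = iid @ np.linalg.cholesky(R).T
        g = genotypes_from_matrix(Xc, positions=[100, 200, 300])
        assert prune_ld(g, r2_max=0.1, window_bp=250_000) == ["v0", "v2"]

    def test_window_limits_comparisons(self):
        rng = np.random.default_rng(3)
        col = rng.integers(0, 3, 200).astype(float)
        g = genotypes_from_matrix(
            np.column_stack([col, col]), positions=[100, 300_000]
        )
        # identical variants but farther apart than the window: both kept
        assert prune_ld(g, r2_max=0.1, window_bp=250_000) == ["v0", "v1"]

    def test_retained_pairs_respect_r2_bound(self, small_cohort):
        kept = prune_ld(small_cohort, r2_max=0.1, window_bp=250_000)
        sub = small_cohort.subset(kept)
        X = sub.standardized()
        corr = X.T @ X / X.shape[0]
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                vi, vj = sub.variants[i], sub.variants[j]
                if vi.chrom == vj.chrom and abs(vi.pos - vj.pos) <= 250_000:
                    assert corr[i, j] ** 2 <= 0.1 + 1e-12


def _model_from(genotypes, cols, weights, pid="P0"):
    vs = [genotypes.variants[c] for c in cols]
    return PredictionModel(
        protein_id=pid, gene=pid, method="top1",
        snp_ids=[v.id for v in vs], chroms=[v.chrom for v in vs],
        positions=[v.pos for v in vs],
        effect_alleles=[v.effect_allele for v in vs],
        other_alleles=[v.ref_allele for v in vs],
        weights=np.asarray(weights, float),
        cv_r2=0.1, cv_p=0.001, n_cis=len(cols), n_trans=0,
    )


class TestExternalValidate:
    def test_perfect_prediction(self, small_cohort):
        m = _model_from(small_cohort, [0, 1], [0.5, -0.2])
        measured = small_cohort.standardized()[:, [0, 1]] @ np.array([0.5, -0.2])
        res = external_validate(m, small_cohort, measured)
        assert res.r == pytest.approx(1.0) and res.passed

    def test_pass_rule_at_r_threshold(self, small_cohort):
        m = _model_from(small_cohort, [0], [1.0])
        p = small_cohort.standardized()[:, 0]
        rng = np.random.default_rng(0)
        q = rng.standard_normal(p.size)
        q -= p * (q @ p) / (p @ p)
        q = (q - q.mean()) / q.std()
        measured = 0.1 * p + np.sqrt(1 - 0.01) * q
        res = external_validate(m, small_cohort, measured)
        assert res.r == pytest.approx(0.1, abs=1e-9)
        assert res.passed == (res.r >= 0.1)  # inclusive rule
        res_below = external_validate(m, small_cohort,
                                      0.05 * p + np.sqrt(1 - 0.0025) * q)
        assert not res_below.passed

    def test_null_pass_rate_matches_t_tail(self, small_cohort):
        m = _model_from(small_cohort, [3], [1.0])
        n = small_cohort.n_samples
        rng = np.random.default_rng(1)
        passes = sum(
            external_validate(m, small_cohort, rng.standard_normal(n)).passed
            for _ in range(500)
        )
        r0 = 0.1
        t0 = r0 * np.sqrt((n - 2) / (1 - r0**2))
        expected = stats.t.sf(t0, df=n - 2)
        se = np.sqrt(expected * (1 - expected) / 500)
        assert abs(passes / 500 - expected) < 4 * se

    def test_swapped_alleles_flip_weight_sign(self, small_cohort):
        m = _model_from(small_cohort, [0], [0.7])
        v = small_cohort.variants[0]
        flipped = genotypes_from_matrix(
            2.0 - small_cohort.dosages[:, [0]], positions=[v.pos]
        )
        # flipped cohort counts the other allele; rename alleles accordingly
        from pwaskit import VariantSpec, GenotypeMatrix

        fv = VariantSpec(chrom=v.chrom, pos=v.pos, id=v.id,
                         ref_allele=v.effect_allele,
                         effect_allele=v.ref_allele, maf=v.maf)
        flipped = GenotypeMatrix(flipped.dosages, [fv], flipped.sample_ids)
        measured = small_cohort.standardized()[:, 0] * 0.7
        res = external_validate(m, flipped, measured)
        assert res.r == pytest.approx(1.0)
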