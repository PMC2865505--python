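"""Inference engine: residuals, noise updates, the bound, schedules."""

import numpy as np
import pytest
from scipy.special import digamma, gammaln

import peerqtl as pq
from peerqtl.model import (ModelState, NoiseState, corrected_expression,
                           residual_for, update_noise, variational_bound)

LOG2PI = np.log(2 * np.pi)


def _min_rel_step(trace):
    bt = np.asarray(trace)
    d = np.diff(bt)
    return float((d / np.maximum(np.abs(bt[1:]), 1.0)).min()) if len(bt) > 1 else 0.0


class TestResidualFor:
    def test_hidden_only_model_residual_is_centred_data(self):
        rng = np.random.default_rng(0)
        Y = rng.standard_normal((12, 8)) + 3.0
        fit = pq.VBQTL(Y, K_hidden=2, max_iter=5).fit()
        R = residual_for("hidden", fit.state, fit.model.expr)
        assert np.allclose(R, Y - Y.mean(axis=1, keepdims=True), atol=1e-12)

    def test_matches_direct_summation_oracle(self):
        """Three-component fit on a 20x10 matrix: residual equals the
        brute-force Y - sum of the other components' means."""
        cfg = pq.SimConfig(G=20, N=10, S=6, n_hidden=2, n_known=2,
                           n_hotspots=1, seed=4)
        expr, geno, covs, _ = pq.simulate(cfg)
        fit = pq.VBQTL(expr, geno, covs, K_hidden=3, max_iter=4).fit()
        st = fit.state
        Yc = expr.values - expr.values.mean(axis=1, keepdims=True)
        for active in ("genetic", "known", "hidden"):
            expected = Yc.copy()
            for name, comp in st.components().items():
                if name != active:
                    expected -= comp.contrib_mean
            assert np.allclose(residual_for(active, st, expr), expected, atol=1e-10)

    def test_algebraic_identity_between_components(self):
        """Adding back the other components' means always recovers the same
        centred data, whichever component is active."""
        cfg = pq.SimConfig(G=15, N=12, S=5, seed=5)
        expr, geno, covs, _ = pq.simulate(cfg)
        fit = pq.VBQTL(expr, geno, covs, K_hidden=2, max_iter=3).fit()
        st = fit.state
        recovered = []
        for active in ("genetic", "known", "hidden"):
            R = residual_for(active, st, expr)
            for name, comp in st.components().items():
                if name != active:
                    R = R + comp.contrib_mean
            recovered.append(R)
        assert np.allclose(recovered[0], recovered[1], atol=1e-10)
        assert np.allclose(recovered[1], recovered[2], atol=1e-10)

    def test_unknown_label_raises(self):
        fit = pq.VBQTL(np.random.default_rng(1).standard_normal((4, 5)),
                       K_hidden=1, max_iter=2).fit()
        with pytest.raises(ValueError, match="component"):
            residual_for("batch", fit.state, fit.model.expr)


class TestUpdateNoise:
    def test_hand_computed_two_point_gene(self):
        """No components, broad prior, one gene with values {+1, -1}:
        E[RSS] = 2 so E[tau] = (1e-3 + 1)/(1e-3 + 1) = 1."""
        Y = np.array([[1.0, -1.0]])
        fit = pq.VBQTL(Y, K_hidden=0).fit()
        noise = update_noise(fit.state, fit.model.expr)
        assert noise.shape_g[0] == pytest.approx(1e-3 + 1.0)
        assert noise.rate_g[0] == pytest.approx(1e-3 + 1.0)
        assert noise.expected_precision[0] == pytest.approx(1.0, abs=1e-9)

    def test_exact_fit_closed_form(self):
        """When contributions reproduce Y with zero posterior variance the
        rate stays at the prior and the precision is (a0 + n/2)/b0."""
        rng = np.random.default_rng(2)
        G, N = 6, 9
        Y = rng.standard_normal((G, N))
        fit = pq.VBQTL(Y, K_hidden=0, center_genes=False,
                       covariates=None).fit()
        st = fit.state
        # forge a known component that reproduces Y exactly, no uncertainty
        from peerqtl.known import KnownFactorState
        kn = KnownFactorState.initialize(np.ones((1, N)), G, 1e-3, 1e-3)
        kn.contrib_mean = Y.copy()
        kn.contrib_var_gene = np.zeros(G)
        st.known = kn
        noise = update_noise(st, fit.model.expr)
        assert np.allclose(noise.rate_g, 1e-3)
        assert np.allclose(noise.expected_precision, (1e-3 + N / 2) / 1e-3)

    def test_expectation_matches_monte_carlo(self):
        """The analytic E[RSS] agrees with 1e5 posterior draws within 1%."""
        rng = np.random.default_rng(3)
        G, N, K = 4, 6, 2
        Y = rng.standard_normal((G, N)) * 2.0
        fit = pq.VBQTL(Y, K_hidden=K, max_iter=10).fit()
        st = fit.state
        hid = st.hidden
        Yc = Y - Y.mean(axis=1, keepdims=True)
        analytic = float(((Yc - hid.contrib_mean) ** 2).sum()
                         + hid.contrib_var_gene.sum())

        draws = 100_000
        chol_w = np.linalg.cholesky(hid.loadings_cov)       # (G,K,K)
        chol_x = np.linalg.cholesky(hid.activations_cov)    # (N,K,K)
        total = 0.0
        rng2 = np.random.default_rng(4)
        for _ in range(20):
            b = draws // 20
            ew = rng2.standard_normal((b, G, K))
            ex = rng2.standard_normal((b, N, K))
            W = hid.loadings_mean[None] + np.einsum("gij,bgj->bgi", chol_w, ew)
            X = hid.activations_mean[None] + np.einsum("nij,bnj->bni", chol_x, ex)
            C = np.einsum("bgk,bnk->bgn", W, X)
            total += float(np.sum((Yc[None] - C) ** 2))
        mc = total / draws
        assert analytic == pytest.approx(mc, rel=0.01)


class TestBound:
    def test_scalar_oracle(self):
        """Single gene, single factor: the bound matches an independently
        coded scalar-case evaluation to 1e-8."""
        rng = np.random.default_rng(5)
        N = 4
        y = rng.standard_normal((1, N))
        fit = pq.VBQTL(y, K_hidden=1, max_iter=3).fit()
        st = fit.state
        hid, noise = st.hidden, st.noise
        yc = (y - y.mean())[0]
        a0 = b0 = 1e-3

        mu_w = hid.loadings_mean[0, 0]
        s_w = hid.loadings_cov[0, 0, 0]
        m = hid.activations_mean[:, 0]
        s_x = hid.activations_cov[:, 0, 0]
        at, bt = noise.shape_g[0], noise.rate_g[0]
        etau, eltau = at / bt, digamma(at) - np.log(bt)
        ew2, ex2 = mu_w ** 2 + s_w, m ** 2 + s_x

        esq = sum((yc[n] - mu_w * m[n]) ** 2 + ew2 * ex2[n]
                  - (mu_w * m[n]) ** 2 for n in range(N))
        ref = 0.5 * N * (eltau - LOG2PI) - 0.5 * etau * esq

        def gamma_term(a, b, pa, pb):
            el, et = digamma(a) - np.log(b), a / b
            return (pa * np.log(pb) - gammaln(pa) + (pa - 1) * el - pb * et
                    - (a * np.log(b) - gammaln(a) + (a - 1) * el - a))

        ref += gamma_term(at, bt, a0, b0)
        aa, ba = hid.ard_shape[0], hid.ard_rate[0]
        ealpha, elalpha = aa / ba, digamma(aa) - np.log(ba)
        ref += 0.5 * (elalpha - LOG2PI) - 0.5 * ealpha * ew2
        ref += 0.5 * np.log(s_w) + 0.5 * (1 + LOG2PI)
        ref += sum(-0.5 * LOG2PI - 0.5 * ex2[n]
                   + 0.5 * np.log(s_x[n]) + 0.5 * (1 + LOG2PI)
                   for n in range(N))
        ref += gamma_term(aa, ba, a0, b0)
        assert variational_bound(st, fit.model.expr) == pytest.approx(ref, abs=1e-8)

    def test_monotone_on_every_sweep(self):
        cfg = pq.SimConfig(G=80, N=40, S=25, seed=6)
        expr, geno, covs, _ = pq.simulate(cfg)
        for sched in ("iVBQTL", "fVBQTL"):
            fit = pq.VBQTL(expr, geno, covs, K_hidden=5, schedule=sched,
                           max_iter=40, tol=1e-6).fit()
            assert _min_rel_step(fit.bound_trace) > -1e-6

    def test_noise_perturbation_reduces_bound_and_update_restores(self):
        rng = np.random.default_rng(7)
        Y = rng.standard_normal((30, 20))
        fit = pq.VBQTL(Y, K_hidden=3, max_iter=30, tol=1e-7).fit()
        st = fit.state
        b_opt = variational_bound(st, fit.model.expr)
        st.noise = NoiseState(st.noise.shape_g, st.noise.rate_g * 3.0)
        b_pert = variational_bound(st, fit.model.expr)
        assert b_pert < b_opt
        st.noise = update_noise(st, fit.model.expr)
        b_restored = variational_bound(st, fit.model.expr)
        assert b_restored >= b_pert
        assert b_restored == pytest.approx(b_opt, abs=1e-6 * abs(b_opt))


class TestFit:
    def test_null_model_reduces_to_noise_fit(self):
        rng = np.random.default_rng(8)
        Y = rng.standard_normal((25, 14)) + 1.0
        fit = pq.VBQTL(Y, K_hidden=0).fit()
        Yc = Y - Y.mean(axis=1, keepdims=True)
        assert np.allclose(residual_for("hidden", fit.state, fit.model.expr), Yc)
        var = (Yc ** 2).mean(axis=1)
        expected = (1e-3 + 7) / (1e-3 + 0.5 * (Yc ** 2).sum(axis=1))
        assert np.allclose(fit.noise_precision, expected, rtol=1e-10)

    def test_noiseless_rank1_recovers_single_factor(self):
        rng = np.random.default_rng(9)
        Y = np.outer(rng.standard_normal(50), rng.standard_normal(20))
        fit = pq.VBQTL(Y, K_hidden=5, max_iter=200, tol=1e-8).fit()
        assert len(fit.active_factors(1e-3)) == 1
        err = np.linalg.norm(fit.state.hidden.contrib_mean
                             - (Y - Y.mean(axis=1, keepdims=True)))
        assert err < 1e-3 * np.linalg.norm(Y)

    def test_deterministic_given_seed(self):
        cfg = pq.SimConfig(G=60, N=30, S=15, seed=10)
        expr, geno, covs, _ = pq.simulate(cfg)
        t1 = pq.VBQTL(expr, geno, covs, K_hidden=4, max_iter=15, seed=3).fit()
        t2 = pq.VBQTL(expr, geno, covs, K_hidden=4, max_iter=15, seed=3).fit()
        assert t1.bound_trace.tolist() == t2.bound_trace.tolist()  # bitwise

    def test_k_exceeding_n_warns_and_clamps(self):
        rng = np.random.default_rng(11)
        Y = rng.standard_normal((20, 6))
        with pytest.warns(UserWarning, match="clamping"):
            fit = pq.VBQTL(Y, K_hidden=50, max_iter=3).fit()
        assert fit.state.hidden.n_factors == 6

    def test_unaligned_inputs_rejected(self):
        expr = pq.ExpressionMatrix(np.zeros((2, 3)), ["g1", "g2"], ["a", "b", "c"])
        geno = pq.GenotypeMatrix(np.zeros((1, 3), int), ["s"], ["chr1"], [1],
                                 ["c", "b", "a"], 1)
        with pytest.raises(ValueError, match="align"):
            pq.VBQTL(expr, geno)

    def test_fit_with_missing_entries(self):
        cfg = pq.SimConfig(G=40, N=25, S=10, seed=12)
        expr, geno, covs, _ = pq.simulate(cfg)
        vals = expr.values.copy()
        rng = np.random.default_rng(13)
        holes = rng.random(vals.shape) < 0.05
        vals[holes] = np.nan
        expr2 = pq.ExpressionMatrix(vals, expr.gene_ids, expr.individual_ids)
        fit = pq.VBQTL(expr2, geno, covs, K_hidden=3, max_iter=15).fit()
        assert _min_rel_step(fit.bound_trace) > -1e-6
        R = fit.residuals()
        assert np.array_equal(R.missing_mask, expr2.missing_mask)

    def test_schedules_agree_when_genetic_is_sparse_and_orthogonal(self):
        """With few, modest genetic effects independent of the factors the two
        schedules give residuals within 1% (Frobenius) of each other."""
        cfg = pq.SimConfig(seed=7, n_hotspots=0, frac_cis_genes=0.05,
                           cis_effect_range=(1.0, 2.0))
        expr, geno, covs, _ = pq.simulate(cfg)
        kw = dict(K_hidden=10, max_iter=200, tol=1e-6, prior_inclusion=1e-3)
        ri = pq.VBQTL(expr, geno, covs, schedule="iVBQTL", **kw).fit()
        rf = pq.VBQTL(expr, geno, covs, schedule="fVBQTL", **kw).fit()
        d = np.linalg.norm(ri.residuals().values - rf.residuals().values)
        assert d < 0.01 * np.linalg.norm(expr.values)


class TestCorrectedExpression:
    def test_empty_removal_returns_input(self):
        rng = np.random.default_rng(14)
        Y = rng.standard_normal((10, 8))
        fit = pq.VBQTL(Y, K_hidden=2, max_iter=4).fit()
        out = corrected_expression(fit.state, fit.model.expr, remove=())
        assert np.array_equal(out.values, fit.model.expr.values)

    def test_rank1_removal_leaves_tiny_residual(self):
        rng = np.random.default_rng(15)
        Y = np.outer(rng.standard_normal(40), rng.standard_normal(25))
        fit = pq.VBQTL(Y, K_hidden=3, max_iter=200, tol=1e-8).fit()
        out = fit.residuals(remove={"hidden"})
        resid_c = out.values - out.values.mean(axis=1, keepdims=True)
        assert np.linalg.norm(resid_c) < 1e-3 * np.linalg.norm(Y)

    def test_unfitted_component_rejected(self):
        fit = pq.VBQTL(np.random.default_rng(16).standard_normal((5, 6)),
                       K_hidden=1, max_iter=2).fit()
        with pytest.raises(ValueError, match="not fitted"):
            corrected_expression(fit.state, fit.model.expr, remove={"genetic"})

    def test_genetic_kept_by_default(self):
        cfg = pq.SimConfig(G=30, N=20, S=8, seed=17)
        expr, geno, covs, _ = pq.simulate(cfg)
        fit = pq.VBQTL(expr, geno, covs, K_hidden=2, max_iter=5).fit()
        resid = fit.residuals()
        expected = (expr.values - fit.state.known.contrib_mean
                    - fit.state.hidden.contrib_mean)
        assert np.allclose(resid.values, expected)


def test_save_load_round_trip(tmp_path):
    cfg = pq.SimConfig(G=25, N=15, S=6, seed=18)
    expr, geno, covs, _ = pq.simulate(cfg)
    fit = pq.VBQTL(expr, geno, covs, K_hidden=2, max_iter=5).fit()
    path = tmp_path / "fit.npz"
    fit.save(path)
    arrays, meta = pq.load_fit(path)
    assert meta["gene_ids"] == expr.gene_ids
    assert np.allclose(arrays["hidden_contrib_mean"], fit.state.hidden.contrib_mean)
    assert np.allclose(arrays["bound_trace"], fit.bound_trace)
    assert meta["hyper"]["K_hidden"] == 2
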