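"""Shared fixtures.

The expensive session fixture runs the full method comparison on the
default simulation over ten seeds once; ordering and calibration tests
read from it instead of refitting.
"""

from __future__ import annotations

import numpy as np
import pytest

import peerqtl as pq

N_SEEDS = 10
FPR = 1e-3
FIT_KW = dict(max_iter=60, tol=1e-4)


def _map_scores(resid, geno, truth):
    calls, _ = pq.map_eqtls(resid, geno, truth.annotations, test="ttest", fpr=FPR)
    si, spec = pq.eqtl_sensitivity(calls, truth, "immediate")
    sd, _ = pq.eqtl_sensitivity(calls, truth, "downstream")
    return si, sd, spec


def _min_rel_bound_step(trace):
    bt = np.asarray(trace)
    if len(bt) < 2:
        return 0.0
    d = np.diff(bt)
    return float((d / np.maximum(np.abs(bt[1:]), 1.0)).min())


@pytest.fixture(scope="session")
def bench():
    """Per-seed method comparison on the default simulated study design."""
    per_seed = []
    for seed in range(N_SEEDS):
        cfg = pq.SimConfig(seed=seed)
        expr, geno, covs, truth = pq.simulate(cfg)
        Z = pq.standardize_genotypes(geno.values)
        Y = expr.values
        rec = {"seed": seed}

        # --- PCA across the K grid -------------------------------------
        res0 = pq.correct_standard(expr, covs)
        mses = []
        for K in range(1, 51):
            r = pq.correct_pca(expr, covs, K=K)
            est = res0.residuals.values - r.residuals.values
            mses.append(pq.mse_contribution(est, truth, "combined"))
            if K in (10, 50):
                rec[f"pca{K}_mse_combined"] = mses[-1]
                si, sd, spec = _map_scores(r.residuals, geno, truth)
                rec[f"pca{K}_sens_imm"] = si
                rec[f"pca{K}_sens_down"] = sd
                rec[f"pca{K}_spec"] = spec
        rec["pca_argmin_K"] = int(np.argmin(mses)) + 1

        # --- Standard and Ideal -----------------------------------------
        si, sd, spec = _map_scores(res0.residuals, geno, truth)
        rec.update(standard_sens_imm=si, standard_sens_down=sd, standard_spec=spec)
        ideal = pq.ExpressionMatrix(
            Y - truth.contributions["hidden"] - truth.contributions["known"],
            expr.gene_ids, expr.individual_ids)
        si, sd, spec = _map_scores(ideal, geno, truth)
        rec.update(ideal_sens_imm=si, ideal_sens_down=sd, ideal_spec=spec)

        # --- PCAsig / SVA across the significance-cutoff range ------------
        for alpha, tag in ((1e-5, "lo"), (1e-2, "hi")):
            rec[f"pcasig_n_{tag}"] = pq.pcasig_num_components(
                expr, alpha=alpha, n_perm=100, seed=seed, covs=covs)
            sva = pq.correct_sva(expr, covs, alpha=alpha, n_perm=100, seed=seed)
            rec[f"sva_n_{tag}"] = sva.n_components
            if tag == "hi":
                si, sd, spec = _map_scores(sva.residuals, geno, truth)
                rec.update(sva_sens_imm=si, sva_sens_down=sd, sva_spec=spec)

        # --- VBQTL schedules ------------------------------------------------
        for sched, K, tag in (("iVBQTL", 10, "iv10"),
                              ("fVBQTL", 10, "fv10"),
                              ("fVBQTL", 50, "fv50")):
            fit = pq.VBQTL(expr, geno, covs, K_hidden=K,
                           schedule=sched, **FIT_KW).fit()
            hid = fit.state.hidden.contrib_mean
            rec[f"{tag}_mse_hidden"] = pq.mse_contribution(hid, truth, "hidden")
            rec[f"{tag}_mse_combined"] = pq.mse_contribution(hid, truth, "combined")
            si, sd, spec = _map_scores(fit.residuals(), geno, truth)
            rec[f"{tag}_sens_imm"] = si
            rec[f"{tag}_sens_down"] = sd
            rec[f"{tag}_spec"] = spec
            rec[f"{tag}_min_bound_step"] = _min_rel_bound_step(fit.bound_trace)
            rec[f"{tag}_absorption"] = float(np.mean([
                pq.hotspot_absorption(hid, Z[s], truth)
                for s in truth.regulator_snps]))
            if tag == "fv50":
                rec["fv50_n_active"] = len(fit.active_factors())
        per_seed.append(rec)
    return per_seed


@pytest.fixture()
def small_sim():
    """A quick, fully featured simulated dataset for unit tests."""
    cfg = pq.SimConfig(G=150, N=60, S=50, seed=11)
    return pq.simulate(cfg)


def mean_over(bench, key):
    return float(np.mean([rec[key] for rec in bench]))
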