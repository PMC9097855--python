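"""Monte-Carlo calibration and recovery studies over the built-in scenarios.

These loops exercise the full screen + outcome-model machinery across
replicated synthetic cohorts: null calibration of the per-cluster FDR
screen and of the direct-effect test, and parameter recovery / case
classification under planted effects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import genetics as gen
from . import mediation as med
from . import synth


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1, np.uint32)[0]) for s in np.random.SeedSequence(seed).spawn(n)]


def null_calibration(
    n_reps: int = 100,
    n_subjects: int = 500,
    n_snps: int = 500,
    K: int = 10,
    q: float = 0.05,
    seed: int = 0,
    n_pcs: int = 2,
) -> dict:
    """Null-scenario calibration of the screen and the direct-effect test.

    Per replicate: generate a null cohort, run the per-cluster BH screen at
    ``q``, and fit the outcome model for every SNP with a fixed single
    mediator cluster (cluster 0; under the null the screen selects nothing,
    so a reference mediator is needed to measure the eta test).  Returns the
    fraction of replicates with zero selected (SNP, cluster) pairs, the
    fraction of per-cluster BH families selecting zero SNPs (the quantity
    FDR control bounds at 1-q under the global null), and the pooled raw
    ``p_eta < 0.05`` rejection rate.
    """
    seeds = _child_seeds(seed, n_reps)
    zero_sel = 0
    zero_families = 0
    n_rej = 0
    n_tests = 0
    for s in seeds:
        bundle = synth.scenario("null", n_subjects, seed=s, n_snps=n_snps, K=K)
        Z = gen.make_covariate_table(bundle.covariates, bundle.genotypes, n_pcs=n_pcs)
        assoc = gen.fdr_select(
            gen.cluster_gwas(bundle.proportions, bundle.genotypes, Z), q=q
        )
        per_cluster = assoc.groupby("cluster")["selected"].sum()
        zero_families += int((per_cluster == 0).sum())
        if int(assoc["selected"].sum()) == 0:
            zero_sel += 1
        # vectorized eta test: Y on [1, x_g, omega_0, Z] for every SNP g
        y = bundle.traits.iloc[:, 1].to_numpy(float)
        Zm = Z[[c for c in Z.columns if c != "subject_id"]].to_numpy(float)
        n = len(y)
        B = np.column_stack([np.ones(n), bundle.proportions.weights[:, :1], Zm])
        coef_y, *_ = np.linalg.lstsq(B, y, rcond=None)
        y_t = y - B @ coef_y
        X = bundle.genotypes.dosages
        coef_x, *_ = np.linalg.lstsq(B, X, rcond=None)
        X_t = X - B @ coef_x
        sxx = (X_t**2).sum(axis=0)
        beta = (X_t * y_t[:, None]).sum(axis=0) / sxx
        sse = float(y_t @ y_t) - beta**2 * sxx
        df = n - B.shape[1] - 1
        se = np.sqrt(np.maximum(sse, 0.0) / df / sxx)
        t = beta / se
        from scipy import stats

        p = 2 * stats.t.sf(np.abs(t), df)
        n_rej += int((p < 0.05).sum())
        n_tests += len(p)
    return {
        "frac_zero_selected": zero_sel / n_reps,
        "frac_cluster_families_zero": zero_families / (n_reps * K),
        "eta_rejection_rate": n_rej / n_tests,
        "n_reps": n_reps,
    }


def mediation_recovery(
    scenario_name: str = "full_mediation",
    n_reps: int = 100,
    n_subjects: int = 2000,
    n_snps: int = 500,
    K: int = 10,
    q: float = 0.05,
    level: float = 0.05,
    seed: int = 0,
    run_screen: bool = True,
    n_pcs: int = 2,
) -> pd.DataFrame:
    """Replicated recovery of the planted direct and indirect effects.

    With ``run_screen=True`` the per-cluster FDR screen determines each
    replicate's active set (falling back to the planted cluster when the
    planted pair is missed, recorded in ``planted_selected``); otherwise
    the planted cluster is used directly (cheap mode for invariants that do
    not depend on the screen).  One row per replicate with the estimates,
    their SEs, component p-values and the case label.
    """
    seeds = _child_seeds(seed, n_reps)
    rows = []
    for s in seeds:
        bundle = synth.scenario(scenario_name, n_subjects, seed=s, n_snps=n_snps, K=K)
        g_star, k_star = bundle.planted_snp, bundle.planted_cluster
        snp_id = bundle.planted_snp_id
        y = bundle.traits.iloc[:, 1].to_numpy(float)
        x = bundle.genotypes.dosages[:, g_star]
        W = bundle.proportions.weights
        if run_screen:
            Z = gen.make_covariate_table(bundle.covariates, bundle.genotypes, n_pcs=n_pcs)
            assoc = gen.fdr_select(
                gen.cluster_gwas(bundle.proportions, bundle.genotypes, Z), q=q
            )
            amap = gen.active_sets(assoc)
            S = amap.get(snp_id, [])
            planted_selected = k_star in S
            if not planted_selected:
                S = sorted(set(S) | {k_star})
            blook = {
                int(r.cluster): (float(r.beta_hat), float(r.p))
                for r in assoc[assoc["snp"] == snp_id].itertuples()
            }
        else:
            Z = gen.make_covariate_table(bundle.covariates, None, n_pcs=0)
            S = [k_star]
            planted_selected = True
            Zm = Z[[c for c in Z.columns if c != "subject_id"]].to_numpy(float)
            res = gen._marginal_ols(
                x,
                W[:, [k_star]]
                - np.column_stack([np.ones(len(y)), Zm])
                @ np.linalg.lstsq(
                    np.column_stack([np.ones(len(y)), Zm]), W[:, [k_star]], rcond=None
                )[0],
                np.column_stack([np.ones(len(y)), Zm]),
            )
            beta_hat, se_b, _, p_b, _, _ = res
            blook = {k_star: (float(beta_hat[0]), float(p_b[0]))}
        om = med.outcome_model(y, x, W[:, S], Z, clusters=S)
        summ = med.compute_effects(om, {k: blook[k] for k in S}, snp=snp_id)
        label = med.classify_case(
            summ.p_eta, [(p["p_beta"], p["p_alpha"]) for p in summ.paths], level=level
        )
        path = next(p for p in summ.paths if p["k"] == k_star)
        se_beta = None
        if not run_screen:
            se_beta = float(se_b[0])
        rows.append(
            {
                "eta_hat": summ.ade,
                "se_eta": om.se_eta,
                "p_eta": summ.p_eta,
                "aie_hat": summ.aie,
                "beta_hat": path["beta"],
                "p_beta": path["p_beta"],
                "se_beta": se_beta,
                "alpha_hat": path["alpha"],
                "se_alpha": om.se_alpha[k_star],
                "p_alpha": path["p_alpha"],
                "planted_selected": planted_selected,
                "case_label": label,
                "planted_eta": bundle.planted_eta,
                "planted_beta": bundle.planted_beta,
                "planted_alpha": bundle.planted_alpha,
                "planted_aie": bundle.planted_aie,
            }
        )
    return pd.DataFrame(rows)
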