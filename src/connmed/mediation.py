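"""Outcome model, effect decomposition and the three-case classification.

For a screened SNP g with active cluster set S^g, the outcome model is

    Y_i = eta0 + x_ig * eta + sum_{k in S^g} omega_ik * alpha_k + Z_i' xi + eps

fitted by OLS.  The average direct effect (ADE) is eta-hat; the average
indirect effect (AIE) is the product-of-coefficients sum
``sum_k alpha_k-hat * beta_k-hat`` with beta_k-hat taken from the screen fit
(same covariates).  The percent mediated uses the absolute-value form

    %GE = 100 |AIE| / (|ADE| + |AIE|)

which stays in [0, 100] even when the two effects carry opposite signs.
An indirect path is called significant by joint significance: both its
beta_k and alpha_k tests rejecting at the working level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "OutcomeModelResult",
    "MediationSummary",
    "BootstrapResult",
    "CollinearityError",
    "outcome_model",
    "percent_mediated",
    "compute_effects",
    "classify_case",
    "fdr_adjust_mediation",
    "bootstrap_mediation",
    "mediate_all",
]

SUMMARY_COLUMNS = [
    "trait",
    "snp",
    "ADE",
    "p_ADE",
    "AIE",
    "clusters",
    "p_beta_k",
    "p_alpha_k",
    "pct_GE",
    "pct_defined",
    "case_label",
    "note",
]


class CollinearityError(ValueError):
    """Rank-deficient outcome design."""


@dataclass
class OutcomeModelResult:
    eta0_hat: float
    eta_hat: float
    alpha_hat: dict[int, float]
    xi_hat: np.ndarray
    se_eta: float
    p_eta: float
    se_alpha: dict[int, float]
    p_alpha: dict[int, float]
    sigma2_sq_hat: float
    n: int
    df: int
    clusters: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.df <= 0:
            raise ValueError("outcome model has non-positive residual df")


@dataclass
class MediationSummary:
    snp: str
    trait: str
    ade: float
    p_eta: float
    aie: float
    pct_mediated: float  # NaN when undefined
    pct_defined: bool
    paths: list[dict]  # one per active cluster: k, beta, p_beta, alpha, p_alpha
    case_label: str = ""


@dataclass
class BootstrapResult:
    ade_samples: np.ndarray
    aie_samples: np.ndarray
    ci_ade: tuple[float, float]
    ci_aie: tuple[float, float]
    p_ade: float
    p_aie: float
    n_boot: int
    n_skipped: int
    seed: int

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if self.ci_ade[0] > self.ci_ade[1] or self.ci_aie[0] > self.ci_aie[1]:
            raise ValueError("CI bounds out of order")


def _ols(X: np.ndarray, y: np.ndarray):
    """OLS fit returning coefficients, SEs, p-values, sigma^2 and df."""
    n, q = X.shape
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < q:
        raise CollinearityError(
            "outcome design is rank deficient; note that all K simplex "
            "columns plus an intercept are collinear (sum omega = 1) -- "
            "drop one cluster"
        )
    resid = y - X @ coef
    df = n - q
    if df <= 0:
        raise ValueError("not enough subjects for the requested design")
    sigma2 = float(resid @ resid) / df
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * np.diag(XtX_inv))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, coef / se, np.inf * np.sign(coef))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return coef, se, p, sigma2, df


def outcome_model(
    Y: np.ndarray,
    x_g: np.ndarray,
    omega_S: np.ndarray,
    Z: pd.DataFrame | np.ndarray,
    clusters: list[int] | None = None,
) -> OutcomeModelResult:
    """OLS of the trait on ``[1, dosage, active clusters, covariates]``.

    Subjects with a missing dosage (or trait) are dropped.  Two-sided
    t-tests are reported for eta and every alpha_k on ``n - (2+|S|+p)`` df.
    """
    Y = np.asarray(Y, dtype=float)
    x_g = np.asarray(x_g, dtype=float)
    omega_S = np.asarray(omega_S, dtype=float)
    if omega_S.ndim == 1:
        omega_S = omega_S[:, None]
    if omega_S.shape[1] < 1:
        raise ValueError("the active cluster set must be non-empty")
    if isinstance(Z, pd.DataFrame):
        Zm = Z[[c for c in Z.columns if c != "subject_id"]].to_numpy(dtype=float)
    else:
        Zm = np.asarray(Z, dtype=float)
    clusters = list(clusters) if clusters is not None else list(range(omega_S.shape[1]))

    mask = ~np.isnan(x_g) & ~np.isnan(Y)
    Y, x_g, omega_S, Zm = Y[mask], x_g[mask], omega_S[mask], Zm[mask]
    n = Y.shape[0]
    X = np.column_stack([np.ones(n), x_g, omega_S, Zm])
    coef, se, p, sigma2, df = _ols(X, Y)

    nS = omega_S.shape[1]
    return OutcomeModelResult(
        eta0_hat=float(coef[0]),
        eta_hat=float(coef[1]),
        alpha_hat={k: float(coef[2 + j]) for j, k in enumerate(clusters)},
        xi_hat=coef[2 + nS :],
        se_eta=float(se[1]),
        p_eta=float(p[1]),
        se_alpha={k: float(se[2 + j]) for j, k in enumerate(clusters)},
        p_alpha={k: float(p[2 + j]) for j, k in enumerate(clusters)},
        sigma2_sq_hat=sigma2,
        n=n,
        df=df,
        clusters=clusters,
    )


def percent_mediated(ade: float, aie: float) -> float:
    """Absolute-value percent of the global effect carried by the mediator.

    Returns NaN when ADE = AIE = 0 (undefined, not zero).
    """
    denom = abs(ade) + abs(aie)
    if denom == 0.0:
        return float("nan")
    # ratio computed first so the result cannot exceed 100 in floating point
    return 100.0 * (abs(aie) / denom)


def compute_effects(
    outcome: OutcomeModelResult,
    beta_info: dict[int, tuple[float, float]],
    snp: str = "",
    trait: str = "",
) -> MediationSummary:
    """Assemble ADE, AIE and percent mediated for one (SNP, trait) pair.

    ``beta_info`` maps each active cluster to its screen estimate
    ``(beta_hat, p_beta)``; a missing cluster is an error.
    """
    missing = [k for k in outcome.clusters if k not in beta_info]
    if missing:
        raise ValueError(f"no screen beta_hat for active cluster(s) {missing}")
    ade = outcome.eta_hat
    paths = []
    aie = 0.0
    for k in outcome.clusters:
        b, pb = beta_info[k]
        a = outcome.alpha_hat[k]
        aie += a * b
        paths.append(
            {
                "k": k,
                "beta": b,
                "p_beta": pb,
                "alpha": a,
                "p_alpha": outcome.p_alpha[k],
            }
        )
    pct = percent_mediated(ade, aie)
    return MediationSummary(
        snp=snp,
        trait=trait,
        ade=ade,
        p_eta=outcome.p_eta,
        aie=aie,
        pct_mediated=pct,
        pct_defined=not np.isnan(pct),
        paths=paths,
    )


def classify_case(
    p_eta: float,
    path_p: list[tuple[float, float]],
    level: float = 0.05,
) -> str:
    """Three-case mediation outcome (plus 'neither').

    An indirect path is significant iff both its beta and alpha component
    p-values fall below ``level`` (joint significance for H0: alpha*beta=0);
    any significant path makes the indirect effect significant.
    """
    if not 0 <= p_eta <= 1:
        raise ValueError("p_eta must lie in [0, 1]")
    for pb, pa in path_p:
        if not (0 <= pb <= 1 and 0 <= pa <= 1):
            raise ValueError("path p-values must lie in [0, 1]")
    direct = p_eta < level
    indirect = any(pb < level and pa < level for pb, pa in path_p)
    if direct and indirect:
        return "both"
    if direct:
        return "direct_only"
    if indirect:
        return "indirect_only"
    return "neither"


def _bh(p: np.ndarray) -> np.ndarray:
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def fdr_adjust_mediation(summaries: pd.DataFrame, q: float = 0.05) -> pd.DataFrame:
    """BH adjustment across SNPs, per trait, per p-value family.

    The eta family is adjusted over the (trait, snp) rows; the beta and
    alpha path families are each adjusted over all paths of the trait.
    Adds ``p_ADE_fdr``, ``p_beta_k_fdr`` and ``p_alpha_k_fdr`` columns
    (path columns semicolon-joined like their raw counterparts).
    """
    out = summaries.copy()
    out["p_ADE_fdr"] = np.nan
    out["p_beta_k_fdr"] = ""
    out["p_alpha_k_fdr"] = ""
    for _, idx in out.groupby("trait").groups.items():
        idx = list(idx)
        out.loc[idx, "p_ADE_fdr"] = _bh(out.loc[idx, "p_ADE"].to_numpy(dtype=float))
        for col, col_adj in (("p_beta_k", "p_beta_k_fdr"), ("p_alpha_k", "p_alpha_k_fdr")):
            lengths, flat = [], []
            for v in out.loc[idx, col]:
                vals = [float(t) for t in str(v).split(";") if t not in ("", "nan")]
                lengths.append(len(vals))
                flat.extend(vals)
            adj = _bh(np.asarray(flat, dtype=float))
            pos = 0
            joined = []
            for m in lengths:
                joined.append(";".join(f"{x:.6g}" for x in adj[pos : pos + m]))
                pos += m
            out.loc[idx, col_adj] = joined
    return out


def bootstrap_mediation(
    Y: np.ndarray,
    x_g: np.ndarray,
    omega_S: np.ndarray,
    Z: pd.DataFrame | np.ndarray,
    n_boot: int = 500,
    seed: int = 0,
    clusters: list[int] | None = None,
) -> BootstrapResult:
    """Non-parametric bootstrap of ADE and AIE.

    Subjects are resampled with replacement; both model layers (screen fit
    of each active cluster on the dosage, and the outcome model) are refit
    per replicate.  Reports percentile 95% CIs and two-sided sign-based
    bootstrap p-values ``2 min(frac <= 0, frac >= 0)``.  Degenerate
    replicates (e.g. a monomorphic resample) are skipped and counted.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    Y = np.asarray(Y, dtype=float)
    x_g = np.asarray(x_g, dtype=float)
    omega_S = np.asarray(omega_S, dtype=float)
    if omega_S.ndim == 1:
        omega_S = omega_S[:, None]
    if isinstance(Z, pd.DataFrame):
        Zm = Z[[c for c in Z.columns if c != "subject_id"]].to_numpy(dtype=float)
    else:
        Zm = np.asarray(Z, dtype=float)
    mask = ~np.isnan(x_g) & ~np.isnan(Y)
    Y, x_g, omega_S, Zm = Y[mask], x_g[mask], omega_S[mask], Zm[mask]
    n = Y.shape[0]
    rng = np.random.default_rng(seed)

    ade_s, aie_s = [], []
    n_skipped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        xb = x_g[idx]
        if np.var(xb) == 0:
            n_skipped += 1
            continue
        Wb, Yb, Zb = omega_S[idx], Y[idx], Zm[idx]
        B1 = np.column_stack([np.ones(n), xb, Zb])
        try:
            beta_b, _, rank1, _ = np.linalg.lstsq(B1, Wb, rcond=None)
            if rank1 < B1.shape[1]:
                raise CollinearityError("degenerate screen design")
            X2 = np.column_stack([np.ones(n), xb, Wb, Zb])
            coef2, _, rank2, _ = np.linalg.lstsq(X2, Yb, rcond=None)
            if rank2 < X2.shape[1]:
                raise CollinearityError("degenerate outcome design")
        except (CollinearityError, np.linalg.LinAlgError):
            n_skipped += 1
            continue
        ade_s.append(coef2[1])
        alpha_b = coef2[2 : 2 + omega_S.shape[1]]
        aie_s.append(float(alpha_b @ beta_b[1]))
    ade_s = np.asarray(ade_s)
    aie_s = np.asarray(aie_s)
    if ade_s.size == 0:
        raise ValueError("every bootstrap replicate was degenerate")

    def _p(v: np.ndarray) -> float:
        return float(2.0 * min((v <= 0).mean(), (v >= 0).mean()))

    return BootstrapResult(
        ade_samples=ade_s,
        aie_samples=aie_s,
        ci_ade=tuple(np.percentile(ade_s, [2.5, 97.5])),
        ci_aie=tuple(np.percentile(aie_s, [2.5, 97.5])),
        p_ade=_p(ade_s),
        p_aie=_p(aie_s),
        n_boot=n_boot,
        n_skipped=n_skipped,
        seed=seed,
    )


def _summary_row(s: MediationSummary) -> dict:
    return {
        "trait": s.trait,
        "snp": s.snp,
        "ADE": s.ade,
        "p_ADE": s.p_eta,
        "AIE": s.aie,
        "clusters": ";".join(str(p["k"]) for p in s.paths),
        "p_beta_k": ";".join(f"{p['p_beta']:.6g}" for p in s.paths),
        "p_alpha_k": ";".join(f"{p['p_alpha']:.6g}" for p in s.paths),
        "pct_GE": s.pct_mediated,
        "pct_defined": s.pct_defined,
        "case_label": s.case_label,
        "note": "",
    }


def mediate_all(
    active_map: dict[str, list[int]],
    assoc: pd.DataFrame,
    omega,
    G,
    Z: pd.DataFrame,
    traits: pd.DataFrame,
    level: float = 0.05,
    q: float = 0.05,
) -> pd.DataFrame:
    """Run the outcome model for every (selected SNP, trait) pair.

    Per-pair failures are recorded as flagged rows (``case_label='error'``)
    without aborting the sweep.  The returned table carries the screen-side
    and outcome-side path p-values, percent mediated, the case label and
    BH-adjusted p-value columns.
    """
    W = omega.weights if hasattr(omega, "weights") else np.asarray(omega, float)
    snp_col = {s: j for j, s in enumerate(G.snp_ids)}
    trait_cols = [c for c in traits.columns if c != "subject_id"]
    beta_lookup = {
        (r.snp, int(r.cluster)): (float(r.beta_hat), float(r.p))
        for r in assoc.itertuples()
    }
    rows = []
    for trait in trait_cols:
        y = traits[trait].to_numpy(dtype=float)
        for snp in sorted(active_map):
            S = active_map[snp]
            try:
                x = G.dosages[:, snp_col[snp]]
                om = outcome_model(y, x, W[:, S], Z, clusters=S)
                binfo = {k: beta_lookup[(snp, k)] for k in S}
                summ = compute_effects(om, binfo, snp=snp, trait=trait)
                summ.case_label = classify_case(
                    summ.p_eta,
                    [(p["p_beta"], p["p_alpha"]) for p in summ.paths],
                    level=level,
                )
                rows.append(_summary_row(summ))
            except (ValueError, KeyError, np.linalg.LinAlgError) as exc:
                rows.append(
                    {
                        "trait": trait,
                        "snp": snp,
                        "ADE": np.nan,
                        "p_ADE": np.nan,
                        "AIE": np.nan,
                        "clusters": ";".join(map(str, S)),
                        "p_beta_k": "",
                        "p_alpha_k": "",
                        "pct_GE": np.nan,
                        "pct_defined": False,
                        "case_label": "error",
                        "note": str(exc),
                    }
                )
    table = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    if table.empty:
        for c in ("p_ADE_fdr", "p_beta_k_fdr", "p_alpha_k_fdr"):
            table[c] = pd.Series(dtype=float)
        return table
    ok = table["case_label"] != "error"
    adjusted = fdr_adjust_mediation(table[ok], q=q)
    table = table.merge(
        adjusted[["trait", "snp", "p_ADE_fdr", "p_beta_k_fdr", "p_alpha_k_fdr"]],
        on=["trait", "snp"],
        how="left",
    )
    return table
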