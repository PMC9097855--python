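"""Genotype QC, population-structure PCs, and the per-cluster SNP screen.

Each connectome cluster weight is regressed on every SNP's additive
minor-allele dosage plus confounders (age, sex, top genotype PCs):

    omega_ik = b0 + x_ig * beta_k + Z_i' gamma_k + eps,   eps ~ N(0, s1^2)

The screen tests H0: beta_k = 0 per (SNP, cluster) with Benjamini-Hochberg
FDR control applied within each cluster separately.  Surviving SNPs are
greedily LD-pruned (r^2 threshold) to lead SNPs, and each selected SNP g
carries an active cluster set S^g used downstream as its mediators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GenotypeMatrix",
    "QCReport",
    "recode_minor_allele",
    "qc_filter",
    "hwe_test",
    "genotype_pca",
    "make_covariate_table",
    "cluster_gwas",
    "fdr_select",
    "ld_r2",
    "lead_snps",
    "active_sets",
]

ASSOC_COLUMNS = [
    "snp",
    "cluster",
    "beta_hat",
    "se",
    "t",
    "p",
    "df",
    "sigma1_sq_hat",
    "degenerate",
]


class EmptyDataError(ValueError):
    """All subjects or all variants were removed."""


@dataclass
class GenotypeMatrix:
    """Additive dosage matrix, ``n_subjects x n_snps``.

    Dosages count copies of the designated (ideally minor) allele and are
    0/1/2 with ``NaN`` marking missing calls.
    """

    dosages: np.ndarray
    snp_ids: list[str]
    subject_ids: list[str]
    minor_alleles: list[str] = field(default_factory=list)
    major_alleles: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (subjects x SNPs)")
        n, g = self.dosages.shape
        if len(self.snp_ids) != g or len(self.subject_ids) != n:
            raise ValueError("id lists must match the dosage matrix shape")
        obs = self.dosages[~np.isnan(self.dosages)]
        if obs.size and not np.isin(obs, (0.0, 1.0, 2.0)).all():
            raise ValueError("non-missing dosages must be 0, 1 or 2")
        if not self.minor_alleles:
            self.minor_alleles = ["A"] * g
        if not self.major_alleles:
            self.major_alleles = ["B"] * g

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Frequency of the counted allele per SNP (non-missing subjects)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def subset(self, subj_mask=None, snp_mask=None) -> "GenotypeMatrix":
        d = self.dosages
        sids = self.subject_ids
        gids, mi, ma = self.snp_ids, self.minor_alleles, self.major_alleles
        if subj_mask is not None:
            d = d[subj_mask]
            sids = [s for s, keep in zip(self.subject_ids, subj_mask) if keep]
        if snp_mask is not None:
            d = d[:, snp_mask]
            gids = [s for s, keep in zip(gids, snp_mask) if keep]
            mi = [s for s, keep in zip(mi, snp_mask) if keep]
            ma = [s for s, keep in zip(ma, snp_mask) if keep]
        return GenotypeMatrix(d.copy(), list(gids), list(sids), list(mi), list(ma))


@dataclass
class QCReport:
    n_subjects_in: int
    n_snps_in: int
    n_subjects_removed: int
    n_variants_missing_removed: int
    n_variants_hwe_removed: int
    n_subjects_out: int
    n_snps_out: int

    def __str__(self) -> str:  # plain-text report
        return (
            f"genotype QC: {self.n_subjects_in} subjects, {self.n_snps_in} variants in\n"
            f"  subjects removed (missingness): {self.n_subjects_removed}\n"
            f"  variants removed (missingness): {self.n_variants_missing_removed}\n"
            f"  variants removed (HWE):         {self.n_variants_hwe_removed}\n"
            f"  {self.n_subjects_out} subjects, {self.n_snps_out} variants out"
        )


def recode_minor_allele(G: GenotypeMatrix) -> GenotypeMatrix:
    """Flip SNPs so dosages count the minor allele.

    A SNP whose counted-allele frequency exceeds 0.5 (among non-missing
    subjects) is flipped ``x -> 2 - x`` and its allele labels swapped; a
    frequency of exactly 0.5 is left as-is.  Idempotent.
    """
    d = G.dosages.copy()
    n_obs = (~np.isnan(d)).sum(axis=0)
    if np.any(n_obs == 0):
        bad = [G.snp_ids[j] for j in np.flatnonzero(n_obs == 0)]
        raise ValueError(f"SNP(s) with all genotypes missing: {bad}")
    freq = np.nanmean(d, axis=0) / 2.0
    flip = freq > 0.5
    d[:, flip] = 2.0 - d[:, flip]
    minor = [ma if f else mi for mi, ma, f in zip(G.minor_alleles, G.major_alleles, flip)]
    major = [mi if f else ma for mi, ma, f in zip(G.minor_alleles, G.major_alleles, flip)]
    return GenotypeMatrix(d, list(G.snp_ids), list(G.subject_ids), minor, major)


def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """One-df chi-square goodness-of-fit test of Hardy-Weinberg equilibrium.

    Expected counts come from the sample allele frequency.  Monomorphic
    inputs return p = 1 by convention (no test possible).
    """
    n = n_AA + n_Aa + n_aa
    if n <= 0:
        raise ValueError("total genotype count must be positive")
    p = (2 * n_AA + n_Aa) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    q = 1.0 - p
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n_AA, n_Aa, n_aa], dtype=float)
    statistic = np.sum((observed - expected) ** 2 / expected)
    return float(stats.chi2.sf(statistic, df=1))


def qc_filter(
    G: GenotypeMatrix,
    max_subject_missing: float = 0.10,
    max_variant_missing: float = 0.10,
    hwe_alpha: float = 1e-7,
) -> tuple[GenotypeMatrix, QCReport]:
    """Standard genotype QC: subject missingness, variant missingness, HWE.

    Applied in that order: subjects with more than ``max_subject_missing``
    of genotypes missing are dropped, then variants with more than
    ``max_variant_missing`` missing, then variants with HWE p below
    ``hwe_alpha``.
    """
    n_in, g_in = G.n_subjects, G.n_snps
    miss_subj = np.isnan(G.dosages).mean(axis=1)
    keep_subj = miss_subj <= max_subject_missing
    if not keep_subj.any():
        raise EmptyDataError("all subjects removed by missingness filter")
    G1 = G.subset(subj_mask=keep_subj)

    miss_var = np.isnan(G1.dosages).mean(axis=0)
    keep_var = miss_var <= max_variant_missing
    n_var_miss = int((~keep_var).sum())
    if not keep_var.any():
        raise EmptyDataError("all variants removed by missingness filter")
    G2 = G1.subset(snp_mask=keep_var)

    keep_hwe = np.ones(G2.n_snps, dtype=bool)
    for j in range(G2.n_snps):
        col = G2.dosages[:, j]
        col = col[~np.isnan(col)]
        n2 = int((col == 2).sum())
        n1 = int((col == 1).sum())
        n0 = int((col == 0).sum())
        if hwe_test(n2, n1, n0) < hwe_alpha:
            keep_hwe[j] = False
    n_hwe = int((~keep_hwe).sum())
    if not keep_hwe.any():
        raise EmptyDataError("all variants removed by the HWE filter")
    G3 = G2.subset(snp_mask=keep_hwe)

    report = QCReport(
        n_subjects_in=n_in,
        n_snps_in=g_in,
        n_subjects_removed=int((~keep_subj).sum()),
        n_variants_missing_removed=n_var_miss,
        n_variants_hwe_removed=n_hwe,
        n_subjects_out=G3.n_subjects,
        n_snps_out=G3.n_snps,
    )
    return G3, report


def genotype_pca(G: GenotypeMatrix, n_components: int = 2) -> np.ndarray:
    """Per-subject scores on the top genotype principal components.

    Missing entries are mean-imputed per SNP; columns are centered and
    scaled by sqrt(2 p (1-p)); monomorphic SNPs are dropped.  Each
    component's sign is fixed by making its largest-magnitude SNP loading
    positive.
    """
    if G.n_subjects < 2:
        raise ValueError("genotype PCA needs at least 2 subjects")
    X = G.dosages.copy()
    col_mean = np.nanmean(X, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(X))
    X[nan_r, nan_c] = col_mean[nan_c]
    p_hat = col_mean / 2.0
    scale = np.sqrt(2.0 * p_hat * (1.0 - p_hat))
    poly = (scale > 0) & (X.var(axis=0) > 0)
    if not poly.any():
        return np.zeros((G.n_subjects, n_components))
    Xs = (X[:, poly] - col_mean[poly]) / scale[poly]
    U, S, Vt = np.linalg.svd(Xs, full_matrices=False)
    rank = int((S > max(S[0], 1e-300) * 1e-10).sum()) if S.size else 0
    if n_components > rank:
        raise ValueError(
            f"n_components={n_components} exceeds the rank ({rank}) of the genotype matrix"
        )
    scores = U[:, :n_components] * S[:n_components]
    for c in range(n_components):
        j = int(np.argmax(np.abs(Vt[c])))
        if Vt[c, j] < 0:
            scores[:, c] = -scores[:, c]
    return scores


def make_covariate_table(
    covariates: pd.DataFrame, G: GenotypeMatrix | None = None, n_pcs: int = 2
) -> pd.DataFrame:
    """Assemble the confounder table: age, sex, and top genotype PCs.

    ``covariates`` must carry ``subject_id``, ``age`` and ``sex`` columns;
    rows are aligned to ``G.subject_ids`` when genotypes are given.
    """
    cov = covariates.set_index("subject_id")
    if G is not None:
        cov = cov.loc[G.subject_ids]
    Z = cov[["age", "sex"]].astype(float).copy()
    if G is not None and n_pcs > 0:
        pcs = genotype_pca(G, n_components=n_pcs)
        for c in range(n_pcs):
            Z[f"PC{c + 1}"] = pcs[:, c]
    if Z.isna().any().any():
        raise ValueError("covariate table contains missing values")
    return Z.reset_index()


def _covariate_matrix(Z: pd.DataFrame) -> np.ndarray:
    cols = [c for c in Z.columns if c != "subject_id"]
    return Z[cols].to_numpy(dtype=float)


def _marginal_ols(x: np.ndarray, Ybase: np.ndarray, B: np.ndarray):
    """Exact OLS slope of each column of Ybase on x, adjusting for B.

    Frisch-Waugh: residualize both on the base design B (intercept +
    covariates); slope, SE, t and p equal the full-model quantities.
    """
    n, q = B.shape
    coef_x, *_ = np.linalg.lstsq(B, x, rcond=None)
    x_t = x - B @ coef_x
    sxx = float(x_t @ x_t)
    df = n - q - 1
    if sxx <= 1e-12 or df <= 0:
        return None
    beta = (x_t @ Ybase) / sxx
    sse = (Ybase**2).sum(axis=0) - beta**2 * sxx
    sigma2 = np.maximum(sse, 0.0) / df
    se = np.sqrt(sigma2 / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return beta, se, t, p, df, sigma2


def cluster_gwas(
    omega, G: GenotypeMatrix, Z: pd.DataFrame
) -> pd.DataFrame:
    """Per-(SNP, cluster) association screen.

    For every SNP g and cluster k, fits OLS of ``omega[:, k]`` on
    ``[1, x_g, Z]`` and reports the dosage slope with its t statistic and
    two-sided p-value (t distribution, ``n - p - 2`` df).  Subjects with a
    missing dosage are dropped per SNP.  SNPs monomorphic after subsetting
    are emitted with ``p = 1`` and ``degenerate = True``.
    """
    W = omega.weights if hasattr(omega, "weights") else np.asarray(omega, float)
    n, K = W.shape
    if G.n_subjects != n:
        raise ValueError("connectome and genotype matrices disagree on subjects")
    Zm = _covariate_matrix(Z)
    if Zm.shape[0] != n:
        raise ValueError("covariate table does not match the subject count")
    B = np.column_stack([np.ones(n), Zm])

    # residualize omega on the base design once (fast path, complete data)
    coefs, *_ = np.linalg.lstsq(B, W, rcond=None)
    W_t = W - B @ coefs

    rows = []
    complete = ~np.isnan(G.dosages).any(axis=0)
    for j in range(G.n_snps):
        x = G.dosages[:, j]
        if complete[j]:
            res = _marginal_ols(x, W_t, B)
        else:
            mask = ~np.isnan(x)
            Bs = B[mask]
            coefs_s, *_ = np.linalg.lstsq(Bs, W[mask], rcond=None)
            res = _marginal_ols(x[mask], W[mask] - Bs @ coefs_s, Bs)
        if res is None:
            for k in range(K):
                rows.append((G.snp_ids[j], k, 0.0, np.nan, np.nan, 1.0, 0, np.nan, True))
            continue
        beta, se, t, p, df, sigma2 = res
        for k in range(K):
            rows.append(
                (G.snp_ids[j], k, beta[k], se[k], t[k], p[k], df, sigma2[k], False)
            )
    return pd.DataFrame(rows, columns=ASSOC_COLUMNS)


def fdr_select(assoc: pd.DataFrame, q: float = 0.05) -> pd.DataFrame:
    """Benjamini-Hochberg selection, applied within each cluster separately.

    Adds ``fdr_p`` (BH-adjusted p) and ``selected`` columns.
    """
    out = assoc.copy()
    out["fdr_p"] = np.nan
    out["selected"] = False
    for _, idx in out.groupby("cluster").groups.items():
        p = out.loc[idx, "p"].to_numpy()
        reject, padj, *_ = multipletests(p, alpha=q, method="fdr_bh")
        out.loc[idx, "fdr_p"] = padj
        out.loc[idx, "selected"] = reject
    out["selected"] &= ~out["degenerate"].astype(bool)
    return out


def ld_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Computed over pairwise-complete subjects; invariant to allele flips of
    either argument.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    mask = ~np.isnan(g1) & ~np.isnan(g2)
    if mask.sum() < 2:
        raise ValueError("fewer than 2 shared non-missing subjects")
    a, b = g1[mask], g2[mask]
    if np.var(a) == 0 or np.var(b) == 0:
        raise ValueError("zero-variance dosage vector in r^2 computation")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def lead_snps(
    assoc: pd.DataFrame, G: GenotypeMatrix, r2_max: float = 0.1
) -> list[str]:
    """Greedy LD pruning of FDR-selected SNPs to independent lead SNPs.

    Selected SNPs are ordered by their best (smallest) p-value, ties broken
    by SNP id; a SNP is accepted iff its r^2 with every already-accepted
    SNP is at most ``r2_max``.
    """
    sel = assoc[assoc["selected"]]
    if sel.empty:
        raise ValueError("no selected associations to prune")
    best = sel.groupby("snp")["p"].min().reset_index()
    best = best.sort_values(["p", "snp"], kind="stable")
    col = {s: i for i, s in enumerate(G.snp_ids)}
    accepted: list[str] = []
    for snp in best["snp"]:
        x = G.dosages[:, col[snp]]
        ok = True
        for a in accepted:
            if ld_r2(x, G.dosages[:, col[a]]) > r2_max:
                ok = False
                break
        if ok:
            accepted.append(snp)
    return accepted


def active_sets(assoc: pd.DataFrame) -> dict[str, list[int]]:
    """Invert selected (SNP, cluster) pairs into SNP -> active cluster set.

    SNPs with no selected cluster do not appear.
    """
    sel = assoc[assoc["selected"]]
    out: dict[str, list[int]] = {}
    for snp, grp in sel.groupby("snp"):
        out[str(snp)] = sorted(int(k) for k in grp["cluster"])
    return out
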