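"""Synthetic cohorts with planted genotype -> connectome -> trait structure.

The generator emulates the data a connectome mediation study consumes:
Hardy-Weinberg genotypes with configurable MAF and missingness, age/sex
covariates with optional sibling-pair family structure, per-subject fiber
endpoint clouds drawn from K ground-truth clusters, and cognitive traits.
Cluster proportions follow the screen's linear model (baseline +
dosage*beta + covariates*gamma + Gaussian noise) mapped onto the simplex by
clipping at a small floor and renormalizing; traits follow the outcome
model (direct dosage effect eta, mediator effects alpha, covariate effects
xi, Gaussian noise).

The built-in scenarios plant genotype effects that sum to zero across
clusters: a dosage that shifts fiber mass into one bundle must draw it from
the others, and this compositional choice also keeps the planted slope
unattenuated by the simplex renormalization, so regression recovers the
planted values unbiasedly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectome import ConnectomeMatrix, FiberSet
from .genetics import GenotypeMatrix

__all__ = [
    "ClusterBlueprint",
    "EffectSpec",
    "ScenarioBundle",
    "SCENARIOS",
    "default_blueprint",
    "gen_genotypes",
    "gen_subjects",
    "gen_proportions",
    "gen_streamlines",
    "gen_traits",
    "scenario",
]

SCENARIOS = ("null", "direct_only", "indirect_only", "full_mediation")

#: default planted effect sizes (see docs/methods.md for the calibration)
DEFAULT_BETA = 0.005  # proportion units per minor allele
DEFAULT_ETA = 2.0  # trait units per minor allele (direct effect)
DEFAULT_ALPHA = 55.0  # trait units per unit cluster proportion
DEFAULT_SIGMA1 = 0.02  # residual SD of the cluster-weight model
DEFAULT_SIGMA2 = 10.0  # residual SD of the trait model
DEFAULT_ETA0 = 100.0  # trait intercept (NIH-toolbox-like scale)
DEFAULT_XI = (0.2, 1.0)  # (age, sex) effects on the trait
PLANTED_MAF = 0.3

CLIP_FLOOR = 1e-6


class DegenerateSimplexError(ValueError):
    """A proportion row collapsed entirely onto the clip floor."""


@dataclass
class ClusterBlueprint:
    """Ground truth behind the population fiber clusters.

    ``centers`` holds one endpoint pair per cluster, shape ``(K, 2, 3)`` in
    mm; ``spread`` is the isotropic per-cluster endpoint SD; and
    ``baseline_props`` the population-mean cluster proportions (a simplex
    vector).
    """

    K_true: int
    centers: np.ndarray
    spread: float | np.ndarray
    baseline_props: np.ndarray

    def __post_init__(self) -> None:
        if self.K_true < 1:
            raise ValueError("K_true must be >= 1")
        self.centers = np.asarray(self.centers, dtype=float).reshape(self.K_true, 2, 3)
        self.spread = np.broadcast_to(
            np.asarray(self.spread, dtype=float), (self.K_true,)
        ).copy()
        if np.any(self.spread <= 0):
            raise ValueError("spread must be positive")
        self.baseline_props = np.asarray(self.baseline_props, dtype=float)
        if self.baseline_props.shape != (self.K_true,):
            raise ValueError("baseline_props must have length K_true")
        if np.any(self.baseline_props < 0) or abs(self.baseline_props.sum() - 1) > 1e-12:
            raise ValueError("baseline_props must be nonnegative and sum to 1")


@dataclass
class EffectSpec:
    """Planted effects for both model layers.

    ``beta_map``: (snp index, cluster) -> genotype effect on that cluster's
    proportion; ``eta_map``: snp index -> direct trait effect; ``alpha``:
    per-cluster mediator effects on the trait; ``xi``: covariate effects on
    the trait; ``gamma``: optional (p x K) covariate effects on the
    proportions; ``sigma1``/``sigma2``: residual SDs of the two layers.
    """

    beta_map: dict[tuple[int, int], float] = field(default_factory=dict)
    eta_map: dict[int, float] = field(default_factory=dict)
    alpha: np.ndarray | None = None
    xi: np.ndarray | None = None
    gamma: np.ndarray | None = None
    eta0: float = DEFAULT_ETA0
    sigma1: float = DEFAULT_SIGMA1
    sigma2: float = DEFAULT_SIGMA2

    def __post_init__(self) -> None:
        if self.sigma1 < 0 or self.sigma2 < 0:
            raise ValueError("residual SDs must be nonnegative")
        if self.alpha is not None:
            self.alpha = np.asarray(self.alpha, dtype=float)
        if self.xi is not None:
            self.xi = np.asarray(self.xi, dtype=float)
        if self.gamma is not None:
            self.gamma = np.asarray(self.gamma, dtype=float)


def default_blueprint(K: int, spread: float = 4.0) -> ClusterBlueprint:
    """Well-separated endpoint-pair centers on a Fibonacci sphere (r=60mm).

    2K points are placed quasi-uniformly on the sphere; cluster k pairs
    point k with point k+K, giving inter-cluster endpoint separations far
    larger than the default 4 mm spread.
    """
    m = 2 * K
    i = np.arange(m)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - (2.0 * i + 1.0) / m
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    theta = golden * i
    pts = 60.0 * np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    centers = np.stack([pts[:K], pts[K:]], axis=1)
    return ClusterBlueprint(
        K_true=K,
        centers=centers,
        spread=spread,
        baseline_props=np.full(K, 1.0 / K),
    )


def gen_genotypes(
    n_subjects: int,
    n_snps: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    missing_rate: float = 0.0,
    seed: int = 0,
    mafs: np.ndarray | None = None,
) -> GenotypeMatrix:
    """Hardy-Weinberg genotypes: dosage ~ Binomial(2, maf) per SNP.

    MAFs are drawn uniformly in ``maf_range`` unless given explicitly;
    missingness is applied independently per entry.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must lie in [0, 1)")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    rng = np.random.default_rng(seed)
    if mafs is None:
        mafs = rng.uniform(lo, hi, n_snps)
    else:
        mafs = np.asarray(mafs, dtype=float)
        if mafs.shape != (n_snps,):
            raise ValueError("mafs must have length n_snps")
    d = rng.binomial(2, mafs[None, :], size=(n_subjects, n_snps)).astype(float)
    if missing_rate > 0:
        d[rng.random((n_subjects, n_snps)) < missing_rate] = np.nan
    return GenotypeMatrix(
        d,
        snp_ids=[f"snp{j:05d}" for j in range(n_snps)],
        subject_ids=[f"sub{i:05d}" for i in range(n_subjects)],
    )


def gen_subjects(
    n_subjects: int,
    seed: int = 0,
    age_range: tuple[int, int] = (22, 36),
    sibling_pair_fraction: float = 0.0,
) -> pd.DataFrame:
    """Covariate table: age, sex, and family ids with optional sibling pairs.

    ``floor(sibling_pair_fraction * n / 2)`` families of size two are
    created; the remaining subjects are singletons.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if not 0 <= sibling_pair_fraction <= 1:
        raise ValueError("sibling_pair_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    age = rng.integers(age_range[0], age_range[1] + 1, n_subjects)
    sex = rng.integers(0, 2, n_subjects)
    n_pairs = int(sibling_pair_fraction * n_subjects / 2)
    family = []
    for i in range(n_subjects):
        if i < 2 * n_pairs:
            family.append(f"fam{i // 2:05d}")
        else:
            family.append(f"fam{n_pairs + (i - 2 * n_pairs):05d}")
    return pd.DataFrame(
        {
            "subject_id": [f"sub{i:05d}" for i in range(n_subjects)],
            "family_id": family,
            "age": age,
            "sex": sex,
        }
    )


def _imputed_dosages(G: GenotypeMatrix) -> np.ndarray:
    X = G.dosages.copy()
    if np.isnan(X).any():
        mean = np.nanmean(X, axis=0)
        r, c = np.nonzero(np.isnan(X))
        X[r, c] = mean[c]
    return X


def _covariate_design(covariates: pd.DataFrame) -> np.ndarray:
    return covariates[["age", "sex"]].to_numpy(dtype=float)


def gen_proportions(
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame,
    blueprint: ClusterBlueprint,
    effects: EffectSpec,
    seed: int = 0,
) -> ConnectomeMatrix:
    """Cluster proportions from the linear screen model, mapped to the simplex.

    ``u_ik = baseline_k + x_ig beta_k + Z_i gamma_k + N(0, sigma1^2)`` is
    clipped at 1e-6 and the row renormalized.  A row whose every entry hits
    the floor (pathological sigma1) raises :class:`DegenerateSimplexError`.
    """
    K = blueprint.K_true
    for (g, k) in effects.beta_map:
        if not (0 <= k < K):
            raise ValueError(f"beta_map cluster index {k} out of range [0, {K})")
        if not (0 <= g < genotypes.n_snps):
            raise ValueError(f"beta_map SNP index {g} out of range")
    rng = np.random.default_rng(seed)
    n = genotypes.n_subjects
    X = _imputed_dosages(genotypes)
    u = np.tile(blueprint.baseline_props, (n, 1))
    for (g, k), b in effects.beta_map.items():
        u[:, k] += X[:, g] * b
    if effects.gamma is not None:
        u += _covariate_design(covariates) @ effects.gamma
    if effects.sigma1 > 0:
        u += rng.normal(0.0, effects.sigma1, size=(n, K))
    clipped = u < CLIP_FLOOR
    u[clipped] = CLIP_FLOOR
    all_floor = clipped.all(axis=1)
    if all_floor.any():
        raise DegenerateSimplexError(
            f"{int(all_floor.sum())} subject row(s) collapsed onto the clip floor; "
            "sigma1 is too large for the baseline proportions"
        )
    u /= u.sum(axis=1, keepdims=True)
    return ConnectomeMatrix(u, list(genotypes.subject_ids))


def gen_streamlines(
    proportions: ConnectomeMatrix,
    blueprint: ClusterBlueprint,
    fibers_per_subject: int = 200,
    seed: int = 0,
) -> list[FiberSet]:
    """Per-subject tractograms around the blueprint cluster centers.

    Cluster counts are Multinomial(m_i, omega_i); each fiber's endpoints
    are Gaussian around the cluster's center pair, with 4-60 points
    linearly interpolated in between to emulate raw tractography sampling.
    """
    if fibers_per_subject < 1:
        raise ValueError("fibers_per_subject must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for i, sid in enumerate(proportions.subject_ids):
        counts = rng.multinomial(fibers_per_subject, proportions.weights[i])
        fibers = []
        for k, c in enumerate(counts):
            if c == 0:
                continue
            a = blueprint.centers[k, 0] + rng.normal(0, blueprint.spread[k], (c, 3))
            b = blueprint.centers[k, 1] + rng.normal(0, blueprint.spread[k], (c, 3))
            npts = rng.integers(4, 61, c)
            for j in range(c):
                t = np.linspace(0.0, 1.0, npts[j])[:, None]
                fibers.append(a[j] * (1 - t) + b[j] * t)
        out.append(FiberSet(sid, fibers))
    return out


def gen_traits(
    genotypes: GenotypeMatrix,
    proportions: ConnectomeMatrix,
    covariates: pd.DataFrame,
    effects: EffectSpec,
    seed: int = 0,
    trait_name: str = "cogscore",
) -> pd.DataFrame:
    """Traits from the outcome model, summing direct effects over eta_map."""
    rng = np.random.default_rng(seed)
    n = genotypes.n_subjects
    X = _imputed_dosages(genotypes)
    y = np.full(n, effects.eta0, dtype=float)
    for g, eta in effects.eta_map.items():
        y += X[:, g] * eta
    if effects.alpha is not None:
        if effects.alpha.shape != (proportions.K,):
            raise ValueError("alpha must have length K")
        y += proportions.weights @ effects.alpha
    if effects.xi is not None:
        y += _covariate_design(covariates) @ effects.xi
    if effects.sigma2 > 0:
        y += rng.normal(0.0, effects.sigma2, n)
    return pd.DataFrame({"subject_id": genotypes.subject_ids, trait_name: y})


@dataclass
class ScenarioBundle:
    """Everything a downstream stage needs, plus the planted ground truth."""

    name: str
    genotypes: GenotypeMatrix
    covariates: pd.DataFrame
    proportions: ConnectomeMatrix
    traits: pd.DataFrame
    fiber_sets: list[FiberSet] | None
    blueprint: ClusterBlueprint
    effects: EffectSpec
    planted_snp: int
    planted_cluster: int

    @property
    def planted_snp_id(self) -> str:
        return self.genotypes.snp_ids[self.planted_snp]

    @property
    def planted_eta(self) -> float:
        return self.effects.eta_map.get(self.planted_snp, 0.0)

    @property
    def planted_beta(self) -> float:
        return self.effects.beta_map.get((self.planted_snp, self.planted_cluster), 0.0)

    @property
    def planted_alpha(self) -> float:
        if self.effects.alpha is None:
            return 0.0
        return float(self.effects.alpha[self.planted_cluster])

    @property
    def planted_aie(self) -> float:
        return self.planted_alpha * self.planted_beta


def scenario(
    name: str,
    n_subjects: int,
    seed: int = 0,
    n_snps: int = 500,
    K: int = 10,
    fibers_per_subject: int = 0,
    maf_range: tuple[float, float] = (0.05, 0.5),
    missing_rate: float = 0.0,
    sibling_pair_fraction: float = 0.0,
    beta: float = DEFAULT_BETA,
    eta: float = DEFAULT_ETA,
    alpha: float = DEFAULT_ALPHA,
) -> ScenarioBundle:
    """One of the four canonical mediation truth states, fully generated.

    ``null``: no effects anywhere.  ``direct_only``: direct trait effect
    eta, no mediator effect (alpha = 0; the SNP still shifts proportions so
    the screen can find it).  ``indirect_only``: eta = 0 with a live
    genotype -> cluster -> trait path.  ``full_mediation``: both.  The SNP
    and cluster carrying the planted effects are index 0; the planted SNP's
    MAF is fixed at 0.3 so the study's power is reproducible.  Set
    ``fibers_per_subject > 0`` to also generate streamlines.

    A single master seed is split into independent per-stage child seeds,
    so any one stage can be regenerated on its own.
    """
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    children = np.random.SeedSequence(seed).spawn(6)
    child = [int(c.generate_state(1, np.uint32)[0]) for c in children]

    g_star, k_star = 0, 0
    rng_maf = np.random.default_rng(child[0])
    mafs = rng_maf.uniform(maf_range[0], maf_range[1], n_snps)
    mafs[g_star] = PLANTED_MAF

    b = 0.0 if name == "null" else beta
    e = eta if name in ("direct_only", "full_mediation") else 0.0
    a = alpha if name in ("indirect_only", "full_mediation") else 0.0

    beta_map: dict[tuple[int, int], float] = {}
    if b != 0.0:
        # compositional planting: mass moved into k_star is drawn evenly
        # from the other clusters, so the row-sum (and hence the simplex
        # renormalization) is unaffected by dosage
        beta_map[(g_star, k_star)] = b
        for k in range(K):
            if k != k_star:
                beta_map[(g_star, k)] = -b / (K - 1)
    alpha_vec = np.zeros(K)
    alpha_vec[k_star] = a
    effects = EffectSpec(
        beta_map=beta_map,
        eta_map={g_star: e} if e != 0.0 else {},
        alpha=alpha_vec,
        xi=np.asarray(DEFAULT_XI),
    )

    blueprint = default_blueprint(K)
    genotypes = gen_genotypes(
        n_subjects, n_snps, maf_range, missing_rate, seed=child[1], mafs=mafs
    )
    covariates = gen_subjects(
        n_subjects, seed=child[2], sibling_pair_fraction=sibling_pair_fraction
    )
    proportions = gen_proportions(genotypes, covariates, blueprint, effects, seed=child[3])
    traits = gen_traits(genotypes, proportions, covariates, effects, seed=child[4])
    fiber_sets = None
    if fibers_per_subject > 0:
        fiber_sets = gen_streamlines(
            proportions, blueprint, fibers_per_subject, seed=child[5]
        )
    return ScenarioBundle(
        name=name,
        genotypes=genotypes,
        covariates=covariates,
        proportions=proportions,
        traits=traits,
        fiber_sets=fiber_sets,
        blueprint=blueprint,
        effects=effects,
        planted_snp=g_star,
        planted_cluster=k_star,
    )
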