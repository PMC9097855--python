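"""Orchestration of the four stages plus the robustness utilities.

The pipeline runs synth (optional) -> connectome -> genetics -> mediation,
writing every intermediate artifact and a run log, fully reproducible from
one flat config file plus a master seed.  Robustness utilities mirror the
study's checks: a split-half refit of the outcome model and
one-subject-per-family subsampling (which also realizes keep-one-MZ-twin
when MZ pairs are labeled as families).
"""

from __future__ import annotations

import dataclasses
import datetime
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import connectome as conn
from . import genetics as gen
from . import io as cio
from . import mediation as med
from . import synth

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "RunLog",
    "PipelineResult",
    "run_pipeline",
    "split_half_validation",
    "subsample_one_per_family",
]


@dataclass
class RunConfig:
    """Flat, serializable configuration of one pipeline run."""

    # data source: either a synth scenario or input paths
    scenario: str | None = "full_mediation"
    n_subjects: int = 870
    n_snps: int = 500
    fibers_per_subject: int = 0
    endpoints_path: str | None = None
    genotypes_path: str | None = None
    covariates_path: str | None = None
    traits_path: str | None = None
    # connectome
    K: int = 10
    batch_size: int = 1024
    n_iter: int = 200
    use_true_proportions: bool = True
    # genetics
    max_subject_missing: float = 0.10
    max_variant_missing: float = 0.10
    hwe_alpha: float = 1e-7
    n_pcs: int = 2
    fdr_q: float = 0.05
    ld_r2_max: float = 0.1
    # mediation
    alpha_level: float = 0.05
    n_boot: int = 500
    # bookkeeping
    seed: int = 0
    out_dir: str | None = None

    def to_file(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        data = yaml.safe_load(path.read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class RunLog:
    """One record per executed stage: parameters, counts, warnings."""

    records: list[dict] = field(default_factory=list)

    def add(self, stage: str, params: dict, counts: dict, warnings: list[str] | None = None) -> None:
        self.records.append(
            {
                "stage": stage,
                "timestamp": datetime.datetime.now().isoformat(timespec="seconds"),
                "params": params,
                "counts": counts,
                "warnings": warnings or [],
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)


@dataclass
class PipelineResult:
    omega: conn.ConnectomeMatrix
    assoc: pd.DataFrame
    active_map: dict[str, list[int]]
    mediation: pd.DataFrame
    lead: list[str]
    runlog: RunLog
    genotypes: gen.GenotypeMatrix
    covariates_used: pd.DataFrame
    traits: pd.DataFrame


def _load_inputs(config: RunConfig):
    if config.scenario is not None:
        bundle = synth.scenario(
            config.scenario,
            n_subjects=config.n_subjects,
            seed=config.seed,
            n_snps=config.n_snps,
            K=config.K,
            fibers_per_subject=config.fibers_per_subject,
        )
        return bundle.genotypes, bundle.covariates, bundle.traits, bundle.fiber_sets, bundle.proportions
    for name, p in (
        ("genotypes", config.genotypes_path),
        ("covariates", config.covariates_path),
        ("traits", config.traits_path),
    ):
        if p is None:
            raise ValueError(f"no scenario and no {name} path configured")
        if not Path(p).exists():
            raise FileNotFoundError(f"{name} file not found: {p}")
    gp = Path(config.genotypes_path)
    if gp.suffix == ".bed" or gp.with_suffix(".bed").exists() and gp.suffix == "":
        G = cio.read_plink_bed(gp.with_suffix(""))
    elif gp.suffix == ".bed":
        G = cio.read_plink_bed(gp.with_suffix(""))
    else:
        G = cio.read_genotypes_raw(gp)
    cov = cio.read_table_tsv(config.covariates_path)
    traits = cio.read_table_tsv(config.traits_path)
    fiber_sets = None
    if config.endpoints_path is not None:
        fiber_sets = cio.read_endpoints_tsv(config.endpoints_path)
    return G, cov, traits, fiber_sets, None


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute all stages; write artifacts when ``config.out_dir`` is set.

    Stage failures abort with the run log flushed to disk first.
    """
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
        config.to_file(out / "config.yaml")
    log = RunLog()
    try:
        result = _run_stages(config, log, out)
    finally:
        if out:
            log.to_frame().to_json(out / "runlog.json", orient="records", indent=1)
    return result


def _run_stages(config: RunConfig, log: RunLog, out: Path | None) -> PipelineResult:
    G, cov, traits, fiber_sets, true_props = _load_inputs(config)
    log.add(
        "data",
        {"scenario": config.scenario, "seed": config.seed},
        {"n_subjects": G.n_subjects, "n_snps": G.n_snps},
    )

    # connectome stage
    if fiber_sets is not None and not (config.use_true_proportions and true_props is not None):
        C = conn.pool_fibers(fiber_sets)
        model = conn.fit_clusters(
            C, config.K, batch_size=config.batch_size, n_iter=config.n_iter, seed=config.seed
        )
        labels = conn.assign(model, C)
        omega = conn.connectome_weights(labels, C.subject_index, config.K)
        if out:
            cio.write_cluster_model(model, out / "cluster_model.json")
    elif true_props is not None:
        omega = true_props
    elif fiber_sets is not None:
        C = conn.pool_fibers(fiber_sets)
        model = conn.fit_clusters(
            C, config.K, batch_size=config.batch_size, n_iter=config.n_iter, seed=config.seed
        )
        labels = conn.assign(model, C)
        omega = conn.connectome_weights(labels, C.subject_index, config.K)
    else:
        raise ValueError("no streamlines and no proportion source available")
    log.add(
        "connectome",
        {"K": config.K, "batch_size": config.batch_size, "n_iter": config.n_iter},
        {"n_subjects": omega.n_subjects, "K": omega.K},
    )
    if out:
        cio.write_omega_tsv(omega, out / "omega.tsv")

    # genetics stage: align subjects, recode, QC, PCs, screen
    common = [s for s in omega.subject_ids if s in set(G.subject_ids)]
    subj_mask = np.isin(np.asarray(G.subject_ids), common)
    G = G.subset(subj_mask=subj_mask)
    order = {s: i for i, s in enumerate(omega.subject_ids)}
    G_order = np.argsort([order[s] for s in G.subject_ids], kind="stable")
    G = gen.GenotypeMatrix(
        G.dosages[G_order],
        G.snp_ids,
        [G.subject_ids[i] for i in G_order],
        G.minor_alleles,
        G.major_alleles,
    )
    G = gen.recode_minor_allele(G)
    G, qc_report = gen.qc_filter(
        G,
        max_subject_missing=config.max_subject_missing,
        max_variant_missing=config.max_variant_missing,
        hwe_alpha=config.hwe_alpha,
    )
    keep = np.isin(np.asarray(omega.subject_ids), G.subject_ids)
    omega = conn.ConnectomeMatrix(
        omega.weights[keep], [s for s, k in zip(omega.subject_ids, keep) if k]
    )
    Z = gen.make_covariate_table(cov, G, n_pcs=config.n_pcs)
    assoc = gen.cluster_gwas(omega, G, Z)
    assoc = gen.fdr_select(assoc, q=config.fdr_q)
    active_map = gen.active_sets(assoc)
    lead: list[str] = []
    if active_map:
        lead = gen.lead_snps(assoc, G, r2_max=config.ld_r2_max)
    log.add(
        "genetics",
        {
            "max_subject_missing": config.max_subject_missing,
            "max_variant_missing": config.max_variant_missing,
            "hwe_alpha": config.hwe_alpha,
            "n_pcs": config.n_pcs,
            "fdr_q": config.fdr_q,
            "ld_r2_max": config.ld_r2_max,
        },
        {
            "n_snps_post_qc": G.n_snps,
            "n_selected_pairs": int(assoc["selected"].sum()),
            "n_active_snps": len(active_map),
            "n_lead_snps": len(lead),
        },
        warnings=[str(qc_report)],
    )
    if out:
        cio.write_table_tsv(assoc, out / "cluster_assoc.tsv")
        (out / "qc_report.txt").write_text(str(qc_report) + "\n")
        pd.DataFrame(
            [(s, ";".join(map(str, ks))) for s, ks in sorted(active_map.items())],
            columns=["snp", "clusters"],
        ).to_csv(out / "active_sets.tsv", sep="\t", index=False)

    # mediation stage
    traits_aligned = traits.set_index("subject_id").loc[omega.subject_ids].reset_index()
    mediation = med.mediate_all(
        active_map, assoc, omega, G, Z, traits_aligned,
        level=config.alpha_level, q=config.fdr_q,
    )
    log.add(
        "mediation",
        {"alpha_level": config.alpha_level, "fdr_q": config.fdr_q},
        {"n_pairs": len(mediation)},
    )
    if out:
        cio.write_table_tsv(mediation, out / "mediation.tsv")
    return PipelineResult(
        omega=omega,
        assoc=assoc,
        active_map=active_map,
        mediation=mediation,
        lead=lead,
        runlog=log,
        genotypes=G,
        covariates_used=Z,
        traits=traits_aligned,
    )


def split_half_validation(
    omega,
    G,
    Z: pd.DataFrame,
    traits: pd.DataFrame,
    active_map: dict[str, list[int]],
    seed: int = 0,
    level: float = 0.05,
):
    """Random equal split; both model layers refit per half per selected SNP.

    Returns the two per-half mediation tables and a concordance report
    listing SNPs whose direct (resp. indirect) effect is significant in
    both halves.
    """
    n = omega.n_subjects
    if n < 4:
        raise ValueError("split-half validation needs at least 4 subjects")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    halves = [np.sort(perm[: n // 2]), np.sort(perm[n // 2 :])]
    tables = []
    for idx in halves:
        W = conn.ConnectomeMatrix(
            omega.weights[idx], [omega.subject_ids[i] for i in idx]
        )
        Gh = G.subset(subj_mask=np.isin(np.arange(n), idx))
        Zh = Z.iloc[idx].reset_index(drop=True)
        th = traits.iloc[idx].reset_index(drop=True)
        assoc_h = gen.cluster_gwas(W, Gh, Zh)
        tables.append(
            med.mediate_all(active_map, assoc_h, W, Gh, Zh, th, level=level)
        )
    t1, t2 = tables
    concordant_direct, concordant_indirect = [], []
    for (trait, snp), row1 in t1.set_index(["trait", "snp"]).iterrows():
        if (trait, snp) not in t2.set_index(["trait", "snp"]).index:
            continue
        row2 = t2.set_index(["trait", "snp"]).loc[(trait, snp)]
        lab1, lab2 = row1["case_label"], row2["case_label"]
        if {lab1, lab2} <= {"both", "direct_only"}:
            concordant_direct.append((trait, snp))
        if {lab1, lab2} <= {"both", "indirect_only"}:
            concordant_indirect.append((trait, snp))
    report = {
        "concordant_direct": concordant_direct,
        "concordant_indirect": concordant_indirect,
        "seed": seed,
    }
    return t1, t2, report


def subsample_one_per_family(covariates: pd.DataFrame, seed: int = 0) -> list[str]:
    """Keep exactly one uniformly chosen subject per family id."""
    if "family_id" not in covariates.columns:
        raise ValueError("covariate table has no family_id column")
    rng = np.random.default_rng(seed)
    kept = []
    for _, grp in covariates.groupby("family_id", sort=True):
        ids = list(grp["subject_id"])
        kept.append(ids[rng.integers(len(ids))] if len(ids) > 1 else ids[0])
    order = {s: i for i, s in enumerate(covariates["subject_id"])}
    return sorted(kept, key=order.__getitem__)
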