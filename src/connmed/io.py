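"""Readers and writers for the pipeline's on-disk artifacts.

Streamlines: TRK/TCK (via nibabel) or a plain-text endpoints table (one
row per fiber: subject_id, x1 y1 z1 x2 y2 z2).  Genotypes: PLINK
.raw-style TSV or a .bed/.bim/.fam triplet.  Matrices and tables: TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import nibabel as nib

from .connectome import ClusterModel, ConnectomeMatrix, FiberSet
from .genetics import GenotypeMatrix

__all__ = [
    "write_endpoints_tsv",
    "read_endpoints_tsv",
    "write_tractogram",
    "read_tractogram",
    "write_genotypes_raw",
    "read_genotypes_raw",
    "write_plink_bed",
    "read_plink_bed",
    "write_omega_tsv",
    "read_omega_tsv",
    "write_table_tsv",
    "read_table_tsv",
    "write_cluster_model",
    "read_cluster_model",
]


# ---------------------------------------------------------------- streamlines

def write_endpoints_tsv(fiber_sets: list[FiberSet], path) -> None:
    rows = []
    for fs in fiber_sets:
        for f in fs.fibers:
            rows.append([fs.subject_id, *f[0], *f[-1]])
    df = pd.DataFrame(rows, columns=["subject_id", "x1", "y1", "z1", "x2", "y2", "z2"])
    df.to_csv(path, sep="\t", index=False)


def read_endpoints_tsv(path) -> list[FiberSet]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"endpoints file not found: {path}")
    df = pd.read_csv(path, sep="\t")
    need = {"subject_id", "x1", "y1", "z1", "x2", "y2", "z2"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: missing endpoint columns {sorted(need - set(df.columns))}")
    out = []
    for sid, grp in df.groupby("subject_id", sort=False):
        a = grp[["x1", "y1", "z1"]].to_numpy(float)
        b = grp[["x2", "y2", "z2"]].to_numpy(float)
        out.append(FiberSet(str(sid), [np.vstack([a[j], b[j]]) for j in range(len(grp))]))
    return out


def write_tractogram(fiber_set: FiberSet, path) -> None:
    """Write one subject's streamlines as TRK or TCK (by extension)."""
    tg = nib.streamlines.Tractogram(fiber_set.fibers, affine_to_rasmm=np.eye(4))
    nib.streamlines.save(tg, str(path))


def read_tractogram(path, subject_id: str | None = None) -> FiberSet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"tractogram not found: {path}")
    tf = nib.streamlines.load(str(path))
    sid = subject_id if subject_id is not None else path.stem
    return FiberSet(sid, [np.asarray(s, dtype=float) for s in tf.streamlines])


# ------------------------------------------------------------------ genotypes

def write_genotypes_raw(G: GenotypeMatrix, path) -> None:
    """PLINK .raw-style TSV: FID IID then one dosage column per SNP."""
    cols = {"FID": G.subject_ids, "IID": G.subject_ids}
    for j, snp in enumerate(G.snp_ids):
        cols[f"{snp}_{G.minor_alleles[j]}"] = G.dosages[:, j]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_genotypes_raw(path) -> GenotypeMatrix:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"genotype file not found: {path}")
    df = pd.read_csv(path, sep="\t", na_values="NA")
    if "IID" not in df.columns:
        raise ValueError(f"{path}: not a .raw-style file (no IID column)")
    snp_cols = [c for c in df.columns if c not in ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")]
    snp_ids, minors = [], []
    for c in snp_cols:
        if "_" in c:
            name, allele = c.rsplit("_", 1)
        else:
            name, allele = c, "A"
        snp_ids.append(name)
        minors.append(allele)
    return GenotypeMatrix(
        df[snp_cols].to_numpy(dtype=float),
        snp_ids=snp_ids,
        subject_ids=[str(s) for s in df["IID"]],
        minor_alleles=minors,
    )


_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# PLINK 2-bit codes, dosage of allele A1: 00 -> 2, 10 -> 1, 11 -> 0, 01 -> missing
_BED_CODE_TO_DOSAGE = {0b00: 2.0, 0b10: 1.0, 0b11: 0.0, 0b01: np.nan}
_DOSAGE_TO_CODE = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}


def write_plink_bed(G: GenotypeMatrix, prefix) -> None:
    """Write a SNP-major .bed/.bim/.fam triplet (A1 = counted allele)."""
    prefix = Path(prefix)
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for j, snp in enumerate(G.snp_ids):
            fh.write(f"1\t{snp}\t0\t{j + 1}\t{G.minor_alleles[j]}\t{G.major_alleles[j]}\n")
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for sid in G.subject_ids:
            fh.write(f"{sid}\t{sid}\t0\t0\t0\t-9\n")
    n = G.n_subjects
    nbytes = (n + 3) // 4
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        for j in range(G.n_snps):
            row = bytearray(nbytes)
            for i in range(n):
                v = G.dosages[i, j]
                code = 0b01 if np.isnan(v) else _DOSAGE_TO_CODE[float(v)]
                row[i // 4] |= code << (2 * (i % 4))
            fh.write(bytes(row))


def read_plink_bed(prefix) -> GenotypeMatrix:
    prefix = Path(prefix)
    bim_path, fam_path, bed_path = (
        prefix.with_suffix(".bim"),
        prefix.with_suffix(".fam"),
        prefix.with_suffix(".bed"),
    )
    for p in (bim_path, fam_path, bed_path):
        if not p.exists():
            raise FileNotFoundError(f"PLINK file not found: {p}")
    snp_ids, a1, a2 = [], [], []
    with open(bim_path) as fh:
        for rec, line in enumerate(fh):
            fields = line.split()
            if len(fields) < 6:
                raise ValueError(f"{bim_path}: truncated record {rec} ({len(fields)} fields, need 6)")
            snp_ids.append(fields[1])
            a1.append(fields[4])
            a2.append(fields[5])
    subject_ids = []
    with open(fam_path) as fh:
        for rec, line in enumerate(fh):
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{fam_path}: truncated record {rec}")
            subject_ids.append(fields[1])
    n, g = len(subject_ids), len(snp_ids)
    nbytes = (n + 3) // 4
    raw = bed_path.read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise ValueError(f"{bed_path}: bad magic bytes (not a SNP-major .bed file)")
    expected = 3 + nbytes * g
    if len(raw) != expected:
        raise ValueError(f"{bed_path}: size {len(raw)} != expected {expected} for {n} subjects x {g} SNPs")
    data = np.frombuffer(raw[3:], dtype=np.uint8).reshape(g, nbytes)
    dosages = np.empty((n, g))
    shifts = 2 * (np.arange(n) % 4)
    byte_idx = np.arange(n) // 4
    codes = (data[:, byte_idx] >> shifts[None, :]) & 0b11
    lut = np.array([2.0, np.nan, 1.0, 0.0])
    dosages = lut[codes].T
    return GenotypeMatrix(dosages, snp_ids, subject_ids, a1, a2)


# ----------------------------------------------------------- tables & models

def write_omega_tsv(omega: ConnectomeMatrix, path) -> None:
    df = pd.DataFrame(
        omega.weights, columns=[f"w{k + 1}" for k in range(omega.K)]
    )
    df.insert(0, "subject_id", omega.subject_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_omega_tsv(path) -> ConnectomeMatrix:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"connectome file not found: {path}")
    df = pd.read_csv(path, sep="\t")
    wcols = [c for c in df.columns if c.startswith("w")]
    W = df[wcols].to_numpy(float)
    W = W / W.sum(axis=1, keepdims=True)  # absorb decimal round-trip error
    return ConnectomeMatrix(W, [str(s) for s in df["subject_id"]])


def write_table_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_table_tsv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"table not found: {path}")
    return pd.read_csv(path, sep="\t")


def write_cluster_model(model: ClusterModel, path) -> None:
    payload = {
        "K": model.K,
        "centroids": model.centroids.tolist(),
        "batch_size": model.batch_size,
        "n_iter": model.n_iter,
        "seed": model.seed,
        "inertia": model.inertia,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_cluster_model(path) -> ClusterModel:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cluster model not found: {path}")
    payload = json.loads(path.read_text())
    return ClusterModel(
        K=payload["K"],
        centroids=np.asarray(payload["centroids"]),
        batch_size=payload["batch_size"],
        n_iter=payload["n_iter"],
        seed=payload["seed"],
        inertia=payload["inertia"],
    )
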