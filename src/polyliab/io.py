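"""Genotype container plus PLINK .bed/.bim/.fam and TSV-dosage I/O.

The in-memory representation is a subjects x variants additive dosage
matrix (dosage counts the A1 allele, 0/1/2, NaN = missing) with a variant
metadata table and optional per-subject ancestry-cluster labels.

The binary PLINK codec is the standard SNP-major 2-bit encoding
(magic ``6c 1b 01``; 00 = hom A1, 01 = missing, 10 = het, 11 = hom A2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ["id", "chrom", "pos", "allele1", "allele2"]

_PLINK_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit code -> dosage of allele1; 1 (binary 01) is the missing code
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


@dataclass
class GenotypeMatrix:
    """Subjects x variants additive dosage matrix with metadata."""

    dosages: np.ndarray  # float array, n_subjects x m_variants, NaN = missing
    subject_ids: np.ndarray
    variants: pd.DataFrame  # columns: id, chrom, pos, allele1, allele2
    clusters: np.ndarray | None = None  # per-subject cluster labels

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.subject_ids = np.asarray(self.subject_ids).astype(str)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (subjects x variants)")
        if self.dosages.shape[0] != len(self.subject_ids):
            raise ValueError("subject_ids length does not match dosage rows")
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variant table missing columns: {missing}")
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError("variant table length does not match dosage columns")
        if self.clusters is not None:
            self.clusters = np.asarray(self.clusters)
            if len(self.clusters) != len(self.subject_ids):
                raise ValueError("clusters length does not match subjects")

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def m_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def variant_ids(self) -> np.ndarray:
        return self.variants["id"].to_numpy()

    def subset_subjects(self, ids) -> "GenotypeMatrix":
        order = {s: i for i, s in enumerate(self.subject_ids)}
        try:
            idx = np.array([order[str(s)] for s in ids])
        except KeyError as exc:  # pragma: no cover - message only
            raise KeyError(f"unknown subject id {exc}") from exc
        return GenotypeMatrix(
            self.dosages[idx],
            self.subject_ids[idx],
            self.variants.copy(),
            None if self.clusters is None else self.clusters[idx],
        )

    def subset_variants(self, variant_ids) -> "GenotypeMatrix":
        order = {v: i for i, v in enumerate(self.variants["id"])}
        idx = np.array([order[v] for v in variant_ids])
        return GenotypeMatrix(
            self.dosages[:, idx],
            self.subject_ids,
            self.variants.iloc[idx].reset_index(drop=True),
            self.clusters,
        )


# ---------------------------------------------------------------------------
# TSV dosage dialect: variants on rows of a header'd TSV, one column per
# subject, metadata columns first.
# ---------------------------------------------------------------------------

def write_dosage_tsv(geno: GenotypeMatrix, path: str | Path) -> None:
    meta = geno.variants[VARIANT_COLUMNS].copy()
    dose = pd.DataFrame(geno.dosages.T, columns=geno.subject_ids)
    pd.concat([meta.reset_index(drop=True), dose], axis=1).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    table = pd.read_csv(path, sep="\t", na_values=["NA"])
    missing = [c for c in VARIANT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"dosage TSV missing metadata columns: {missing}")
    subject_cols = [c for c in table.columns if c not in VARIANT_COLUMNS]
    variants = table[VARIANT_COLUMNS].copy()
    dosages = table[subject_cols].to_numpy(dtype=float).T
    return GenotypeMatrix(dosages, np.array(subject_cols), variants)


# ---------------------------------------------------------------------------
# PLINK binary triplet
# ---------------------------------------------------------------------------

def write_plink(geno: GenotypeMatrix, prefix: str | Path) -> None:
    prefix = Path(prefix)
    n = geno.n_subjects
    bim = geno.variants.assign(cm=0)[["chrom", "id", "cm", "pos", "allele1", "allele2"]]
    bim.to_csv(Path(str(prefix) + ".bim"), sep="\t", index=False, header=False)
    fam = pd.DataFrame(
        {
            "fid": geno.subject_ids,
            "iid": geno.subject_ids,
            "pat": 0,
            "mat": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(Path(str(prefix) + ".fam"), sep="\t", index=False, header=False)

    dose = geno.dosages
    # map dosage -> 2-bit code: 2 -> 00, missing -> 01, 1 -> 10, 0 -> 11
    codes = np.full(dose.shape, 1, dtype=np.uint8)
    codes[dose == 2] = 0
    codes[dose == 1] = 2
    codes[dose == 0] = 3
    n_bytes = (n + 3) // 4
    padded = np.zeros((dose.shape[1], n_bytes * 4), dtype=np.uint8)
    padded[:, :n] = codes.T
    packed = (
        padded[:, 0::4]
        | (padded[:, 1::4] << 2)
        | (padded[:, 2::4] << 4)
        | (padded[:, 3::4] << 6)
    )
    with open(Path(str(prefix) + ".bed"), "wb") as fh:
        fh.write(_PLINK_MAGIC)
        fh.write(packed.tobytes())


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    prefix = Path(prefix)
    bim = pd.read_csv(
        Path(str(prefix) + ".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos", "allele1", "allele2"],
        dtype={"id": str, "allele1": str, "allele2": str},
    )
    fam = pd.read_csv(Path(str(prefix) + ".fam"), sep=r"\s+", header=None, dtype=str)
    subject_ids = fam[1].to_numpy()
    n, m = len(subject_ids), len(bim)
    raw = np.fromfile(Path(str(prefix) + ".bed"), dtype=np.uint8)
    if bytes(raw[:3]) != _PLINK_MAGIC:
        raise ValueError(f"{prefix}.bed is not a SNP-major PLINK bed file")
    n_bytes = (n + 3) // 4
    body = raw[3:].reshape(m, n_bytes)
    codes = np.empty((m, n_bytes * 4), dtype=np.uint8)
    codes[:, 0::4] = body & 0x03
    codes[:, 1::4] = (body >> 2) & 0x03
    codes[:, 2::4] = (body >> 4) & 0x03
    codes[:, 3::4] = (body >> 6) & 0x03
    dosages = _CODE_TO_DOSAGE[codes[:, :n]].T
    variants = bim[["id", "chrom", "pos", "allele1", "allele2"]].copy()
    return GenotypeMatrix(dosages, subject_ids, variants)


def make_variant_table(m: int, prefix: str = "sim", chrom: int = 1) -> pd.DataFrame:
    """Default variant metadata: ids sim1..simM, chromosome 1, positions 1..M."""
    return pd.DataFrame(
        {
            "id": [f"{prefix}{i + 1}" for i in range(m)],
            "chrom": chrom,
            "pos": np.arange(1, m + 1),
            "allele1": "A",
            "allele2": "B",
        }
    )
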