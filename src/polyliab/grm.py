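"""Cluster-aware allele-frequency estimation and GRM construction.

Allele frequencies are estimated from an unmatched-control pool, never
from the analysis sample, in two layers: raw within-cluster frequencies
and a pooled overall frequency. The final cluster-specific estimate is an
empirical-Bayes beta-binomial posterior mean that shrinks each cluster's
raw frequency toward the pooled frequency, with the prior strength set by
a method-of-moments estimate of the across-cluster divergence.

Three GRM standardizations are built from these frequencies:

* ``CLS``  — genotypes standardized within clusters using the EB
  cluster-specific frequencies (removes structure-induced bias in
  relatedness for subjects outside the dominant cluster);
* ``POP``  — genotypes standardized with the pooled frequencies;
* ``STD``  — the GCTA-default formula on all-sample frequencies, with its
  distinct diagonal estimator.
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import GenotypeMatrix

logger = logging.getLogger(__name__)

MODES = ("CLS", "POP", "STD")
_PRIOR_STRENGTH_FLOOR = 20.0


@dataclass
class FrequencyEstimates:
    """Pool-based allele-frequency estimates, raw and EB-shrunk."""

    variant_ids: np.ndarray
    pooled: np.ndarray  # (m,)
    raw: np.ndarray  # (k, m), NaN where a cluster is absent from the pool
    eb: np.ndarray  # (k, m)
    cluster_labels: np.ndarray  # (k,)
    n_per_cluster: np.ndarray  # diploid subject counts
    prior_strength: float
    fst_hat: float

    def eb_for(self, cluster_label) -> np.ndarray:
        idx = int(np.flatnonzero(self.cluster_labels == cluster_label)[0])
        return self.eb[idx]


@dataclass
class GRM:
    """N x N genomic relationship matrix tagged by standardization mode."""

    matrix: np.ndarray
    mode: str
    m_variants: int
    subject_ids: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.subject_ids = np.asarray(self.subject_ids).astype(str)
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        n = len(self.subject_ids)
        if self.matrix.shape != (n, n):
            raise ValueError("GRM shape does not match subject count")
        if not np.isfinite(self.matrix).all():
            raise ValueError("GRM contains non-finite entries")
        if self.m_variants < 1:
            raise ValueError("GRM must be built from at least one variant")

    def index_of(self, ids) -> np.ndarray:
        order = {s: i for i, s in enumerate(self.subject_ids)}
        return np.array([order[str(s)] for s in ids])

    # -- GCTA binary triplet + TSV -------------------------------------

    def save(self, prefix: str | Path) -> None:
        prefix = str(prefix)
        n = len(self.subject_ids)
        tri = self.matrix[np.tril_indices(n)]
        np.asarray(tri, dtype="<f4").tofile(prefix + ".grm.bin")
        np.full(tri.shape, self.m_variants, dtype="<f4").tofile(prefix + ".grm.N.bin")
        with open(prefix + ".grm.id", "w") as fh:
            for s in self.subject_ids:
                fh.write(f"{s}\t{s}\n")

    @classmethod
    def load(cls, prefix: str | Path, mode: str = "STD") -> "GRM":
        prefix = str(prefix)
        ids = pd.read_csv(prefix + ".grm.id", sep="\t", header=None)[1].astype(str).to_numpy()
        n = len(ids)
        tri = np.fromfile(prefix + ".grm.bin", dtype="<f4").astype(float)
        counts = np.fromfile(prefix + ".grm.N.bin", dtype="<f4")
        mat = np.zeros((n, n))
        mat[np.tril_indices(n)] = tri
        mat = mat + mat.T - np.diag(np.diag(mat))
        return cls(mat, mode, int(round(float(counts[0]))), ids)

    def save_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.matrix, index=self.subject_ids, columns=self.subject_ids).to_csv(
            path, sep="\t", index_label="subject_id"
        )


def _moment_fst(raw: np.ndarray, pooled: np.ndarray, n_per_cluster: np.ndarray) -> float:
    """Weir-Cockerham-style moment estimate of across-cluster divergence.

    Ratio-of-sums estimator: the across-cluster variance of raw
    frequencies, minus its expected binomial sampling contribution,
    relative to pooled p(1-p).
    """
    ok = np.isfinite(raw).all(axis=0)
    raw, pooled = raw[:, ok], pooled[ok]
    k = raw.shape[0]
    if k < 2 or raw.shape[1] == 0:
        return 0.0
    s2 = raw.var(axis=0, ddof=1)
    sampling = (pooled * (1 - pooled) * np.mean(1.0 / (2.0 * n_per_cluster)))
    num = np.sum(s2 - sampling)
    den = np.sum(pooled * (1 - pooled))
    return float(np.clip(num / den, 0.0, 0.5)) if den > 0 else 0.0


def estimate_frequencies(
    pool: GenotypeMatrix,
    clusters: np.ndarray | None = None,
    prior_strength: float | None = None,
) -> FrequencyEstimates:
    """Pooled, raw per-cluster and EB-shrunk cluster allele frequencies.

    EB shrinkage is the beta-binomial posterior mean
    ``p_k = (c_k + m * p_bar) / (2 n_k + m)`` with ``c_k`` the cluster
    allele count, ``p_bar`` the pooled frequency and prior strength
    ``m = (1 - F) / F`` from the moment estimate of divergence, floored at
    20 (overridable via ``prior_strength``). Estimates are clamped away
    from 0/1 by one pool allele count.
    """
    if pool.n_subjects == 0:
        raise ValueError("frequency-estimation pool is empty")
    clusters = pool.clusters if clusters is None else np.asarray(clusters)
    if clusters is None:
        clusters = np.zeros(pool.n_subjects, dtype=int)
    dose = pool.dosages
    all_missing = np.all(np.isnan(dose), axis=0)
    if all_missing.any():
        bad = pool.variant_ids[all_missing]
        raise ValueError(f"variants missing in every pool subject: {list(bad[:10])}")
    pooled = np.nanmean(dose, axis=0) / 2.0
    labels = np.unique(clusters)
    k, m = len(labels), pool.m_variants
    raw = np.full((k, m), np.nan)
    counts = np.zeros((k, m))
    n_k = np.zeros(k)
    for i, lab in enumerate(labels):
        rows = clusters == lab
        n_k[i] = rows.sum()
        sub = dose[rows]
        denom = 2.0 * np.sum(~np.isnan(sub), axis=0)
        counts[i] = np.nansum(sub, axis=0)
        with np.errstate(invalid="ignore"):
            raw[i] = np.where(denom > 0, counts[i] / np.maximum(denom, 1), np.nan)
    fst_hat = _moment_fst(raw, pooled, n_k)
    if prior_strength is not None:
        prior = float(prior_strength)
    else:
        prior = (1.0 - fst_hat) / fst_hat if fst_hat > 0 else np.inf
        prior = max(min(prior, 1e12), _PRIOR_STRENGTH_FLOOR)
    eb = np.empty_like(raw)
    for i in range(k):
        eb[i] = (counts[i] + prior * pooled) / (2.0 * n_k[i] + prior)
        absent = ~np.isfinite(raw[i])
        if absent.any():
            logger.warning(
                "cluster %s missing pool data for %d variants; falling back to pooled frequency",
                labels[i], int(absent.sum()),
            )
            eb[i, absent] = pooled[absent]
    n_pool = pool.n_subjects
    lo = 1.0 / (2.0 * n_pool + 2.0)
    eb = np.clip(eb, lo, 1.0 - lo)
    pooled_c = np.clip(pooled, lo, 1.0 - lo)
    return FrequencyEstimates(
        variant_ids=pool.variant_ids.copy(),
        pooled=pooled_c,
        raw=raw,
        eb=eb,
        cluster_labels=labels,
        n_per_cluster=n_k,
        prior_strength=float(prior),
        fst_hat=fst_hat,
    )


def polymorphic_mask(freqs: FrequencyEstimates, pool: GenotypeMatrix) -> np.ndarray:
    """Variants polymorphic in the pool (raw pooled frequency in (0,1))."""
    raw_pooled = np.nanmean(pool.dosages, axis=0) / 2.0
    mask = (raw_pooled > 0) & (raw_pooled < 1)
    dropped = int((~mask).sum())
    if dropped:
        logger.info("excluding %d monomorphic-in-pool variants from GRM", dropped)
    return mask


def standardize_genotypes(
    genotypes: GenotypeMatrix,
    freqs: FrequencyEstimates,
    mode: str,
    clusters: np.ndarray | None = None,
) -> np.ndarray:
    """Standardize dosages as (x - 2p)/sqrt(2p(1-p)).

    ``mode='CLS'`` uses the EB cluster-specific frequency of each
    subject's cluster; ``mode='POP'`` the pooled frequency. Missing
    dosages are mean-imputed to 2p (and hence standardize to 0).
    """
    if mode not in ("CLS", "POP"):
        raise ValueError(f"mode must be 'CLS' or 'POP', got {mode!r}")
    if not np.array_equal(freqs.variant_ids, genotypes.variant_ids):
        raise ValueError("frequency estimates do not match the genotype variant set")
    dose = genotypes.dosages
    if mode == "POP":
        p = np.broadcast_to(freqs.pooled, dose.shape)
    else:
        clusters = genotypes.clusters if clusters is None else np.asarray(clusters)
        if clusters is None:
            raise ValueError("CLS standardization requires cluster labels")
        p = np.empty_like(dose)
        for lab in np.unique(clusters):
            rows = clusters == lab
            p[rows] = freqs.eb_for(lab)
    assert ((p > 0) & (p < 1)).all(), "frequencies must be clamped inside (0, 1)"
    x = np.where(np.isnan(dose), 2.0 * p, dose)
    return (x - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))


def compute_grm(
    genotypes: GenotypeMatrix,
    mode: str = "STD",
    freqs: FrequencyEstimates | None = None,
    clusters: np.ndarray | None = None,
    variant_mask: np.ndarray | None = None,
) -> GRM:
    """Build a GRM in the requested standardization mode.

    CLS/POP: ``A = Z Z' / M`` for pool-frequency-standardized ``Z``
    (requires ``freqs``). STD: the GCTA default on all-sample
    frequencies — the usual cross-product off-diagonal but a
    method-of-moments diagonal ``1 + (x^2 - (1+2p)x + 2p^2)/(2p(1-p))``
    averaged over variants.
    """
    if genotypes.n_subjects < 2:
        raise ValueError("need at least 2 subjects for a GRM")
    if mode in ("CLS", "POP"):
        if freqs is None:
            raise ValueError(f"{mode} mode requires FrequencyEstimates from the control pool")
        geno = genotypes
        mask = variant_mask
        if mask is not None:
            geno = _mask_variants(genotypes, mask)
            freqs = _mask_freqs(freqs, mask)
        z = standardize_genotypes(geno, freqs, mode, clusters)
        m = z.shape[1]
        if m == 0:
            raise ValueError("zero usable variants for GRM")
        a = (z @ z.T) / m
        return GRM(a, mode, m, genotypes.subject_ids)
    if mode != "STD":
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    dose = genotypes.dosages
    p = np.nanmean(dose, axis=0) / 2.0
    keep = (p > 0) & (p < 1)
    if variant_mask is not None:
        keep &= variant_mask
    if not keep.any():
        raise ValueError("zero usable variants for GRM")
    x = dose[:, keep]
    p = p[keep]
    x = np.where(np.isnan(x), 2 * p, x)
    het = 2.0 * p * (1.0 - p)
    z = (x - 2 * p) / np.sqrt(het)
    m = z.shape[1]
    a = (z @ z.T) / m
    # GCTA's diagonal uses a distinct estimator
    diag = 1.0 + ((x**2 - (1 + 2 * p) * x + 2 * p**2) / het).mean(axis=1)
    np.fill_diagonal(a, diag)
    return GRM(a, "STD", m, genotypes.subject_ids)


def _mask_variants(genotypes: GenotypeMatrix, mask: np.ndarray) -> GenotypeMatrix:
    return GenotypeMatrix(
        genotypes.dosages[:, mask],
        genotypes.subject_ids,
        genotypes.variants.loc[mask].reset_index(drop=True),
        genotypes.clusters,
    )


def _mask_freqs(freqs: FrequencyEstimates, mask: np.ndarray) -> FrequencyEstimates:
    return FrequencyEstimates(
        variant_ids=freqs.variant_ids[mask],
        pooled=freqs.pooled[mask],
        raw=freqs.raw[:, mask],
        eb=freqs.eb[:, mask],
        cluster_labels=freqs.cluster_labels,
        n_per_cluster=freqs.n_per_cluster,
        prior_strength=freqs.prior_strength,
        fst_hat=freqs.fst_hat,
    )
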