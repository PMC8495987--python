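"""Ancestry eigenvectors, clustering and matched case-control pairs.

The workflow mirrors standard GWAS practice: LD-prune the variants with a
moving-window r^2 filter, eigendecompose the (all-sample-standardized)
genomic relationship matrix restricted to the pruned set, cluster subjects
on the top eigenvectors, and form genetically matched 1:1 case-control
pairs within clusters by minimum-total-distance optimal assignment in the
eigenvector space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .io import GenotypeMatrix

logger = logging.getLogger(__name__)

_RANK_TOL = 1e-8


@dataclass
class AncestrySpace:
    """Top-d eigenvectors of the GRM, with optional cluster assignment."""

    eigenvectors: np.ndarray  # N x d, orthonormal columns
    eigenvalues: np.ndarray
    subject_ids: np.ndarray
    clusters: np.ndarray | None = None

    @property
    def d(self) -> int:
        return self.eigenvectors.shape[1]

    @property
    def n_clusters(self) -> int:
        if self.clusters is None:
            raise ValueError("clusters not assigned yet")
        return int(len(np.unique(self.clusters)))


@dataclass
class MatchedPairs:
    """1:1 case-control pairs with eigenvector-space distances."""

    pairs: pd.DataFrame  # columns: case_id, control_id, distance
    unmatched_controls: list[str] = field(default_factory=list)
    unmatched_cases: list[str] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def mean_distance(self) -> float:
        return float(self.pairs["distance"].mean())

    def subject_ids(self) -> np.ndarray:
        """All paired subjects, cases then controls, fold by fold."""
        return np.concatenate([self.pairs["case_id"].to_numpy(), self.pairs["control_id"].to_numpy()])


def _pairwise_r2(dosages: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between dosage columns.

    Monomorphic columns (zero variance) get r^2 = 0 against everything:
    their correlation is undefined, so they never trigger removal.
    """
    x = dosages - dosages.mean(axis=0)
    sd = x.std(axis=0)
    ok = sd > 0
    xs = np.zeros_like(x)
    xs[:, ok] = x[:, ok] / sd[ok]
    r = (xs.T @ xs) / x.shape[0]
    return r**2


def ld_prune(
    genotypes: GenotypeMatrix,
    window: int = 50,
    step: int = 5,
    r2_max: float = 0.64,
) -> list[str]:
    """Greedy moving-window LD pruning of variants.

    Within each ``window``-variant block (ordered by genomic position),
    any retained pair with squared dosage correlation > ``r2_max`` loses
    its later-positioned member (ties broken by lexicographically larger
    id); the window then advances by ``step`` variants.
    """
    if not (window >= step >= 1):
        raise ValueError(f"need window >= step >= 1, got window={window}, step={step}")
    if not 0 < r2_max <= 1:
        raise ValueError(f"r2_max must be in (0, 1], got {r2_max}")
    variants = genotypes.variants
    order = np.lexsort((variants["id"].to_numpy(), variants["pos"].to_numpy(), variants["chrom"].to_numpy()))
    dose = np.nan_to_num(genotypes.dosages, nan=0.0)[:, order]
    ids = variants["id"].to_numpy()[order]
    m = len(ids)
    retained = np.ones(m, dtype=bool)
    for start in range(0, m, step):
        block = np.flatnonzero(retained[start : start + window]) + start
        if len(block) < 2:
            continue
        r2 = _pairwise_r2(dose[:, block])
        np.fill_diagonal(r2, 0.0)
        alive = np.ones(len(block), dtype=bool)
        while True:
            sub = np.where(np.outer(alive, alive), r2, 0.0)
            i, j = np.unravel_index(np.argmax(sub), sub.shape)
            if sub[i, j] <= r2_max:
                break
            # remove the later of the pair; block order is positional
            drop = max(i, j)
            alive[drop] = False
            retained[block[drop]] = False
    kept = ids[retained]
    logger.info("LD pruning retained %d of %d variants", len(kept), m)
    # return in the original variant-table order
    keep_set = set(kept)
    return [v for v in variants["id"] if v in keep_set]


def _std_grm(dosages: np.ndarray) -> np.ndarray:
    """All-sample-frequency standardized GRM (for ancestry eigenvectors)."""
    x = np.nan_to_num(dosages, nan=np.nan)
    p = np.nanmean(dosages, axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic variants for eigenvector computation")
    x = dosages[:, poly]
    p = p[poly]
    x = np.where(np.isnan(x), 2 * p, x)
    z = (x - 2 * p) / np.sqrt(2 * p * (1 - p))
    return (z @ z.T) / z.shape[1]


def compute_eigenvectors(
    genotypes: GenotypeMatrix,
    variant_ids: list[str] | None = None,
    d: int = 3,
) -> AncestrySpace:
    """Top-d eigenvectors of the standardized GRM on a variant subset.

    Eigenvectors are unit-norm with a deterministic sign convention (the
    largest-magnitude coordinate of each vector is positive).
    """
    if d < 1:
        raise ValueError(f"d must be >= 1, got {d}")
    geno = genotypes if variant_ids is None else genotypes.subset_variants(variant_ids)
    if geno.m_variants == 0:
        raise ValueError("variant subset is empty")
    grm = _std_grm(geno.dosages)
    vals, vecs = np.linalg.eigh(grm)
    vals, vecs = vals[::-1], vecs[:, ::-1]
    rank = int((vals > _RANK_TOL * max(vals[0], 1.0)).sum())
    if d > rank:
        raise ValueError(f"requested d={d} eigenvectors but GRM numerical rank is {rank}")
    vecs = vecs[:, :d].copy()
    for j in range(d):
        if vecs[np.argmax(np.abs(vecs[:, j])), j] < 0:
            vecs[:, j] *= -1
    return AncestrySpace(vecs, vals[:d].copy(), genotypes.subject_ids.copy())


def choose_k_by_silhouette(space: AncestrySpace, k_range=range(2, 9), seed: int = 0) -> int:
    """Cluster count with the largest average silhouette on the eigenvectors."""
    best_k, best_s = None, -np.inf
    for k in k_range:
        if k >= len(space.subject_ids):
            continue
        labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(space.eigenvectors)
        if len(np.unique(labels)) < 2:
            continue
        s = silhouette_score(space.eigenvectors, labels)
        if s > best_s:
            best_k, best_s = k, s
    if best_k is None:
        raise ValueError("could not choose k: no valid clustering in range")
    return best_k


def cluster_subjects(space: AncestrySpace, k: int | None = None, seed: int = 0) -> AncestrySpace:
    """K-means on the eigenvector coordinates with deterministic seeding.

    ``k=None`` selects the cluster count by largest average silhouette over
    k in 2..8. Labels are relabeled by descending cluster size.
    """
    n = len(space.subject_ids)
    if k is not None and (k < 1 or k > n):
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if k == 1:
        labels = np.zeros(n, dtype=int)
    else:
        if k is None:
            k = choose_k_by_silhouette(space, seed=seed)
        labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(space.eigenvectors)
    # relabel by descending size; break size ties by original label
    sizes = pd.Series(labels).value_counts().sort_values(ascending=False)
    order = sorted(sizes.index, key=lambda lab: (-sizes[lab], lab))
    remap = {old: new for new, old in enumerate(order)}
    labels = np.array([remap[lab] for lab in labels])
    return AncestrySpace(space.eigenvectors, space.eigenvalues, space.subject_ids, labels)


def match_pairs(space: AncestrySpace, subjects: pd.DataFrame) -> MatchedPairs:
    """Minimum-total-distance 1:1 case-control matching within clusters.

    ``subjects`` needs columns subject_id and status (1 = case). Distances
    are Euclidean in the eigenvector space; within each cluster the optimal
    assignment is found exactly. Controls (or cases) left over in a
    cluster are reported unmatched.
    """
    if space.clusters is None:
        raise ValueError("cluster assignment required before matching")
    status = subjects.set_index("subject_id")["status"]
    coords = {sid: space.eigenvectors[i] for i, sid in enumerate(space.subject_ids)}
    cluster_of = {sid: space.clusters[i] for i, sid in enumerate(space.subject_ids)}
    rows, unmatched_controls, unmatched_cases = [], [], []
    for k in np.unique(space.clusters):
        members = [sid for sid in status.index if sid in cluster_of and cluster_of[sid] == k]
        case_ids = [sid for sid in members if status[sid] == 1]
        ctrl_ids = [sid for sid in members if status[sid] == 0]
        if case_ids and not ctrl_ids:
            logger.warning("cluster %s has %d cases but no controls; left unmatched", k, len(case_ids))
            unmatched_cases.extend(case_ids)
            continue
        if not case_ids:
            unmatched_controls.extend(ctrl_ids)
            continue
        cmat = np.array([coords[c] for c in case_ids])
        tmat = np.array([coords[c] for c in ctrl_ids])
        dist = np.sqrt(((cmat[:, None, :] - tmat[None, :, :]) ** 2).sum(axis=2))
        ri, ci = linear_sum_assignment(dist)
        paired_cases, paired_ctrls = set(), set()
        for i, j in zip(ri, ci):
            rows.append(
                {"case_id": case_ids[i], "control_id": ctrl_ids[j], "distance": float(dist[i, j])}
            )
            paired_cases.add(case_ids[i])
            paired_ctrls.add(ctrl_ids[j])
        unmatched_cases.extend([c for c in case_ids if c not in paired_cases])
        unmatched_controls.extend([c for c in ctrl_ids if c not in paired_ctrls])
    pairs = pd.DataFrame(rows, columns=["case_id", "control_id", "distance"])
    if len(pairs):
        logger.info("matched %d pairs, mean distance %.4g", len(pairs), pairs["distance"].mean())
    return MatchedPairs(pairs, unmatched_controls, unmatched_cases)


def pair_within_clusters(subjects: pd.DataFrame, cluster_col: str = "cluster") -> MatchedPairs:
    """Cluster-matched 1:1 pairing without eigenvector distances.

    Pairs cases to controls in order within each cluster (distance
    recorded as NaN-free 0.0). Useful when the sampling design already
    fixed the case and control cluster compositions to be equal and only
    the pairing bookkeeping is needed.
    """
    rows = []
    unmatched_cases, unmatched_controls = [], []
    for k, grp in subjects.groupby(cluster_col):
        case_ids = grp.loc[grp["status"] == 1, "subject_id"].tolist()
        ctrl_ids = grp.loc[grp["status"] == 0, "subject_id"].tolist()
        n = min(len(case_ids), len(ctrl_ids))
        rows += [
            {"case_id": c, "control_id": t, "distance": 0.0}
            for c, t in zip(case_ids[:n], ctrl_ids[:n])
        ]
        unmatched_cases += case_ids[n:]
        unmatched_controls += ctrl_ids[n:]
    pairs = pd.DataFrame(rows, columns=["case_id", "control_id", "distance"])
    return MatchedPairs(pairs, unmatched_controls, unmatched_cases)
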