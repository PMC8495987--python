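"""Pruning + thresholding polygenic risk scores from GWAS summary statistics.

A PRS is built in three steps: align the summary-statistic effect alleles
to the genotype file's counted allele (flipping effect signs where the
alleles are swapped, dropping strand-ambiguous A/T and C/G variants),
LD-clump the aligned statistics greedily by ascending p-value against a
reference panel, and score each subject as the effect-weighted sum of
dosages over the retained index variants (standardized afterwards).

The p-value threshold defaults to 0.01, deliberately sparse so that the
PRS stays only weakly correlated with the GRM-based genomic prediction it
is later combined with.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ScoreVector
from .io import GenotypeMatrix

logger = logging.getLogger(__name__)

STAT_COLUMNS = ["id", "effect_allele", "other_allele", "beta", "p"]
_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_VALID_ALLELES = {"A", "C", "G", "T"}


@dataclass
class PRSConfig:
    p_threshold: float = 0.01
    clump_r2: float = 0.1
    clump_window_kb: float = 250.0
    drop_ambiguous: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold <= 1:
            raise ValueError(f"p_threshold must be in (0, 1], got {self.p_threshold}")
        if not 0 < self.clump_r2 <= 1:
            raise ValueError(f"clump_r2 must be in (0, 1], got {self.clump_r2}")


def read_summary_stats(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Load a summary-statistics TSV, renaming columns via ``column_map``
    (maps file column -> canonical name in id/effect_allele/other_allele/beta/p)."""
    stats = pd.read_csv(path, sep="\t")
    if column_map:
        stats = stats.rename(columns=column_map)
    missing = [c for c in STAT_COLUMNS if c not in stats.columns]
    if missing:
        raise ValueError(f"summary statistics missing columns: {missing}")
    return validate_summary_stats(stats[STAT_COLUMNS].copy())


def validate_summary_stats(stats: pd.DataFrame) -> pd.DataFrame:
    bad_p = ~((stats["p"] > 0) & (stats["p"] <= 1))
    if bad_p.any():
        raise ValueError(f"{int(bad_p.sum())} summary-stat p-values outside (0, 1]")
    for col in ("effect_allele", "other_allele"):
        bad = ~stats[col].isin(_VALID_ALLELES)
        if bad.any():
            raise ValueError(f"{int(bad.sum())} invalid alleles in column {col}")
    return stats


def align_alleles(
    stats: pd.DataFrame,
    genotypes: GenotypeMatrix,
    drop_ambiguous: bool = True,
) -> pd.DataFrame:
    """Orient effect sizes to the genotype file's counted allele (allele1).

    Effects are negated when the stats' effect allele equals the genotype
    file's allele2; variants with non-matching allele pairs, unknown ids,
    or (optionally) strand-ambiguous A/T / C/G pairs are dropped, with
    counts logged.
    """
    var = genotypes.variants.set_index("id")
    n_in = len(stats)
    stats = stats[stats["id"].isin(var.index)].copy()
    n_unmatched = n_in - len(stats)
    if len(stats) == 0:
        raise ValueError("no overlapping variants between summary stats and genotypes")
    if drop_ambiguous:
        amb = [
            (ea, oa) in _AMBIGUOUS
            for ea, oa in zip(stats["effect_allele"], stats["other_allele"])
        ]
        n_ambiguous = int(np.sum(amb))
        stats = stats[~np.array(amb)]
    else:
        n_ambiguous = 0
    a1 = var.loc[stats["id"], "allele1"].to_numpy()
    a2 = var.loc[stats["id"], "allele2"].to_numpy()
    same = (stats["effect_allele"].to_numpy() == a1) & (stats["other_allele"].to_numpy() == a2)
    flipped = (stats["effect_allele"].to_numpy() == a2) & (stats["other_allele"].to_numpy() == a1)
    n_mismatch = int((~(same | flipped)).sum())
    stats = stats[same | flipped].copy()
    stats.loc[flipped[same | flipped], "beta"] *= -1.0
    if len(stats) == 0:
        raise ValueError("no variants left after allele alignment")
    logger.info(
        "allele alignment: %d kept (%d flipped), %d unmatched ids, %d ambiguous, %d allele mismatches",
        len(stats), int(flipped.sum()), n_unmatched, n_ambiguous, n_mismatch,
    )
    return stats.reset_index(drop=True)


def clump(
    stats: pd.DataFrame,
    reference: GenotypeMatrix,
    config: PRSConfig | None = None,
) -> list[str]:
    """Greedy LD clumping: best remaining p-value becomes an index variant;
    variants within the window with r^2 above the threshold to it are
    removed; repeat. Returns index variants with p below the threshold.
    """
    config = config or PRSConfig()
    var = reference.variants.set_index("id")
    stats = stats[stats["id"].isin(var.index)]
    candidates = stats[stats["p"] < config.p_threshold].copy()
    if candidates.empty:
        logger.warning("no variants below the p threshold %g", config.p_threshold)
        return []
    candidates["pos"] = var.loc[candidates["id"], "pos"].to_numpy()
    candidates["chrom"] = var.loc[candidates["id"], "chrom"].to_numpy()
    # stable greedy order: ascending p, ties by id
    candidates = candidates.sort_values(["p", "id"], kind="mergesort").reset_index(drop=True)
    ref = reference.subset_variants(candidates["id"].tolist())
    dose = np.nan_to_num(ref.dosages, nan=0.0)
    alive = np.ones(len(candidates), dtype=bool)
    kept: list[str] = []
    window = config.clump_window_kb * 1000.0
    pos = candidates["pos"].to_numpy(dtype=float)
    chrom = candidates["chrom"].to_numpy()
    x = dose - dose.mean(axis=0)
    sd = x.std(axis=0)
    for i in range(len(candidates)):
        if not alive[i]:
            continue
        kept.append(candidates.loc[i, "id"])
        alive[i] = False
        near = alive & (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= window)
        idx = np.flatnonzero(near)
        if idx.size == 0 or sd[i] == 0:
            continue
        ok = sd[idx] > 0
        r = (x[:, idx[ok]].T @ x[:, i]) / (len(x) * sd[idx[ok]] * sd[i])
        drop = idx[ok][r**2 > config.clump_r2]
        alive[drop] = False
    logger.info("clumping retained %d of %d sub-threshold variants", len(kept), len(candidates))
    return kept


def score(
    genotypes: GenotypeMatrix,
    stats: pd.DataFrame,
    index_variants: list[str],
    name: str = "PRS",
) -> ScoreVector:
    """Effect-weighted allele-dosage sum over index variants, standardized.

    Missing dosages are mean-imputed per variant before weighting.
    """
    if not index_variants:
        raise ValueError("index variant set is empty")
    sub = genotypes.subset_variants(index_variants)
    betas = stats.set_index("id").loc[index_variants, "beta"].to_numpy(dtype=float)
    dose = sub.dosages
    col_mean = np.nanmean(dose, axis=0)
    dose = np.where(np.isnan(dose), col_mean, dose)
    raw = dose @ betas
    if raw.std() == 0:
        # all effects zero (or constant dosages): return the raw zeros unstandardized
        return ScoreVector(name, genotypes.subject_ids, raw, standardized=False, raw=raw)
    return ScoreVector.from_raw(name, genotypes.subject_ids, raw, provenance=f"P+T over {len(index_variants)} variants")
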