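"""Synthetic structured-population cohort generator.

Emulates the statistical structure the downstream analysis assumes:

* k ancestry clusters whose allele frequencies diverge from a shared
  ancestral frequency under the Balding-Nichols model (Beta-distributed
  cluster frequencies with divergence parameter F);
* a polygenic liability built from standardized causal genotypes with
  common-variant heritability h2 (default 0.70);
* binary diagnosis by thresholding liability at the quantile set by the
  population prevalence (default 1.5%);
* rare potentially-damaging-variant (PDV) carriers whose liability is
  shifted by delta, chosen by default so that carrier status carries a
  15-fold excess of disease odds;
* ascertained sampling: cases collected by rejection sampling, controls
  matched to the cases' cluster composition, plus an extra unmatched
  control pool used only for allele-frequency estimation.

Ground truth (liability, polygenic score, carrier flags, causal effects)
is returned alongside the data so recovery tests can score the analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core import spawn_rng
from .io import GenotypeMatrix, make_variant_table, write_dosage_tsv, write_plink
from .liability import carrier_shift, threshold_from_prevalence

logger = logging.getLogger(__name__)

_ASCERTAINMENT_CAP = 10_000_000
_BATCH = 20_000


@dataclass
class SimConfig:
    """Parameters of one synthetic cohort draw."""

    n_cases: int = 500
    n_matched_controls: int = 500
    n_pool_controls: int = 1000
    k_clusters: int = 4
    cluster_weights: np.ndarray | None = None  # defaults to uniform
    fst: float = 0.01
    m_snps: int = 5000
    m_causal: int = 500
    h2: float = 0.70
    prevalence: float = 0.015
    pdv_rate: float = 0.008
    pdv_shift: float | None = None  # default: carrier_shift(K, 15, odds_ratio)
    pdv_risk_ratio: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cluster_weights is None:
            self.cluster_weights = np.full(self.k_clusters, 1.0 / self.k_clusters)
        self.cluster_weights = np.asarray(self.cluster_weights, dtype=float)
        if len(self.cluster_weights) != self.k_clusters:
            raise ValueError("cluster_weights length must equal k_clusters")
        if abs(self.cluster_weights.sum() - 1.0) > 1e-8 or (self.cluster_weights < 0).any():
            raise ValueError("cluster_weights must be a probability simplex")
        if not 0 < self.fst < 1:
            raise ValueError(f"fst must be in (0, 1), got {self.fst}")
        if self.m_causal > self.m_snps:
            raise ValueError("m_causal cannot exceed m_snps")
        if not 0 <= self.h2 <= 1:
            raise ValueError(f"h2 must be in [0, 1], got {self.h2}")
        if not 0 < self.prevalence < 1:
            raise ValueError(f"prevalence must be in (0, 1), got {self.prevalence}")
        if not 0 <= self.pdv_rate < 1:
            raise ValueError(f"pdv_rate must be in [0, 1), got {self.pdv_rate}")
        if self.pdv_shift is None:
            self.pdv_shift = (
                carrier_shift(self.prevalence, self.pdv_risk_ratio, "odds_ratio")
                if self.pdv_rate > 0
                else 0.0
            )


@dataclass
class SimTruth:
    """Ground truth aligned to the subject table rows."""

    true_polygenic: np.ndarray
    true_liability: np.ndarray
    cluster_label: np.ndarray
    carrier_flag: np.ndarray
    causal_index: np.ndarray  # column indices of causal variants
    causal_effects: np.ndarray  # on the standardized-genotype scale
    ancestral_freqs: np.ndarray
    cluster_freqs: np.ndarray  # k x m
    pdv_shift: float

    def to_frame(self, subject_ids) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": np.asarray(subject_ids),
                "true_polygenic": self.true_polygenic,
                "true_liability": self.true_liability,
                "cluster": self.cluster_label,
                "carrier_flag": self.carrier_flag.astype(int),
            }
        )


def draw_structured_frequencies(
    m_snps: int, k_clusters: int, fst: float, rng: np.random.Generator | int
) -> tuple[np.ndarray, np.ndarray]:
    """Balding-Nichols cluster allele frequencies.

    Ancestral frequencies are uniform on [0.05, 0.95]; each cluster's
    frequency is Beta(p(1-F)/F, (1-p)(1-F)/F), whose mean is p and whose
    variance is F p(1-p).

    Returns ``(ancestral, cluster_freqs)`` with ``cluster_freqs`` of shape
    (k_clusters, m_snps), all entries clipped into (0, 1).
    """
    if m_snps < 1:
        raise ValueError(f"m_snps must be positive, got {m_snps}")
    if k_clusters < 1:
        raise ValueError(f"k_clusters must be positive, got {k_clusters}")
    if not 0 < fst < 1:
        raise ValueError(f"fst must be in (0, 1), got {fst}")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    ancestral = rng.uniform(0.05, 0.95, size=m_snps)
    scale = (1.0 - fst) / fst
    cluster = rng.beta(ancestral * scale, (1.0 - ancestral) * scale, size=(k_clusters, m_snps))
    eps = 1e-6
    return ancestral, np.clip(cluster, eps, 1.0 - eps)



def _draw_effects(rng: np.random.Generator, m_causal: int, h2: float) -> np.ndarray:
    """Causal effects on the standardized-genotype scale.

    Drawn Normal(0, h2/m) then rescaled so the realized genetic variance
    sum(beta^2) equals h2 exactly; this pins the liability variance at 1
    so the realized prevalence and carrier odds match their targets up to
    binomial noise rather than drifting with the effect draw.
    """
    effects = rng.normal(0.0, np.sqrt(h2 / m_causal), size=m_causal)
    if h2 > 0:
        effects *= np.sqrt(h2 / np.sum(effects**2))
    else:
        effects[:] = 0.0
    return effects


def trait_architecture(config: SimConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """The trait's fixed genetic architecture for a given seed.

    Returns ``(ancestral_freqs, cluster_freqs, causal_index, effects)``
    drawn from a substream keyed only by the seed and architecture
    parameters, so every sample drawn under the same config (analysis
    cohort, unascertained population, independent discovery GWAS) shares
    one trait.
    """
    rng = spawn_rng(config.seed, "architecture")
    ancestral, cluster_freqs = draw_structured_frequencies(
        config.m_snps, config.k_clusters, config.fst, rng
    )
    causal_idx = np.sort(rng.choice(config.m_snps, size=config.m_causal, replace=False))
    effects = _draw_effects(rng, config.m_causal, config.h2)
    return ancestral, cluster_freqs, causal_idx, effects


def _liability_batch(
    n: int,
    config: SimConfig,
    cluster_freqs_causal: np.ndarray,
    effects: np.ndarray,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Draw an unascertained batch: cluster, causal genotypes, liability."""
    clusters = rng.choice(config.k_clusters, size=n, p=config.cluster_weights)
    freqs = cluster_freqs_causal[clusters]  # n x m_causal
    geno = rng.binomial(2, freqs).astype(np.int8)
    # standardize with the true cluster frequencies so the polygenic
    # component is orthogonal to ancestry structure
    z = (geno - 2.0 * freqs) / np.sqrt(2.0 * freqs * (1.0 - freqs))
    polygenic = z @ effects
    carrier = rng.random(n) < config.pdv_rate
    env = rng.normal(0.0, np.sqrt(max(1.0 - config.h2, 0.0)), size=n)
    liability = polygenic + config.pdv_shift * carrier + env
    return {
        "clusters": clusters,
        "geno_causal": geno,
        "polygenic": polygenic,
        "carrier": carrier,
        "liability": liability,
    }


def simulate_population(config: SimConfig, n: int, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Unascertained population sample (no genotype matrix).

    Returns a table with cluster, carrier flag, true polygenic and
    liability, and binary status — suitable for validating prevalence,
    heritability bookkeeping and the realized carrier risk ratio.
    """
    rng = spawn_rng(config.seed, "population") if rng is None else rng
    _, cluster_freqs, causal_idx, effects = trait_architecture(config)
    t = threshold_from_prevalence(config.prevalence)
    out = []
    remaining = n
    while remaining > 0:
        b = _liability_batch(min(remaining, _BATCH), config, cluster_freqs[:, causal_idx], effects, rng)
        out.append(b)
        remaining -= len(b["liability"])
    cat = {k: np.concatenate([b[k] for b in out]) for k in ("clusters", "polygenic", "carrier", "liability")}
    return pd.DataFrame(
        {
            "subject_id": [f"P{i + 1}" for i in range(n)],
            "cluster": cat["clusters"],
            "carrier_flag": cat["carrier"].astype(int),
            "true_polygenic": cat["polygenic"],
            "true_liability": cat["liability"],
            "status": (cat["liability"] > t).astype(int),
        }
    )


def realized_risk_ratio(subjects: pd.DataFrame) -> dict[str, float]:
    """Carrier risk ratio and odds ratio from an unascertained sample.

    Expects ``status`` and ``carrier_flag`` columns. Returns
    ``{"risk_ratio", "odds_ratio", ...}`` from the 2x2 contingency table.
    """
    carrier = subjects["carrier_flag"].to_numpy().astype(bool)
    status = subjects["status"].to_numpy().astype(bool)
    n_carrier = carrier.sum()
    n_non = (~carrier).sum()
    if n_carrier == 0 or n_non == 0:
        raise ValueError("risk ratio undefined: need both carriers and non-carriers")
    k_carrier = status[carrier].mean()
    k_non = status[~carrier].mean()
    if k_non == 0:
        raise ValueError("risk ratio undefined: no affected non-carriers")
    rr = k_carrier / k_non
    if k_carrier >= 1 or k_non >= 1:
        raise ValueError("odds ratio undefined: a group is fully affected")
    orr = (k_carrier / (1 - k_carrier)) / (k_non / (1 - k_non))
    return {
        "risk_ratio": float(rr),
        "odds_ratio": float(orr),
        "risk_carrier": float(k_carrier),
        "risk_non_carrier": float(k_non),
        "n_carriers": int(n_carrier),
    }


def simulate_cohort(
    config: SimConfig, sample_stream: str = "cohort"
) -> tuple[GenotypeMatrix, pd.DataFrame, SimTruth]:
    """Ascertained case-control cohort with ground truth.

    Rejection-samples the population until ``n_cases`` affected subjects
    are found; draws ``n_matched_controls`` unaffected subjects with the
    same per-cluster composition as the cases, plus ``n_pool_controls``
    unaffected subjects irrespective of cluster (the frequency-estimation
    pool). The subject table has columns subject_id, cohort
    (case / matched_control / pool_control), status, cluster,
    carrier_flag.
    """
    rng = spawn_rng(config.seed, sample_stream)
    ancestral, cluster_freqs, causal_idx, effects = trait_architecture(config)
    t = threshold_from_prevalence(config.prevalence)

    cases: list[dict] = []
    controls_by_cluster: dict[int, list[dict]] = {k: [] for k in range(config.k_clusters)}
    pool: list[dict] = []
    drawn = 0
    control_quota: np.ndarray | None = None

    def _record(batch, i):
        return {
            "cluster": int(batch["clusters"][i]),
            "geno_causal": batch["geno_causal"][i],
            "polygenic": float(batch["polygenic"][i]),
            "carrier": bool(batch["carrier"][i]),
            "liability": float(batch["liability"][i]),
        }

    def _quota_unfilled() -> bool:
        if control_quota is None:
            return True
        return any(
            len(controls_by_cluster[k]) < control_quota[k] for k in range(config.k_clusters)
        )

    while True:
        need_cases = len(cases) < config.n_cases
        need_pool = len(pool) < config.n_pool_controls
        if not need_cases and not need_pool and not _quota_unfilled():
            break
        if drawn >= _ASCERTAINMENT_CAP:
            raise RuntimeError(
                f"ascertainment cap of {_ASCERTAINMENT_CAP} draws reached with "
                f"{len(cases)}/{config.n_cases} cases; prevalence {config.prevalence} "
                "may be too low for the requested sample sizes"
            )
        batch = _liability_batch(_BATCH, config, cluster_freqs[:, causal_idx], effects, rng)
        drawn += _BATCH
        affected = batch["liability"] > t
        for i in np.flatnonzero(affected):
            if len(cases) < config.n_cases:
                cases.append(_record(batch, i))
        if len(cases) == config.n_cases and control_quota is None:
            case_clusters = np.array([c["cluster"] for c in cases])
            control_quota = np.bincount(case_clusters, minlength=config.k_clusters)
            control_quota = np.round(
                control_quota * config.n_matched_controls / config.n_cases
            ).astype(int)
            # fix rounding so the quota sums exactly
            diff = config.n_matched_controls - control_quota.sum()
            control_quota[np.argmax(control_quota)] += diff
        for i in np.flatnonzero(~affected):
            k = int(batch["clusters"][i])
            if control_quota is not None and len(controls_by_cluster[k]) < control_quota[k]:
                controls_by_cluster[k].append(_record(batch, i))
            elif len(pool) < config.n_pool_controls:
                pool.append(_record(batch, i))

    matched = [rec for k in range(config.k_clusters) for rec in controls_by_cluster[k]]
    records = cases + matched + pool
    cohorts = (
        ["case"] * len(cases)
        + ["matched_control"] * len(matched)
        + ["pool_control"] * len(pool)
    )
    n_total = len(records)
    clusters = np.array([r["cluster"] for r in records])
    carrier = np.array([r["carrier"] for r in records])
    polygenic = np.array([r["polygenic"] for r in records])
    liability = np.array([r["liability"] for r in records])
    status = (liability > t).astype(int)

    # fill in the non-causal genotypes for retained subjects only
    geno = np.empty((n_total, config.m_snps), dtype=np.int8)
    non_causal = np.setdiff1d(np.arange(config.m_snps), causal_idx)
    freqs_nc = cluster_freqs[:, non_causal]
    for k in range(config.k_clusters):
        rows = np.flatnonzero(clusters == k)
        if rows.size:
            geno[np.ix_(rows, non_causal)] = rng.binomial(
                2, np.broadcast_to(freqs_nc[k], (rows.size, len(non_causal)))
            ).astype(np.int8)
    geno[:, causal_idx] = np.vstack([r["geno_causal"] for r in records])

    subject_ids = np.array([f"S{i + 1}" for i in range(n_total)])
    subjects = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "cohort": cohorts,
            "status": status,
            "cluster": clusters,
            "carrier_flag": carrier.astype(int),
        }
    )
    truth = SimTruth(
        true_polygenic=polygenic,
        true_liability=liability,
        cluster_label=clusters,
        carrier_flag=carrier,
        causal_index=causal_idx,
        causal_effects=effects,
        ancestral_freqs=ancestral,
        cluster_freqs=cluster_freqs,
        pdv_shift=config.pdv_shift,
    )
    genotypes = GenotypeMatrix(
        geno.astype(float), subject_ids, make_variant_table(config.m_snps), clusters
    )
    logger.info(
        "simulated cohort: %d cases, %d matched controls, %d pool controls (%d draws)",
        len(cases), len(matched), len(pool), drawn,
    )
    return genotypes, subjects, truth


# ---------------------------------------------------------------------------
# Synthetic PDV annotation records for the carrier-calling stage
# ---------------------------------------------------------------------------

SYNTHETIC_RISK_GENES = [f"RISK{i + 1}" for i in range(20)]
_DECOY_GENES = [f"DECOY{i + 1}" for i in range(20)]


def generate_pdv_records(
    subjects: pd.DataFrame,
    seed: int = 0,
    undetermined_rate: float = 0.01,
    decoy_rate: float = 0.05,
) -> tuple[pd.DataFrame, list[str]]:
    """Synthetic per-subject variant annotation table for carrier calling.

    Every flagged carrier gets one qualifying record (damaging CNV, PTV in
    a risk gene, or missense with MPC > 2 in a risk gene); a small fraction
    of subjects get trisomy / large-CNV records (undetermined) or
    non-qualifying decoy records. Returns ``(records, risk_gene_set)``.
    """
    rng = spawn_rng(seed, "pdv-records")
    rows = []
    for _, row in subjects.iterrows():
        sid = row["subject_id"]
        if rng.random() < undetermined_rate and row["status"] == 1:
            cls = "TRISOMY" if rng.random() < 0.5 else "CNV"
            rows.append(
                {
                    "subject_id": sid,
                    "gene": rng.choice(SYNTHETIC_RISK_GENES),
                    "var_class": cls,
                    "mpc": np.nan,
                    "cnv_damaging": cls == "CNV",
                    "cnv_large_or_multiple": True,
                }
            )
            continue
        if row["carrier_flag"] == 1:
            cls = rng.choice(["CNV", "PTV", "MIS"], p=[0.5, 0.3, 0.2])
            rows.append(
                {
                    "subject_id": sid,
                    "gene": rng.choice(SYNTHETIC_RISK_GENES),
                    "var_class": cls,
                    "mpc": float(rng.uniform(2.1, 4.0)) if cls == "MIS" else np.nan,
                    "cnv_damaging": cls == "CNV",
                    "cnv_large_or_multiple": False,
                }
            )
        elif rng.random() < decoy_rate:
            # non-qualifying: decoy gene, or low-MPC missense in a risk gene
            if rng.random() < 0.5:
                rows.append(
                    {
                        "subject_id": sid,
                        "gene": rng.choice(_DECOY_GENES),
                        "var_class": rng.choice(["PTV", "MIS"]),
                        "mpc": float(rng.uniform(0.0, 2.0)),
                        "cnv_damaging": False,
                        "cnv_large_or_multiple": False,
                    }
                )
            else:
                rows.append(
                    {
                        "subject_id": sid,
                        "gene": rng.choice(SYNTHETIC_RISK_GENES),
                        "var_class": "MIS",
                        "mpc": float(rng.uniform(0.0, 2.0)),
                        "cnv_damaging": False,
                        "cnv_large_or_multiple": False,
                    }
                )
    return pd.DataFrame(rows), list(SYNTHETIC_RISK_GENES)


def write_cohort(
    genotypes: GenotypeMatrix,
    subjects: pd.DataFrame,
    truth: SimTruth,
    outdir: str | Path,
    fmt: str = "plink",
) -> None:
    """Write genotypes (PLINK triplet or dosage TSV), subject and truth TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if fmt == "plink":
        write_plink(genotypes, outdir / "genotypes")
    elif fmt == "tsv":
        write_dosage_tsv(genotypes, outdir / "genotypes.tsv")
    else:
        raise ValueError(f"format must be 'plink' or 'tsv', got {fmt!r}")
    subjects.to_csv(outdir / "subjects.tsv", sep="\t", index=False)
    truth.to_frame(genotypes.subject_ids).to_csv(outdir / "truth.tsv", sep="\t", index=False)


def simulate_gwas_stats(config: SimConfig, n_cases_gwas: int = 1000, seed: int | None = None) -> pd.DataFrame:
    """Summary statistics from an independent simulated case-control GWAS.

    Draws a fresh ascertained cohort of the same trait (identical
    architecture substream, independent subject substream keyed by
    ``seed``), then computes per-variant allele-count log odds
    ratios (with Haldane-Anscombe correction) and chi-square p-values.
    Effect alleles follow the simulated variant table (allele1 counted).
    """
    from dataclasses import replace
    from scipy.stats import chi2 as _chi2

    cfg = replace(
        config,
        n_cases=n_cases_gwas,
        n_matched_controls=n_cases_gwas,
        n_pool_controls=0,
    )
    stream = f"gwas-{config.seed if seed is None else seed}"
    geno, subjects, _ = simulate_cohort(cfg, sample_stream=stream)
    case = subjects["status"].to_numpy() == 1
    dose = geno.dosages
    a_case = np.nansum(dose[case], axis=0)
    a_ctrl = np.nansum(dose[~case], axis=0)
    n_case = 2.0 * case.sum()
    n_ctrl = 2.0 * (~case).sum()
    b_case = n_case - a_case
    b_ctrl = n_ctrl - a_ctrl
    # Haldane-Anscombe correction keeps the log-OR finite
    log_or = np.log(((a_case + 0.5) * (b_ctrl + 0.5)) / ((b_case + 0.5) * (a_ctrl + 0.5)))
    se = np.sqrt(1 / (a_case + 0.5) + 1 / (b_case + 0.5) + 1 / (a_ctrl + 0.5) + 1 / (b_ctrl + 0.5))
    z2 = (log_or / se) ** 2
    p = np.clip(_chi2.sf(z2, 1), 1e-300, 1.0)
    var = geno.variants
    return pd.DataFrame(
        {
            "id": var["id"],
            "effect_allele": var["allele1"],
            "other_allele": var["allele2"],
            "beta": log_or,
            "p": p,
        }
    )
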