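"""Score evaluation, the weighted genomic risk score (WGRS) and the pTDT.

Evaluation is a maximum-likelihood logistic regression of case status on
a standardized score: the odds ratio per SD of score, its Wald 95% CI and
p-value, and Nagelkerke's pseudo-R^2

    R^2_N = [1 - (L0/L1)^(2/n)] / [1 - L0^(2/n)]

with L0/L1 the null and fitted likelihoods. The WGRS is a convex
combination of standardized component scores with weights proportional to
each component's pseudo-R^2 (or equal weights), restandardized after
combination. The pTDT tests whether affected children's scores deviate
from their parents' midpoint, in units of the midparent SD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .core import ScoreVector, standardize

logger = logging.getLogger(__name__)

WEIGHT_SCHEMES = ("pseudoR2", "equal")


@dataclass
class EvalResult:
    """Logistic-regression summary of a score's case-control separation."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    pseudo_r2: float
    n: int
    separation: bool = False

    def to_dict(self) -> dict:
        return {
            "OR": self.odds_ratio,
            "CI95": [self.ci_low, self.ci_high],
            "P": self.p_value,
            "pseudo_R2": self.pseudo_r2,
            "n": self.n,
            "separation": self.separation,
        }


@dataclass
class WGRSWeights:
    components: list[str]
    weights: np.ndarray
    scheme: str

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if (self.weights < 0).any() or abs(self.weights.sum() - 1.0) > 1e-8:
            raise ValueError("weights must be nonnegative and sum to 1")


def nagelkerke_r2(llf_null: float, llf_full: float, n: int) -> float:
    """Nagelkerke pseudo-R^2 from log-likelihoods."""
    cox_snell = 1.0 - np.exp(2.0 * (llf_null - llf_full) / n)
    max_r2 = 1.0 - np.exp(2.0 * llf_null / n)
    return float(cox_snell / max_r2) if max_r2 > 0 else 0.0


def evaluate_score(score: ScoreVector | np.ndarray, status) -> EvalResult:
    """OR per SD, Wald CI/p and Nagelkerke pseudo-R^2 for a score."""
    x = score.values if isinstance(score, ScoreVector) else np.asarray(score, dtype=float)
    y = np.asarray(status, dtype=float)
    if x.shape[0] != y.shape[0]:
        raise ValueError("score and status length mismatch")
    if len(np.unique(y)) < 2:
        raise ValueError("both case and control statuses are required")
    design = sm.add_constant(x)
    model = sm.Logit(y, design)
    try:
        with np.errstate(all="ignore"):
            fit = model.fit(disp=0, maxiter=200)
        separation = not np.isfinite(fit.bse).all() or np.abs(fit.params[1]) > 30
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
        separation = True
        fit = None
    if separation or fit is None:
        logger.warning("complete separation detected; returning infinite-OR sentinel")
        return EvalResult(np.inf, np.nan, np.nan, 0.0, 1.0, len(y), separation=True)
    beta, se = fit.params[1], fit.bse[1]
    z = sps.norm.ppf(0.975)
    llf_null = sm.Logit(y, np.ones((len(y), 1))).fit(disp=0).llf
    return EvalResult(
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - z * se)),
        ci_high=float(np.exp(beta + z * se)),
        p_value=float(fit.pvalues[1]),
        pseudo_r2=nagelkerke_r2(llf_null, fit.llf, len(y)),
        n=len(y),
        separation=False,
    )


def pseudo_r2_weights(pseudo_r2s) -> np.ndarray:
    """Normalize component pseudo-R^2 values into convex weights."""
    r2 = np.asarray(pseudo_r2s, dtype=float)
    total = r2.sum()
    if total <= 0:
        raise ValueError("all pseudo-R^2 are zero")
    return r2 / total


def combine_wgrs(
    components: list[ScoreVector],
    status,
    scheme: str = "pseudoR2",
) -> tuple[ScoreVector, WGRSWeights]:
    """Weighted genomic risk score from standardized component scores.

    pseudoR2 scheme: weight_i = R2_i / sum(R2); falls back to equal
    weights (with a warning) if every component's pseudo-R^2 is zero.
    The combined score is restandardized to mean 0, SD 1.
    """
    if scheme not in WEIGHT_SCHEMES:
        raise ValueError(f"scheme must be one of {WEIGHT_SCHEMES}, got {scheme!r}")
    if not components:
        raise ValueError("need at least one component score")
    ids = components[0].subject_ids
    for c in components[1:]:
        if not np.array_equal(c.subject_ids, ids):
            raise ValueError("components must cover the same subjects in the same order")
    for c in components:
        if not c.standardized:
            raise ValueError(f"component {c.name} is not standardized")
    names = [c.name for c in components]
    if scheme == "equal":
        w = np.full(len(components), 1.0 / len(components))
    else:
        r2 = np.array([evaluate_score(c, status).pseudo_r2 for c in components])
        if r2.sum() <= 0:
            logger.warning("all component pseudo-R^2 are zero; falling back to equal weights")
            w = np.full(len(components), 1.0 / len(components))
            scheme = "equal"
        else:
            w = pseudo_r2_weights(r2)
    combined = np.sum([wi * c.values for wi, c in zip(w, components)], axis=0)
    wgrs = ScoreVector.from_raw(
        "WGRS", ids, combined, provenance=f"{scheme} weights over {names}"
    )
    return wgrs, WGRSWeights(names, w, scheme)


@dataclass
class PTDTResult:
    mean_deviation: float
    t_statistic: float
    p_value: float
    n_trios: int


def ptdt(child_scores, mother_scores, father_scores) -> PTDTResult:
    """Polygenic transmission disequilibrium test over complete trios.

    deviation_i = (child_i - midparent_i) / SD(midparent); one-sample
    t-test of zero mean deviation.
    """
    child = np.asarray(child_scores, dtype=float)
    mother = np.asarray(mother_scores, dtype=float)
    father = np.asarray(father_scores, dtype=float)
    if not (len(child) == len(mother) == len(father)):
        raise ValueError("trio score vectors must have equal length")
    if len(child) < 2:
        raise ValueError("need at least 2 complete trios")
    midparent = (mother + father) / 2.0
    sd_mid = midparent.std(ddof=1)
    if sd_mid == 0:
        raise ValueError("midparent scores have zero variance")
    dev = (child - midparent) / sd_mid
    if np.allclose(dev, dev[0]):
        # zero within-trio variance: t-test degenerates
        t_stat = 0.0 if np.isclose(dev[0], 0) else np.inf
        p = 1.0 if t_stat == 0 else 0.0
    else:
        t_stat, p = sps.ttest_1samp(dev, 0.0)
    return PTDTResult(float(dev.mean()), float(t_stat), float(p), len(child))


def burden_contrasts(
    score: ScoreVector,
    subjects: pd.DataFrame,
    carrier_calls: pd.DataFrame | None = None,
    n_boot: int = 2000,
    seed: int = 0,
) -> dict:
    """Group means of a burden score with bootstrap 95% CIs.

    Groups: controls, all cases, carrier cases, non-carrier cases and
    per-most-severe-class (CNV/PTV/MIS) cases. Undetermined subjects are
    excluded from carrier contrasts but stay in the all-case group. Also
    reports the logistic OR of carrier status on the score among cases.
    """
    rng = np.random.default_rng(seed)
    s = score.to_series()
    info = subjects.set_index("subject_id")
    status = info.loc[s.index, "status"]
    groups: dict[str, np.ndarray] = {
        "controls": s[status == 0].to_numpy(),
        "cases": s[status == 1].to_numpy(),
    }
    carrier_eval = None
    if carrier_calls is not None:
        calls = carrier_calls.set_index("subject_id").reindex(s.index)
        is_case = (status == 1).to_numpy()
        det = (calls["status"] != "undetermined").to_numpy() & is_case
        carrier = (calls["status"] == "carrier").to_numpy()
        groups["carrier_cases"] = s[det & carrier].to_numpy()
        groups["non_carrier_cases"] = s[det & ~carrier].to_numpy()
        for cls in ("CNV", "PTV", "MIS"):
            members = det & carrier & (calls["most_severe"] == cls).to_numpy()
            if members.any():
                groups[f"carrier_cases_{cls}"] = s[members].to_numpy()
        if groups["carrier_cases"].size and groups["non_carrier_cases"].size:
            sub = s[det].to_numpy()
            lab = carrier[det].astype(float)
            try:
                carrier_eval = evaluate_score(
                    ScoreVector("score", s.index[det].to_numpy(), standardize(sub)), lab
                ).to_dict()
            except ValueError:
                carrier_eval = None
    out: dict = {"groups": {}, "n_boot": n_boot}
    for name, vals in groups.items():
        if vals.size == 0:
            logger.warning("group %s is empty; omitted", name)
            continue
        boots = rng.choice(vals, size=(n_boot, vals.size), replace=True).mean(axis=1)
        lo, hi = np.percentile(boots, [2.5, 97.5])
        out["groups"][name] = {
            "n": int(vals.size),
            "mean": float(vals.mean()),
            "ci95": [float(lo), float(hi)],
        }
    if carrier_eval is not None:
        out["carrier_vs_noncarrier_logistic"] = carrier_eval
    return out
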