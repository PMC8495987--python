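"""G-BLUP genomic prediction with the leave-matched-pair-out plan.

The mixed-model prediction for test subjects given training phenotypes is

    g_test = K_test,train (K_train,train + lambda I)^-1 (y_train - y_bar)

with ridge ``lambda = (1 - h2)/h2`` and h2 a fixed heritability input
(default 0.70, never estimated here). The training plan holds out one
matched case-control pair at a time and trains on the other N - 2
subjects; iterating over all pairs yields one out-of-sample genomic
prediction (GP) per subject, which is then standardized to mean 0, SD 1.

Refitting per pair is accelerated by precomputing M = (K + lambda I)^-1
once and removing each pair S with the block (Schur-complement) downdate

    (A_-S,-S)^-1 = M_-S,-S - M_-S,S (M_S,S)^-1 M_S,-S.

The per-pair prediction operator rows are cached, so re-scoring a new
phenotype vector (e.g. a within-pair permutation null for genomic
control) costs one matrix-vector product.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.stats import chi2

from .ancestry import MatchedPairs
from .core import ScoreVector
from .grm import GRM

logger = logging.getLogger(__name__)

_JITTER = 1e-8
CHI2_1_MEDIAN = float(chi2.ppf(0.5, 1))  # 0.4549...


def _ridge_lambda(h2: float) -> float:
    if not 0 < h2 < 1:
        raise ValueError(f"h2 must be in (0, 1), got {h2}")
    return (1.0 - h2) / h2


def _solve_spd(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    try:
        return scipy.linalg.solve(a, b, assume_a="pos")
    except np.linalg.LinAlgError:
        logger.warning("SPD solve failed; retrying with %.0e diagonal jitter", _JITTER)
        try:
            return scipy.linalg.solve(a + _JITTER * np.eye(a.shape[0]), b, assume_a="pos")
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "GRM system is numerically singular even after jitter; "
                "consider pruning duplicate subjects or increasing lambda"
            ) from exc


def blup_predict(
    grm: GRM,
    train_ids,
    train_phenotypes,
    test_ids,
    h2: float = 0.70,
) -> np.ndarray:
    """Raw (unstandardized) G-BLUP predictions for the test subjects.

    The training phenotypes are centered to mean 0; predictions for
    subjects with no covariance to the training set are exactly 0.
    """
    lam = _ridge_lambda(h2)
    tr = grm.index_of(train_ids)
    te = grm.index_of(test_ids)
    if np.intersect1d(tr, te).size:
        raise ValueError("train and test ids overlap")
    y = np.asarray(train_phenotypes, dtype=float)
    if y.shape[0] != tr.shape[0]:
        raise ValueError("phenotype length does not match training ids")
    yc = y - y.mean()
    a = grm.matrix[np.ix_(tr, tr)] + lam * np.eye(len(tr))
    alpha = _solve_spd(a, yc)
    return grm.matrix[np.ix_(te, tr)] @ alpha


@dataclass
class LeavePairOutOperator:
    """Cached leave-pair-out prediction operator.

    ``weights`` is (N, N): row i holds the linear functional mapping the
    full phenotype vector (restricted to subject i's training fold, i.e.
    with the held-out pair's entries zeroed) to subject i's raw GP.
    ``fold_of`` maps each subject row to its pair index. Applying the
    operator to any phenotype vector (``predict_raw``) reproduces the
    naive per-pair refit, including the per-fold recentring of y.
    """

    subject_ids: np.ndarray
    weights: np.ndarray
    row_sums: np.ndarray  # per row, sum of training-fold weights
    fold_of: np.ndarray
    pair_index: np.ndarray  # (n_pairs, 2) row indices of each pair

    def predict_raw(self, phenotypes: np.ndarray) -> np.ndarray:
        y = np.asarray(phenotypes, dtype=float)
        n = len(y)
        total = y.sum()
        out = self.weights @ y
        # correct for centering on each training fold: subtract
        # w.1 * mean(y_fold) where the fold excludes the subject's pair
        pair_sums = y[self.pair_index].sum(axis=1)
        fold_means = (total - pair_sums[self.fold_of]) / (n - 2)
        return out - self.row_sums * fold_means

    def predict(self, phenotypes: np.ndarray, name: str = "GP") -> ScoreVector:
        raw = self.predict_raw(phenotypes)
        return ScoreVector.from_raw(name, self.subject_ids, raw, provenance="leave-pair-out G-BLUP")


def build_leave_pair_out(grm: GRM, pairs: MatchedPairs, h2: float = 0.70) -> LeavePairOutOperator:
    """Precompute the leave-pair-out operator for all matched pairs."""
    if pairs.n_pairs < 2:
        raise ValueError(f"need at least 2 matched pairs, got {pairs.n_pairs}")
    lam = _ridge_lambda(h2)
    case_idx = grm.index_of(pairs.pairs["case_id"])
    ctrl_idx = grm.index_of(pairs.pairs["control_id"])
    scored = np.concatenate([np.stack([case_idx, ctrl_idx], axis=1).ravel()])
    if len(np.unique(scored)) != len(scored):
        raise ValueError("each scored subject must belong to exactly one pair")
    subj = np.stack([case_idx, ctrl_idx], axis=1)  # (P, 2) GRM row indices
    order = subj.ravel()
    k = grm.matrix[np.ix_(order, order)]
    n = k.shape[0]
    m = _solve_spd(k + lam * np.eye(n), np.eye(n))
    weights = np.zeros((n, n))
    fold_of = np.repeat(np.arange(len(subj)), 2)
    local_pairs = np.arange(n).reshape(-1, 2)
    for pidx, s in enumerate(local_pairs):
        # G = K[S,:] M ; then peel off the S columns via the Schur downdate
        g = k[s, :] @ m
        c = m[np.ix_(s, s)]
        h = g - (g[:, s] @ np.linalg.inv(c)) @ m[s, :]
        h[:, s] = 0.0
        weights[s, :] = h
    row_sums = weights.sum(axis=1)
    subject_ids = grm.subject_ids[order]
    return LeavePairOutOperator(subject_ids, weights, row_sums, fold_of, local_pairs)


def leave_pair_out_gp(
    grm: GRM,
    pairs: MatchedPairs,
    phenotypes: dict | "pd.Series",
    h2: float = 0.70,
) -> ScoreVector:
    """GP via leave-matched-pair-out G-BLUP, standardized to mean 0, SD 1.

    ``phenotypes`` maps subject id -> phenotype (case = 1, control = 0;
    the coding is immaterial up to affine transformation because each
    training fold is centered and GP is standardized afterwards).
    """
    op = build_leave_pair_out(grm, pairs, h2)
    y = np.array([float(phenotypes[s]) for s in op.subject_ids])
    return op.predict(y)


def naive_leave_pair_out_gp(
    grm: GRM,
    pairs: MatchedPairs,
    phenotypes,
    h2: float = 0.70,
) -> ScoreVector:
    """Reference implementation: explicit refit for every held-out pair."""
    ids = pairs.subject_ids()
    raw = {}
    for _, row in pairs.pairs.iterrows():
        test = [row["case_id"], row["control_id"]]
        train = [s for s in ids if s not in test]
        y = np.array([float(phenotypes[s]) for s in train])
        pred = blup_predict(grm, train, y, test, h2)
        raw[test[0]], raw[test[1]] = pred
    ordered = np.concatenate([pairs.pairs["case_id"].to_numpy(), pairs.pairs["control_id"].to_numpy()])
    return ScoreVector.from_raw("GP", ordered, np.array([raw[s] for s in ordered]), provenance="naive refit")


# ---------------------------------------------------------------------------
# Genomic control
# ---------------------------------------------------------------------------

def gc_lambda(statistics) -> float:
    """Genomic-control inflation factor: median chi-square over 0.4549."""
    stats = np.asarray(statistics, dtype=float)
    if stats.size == 0:
        raise ValueError("gc_lambda needs at least one statistic")
    if not np.isfinite(stats).all() or (stats < 0).any():
        raise ValueError("statistics must be finite and nonnegative")
    return float(np.median(stats) / CHI2_1_MEDIAN)


def gc_correct(statistic: float, lam: float) -> float:
    """Deflate a chi-square statistic by lambda (floored at 1)."""
    return float(statistic / max(lam, 1.0))


def case_control_chi2(score: np.ndarray, status: np.ndarray) -> float:
    """Wald chi-square for the case-control contrast of a score.

    Logistic regression of status on the score; returns the squared Wald
    z of the slope.
    """
    import statsmodels.api as sm

    x = sm.add_constant(np.asarray(score, dtype=float))
    fit = sm.GLM(np.asarray(status, dtype=float), x, family=sm.families.Binomial()).fit()
    return float((fit.params[1] / fit.bse[1]) ** 2)


def permutation_gc_lambda(
    op: LeavePairOutOperator,
    status: np.ndarray,
    n_permutations: int = 200,
    seed: int = 0,
) -> float:
    """Estimate the GC inflation factor from a within-pair permutation null.

    For each permutation the case/control labels are flipped independently
    within each matched pair, GP is re-scored through the cached operator,
    and the Wald chi-square of the case-control contrast recorded;
    lambda is the null median over 0.4549.
    """
    rng = np.random.default_rng(seed)
    status = np.asarray(status, dtype=float)
    stats = np.empty(n_permutations)
    for b in range(n_permutations):
        y = status.copy()
        flip = rng.random(len(op.pair_index)) < 0.5
        for pidx in np.flatnonzero(flip):
            i, j = op.pair_index[pidx]
            y[i], y[j] = y[j], y[i]
        gp = op.predict_raw(y)
        sd = gp.std()
        stats[b] = case_control_chi2((gp - gp.mean()) / sd, y) if sd > 0 else 0.0
    return gc_lambda(stats)
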