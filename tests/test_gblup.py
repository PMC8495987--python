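"""G-BLUP prediction, the leave-pair-out downdate and genomic control."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from polyliab.ancestry import MatchedPairs, pair_within_clusters
from polyliab.gblup import (
    blup_predict,
    build_leave_pair_out,
    case_control_chi2,
    gc_correct,
    gc_lambda,
    leave_pair_out_gp,
    naive_leave_pair_out_gp,
    permutation_gc_lambda,
)
from polyliab.grm import GRM, compute_grm, estimate_frequencies, polymorphic_mask
from polyliab.io import GenotypeMatrix, make_variant_table
from polyliab.simdata import SimConfig, simulate_cohort

from conftest import random_genotypes


def _random_grm(rng, n, m=300):
    z = rng.normal(size=(n, m))
    ids = np.array([f"s{i}" for i in range(n)])
    return GRM(z @ z.T / m, "STD", m, ids)


def _pairs(ids):
    half = len(ids) // 2
    return MatchedPairs(
        pd.DataFrame({"case_id": ids[:half], "control_id": ids[half:], "distance": 0.0})
    )


class TestBlupPredict:
    def test_infinite_shrinkage_limit(self, rng):
        grm = _random_grm(rng, 12)
        ids = grm.subject_ids
        y = rng.random(8)
        pred = blup_predict(grm, ids[:8], y, ids[8:], h2=1e-9)
        assert np.abs(pred).max() < 1e-6

    def test_zero_covariance_gives_zero_prediction(self):
        ids = np.array([f"s{i}" for i in range(6)])
        grm = GRM(np.eye(6), "STD", 10, ids)
        pred = blup_predict(grm, ids[:4], [1.0, 0.0, 1.0, 0.0], ids[4:], h2=0.5)
        assert np.allclose(pred, 0.0)

    def test_matches_mixed_model_equation_oracle(self, rng):
        """Independent route: solve for the training subjects' genetic
        values u from (I + lambda K^-1) u = y_c, then propagate
        g_test = K_test,train K_train^-1 u."""
        grm = _random_grm(rng, 6, m=50)
        ids = grm.subject_ids
        h2 = 0.7
        lam = (1 - h2) / h2
        y = np.array([1.0, 0.0, 1.0, 0.0])
        yc = y - y.mean()
        k_tr = grm.matrix[:4, :4]
        u = np.linalg.solve(np.eye(4) + lam * np.linalg.inv(k_tr), yc)
        oracle = grm.matrix[4:, :4] @ np.linalg.solve(k_tr, u)
        pred = blup_predict(grm, ids[:4], y, ids[4:], h2=h2)
        assert np.allclose(pred, oracle, atol=1e-10)

    def test_overlapping_train_test_rejected(self, rng):
        grm = _random_grm(rng, 6)
        ids = grm.subject_ids
        with pytest.raises(ValueError, match="overlap"):
            blup_predict(grm, ids[:4], np.zeros(4), ids[3:], h2=0.5)

    @pytest.mark.parametrize("h2", [0.0, 1.0, -0.2])
    def test_invalid_h2(self, rng, h2):
        grm = _random_grm(rng, 6)
        ids = grm.subject_ids
        with pytest.raises(ValueError):
            blup_predict(grm, ids[:4], np.zeros(4), ids[4:], h2=h2)


class TestLeavePairOut:
    def test_downdate_equals_naive_refit(self, rng):
        grm = _random_grm(rng, 40, m=500)
        pairs = _pairs(grm.subject_ids)
        pheno = {s: float(i < 20) for i, s in enumerate(grm.subject_ids)}
        fast = leave_pair_out_gp(grm, pairs, pheno).to_series()
        naive = naive_leave_pair_out_gp(grm, pairs, pheno).to_series()
        rel = np.abs(fast - naive.reindex(fast.index)).max() / np.abs(naive).max()
        assert rel <= 1e-8

    def test_invariant_to_phenotype_shift(self, rng):
        grm = _random_grm(rng, 20)
        pairs = _pairs(grm.subject_ids)
        base = {s: float(i % 2) for i, s in enumerate(grm.subject_ids)}
        shifted = {s: v + 11.0 for s, v in base.items()}
        gp1 = leave_pair_out_gp(grm, pairs, base)
        gp2 = leave_pair_out_gp(grm, pairs, shifted)
        assert np.allclose(gp1.values, gp2.values, atol=1e-8)

    def test_scored_subject_in_two_pairs_rejected(self, rng):
        grm = _random_grm(rng, 6)
        ids = grm.subject_ids
        pairs = MatchedPairs(
            pd.DataFrame(
                {"case_id": [ids[0], ids[0]], "control_id": [ids[1], ids[2]], "distance": 0.0}
            )
        )
        with pytest.raises(ValueError, match="exactly one pair"):
            build_leave_pair_out(grm, pairs)

    def test_fewer_than_two_pairs_rejected(self, rng):
        grm = _random_grm(rng, 4)
        pairs = MatchedPairs(
            pd.DataFrame({"case_id": [grm.subject_ids[0]], "control_id": [grm.subject_ids[1]], "distance": 0.0})
        )
        with pytest.raises(ValueError, match="at least 2"):
            build_leave_pair_out(grm, pairs)

    def test_gp_standardized(self, rng):
        grm = _random_grm(rng, 30)
        pairs = _pairs(grm.subject_ids)
        pheno = {s: float(i < 15) for i, s in enumerate(grm.subject_ids)}
        gp = leave_pair_out_gp(grm, pairs, pheno)
        assert gp.values.mean() == pytest.approx(0.0, abs=1e-10)
        assert gp.values.std() == pytest.approx(1.0, abs=1e-10)


def _simulated_gp(h2_sim, h2_fit=0.70, seed=0, n_cases=100, m=800):
    cfg = SimConfig(
        n_cases=n_cases, n_matched_controls=n_cases, n_pool_controls=200,
        k_clusters=2, fst=0.02, m_snps=m, m_causal=m // 5,
        h2=h2_sim, pdv_rate=0.0, seed=seed,
    )
    geno, subjects, truth = simulate_cohort(cfg)
    analysis = subjects[subjects["cohort"] != "pool_control"]
    pairs = pair_within_clusters(analysis)
    pool = geno.subset_subjects(subjects.loc[subjects["cohort"] == "pool_control", "subject_id"])
    est = estimate_frequencies(pool)
    mask = polymorphic_mask(est, pool)
    paired_geno = geno.subset_subjects(pairs.subject_ids())
    kin = compute_grm(paired_geno, "CLS", est, variant_mask=mask)
    status = subjects.set_index("subject_id")["status"]
    gp = leave_pair_out_gp(kin, pairs, status, h2=h2_fit)
    y = status.loc[gp.subject_ids].to_numpy(dtype=float)
    return gp, y


class TestRecoveryProperties:
    def test_case_control_separation_increases_with_h2(self):
        gaps = []
        for h2 in (0.1, 0.4, 0.7):
            diffs = []
            for seed in (1, 2, 3):
                gp, y = _simulated_gp(h2, seed=seed)
                diffs.append(gp.values[y == 1].mean() - gp.values[y == 0].mean())
            gaps.append(np.mean(diffs))
        assert gaps[0] < gaps[2]
        assert gaps[1] < gaps[2] + 0.05  # monotone up to seed noise

    def test_pop_mode_gp_leaks_cluster_signal_cls_reduces_it(self):
        """With cases concentrated in the minor cluster and no true genetic
        signal (h2 ~ 0), pooled-frequency standardization lets ancestry
        leak into GP; cluster-specific standardization damps it."""
        rng = np.random.default_rng(77)
        from polyliab.simdata import draw_structured_frequencies

        m = 1500
        _, clu = draw_structured_frequencies(m, 2, 0.05, 9)
        n_major, n_minor = 160, 40
        n = n_major + n_minor
        clusters = np.array([0] * n_major + [1] * n_minor)
        dose = np.vstack(
            [rng.binomial(2, clu[0], size=(n_major, m)),
             rng.binomial(2, clu[1], size=(n_minor, m))]
        ).astype(float)
        ids = np.array([f"s{i}" for i in range(n)])
        geno = GenotypeMatrix(dose, ids, make_variant_table(m), clusters)
        # phenotype tracks the minor cluster: 75% of minor are cases,
        # 25% of major are cases -> imbalance in the ancestry space
        status = np.zeros(n)
        status[:40] = 1
        status[n_major:][:30] = 1
        # pool drawn separately with the same imbalance
        pool_dose = np.vstack(
            [rng.binomial(2, clu[0], size=(160, m)), rng.binomial(2, clu[1], size=(40, m))]
        ).astype(float)
        pool = GenotypeMatrix(
            pool_dose, np.array([f"p{i}" for i in range(200)]), make_variant_table(m),
            np.array([0] * 160 + [1] * 40),
        )
        est = estimate_frequencies(pool)
        mask = polymorphic_mask(est, pool)
        cases = ids[status == 1]
        ctrls = ids[status == 0][: len(cases)]
        pairs = MatchedPairs(pd.DataFrame({"case_id": cases, "control_id": ctrls, "distance": 0.0}))
        gaps = {}
        for mode in ("POP", "CLS"):
            kin = compute_grm(geno, mode, est, clusters, variant_mask=mask)
            gp = leave_pair_out_gp(kin, pairs, dict(zip(ids, status)))
            lab = np.array([clusters[list(ids).index(s)] for s in gp.subject_ids])
            gaps[mode] = abs(gp.values[lab == 1].mean() - gp.values[lab == 0].mean())
        assert gaps["POP"] > gaps["CLS"]


class TestGenomicControl:
    def test_definition_at_the_null_median(self):
        assert gc_lambda([chi2.ppf(0.5, 1)] * 7) == pytest.approx(1.0, abs=1e-6)

    def test_chi_square_draws_give_unit_lambda(self):
        x = chi2.rvs(1, size=100_000, random_state=3)
        assert gc_lambda(x) == pytest.approx(1.0, abs=0.02)

    def test_scale_equivariance(self):
        x = chi2.rvs(1, size=100_000, random_state=4)
        assert gc_lambda(2 * x) == pytest.approx(2.0, abs=0.04)

    def test_correction_floors_lambda_at_one(self):
        assert gc_correct(4.0, 0.5) == pytest.approx(4.0)
        assert gc_correct(4.0, 2.0) == pytest.approx(2.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            gc_lambda([])

    def test_permutation_null_is_calibrated_after_gc(self, rng):
        """Within-pair label permutations should rarely reject once the
        observed statistic is deflated by the permutation lambda."""
        grm = _random_grm(rng, 60, m=100)  # m << n: strongly overfit, inflated null
        pairs = _pairs(grm.subject_ids)
        op = build_leave_pair_out(grm, pairs)
        status = np.array([1.0] * 30 + [0.0] * 30)
        lam = permutation_gc_lambda(op, status, n_permutations=100, seed=5)
        assert lam > 0
        rejections = 0
        n_rep = 40
        for rep in range(n_rep):
            y = status.copy()
            flip = rng.random(30) < 0.5
            for pidx in np.flatnonzero(flip):
                i, j = op.pair_index[pidx]
                y[i], y[j] = y[j], y[i]
            gp = op.predict_raw(y)
            stat = case_control_chi2((gp - gp.mean()) / gp.std(), y)
            if gc_correct(stat, lam) > chi2.ppf(0.95, 1):
                rejections += 1
        assert rejections / n_rep <= 0.15
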