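"""Empirical-Bayes frequency shrinkage and the three GRM standardizations."""

import numpy as np
import pytest
from scipy import stats as sps

from polyliab.grm import (
    GRM,
    compute_grm,
    estimate_frequencies,
    polymorphic_mask,
    standardize_genotypes,
)
from polyliab.io import GenotypeMatrix, make_variant_table
from polyliab.simdata import draw_structured_frequencies

from conftest import random_genotypes


def _pool_with_counts(counts_by_cluster, n_per_cluster):
    """Pool whose per-cluster allele counts are exactly as requested."""
    cols = []
    clusters = []
    for k, (count, n_k) in enumerate(zip(counts_by_cluster, n_per_cluster)):
        # dosage column realizing `count` alleles over n_k subjects
        twos, rem = divmod(count, 2)
        col = [2.0] * twos + ([1.0] if rem else []) + [0.0] * (n_k - twos - rem)
        cols.append(col)
        clusters += [k] * n_k
    dose = np.concatenate(cols)[:, None]
    ids = np.array([f"s{i}" for i in range(len(dose))])
    return GenotypeMatrix(dose, ids, make_variant_table(1), np.array(clusters))


class TestFrequencyEstimates:
    def test_posterior_mean_matches_beta_binomial_oracle(self):
        # raw cluster 0.30 over n_k = 50 (allele count 30), pooled 0.50,
        # prior strength m = 100: EB = (30 + 100*0.5) / (100 + 100) = 0.40
        pool = _pool_with_counts([30, 70], [50, 50])
        est = estimate_frequencies(pool, prior_strength=100)
        assert est.pooled[0] == pytest.approx(0.5)
        assert est.raw[0, 0] == pytest.approx(0.30)
        # independent oracle: Beta(m*pbar, m*(1-pbar)) prior + binomial count
        a, b = 100 * 0.5, 100 * 0.5
        posterior_mean = (a + 30) / (a + b + 100)
        assert est.eb[0, 0] == pytest.approx(posterior_mean)
        assert est.eb[0, 0] == pytest.approx(0.40)

    def test_single_cluster_no_shrinkage(self, rng):
        geno = random_genotypes(rng, 80, 20)
        geno.clusters = np.zeros(80, dtype=int)
        est = estimate_frequencies(geno)
        assert np.allclose(est.eb[0], est.raw[0])
        assert np.allclose(est.raw[0], est.pooled)

    def test_large_cluster_limit_approaches_raw(self):
        pool = _pool_with_counts([3000, 7000], [5000, 5000])
        est = estimate_frequencies(pool, prior_strength=100)
        assert abs(est.eb[0, 0] - est.raw[0, 0]) < 0.005

    def test_eb_lies_between_raw_and_pooled(self, rng):
        _, clu = draw_structured_frequencies(50, 3, 0.05, 1)
        dose = np.vstack([rng.binomial(2, clu[k], size=(40, 50)) for k in range(3)]).astype(float)
        clusters = np.repeat(np.arange(3), 40)
        pool = GenotypeMatrix(dose, [f"s{i}" for i in range(120)], make_variant_table(50), clusters)
        est = estimate_frequencies(pool)
        lo = np.minimum(est.raw, est.pooled) - 1e-9
        hi = np.maximum(est.raw, est.pooled) + 1e-9
        inside = (est.eb >= lo) & (est.eb <= hi)
        assert inside.all()

    def test_empty_pool_rejected(self):
        geno = GenotypeMatrix(np.empty((0, 2)), [], make_variant_table(2))
        with pytest.raises(ValueError):
            estimate_frequencies(geno)

    def test_all_missing_variant_rejected(self, rng):
        geno = random_genotypes(rng, 10, 3)
        geno.dosages[:, 1] = np.nan
        with pytest.raises(ValueError, match="missing in every pool subject"):
            estimate_frequencies(geno)


class TestStandardization:
    def test_centering_and_closed_form(self, rng):
        geno = random_genotypes(rng, 40, 5)
        geno.clusters = np.zeros(40, dtype=int)
        est = estimate_frequencies(geno)
        z = standardize_genotypes(geno, est, "POP")
        p = est.pooled
        # x = 2 maps to (2 - 2p)/sqrt(2p(1-p))
        manual = (2.0 - 2 * p) / np.sqrt(2 * p * (1 - p))
        i, j = np.argwhere(geno.dosages == 2.0)[0]
        assert z[i, j] == pytest.approx(manual[j])

    def test_exact_centering_at_2p(self):
        pool = _pool_with_counts([50], [50])  # p = 0.5
        est = estimate_frequencies(pool)
        geno = GenotypeMatrix([[1.0]], ["a"], make_variant_table(1), np.array([0]))
        z = standardize_genotypes(geno, est, "CLS")
        assert z[0, 0] == pytest.approx(0.0)

    def test_missing_dosage_standardizes_to_zero(self, rng):
        geno = random_genotypes(rng, 30, 4)
        est = estimate_frequencies(geno)
        geno2 = GenotypeMatrix(geno.dosages.copy(), geno.subject_ids, geno.variants)
        geno2.dosages[3, 2] = np.nan
        z = standardize_genotypes(geno2, est, "POP")
        assert z[3, 2] == pytest.approx(0.0)

    def test_cls_column_means_near_zero_per_cluster(self, rng):
        _, clu = draw_structured_frequencies(300, 2, 0.1, 5)
        dose = np.vstack([rng.binomial(2, clu[k], size=(300, 300)) for k in range(2)]).astype(float)
        clusters = np.repeat([0, 1], 300)
        pool = GenotypeMatrix(dose, [f"s{i}" for i in range(600)], make_variant_table(300), clusters)
        est = estimate_frequencies(pool)
        z = standardize_genotypes(pool, est, "CLS")
        for k in (0, 1):
            assert np.abs(z[clusters == k].mean(axis=0)).mean() < 0.05


class TestGRMConstruction:
    def test_duplicate_subject_offdiagonal_matches_diagonal(self, rng):
        geno = random_genotypes(rng, 30, 500)
        geno.dosages[1] = geno.dosages[0]
        geno.clusters = np.zeros(30, dtype=int)
        est = estimate_frequencies(geno)
        # POP diagonal is the plain cross-product, so the identity is exact
        a = compute_grm(geno, "POP", est).matrix
        assert a[0, 1] == pytest.approx(a[0, 0], abs=1e-12)
        # STD's method-of-moments diagonal only agrees in expectation
        a_std = compute_grm(geno, "STD").matrix
        assert a_std[0, 1] == pytest.approx(a_std[0, 0], rel=0.15)

    def test_hwe_single_population_moments(self, rng):
        geno = random_genotypes(rng, 100, 10_000)
        a = compute_grm(geno, "STD").matrix
        off = a[~np.eye(100, dtype=bool)]
        # in-sample frequency centering forces the off-diagonal mean to
        # about -1/(n-1); unrelatedness means "zero up to that artifact"
        assert off.mean() == pytest.approx(-1 / 99, abs=0.005)
        assert np.diag(a).mean() == pytest.approx(1.0, abs=0.02)

    def test_std_formula_matches_direct_oracle(self, rng):
        geno = random_genotypes(rng, 12, 40)
        a = compute_grm(geno, "STD").matrix
        x = geno.dosages
        p = x.mean(axis=0) / 2
        het = 2 * p * (1 - p)
        n = 12
        oracle = np.empty((n, n))
        for j in range(n):
            for k in range(n):
                if j == k:
                    oracle[j, j] = 1 + np.mean(
                        (x[j] ** 2 - (1 + 2 * p) * x[j] + 2 * p**2) / het
                    )
                else:
                    oracle[j, k] = np.mean((x[j] - 2 * p) * (x[k] - 2 * p) / het)
        assert np.allclose(a, oracle, atol=1e-10)

    def test_positive_semidefinite_when_overdetermined(self, rng):
        geno = random_genotypes(rng, 40, 400)
        for mode in ("STD",):
            a = compute_grm(geno, mode).matrix
            # STD's diagonal correction can break PSD slightly; check the
            # cross-product modes strictly below
            assert np.linalg.eigvalsh(a).min() > -0.1
        geno.clusters = np.zeros(40, dtype=int)
        est = estimate_frequencies(geno)
        mask = polymorphic_mask(est, geno)
        for mode in ("CLS", "POP"):
            a = compute_grm(geno, mode, est, variant_mask=mask).matrix
            assert np.linalg.eigvalsh(a).min() > -1e-8

    def test_single_cluster_cls_equals_pop(self, rng):
        geno = random_genotypes(rng, 50, 200)
        geno.clusters = np.zeros(50, dtype=int)
        est = estimate_frequencies(geno)
        a_cls = compute_grm(geno, "CLS", est).matrix
        a_pop = compute_grm(geno, "POP", est).matrix
        assert np.allclose(a_cls, a_pop)

    def test_invariant_to_subject_permutation(self, rng):
        geno = random_genotypes(rng, 25, 100)
        a = compute_grm(geno, "STD").matrix
        perm = rng.permutation(25)
        geno_p = GenotypeMatrix(geno.dosages[perm], geno.subject_ids[perm], geno.variants)
        a_p = compute_grm(geno_p, "STD").matrix
        assert np.allclose(a_p, a[np.ix_(perm, perm)], atol=1e-12)

    def test_pop_mode_biased_within_minor_cluster_cls_not(self, rng):
        """Pooled-frequency standardization inflates within-minor-cluster
        relatedness when one cluster dominates the pool; cluster-specific
        frequencies remove the bias (small-scale version)."""
        f, m = 0.05, 2000
        _, clu = draw_structured_frequencies(m, 2, f, 17)
        n_major, n_minor = 150, 50
        dose = np.vstack(
            [rng.binomial(2, clu[0], size=(n_major, m)), rng.binomial(2, clu[1], size=(n_minor, m))]
        ).astype(float)
        clusters = np.array([0] * n_major + [1] * n_minor)
        pool = GenotypeMatrix(dose, [f"s{i}" for i in range(200)], make_variant_table(m), clusters)
        est = estimate_frequencies(pool)
        mask = polymorphic_mask(est, pool)
        a_pop = compute_grm(pool, "POP", est, variant_mask=mask).matrix
        a_cls = compute_grm(pool, "CLS", est, variant_mask=mask).matrix
        minor = clusters == 1
        tri = np.triu(np.ones((200, 200), dtype=bool), 1)
        sel = tri & np.outer(minor, minor)
        assert a_pop[sel].mean() > a_cls[sel].mean() + 0.01
        assert abs(a_cls[sel].mean()) < 0.02

    def test_zero_usable_variants_rejected(self):
        geno = GenotypeMatrix(
            np.full((5, 2), 2.0), [f"s{i}" for i in range(5)], make_variant_table(2)
        )
        with pytest.raises(ValueError):
            compute_grm(geno, "STD")


class TestGRMIO:
    def test_gcta_triplet_roundtrip(self, rng, tmp_path):
        geno = random_genotypes(rng, 15, 60)
        a = compute_grm(geno, "STD")
        a.save(tmp_path / "k")
        b = GRM.load(tmp_path / "k")
        assert np.allclose(a.matrix, b.matrix, atol=1e-6)  # float32 storage
        assert np.array_equal(a.subject_ids, b.subject_ids)
        assert b.m_variants == a.m_variants
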