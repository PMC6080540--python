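"""Hypothesis tests: frozen oracle values, enumeration oracles, null calibration."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gutmwas.containers import CohortMetadata, DistanceMatrix, RelAbundanceMatrix
from gutmwas.diversity import jsd_matrix
from gutmwas.simulate import CohortConfig, simulate_cohort
from gutmwas.stats import (
    DifferentialAbundanceModel,
    bh_adjust,
    chi_square_test,
    fisher_exact_2x2,
    permanova,
    spearman,
    t_test_from_summary,
    wilcoxon_rank_sum,
)

from conftest import random_abundance


class TestWilcoxon:
    def test_exact_enumeration_value(self):
        # all 20 assignments of 6 values into groups of 3: extreme split -> 2/20
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_multisets_exact_p_one(self):
        assert wilcoxon_rank_sum([1, 2, 3], [1, 2, 3], mode="exact") == 1.0

    def test_matches_full_enumeration_small_n(self, rng):
        values = rng.normal(size=9)
        x, y = values[:4], values[4:]
        p = wilcoxon_rank_sum(x, y)
        # enumeration oracle: rank-sum tail probability over all C(9,4) splits
        ranks = sps.rankdata(values)
        obs = ranks[:4].sum()
        all_sums = [sum(ranks[list(c)]) for c in itertools.combinations(range(9), 4)]
        mean = np.mean(all_sums)
        tail = np.mean([abs(s - mean) >= abs(obs - mean) - 1e-12 for s in all_sums])
        assert p == pytest.approx(tail, abs=1e-12)

    def test_null_p_distribution_uniform(self):
        rng = np.random.default_rng(5)
        ps = [
            wilcoxon_rank_sum(rng.normal(size=30), rng.normal(size=30))
            for _ in range(500)
        ]
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestBH:
    def test_hand_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.3, 0.3, 0.3]), 0.3)

    def test_single_p_identity(self):
        assert bh_adjust([0.123])[0] == pytest.approx(0.123)

    def test_permutation_invariance_and_q_ge_p(self, rng):
        p = rng.random(40)
        q = bh_adjust(p)
        perm = rng.permutation(40)
        np.testing.assert_allclose(bh_adjust(p[perm]), q[perm], atol=1e-14)
        assert np.all(q >= p - 1e-14)
        assert np.all(q <= 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestSummaryTests:
    """Demographic-table statistics recomputed from printed group summaries."""

    def test_chi_square_premenopausal_ethnicity(self):
        stat, df, p = chi_square_test([[12, 20], [5, 4], [1, 1]])
        assert df == 2
        assert p == pytest.approx(0.607, abs=5e-4)

    def test_chi_square_postmenopausal_ethnicity(self):
        _, _, p = chi_square_test([[33, 34], [8, 9], [3, 3]])
        assert p == pytest.approx(0.985, abs=5e-4)

    def test_chi_square_identical_proportions(self):
        stat, _, p = chi_square_test([[10, 20], [5, 10]])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_chi_square_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_test([[0, 0], [3, 4]])

    def test_pooled_t_postmenopausal_age(self):
        p = t_test_from_summary(57.45, 7.41, 44, 56.89, 6.41, 46, "pooled")
        assert p == pytest.approx(0.702, abs=5e-3)

    def test_welch_t_premenopausal_bmi(self):
        p = t_test_from_summary(22.95, 3.88, 18, 23.01, 1.95, 25, "welch")
        assert p == pytest.approx(0.952, abs=5e-3)

    def test_equal_means_p_one(self):
        assert t_test_from_summary(5, 1, 10, 5, 1, 10) == pytest.approx(1.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            t_test_from_summary(1, 0.0, 10, 2, 1, 10)
        with pytest.raises(ValueError):
            t_test_from_summary(1, 1, 1, 2, 1, 10)


class TestFisher:
    def test_diagonal_table(self):
        assert fisher_exact_2x2([[5, 0], [0, 5]]) == pytest.approx(
            0.0079365, abs=1e-6
        )

    def test_balanced_table_p_one(self):
        assert fisher_exact_2x2([[1, 1], [1, 1]]) == 1.0

    def test_matches_hypergeometric_enumeration(self, rng):
        for _ in range(10):
            t = rng.integers(0, 8, size=(2, 2))
            if t.sum() == 0:
                continue
            p = fisher_exact_2x2(t)
            # enumerate all tables with the same margins
            r1, r2 = t.sum(axis=1)
            c1, _ = t.sum(axis=0)
            n = t.sum()
            p_obs = sps.hypergeom.pmf(t[0, 0], n, r1, c1)
            total = sum(
                sps.hypergeom.pmf(a, n, r1, c1)
                for a in range(max(0, c1 - r2), min(r1, c1) + 1)
                if sps.hypergeom.pmf(a, n, r1, c1) <= p_obs * (1 + 1e-9)
            )
            assert p == pytest.approx(min(total, 1.0), abs=1e-9)


class TestSpearman:
    def test_monotone_rho_one(self):
        rho, _ = spearman([1, 2, 3, 4, 5], [10, 20, 25, 50, 100])
        assert rho == pytest.approx(1.0)

    def test_hand_formula(self):
        rho, _ = spearman([1, 2, 3, 4], [1, 3, 2, 4])
        assert rho == pytest.approx(0.8)

    def test_reversal_rho_minus_one(self):
        rho, _ = spearman([1, 2, 3, 4], [4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_pairwise_deletion(self):
        rho, _ = spearman([1, 2, 3, 4, np.nan], [1, 3, 2, 4, 100.0])
        assert rho == pytest.approx(0.8)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError, match="4"):
            spearman([1, 2, np.nan, np.nan], [1, 2, 3, 4])


class TestPermanova:
    def test_matches_brute_force_f(self, rng):
        m = random_abundance(rng, 12, 10)
        dist = jsd_matrix(m)
        labels = np.array(["a"] * 4 + ["b"] * 6)
        res = permanova(dist, labels, n_perm=99, seed=0)
        # direct two-loop computation of the pseudo-F
        d2 = dist.values ** 2
        n = 10
        ss_tot = sum(d2[i, j] for i in range(n) for j in range(i + 1, n)) / n
        ss_w = 0.0
        for g in ("a", "b"):
            idx = [i for i in range(n) if labels[i] == g]
            ss_w += sum(
                d2[i, j] for i in idx for j in idx if i < j
            ) / len(idx)
        f = ((ss_tot - ss_w) / 1) / (ss_w / (n - 2))
        assert res.pseudo_F == pytest.approx(f, abs=1e-10)
        assert res.R2 == pytest.approx((ss_tot - ss_w) / ss_tot, abs=1e-10)

    def test_matches_skbio(self, rng):
        skbio = pytest.importorskip("skbio")
        m = random_abundance(rng, 15, 12)
        dist = jsd_matrix(m)
        labels = ["a"] * 5 + ["b"] * 7
        res = permanova(dist, np.array(labels), n_perm=99, seed=0)
        sk = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(np.ascontiguousarray(dist.values),
                                 ids=dist.sample_ids),
            grouping=labels, permutations=99,
        )
        assert res.pseudo_F == pytest.approx(sk["test statistic"], rel=1e-9)

    def test_duplicated_points_enumeration(self):
        # two pairs of identical points, groups split across the pairs:
        # only 3 distinct label splits exist, the observed F is maximal -> p=1/3
        d = np.array(
            [[0, 0, 1, 1], [0, 0, 1, 1], [1, 1, 0, 0], [1, 1, 0, 0]], dtype=float
        )
        ids = list("abcd")
        dist = DistanceMatrix(pd.DataFrame(d, index=ids, columns=ids))
        res = permanova(dist, np.array(["g1", "g1", "g2", "g2"]),
                        n_perm=2999, seed=1)
        assert res.p_value == pytest.approx(1 / 3, abs=0.03)

    def test_null_p_uniformity(self, rng):
        m = random_abundance(rng, 10, 16)
        dist = jsd_matrix(m)
        ps = []
        for seed in range(60):
            labels = np.random.default_rng(seed).permutation(
                ["a"] * 8 + ["b"] * 8
            )
            ps.append(permanova(dist, labels, n_perm=99, seed=seed).p_value)
        assert sps.kstest(ps, "uniform").pvalue > 0.005

    def test_label_length_mismatch(self, rng):
        m = random_abundance(rng, 5, 6)
        with pytest.raises(ValueError):
            permanova(jsd_matrix(m), np.array(["a", "b"]), n_perm=99)


class TestDifferentialAbundance:
    def test_spiked_species_recovered(self, small_cohort):
        res = DifferentialAbundanceModel(
            small_cohort.species, small_cohort.metadata
        ).fit()
        sig = set(res.significant.index)
        truth = set(small_cohort.truth.diff_species)
        assert len(sig & truth) / len(truth) >= 0.9
        assert len(sig - truth) / max(len(sig), 1) <= 0.1

    def test_directions_match_truth(self, small_cohort):
        res = DifferentialAbundanceModel(
            small_cohort.species, small_cohort.metadata
        ).fit()
        sig = res.significant
        for feat, d in small_cohort.truth.diff_species.items():
            if feat in sig.index:
                expected = "enriched_in_case" if d > 0 else "enriched_in_control"
                assert sig.loc[feat, "direction"] == expected

    def test_null_cohort_no_q_hits(self):
        cohort = simulate_cohort(
            CohortConfig(seed=2, n_case=30, n_control=30, n_species=150,
                         effect_size=1.0)
        )
        res = DifferentialAbundanceModel(cohort.species, cohort.metadata).fit()
        assert len(res.significant) <= 2  # BH controls FDR; near zero under null

    def test_gene_level_pathway_restriction(self, small_cohort):
        """Differential testing restricted to one pathway's genes reports
        direction counts, mirroring a butyrate-gene style analysis."""
        genes = small_cohort.genes
        subset = genes.select_features(genes.feature_ids[:40])
        res = DifferentialAbundanceModel(subset, small_cohort.metadata).fit()
        counts = res.significant["direction"].value_counts()
        assert set(counts.index) <= {"enriched_in_case", "enriched_in_control"}

    def test_one_group_missing_errors(self, small_cohort):
        meta = small_cohort.metadata
        cases = meta.subset(meta.samples_in(group="case"))
        with pytest.raises(ValueError):
            DifferentialAbundanceModel(small_cohort.species, cases)
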