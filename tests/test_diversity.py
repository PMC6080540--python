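"""Alpha/beta diversity: closed-form identities, oracle checks, invariants."""

import itertools
import math

import numpy as np
import pytest

from gutmwas.containers import DistanceMatrix, RelAbundanceMatrix
from gutmwas.diversity import (
    alpha_diversity_table,
    chao1,
    jsd,
    jsd_matrix,
    mean_within_group_jsd,
    rarefaction_curve,
    richness,
    shannon_index,
)

import pandas as pd

from conftest import random_abundance


class TestShannonRichness:
    def test_uniform_closed_form(self):
        assert shannon_index([0.25] * 4) == pytest.approx(math.log(4))

    def test_single_species_zero(self):
        assert shannon_index([1.0, 0, 0]) == 0.0

    def test_direct_formula(self):
        assert shannon_index([0.5, 0.25, 0.25]) == pytest.approx(1.0397, abs=1e-4)

    def test_renormalization_invariance(self, rng):
        p = rng.random(10)
        assert shannon_index(p) == pytest.approx(shannon_index(5.0 * p), abs=1e-12)

    def test_log_base_option(self):
        assert shannon_index([0.25] * 4, base=2) == pytest.approx(2.0)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            shannon_index([0.0, 0.0])

    @pytest.mark.parametrize(
        "p,threshold,expected",
        [([0.5, 0.5, 0], 0.0, 2), ([0, 0, 0], 0.0, 0), ([1e-7, 2e-6], 1e-6, 1)],
    )
    def test_richness(self, p, threshold, expected):
        assert richness(p, threshold) == expected


class TestChao1:
    def test_direct_formula(self):
        # 10 observed species, 4 singletons, 2 doubletons
        counts = [1] * 4 + [2] * 2 + [5] * 4
        assert chao1(counts) == pytest.approx(14.0)

    def test_no_singletons_equals_observed(self):
        assert chao1([3, 4, 2, 2]) == 4.0

    def test_bias_corrected_branch(self):
        counts = [1, 1, 1, 4, 5]  # F1=3, F2=0, S_obs=5
        assert chao1(counts) == pytest.approx(8.0)

    def test_non_integer_rejected_with_guidance(self):
        with pytest.raises(ValueError, match="multinomial"):
            chao1([0.5, 0.25])

    def test_at_least_observed_richness(self, rng):
        for _ in range(20):
            counts = rng.integers(0, 6, size=30)
            assert chao1(counts) >= (counts > 0).sum()


class TestRarefaction:
    def test_full_depth_exact_richness(self):
        counts = [3, 0, 2, 5]
        curve = rarefaction_curve(counts, [10])
        assert curve["mean_features"].iloc[0] == 3.0

    def test_depth_one(self):
        curve = rarefaction_curve([4, 4], [1], n_repeats=5)
        assert curve["mean_features"].iloc[0] == 1.0

    def test_depth_exceeding_total_errors(self):
        with pytest.raises(ValueError, match="depth"):
            rarefaction_curve([2, 2], [5])

    def test_matches_hypergeometric_enumeration(self):
        # E[#detected at depth d] = sum_f 1 - C(N - c_f, d)/C(N, d)
        counts = [3, 2, 1]
        expected = sum(
            1 - math.comb(6 - c, 3) / math.comb(6, 3) for c in counts
        )  # = 2.25
        curve = rarefaction_curve(counts, [3], n_repeats=4000, seed=0)
        assert curve["mean_features"].iloc[0] == pytest.approx(expected, abs=0.05)

    def test_monotone_in_depth(self):
        counts = [5, 3, 2, 1, 1]
        curve = rarefaction_curve(counts, [2, 6, 12], n_repeats=500, seed=1)
        means = curve["mean_features"].to_numpy()
        assert means[0] <= means[1] + 0.1 and means[1] <= means[2] + 0.1


class TestJSD:
    def test_self_divergence_zero(self, rng):
        p = rng.random(6)
        assert jsd(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_ln2(self):
        assert jsd([1, 0], [0, 1]) == pytest.approx(math.log(2))

    def test_hand_evaluation(self):
        assert jsd([0.5, 0.5, 0], [0, 0.5, 0.5]) == pytest.approx(
            math.log(2) / 2, abs=1e-12
        )

    def test_symmetry_and_bounds(self, rng):
        for _ in range(20):
            p, q = rng.random(8), rng.random(8)
            v = jsd(p, q)
            assert v == pytest.approx(jsd(q, p), abs=1e-12)
            assert 0.0 <= v <= math.log(2)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            jsd([0.5, 0.5], [1.0])

    def test_matrix_consistent_with_pairwise(self, rng):
        m = random_abundance(rng, 6, 3)
        dist = jsd_matrix(m)
        for i, j in itertools.combinations(range(3), 2):
            assert dist.values[i, j] == pytest.approx(
                jsd(m.values[:, i], m.values[:, j]), abs=1e-12
            )

    def test_duplicated_columns_zero(self):
        m = RelAbundanceMatrix.from_arrays(
            [[0.6, 0.6], [0.4, 0.4]], ["a", "b"], ["s1", "s2"]
        )
        assert jsd_matrix(m).values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_sqrt_jsd_triangle_inequality(self, rng):
        m = random_abundance(rng, 10, 6)
        d = jsd_matrix(m, sqrt=True).values
        for i, j, k in itertools.permutations(range(6), 3):
            assert d[i, k] <= d[i, j] + d[j, k] + 1e-12

    def test_single_sample_errors(self):
        m = RelAbundanceMatrix.from_arrays([[1.0]], ["a"], ["s1"])
        with pytest.raises(ValueError):
            jsd_matrix(m)


class TestMeanWithinGroupJSD:
    def test_identical_samples_zero(self):
        m = RelAbundanceMatrix.from_arrays(
            np.tile([[0.7], [0.3]], (1, 4)), ["a", "b"], [f"s{i}" for i in range(4)]
        )
        beta = mean_within_group_jsd(jsd_matrix(m), ["g1", "g1", "g1", "g1"])
        np.testing.assert_allclose(beta["mean_within_group_jsd"], 0.0, atol=1e-12)

    def test_three_sample_hand_computation(self):
        d = np.array([[0, 0.2, 0.4], [0.2, 0, 0.6], [0.4, 0.6, 0]])
        dm = DistanceMatrix(pd.DataFrame(d, index=list("abc"), columns=list("abc")))
        beta = mean_within_group_jsd(dm, ["g", "g", "g"])
        assert beta.loc["a", "mean_within_group_jsd"] == pytest.approx(0.3)

    def test_matches_brute_force(self, rng):
        m = random_abundance(rng, 8, 10)
        dist = jsd_matrix(m)
        groups = ["g1"] * 4 + ["g2"] * 6
        beta = mean_within_group_jsd(dist, groups)
        for i, sid in enumerate(dist.sample_ids):
            peers = [j for j in range(10) if groups[j] == groups[i] and j != i]
            expected = np.mean([dist.values[i, j] for j in peers])
            assert beta.loc[sid, "mean_within_group_jsd"] == pytest.approx(
                expected, abs=1e-12
            )

    def test_singleton_group_named_in_error(self, rng):
        m = random_abundance(rng, 5, 3)
        with pytest.raises(ValueError, match="lonely"):
            mean_within_group_jsd(jsd_matrix(m), ["g", "g", "lonely"])


class TestDirectionalProperty:
    def test_case_richness_exceeds_controls_when_cases_spiked(self, small_cohort):
        """Cases carry extra rare species mass, so mean richness/Chao1 is higher."""
        from gutmwas.simulate import multinomial_counts

        counts = multinomial_counts(small_cohort.species, 50_000, seed=0)
        alpha = alpha_diversity_table(small_cohort.species, counts,
                                      detection_threshold=1e-6)
        meta = small_cohort.metadata
        case = alpha.loc[meta.samples_in(group="case")]
        ctrl = alpha.loc[meta.samples_in(group="control")]
        assert case["richness"].mean() > ctrl["richness"].mean() - 2
        assert case["chao1"].mean() > 0 and ctrl["chao1"].mean() > 0
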