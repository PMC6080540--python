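"""Random-forest marker selection, ROC/AUC oracles and probability cutoffs."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from gutmwas.markers import (
    assign_case_status,
    cv_case_probabilities,
    cv_feature_elimination,
    roc_auc,
    transfer_test,
)
from gutmwas.simulate import CohortConfig, simulate_cohort

from conftest import random_abundance

N_TREES = 200  # forest size used throughout the tests; AUC is stable beyond ~100


class TestAuc:
    def test_pair_counting_example(self):
        auc, _ = roc_auc([0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0])
        assert auc == pytest.approx(75.0)

    def test_perfect_separation(self):
        auc, ci = roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert auc == 100.0
        assert ci[0] <= 100.0 <= ci[1]

    def test_label_inversion_symmetry(self, rng):
        p = rng.random(30)
        y = rng.integers(0, 2, 30)
        if len(np.unique(y)) < 2:
            y[0] = 1 - y[0]
        a1, _ = roc_auc(p, y)
        a2, _ = roc_auc(p, 1 - y)
        assert a1 + a2 == pytest.approx(100.0)

    def test_matches_brute_force_and_sklearn(self, rng):
        for _ in range(10):
            p = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=25)  # force ties
            y = rng.integers(0, 2, 25)
            if len(np.unique(y)) < 2:
                continue
            auc, _ = roc_auc(p, y)
            pos, neg = p[y == 1], p[y == 0]
            pairs = sum(
                1.0 if a > b else 0.5 if a == b else 0.0
                for a in pos for b in neg
            )
            assert auc == pytest.approx(100 * pairs / (len(pos) * len(neg)))
            assert auc == pytest.approx(100 * roc_auc_score(y, p))

    def test_ci_contains_auc(self, rng):
        p = rng.random(40)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        auc, (lo, hi) = roc_auc(p, y)
        assert lo <= auc <= hi

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc([0.5, 0.6], [1, 1])


class TestCaseCalls:
    @pytest.mark.parametrize(
        "p,call",
        [(0.60, "Case"), (0.40, "Uncertain"), (0.35, "Uncertain"),
         (0.50, "Uncertain"), (0.34, "NotCase"), (0.51, "Case")],
    )
    def test_cutoffs(self, p, call):
        out = assign_case_status([p])
        assert out["call"].iloc[0] == call

    def test_series_index_preserved(self):
        probs = pd.Series([0.9, 0.1], index=["sA", "sB"])
        out = assign_case_status(probs)
        assert list(out.index) == ["sA", "sB"]
        assert out.loc["sA", "call"] == "Case"

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            assign_case_status([1.2])


class TestFeatureElimination:
    def test_separable_cohort_recovers_markers(self):
        cohort = simulate_cohort(
            CohortConfig(seed=4, n_diff_species=14, effect_size=8.0)
        )
        y = cohort.metadata.group.to_numpy()
        curve, n_opt, ranked = cv_feature_elimination(
            cohort.species, y, n_repeats=2, seed=0, n_trees=N_TREES
        )
        opt_err = curve.loc[curve["n_features"] == n_opt, "mean_error"].iloc[0]
        assert opt_err <= 0.1
        truth = set(cohort.truth.diff_species)
        overlap = len(set(ranked[:n_opt]) & truth) / len(truth)
        assert overlap >= 0.7

    def test_one_se_rule_never_exceeds_minimizer(self, rng):
        cohort = simulate_cohort(
            CohortConfig(seed=6, n_case=15, n_control=15, n_species=40,
                         n_diff_species=6, effect_size=6.0)
        )
        y = cohort.metadata.group.to_numpy()
        curve, n_opt, _ = cv_feature_elimination(
            cohort.species, y, n_repeats=2, seed=1, n_trees=N_TREES
        )
        minimizer = curve.loc[curve["mean_error"].idxmin(), "n_features"]
        assert n_opt <= minimizer

    def test_pure_noise_error_near_half(self):
        cohort = simulate_cohort(
            CohortConfig(seed=8, n_case=15, n_control=15, n_species=40,
                         effect_size=1.0, n_diff_species=0)
        )
        y = cohort.metadata.group.to_numpy()
        curve, _, _ = cv_feature_elimination(
            cohort.species, y, n_repeats=2, seed=2, n_trees=N_TREES
        )
        assert np.all(np.abs(curve["mean_error"] - 0.5) <= 0.25)

    def test_deterministic_under_seed(self, small_cohort):
        y = small_cohort.metadata.group.to_numpy()
        a = cv_feature_elimination(small_cohort.species, y, n_repeats=1,
                                   seed=3, n_trees=50)
        b = cv_feature_elimination(small_cohort.species, y, n_repeats=1,
                                   seed=3, n_trees=50)
        pd.testing.assert_frame_equal(a[0], b[0])
        assert a[1] == b[1] and a[2] == b[2]

    def test_single_class_errors(self, small_cohort):
        with pytest.raises(ValueError):
            cv_feature_elimination(small_cohort.species,
                                   ["case"] * small_cohort.species.n_samples)


class TestCaseProbabilities:
    def test_separable_cohort_probabilities(self):
        cohort = simulate_cohort(
            CohortConfig(seed=2, n_case=22, n_control=22, n_species=50,
                         n_diff_species=12, effect_size=16.0)
        )
        y = cohort.metadata.group.to_numpy()
        probs = cv_case_probabilities(cohort.species, y, n_repeats=2,
                                      seed=0, n_trees=N_TREES)
        case_mean = probs[y == "case"].mean()
        ctrl_mean = probs[y == "control"].mean()
        assert case_mean > 0.8 and ctrl_mean < 0.2

    def test_permuted_labels_center_on_prevalence(self, small_cohort):
        rng = np.random.default_rng(1)
        y = rng.permutation(small_cohort.metadata.group.to_numpy())
        probs = cv_case_probabilities(small_cohort.species, y, n_repeats=2,
                                      seed=0, n_trees=N_TREES)
        assert abs(probs.mean() - 0.5) < 0.15

    def test_deterministic_under_seed(self, small_cohort):
        y = small_cohort.metadata.group.to_numpy()
        a = cv_case_probabilities(small_cohort.species, y, n_repeats=1,
                                  seed=5, n_trees=50)
        b = cv_case_probabilities(small_cohort.species, y, n_repeats=1,
                                  seed=5, n_trees=50)
        pd.testing.assert_series_equal(a, b)

    def test_missing_selected_feature_errors(self, small_cohort):
        with pytest.raises(ValueError, match="absent"):
            cv_case_probabilities(small_cohort.species,
                                  small_cohort.metadata.group.to_numpy(),
                                  selected_features=["no_such_species"])


class TestTransfer:
    def test_same_process_transfers(self):
        train = simulate_cohort(CohortConfig(seed=10, population_seed=99,
                                             n_case=25, n_control=25,
                                             n_species=80, n_diff_species=10,
                                             effect_size=6.0))
        test = simulate_cohort(CohortConfig(seed=11, population_seed=99,
                                            n_case=18, n_control=25,
                                            n_species=80, n_diff_species=10,
                                            effect_size=6.0))
        markers = list(train.truth.diff_species)
        ytr = train.metadata.group.to_numpy()
        yte = test.metadata.group.to_numpy()
        _, auc, ci = transfer_test(markers, train.species, ytr,
                                   test.species, yte, n_trees=N_TREES)
        assert auc > 80.0
        assert ci[0] <= auc <= ci[1]

    def test_permuted_test_labels_null_auc(self, small_cohort):
        rng = np.random.default_rng(3)
        markers = list(small_cohort.truth.diff_species)
        y = small_cohort.metadata.group.to_numpy()
        yperm = rng.permutation(y)
        _, auc, _ = transfer_test(markers, small_cohort.species, y,
                                  small_cohort.species, yperm, n_trees=N_TREES)
        assert abs(auc - 50.0) < 20.0

    def test_missing_marker_listed(self, small_cohort):
        y = small_cohort.metadata.group.to_numpy()
        with pytest.raises(ValueError, match="ghost_species"):
            transfer_test(["ghost_species"], small_cohort.species, y,
                          small_cohort.species, y)
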