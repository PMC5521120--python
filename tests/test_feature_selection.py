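import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from afseq.feature_selection import (
    FeatureSubset,
    GAParams,
    class_entropy,
    discretize,
    ga_wrapper_select,
    ig_filter,
    information_gain,
    redundancy_reduce,
    spearman_matrix,
)
from afseq.matrix import DescriptorMatrix


def brute_force_ig(binned, labels):
    """Independent contingency-table oracle: IG = H(X) - H(X|Y), base 2."""
    n = len(labels)

    def entropy(counts):
        return -sum(c / n_ * math.log2(c / n_)
                    for n_ in [sum(counts)] for c in counts if c > 0)

    h_x = entropy(list(Counter(labels).values()))
    cond = 0.0
    for bin_id, n_y in Counter(binned).items():
        sub = [labels[i] for i in range(n) if binned[i] == bin_id]
        cond += (n_y / n) * entropy(list(Counter(sub).values()))
    return h_x - cond


def _matrix(columns: dict[str, list[float]], labels) -> DescriptorMatrix:
    df = pd.DataFrame(columns, index=[f"i{k}" for k in range(len(labels))], dtype=float)
    return DescriptorMatrix(df, np.array(labels, dtype=int))


class TestDiscretize:
    def test_median_split(self):
        bins = discretize(np.arange(1, 11, dtype=float), n_bins=2)
        assert bins.tolist() == [0] * 5 + [1] * 5

    def test_constant_column_single_bin(self):
        assert set(discretize(np.full(8, 3.0)).tolist()) == {0}

    def test_tied_values_share_one_bin(self):
        bins = discretize(np.array([1, 1, 1, 1, 2, 2, 2, 2], dtype=float), n_bins=2)
        assert bins.tolist() == [0, 0, 0, 0, 1, 1, 1, 1]

    def test_empty_column_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            discretize(np.array([]))

    def test_order_independent(self):
        v = np.array([5.0, 1.0, 3.0, 2.0, 4.0, 6.0])
        perm = np.array([3, 0, 5, 1, 4, 2])
        assert np.array_equal(discretize(v, 3)[perm], discretize(v[perm], 3))


class TestInformationGain:
    def test_perfect_separator_reaches_class_entropy(self):
        res = information_gain(np.array([0, 0, 1, 1]), np.array([1, 1, 0, 0]))
        assert res.ig == pytest.approx(1.0)
        assert res.class_entropy == pytest.approx(1.0)

    def test_independent_feature_has_zero_gain(self):
        res = information_gain(np.array([0, 1, 0, 1]), np.array([1, 1, 0, 0]))
        assert res.ig == pytest.approx(0.0, abs=1e-12)

    def test_benchmark_class_entropy(self):
        # 691 enzymes vs 487 non-enzymes
        y = np.r_[np.ones(691, dtype=int), np.zeros(487, dtype=int)]
        res = information_gain(np.zeros(1178, dtype=int), y)
        assert res.class_entropy == pytest.approx(0.9784, abs=1e-3)
        assert res.ig == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_bruteforce_contingency_oracle(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(4, 40))
        binned = rng.integers(0, 4, size=n)
        labels = rng.integers(0, 2, size=n)
        if len(set(labels.tolist())) < 2:
            labels[0] = 1 - labels[0]
        res = information_gain(binned, labels)
        assert res.ig == pytest.approx(brute_force_ig(binned.tolist(), labels.tolist()),
                                       abs=1e-12)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.integers(0, 10_000))
    def test_invariant_under_bin_relabeling_and_label_swap(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        binned = rng.integers(0, 5, size=n)
        labels = rng.integers(0, 2, size=n)
        base = information_gain(binned, labels).ig
        relabeled = (4 - binned)  # bijective relabeling of the bins
        assert information_gain(relabeled, labels).ig == pytest.approx(base, abs=1e-12)
        assert information_gain(binned, 1 - labels).ig == pytest.approx(base, abs=1e-12)

    def test_ig_bounded_by_class_entropy(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            binned = rng.integers(0, 6, size=25)
            labels = rng.integers(0, 2, size=25)
            res = information_gain(binned, labels)
            assert 0.0 <= res.ig <= res.class_entropy + 1e-12

    def test_non_binary_labels_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            information_gain(np.array([0, 1]), np.array([0, 2]))


class TestIGFilter:
    def test_separator_retained_noise_mostly_dropped(self):
        rng = np.random.default_rng(1)
        labels = [1] * 20 + [0] * 20
        cols = {"sep": [1.0] * 20 + [0.0] * 20}
        for k in range(5):
            cols[f"noise{k}"] = rng.normal(size=40).tolist()
        subset = ig_filter(_matrix(cols, labels))
        assert "sep" in subset.names
        assert subset.names[0] == "sep"  # ordered by descending gain

    def test_constant_matrix_gives_empty_subset(self):
        subset = ig_filter(_matrix({"c1": [1.0] * 8, "c2": [2.0] * 8}, [1] * 4 + [0] * 4))
        assert subset.names == []

    def test_zero_fraction_retains_everything(self):
        m = _matrix({"a": [1, 2, 3, 4], "b": [4, 4, 4, 4]}, [1, 1, 0, 0])
        assert len(ig_filter(m, fraction=0.0)) == 2

    def test_unlabeled_matrix_rejected(self):
        m = DescriptorMatrix(pd.DataFrame({"a": [1.0, 2.0]}, index=["x", "y"]))
        with pytest.raises(ValueError, match="label"):
            ig_filter(m)


class TestRedundancyReduce:
    def test_identical_columns_collapse_to_one(self):
        m = _matrix({"f": [1, 2, 3, 4], "g": [1, 2, 3, 4]}, [1, 1, 0, 0])
        subset = redundancy_reduce(m, FeatureSubset(["f", "g"], "ig"))
        assert len(subset) == 1

    def test_weakly_correlated_columns_all_survive(self):
        # pairwise |rho| of {a,b,c} is {0, 0.6, 0.8}, all below the cutoff
        m = _matrix(
            {"a": [1, 2, 3, 4], "b": [2, 4, 1, 3], "c": [2, 1, 4, 3]}, [1, 1, 0, 0]
        )
        subset = redundancy_reduce(m, FeatureSubset(["a", "b", "c"], "ig"))
        assert sorted(subset.names) == ["a", "b", "c"]

    def test_monotone_transform_links_through_chain(self):
        # rho(f, 2f) = 1 links them; g is rank-independent and survives alone
        f = [1.0, 5.0, 2.0, 4.0, 3.0]
        m = _matrix({"f": f, "f2": [2 * x for x in f], "g": [2, 4, 5, 1, 3]},
                    [1, 1, 1, 0, 0])
        subset = redundancy_reduce(m, FeatureSubset(["f", "f2", "g"], "ig"))
        assert len(subset) == 2
        assert "g" in subset.names
        assert set(subset.names) & {"f", "f2"}

    def test_anticorrelated_duplicates_are_redundant(self):
        f = [1.0, 2.0, 3.0, 4.0]
        m = _matrix({"f": f, "neg": [-x for x in f]}, [1, 1, 0, 0])
        assert len(redundancy_reduce(m, FeatureSubset(["f", "neg"], "ig"))) == 1
        # signed mode keeps both
        assert len(redundancy_reduce(m, FeatureSubset(["f", "neg"], "ig"),
                                     absolute=False)) == 2

    def test_no_surviving_pair_exceeds_cutoff(self, tiny_matrix):
        labeled = tiny_matrix
        subset = FeatureSubset(list(labeled.feature_names[:80]), "ig")
        reduced = redundancy_reduce(labeled, subset, rho=0.95)
        assert 1 <= len(reduced) <= len(subset)
        rho = spearman_matrix(labeled.select(reduced.names).values)
        off_diag = np.abs(rho[~np.eye(len(reduced), dtype=bool)])
        assert (off_diag < 0.95).all()

    def test_empty_subset_passthrough(self, tiny_matrix):
        assert len(redundancy_reduce(tiny_matrix, FeatureSubset([], "ig"))) == 0


class TestGAWrapper:
    def _planted(self, seed=0, n=40, noise=8):
        rng = np.random.default_rng(seed)
        labels = [1] * (n // 2) + [0] * (n // 2)
        cols = {"sep": [float(l) * 10 + rng.normal() * 0.01 for l in labels]}
        for k in range(noise):
            cols[f"n{k}"] = rng.normal(size=n).tolist()
        return _matrix(cols, labels)

    def test_perfect_separator_reaches_unit_fitness(self):
        m = self._planted()
        subset = FeatureSubset(list(m.feature_names), "redundancy")
        result = ga_wrapper_select(m, subset, ga=GAParams(population=10, generations=5),
                                   seed=3)
        assert result.fitness == pytest.approx(1.0)
        assert "sep" in result.names

    def test_deterministic_given_seed(self):
        m = self._planted(seed=1)
        subset = FeatureSubset(list(m.feature_names), "redundancy")
        ga = GAParams(population=8, generations=4)
        r1 = ga_wrapper_select(m, subset, ga=ga, seed=42)
        r2 = ga_wrapper_select(m, subset, ga=ga, seed=42)
        assert r1.names == r2.names
        assert r1.fitness == r2.fitness

    def test_degenerate_search_returns_evaluated_chromosome(self):
        m = self._planted(seed=2)
        subset = FeatureSubset(list(m.feature_names), "redundancy")
        result = ga_wrapper_select(m, subset, ga=GAParams(population=1, generations=0),
                                   seed=0)
        assert 1 <= len(result) <= len(subset)
        assert result.fitness is not None

    def test_fold_count_reduced_for_tiny_classes(self):
        rng = np.random.default_rng(0)
        labels = [1, 1, 1, 0, 0, 0]
        m = _matrix({"a": (rng.normal(size=6) + np.array(labels) * 5).tolist()}, labels)
        result = ga_wrapper_select(m, FeatureSubset(["a"], "redundancy"),
                                   ga=GAParams(population=2, generations=1), seed=0)
        assert result.fitness is not None

    def test_empty_candidate_subset_rejected(self, tiny_matrix):
        with pytest.raises(ValueError, match="nonempty"):
            ga_wrapper_select(tiny_matrix, FeatureSubset([], "redundancy"))


def test_subset_rejects_duplicates():
    with pytest.raises(ValueError, match="duplicates"):
        FeatureSubset(["a", "a"], "ig")


def test_class_entropy_balanced_is_one_bit():
    assert class_entropy(np.array([0, 1, 0, 1])) == pytest.approx(1.0)
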