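"""Entropy / mutual information estimator against brute-force oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from drydown.infotheory import (
    EstimatorConfig,
    conditional_entropy,
    discretize,
    entropy,
    joint_entropy,
    mi_table,
    mutual_information,
    mutual_information_from_labels,
)


def brute_force_mi_bits(counts):
    """Independent oracle: direct double sum over the joint distribution."""
    c = np.asarray(counts, dtype=float)
    n = c.sum()
    p = c / n
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    total = 0.0
    for i in range(p.shape[0]):
        for j in range(p.shape[1]):
            if p[i, j] > 0:
                total += p[i, j] * np.log2(p[i, j] / (px[i] * py[j]))
    return total


def labels_from_counts(counts):
    xs, ys = [], []
    for (i, j), c in np.ndenumerate(np.asarray(counts)):
        xs.extend([i] * int(c))
        ys.extend([j] * int(c))
    return np.array(xs), np.array(ys)


class TestDiscretize:
    def test_equal_width_four_values_two_bins(self):
        d = discretize([1, 2, 3, 4], n_bins=2, scheme="equal_width")
        assert d.labels.tolist() == [0, 0, 1, 1]

    def test_constant_series_single_bin_zero_entropy(self):
        with pytest.warns(UserWarning, match="constant"):
            d = discretize([7.0] * 5, n_bins=2, scheme="quantile")
        assert d.labels.tolist() == [0] * 5
        assert entropy(d.labels) == 0.0

    @pytest.mark.parametrize("n", [4, 6, 10, 20])
    def test_quantile_equal_counts_on_monotone_series(self, n):
        # brute-force rank check: strictly monotone series of even length
        values = np.cumsum(np.random.default_rng(n).uniform(0.1, 1, n))
        d = discretize(values, n_bins=2, scheme="quantile")
        counts = np.bincount(d.labels, minlength=2)
        assert counts[0] == counts[1] == n // 2
        # lower-ranked half must carry label 0
        order = np.argsort(values)
        assert set(d.labels[order[: n // 2]]) == {0}

    def test_rejects_nan_and_short_input(self):
        with pytest.raises(ValueError):
            discretize([1.0, np.nan, 2.0], 2)
        with pytest.raises(ValueError):
            discretize([1.0], 2)


class TestEntropy:
    def test_uniform_four_bins_is_two_bits(self):
        assert entropy([0, 1, 2, 3]) == pytest.approx(2.0, abs=1e-12)

    def test_single_bin_is_zero(self):
        assert entropy([2, 2, 2]) == 0.0

    def test_three_one_split(self):
        # direct evaluation: -(0.75 log2 0.75 + 0.25 log2 0.25)
        expected = -(0.75 * np.log2(0.75) + 0.25 * np.log2(0.25))
        assert entropy([0, 0, 0, 1]) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.8113, abs=1e-4)

    def test_conditional_entropy_identical_is_zero(self):
        x = np.array([0, 1, 0, 1, 1])
        assert conditional_entropy(x, x) == pytest.approx(0.0, abs=1e-12)

    def test_conditional_entropy_constant_condition(self):
        x = np.array([0, 1, 2, 3])
        y = np.zeros(4, dtype=int)
        assert conditional_entropy(x, y) == pytest.approx(entropy(x), abs=1e-12)

    def test_conditional_entropy_against_enumerated_joint(self):
        counts = [[2, 1], [1, 2]]
        x, y = labels_from_counts(counts)
        # brute force: H(X,Y) - H(Y) from the joint histogram
        p = np.array(counts) / 6.0
        h_joint = -(p * np.log2(p)).sum()
        h_y = entropy(y)
        assert conditional_entropy(x, y) == pytest.approx(h_joint - h_y,
                                                          abs=1e-12)


class TestMutualInformation:
    def test_perfectly_matched_binary_is_one_bit(self):
        x = np.array([0, 1] * 10)
        assert mutual_information_from_labels(x, x.copy()) == pytest.approx(
            1.0, abs=1e-12)

    def test_independence_limit(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 2, 4000)
        y = rng.integers(0, 2, 4000)
        # plug-in bias ceiling for 2x2: (k-1)^2 / (2 n ln 2) plus slack
        assert mutual_information_from_labels(x, y) < 5.0 / (2 * 4000 * np.log(2))

    def test_known_joint_distribution(self):
        counts = np.array([[4, 1], [1, 4]])  # joint probs 0.4/0.1
        x, y = labels_from_counts(counts)
        got = mutual_information_from_labels(x, y)
        assert got == pytest.approx(brute_force_mi_bits(counts), abs=1e-12)
        assert got == pytest.approx(0.2781, abs=1e-4)

    def test_random_tables_match_brute_force(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            counts = rng.integers(0, 5, size=(3, 3))
            if counts.sum() == 0:
                continue
            x, y = labels_from_counts(counts)
            assert mutual_information_from_labels(x, y) == pytest.approx(
                brute_force_mi_bits(counts), abs=1e-12)

    @given(st.lists(st.tuples(st.integers(0, 2), st.integers(0, 2)),
                    min_size=2, max_size=40))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_symmetry_and_bounds(self, pairs):
        x = np.array([p[0] for p in pairs])
        y = np.array([p[1] for p in pairs])
        ixy = mutual_information_from_labels(x, y)
        iyx = mutual_information_from_labels(y, x)
        assert ixy == pytest.approx(iyx, abs=1e-12)
        assert -1e-12 <= ixy <= min(entropy(x), entropy(y)) + 1e-12

    def test_quantile_binning_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=31)
        y = rng.normal(size=31) + 0.5 * x
        base = mutual_information(x, y, n_bins=2, scheme="quantile").mi
        for fx, fy in ((np.exp, lambda v: v ** 3),
                       (lambda v: 2 * v + 1, np.exp)):
            got = mutual_information(fx(x), fy(y), n_bins=2,
                                     scheme="quantile").mi
            assert got == pytest.approx(base, abs=1e-12)

    def test_insufficient_pairs_flagged_not_raised(self):
        res = mutual_information([1.0, 2.0], [3.0, 1.0])
        assert not res.reliable

    def test_nan_pairs_dropped(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0, 6.0]
        y = [2.0, 1.0, 3.0, np.nan, 5.0, 7.0]
        res = mutual_information(x, y)
        assert res.n == 4


class TestMITable:
    @staticmethod
    def _toy_summary():
        import pandas as pd

        class Summary:
            pass

        days = np.arange(16)
        rng = np.random.default_rng(5)
        frame = pd.DataFrame(
            {
                "sap_flow": np.linspace(200, 20, 16) + rng.normal(0, 5, 16),
                "psi_pd": -np.linspace(0.1, 1.4, 16),
                "psi_md": -np.linspace(0.8, 1.6, 16) + rng.normal(0, 0.05, 16),
                "vpd": rng.uniform(0.4, 0.9, 16),
            },
            index=pd.Index(days, name="day"),
        )
        s = Summary()
        s.pooled = frame
        s.per_tree = {"T1": frame}
        return s

    def test_self_information_equals_entropy(self):
        summary = self._toy_summary()
        cfg = EstimatorConfig(measurements=("psi_pd",), targets=("psi_pd",))
        out = mi_table(summary, cfg)
        for row in out.itertuples():
            assert row.mi_bits == pytest.approx(row.h_x, abs=1e-12)
            assert row.h_x == pytest.approx(row.h_y, abs=1e-12)

    def test_period_stratification_sample_sizes(self):
        summary = self._toy_summary()
        out = mi_table(summary, EstimatorConfig(measurements=("vpd",),
                                                targets=("sap_flow",)))
        n = out.set_index("period")["n"]
        assert n["full"] == 16 and n["drydown"] == 10 and n["recovery"] == 6

    def test_unknown_target_rejected(self):
        with pytest.raises(ValueError, match="valid targets"):
            mi_table(self._toy_summary(),
                     EstimatorConfig(targets=("nonexistent",)))

    def test_pure_noise_measurement_mean_mi_below_bias_ceiling(self):
        # permutation-null style check: a measurement carrying no signal
        # should average below the plug-in bias ceiling for (n, bins)
        import pandas as pd

        n = 100
        signal = np.linspace(0, 1, n)
        mis = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            mis.append(mutual_information(rng.normal(size=n), signal,
                                          n_bins=2).mi)
        ceiling = 1.0 / (2 * n * np.log(2))  # (k-1)^2 / (2 n ln 2)
        assert np.mean(mis) < 3 * ceiling
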