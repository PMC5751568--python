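"""Mutual-information scoring, Fisher ratio, band ranking."""

import numpy as np
import pytest

from bandcsp.bandselect import (
    FeatureMatrix,
    fisher_ratio,
    mutual_information,
    rank_bands,
    rank_bands_fisher,
)


def brute_force_mi_bits(x, y):
    """Independent plug-in MI: explicit double loop over the joint support."""
    x, y = np.asarray(x), np.asarray(y)
    n = len(x)
    total = 0.0
    for xv in np.unique(x):
        for yv in np.unique(y):
            pxy = np.mean((x == xv) & (y == yv))
            if pxy > 0:
                total += pxy * np.log2(pxy / (np.mean(x == xv) * np.mean(y == yv)))
    return total


def entropy_bits(values):
    vals, counts = np.unique(np.asarray(values), return_counts=True)
    p = counts / counts.sum()
    return -np.sum(p * np.log2(p))


class TestMutualInformation:
    def test_feature_identical_to_label_gives_one_bit(self):
        y = np.array([1, 2] * 50)
        assert mutual_information(y.astype(float), y) == pytest.approx(1.0)

    def test_constant_feature_gives_zero(self):
        y = np.array([1, 2] * 10)
        assert mutual_information(np.ones(20), y) == 0.0

    def test_matches_brute_force_on_discrete_joint(self):
        # cell probabilities [[0.4, 0.1], [0.1, 0.4]] realised exactly at N=40
        x = np.repeat([0.0, 0.0, 1.0, 1.0], [16, 4, 4, 16])
        y = np.repeat([1, 2, 1, 2], [16, 4, 4, 16])
        got = mutual_information(x, y)
        assert got == pytest.approx(brute_force_mi_bits(x, y), abs=1e-12)
        assert got == pytest.approx(0.27807190511263774, abs=1e-12)

    def test_joint_entropy_identity_on_discrete_toys(self):
        # entropy-sum identity: I = H(X) + H(Y) − H(X, Y), exactly, on toys
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = rng.integers(0, 3, 60).astype(float)
            y = rng.integers(1, 3, 60)
            joint = [f"{a}|{b}" for a, b in zip(x, y)]
            ident = entropy_bits(x) + entropy_bits(y) - entropy_bits(joint)
            assert mutual_information(x, y) == pytest.approx(ident, abs=1e-12)

    def test_bounds(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(200)
        y = rng.integers(1, 3, 200)
        mi = mutual_information(x, y)
        assert 0.0 <= mi <= entropy_bits(y) + 1e-12

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(150)
        y = np.where(x + 0.5 * rng.standard_normal(150) > 0, 2, 1)
        a = mutual_information(x, y)
        b = mutual_information(np.exp(3 * x), y)
        assert a == pytest.approx(b, abs=1e-12)

    def test_permuted_labels_near_zero(self):
        rng = np.random.default_rng(3)
        vals = []
        y = np.array([1, 2] * 100)
        for _ in range(100):
            x = rng.standard_normal(200)
            vals.append(mutual_information(x, y))
        assert np.mean(vals) < 0.05

    def test_agrees_with_sklearn_on_discrete(self):
        from sklearn.metrics import mutual_info_score

        rng = np.random.default_rng(4)
        x = rng.integers(0, 4, 80).astype(float)
        y = rng.integers(1, 3, 80)
        ours = mutual_information(x, y)
        ref = mutual_info_score(x, y) / np.log(2)  # nats → bits
        assert ours == pytest.approx(ref, abs=1e-10)

    def test_parzen_estimator_sane(self):
        rng = np.random.default_rng(5)
        y = np.array([1, 2] * 100)
        separated = np.where(y == 1, -2.0, 2.0) + 0.1 * rng.standard_normal(200)
        noise = rng.standard_normal(200)
        hi = mutual_information(separated, y, estimator="parzen")
        lo = mutual_information(noise, y, estimator="parzen")
        assert hi > 0.9
        assert lo < 0.1

    def test_errors(self):
        with pytest.raises(ValueError):
            mutual_information(np.ones(10), np.ones(10, dtype=int))
        with pytest.raises(ValueError):
            mutual_information(np.ones(2), np.array([1, 2]))


class TestFisherRatio:
    def test_identical_distributions_zero(self):
        x = np.array([1.0, 2, 3, 1, 2, 3])
        y = np.array([1, 1, 1, 2, 2, 2])
        assert fisher_ratio(x, y) == 0.0

    def test_arithmetic_example(self):
        rng = np.random.default_rng(0)
        # class means 1 and 3, unit unbiased variances, realised exactly
        base = np.array([-1.0, 0.0, 1.0]) / np.std([-1.0, 0, 1], ddof=1)
        x = np.concatenate([base + 1, base + 3])
        y = np.array([1, 1, 1, 2, 2, 2])
        assert fisher_ratio(x, y) == pytest.approx(2.0)

    def test_population_value_monte_carlo(self):
        rng = np.random.default_rng(1)
        n = 200_000
        x = np.concatenate([rng.normal(0, 1, n), rng.normal(1, 1, n)])
        y = np.repeat([1, 2], n)
        assert fisher_ratio(x, y) == pytest.approx(0.5, abs=0.01)

    def test_degenerate_cases(self):
        y = np.array([1, 1, 2, 2])
        assert fisher_ratio(np.array([3.0, 3, 3, 3]), y) == 0.0
        with pytest.raises(ValueError):
            fisher_ratio(np.array([1.0, 1, 2, 2]), y)


class TestRankBands:
    def _fm(self, cols, owners):
        return FeatureMatrix(np.column_stack(cols), np.array(owners))

    def test_full_ranking_is_permutation(self):
        rng = np.random.default_rng(0)
        y = np.array([1, 2] * 30)
        cols = [rng.standard_normal(60) for _ in range(6)]
        fm = self._fm(cols, [1, 1, 2, 2, 3, 3])
        order, scores = rank_bands(fm, y, r=3)
        assert sorted(order) == [1, 2, 3]
        vals = [scores.per_band[b] for b in order]
        assert vals == sorted(vals, reverse=True)

    def test_tie_break_to_lower_index(self):
        rng = np.random.default_rng(1)
        y = np.array([1, 2] * 20)
        col = rng.standard_normal(40)
        fm = self._fm([col, col], [7, 3])
        order, _ = rank_bands(fm, y, r=2)
        assert order == [3, 7]

    def test_informative_band_ranks_first(self):
        rng = np.random.default_rng(2)
        y = np.array([1, 2] * 40)
        good = np.where(y == 1, -1.0, 1.0) + 0.3 * rng.standard_normal(80)
        fm = self._fm(
            [rng.standard_normal(80), good, rng.standard_normal(80)], [1, 2, 3]
        )
        order, scores = rank_bands(fm, y, r=1)
        assert order == [2]
        assert scores.per_band[2] == max(scores.per_band.values())

    def test_per_band_is_max_over_columns(self):
        rng = np.random.default_rng(3)
        y = np.array([1, 2] * 25)
        c1, c2 = rng.standard_normal(50), np.where(y == 1, -1.0, 1.0)
        fm = self._fm([c1, c2], [5, 5])
        _, scores = rank_bands(fm, y, r=1)
        assert scores.per_band[5] == pytest.approx(scores.per_feature.max())

    def test_reproducible(self):
        rng = np.random.default_rng(4)
        y = np.array([1, 2] * 30)
        cols = [rng.standard_normal(60) for _ in range(8)]
        fm = self._fm(cols, [1, 1, 2, 2, 3, 3, 4, 4])
        a = rank_bands(fm, y, r=4)
        b = rank_bands(fm, y, r=4)
        assert a[0] == b[0]
        assert np.array_equal(a[1].per_feature, b[1].per_feature)

    def test_r_out_of_range(self):
        fm = self._fm([np.arange(8.0)], [1])
        with pytest.raises(ValueError):
            rank_bands(fm, np.array([1, 2] * 4), r=2)


class TestRankBandsFisher:
    def test_all_indices_returned(self):
        rng = np.random.default_rng(0)
        bp = rng.random((30, 5)) + 0.1
        y = np.array([1, 2] * 15)
        assert sorted(rank_bands_fisher(bp, y, 5)) == [1, 2, 3, 4, 5]

    def test_planted_band_ranked_first(self):
        rng = np.random.default_rng(1)
        y = np.array([1, 2] * 30)
        bp = rng.random((60, 4)) + 1.0
        bp[:, 2] += np.where(y == 2, 2.0, 0.0)
        assert rank_bands_fisher(bp, y, 1) == [3]

    def test_duplicate_columns_lower_index_first(self):
        rng = np.random.default_rng(2)
        y = np.array([1, 2] * 10)
        col = rng.random(20)
        bp = np.column_stack([col, col])
        assert rank_bands_fisher(bp, y, 2) == [1, 2]
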