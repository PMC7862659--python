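import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tuberome import (CountTable, ValidationError, build_network,
                      spearman_matrix, threshold_network)
from tuberome.corr_network import STORAGE_NODE


def _table(arr):
    arr = np.asarray(arr)
    return CountTable([f"S{i}" for i in range(arr.shape[0])],
                      [f"O{j}" for j in range(arr.shape[1])], arr)


def _rank_then_pearson(x):
    """Independent oracle: average-rank transform then Pearson."""
    ranks = pd.DataFrame(x).rank().to_numpy()
    return np.corrcoef(ranks, rowvar=False)


class TestSpearmanMatrix:
    def test_monotone_pair_rho_one(self):
        t = _table([[1, 2], [2, 4], [3, 9], [4, 16]])
        r, _ = spearman_matrix(t, [1, 2, 3, 4],
                               use_relative_abundance=False)
        assert r.loc["O0", "O1"] == pytest.approx(1.0)

    def test_reversed_ranks_rho_minus_one(self):
        t = _table([[1, 40], [2, 30], [3, 20], [4, 10]])
        r, _ = spearman_matrix(t, [1, 2, 3, 4],
                               use_relative_abundance=False)
        assert r.loc["O0", "O1"] == pytest.approx(-1.0)

    def test_textbook_example(self):
        # x=[1..5], y=[2,1,4,3,5]: rho = 1 - 6*4/120 = 0.8
        t = _table([[1, 2], [2, 1], [3, 4], [4, 3], [5, 5]])
        r, _ = spearman_matrix(t, [1, 2, 3, 4, 5],
                               use_relative_abundance=False)
        assert r.loc["O0", "O1"] == pytest.approx(0.8)

    def test_brute_force_oracle_with_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            counts = rng.integers(0, 6, size=(20, 10))
            counts[:, 0] += 1
            t = _table(counts)
            days = rng.integers(130, 170, 20).astype(float)
            r, _ = spearman_matrix(t, days, use_relative_abundance=False)
            oracle = _rank_then_pearson(
                np.column_stack([counts, days]))
            assert np.allclose(r.to_numpy(), oracle, atol=1e-12)

    def test_storage_node_last(self):
        t = _table(np.arange(20).reshape(4, 5) + 1)
        r, p = spearman_matrix(t, [1, 2, 3, 4])
        assert r.index[-1] == STORAGE_NODE
        assert p.shape == r.shape

    def test_constant_node_warns_and_zeroes(self):
        t = _table([[5, 1], [5, 2], [5, 3], [5, 4]])
        with pytest.warns(UserWarning, match="constant"):
            r, p = spearman_matrix(t, [1, 2, 3, 4],
                                   use_relative_abundance=False)
        assert r.loc["O0", "O1"] == 0 and p.loc["O0", "O1"] == 1

    def test_too_few_samples_rejected(self):
        t = _table([[1, 2], [3, 4], [5, 6]])
        with pytest.raises(ValidationError):
            spearman_matrix(t, [1, 2, 3])


class TestThresholdNetwork:
    def _rp(self, r01, p01):
        ids = ["a", "b"]
        r = pd.DataFrame([[1.0, r01], [r01, 1.0]], index=ids, columns=ids)
        p = pd.DataFrame([[0.0, p01], [p01, 0.0]], index=ids, columns=ids)
        return r, p

    def test_below_r_threshold_removed(self):
        net = threshold_network(*self._rp(0.49, 1e-6))
        assert net.edges == []

    def test_above_p_threshold_removed(self):
        net = threshold_network(*self._rp(0.9, 0.01))
        assert net.edges == []

    def test_negative_edge_modes(self):
        r, p = self._rp(-0.8, 1e-5)
        assert threshold_network(r, p, mode="absolute").edges == [
            ("a", "b", -0.8)]
        assert threshold_network(r, p, mode="positive").edges == []

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        ids = [f"n{i}" for i in range(6)]
        m = rng.uniform(-1, 1, (6, 6))
        r = pd.DataFrame((m + m.T) / 2, index=ids, columns=ids)
        np.fill_diagonal(r.values, 1.0)
        p = pd.DataFrame(rng.uniform(0, 0.01, (6, 6)), index=ids,
                         columns=ids)
        p.values[:] = (p.values + p.values.T) / 2
        np.fill_diagonal(p.values, 0.0)
        once = threshold_network(r, p)
        twice = threshold_network(once.r, p)
        assert once.edges == twice.edges

    def test_edge_count_monotone_in_thresholds(self):
        rng = np.random.default_rng(2)
        ids = [f"n{i}" for i in range(10)]
        m = rng.uniform(-1, 1, (10, 10))
        r = pd.DataFrame((m + m.T) / 2, index=ids, columns=ids)
        np.fill_diagonal(r.values, 1.0)
        p = pd.DataFrame(np.full((10, 10), 1e-6), index=ids, columns=ids)
        np.fill_diagonal(p.values, 0.0)
        sizes = [len(threshold_network(r, p, r_threshold=rt).edges)
                 for rt in (0.2, 0.4, 0.6, 0.8)]
        assert sizes == sorted(sizes, reverse=True)

    def test_bad_thresholds_rejected(self):
        with pytest.raises(ValueError):
            threshold_network(*self._rp(0.5, 0.5), r_threshold=1.5)


class TestBuildNetwork:
    def test_storage_sign_flips_under_day_reversal(self):
        """Reversing the storage-day order negates every storage-node rho,
        the basis for the long/short direction swap."""
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 50, size=(24, 8))
        counts[:, 0] += 1
        days = np.repeat(np.linspace(130, 170, 8), 3)
        t = _table(counts)
        n1 = build_network(t, days, r_threshold=0.0, p_threshold=1.0)
        n2 = build_network(t, days.max() + days.min() - days,
                           r_threshold=0.0, p_threshold=1.0)
        c1 = n1.r[STORAGE_NODE].drop(STORAGE_NODE)
        c2 = n2.r[STORAGE_NODE].drop(STORAGE_NODE)
        assert np.allclose(c1.to_numpy(), -c2.to_numpy(), atol=1e-12)

    def test_degrees_match_edges(self):
        rng = np.random.default_rng(4)
        counts = rng.integers(0, 30, size=(12, 6))
        counts[:, 0] += 1
        t = _table(counts)
        net = build_network(t, rng.uniform(130, 170, 12),
                            r_threshold=0.3, p_threshold=0.5)
        assert net.degree().sum() == 2 * len(net.edges)
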