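import itertools

import numpy as np
import pytest

from tuberome import (CountTable, DistanceMatrix, ValidationError,
                      bray_curtis, cap, pcoa, permanova)
from tuberome.betadiv import _permanova_stats


def _dm(values, ids=None):
    values = np.asarray(values, dtype=float)
    return DistanceMatrix(ids or [f"S{i}" for i in range(len(values))],
                          values)


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        t = CountTable(["a", "b"], ["x", "y"], np.array([[3, 7], [3, 7]]))
        assert bray_curtis(t).values[0, 1] == 0

    def test_disjoint_samples_one(self):
        t = CountTable(["a", "b"], ["x", "y"], np.array([[5, 0], [0, 9]]))
        assert bray_curtis(t).values[0, 1] == 1

    def test_hand_computed_value(self):
        t = CountTable(["a", "b"], ["x", "y"], np.array([[2, 2], [4, 0]]))
        assert bray_curtis(t).values[0, 1] == pytest.approx(0.5)

    def test_direct_formula_on_random_data(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 40, size=(6, 10)).astype(float)
        x[:, 0] += 1
        dm = bray_curtis(x).values
        for i, j in itertools.combinations(range(6), 2):
            expect = 1 - 2 * np.minimum(x[i], x[j]).sum() / (
                x[i].sum() + x[j].sum())
            assert dm[i, j] == pytest.approx(expect, abs=1e-12)

    def test_normalisation_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.integers(1, 50, size=(5, 8)).astype(float)
        props = x / x.sum(axis=1, keepdims=True)
        assert np.allclose(bray_curtis(props).values, bray_curtis(
            props * 1.0).values, atol=1e-12)
        # proportions vs raw counts after per-sample normalisation
        assert np.allclose(bray_curtis(x / x.sum(axis=1, keepdims=True)
                                       ).values,
                           bray_curtis(props).values, atol=1e-12)

    def test_zero_total_sample_rejected(self):
        t = CountTable(["a", "b"], ["x"], np.array([[1], [0]]))
        with pytest.raises(ValidationError, match="b"):
            bray_curtis(t)


class TestPermanova:
    def test_identical_compositions_f0_p1(self):
        d = np.zeros((6, 6))
        res = permanova(_dm(d), list("aaabbb"), n_perm=99, seed=0)
        assert res.pseudo_F == 0 and res.p == 1 and res.R2 == 0

    def test_exhaustive_enumeration_oracle(self):
        """Two tight, well-separated 4-sample clusters: the permutation p
        converges to the exact p over all C(8,4) = 70 balanced label
        assignments."""
        rng = np.random.default_rng(3)
        pts = np.vstack([rng.normal(0, .05, (4, 2)),
                         rng.normal(5, .05, (4, 2))])
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        d /= d.max()
        dm = _dm(d)
        labels = np.array([0] * 4 + [1] * 4)
        f_obs, _ = _permanova_stats(d ** 2, labels, 2)
        hits = 0
        total = 0
        for combo in itertools.combinations(range(8), 4):
            lab = np.zeros(8, dtype=int)
            lab[list(combo)] = 1
            f, _ = _permanova_stats(d ** 2, lab, 2)
            total += 1
            hits += f >= f_obs - 1e-12
        exact = hits / total
        assert total == 70 and exact == pytest.approx(2 / 70)
        res = permanova(dm, labels, n_perm=9999, seed=0)
        assert res.p == pytest.approx(exact, abs=0.01)
        assert res.R2 > 0.95

    def test_skbio_cross_check(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(4)
        x = rng.integers(1, 60, size=(9, 12)).astype(float)
        labels = list("aaabbbccc")
        dm = bray_curtis(x)
        mine = permanova(dm, labels, n_perm=99, seed=0)
        ref = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(dm.values, dm.sample_ids), labels,
            permutations=99)
        assert mine.pseudo_F == pytest.approx(ref["test statistic"],
                                              rel=1e-10)

    def test_label_renaming_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.integers(1, 40, size=(8, 6)).astype(float)
        dm = bray_curtis(x)
        a = permanova(dm, list("xxxxyyyy"), n_perm=49, seed=7)
        b = permanova(dm, list("qqqqzzzz"), n_perm=49, seed=7)
        assert a.pseudo_F == b.pseudo_F and a.p == b.p

    def test_all_singletons_rejected(self):
        d = np.ones((3, 3)) - np.eye(3)
        with pytest.raises(ValidationError):
            permanova(_dm(d), ["a", "b", "c"], n_perm=9)


class TestPcoa:
    def test_equilateral_three_points(self):
        d = np.ones((3, 3)) - np.eye(3)
        res = pcoa(_dm(d))
        pos = res.eigenvalues[res.eigenvalues > 0]
        assert len(pos) == 2 and pos[0] == pytest.approx(pos[1])
        emb = res.coordinates
        dists = np.sqrt(((emb[:, None] - emb[None]) ** 2).sum(-1))
        off = dists[np.triu_indices(3, 1)]
        assert np.allclose(off, off[0])

    def test_euclidean_embedding_oracle(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(7, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        scale = d.max()
        res = pcoa(_dm(d / scale))
        emb = res.coordinates
        back = np.sqrt(((emb[:, None] - emb[None]) ** 2).sum(-1)) * scale
        assert np.allclose(back, d, atol=1e-8)

    def test_duplicate_samples_coincide(self):
        rng = np.random.default_rng(7)
        x = rng.integers(1, 30, size=(4, 6)).astype(float)
        x = np.vstack([x, x[0]])
        res = pcoa(bray_curtis(x))
        assert np.allclose(res.coordinates[0], res.coordinates[-1],
                           atol=1e-9)

    def test_gower_identity(self):
        # total positive eigenvalue mass equals SS_total for a Euclidean
        # distance matrix
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(6, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        d /= d.max()
        res = pcoa(_dm(d))
        ss_total = (d[np.triu_indices(6, 1)] ** 2).sum() / 6
        assert res.eigenvalues[res.eigenvalues > 0].sum() == pytest.approx(
            ss_total, abs=1e-8)

    def test_centred_and_ordered(self):
        rng = np.random.default_rng(9)
        x = rng.integers(1, 30, size=(8, 10)).astype(float)
        res = pcoa(bray_curtis(x))
        assert np.allclose(res.coordinates.mean(axis=0), 0, atol=1e-9)
        assert (np.diff(res.eigenvalues) <= 1e-12).all()


class TestCap:
    def test_planted_separation(self):
        rng = np.random.default_rng(10)
        a = rng.poisson([40, 5, 5, 1, 1, 1], size=(8, 6))
        b = rng.poisson([5, 40, 5, 1, 1, 1], size=(8, 6))
        x = np.vstack([a, b]).astype(float) + 1
        labels = ["a"] * 8 + ["b"] * 8
        res = cap(bray_curtis(x), labels)
        assert res.constrained
        ax1 = res.coordinates[:, 0]
        ga, gb = ax1[:8], ax1[8:]
        between = (ga.mean() - gb.mean()) ** 2
        within = ga.var() + gb.var()
        assert between > within

    def test_single_level_rejected(self):
        d = np.ones((4, 4)) - np.eye(4)
        with pytest.raises(ValidationError):
            cap(_dm(d), ["a"] * 4)

    def test_too_many_axes_rejected(self):
        d = np.ones((4, 4)) - np.eye(4)
        with pytest.raises(ValidationError):
            cap(_dm(d), ["a", "a", "b", "b"], n_pcoa_axes=10)

    def test_axis_count_bounded_by_groups(self):
        rng = np.random.default_rng(11)
        x = rng.integers(1, 40, size=(12, 8)).astype(float)
        labels = list("aaaabbbbcccc")
        res = cap(bray_curtis(x), labels)
        assert res.coordinates.shape[1] <= 2
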