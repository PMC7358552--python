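"""Diversity statistics against independent oracles and closed forms."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import mantel as skbio_mantel

import metahab as mh
from metahab.model import ValidationError

from conftest import habitat_meta, random_table


def chao1_oracle(counts):
    """Direct recount of the bias-corrected estimator."""
    counts = np.asarray(counts)
    s_obs = (counts > 0).sum()
    f1 = (counts == 1).sum()
    f2 = (counts == 2).sum()
    return s_obs + f1 * (f1 - 1) / (2 * (f2 + 1))


class TestChao1:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((5, 3, 1, 1, 2), 5.5),
            ((1, 1), 3.0),
            ((5, 3, 4), 3.0),  # no singletons/doubletons: Chao1 = S_obs
        ],
    )
    def test_hand_values(self, counts, expected):
        assert mh.chao1(counts) == pytest.approx(expected)

    def test_empty_sample_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            assert mh.chao1([0, 0]) == 0.0

    def test_matches_recount_oracle(self, rng):
        for _ in range(200):
            counts = rng.integers(0, 6, size=rng.integers(3, 30))
            if counts.sum() == 0:
                continue
            assert mh.chao1(counts) == pytest.approx(chao1_oracle(counts))

    def test_at_least_observed_richness(self, rng):
        for _ in range(50):
            counts = rng.integers(0, 4, size=20)
            if counts.sum() == 0:
                continue
            assert mh.chao1(counts) >= (counts > 0).sum()


class TestBrayCurtis:
    def test_hand_values(self, tiny_table):
        dm = mh.bray_curtis(tiny_table)
        assert dm["s1", "s2"] == pytest.approx(1 / 3)  # (6,2) vs (2,2)
        assert dm["s1", "s3"] == pytest.approx(1.0)  # disjoint
        assert dm["s1", "s1"] == 0.0

    def test_identical_samples(self):
        t = mh.OtuTable(["a", "b"], ["o1", "o2"], np.array([[3, 4], [3, 4]]))
        assert mh.bray_curtis(t)["a", "b"] == 0.0

    def test_matches_loop_oracle(self, rng):
        t = random_table(rng, n_samples=6, n_otus=12)
        dm = mh.bray_curtis(t)
        for i in range(6):
            for j in range(6):
                x, y = t.counts[i], t.counts[j]
                expected = np.abs(x - y).sum() / (x + y).sum()
                assert abs(dm[t.sample_ids[i], t.sample_ids[j]] - expected) < 1e-12

    def test_all_zero_pair_warns(self):
        t = mh.OtuTable(["a", "b", "c"], ["o1"], np.array([[0], [0], [5]]))
        with pytest.warns(UserWarning, match="all-zero"):
            dm = mh.bray_curtis(t)
        assert dm["a", "b"] == 0.0


class TestPcoa:
    def test_recovers_euclidean_configuration(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 2.0], [-1.0, 1.0]])
        d = squareform(pdist(pts))
        res = mh.pcoa(DistanceMatrix(d, ids=list("abcd")))
        rec = squareform(pdist(res.axes.to_numpy()))
        assert np.abs(rec - d).max() < 1e-8

    def test_two_samples_closed_form(self):
        res = mh.pcoa(DistanceMatrix([[0, 3], [3, 0]], ids=["a", "b"]))
        coords = np.sort(res.axes.to_numpy()[:, 0])
        assert coords == pytest.approx([-1.5, 1.5])

    def test_permutation_invariant_eigenvalues(self, rng):
        t = random_table(rng, n_samples=7)
        dm = mh.bray_curtis(t)
        perm = list(rng.permutation(t.sample_ids))
        e1 = mh.pcoa(dm).eigenvalues
        e2 = mh.pcoa(dm.filter(perm)).eigenvalues
        assert np.allclose(e1, e2, atol=1e-10)

    def test_positive_eigenvalues_equal_centered_ss(self):
        pts = np.random.default_rng(1).normal(size=(6, 3))
        d = squareform(pdist(pts))
        res = mh.pcoa(DistanceMatrix(d, ids=[str(i) for i in range(6)]))
        centered = pts - pts.mean(axis=0)
        assert res.eigenvalues.sum() == pytest.approx((centered**2).sum(), abs=1e-8)

    def test_proportions_bounded(self, rng):
        t = random_table(rng)
        res = mh.pcoa(mh.bray_curtis(t))
        assert res.proportion_explained.sum() <= 1 + 1e-12
        assert (np.diff(res.eigenvalues) <= 1e-12).all()  # descending


class TestGroupTests:
    def _clouds(self, sep, rng, n=10):
        a = rng.normal(0, 1, size=(n, 3))
        b = rng.normal(sep, 1, size=(n, 3))
        pts = np.vstack([a, b])
        ids = [f"x{i}" for i in range(2 * n)]
        dm = DistanceMatrix(squareform(pdist(pts)), ids=ids)
        groups = pd.Series(["a"] * n + ["b"] * n, index=ids)
        return dm, groups

    def test_strong_separation_minimal_p(self, rng):
        dm, groups = self._clouds(50, rng)
        res = mh.permanova(dm, groups, permutations=99, seed=1)
        # minimal attainable p unless a random shuffle recreates the exact
        # partition (a measure ~1e-5 tie), which counts as one extra hit
        assert res.p_value <= 2 / 100
        assert res.statistic > 100
        assert 0.8 < res.extras["R2"] <= 1.0

    def test_deterministic_with_seed(self, rng):
        dm, groups = self._clouds(0.5, rng)
        p1 = mh.permanova(dm, groups, permutations=199, seed=7).p_value
        p2 = mh.permanova(dm, groups, permutations=199, seed=7).p_value
        assert p1 == p2

    def test_anosim_range(self, rng):
        dm, groups = self._clouds(2, rng)
        res = mh.anosim(dm, groups, permutations=99, seed=0)
        assert -1 <= res.statistic <= 1
        assert res.statistic > 0.5

    def test_singleton_group_rejected(self, rng):
        dm, groups = self._clouds(1, rng, n=3)
        groups.iloc[0] = "c"
        with pytest.raises(ValidationError, match="size 1"):
            mh.permanova(dm, groups)


class TestMantel:
    def _random_dm(self, rng, n=12):
        pts = rng.normal(size=(n, 3))
        return DistanceMatrix(squareform(pdist(pts)), ids=[f"s{i}" for i in range(n)])

    def test_identity(self, rng):
        d1 = self._random_dm(rng)
        res = mh.mantel(d1, d1, permutations=99, seed=0)
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 100)

    def test_partial_with_self_control(self, rng):
        d1 = self._random_dm(rng)
        d2 = self._random_dm(rng)
        res = mh.mantel(d1, d2, permutations=9, partial=d2, seed=0)
        assert abs(res.statistic) < 1e-8

    def test_id_mismatch(self, rng):
        d1 = self._random_dm(rng)
        d2 = DistanceMatrix(np.asarray(d1.data), ids=[f"t{i}" for i in range(12)])
        with pytest.raises(ValidationError, match="mismatch"):
            mh.mantel(d1, d2)

    def test_agrees_with_skbio(self, rng):
        """Dual route: same r as scikit-bio's Mantel, compatible p."""
        d1, d2 = self._random_dm(rng), self._random_dm(rng)
        ours = mh.mantel(d1, d2, permutations=999, seed=3)
        r_ref, p_ref, _ = skbio_mantel(d1, d2, permutations=999, seed=3)
        assert ours.statistic == pytest.approx(r_ref, abs=1e-12)
        assert abs(ours.p_value - p_ref) < 0.12

    def test_default_permutations(self, rng):
        d1 = self._random_dm(rng, n=6)
        assert mh.mantel(d1, d1, seed=0).permutations == 10000


class TestFeatureWeightCorrelation:
    def _table_meta(self, rel_rows, weights):
        counts = (np.array(rel_rows) * 1000).astype(int)
        ids = [f"f{i}" for i in range(len(weights))]
        t = mh.OtuTable(ids, [f"o{j}" for j in range(counts.shape[1])], counts)
        return t, habitat_meta(ids, ["gill"] * len(ids), weights)

    def test_monotone_feature(self):
        w = [10.0, 20.0, 30.0, 40.0]
        rows = [[0.1, 0.9], [0.2, 0.8], [0.3, 0.7], [0.4, 0.6]]
        t, meta = self._table_meta(rows, w)
        res = mh.feature_weight_correlation(t, meta)
        assert res.loc["o0", "rho"] == pytest.approx(1.0)
        assert res.loc["o1", "rho"] == pytest.approx(-1.0)

    def test_weight_reversal_flips_sign(self, rng):
        n = 10
        counts = rng.integers(1, 50, size=(n, 5))
        ids = [f"f{i}" for i in range(n)]
        t = mh.OtuTable(ids, [f"o{j}" for j in range(5)], counts)
        w = list(rng.uniform(10, 100, n))
        r1 = mh.feature_weight_correlation(t, habitat_meta(ids, ["gill"] * n, w))
        r2 = mh.feature_weight_correlation(
            t, habitat_meta(ids, ["gill"] * n, list(reversed(sorted(w))))
        )
        # reversing the weight *order* flips rho computed on sorted ranks
        w_sorted = sorted(w)
        r3 = mh.feature_weight_correlation(t, habitat_meta(ids, ["gill"] * n, w_sorted))
        assert np.allclose(r3["rho"], -r2["rho"], equal_nan=True)

    def test_constant_feature_missing(self):
        t, meta = self._table_meta([[0.5, 0.5], [0.5, 0.5], [0.5, 0.5], [0.5, 0.5]], [1, 2, 3, 4])
        res = mh.feature_weight_correlation(t, meta)
        assert res["rho"].isna().all()

    def test_requires_weights(self):
        t = mh.OtuTable(["w1", "w2"], ["o1"], np.array([[1], [2]]))
        meta = habitat_meta(["w1", "w2"], ["water", "water"])
        with pytest.raises(ValidationError, match="weight"):
            mh.feature_weight_correlation(t, meta)
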