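"""Null models of community assembly: betaMNTD/betaNTI, RC_Bray, classification."""

import itertools

import numpy as np
import pytest
from skbio import TreeNode

import metahab as mh
from metahab.assembly import (
    PROCESSES,
    RaupCrickNull,
    cophenetic_matrix,
    profile_from_turnover,
    within_group_pairs,
)
from metahab.model import ValidationError

from conftest import habitat_meta


def bmntd_oracle(x, y, d):
    """Independent double-loop betaMNTD."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    fx = x / x.sum()
    fy = y / y.sum()
    ix = [i for i in range(len(x)) if x[i] > 0]
    iy = [j for j in range(len(y)) if y[j] > 0]
    sx = sum(fx[i] * min(d[i][j] for j in iy) for i in ix)
    sy = sum(fy[j] * min(d[j][i] for i in ix) for j in iy)
    return 0.5 * (sx + sy)


class TestBmntd:
    def test_self_is_zero(self, four_tip_tree):
        x = np.array([3, 1, 0, 0])
        assert mh.bmntd(x, x, tree=four_tip_tree, otu_ids=list("ABCD")) == 0.0

    def test_star_tree_disjoint(self):
        b = 1.5
        star = TreeNode.read([f"(A:{b},B:{b},C:{b},D:{b});"])
        x = np.array([1, 1, 0, 0])
        y = np.array([0, 0, 1, 1])
        assert mh.bmntd(x, y, tree=star, otu_ids=list("ABCD")) == pytest.approx(2 * b)

    def test_four_tip_hand_value(self, four_tip_tree):
        x = np.array([1, 0, 0, 0])
        y = np.array([0, 0, 1, 0])
        assert mh.bmntd(x, y, tree=four_tip_tree, otu_ids=list("ABCD")) == pytest.approx(4.0)

    def test_shared_taxa_contribute_zero(self, four_tip_tree):
        # identical support, different abundances -> every taxon matches itself
        x = np.array([3, 1, 2, 0])
        y = np.array([1, 5, 9, 0])
        assert mh.bmntd(x, y, tree=four_tip_tree, otu_ids=list("ABCD")) == 0.0

    def test_matches_double_loop_oracle(self, rng):
        for seed in range(8):
            tree = mh.simulate_phylogeny(8, seed=seed)
            ids = [t.name for t in tree.tips()]
            d = cophenetic_matrix(tree, ids)
            x = rng.integers(0, 5, size=8)
            y = rng.integers(0, 5, size=8)
            if x.sum() == 0 or y.sum() == 0:
                continue
            assert mh.bmntd(x, y, dist=d) == pytest.approx(
                bmntd_oracle(x, y, d), abs=1e-12
            )

    def test_missing_otu_named(self, four_tip_tree):
        with pytest.raises(ValidationError, match="E"):
            mh.bmntd(
                np.array([1, 0, 0, 0, 2]),
                np.array([0, 1, 0, 0, 0]),
                tree=four_tip_tree,
                otu_ids=list("ABCDE"),
            )


class TestBnti:
    def test_identical_pair_nonpositive(self):
        tree = mh.simulate_phylogeny(10, seed=0)
        ids = [t.name for t in tree.tips()]
        x = np.zeros(10)
        x[:3] = (5, 2, 1)
        z = mh.bnti(x, x, tree=tree, otu_ids=ids, n_null=99, seed=1)
        assert z <= 0

    def test_exhaustive_five_tip_oracle(self):
        """Sampled null mean/sd match enumeration over all 120 tip relabelings."""
        tree = mh.simulate_phylogeny(5, seed=4)
        ids = [t.name for t in tree.tips()]
        d = cophenetic_matrix(tree, ids)
        x = np.array([4, 1, 0, 0, 0])
        y = np.array([0, 0, 3, 2, 0])
        exact = [
            bmntd_oracle(x[list(perm)], y[list(perm)], d)
            for perm in itertools.permutations(range(5))
        ]
        # relabeling taxa of the communities == relabeling tips of the tree
        mu_exact, sd_exact = np.mean(exact), np.std(exact)
        n_null = 4000
        z, obs, mu, sd = mh.bnti(
            x, y, dist=d, n_null=n_null, seed=9, full_output=True
        )
        se_mu = sd_exact / np.sqrt(n_null)
        se_sd = sd_exact / np.sqrt(2 * n_null)
        assert abs(mu - mu_exact) <= 3 * se_mu
        assert abs(sd - sd_exact) <= 3 * se_sd
        assert obs == pytest.approx(bmntd_oracle(x, y, d))

    def test_zero_spread_warns_and_zero(self):
        star = TreeNode.read(["(A:1,B:1,C:1,D:1);"])
        ids = list("ABCD")
        d = cophenetic_matrix(star, ids)
        x = np.array([1, 0, 0, 0])
        y = np.array([0, 1, 0, 0])
        with pytest.warns(UserWarning, match="zero spread"):
            z = mh.bnti(x, y, dist=d, n_null=99, seed=0)
        assert z == 0.0

    def test_clade_separation_increases_bnti(self):
        """Moving the partner community to the opposite clade raises betaNTI."""
        tree = TreeNode.read(
            ["((A:1,B:1,C:1,D:1):8,(E:1,F:1,G:1,H:1):8);"]
        )
        ids = list("ABCDEFGH")
        d = cophenetic_matrix(tree, ids)
        x = np.array([3, 2, 1, 1, 0, 0, 0, 0])
        same = np.array([1, 1, 2, 3, 0, 0, 0, 0])
        opposite = np.array([0, 0, 0, 0, 1, 1, 2, 3])
        z_same = np.mean(
            [mh.bnti(x, same, dist=d, n_null=199, seed=s) for s in range(10)]
        )
        z_opp = np.mean(
            [mh.bnti(x, opposite, dist=d, n_null=199, seed=s) for s in range(10)]
        )
        assert z_opp > z_same

    def test_n_null_floor(self):
        d = np.ones((3, 3)) - np.eye(3)
        with pytest.raises(ValidationError, match="99"):
            mh.bnti(np.array([1, 0, 0]), np.array([0, 1, 0]), dist=d, n_null=10)


def _context_table(rng, n_samples=10, n_otus=30, depth=300):
    counts = np.vstack(
        [rng.multinomial(depth, rng.dirichlet(np.ones(n_otus))) for _ in range(n_samples)]
    )
    return mh.OtuTable(
        [f"s{i}" for i in range(n_samples)], [f"o{j}" for j in range(n_otus)], counts
    )


class TestRcBray:
    def test_identical_common_pair_near_minus_one(self, rng):
        table = _context_table(rng)
        x = table.counts.sum(axis=0) // 2  # maximally common composition
        rc = mh.rc_bray(x, x, table, n_null=99, seed=0)
        assert rc <= -0.9

    def test_null_preserves_richness_and_reads(self, rng):
        table = _context_table(rng)
        ctx = RaupCrickNull(table)
        g = np.random.default_rng(0)
        null = ctx.sample_null(7, 120, g)
        assert (null > 0).sum() == 7
        assert null.sum() == 120

    def test_null_pairs_centered_at_zero(self, rng):
        """Pairs generated by the null model itself score RC ~ uniform(-1,1):
        centred near zero, not stacked at the extremes."""
        table = _context_table(rng, n_samples=12)
        ctx = RaupCrickNull(table)
        g = np.random.default_rng(99)
        rcs = [
            mh.rc_bray(
                ctx.sample_null(20, 300, g),
                ctx.sample_null(20, 300, g),
                table,
                n_null=299,
                seed=i,
            )
            for i in range(10)
        ]
        assert abs(np.mean(rcs)) < 0.45
        assert np.ptp(rcs) > 0.2  # genuinely spread, not degenerate

    def test_excess_richness_rejected(self, rng):
        table = _context_table(rng, n_otus=5)
        with pytest.raises(ValidationError, match="richness"):
            RaupCrickNull(table).sample_null(6, 100, np.random.default_rng(0))

    def test_deterministic(self, rng):
        table = _context_table(rng)
        a = mh.rc_bray(table.counts[0], table.counts[1], table, n_null=99, seed=3)
        b = mh.rc_bray(table.counts[0], table.counts[1], table, n_null=99, seed=3)
        assert a == b


class TestClassification:
    @pytest.mark.parametrize(
        "z,rc,expected",
        [
            (2.5, 0.0, "heterogeneous_selection"),
            (-2.5, 0.0, "homogeneous_selection"),
            (0.0, -0.97, "homogenizing_dispersal"),
            (0.0, 0.97, "dispersal_limitation"),
            (0.0, 0.0, "undominated"),
            (2.0, 0.0, "undominated"),  # boundary inclusive to non-selection
            (0.0, 0.95, "undominated"),
            (-2.0, -0.95, "undominated"),
        ],
    )
    def test_rules(self, z, rc, expected):
        assert mh.classify_process(z, rc) == expected

    def test_plane_partition(self):
        """Every grid point maps to exactly one of the five processes."""
        zs = np.linspace(-4, 4, 100)
        rcs = np.linspace(-1, 1, 100)
        seen = set()
        for z in zs:
            for rc in rcs:
                p = mh.classify_process(z, rc)
                assert p in PROCESSES
                seen.add(p)
        assert seen == set(PROCESSES)

    def test_rc_out_of_range(self):
        with pytest.raises(ValidationError):
            mh.classify_process(0.0, 1.5)


class TestProfiles:
    def test_three_samples_three_pairs(self, rng):
        table = _context_table(rng, n_samples=3, n_otus=20)
        tree = mh.simulate_phylogeny(20, seed=0)
        table = mh.OtuTable(table.sample_ids, [f"OTU_{j + 1}" for j in range(20)], table.counts)
        meta = habitat_meta(table.sample_ids, ["gill"] * 3)
        profiles = mh.assembly_profile(table, meta, tree, n_null=99, seed=0)
        prof = profiles["gill"]
        assert prof.n_pairs == 3
        assert sum(prof.fractions.values()) == pytest.approx(1.0, abs=1e-12)
        assert all(f in (0, 1 / 3, 2 / 3, 1.0) for f in prof.fractions.values())

    def test_within_group_pairs(self):
        meta = habitat_meta(["a", "b", "c", "d"], ["gill", "gill", "skin", "skin"])
        pairs = within_group_pairs(meta)
        assert pairs["gill"] == [("a", "b")]
        assert pairs["skin"] == [("c", "d")]

    def test_profile_fraction_arithmetic(self):
        import pandas as pd

        turnover = pd.DataFrame({"process": ["undominated"] * 2 + ["dispersal_limitation"]})
        prof = profile_from_turnover(turnover, "g")
        assert prof.fractions["undominated"] == pytest.approx(2 / 3)
        assert prof.fractions["heterogeneous_selection"] == 0.0
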