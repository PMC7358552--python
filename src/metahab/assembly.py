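"""Null-model quantification of community assembly processes.

For every sample pair, two null models position the observed turnover
against chance expectations:

* **betaMNTD / betaNTI** — the abundance-weighted mean distance from each
  taxon to its nearest relative in the other community, standardised
  against a null that shuffles tip labels across the whole regional tree.
  betaNTI > +2 indicates heterogeneous selection, betaNTI < -2 homogeneous
  selection.
* **RC_Bray** — the position of the observed Bray-Curtis dissimilarity
  within a null that reassembles both communities at fixed richness and
  read depth, drawing taxa by occupancy frequency and reads by
  metacommunity relative abundance; rescaled to [-1, 1].

Pairs with |betaNTI| <= 2 fall through to RC_Bray: < -0.95 homogenizing
dispersal, > +0.95 dispersal limitation, otherwise undominated.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis
from skbio import TreeNode

from .model import OtuTable, ValidationError, spawn_seeds

logger = logging.getLogger(__name__)

PROCESSES = (
    "heterogeneous_selection",
    "homogeneous_selection",
    "homogenizing_dispersal",
    "dispersal_limitation",
    "undominated",
)

BNTI_THRESHOLD = 2.0
RC_THRESHOLD = 0.95


@dataclass
class PairwiseTurnover:
    sample_a: str
    sample_b: str
    bmntd_obs: float
    bnti: float
    rc_bray: float
    process: str


@dataclass
class AssemblyProfile:
    group: str
    n_pairs: int
    fractions: dict[str, float]


def cophenetic_matrix(tree: TreeNode, otu_ids: list[str]) -> np.ndarray:
    """Tip-to-tip path-length matrix ordered by ``otu_ids``."""
    dm = tree.tip_tip_distances()
    missing = [o for o in otu_ids if o not in dm.ids]
    if missing:
        raise ValidationError(f"OTU(s) absent from tree: {missing[:5]}")
    return np.asarray(dm.filter(otu_ids).data, dtype=float)


def _bmntd_from_dist(
    fx: np.ndarray, ix: np.ndarray, fy: np.ndarray, iy: np.ndarray, d: np.ndarray
) -> float:
    """Abundance-weighted betaMNTD given nonzero index sets and distances."""
    sub = d[np.ix_(ix, iy)]
    return 0.5 * (float(fx @ sub.min(axis=1)) + float(fy @ sub.min(axis=0)))


def bmntd(
    x: np.ndarray,
    y: np.ndarray,
    tree: TreeNode | None = None,
    otu_ids: list[str] | None = None,
    dist: np.ndarray | None = None,
) -> float:
    """Abundance-weighted beta mean-nearest-taxon distance between two samples.

    ``x`` and ``y`` are count (or abundance) vectors over ``otu_ids``.
    Distances may be supplied directly (``dist``) or derived from ``tree``.
    Taxa present in both communities contribute zero (their nearest
    neighbour in the other community is themselves).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if dist is None:
        if tree is None or otu_ids is None:
            raise ValidationError("bmntd needs either dist or (tree, otu_ids)")
        nz = sorted(set(np.nonzero(x)[0]) | set(np.nonzero(y)[0]))
        ids = [otu_ids[i] for i in nz]
        dist_nz = cophenetic_matrix(tree, ids)
        remap = {orig: k for k, orig in enumerate(nz)}
        ix = np.array([remap[i] for i in np.nonzero(x)[0]])
        iy = np.array([remap[i] for i in np.nonzero(y)[0]])
        fx = x[x > 0] / x.sum()
        fy = y[y > 0] / y.sum()
        return _bmntd_from_dist(fx, ix, fy, iy, dist_nz)
    if x.sum() == 0 or y.sum() == 0:
        raise ValidationError("empty sample in bmntd")
    ix = np.nonzero(x)[0]
    iy = np.nonzero(y)[0]
    fx = x[ix] / x.sum()
    fy = y[iy] / y.sum()
    return _bmntd_from_dist(fx, ix, fy, iy, dist)


def bnti(
    x: np.ndarray,
    y: np.ndarray,
    tree: TreeNode | None = None,
    otu_ids: list[str] | None = None,
    n_null: int = 999,
    seed: int | None = None,
    dist: np.ndarray | None = None,
    null_perms: np.ndarray | None = None,
    full_output: bool = False,
):
    """Standardised effect size of betaMNTD against a tip-shuffling null.

    The null shuffles tip labels uniformly across ALL tips of the regional
    tree (equivalently, permutes the rows/columns of the full cophenetic
    matrix) and recomputes betaMNTD ``n_null`` times.  Precomputed
    permutations may be shared across pairs via ``null_perms``.  With
    ``full_output`` returns ``(bnti, bmntd_obs, null_mean, null_sd)``.
    """
    if n_null < 99:
        raise ValidationError("n_null must be >= 99")
    if dist is None:
        if tree is None or otu_ids is None:
            raise ValidationError("bnti needs either dist or (tree, otu_ids)")
        dist = cophenetic_matrix(tree, otu_ids)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ix = np.nonzero(x)[0]
    iy = np.nonzero(y)[0]
    if len(ix) == 0 or len(iy) == 0:
        raise ValidationError("empty sample in bnti")
    fx = x[ix] / x.sum()
    fy = y[iy] / y.sum()
    obs = _bmntd_from_dist(fx, ix, fy, iy, dist)
    npool = dist.shape[0]
    if null_perms is None:
        rng = np.random.default_rng(seed)
        null_perms = np.array([rng.permutation(npool) for _ in range(n_null)])
    nulls = np.empty(len(null_perms))
    for k, perm in enumerate(null_perms):
        nulls[k] = _bmntd_from_dist(fx, perm[ix], fy, perm[iy], dist)
    sd = nulls.std(ddof=0)
    mean = nulls.mean()
    if sd == 0:
        warnings.warn(
            "bnti: null distribution has zero spread; reporting 0",
            UserWarning,
            stacklevel=2,
        )
        z = 0.0
    else:
        z = float((obs - mean) / sd)
    if full_output:
        return z, obs, float(mean), float(sd)
    return z


class RaupCrickNull:
    """Shared metacommunity context for RC_Bray nulls.

    Null communities preserve each sample's observed richness and total
    reads: taxa are selected sequentially without replacement with
    probability proportional to occupancy frequency across all samples of
    the reference table; reads are then allocated to the selected taxa by a
    multinomial draw with probabilities proportional to metacommunity-wide
    relative abundances.
    """

    def __init__(self, table: OtuTable):
        occupancy = (table.counts > 0).sum(axis=0).astype(float)
        totals = table.counts.sum(axis=0).astype(float)
        if occupancy.sum() == 0:
            raise ValidationError("empty metacommunity")
        self.occupancy = occupancy / occupancy.sum()
        self.abundance = totals / totals.sum()
        self.pool = int((occupancy > 0).sum())
        self.n_otus = table.n_otus

    def sample_null(self, richness: int, reads: int, rng: np.random.Generator) -> np.ndarray:
        if richness > self.pool:
            raise ValidationError(
                f"sample richness {richness} exceeds occupied pool {self.pool}"
            )
        chosen = rng.choice(
            self.n_otus, size=richness, replace=False, p=self.occupancy
        )
        p = self.abundance[chosen]
        if p.sum() == 0:
            p = np.full(richness, 1.0 / richness)
        else:
            p = p / p.sum()
        out = np.zeros(self.n_otus)
        # every selected taxon keeps at least one read (fixed richness)
        out[chosen] = 1
        if reads > richness:
            out[chosen] += rng.multinomial(reads - richness, p)
        return out


def rc_bray(
    x: np.ndarray,
    y: np.ndarray,
    table: OtuTable,
    n_null: int = 999,
    seed: int | None = None,
    null_ctx: RaupCrickNull | None = None,
) -> float:
    """Raup-Crick position of observed Bray-Curtis within the assembly null.

    RC_raw = (#{null < obs} + 0.5 #{|null - obs| <= 1e-10}) / n_null,
    rescaled as 2*RC_raw - 1 into [-1, 1].
    """
    if n_null < 99:
        raise ValidationError("n_null must be >= 99")
    ctx = null_ctx if null_ctx is not None else RaupCrickNull(table)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    obs = float(braycurtis(x, y))
    rng = np.random.default_rng(seed)
    rx, ry = int((x > 0).sum()), int((y > 0).sum())
    tx, ty = int(x.sum()), int(y.sum())
    below = ties = 0
    for _ in range(n_null):
        bc = braycurtis(ctx.sample_null(rx, tx, rng), ctx.sample_null(ry, ty, rng))
        if abs(bc - obs) <= 1e-10:
            ties += 1
        elif bc < obs:
            below += 1
    rc_raw = (below + 0.5 * ties) / n_null
    return float(2.0 * rc_raw - 1.0)


def classify_process(bnti_value: float, rc: float) -> str:
    """Five-way assembly-process call from (betaNTI, RC_Bray).

    Selection when |betaNTI| > 2 (sign separates heterogeneous from
    homogeneous); otherwise RC_Bray < -0.95 homogenizing dispersal,
    > +0.95 dispersal limitation, else undominated.  Boundary ties fall to
    the non-selection / undominated side.
    """
    if not -1.0 - 1e-9 <= rc <= 1.0 + 1e-9:
        raise ValidationError(f"RC_Bray out of [-1, 1]: {rc}")
    if bnti_value > BNTI_THRESHOLD:
        return "heterogeneous_selection"
    if bnti_value < -BNTI_THRESHOLD:
        return "homogeneous_selection"
    if rc < -RC_THRESHOLD:
        return "homogenizing_dispersal"
    if rc > RC_THRESHOLD:
        return "dispersal_limitation"
    return "undominated"


def pairwise_turnover(
    table: OtuTable,
    tree: TreeNode,
    pairs: list[tuple[str, str]],
    n_null: int = 999,
    seed: int | None = None,
    rc_table: OtuTable | None = None,
) -> pd.DataFrame:
    """betaMNTD, betaNTI, RC_Bray and the process call for each pair.

    The betaNTI null permutations and the RC metacommunity context are
    shared across pairs for efficiency.  ``rc_table`` sets the
    metacommunity reference for RC nulls (defaults to ``table``).
    """
    dist = cophenetic_matrix(tree, table.otu_ids)
    ctx = RaupCrickNull(rc_table if rc_table is not None else table)
    s_perm, s_rc = spawn_seeds(seed if seed is not None else 0, 2)
    rng = np.random.default_rng(s_perm)
    null_perms = np.array([rng.permutation(dist.shape[0]) for _ in range(n_null)])
    rows = []
    for k, (a, b) in enumerate(pairs):
        x = table.sample_vector(a).astype(float)
        y = table.sample_vector(b).astype(float)
        obs = bmntd(x, y, dist=dist)
        z = bnti(x, y, dist=dist, n_null=n_null, null_perms=null_perms)
        rc = rc_bray(x, y, table, n_null=n_null, seed=s_rc + k, null_ctx=ctx)
        rows.append(
            {
                "sample_a": a,
                "sample_b": b,
                "bmntd_obs": obs,
                "bnti": z,
                "rc_bray": rc,
                "process": classify_process(z, rc),
            }
        )
    return pd.DataFrame(rows)


def within_group_pairs(meta: pd.DataFrame, group_by: str = "habitat") -> dict[str, list]:
    out: dict[str, list] = {}
    for g, sub in meta.groupby(group_by, sort=False):
        ids = list(sub.index)
        out[g] = [(ids[i], ids[j]) for i in range(len(ids)) for j in range(i + 1, len(ids))]
    return out


def profile_from_turnover(turnover: pd.DataFrame, group: str) -> AssemblyProfile:
    """Process fractions over a set of classified pairs (exact rationals)."""
    n = len(turnover)
    counts = turnover["process"].value_counts()
    fractions = {p: float(counts.get(p, 0)) / n for p in PROCESSES}
    return AssemblyProfile(group=group, n_pairs=n, fractions=fractions)


def assembly_profile(
    table: OtuTable,
    meta: pd.DataFrame,
    tree: TreeNode,
    group_by: str = "habitat",
    n_null: int = 999,
    seed: int | None = None,
) -> dict[str, AssemblyProfile]:
    """Per-group process-fraction profiles over within-group sample pairs.

    Groups with fewer than 2 samples are skipped with a warning.  Samples
    are pooled across sites and months within each group.
    """
    meta = meta.loc[[s for s in table.sample_ids if s in meta.index]]
    profiles: dict[str, AssemblyProfile] = {}
    sub_seeds = spawn_seeds(seed if seed is not None else 0, max(len(set(meta[group_by])), 1))
    for k, (g, pairs) in enumerate(within_group_pairs(meta, group_by).items()):
        if not pairs:
            logger.warning("group %r has < 2 samples; skipped", g)
            continue
        turnover = pairwise_turnover(
            table, tree, pairs, n_null=n_null, seed=sub_seeds[k]
        )
        profiles[g] = profile_from_turnover(turnover, g)
    return profiles
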