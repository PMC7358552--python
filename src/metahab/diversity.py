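"""Alpha/beta diversity, ordination, group tests and feature correlations.

Chao1 and Bray-Curtis come from scikit-bio/scipy; PCoA wraps scikit-bio's
implementation with an explicit retention rule (positive eigenvalues only,
proportions over the positive-eigenvalue sum).  PERMANOVA and ANOSIM
delegate to scikit-bio.  The Mantel family (simple and partial, with
simultaneous row/column permutation) is implemented here because no
installed package provides the partial variant; the simple case is
cross-checked against scikit-bio in the test suite.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import false_discovery_control, spearmanr
from skbio import DistanceMatrix
from skbio.diversity.alpha import chao1 as _skbio_chao1
from skbio.stats.distance import anosim as _skbio_anosim
from skbio.stats.distance import permanova as _skbio_permanova
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .model import OtuTable, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class OrdinationResult:
    """PCoA embedding: sample coordinates with per-axis variance explained."""

    axes: pd.DataFrame  # samples x retained axes
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


@dataclass
class GroupTestResult:
    statistic_name: str  # pseudo_F | R2 | anosim_R | mantel_r
    statistic: float
    permutations: int
    p_value: float
    extras: dict | None = None


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1-1) / (2(F2+1))."""
    counts = np.asarray(counts)
    if counts.sum() == 0:
        warnings.warn("chao1: empty sample, returning 0", UserWarning, stacklevel=2)
        return 0.0
    return float(_skbio_chao1(counts.astype(int), bias_corrected=True))


def alpha_diversity(table: OtuTable) -> pd.Series:
    """Per-sample Chao1."""
    return pd.Series(
        [chao1(row) for row in table.counts], index=table.sample_ids, name="chao1"
    )


def bray_curtis(table: OtuTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity on counts, in [0, 1].

    A pair of all-zero samples is assigned distance 0 with a warning
    (scipy leaves it undefined).
    """
    if table.n_samples < 2:
        raise ValidationError("need >= 2 samples for a distance matrix")
    with np.errstate(invalid="ignore"):
        condensed = pdist(table.counts.astype(float), metric="braycurtis")
    if np.isnan(condensed).any():
        warnings.warn(
            "bray_curtis: pair(s) of all-zero samples assigned distance 0",
            UserWarning,
            stacklevel=2,
        )
        condensed = np.nan_to_num(condensed, nan=0.0)
    return DistanceMatrix(squareform(condensed), ids=table.sample_ids)


def pcoa(dm: DistanceMatrix) -> OrdinationResult:
    """Principal coordinate analysis (Gower double-centering + eigh).

    Axes with eigenvalue > 1e-10 are retained; ``proportion_explained``
    uses the sum of positive eigenvalues as denominator.
    """
    if not isinstance(dm, DistanceMatrix):
        dm = DistanceMatrix(dm)  # raises on asymmetric input
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # negative-eigenvalue chatter
        res = _skbio_pcoa(dm, method="eigh", warn_neg_eigval=False)
    eig = res.eigvals.to_numpy()
    keep = eig > 1e-10
    pos_sum = eig[eig > 0].sum()
    axes = res.samples.loc[:, keep]
    axes.index = list(dm.ids)
    return OrdinationResult(
        axes=axes,
        eigenvalues=eig[keep],
        proportion_explained=eig[keep] / pos_sum if pos_sum > 0 else eig[keep],
    )


def _grouping(dm: DistanceMatrix, groups) -> pd.Series:
    groups = pd.Series(groups) if not isinstance(groups, pd.Series) else groups
    if set(groups.index) >= set(dm.ids):
        groups = groups.loc[list(dm.ids)]
    if len(groups) != len(dm.ids):
        raise ValidationError("grouping length does not match distance matrix")
    sizes = groups.value_counts()
    if len(sizes) < 2:
        raise ValidationError("need >= 2 groups")
    if (sizes < 2).any():
        raise ValidationError(f"group(s) of size 1: {list(sizes[sizes < 2].index)}")
    return groups


def permanova(
    dm: DistanceMatrix, groups, permutations: int = 999, seed: int | None = None
) -> GroupTestResult:
    """Permutational MANOVA across groups; reports pseudo-F and R^2."""
    groups = _grouping(dm, groups)
    res = _skbio_permanova(dm, list(groups), permutations=permutations, seed=seed)
    f = float(res["test statistic"])
    n, k = len(dm.ids), groups.nunique()
    # F = (SSA/(k-1)) / (SSW/(n-k))  =>  R2 = SSA / (SSA + SSW)
    r2 = 1.0 / (1.0 + (n - k) / ((k - 1) * f)) if f > 0 else 0.0
    return GroupTestResult(
        "pseudo_F", f, permutations, float(res["p-value"]), extras={"R2": r2}
    )


def anosim(
    dm: DistanceMatrix, groups, permutations: int = 999, seed: int | None = None
) -> GroupTestResult:
    """Rank-based ANOSIM R in [-1, 1] with permutation p-value."""
    groups = _grouping(dm, groups)
    res = _skbio_anosim(dm, list(groups), permutations=permutations, seed=seed)
    return GroupTestResult(
        "anosim_R", float(res["test statistic"]), permutations, float(res["p-value"])
    )


def _condensed(dm: DistanceMatrix) -> np.ndarray:
    return squareform(np.asarray(dm.data), checks=False)


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    permutations: int = 10000,
    partial: DistanceMatrix | None = None,
    seed: int | None = None,
) -> GroupTestResult:
    """(Partial) Mantel test between two distance matrices.

    Pearson r over upper-triangle entries; with ``partial`` the correlation
    is between residuals of both matrices after regressing each on the
    third.  The p-value permutes rows and columns of ``d1`` simultaneously
    (two-sided, with +1 smoothing).
    """
    if list(d1.ids) != list(d2.ids):
        if set(d1.ids) != set(d2.ids):
            raise ValidationError("distance matrices have mismatched ids")
        d2 = d2.filter(d1.ids)
    if partial is not None and list(partial.ids) != list(d1.ids):
        if set(partial.ids) != set(d1.ids):
            raise ValidationError("partial matrix has mismatched ids")
        partial = partial.filter(d1.ids)
    if permutations < 1:
        raise ValidationError("permutations must be >= 1")
    n = len(d1.ids)
    sq1 = np.asarray(d1.data)
    x2 = _condensed(d2)
    x3 = _condensed(partial) if partial is not None else None

    def corr(v1: np.ndarray) -> float:
        if x3 is None:
            return float(np.corrcoef(v1, x2)[0, 1])
        r12 = np.corrcoef(v1, x2)[0, 1]
        r13 = np.corrcoef(v1, x3)[0, 1]
        r23 = np.corrcoef(x2, x3)[0, 1]
        den = np.sqrt((1 - r13**2) * (1 - r23**2))
        return float((r12 - r13 * r23) / den) if den > 0 else 0.0

    r_obs = corr(_condensed(d1))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        v1 = squareform(sq1[np.ix_(perm, perm)], checks=False)
        if abs(corr(v1)) >= abs(r_obs) - 1e-12:
            hits += 1
    p = (hits + 1) / (permutations + 1)
    return GroupTestResult("mantel_r", r_obs, permutations, p)


def feature_weight_correlation(table: OtuTable, meta: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlation of each OTU's relative abundance with body weight.

    Returns a frame indexed by OTU id with ``rho``, ``p`` and BH-adjusted
    ``q``.  Constant features yield missing rho/p and are excluded from the
    BH correction.
    """
    meta = meta.loc[list(table.sample_ids)]
    w = meta["body_weight_g"].to_numpy(dtype=float)
    if np.isnan(w).any():
        raise ValidationError("all samples must have body weight")
    rel = table.relative_abundance()
    rho = np.full(table.n_otus, np.nan)
    pval = np.full(table.n_otus, np.nan)
    for j in range(table.n_otus):
        col = rel[:, j]
        if np.ptp(col) == 0:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r, p = spearmanr(col, w)
        rho[j], pval[j] = r, p
    q = np.full(table.n_otus, np.nan)
    ok = ~np.isnan(pval)
    if ok.any():
        q[ok] = false_discovery_control(pval[ok], method="bh")
    return pd.DataFrame({"rho": rho, "p": pval, "q": q}, index=table.otu_ids)
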