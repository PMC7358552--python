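"""Hierarchical additive diversity partitioning with Rao quadratic entropy.

Total metacommunity diversity is decomposed over three nested scales:

    gamma_ecosystem = beta_inter_habitats + mean beta_intra_habitat
                      + mean alpha_local_community

Rao's Q(p, d) = sum_ij d_ij p_i p_j is the expected dissimilarity between
two randomly drawn reads.  With the taxonomic distance (d_ij = 1 for
i != j) Q reduces to Gini-Simpson; with phylogenetic distances d is the
cophenetic matrix rescaled into [0, 1].

Pooling is by unweighted means: every sample counts equally within its
habitat and every habitat counts equally within the ecosystem, so habitats
with unequal sample numbers are treated symmetrically.

The ``equivalent_numbers`` correction (Jost) transforms each *averaged* Q
to 1/(1-Q) before differencing.  The top-level components come from the
telescoping chain

    L0 = T(mean_h alpha_h)   L1 = T(mean_h gamma_h)   L2 = T(gamma_eco)

with alpha = L0, beta_intra = L1 - L0, beta_inter = L2 - L1, which keeps
additivity exact and every component non-negative whenever Q is concave
(taxonomic distances; ultrametric phylogenetic distances).  Per-habitat
corrected beta_intra,h = T(gamma_h) - T(alpha_h) is reported for each
habitat but, being a nonlinear transform, does not average to the pooled
corrected beta_intra.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

from .model import OtuTable, ValidationError


@dataclass
class DiversityPartition:
    gamma_ecosystem: float
    beta_inter_habitats: float
    beta_intra_mean: float
    alpha_local_mean: float
    per_habitat: pd.DataFrame  # gamma_habitat, beta_intra, alpha_local_mean, beta_intra_percent
    percents: dict[str, float]  # each top-level component as % of gamma_ecosystem
    distance_mode: str
    correction: str


def rao_entropy(p: np.ndarray, d: np.ndarray | None = None) -> float:
    """Rao quadratic entropy Q = sum_ij d_ij p_i p_j.

    ``d=None`` uses the taxonomic distance (1 off-diagonal), for which
    Q = 1 - sum p_i^2 (Gini-Simpson).
    """
    p = np.asarray(p, dtype=float)
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValidationError(f"abundance vector sums to {p.sum()}, not 1")
    if d is None:
        return float(1.0 - p @ p)
    d = np.asarray(d, dtype=float)
    return float(p @ d @ p)


def taxon_distance_matrix(
    otu_ids: list[str], mode: str = "taxonomic", tree: TreeNode | None = None
) -> np.ndarray | None:
    """Build the taxon dissimilarity matrix for the requested mode.

    Taxonomic mode returns None (handled in closed form).  Phylogenetic
    mode returns cophenetic distances divided by their maximum, so Q stays
    comparable across modes.
    """
    if mode == "taxonomic":
        return None
    if mode != "phylogenetic":
        raise ValidationError(f"unknown distance mode {mode!r}")
    if tree is None:
        raise ValidationError("phylogenetic mode requires a tree")
    dm = tree.tip_tip_distances()
    missing = [o for o in otu_ids if o not in dm.ids]
    if missing:
        raise ValidationError(f"OTU(s) absent from tree: {missing[:5]}")
    d = np.asarray(dm.filter(otu_ids).data, dtype=float)
    dmax = d.max()
    return d / dmax if dmax > 0 else d


def _equiv(q: float) -> float:
    if q >= 1.0:
        raise ValidationError("Q >= 1 cannot be converted to equivalent numbers")
    return 1.0 / (1.0 - q)


def partition_diversity(
    table: OtuTable,
    meta: pd.DataFrame,
    distance_mode: str = "taxonomic",
    correction: str = "equivalent_numbers",
    tree: TreeNode | None = None,
) -> DiversityPartition:
    """Three-level additive Rao partition of a habitat-structured table."""
    if correction not in ("none", "equivalent_numbers"):
        raise ValidationError(f"unknown correction {correction!r}")
    meta = meta.loc[[s for s in table.sample_ids if s in meta.index]]
    habitats = list(dict.fromkeys(meta["habitat"]))
    if len(habitats) < 2:
        raise ValidationError("need >= 2 habitats for a partition")
    d = taxon_distance_matrix(table.otu_ids, distance_mode, tree)
    rel = pd.DataFrame(
        table.relative_abundance(), index=table.sample_ids, columns=table.otu_ids
    )

    alpha_h: dict[str, float] = {}
    gamma_h: dict[str, float] = {}
    habitat_profiles = []
    for h in habitats:
        ids = meta.index[meta["habitat"] == h]
        profiles = rel.loc[ids].to_numpy()
        if profiles.sum() == 0:
            raise ValidationError(f"habitat {h!r} has zero total counts")
        alphas = [rao_entropy(p, d) for p in profiles]
        alpha_h[h] = float(np.mean(alphas))
        mean_profile = profiles.mean(axis=0)
        gamma_h[h] = rao_entropy(mean_profile, d)
        habitat_profiles.append(mean_profile)
    gamma_eco = rao_entropy(np.mean(habitat_profiles, axis=0), d)

    mean_alpha = float(np.mean(list(alpha_h.values())))
    mean_gamma_h = float(np.mean(list(gamma_h.values())))
    if correction == "none":
        l0, l1, l2 = mean_alpha, mean_gamma_h, gamma_eco
        per_gamma = {h: gamma_h[h] for h in habitats}
        per_alpha = {h: alpha_h[h] for h in habitats}
    else:
        l0, l1, l2 = _equiv(mean_alpha), _equiv(mean_gamma_h), _equiv(gamma_eco)
        per_gamma = {h: _equiv(gamma_h[h]) for h in habitats}
        per_alpha = {h: _equiv(alpha_h[h]) for h in habitats}

    alpha_mean = l0
    beta_intra = l1 - l0
    beta_inter = l2 - l1
    per_habitat = pd.DataFrame(
        {
            "gamma_habitat": per_gamma,
            "beta_intra": {h: per_gamma[h] - per_alpha[h] for h in habitats},
            "alpha_local_mean": per_alpha,
        }
    ).loc[habitats]
    per_habitat["beta_intra_percent"] = np.where(
        per_habitat["gamma_habitat"] > 0,
        100.0 * per_habitat["beta_intra"] / per_habitat["gamma_habitat"],
        0.0,
    )
    percents = (
        {
            "alpha_local_mean": 100.0 * alpha_mean / l2,
            "beta_intra_mean": 100.0 * beta_intra / l2,
            "beta_inter_habitats": 100.0 * beta_inter / l2,
        }
        if l2 > 0
        else {"alpha_local_mean": 0.0, "beta_intra_mean": 0.0, "beta_inter_habitats": 0.0}
    )
    return DiversityPartition(
        gamma_ecosystem=l2,
        beta_inter_habitats=beta_inter,
        beta_intra_mean=beta_intra,
        alpha_local_mean=alpha_mean,
        per_habitat=per_habitat,
        percents=percents,
        distance_mode=distance_mode,
        correction=correction,
    )
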