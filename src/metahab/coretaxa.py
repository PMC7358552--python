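"""Per-habitat core OTU calling and shared/unique (Venn) partitioning.

An OTU is core to a habitat when its relative abundance exceeds the
abundance threshold (default 1%) in strictly more than the prevalence
threshold (default 80%) of that habitat's samples.  A stricter literal
mode additionally requires the abundance gate in every sample where the
OTU is detected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import OtuTable, ValidationError


@dataclass
class CoreSet:
    habitat: str
    core_otu_ids: set[str]
    prevalence: pd.Series  # per-OTU fraction of samples passing the abundance gate
    core_abundance_fraction: float  # mean per-sample summed relative abundance of the core


def find_core(
    table: OtuTable,
    meta: pd.DataFrame,
    habitat: str,
    prevalence_threshold: float = 0.8,
    abundance_threshold: float = 0.01,
    mode: str = "prevalence",
) -> CoreSet:
    """Identify the core OTUs of one habitat.

    ``mode="prevalence"`` (default): core iff rel. abundance >
    ``abundance_threshold`` in > ``prevalence_threshold`` of samples.
    ``mode="strict"``: additionally requires the abundance gate in every
    sample where the OTU is detected at all.
    Both thresholds are strict inequalities.
    """
    for name, t in (("prevalence", prevalence_threshold), ("abundance", abundance_threshold)):
        if not 0.0 < t < 1.0:
            raise ValidationError(f"{name}_threshold must be in (0, 1), got {t}")
    samples = [s for s in table.sample_ids if s in meta.index and meta.at[s, "habitat"] == habitat]
    if not samples:
        raise ValidationError(f"habitat {habitat!r} has no samples")
    sub = table.select_samples(samples)
    rel = sub.relative_abundance()
    passing = rel > abundance_threshold
    prevalence = pd.Series(passing.mean(axis=0), index=table.otu_ids, name="prevalence")
    core_mask = prevalence.to_numpy() > prevalence_threshold
    if mode == "strict":
        detected = sub.counts > 0
        always_pass = (passing | ~detected).all(axis=0) & detected.any(axis=0)
        core_mask &= always_pass
    elif mode != "prevalence":
        raise ValidationError(f"unknown core mode {mode!r}")
    core_ids = {o for o, m in zip(table.otu_ids, core_mask) if m}
    frac = float(rel[:, core_mask].sum(axis=1).mean()) if core_mask.any() else 0.0
    return CoreSet(habitat, core_ids, prevalence, frac)


def core_overlap(core_sets: list[CoreSet]) -> dict[tuple[str, ...], set[str]]:
    """Venn partition of core OTUs across habitats.

    Maps each habitat combination (sorted tuple) to the OTUs core in
    exactly that combination; only non-empty cells are returned and the
    cells partition the union of all core sets.
    """
    if len(core_sets) < 2:
        raise ValidationError("need >= 2 core sets for an overlap table")
    habitats = [c.habitat for c in core_sets]
    if len(set(habitats)) != len(habitats):
        raise ValidationError("duplicate habitat in core sets")
    membership: dict[str, set[str]] = {}
    for c in core_sets:
        for otu in c.core_otu_ids:
            membership.setdefault(otu, set()).add(c.habitat)
    partition: dict[tuple[str, ...], set[str]] = {}
    for otu, habs in membership.items():
        key = tuple(sorted(habs))
        partition.setdefault(key, set()).add(otu)
    return partition


def overlap_counts(partition: dict[tuple[str, ...], set[str]]) -> pd.Series:
    """Cell sizes of a Venn partition, keyed by '&'-joined habitat combos."""
    return pd.Series(
        {"&".join(k): len(v) for k, v in sorted(partition.items())}, dtype=int
    )
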