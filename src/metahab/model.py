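"""Core domain types: OTU tables, sample metadata, phylogenies, rarefaction.

The pipeline's universal currency is the :class:`OtuTable` — a dense
samples x OTUs matrix of non-negative integer read counts with aligned
identifiers.  Sample metadata travels as a pandas ``DataFrame`` validated by
:func:`validate_metadata`; phylogenies are scikit-bio ``TreeNode`` objects
validated by :func:`validate_phylogeny`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger(__name__)

#: Recognised body habitats (four fish mucosal habitats plus ambient water).
HABITATS = ("skin", "gill", "stomach", "hindgut", "water")

#: Fixed-depth normalisation default: reads retained per sample.
DEFAULT_RAREFACTION_DEPTH = 23875

METADATA_COLUMNS = ("sample_id", "habitat", "body_weight_g", "site", "month")


class ValidationError(ValueError):
    """Raised when an input violates a domain invariant."""


@dataclass
class OtuTable:
    """Samples x OTUs count matrix with aligned identifiers.

    Parameters
    ----------
    sample_ids : list of str
        Unique sample identifiers, one per matrix row.
    otu_ids : list of str
        Unique OTU identifiers, one per matrix column.
    counts : ndarray of int, shape (n_samples, n_otus)
        Non-negative integer read counts.
    """

    sample_ids: list[str]
    otu_ids: list[str]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.otu_ids = [str(o) for o in self.otu_ids]
        counts = np.asarray(self.counts)
        if counts.size == 0:
            raise ValidationError("empty OTU table")
        if counts.ndim != 2 or counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise ValidationError(f"duplicate sample id: {dupes}")
        if len(set(self.otu_ids)) != len(self.otu_ids):
            dupes = sorted({o for o in self.otu_ids if self.otu_ids.count(o) > 1})
            raise ValidationError(f"duplicate OTU id: {dupes}")
        if np.any(~np.isfinite(counts.astype(float))):
            raise ValidationError("counts contain NaN or infinite values")
        if np.any(counts < 0):
            raise ValidationError("counts must be non-negative")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValidationError("counts must be integral")
            counts = np.round(counts).astype(np.int64)
        self.counts = np.ascontiguousarray(counts, dtype=np.int64)

    # -- basic views -------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> np.ndarray:
        """Row-normalised counts; all-zero samples stay all-zero."""
        totals = self.sample_totals().astype(float)
        safe = np.where(totals > 0, totals, 1.0)
        return self.counts / safe[:, None]

    def to_dataframe(self) -> pd.DataFrame:
        """Samples x OTUs DataFrame view."""
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)

    # -- reindexing helpers ------------------------------------------------

    def select_samples(self, sample_ids: list[str]) -> "OtuTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return OtuTable(list(sample_ids), list(self.otu_ids), self.counts[idx])

    def sample_vector(self, sample_id: str) -> np.ndarray:
        return self.counts[self.sample_ids.index(sample_id)]

    def drop_empty_otus(self) -> "OtuTable":
        keep = self.counts.sum(axis=0) > 0
        return OtuTable(
            list(self.sample_ids),
            [o for o, k in zip(self.otu_ids, keep) if k],
            self.counts[:, keep],
        )


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate a per-sample metadata frame.

    Requires columns ``sample_id, habitat, body_weight_g, site, month``;
    habitat must be one of :data:`HABITATS`; body weight must be a positive
    real for every non-water sample (water may be missing).  Returns a copy
    indexed by ``sample_id``.
    """
    meta = meta.copy()
    if meta.index.name == "sample_id":
        meta = meta.reset_index()
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValidationError(f"metadata missing columns: {missing}")
    meta["sample_id"] = meta["sample_id"].astype(str).str.strip()
    if meta["sample_id"].duplicated().any():
        dupes = sorted(meta.loc[meta["sample_id"].duplicated(), "sample_id"])
        raise ValidationError(f"duplicate sample id in metadata: {dupes}")
    meta["habitat"] = meta["habitat"].astype(str).str.strip().str.lower()
    bad = sorted(set(meta["habitat"]) - set(HABITATS))
    if bad:
        raise ValidationError(
            f"unknown habitat value(s) {bad}; allowed habitats are {list(HABITATS)}"
        )
    meta["body_weight_g"] = pd.to_numeric(meta["body_weight_g"], errors="coerce")
    nonwater = meta["habitat"] != "water"
    if meta.loc[nonwater, "body_weight_g"].isna().any():
        bad_ids = sorted(meta.loc[nonwater & meta["body_weight_g"].isna(), "sample_id"])
        raise ValidationError(f"body_weight_g missing for non-water sample(s): {bad_ids}")
    if (meta["body_weight_g"].dropna() <= 0).any():
        raise ValidationError("body_weight_g must be positive")
    meta["site"] = meta["site"].astype(str).str.strip()
    meta["month"] = meta["month"].astype(str).str.strip()
    return meta.set_index("sample_id", drop=False)


def validate_phylogeny(tree: TreeNode) -> TreeNode:
    """Check tip-label uniqueness and presence of tip branch lengths."""
    tips = list(tree.tips())
    names = [t.name for t in tips]
    if any(n is None for n in names):
        raise ValidationError("tree has unnamed tips")
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValidationError(f"duplicate tip label: {dupes}")
    for t in tips:
        if t.length is None:
            raise ValidationError(f"tip {t.name!r} has no branch length")
        if t.length < 0:
            raise ValidationError(f"tip {t.name!r} has negative branch length")
    return tree


def align_table_metadata(
    table: OtuTable, meta: pd.DataFrame
) -> tuple[OtuTable, pd.DataFrame]:
    """Restrict table and metadata to their shared samples, in table order."""
    shared = [s for s in table.sample_ids if s in meta.index]
    if not shared:
        raise ValidationError("no shared samples between table and metadata")
    dropped = table.n_samples - len(shared)
    if dropped:
        logger.warning("dropping %d table sample(s) absent from metadata", dropped)
    return table.select_samples(shared), meta.loc[shared]


def rarefy(
    table: OtuTable,
    depth: int = DEFAULT_RAREFACTION_DEPTH,
    seed: int | None = None,
) -> OtuTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Each retained sample's counts are a multivariate-hypergeometric draw of
    ``depth`` reads from its observed reads.  Samples with fewer than
    ``depth`` total reads are dropped with a warning; if every sample is
    below depth an error is raised.  Identical seed implies identical output.
    """
    if depth <= 0:
        raise ValidationError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals()
    keep = totals >= depth
    if not keep.any():
        raise ValidationError(
            f"all {table.n_samples} samples have fewer than {depth} reads"
        )
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    if dropped:
        msg = f"rarefy: dropping {len(dropped)} sample(s) below depth {depth}: {dropped}"
        logger.warning(msg)
        warnings.warn(msg, UserWarning, stacklevel=2)
    out = np.empty((int(keep.sum()), table.n_otus), dtype=np.int64)
    row = 0
    for i in range(table.n_samples):
        if not keep[i]:
            continue
        if totals[i] == depth:
            out[row] = table.counts[i]
        else:
            out[row] = rng.multivariate_hypergeometric(table.counts[i], depth)
        row += 1
    return OtuTable(
        [s for s, k in zip(table.sample_ids, keep) if k], list(table.otu_ids), out
    )


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent sub-seeds (< 2**31) from a master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]
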