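"""Readers and writers for OTU tables (TSV / BIOM-JSON), metadata and trees.

The on-disk table dialect is the common amplicon layout: OTUs as rows,
samples as columns, first column the OTU identifier, with an optional
``#OTU ID`` header token.  In memory tables are dense with samples as rows.
BIOM support covers the v1.0 JSON dialect (dense and sparse).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .model import OtuTable, ValidationError, validate_metadata, validate_phylogeny

OTU_HEADER_TOKENS = ("#OTU ID", "#OTU_ID", "OTU_ID", "OTU ID", "otu_id")


def read_otu_table(path: str | Path, format: str = "tsv") -> OtuTable:
    """Read and validate an OTU table.

    ``format="tsv"`` expects OTUs as rows and samples as columns (the first
    column holds OTU ids); a leading ``# transposed`` comment line flags the
    samples-as-rows orientation.  ``format="biom"`` reads BIOM v1.0 JSON.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        return _read_tsv(path)
    if format == "biom":
        return _read_biom_json(path)
    raise ValidationError(f"unknown table format {format!r}")


def _read_tsv(path: Path) -> OtuTable:
    transposed = False
    skip = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "\t" not in line:
                if "transposed" in line.lower():
                    transposed = True
                skip += 1
            else:
                break
    # pandas mangles duplicate column names; check the raw header first
    with open(path) as fh:
        for _ in range(skip):
            fh.readline()
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise ValidationError(f"duplicate sample id: {dupes}")
    df = pd.read_csv(path, sep="\t", skiprows=skip, index_col=0, dtype=str)
    if df.empty or df.shape[1] == 0:
        raise ValidationError(f"empty OTU table: {path}")
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dupes = sorted(set(df.index[df.index.duplicated()]))
        raise ValidationError(f"duplicate OTU id: {dupes}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric count in {path}: {exc}") from exc
    if np.isnan(values).any():
        raise ValidationError("counts contain NaN")
    if not np.allclose(values, np.round(values)):
        raise ValidationError("non-integer counts in OTU table")
    counts = np.round(values).astype(np.int64)
    if transposed:
        return OtuTable(list(df.index), list(df.columns), counts)
    return OtuTable(list(df.columns), list(df.index), counts.T)


def _read_biom_json(path: Path) -> OtuTable:
    with open(path) as fh:
        doc = json.load(fh)
    try:
        otu_ids = [str(r["id"]) for r in doc["rows"]]
        sample_ids = [str(c["id"]) for c in doc["columns"]]
        shape = tuple(doc["shape"])
        matrix_type = doc.get("matrix_type", "sparse")
        data = doc["data"]
    except (KeyError, TypeError) as exc:
        raise ValidationError(f"not a BIOM v1.0 JSON table: {path}") from exc
    mat = np.zeros(shape, dtype=float)
    if matrix_type == "dense":
        mat[:] = np.asarray(data, dtype=float)
    else:
        for i, j, v in data:
            mat[int(i), int(j)] = v
    if not np.allclose(mat, np.round(mat)):
        raise ValidationError("non-integer counts in BIOM table")
    # BIOM stores observations (OTUs) as rows
    return OtuTable(sample_ids, otu_ids, np.round(mat).astype(np.int64).T)


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    """Write the TSV dialect (OTU rows x sample columns)."""
    df = pd.DataFrame(table.counts.T, index=table.otu_ids, columns=table.sample_ids)
    df.index.name = "#OTU ID"
    df.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read and validate a sample metadata TSV (see :func:`validate_metadata`)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta = pd.read_csv(path, sep="\t", dtype=str, skipinitialspace=True)
    meta.columns = [c.strip().lstrip("#") for c in meta.columns]
    return validate_metadata(meta)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.reset_index(drop=True).to_csv(path, sep="\t", index=False)


def read_newick(path: str | Path) -> TreeNode:
    """Read a rooted newick tree; tips must be uniquely labelled with lengths."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    tree = TreeNode.read(str(path), format="newick")
    return validate_phylogeny(tree)


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")
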