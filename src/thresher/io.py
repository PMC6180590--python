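"""Readers and writers for delimited expression matrices and annotations."""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, SampleAnnotation

__all__ = [
    "read_expression",
    "write_expression",
    "read_gene_list",
    "read_annotation",
]

TRANSFORMS = ("none", "log2p1")


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _clean_gene_id(raw: str) -> str:
    """FireBrowse RSEM composite ids are 'SYMBOL|entrez'; keep the symbol."""
    raw = str(raw).strip()
    if "|" in raw:
        return raw.split("|", 1)[0]
    return raw


def read_expression(
    path: str | Path,
    gene_list_path: str | Path | None = None,
    transform: str = "none",
    annotation: SampleAnnotation | None = None,
) -> ExpressionMatrix:
    """Read a delimited genes x samples matrix.

    Genes are rows; the first column holds gene identifiers (the
    FireBrowse ``symbol|entrez`` dialect is accepted, keeping the symbol).
    An optional gene list restricts rows by case-insensitive symbol match;
    unmatched list entries are reported in a warning. ``transform`` is
    ``"none"`` or ``"log2p1"`` (log2(x + 1), for RNA-Seq-like abundances).
    Duplicate symbols keep the higher-variance row.
    """
    path = Path(path)
    if transform not in TRANSFORMS:
        raise ValueError(f"transform must be one of {TRANSFORMS}")
    df = pd.read_csv(
        path, sep=_sep_for(path), index_col=0, float_precision="round_trip"
    )
    df.index = [_clean_gene_id(g) for g in df.index]

    bad = df.map(lambda v: not isinstance(v, (int, float, np.integer, np.floating)))
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at gene {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    df = df.astype(float)

    if df.index.has_duplicates:
        n_dup = int(df.index.duplicated().sum())
        warnings.warn(
            f"{n_dup} duplicate gene symbol(s); keeping the higher-variance row",
            stacklevel=2,
        )
        first_seen = list(dict.fromkeys(df.index))
        by_var = df.iloc[np.argsort(-df.var(axis=1).to_numpy(), kind="stable")]
        by_var = by_var[~by_var.index.duplicated(keep="first")]
        df = by_var.loc[first_seen]

    if gene_list_path is not None:
        wanted = read_gene_list(gene_list_path)
        lut = {g.lower(): g for g in df.index}
        matched = [lut[w.lower()] for w in wanted if w.lower() in lut]
        unmatched = [w for w in wanted if w.lower() not in lut]
        if unmatched:
            warnings.warn(
                f"{len(unmatched)} gene-list entries not in matrix: {unmatched[:10]}",
                stacklevel=2,
            )
        if not matched:
            raise ValueError("gene list matches no rows of the matrix")
        df = df.loc[matched]

    if transform == "log2p1":
        if (df.to_numpy() < 0).any():
            raise ValueError("log2p1 transform requires non-negative values")
        df = np.log2(df + 1.0)

    groups = annotation.groups() if annotation is not None else None
    types = annotation.sample_types() if annotation is not None else None
    return ExpressionMatrix(df, sample_groups=groups, sample_types=types)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a genes x samples matrix in the delimited format readers accept."""
    path = Path(path)
    out = matrix.values.copy()
    out.index.name = "gene"
    # repr() emits the shortest digit string that round-trips the double
    # exactly, so written matrices reload bit-identically
    out.to_csv(path, sep=_sep_for(path), float_format=lambda x: repr(float(x)))


def read_gene_list(path: str | Path) -> list[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    genes = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.append(line.split("\t")[0])
    return genes


def read_annotation(path: str | Path) -> SampleAnnotation:
    """Sample annotation table with columns sample, group[, sample_type]."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    return SampleAnnotation(df)
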