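"""Shared in-memory containers.

The pipeline operates on a genes x samples expression matrix on a
continuous (already log-like) scale. Genes are rows, samples are columns,
mirroring the convention of most bulk-expression deliverables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ExpressionMatrix:
    """A genes x samples expression matrix with optional sample annotation.

    Parameters
    ----------
    values
        DataFrame with gene identifiers as the index and sample identifiers
        as columns. All entries must be finite numerics.
    sample_groups
        Optional Series mapping sample id -> group label (e.g. cancer-type
        code). Index must be a subset of ``values.columns``.
    sample_types
        Optional Series mapping sample id -> one of
        ``{"primary", "metastasis", "normal"}``.
    """

    values: pd.DataFrame
    sample_groups: pd.Series | None = None
    sample_types: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.shape[0] == 0 or self.values.shape[1] == 0:
            raise ValueError("expression matrix must have at least one gene and one sample")
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("expression matrix contains non-finite values")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene identifiers in expression matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample identifiers in expression matrix")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        """Return a new matrix restricted to ``genes`` (order preserved)."""
        return ExpressionMatrix(
            self.values.loc[list(genes)],
            sample_groups=self.sample_groups,
            sample_types=self.sample_types,
        )

    def to_array(self) -> np.ndarray:
        # canonical C layout: BLAS results (and hence downstream cluster
        # labels) are bit-reproducible regardless of how the frame was built
        return np.ascontiguousarray(self.values.to_numpy(dtype=float))


@dataclass
class SampleAnnotation:
    """Per-sample metadata: group label and tumor/normal/metastasis flag."""

    table: pd.DataFrame = field(repr=False)

    SAMPLE_TYPES = ("primary", "metastasis", "normal")

    def __post_init__(self) -> None:
        required = {"sample", "group"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"annotation missing columns: {sorted(missing)}")
        if self.table["sample"].duplicated().any():
            raise ValueError("duplicate sample ids in annotation")
        if "sample_type" in self.table.columns:
            bad = set(self.table["sample_type"].dropna()) - set(self.SAMPLE_TYPES)
            if bad:
                raise ValueError(f"unknown sample_type values: {sorted(bad)}")

    def groups(self) -> pd.Series:
        return self.table.set_index("sample")["group"]

    def sample_types(self) -> pd.Series | None:
        if "sample_type" not in self.table.columns:
            return None
        return self.table.set_index("sample")["sample_type"]


def near_constant_rows(X: np.ndarray) -> np.ndarray:
    """Boolean mask of rows whose variation is at floating-point noise level."""
    sd = X.std(axis=1, ddof=1)
    scale = np.maximum(1.0, np.abs(X).max(axis=1))
    return sd <= 1e-10 * scale
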