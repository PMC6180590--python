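"""Per-sample scoring of gene clusters ("biological components").

A validated cluster spans a one-dimensional axis with same-sign first-PC
weights, so its per-sample score is the plain arithmetic mean of its
member genes' (transformed-scale) expression. Scores can then be
correlated against an arbitrary genome-wide matrix to produce per-cluster
gene lists, and summarized by sample group for violin/bean-style plotting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .thresher_core import ClusterResult

__all__ = [
    "ComponentScoreMatrix",
    "component_scores",
    "correlate_genome",
    "grouped_distribution_summary",
]


@dataclass
class ComponentScoreMatrix:
    """clusters x samples matrix of component scores."""

    scores: pd.DataFrame  # index: cluster id, columns: sample ids

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.scores.to_numpy(dtype=float))):
            raise ValueError("component scores must be finite")

    @property
    def cluster_ids(self) -> list[int]:
        return list(self.scores.index)

    @property
    def samples(self) -> pd.Index:
        return self.scores.columns


def component_scores(
    matrix: ExpressionMatrix,
    result: ClusterResult,
    sign_adjust: bool = False,
) -> ComponentScoreMatrix:
    """Mean member-gene expression per cluster and sample.

    With ``sign_adjust`` genes whose first-PC weight is negative within the
    cluster are negated before averaging — useful for clusters that fail
    the same-sign validation, where a plain mean would cancel.
    """
    rows = {}
    for c in result.cluster_ids:
        members = result.members(c)
        if not members:
            raise ValueError(f"cluster {c} has no members")
        missing = [g for g in members if g not in matrix.genes]
        if missing:
            raise ValueError(f"cluster {c} members missing from matrix: {missing[:5]}")
        sub = matrix.values.loc[members]
        if sign_adjust and len(members) > 1:
            from .thresher_core import gene_loadings

            w = gene_loadings(matrix.subset_genes(members), 1).weights.to_numpy()[:, 0]
            signs = np.where(w < 0, -1.0, 1.0)
            sub = sub.mul(signs, axis=0)
        rows[c] = sub.mean(axis=0)
    scores = pd.DataFrame(rows).T
    scores.index.name = "cluster"
    return ComponentScoreMatrix(scores)


def correlate_genome(
    scores: ComponentScoreMatrix,
    genome: ExpressionMatrix,
    threshold: float = 0.5,
) -> dict[int, pd.DataFrame]:
    """Genes whose |Pearson r| with a component score reaches ``threshold``.

    Returns, per cluster, a DataFrame (gene, rho) sorted by |rho|
    descending. The threshold is inclusive. Constant genome genes, whose
    correlation is undefined, are excluded with a warning. Samples are
    intersected when the two inputs do not share an identical set.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    common = scores.samples.intersection(genome.samples)
    if len(common) == 0:
        raise ValueError("score and genome matrices share no samples")
    if len(common) < len(scores.samples) or len(common) < len(genome.samples):
        warnings.warn(
            f"sample sets differ; correlating over the {len(common)}-sample intersection",
            stacklevel=2,
        )
    S = scores.scores[common].to_numpy(dtype=float)
    G = genome.values[common].to_numpy(dtype=float)

    g_sd = G.std(axis=1)
    constant = g_sd == 0
    if constant.any():
        warnings.warn(
            f"excluding {int(constant.sum())} constant genome gene(s) from correlation",
            stacklevel=2,
        )
    Gc = G[~constant]
    gene_ids = genome.genes[~constant]
    Gz = (Gc - Gc.mean(axis=1, keepdims=True)) / Gc.std(axis=1, keepdims=True)
    Sz = (S - S.mean(axis=1, keepdims=True)) / S.std(axis=1, keepdims=True)
    rho = (Sz @ Gz.T) / len(common)  # clusters x genes

    out: dict[int, pd.DataFrame] = {}
    for i, c in enumerate(scores.cluster_ids):
        r = rho[i]
        hit = np.abs(r) >= threshold
        df = pd.DataFrame({"gene": gene_ids[hit], "rho": r[hit]})
        df = df.reindex(df["rho"].abs().sort_values(ascending=False).index)
        out[c] = df.reset_index(drop=True)
    return out


def grouped_distribution_summary(
    scores: ComponentScoreMatrix,
    annotation: pd.Series,
) -> pd.DataFrame:
    """Per cluster x group score distributions for plotting.

    ``annotation`` maps sample id -> group label. Unannotated samples are
    excluded with a warning. Returns one row per (cluster, group) with n,
    mean, median, quartiles, and the raw score vector.
    """
    annotated = scores.samples.intersection(annotation.index)
    if len(annotated) < len(scores.samples):
        warnings.warn(
            f"excluding {len(scores.samples) - len(annotated)} unannotated sample(s)",
            stacklevel=2,
        )
    if len(annotated) == 0:
        raise ValueError("no annotated samples")
    groups = annotation.loc[annotated]
    records = []
    for c in scores.cluster_ids:
        row = scores.scores.loc[c, annotated]
        for grp, vals in row.groupby(groups):
            v = vals.to_numpy(dtype=float)
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            records.append(
                {
                    "cluster": c,
                    "group": grp,
                    "n": v.size,
                    "mean": float(v.mean()),
                    "median": float(med),
                    "q1": float(q1),
                    "q3": float(q3),
                    "values": v.tolist(),
                }
            )
    return pd.DataFrame.from_records(records)
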