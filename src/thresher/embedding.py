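"""Sample-space projections: PC scores and the 2-D t-SNE map.

Samples are projected onto the top-D principal components of the
standardized gene matrix; the D-dimensional scores then feed a wrapped
t-SNE to give the 2-D map on which sample groups (e.g. cancer types)
separate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE

from .containers import ExpressionMatrix
from .thresher_core import gene_loadings

__all__ = ["Embedding", "pc_scores", "tsne_embed"]


@dataclass
class Embedding:
    coordinates: pd.DataFrame  # samples x (x, y)
    perplexity: float
    seed: int

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coordinates.to_numpy(dtype=float))):
            raise ValueError("embedding coordinates must be finite")


def pc_scores(matrix: ExpressionMatrix, D: int) -> pd.DataFrame:
    """Sample scores on the top-D PCs of the standardized gene matrix.

    Column j is ``Z^T v_j`` for the j-th eigenvector of the gene
    correlation matrix (same deterministic sign convention as the gene
    loadings), so the score covariance is diag(lambda_1..lambda_D).
    """
    load = gene_loadings(matrix, D)  # sqrt(lambda_j) v_j, shared sign convention
    X = matrix.to_array()
    sd = X.std(axis=1, ddof=1)
    Z = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    W = load.weights.to_numpy()
    lam = np.sum(W * W, axis=0)  # = lambda_j since ||v_j|| = 1
    V = W / np.sqrt(lam)
    scores = Z.T @ V
    return pd.DataFrame(scores, index=matrix.samples, columns=load.weights.columns)


def tsne_embed(
    scores: pd.DataFrame,
    perplexity: float = 30.0,
    seed: int = 0,
    n_iter: int = 1000,
) -> Embedding:
    """2-D t-SNE of the PC score matrix (wrapped, deterministic per seed).

    The scores are already the dimension reduction, so no internal PCA
    step is applied.
    """
    n = scores.shape[0]
    bound = (n - 1) / 3.0
    if perplexity >= bound:
        raise ValueError(
            f"perplexity must be < (n_samples - 1)/3 = {bound:.2f}, got {perplexity}"
        )
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        max_iter=n_iter,
        init="random",
        random_state=seed,
        method="barnes_hut" if n > 50 else "exact",
    )
    coords = tsne.fit_transform(scores.to_numpy(dtype=float))
    df = pd.DataFrame(coords, index=scores.index, columns=["x", "y"])
    return Embedding(coordinates=df, perplexity=float(perplexity), seed=int(seed))
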