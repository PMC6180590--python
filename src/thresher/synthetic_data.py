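"""Synthetic expression data with known latent-factor cluster structure.

The generator emulates the structure the clustering pipeline assumes: G
genes organized into F latent factors, each member gene proportional to
+/-(common factor) plus independent Gaussian noise, a configurable set of
pure-noise "outlier" genes, and samples partitioned into groups with
group-specific factor means (standing in for cancer types). Values are
emitted on the already-transformed (log-like) continuous scale; raw
sequencing counts are not simulated.

A von Mises-Fisher sampler is also provided so the mixture fitter can be
tested against exact draws from its own model family.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

NOISE = "NOISE"


@dataclass
class SyntheticTruth:
    """Ground truth for one generated dataset.

    ``factor_of_gene`` maps each gene to its factor index or the string
    ``"NOISE"``; ``sign_of_gene`` is only defined for factor genes.
    """

    factor_of_gene: dict[str, int | str]
    sign_of_gene: dict[str, int]
    group_of_sample: dict[str, str]
    n_factors: int
    noise_sd: float
    seed: int
    # factor value (group mean + latent draw) per factor and sample; kept
    # in memory for downstream checks, not serialized
    factor_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_factors < 1:
            raise ValueError("n_factors must be >= 1")
        for g, f in self.factor_of_gene.items():
            if f == NOISE:
                if g in self.sign_of_gene:
                    raise ValueError(f"noise gene {g} has a sign")
            elif g not in self.sign_of_gene:
                raise ValueError(f"factor gene {g} lacks a sign")

    def noise_genes(self) -> list[str]:
        return [g for g, f in self.factor_of_gene.items() if f == NOISE]

    def signal_genes(self) -> list[str]:
        return [g for g, f in self.factor_of_gene.items() if f != NOISE]

    def cluster_labels(self) -> dict[str, int]:
        """Planted partition of signal genes: one cluster per (factor, sign).

        Genes of the same factor but opposite sign point in opposite
        directions on the loading hypersphere, so they form distinct
        planted clusters.
        """
        pairs = sorted(
            {(self.factor_of_gene[g], self.sign_of_gene[g]) for g in self.signal_genes()}
        )
        index = {p: i for i, p in enumerate(pairs)}
        return {
            g: index[(self.factor_of_gene[g], self.sign_of_gene[g])]
            for g in self.signal_genes()
        }

    def n_planted_clusters(self) -> int:
        return len(set(self.cluster_labels().values()))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "factor_of_gene": self.factor_of_gene,
            "sign_of_gene": self.sign_of_gene,
            "group_of_sample": self.group_of_sample,
            "n_factors": self.n_factors,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        d["factor_of_gene"] = {
            g: (f if f == NOISE else int(f)) for g, f in d["factor_of_gene"].items()
        }
        d["sign_of_gene"] = {g: int(s) for g, s in d["sign_of_gene"].items()}
        return cls(**d)


def _per_factor_fractions(frac_negative_sign, n_factors: int) -> np.ndarray:
    frac = np.atleast_1d(np.asarray(frac_negative_sign, dtype=float))
    if frac.size == 1:
        frac = np.repeat(frac, n_factors)
    if frac.size != n_factors:
        raise ValueError("frac_negative_sign must be scalar or one value per factor")
    if not np.all(np.isfinite(frac)) or np.any(frac < 0) or np.any(frac > 1):
        raise ValueError("frac_negative_sign values must lie in [0, 1]")
    return frac


def generate_factor_dataset(
    n_samples: int,
    n_groups: int = 1,
    n_factors: int = 1,
    genes_per_factor: int = 8,
    frac_negative_sign: float | Sequence[float] = 0.0,
    n_noise_genes: int = 0,
    factor_group_means: np.ndarray | None = None,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Generate a genes x samples matrix with planted factor clusters.

    Each sample s in group c draws an independent standard-normal latent
    value z[f, s] per factor; a member gene g of factor f with sign
    sigma(g) gets ``sigma(g) * (mean[c, f] + z[f, s]) + eps`` with
    ``eps ~ N(0, noise_sd^2)``. Noise genes are pure ``N(0, noise_sd^2)``.
    Identical arguments and seed give bit-identical output.

    Returns the expression matrix (with group labels attached) and the
    generating :class:`SyntheticTruth`.
    """
    for name, v in [("n_samples", n_samples), ("n_groups", n_groups),
                    ("n_factors", n_factors), ("genes_per_factor", genes_per_factor),
                    ("n_noise_genes", n_noise_genes)]:
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer")
    if n_factors < 1:
        raise ValueError("n_factors must be >= 1")
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    if not np.isfinite(noise_sd) or noise_sd < 0:
        raise ValueError("noise_sd must be finite and non-negative")
    n_signal = n_factors * genes_per_factor
    if n_signal + n_noise_genes == 0 or n_samples == 0:
        raise ValueError("dataset must contain at least one gene and one sample")

    frac = _per_factor_fractions(frac_negative_sign, n_factors)

    if factor_group_means is None:
        factor_group_means = np.zeros((n_groups, n_factors))
    means = np.asarray(factor_group_means, dtype=float)
    if means.shape != (n_groups, n_factors):
        raise ValueError(
            f"factor_group_means must be (n_groups, n_factors) = {(n_groups, n_factors)}"
        )
    if not np.all(np.isfinite(means)):
        raise ValueError("factor_group_means must be finite")

    rng = np.random.default_rng(seed)

    # contiguous, near-equal sample groups
    group_sizes = np.full(n_groups, n_samples // n_groups)
    group_sizes[: n_samples % n_groups] += 1
    group_idx = np.repeat(np.arange(n_groups), group_sizes)
    sample_ids = [f"S{j:04d}" for j in range(n_samples)]
    group_labels = [f"grp{g}" for g in group_idx]

    latent = rng.standard_normal((n_factors, n_samples))
    shifted = latent + means[group_idx].T  # (F, S)

    gene_ids: list[str] = []
    factor_of_gene: dict[str, int | str] = {}
    sign_of_gene: dict[str, int] = {}
    rows = np.empty((n_signal + n_noise_genes, n_samples))
    r = 0
    for f in range(n_factors):
        n_neg = int(round(frac[f] * genes_per_factor))
        for i in range(genes_per_factor):
            gid = f"F{f}G{i:02d}"
            sign = -1 if i < n_neg else 1
            gene_ids.append(gid)
            factor_of_gene[gid] = f
            sign_of_gene[gid] = sign
            rows[r] = sign * shifted[f]
            r += 1
    for i in range(n_noise_genes):
        gid = f"NOISE{i:02d}"
        gene_ids.append(gid)
        factor_of_gene[gid] = NOISE
        rows[r] = 0.0
        r += 1

    rows += noise_sd * rng.standard_normal(rows.shape)

    values = pd.DataFrame(rows, index=gene_ids, columns=sample_ids)
    groups = pd.Series(group_labels, index=sample_ids, name="group")
    matrix = ExpressionMatrix(values, sample_groups=groups)
    truth = SyntheticTruth(
        factor_of_gene=factor_of_gene,
        sign_of_gene=sign_of_gene,
        group_of_sample=dict(zip(sample_ids, group_labels)),
        n_factors=n_factors,
        noise_sd=float(noise_sd),
        seed=int(seed),
        factor_values=shifted,
    )
    return matrix, truth


# Standard study conditions used throughout the test-bench: five factors of
# eight genes (the last factor split 50/50 into anti-correlated halves, so
# six planted clusters), ten pure-noise genes, 500 samples in three groups
# with distinct factor means. noise_sd 1.0 puts within-factor gene
# correlation near 0.5 — the co-expression strength typical of real
# modules — which also keeps the unit-variance noise genes inside the
# residual eigenvalue bulk, where "pure noise => insignificant loading"
# actually holds.
DEFAULT_BUNDLE = dict(
    n_samples=500,
    n_groups=3,
    n_factors=5,
    genes_per_factor=8,
    frac_negative_sign=(0.0, 0.0, 0.0, 0.0, 0.5),
    n_noise_genes=10,
    noise_sd=1.0,
)


def default_group_means(n_groups: int, n_factors: int, scale: float = 2.0) -> np.ndarray:
    """One elevated factor per group (round-robin), magnitude ``scale``."""
    means = np.zeros((n_groups, n_factors))
    for g in range(n_groups):
        means[g, g % n_factors] = scale
    return means


def generate_default_bundle(seed: int = 0) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """The default simulate bundle: planted D=5, six clusters, ten outliers."""
    params = dict(DEFAULT_BUNDLE)
    params["factor_group_means"] = default_group_means(
        params["n_groups"], params["n_factors"]
    )
    return generate_factor_dataset(seed=seed, **params)


def sample_vmf(
    mean_direction: Sequence[float],
    kappa: float,
    n: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw ``n`` unit vectors from a von Mises-Fisher distribution.

    Density on the unit sphere in ``p`` dimensions is proportional to
    ``exp(kappa * mu @ x)``. Uses the exact rejection sampler for the
    tangent-normal decomposition (Wood-style): the cosine ``w = mu @ x`` is
    drawn by rejection from its marginal, and the tangent part is uniform
    on the orthogonal (p-1)-sphere. ``kappa = 0`` is uniform on the sphere.
    """
    mu = np.asarray(mean_direction, dtype=float)
    p = mu.size
    norm = np.linalg.norm(mu)
    if norm == 0:
        raise ValueError("mean_direction must be non-zero")
    if abs(norm - 1.0) > 1e-8:
        raise ValueError("mean_direction must have unit length")
    mu = mu / norm
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    if p < 2:
        raise ValueError("dimension must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if kappa == 0:
        x = rng.standard_normal((n, p))
        return x / np.linalg.norm(x, axis=1, keepdims=True)

    b = (-2.0 * kappa + np.sqrt(4.0 * kappa**2 + (p - 1) ** 2)) / (p - 1)
    x0 = (1.0 - b) / (1.0 + b)
    c = kappa * x0 + (p - 1) * np.log(1.0 - x0**2)

    w = np.empty(n)
    filled = 0
    while filled < n:
        todo = n - filled
        z = rng.beta((p - 1) / 2.0, (p - 1) / 2.0, size=todo)
        u = rng.uniform(size=todo)
        cand = (1.0 - (1.0 + b) * z) / (1.0 - (1.0 - b) * z)
        accept = kappa * cand + (p - 1) * np.log1p(-x0 * cand) - c >= np.log(u)
        good = cand[accept]
        w[filled : filled + good.size] = good
        filled += good.size

    # uniform directions in the tangent (p-1)-subspace orthogonal to e1,
    # then rotate e1 -> mu by a Householder reflection
    v = rng.standard_normal((n, p - 1))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    x = np.empty((n, p))
    x[:, 0] = w
    x[:, 1:] = np.sqrt(np.clip(1.0 - w**2, 0.0, None))[:, None] * v

    e1 = np.zeros(p)
    e1[0] = 1.0
    u_h = e1 - mu
    un = np.linalg.norm(u_h)
    if un > 1e-12:
        u_h /= un
        x = x - 2.0 * np.outer(x @ u_h, u_h)
        # reflection maps e1 -> mu exactly
    return x
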