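"""Loading-vector clustering: outlier filtering plus vMF mixtures.

The three-step algorithm:

1. Estimate the number D of significant principal components from the
   gene correlation spectrum (``pc_dimension``). Each gene then becomes a
   vector of weights in D-dimensional PC space; on standardized data the
   weight of gene g on PC j is ``sqrt(lambda_j) * v_j[g]``, i.e. the
   gene-PC correlation, so the vector magnitude lies in [0, 1].
2. Genes whose weight vector is shorter than a cutoff (default 0.3) carry
   too little structured variation and are removed as outliers.
3. The remaining genes are clustered by the *direction* of their weight
   vectors — points on the unit hypersphere — with a mixture of von
   Mises-Fisher distributions fitted by EM. The number of clusters K is
   chosen by AIC over D <= K <= 2D; the upper bound lets anti-correlated
   genes, which point in opposite directions without adding a dimension,
   land in separate clusters.

The full pipeline runs twice: outliers found on the first pass are removed
and the dimension, loadings and clustering are recomputed on the retained
genes.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, ive

from .containers import ExpressionMatrix, near_constant_rows
from .pc_dimension import auer_gervini_path, compute_spectrum, dimension_by_rule

logger = logging.getLogger(__name__)

OUTLIER = "OUTLIER"

__all__ = [
    "LoadingMatrix",
    "VMFComponent",
    "VMFMixtureFit",
    "ClusterResult",
    "gene_loadings",
    "filter_outliers",
    "vmf_log_density",
    "fit_vmf_mixture",
    "select_clusters",
    "run_thresher",
    "validate_cluster_unidimensionality",
    "OUTLIER",
]


@dataclass
class LoadingMatrix:
    """Per-gene weight vectors in D-dimensional PC space."""

    weights: pd.DataFrame  # genes x D, entry = gene-PC correlation

    @property
    def genes(self) -> pd.Index:
        return self.weights.index

    @property
    def dimension(self) -> int:
        return self.weights.shape[1]

    @property
    def magnitudes(self) -> pd.Series:
        return pd.Series(
            np.linalg.norm(self.weights.to_numpy(), axis=1),
            index=self.weights.index,
            name="magnitude",
        )

    def directions(self) -> pd.DataFrame:
        """Unit direction per gene; zero-magnitude genes raise."""
        W = self.weights.to_numpy(dtype=float)
        norms = np.linalg.norm(W, axis=1)
        if np.any(norms == 0):
            raise ValueError("zero-magnitude gene has no direction")
        return pd.DataFrame(
            W / norms[:, None], index=self.weights.index, columns=self.weights.columns
        )


@dataclass
class VMFComponent:
    mean_direction: np.ndarray  # unit vector mu
    concentration: float  # kappa >= 0
    weight: float  # mixing proportion

    def __post_init__(self) -> None:
        self.mean_direction = np.asarray(self.mean_direction, dtype=float)
        if abs(np.linalg.norm(self.mean_direction) - 1.0) > 1e-6:
            raise ValueError("mean_direction must be a unit vector")
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")


@dataclass
class VMFMixtureFit:
    components: list[VMFComponent]
    log_likelihood: float
    responsibilities: np.ndarray  # points x K, rows sum to 1
    converged: bool
    seed: int
    n_iter: int = 0
    log_likelihood_trace: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def dimension(self) -> int:
        return self.components[0].mean_direction.size

    @property
    def aic(self) -> float:
        # K*D free parameters per model ((D-1) for mu, 1 for kappa) plus K-1 weights
        k, d = self.n_components, self.dimension
        return 2.0 * (k * d + k - 1) - 2.0 * self.log_likelihood

    def hard_assignment(self) -> np.ndarray:
        return np.argmax(self.responsibilities, axis=1)


@dataclass
class ClusterResult:
    """Final gene partition with the outlier set and validation reports."""

    dimension: int
    n_clusters: int
    assignment: pd.Series  # gene -> cluster id (int) or OUTLIER
    outlier_cutoff: float
    magnitudes: pd.Series
    fit: VMFMixtureFit | None
    validation: dict[int, dict] = field(default_factory=dict)
    pass1_dimension: int | None = None

    def members(self, cluster: int) -> list[str]:
        return list(self.assignment.index[self.assignment == cluster])

    @property
    def outliers(self) -> list[str]:
        return list(self.assignment.index[self.assignment == OUTLIER])

    @property
    def cluster_ids(self) -> list[int]:
        return sorted({c for c in self.assignment if c != OUTLIER})


def gene_loadings(matrix: ExpressionMatrix, D: int) -> LoadingMatrix:
    """Weight vectors of every gene on the top-D PCs of the correlation matrix.

    Eigenvector signs are fixed so the largest-magnitude entry of each is
    positive, making the output deterministic.
    """
    if D < 1:
        raise ValueError("D must be >= 1")
    X = matrix.to_array()
    if np.any(near_constant_rows(X)):
        raise ValueError("zero-variance gene; drop constant genes first")
    sd = X.std(axis=1, ddof=1)
    Z = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    C = (Z @ Z.T) / (X.shape[1] - 1)
    evals, evecs = np.linalg.eigh(C)
    evals, evecs = evals[::-1], evecs[:, ::-1]
    rank = int(np.sum(evals > 1e-10))
    if D > rank:
        raise ValueError(f"D={D} exceeds the numerical rank {rank}")
    evals = np.clip(evals[:D], 0.0, None)
    V = evecs[:, :D]
    flip = np.sign(V[np.argmax(np.abs(V), axis=0), np.arange(D)])
    flip[flip == 0] = 1.0
    V = V * flip
    W = V * np.sqrt(evals)
    return LoadingMatrix(
        pd.DataFrame(W, index=matrix.genes, columns=[f"PC{j+1}" for j in range(D)])
    )


def filter_outliers(
    loadings: LoadingMatrix, cutoff: float = 0.3
) -> tuple[list[str], list[str]]:
    """Split genes into (kept, outliers) by loading-vector magnitude.

    A gene is an outlier iff its magnitude is strictly below ``cutoff``;
    short vectors carry mostly unstructured noise and are safe to remove.
    """
    if not (0 < cutoff <= 1):
        raise ValueError("cutoff must lie in (0, 1]")
    mags = loadings.magnitudes
    kept = [g for g, m in mags.items() if m >= cutoff]
    out = [g for g, m in mags.items() if m < cutoff]
    if not kept:
        raise ValueError(
            "all genes fall below the outlier cutoff; lower the cutoff"
        )
    return kept, out


_LOG_2PI = math.log(2.0 * math.pi)


def vmf_log_density(x: np.ndarray, mu: np.ndarray, kappa: float) -> np.ndarray:
    """Log-density of the vMF distribution on the (D-1)-sphere in R^D.

    ``log C_D(kappa) + kappa * mu @ x`` with the normalizer
    ``C_D(k) = k^{D/2-1} / ((2 pi)^{D/2} I_{D/2-1}(k))``; the kappa -> 0
    limit is the uniform density, the reciprocal sphere surface area.
    """
    x = np.atleast_2d(x)
    D = x.shape[1]
    nu = D / 2.0 - 1.0
    if kappa < 1e-8:
        log_c = gammaln(D / 2.0) - math.log(2.0) - (D / 2.0) * math.log(math.pi)
    else:
        # log I_nu(k) = log(ive(nu, k)) + k  (ive is exp-scaled, overflow-safe)
        log_bessel = math.log(float(ive(nu, kappa))) + kappa
        log_c = nu * math.log(kappa) - (D / 2.0) * _LOG_2PI - log_bessel
    return log_c + kappa * (x @ mu)


def _estimate_kappa(rbar: float, D: int, cap: float = 1e5) -> float:
    """Mean-resultant-length approximation to the concentration.

    ``kappa = rbar (D - rbar^2) / (1 - rbar^2)``, capped to avoid overflow
    when a component is nearly degenerate.
    """
    rbar = min(max(rbar, 0.0), 1.0 - 1e-12)
    kappa = rbar * (D - rbar**2) / (1.0 - rbar**2)
    return float(min(kappa, cap))


def _spherical_kmeanspp(X: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding with cosine dissimilarity on unit vectors."""
    n = X.shape[0]
    centers = [X[rng.integers(n)]]
    for _ in range(1, K):
        sim = np.max(X @ np.array(centers).T, axis=1)
        d2 = (1.0 - sim) ** 2
        total = d2.sum()
        if total <= 0:
            centers.append(X[rng.integers(n)])
            continue
        centers.append(X[rng.choice(n, p=d2 / total)])
    return np.array(centers)


def _em_single(
    X: np.ndarray,
    K: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
    kappa_max: float,
) -> VMFMixtureFit:
    n, D = X.shape
    mu = _spherical_kmeanspp(X, K, rng)
    norms = np.linalg.norm(mu, axis=1, keepdims=True)
    mu = mu / norms
    kappa = np.full(K, float(D))
    pi = np.full(K, 1.0 / K)

    prev_ll = -np.inf
    prev_state = None
    trace: list[float] = []
    converged = False
    resp = np.full((n, K), 1.0 / K)
    for _ in range(max_iter):
        # E-step
        log_pdf = np.column_stack(
            [vmf_log_density(X, mu[k], kappa[k]) for k in range(K)]
        )
        log_w = log_pdf + np.log(pi)
        m = log_w.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(log_w - m).sum(axis=1))
        resp = np.exp(log_w - lse[:, None])
        ll = float(lse.sum())
        if ll < prev_ll:
            # the closed-form kappa update is approximate, so a step can
            # overshoot; revert to the last ascent point and stop there
            mu, kappa, pi, resp = prev_state
            converged = True
            break
        trace.append(ll)
        if abs(ll - prev_ll) < tol * max(1.0, abs(ll)):
            converged = True
            prev_ll = ll
            break
        prev_ll = ll
        prev_state = (mu.copy(), kappa.copy(), pi.copy(), resp.copy())

        # M-step
        nk = resp.sum(axis=0)
        for k in range(K):
            if nk[k] < 1e-10:
                # dead component: re-seed from the point worst explained
                worst = int(np.argmin(lse))
                mu[k] = X[worst]
                kappa[k] = float(D)
                pi[k] = 1.0 / n
                continue
            resultant = resp[:, k] @ X
            rnorm = float(np.linalg.norm(resultant))
            if rnorm > 0:
                mu[k] = resultant / rnorm
            kappa[k] = _estimate_kappa(rnorm / nk[k], D, cap=kappa_max)
            pi[k] = nk[k] / n
        pi = pi / pi.sum()

    return VMFMixtureFit(
        components=[
            VMFComponent(mu[k].copy(), float(kappa[k]), float(pi[k])) for k in range(K)
        ],
        log_likelihood=prev_ll,
        responsibilities=resp,
        converged=converged,
        seed=0,
        n_iter=len(trace),
        log_likelihood_trace=np.asarray(trace),
    )


def fit_vmf_mixture(
    directions: np.ndarray | pd.DataFrame,
    K: int,
    n_restarts: int = 20,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-6,
    kappa_max: float = 1e5,
) -> VMFMixtureFit:
    """Fit a K-component von Mises-Fisher mixture to unit vectors by EM.

    Each restart seeds from a spherical k-means++ draw; the fit with the
    best log-likelihood is returned. Deterministic given ``seed``.

    ``kappa_max`` bounds the concentration parameter space. Besides
    preventing numerical overflow, a finite bound removes the degenerate
    likelihood maxima where a component collapses onto a near-duplicate
    pair of points; when directions are estimated loading vectors, a bound
    of the order of the number of samples matches the angular resolution
    the estimates actually support (see :func:`run_thresher`).
    """
    X = np.asarray(
        directions.to_numpy() if isinstance(directions, pd.DataFrame) else directions,
        dtype=float,
    )
    if X.ndim != 2:
        raise ValueError("directions must be a 2-D array of unit vectors")
    n = X.shape[0]
    if not (1 <= K <= n):
        raise ValueError(f"K must satisfy 1 <= K <= {n}")
    norms = np.linalg.norm(X, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ValueError("all directions must be unit vectors")
    X = X / norms[:, None]

    master = np.random.default_rng(seed)
    child_seeds = master.integers(0, 2**31 - 1, size=n_restarts)
    best: VMFMixtureFit | None = None
    for s in child_seeds:
        fit = _em_single(X, K, np.random.default_rng(int(s)), max_iter, tol, kappa_max)
        if best is None or fit.log_likelihood > best.log_likelihood:
            best = fit
    assert best is not None
    best.seed = seed
    return best


def select_clusters(
    directions: np.ndarray | pd.DataFrame,
    D: int,
    seed: int = 0,
    n_restarts: int = 20,
    kappa_max: float = 1e5,
) -> tuple[VMFMixtureFit, int]:
    """Choose K in [D, 2D] by AIC and return the winning mixture fit.

    Ties in AIC break toward the smaller K. K never exceeds the number of
    points.
    """
    if D < 1:
        raise ValueError("D must be >= 1")
    X = directions.to_numpy() if isinstance(directions, pd.DataFrame) else directions
    n = np.asarray(X).shape[0]
    if n < D:
        raise ValueError(f"need at least D={D} points, got {n}")
    best_fit, best_k, best_aic = None, None, np.inf
    for K in range(D, min(2 * D, n) + 1):
        fit = fit_vmf_mixture(
            directions, K, n_restarts=n_restarts, seed=seed, kappa_max=kappa_max
        )
        logger.debug("K=%d AIC=%.3f", K, fit.aic)
        if fit.aic < best_aic - 1e-9:
            best_fit, best_k, best_aic = fit, K, fit.aic
    assert best_fit is not None and best_k is not None
    return best_fit, best_k


def validate_cluster_unidimensionality(
    matrix: ExpressionMatrix, members: list[str], rule: str = "twicemean"
) -> dict:
    """Check that a cluster spans a one-dimensional PC space.

    Reports the estimated dimension of the members-only submatrix, the
    variance fraction of its first PC, and whether all first-PC loadings
    share a sign. A cluster is "valid" when the dimension is at most one
    and the signs agree — members then track a single axis of variation
    with a consistent orientation.
    """
    if len(members) == 0:
        raise ValueError("cluster has no members")
    if len(members) == 1:
        return {
            "n_members": 1,
            "dimension": 1,
            "first_pc_variance_fraction": 1.0,
            "same_sign": True,
            "valid": True,
        }
    sub = matrix.subset_genes(members)
    spectrum = compute_spectrum(sub)
    path = auer_gervini_path(spectrum)
    dim = dimension_by_rule(path, rule)
    ev = spectrum.eigenvalues
    frac = float(ev[0] / ev.sum()) if ev.sum() > 0 else 0.0
    load = gene_loadings(sub, 1)
    w = load.weights.to_numpy()[:, 0]
    same_sign = bool(np.all(w >= 0) or np.all(w <= 0))
    return {
        "n_members": len(members),
        "dimension": int(dim),
        "first_pc_variance_fraction": frac,
        "same_sign": same_sign,
        "valid": bool(dim <= 1 and same_sign),
    }


def run_thresher(
    matrix: ExpressionMatrix,
    rule: str = "twicemean",
    cutoff: float = 0.3,
    seed: int = 0,
    n_restarts: int = 20,
) -> ClusterResult:
    """Run the full two-pass pipeline on an expression matrix.

    Pass 1 estimates D, computes loadings and removes outlier genes; pass 2
    re-estimates D and the loadings on the retained genes and clusters
    their directions. The second pass runs even when no outliers are found.
    """
    X = matrix.to_array()
    constant = list(matrix.genes[near_constant_rows(X)])
    if constant:
        warnings.warn(
            f"{len(constant)} constant gene(s) treated as outliers", stacklevel=2
        )
        working = matrix.subset_genes([g for g in matrix.genes if g not in constant])
    else:
        working = matrix

    # pass 1: dimension and outliers
    spectrum1 = compute_spectrum(working)
    path1 = auer_gervini_path(spectrum1)
    d1 = dimension_by_rule(path1, rule)
    logger.info("pass 1: D=%d on %d genes", d1, working.n_genes)
    if d1 == 0:
        warnings.warn("no significant components found; all genes unassigned", stacklevel=2)
        assignment = pd.Series(OUTLIER, index=matrix.genes, dtype=object)
        mags = pd.Series(0.0, index=matrix.genes)
        return ClusterResult(0, 0, assignment, cutoff, mags, None, {}, pass1_dimension=0)
    load1 = gene_loadings(working, d1)
    kept, outliers = filter_outliers(load1, cutoff)
    outliers = constant + outliers
    logger.info("pass 1: %d outliers", len(outliers))

    # pass 2: recompute on retained genes, then cluster
    retained = working.subset_genes(kept)
    spectrum2 = compute_spectrum(retained)
    path2 = auer_gervini_path(spectrum2)
    d2 = dimension_by_rule(path2, rule)
    logger.info("pass 2: D=%d on %d genes", d2, retained.n_genes)
    if d2 == 0:
        warnings.warn("no significant components on pass 2; all genes unassigned", stacklevel=2)
        assignment = pd.Series(OUTLIER, index=matrix.genes, dtype=object)
        return ClusterResult(
            0, 0, assignment, cutoff, load1.magnitudes.reindex(matrix.genes, fill_value=0.0),
            None, {}, pass1_dimension=d1,
        )
    load2 = gene_loadings(retained, d2)
    # directions are estimated from n_samples observations, so angular
    # structure sharper than kappa ~ n_samples is below the estimation
    # resolution; bounding kappa there keeps AIC from rewarding degenerate
    # splits of tight clusters
    fit, K = select_clusters(
        load2.directions(),
        d2,
        seed=seed,
        n_restarts=n_restarts,
        kappa_max=float(matrix.n_samples),
    )
    labels = fit.hard_assignment()

    assignment = pd.Series(OUTLIER, index=matrix.genes, dtype=object)
    assignment.loc[kept] = labels
    # report pass-2 magnitudes for retained genes, pass-1 for outliers
    mags = load1.magnitudes.reindex(matrix.genes, fill_value=0.0)
    mags.loc[kept] = load2.magnitudes

    validation = {}
    for c in sorted(set(labels)):
        members = [g for g in kept if assignment[g] == c]
        if members:
            validation[int(c)] = validate_cluster_unidimensionality(retained, members, rule)

    return ClusterResult(
        dimension=d2,
        n_clusters=K,
        assignment=assignment,
        outlier_cutoff=cutoff,
        magnitudes=mags,
        fit=fit,
        validation=validation,
        pass1_dimension=d1,
    )
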