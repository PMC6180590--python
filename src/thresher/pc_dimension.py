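"""Bayesian estimation of the number of significant principal components.

The model places a family of exponentially decaying priors, indexed by a
decay parameter Theta >= 0, on the candidate dimension d. With an
isotropic-residual Gaussian profile log-likelihood

    l(d) = -(n_obs / 2) * [ sum_{j<=d} log lambda_j
                            + (n_var - d) * log(mean of lambda_{d+1..}) ]

the MAP dimension at prior decay Theta is ``argmax_d l(d)/n_obs - Theta*d``,
which is a non-increasing step function of Theta. Its exact breakpoint
structure is the upper concave hull of the points ``(d, l(d)/n_obs)``. The
width of the Theta-interval over which a dimension stays MAP is its "step
length"; the advice of the underlying graphical method is to pick the
highest step that is long, and three automated rules for "long" are
implemented: a twice-the-mean threshold, an at-most-one-changepoint split
of the sorted lengths, and a three-group 1-D k-means (upper two groups
long).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import ExpressionMatrix, near_constant_rows

__all__ = [
    "SpectrumProfile",
    "AuerGerviniPath",
    "compute_spectrum",
    "auer_gervini_path",
    "twice_mean_dimension",
    "cpt_dimension",
    "kmeans3_dimension",
    "dimension_by_rule",
    "RULES",
]


@dataclass
class SpectrumProfile:
    """Eigenvalues of the gene-gene correlation (or covariance) matrix."""

    eigenvalues: np.ndarray
    n_obs: int
    n_var: int

    def __post_init__(self) -> None:
        ev = np.asarray(self.eigenvalues, dtype=float)
        if np.any(ev < -1e-10):
            raise ValueError("eigenvalues must be non-negative")
        ev = np.clip(ev, 0.0, None)
        if np.any(np.diff(ev) > 1e-12):
            raise ValueError("eigenvalues must be sorted non-increasing")
        self.eigenvalues = ev


@dataclass
class AuerGerviniPath:
    """MAP dimension as a step function of the prior decay Theta.

    ``dims[i]`` is the MAP dimension on ``[breakpoints[i-1], breakpoints[i])``
    (the first interval starts at Theta=0; the last is unbounded).
    ``step_lengths`` maps each dimension with a *finite* Theta-interval to
    its width; the terminal dimension is excluded.
    """

    breakpoints: np.ndarray
    dims: np.ndarray
    step_lengths: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.breakpoints = np.asarray(self.breakpoints, dtype=float)
        self.dims = np.asarray(self.dims, dtype=int)
        if self.dims.size != self.breakpoints.size + 1:
            raise ValueError("need exactly one more dim than breakpoints")
        if np.any(np.diff(self.dims) >= 0):
            raise ValueError("dims must be strictly decreasing along the path")

    def map_dimension(self, theta: float) -> int:
        """MAP dimension at a given Theta (right-continuous)."""
        i = int(np.searchsorted(self.breakpoints, theta, side="right"))
        return int(self.dims[i])


def compute_spectrum(matrix: ExpressionMatrix, standardize: bool = True) -> SpectrumProfile:
    """Eigen-spectrum of the gene correlation (default) or covariance matrix.

    Zero-variance genes are dropped with a warning when standardizing. The
    eigenvalues of the correlation matrix sum to the number of genes kept.
    """
    X = matrix.to_array()
    if X.shape[0] < 2 or X.shape[1] < 3:
        raise ValueError("need at least 2 genes and 3 samples")
    constant = near_constant_rows(X)
    sd = X.std(axis=1, ddof=1)
    if np.all(constant):
        raise ValueError("all genes are constant")
    if standardize:
        keep = ~constant
        if not np.all(keep):
            warnings.warn(
                f"dropping {int((~keep).sum())} zero-variance gene(s) before standardizing",
                stacklevel=2,
            )
            X = X[keep]
            sd = sd[keep]
        Xc = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    else:
        Xc = X - X.mean(axis=1, keepdims=True)
    C = (Xc @ Xc.T) / (X.shape[1] - 1)
    ev = np.linalg.eigvalsh(C)[::-1]
    ev = np.clip(ev, 0.0, None)
    return SpectrumProfile(eigenvalues=ev, n_obs=matrix.n_samples, n_var=X.shape[0])


def profile_scores(spectrum: SpectrumProfile) -> np.ndarray:
    """Per-observation profile log-likelihood f(d) = l(d)/n_obs for d = 0..dmax.

    Candidate dimensions run from 0 (no significant components) to
    ``min(n_var, n_obs - 1) - 1``, truncated so the residual eigenvalues
    stay positive.
    """
    ev = spectrum.eigenvalues
    pos = ev[ev > 1e-12]
    if pos.size < 2:
        raise ValueError("need at least 2 positive eigenvalues")
    p = spectrum.n_var
    dmax = min(p, spectrum.n_obs - 1, pos.size) - 1
    f = np.empty(dmax + 1)
    logs = np.log(pos)
    cum = np.concatenate([[0.0], np.cumsum(logs)])
    total = ev.sum()
    cum_ev = np.concatenate([[0.0], np.cumsum(ev)])
    for d in range(dmax + 1):
        resid_mean = (total - cum_ev[d]) / (p - d)
        f[d] = -0.5 * (cum[d] + (p - d) * math.log(resid_mean))
    return f


def auer_gervini_path(spectrum: SpectrumProfile) -> AuerGerviniPath:
    """Exact breakpoint structure of ``argmax_d f(d) - Theta*d``.

    Walks the upper concave hull of (d, f(d)) downward from the Theta=0
    maximizer; ties at a breakpoint resolve toward the smaller dimension.
    """
    try:
        f = profile_scores(spectrum)
    except ValueError:
        return AuerGerviniPath(breakpoints=np.array([]), dims=np.array([0]))
    if np.ptp(f) < 1e-12:  # isotropic: f constant in d
        return AuerGerviniPath(breakpoints=np.array([]), dims=np.array([0]))

    # smallest argmax at Theta=0 (parsimony under infinitesimal penalty)
    d = int(np.flatnonzero(f >= f.max() - 1e-12)[0])
    dims = [d]
    breakpoints: list[float] = []
    while d > 0:
        lower = np.arange(d)
        slopes = (f[d] - f[lower]) / (d - lower)
        theta = slopes.min()  # first Theta at which some smaller d overtakes
        nxt = int(lower[np.flatnonzero(slopes <= theta + 1e-15)[0]])
        breakpoints.append(float(theta))
        dims.append(nxt)
        d = nxt

    bp = np.asarray(breakpoints)
    dims_a = np.asarray(dims)
    step_lengths: dict[int, float] = {}
    edges = np.concatenate([[0.0], bp])
    for i in range(len(bp)):  # last interval (terminal dim) is unbounded
        step_lengths[int(dims_a[i])] = float(edges[i + 1] - edges[i])
    return AuerGerviniPath(breakpoints=bp, dims=dims_a, step_lengths=step_lengths)


def _fallback_dimension(step_lengths: dict[int, float]) -> int:
    """No rule fired: the dimension of the single longest finite step,
    ties broken toward the smaller dimension."""
    if not step_lengths:
        return 0
    longest = max(step_lengths.values())
    return min(d for d, s in step_lengths.items() if s >= longest - 1e-15)


def twice_mean_dimension(path: AuerGerviniPath) -> int:
    """Highest dimension whose step is longer than twice the mean step."""
    steps = path.step_lengths
    if not steps:
        return 0
    threshold = 2.0 * (sum(steps.values()) / len(steps))
    long_dims = [d for d, s in steps.items() if s > threshold]
    if long_dims:
        return max(long_dims)
    return _fallback_dimension(steps)


def _amoc_split(y: np.ndarray) -> tuple[int | None, float, float]:
    """Exhaustive at-most-one-change mean-shift search on ``y``.

    Returns (split index tau with segments y[:tau], y[tau:], or None;
    null RSS; best split RSS). tau minimizes the total within-segment
    squared error over all proper splits.
    """
    m = y.size
    rss_null = float(np.sum((y - y.mean()) ** 2))
    best_tau, best_rss = None, np.inf
    for tau in range(1, m):
        a, b = y[:tau], y[tau:]
        rss = float(np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2))
        if rss < best_rss - 1e-15:
            best_tau, best_rss = tau, rss
    return best_tau, rss_null, best_rss


def cpt_dimension(path: AuerGerviniPath) -> int:
    """At-most-one-changepoint rule on the sorted step lengths.

    The finite step lengths are sorted ascending and a single mean-shift
    changepoint is fitted by exhaustive search; it is accepted when the
    SIC-like criterion ``2*(logL_change - logL_null) > 3*log(m)`` holds
    (Gaussian likelihood with profiled common variance). Steps at or above
    the changepoint are "long"; the largest dimension among them wins.
    """
    steps = path.step_lengths
    if not steps:
        return 0
    if len(steps) == 1:
        return next(iter(steps))
    items = sorted(steps.items(), key=lambda kv: (kv[1], kv[0]))
    y = np.array([s for _, s in items])
    m = y.size
    tau, rss_null, rss_alt = _amoc_split(y)
    accepted = False
    if tau is not None and rss_alt > 0 and rss_null > 0:
        # profiled-variance Gaussian: 2*dlogL = m * log(rss_null / rss_alt)
        accepted = m * math.log(rss_null / rss_alt) > 3.0 * math.log(m)
    elif tau is not None and rss_alt == 0 and rss_null > 0:
        accepted = True
    if not accepted:
        return _fallback_dimension(steps)
    long_dims = [d for d, _ in items[tau:]]
    return max(long_dims)


def _best_contiguous_partition(y: np.ndarray, k: int) -> list[np.ndarray]:
    """Optimal 1-D k-means on sorted ``y`` by dynamic programming.

    The optimal 1-D k-means partition is contiguous in sorted order, so an
    exact O(m^2 k) DP over split points recovers it deterministically.
    """
    m = y.size
    pref = np.concatenate([[0.0], np.cumsum(y)])
    pref2 = np.concatenate([[0.0], np.cumsum(y**2)])

    def sse(i: int, j: int) -> float:  # segment y[i:j]
        n = j - i
        s = pref[j] - pref[i]
        return (pref2[j] - pref2[i]) - s * s / n

    cost = np.full((k + 1, m + 1), np.inf)
    back = np.zeros((k + 1, m + 1), dtype=int)
    cost[0, 0] = 0.0
    for kk in range(1, k + 1):
        for j in range(kk, m + 1):
            for i in range(kk - 1, j):
                c = cost[kk - 1, i] + sse(i, j)
                if c < cost[kk, j] - 1e-15:
                    cost[kk, j] = c
                    back[kk, j] = i
    bounds = [m]
    j = m
    for kk in range(k, 0, -1):
        j = back[kk, j]
        bounds.append(j)
    bounds = bounds[::-1]
    return [np.arange(bounds[i], bounds[i + 1]) for i in range(k)]


def kmeans3_dimension(path: AuerGerviniPath) -> int:
    """Three-group k-means on step lengths; medium and large are "long".

    With fewer than three distinct lengths the rule degrades to two groups
    (upper group long); with a single distinct length it falls back to the
    longest-step dimension.
    """
    steps = path.step_lengths
    if not steps:
        return 0
    items = sorted(steps.items(), key=lambda kv: (kv[1], kv[0]))
    y = np.array([s for _, s in items])
    k = min(3, len(np.unique(y)))
    if k == 1:
        return _fallback_dimension(steps)
    segments = _best_contiguous_partition(y, k)
    long_idx = np.concatenate(segments[1:])  # every group above "small"
    return max(items[i][0] for i in long_idx)


RULES = {
    "twicemean": twice_mean_dimension,
    "cpt": cpt_dimension,
    "kmeans3": kmeans3_dimension,
}


def dimension_by_rule(path: AuerGerviniPath, rule: str = "twicemean") -> int:
    try:
        return RULES[rule](path)
    except KeyError:
        raise ValueError(f"unknown rule {rule!r}; choose from {sorted(RULES)}") from None
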