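"""Gaussian kernels, median-heuristic bandwidths, and the biased HSIC estimator.

The Hilbert-Schmidt Independence Criterion (HSIC) is a kernel dependence
measure: for characteristic kernels (the Gaussian kernel used here) it is
zero if and only if the two variables are independent.  Given paired samples
(x_i, y_i), i = 1..n, the biased V-statistic estimator is

    HSIC_hat(X, Y) = (1/n^2) tr(K_X H K_Y H),      H = I - (1/n) 11^T,

where (K_X)_ij = k(x_i, x_j) and (K_Y)_ij = k(y_i, y_j).  The Gaussian
kernel convention throughout the package is

    k(a, b) = exp(-||a - b||^2 / sigma),

i.e. ``sigma`` divides the *squared* Euclidean distance directly (no factor
of two, no squared sigma).  The default bandwidth is accordingly the squared
median pairwise distance of the points the kernel is evaluated on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist

__all__ = [
    "KernelConfig",
    "GramPair",
    "gaussian_gram",
    "median_heuristic",
    "hsic_biased",
]

#: Bandwidth policies: per-variable median heuristic inside each cluster
#: (default), a single joint median over concatenated (x, y) rows, or
#: user-fixed bandwidths.
BANDWIDTH_POLICIES = ("median_per_cluster", "median_joint", "fixed")


@dataclass(frozen=True)
class KernelConfig:
    """Kernel family and bandwidth policy for the two HSIC Gram matrices.

    Parameters
    ----------
    family:
        Kernel family; only ``"gaussian"`` is supported.
    bandwidth_policy:
        One of :data:`BANDWIDTH_POLICIES`.  ``"median_per_cluster"`` computes
        sigma_x from the cluster's x-points and sigma_y from its y-points;
        ``"median_joint"`` uses one shared bandwidth from the concatenated
        (x, y) rows; ``"fixed"`` uses the two fixed bandwidths below.
    fixed_bandwidth_x, fixed_bandwidth_y:
        Bandwidths on the squared-distance scale, required (strictly positive
        and finite) under the ``"fixed"`` policy and ignored otherwise.
    """

    family: str = "gaussian"
    bandwidth_policy: str = "median_per_cluster"
    fixed_bandwidth_x: float | None = None
    fixed_bandwidth_y: float | None = None

    def __post_init__(self) -> None:
        if self.family != "gaussian":
            raise ValueError(f"unsupported kernel family: {self.family!r}")
        if self.bandwidth_policy not in BANDWIDTH_POLICIES:
            raise ValueError(
                f"bandwidth_policy must be one of {BANDWIDTH_POLICIES}, "
                f"got {self.bandwidth_policy!r}"
            )
        if self.bandwidth_policy == "fixed":
            for name in ("fixed_bandwidth_x", "fixed_bandwidth_y"):
                value = getattr(self, name)
                if value is None or not np.isfinite(value) or value <= 0:
                    raise ValueError(
                        f"{name} must be a strictly positive finite number "
                        f"under the 'fixed' policy, got {value!r}"
                    )


@dataclass(frozen=True)
class GramPair:
    """Two Gaussian Gram matrices over the same n samples."""

    k_x: np.ndarray
    k_y: np.ndarray

    @property
    def n(self) -> int:
        return self.k_x.shape[0]


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    if pts.ndim != 2:
        raise ValueError(f"points must be an n x d table, got shape {pts.shape}")
    return pts


def gaussian_gram(points, sigma: float) -> np.ndarray:
    """Gaussian Gram matrix exp(-||p_i - p_j||^2 / sigma).

    Parameters
    ----------
    points:
        n x d array of points (a 1-D array is treated as a column).
    sigma:
        Bandwidth on the squared-distance scale; must be positive and finite.
    """
    pts = _as_points(points)
    if pts.shape[0] < 1:
        raise ValueError("need at least one point")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points contain non-finite values")
    if not np.isfinite(sigma) or sigma <= 0:
        raise ValueError(f"sigma must be positive and finite, got {sigma!r}")
    sq = cdist(pts, pts, metric="sqeuclidean")
    gram = np.exp(-sq / sigma)
    # enforce exact symmetry / unit diagonal against floating noise in cdist
    gram = (gram + gram.T) / 2.0
    np.fill_diagonal(gram, 1.0)
    return gram


def median_heuristic(points) -> float:
    """Squared median pairwise Euclidean distance (self-pairs excluded).

    With the kernel convention exp(-d^2 / sigma) this puts the median-distance
    pair at exp(-1).  If every pairwise distance is zero (all points
    identical) the bandwidth degenerates; we fall back to 1.0 with a warning —
    the resulting Gram matrix is all-ones and contributes exactly zero
    dependence evidence, which is the correct degenerate behaviour.
    """
    pts = _as_points(points)
    if pts.shape[0] < 2:
        raise ValueError("median heuristic needs at least two points")
    med = float(np.median(pdist(pts)))
    if med == 0.0:
        warnings.warn(
            "all points identical; median-heuristic bandwidth falls back to 1.0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 1.0
    return med * med


def hsic_biased(k_x: np.ndarray, k_y: np.ndarray) -> float:
    """Biased HSIC estimator (1/n^2) tr(K_X H K_Y H).

    Computed in O(n^2): both Gram matrices are double-centered (H is
    idempotent, so tr(K_X H K_Y H) = tr((H K_X H)(H K_Y H))) and the trace
    becomes an elementwise product-sum, which makes the estimator exactly
    symmetric in its arguments even in floating point.  The value is
    non-negative up to ~1e-12 roundoff for valid PSD Gram matrices.
    """
    k_x = np.asarray(k_x, dtype=float)
    k_y = np.asarray(k_y, dtype=float)
    if k_x.ndim != 2 or k_x.shape[0] != k_x.shape[1]:
        raise ValueError(f"k_x must be square, got shape {k_x.shape}")
    if k_x.shape != k_y.shape:
        raise ValueError(f"Gram size mismatch: {k_x.shape} vs {k_y.shape}")
    n = k_x.shape[0]
    if n < 2:
        raise ValueError("HSIC needs at least two samples")
    return float(np.sum(_double_center(k_x) * _double_center(k_y)) / (n * n))


def _double_center(k: np.ndarray) -> np.ndarray:
    row = k.mean(axis=1, keepdims=True)
    col = k.mean(axis=0, keepdims=True)
    return k - row - col + k.mean()
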