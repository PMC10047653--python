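"""Local bootstrap: sampling from the null hypothesis X ⫫ Y | Z.

Calibrating a conditional-independence test requires samples that keep the
(X, Z) and (Y, Z) dependence but break any direct X–Y dependence.  The local
bootstrap achieves this with Nadaraya–Watson-style kernel weights: each
z*_i = z_i keeps its observed conditioning value, and x*_i and y*_i are drawn
*independently* from discrete distributions over the observed rows whose
probabilities decay with the z-distance,

    w_j  ∝  exp(-||z_j - z*||^2 / gamma_i),

restricted to the k nearest neighbours of z*_i (k = 10 by default), with the
local bandwidth gamma_i set to the squared distance from z*_i to its k-th
nearest neighbour.  Because the x-index and y-index are drawn independently
for each i, the joint X–Y coupling is destroyed while each marginal
conditional is preserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .statistic import CISample

__all__ = [
    "BootstrapPlan",
    "build_plan",
    "weight_kernel",
    "draw_null_indices",
    "draw_null_sample",
]


@dataclass(frozen=True)
class BootstrapPlan:
    """Per-sample candidate indices, local bandwidths, and sampling weights."""

    candidates: np.ndarray  # (n, k) ints; row i = k nearest neighbours of z_i
    gamma: np.ndarray  # (n,) positive local bandwidths
    weights: np.ndarray  # (n, k) rows sum to 1

    @property
    def n(self) -> int:
        return int(self.candidates.shape[0])

    @property
    def k_nn(self) -> int:
        return int(self.candidates.shape[1])


def weight_kernel(delta, gamma: float) -> float:
    """Gaussian resampling weight exp(-||delta||^2 / gamma) (unnormalised)."""
    if not np.isfinite(gamma) or gamma <= 0:
        raise ValueError(f"gamma must be positive and finite, got {gamma!r}")
    delta = np.asarray(delta, dtype=float)
    return float(np.exp(-np.sum(delta * delta) / gamma))


def build_plan(z, k_nn: int = 10, exclude_self: bool = False) -> BootstrapPlan:
    """Construct candidate sets, local bandwidths, and weights from z.

    For each sample i the candidates are its ``k_nn`` nearest points in
    z-space (itself included, at distance zero, unless ``exclude_self``);
    ties are broken by original index.  ``gamma_i`` is the squared distance
    to the k-th candidate.  Duplicated z-values can make that distance zero;
    we then fall back to the smallest positive candidate distance, and if
    every candidate coincides with z_i, to uniform weights.
    """
    z = np.asarray(z, dtype=float)
    if z.ndim == 1:
        z = z[:, None]
    n = z.shape[0]
    if n < 2:
        raise ValueError("need at least two samples")
    if k_nn < 1:
        raise ValueError(f"k_nn must be >= 1, got {k_nn}")
    limit = n - 1 if exclude_self else n
    if k_nn > limit:
        warnings.warn(
            f"k_nn={k_nn} exceeds the {limit} available neighbours; clamped",
            RuntimeWarning,
            stacklevel=2,
        )
        k_nn = limit

    sq = cdist(z, z, metric="sqeuclidean")
    rank = sq.copy()
    # pin self first (or last) regardless of duplicate z-values
    np.fill_diagonal(rank, np.inf if exclude_self else -1.0)
    order = np.argsort(rank, axis=1, kind="stable")
    candidates = order[:, :k_nn]
    cand_sq = np.take_along_axis(sq, candidates, axis=1)

    gamma = cand_sq[:, -1].copy()
    degenerate = gamma <= 0.0
    if np.any(degenerate):
        positive = np.where(cand_sq > 0.0, cand_sq, np.inf)
        smallest = positive.min(axis=1)
        fallback = np.where(np.isfinite(smallest), smallest, 1.0)
        gamma = np.where(degenerate, fallback, gamma)

    weights = np.exp(-cand_sq / gamma[:, None])
    weights /= weights.sum(axis=1, keepdims=True)
    return BootstrapPlan(candidates, gamma, weights)


def _draw(plan: BootstrapPlan, rng: np.random.Generator) -> np.ndarray:
    """One categorical draw per sample from its candidate weight vector."""
    cum = np.cumsum(plan.weights, axis=1)
    u = rng.random(plan.n)
    pos = np.minimum((u[:, None] >= cum).sum(axis=1), plan.k_nn - 1)
    return plan.candidates[np.arange(plan.n), pos]


def draw_null_indices(
    plan: BootstrapPlan, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Independent x- and y-index draws for one bootstrap replicate.

    The x-indices are drawn first (n uniforms), then the y-indices, so a
    given generator state yields a reproducible replicate.
    """
    return _draw(plan, rng), _draw(plan, rng)


def draw_null_sample(
    sample: CISample, plan: BootstrapPlan, rng: np.random.Generator
) -> CISample:
    """One bootstrap replicate: z* = z exactly, x* and y* resampled locally."""
    if plan.n != sample.n:
        raise ValueError(
            f"plan covers {plan.n} samples but the sample has {sample.n}"
        )
    ix, iy = draw_null_indices(plan, rng)
    return CISample(sample.x[ix], sample.y[iy], sample.z)
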