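"""Clustering of the conditioning variable Z.

The conditional-independence statistic never evaluates kernels on Z; Z enters
only through a k-means partition of the samples.  The cluster count follows a
fixed average-cluster-size rule: M = ceil(n / 50) for n <= 200 and
M = ceil(n / 80) for larger samples, so each cluster holds roughly 50-80
points — enough for a stable local HSIC estimate while keeping the z-values
within a cluster close.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

__all__ = ["ClusterPartition", "choose_cluster_count", "cluster_z"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClusterPartition:
    """Assignment of n samples to m clusters of Z."""

    labels: np.ndarray  # length-n ints in {0..m-1}
    m: int
    sizes: np.ndarray  # length-m ints, all >= 1

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        sizes = np.asarray(self.sizes, dtype=int)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "sizes", sizes)
        if sizes.shape != (self.m,):
            raise ValueError("sizes must have length m")
        if sizes.sum() != labels.shape[0]:
            raise ValueError("cluster sizes must sum to n")
        if np.any(sizes < 1):
            raise ValueError("empty cluster in partition")
        if labels.size and (labels.min() < 0 or labels.max() >= self.m):
            raise ValueError("label out of range")

    @property
    def n(self) -> int:
        return int(self.labels.shape[0])

    def members(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.labels == label)


def choose_cluster_count(
    n: int,
    avg_cluster_size_small: int = 50,
    avg_cluster_size_large: int = 80,
    threshold: int = 200,
) -> int:
    """Cluster count from the average-cluster-size rule.

    Returns ceil(n / avg_cluster_size_small) when n <= threshold and
    ceil(n / avg_cluster_size_large) otherwise.
    """
    if n < 2:
        raise ValueError(f"need n >= 2 samples, got {n}")
    size = avg_cluster_size_small if n <= threshold else avg_cluster_size_large
    return min(max(1, math.ceil(n / size)), n)


def cluster_z(z, m: int, seed: int, standardize: bool = False) -> ClusterPartition:
    """Partition samples into m clusters by k-means on the z-block only.

    Deterministic for a fixed ``seed`` (seeded k-means++ with 10 restarts).
    Z is used raw by default; ``standardize`` optionally scales each z
    coordinate to unit variance first.  Should k-means leave a cluster empty
    (possible on degenerate data), the empty cluster is repaired by moving
    the point farthest from its current centroid into it.
    """
    z = np.asarray(z, dtype=float)
    if z.ndim == 1:
        z = z[:, None]
    if not np.all(np.isfinite(z)):
        raise ValueError("z contains non-finite values")
    n = z.shape[0]
    if m < 1:
        raise ValueError(f"cluster count must be >= 1, got {m}")
    if m > n:
        raise ValueError(f"cannot form {m} clusters from {n} samples")

    if m == 1:
        return ClusterPartition(np.zeros(n, dtype=int), 1, np.array([n]))

    work = z
    if standardize:
        scale = z.std(axis=0)
        scale[scale == 0] = 1.0
        work = z / scale

    km = KMeans(n_clusters=m, n_init=10, random_state=int(seed))
    labels = km.fit_predict(work).astype(int)

    # repair empty clusters: donate the farthest point of the largest cluster
    for empty in range(m):
        while not np.any(labels == empty):
            sizes = np.bincount(labels, minlength=m)
            donor = int(np.argmax(sizes))
            idx = np.flatnonzero(labels == donor)
            centroid = work[idx].mean(axis=0)
            far = idx[np.argmax(((work[idx] - centroid) ** 2).sum(axis=1))]
            labels[far] = empty
            logger.warning(
                "repaired empty cluster %d by reassigning sample %d", empty, far
            )

    sizes = np.bincount(labels, minlength=m)
    return ClusterPartition(labels, m, sizes)
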