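"""The conditional-independence test: statistic + local-bootstrap calibration.

One test run is:

1. choose the cluster count M from the sample size,
2. k-means the observed z once (z is never altered by the bootstrap, so the
   partition is shared by every replicate),
3. compute the observed statistic T with per-cluster median bandwidths,
4. build the local-bootstrap plan once from z,
5. draw K null replicates and recompute the statistic on each,
6. report the Monte-Carlo p-value  p = (1/K) sum_k 1{T_k >= T}  and reject
   when p < alpha.

By default the observed per-cluster bandwidths are reused on every replicate
(``bandwidth_refresh="reuse_observed"``), which keeps the statistic
functional identical across the null histogram and allows the per-cluster
Gram matrices to be precomputed over the full sample; replicates then only
gather sub-matrices.  ``"recompute_per_replicate"`` re-runs the median
heuristic on each replicate instead.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist

from .bootstrap import BootstrapPlan, build_plan, draw_null_indices, draw_null_sample
from .kernels import KernelConfig, hsic_biased
from .partition import ClusterPartition, choose_cluster_count, cluster_z
from .statistic import CISample, StatisticBreakdown, bhsic_statistic

__all__ = ["TestConfig", "TestResult", "compute_p_value", "run_test"]

logger = logging.getLogger(__name__)

# fast path precomputes 2M full n x n Gram matrices; cap the footprint
_FAST_PATH_BYTES = 2 * 10**8


@dataclass(frozen=True)
class TestConfig:
    """All tunables of one test run.

    ``n_bootstrap`` is the number K of null replicates; ``alpha`` the
    significance level; ``k_nn`` the candidate-set size of the local
    bootstrap; the three ``avg_cluster_size``/``threshold`` fields define the
    cluster-count rule.  ``add_one_correction`` switches the p-value to
    (1 + #{T_k >= T}) / (1 + K), which is never anti-conservative at
    finite K.
    """

    n_bootstrap: int = 1000
    alpha: float = 0.05
    k_nn: int = 10
    avg_cluster_size_small: int = 50
    avg_cluster_size_large: int = 80
    size_threshold: int = 200
    kernel: KernelConfig = field(default_factory=KernelConfig)
    seed: int | None = None
    bandwidth_refresh: str = "reuse_observed"
    exclude_self: bool = False
    standardize_z: bool = False
    add_one_correction: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if self.bandwidth_refresh not in ("reuse_observed", "recompute_per_replicate"):
            raise ValueError(
                f"unknown bandwidth_refresh: {self.bandwidth_refresh!r}"
            )


@dataclass(frozen=True)
class TestResult:
    """Observed statistic, null histogram, p-value, and full provenance."""

    statistic: float
    null_statistics: np.ndarray
    p_value: float
    reject: bool
    partition: ClusterPartition
    breakdown: StatisticBreakdown
    config: TestConfig
    seed: int


def compute_p_value(observed: float, null_stats, add_one: bool = False) -> float:
    """Monte-Carlo p-value: fraction of null statistics >= the observed one.

    Ties count as exceedances.  ``add_one`` applies the (1+count)/(1+K)
    finite-sample correction.
    """
    nulls = np.asarray(null_stats, dtype=float)
    if nulls.size == 0:
        raise ValueError("null statistics must be non-empty")
    count = int(np.count_nonzero(nulls >= observed))
    if add_one:
        return (count + 1) / (nulls.size + 1)
    return count / nulls.size


def _center_product(k_x: np.ndarray, k_y: np.ndarray) -> float:
    """(1/n^2) tr(K_X H K_Y H) without re-validating the inputs."""
    from .kernels import _double_center

    n = k_x.shape[0]
    return float(np.sum(_double_center(k_x) * _double_center(k_y)) / (n * n))


def _null_statistics_reuse(
    sample: CISample,
    part: ClusterPartition,
    breakdown: StatisticBreakdown,
    plan: BootstrapPlan,
    rng: np.random.Generator,
    n_bootstrap: int,
) -> np.ndarray:
    """Null statistics with the observed per-cluster bandwidths reused."""
    n = sample.n
    clusters: list[tuple[np.ndarray, float, float]] = []
    for label in range(part.m):
        members = part.members(label)
        sx, sy = breakdown.bandwidths[label]
        if members.size < 2 or not (math.isfinite(sx) and math.isfinite(sy)):
            continue  # singleton clusters contribute 0 to every replicate
        clusters.append((members, sx, sy))

    fast = len(clusters) * n * n * 16 <= _FAST_PATH_BYTES
    if fast:
        sq_x = cdist(sample.x, sample.x, metric="sqeuclidean")
        sq_y = cdist(sample.y, sample.y, metric="sqeuclidean")
        grams = [
            (members, np.exp(-sq_x / sx), np.exp(-sq_y / sy))
            for members, sx, sy in clusters
        ]

    nulls = np.empty(n_bootstrap)
    for k in range(n_bootstrap):
        ix, iy = draw_null_indices(plan, rng)
        total = 0.0
        if fast:
            for members, ex, ey in grams:
                a = ix[members]
                b = iy[members]
                total += _center_product(ex[np.ix_(a, a)], ey[np.ix_(b, b)])
        else:
            for members, sx, sy in clusters:
                xs = sample.x[ix[members]]
                ys = sample.y[iy[members]]
                kx = np.exp(-cdist(xs, xs, metric="sqeuclidean") / sx)
                ky = np.exp(-cdist(ys, ys, metric="sqeuclidean") / sy)
                total += hsic_biased(kx, ky)
        nulls[k] = total
    return nulls


def _null_statistics_recompute(
    sample: CISample,
    part: ClusterPartition,
    kconf: KernelConfig,
    plan: BootstrapPlan,
    rng: np.random.Generator,
    n_bootstrap: int,
) -> np.ndarray:
    """Null statistics with bandwidths re-estimated on every replicate."""
    nulls = np.empty(n_bootstrap)
    for k in range(n_bootstrap):
        null_sample = draw_null_sample(sample, plan, rng)
        with warnings.catch_warnings():
            # resampling can duplicate rows; the bandwidth fallback is routine here
            warnings.simplefilter("ignore", RuntimeWarning)
            nulls[k] = bhsic_statistic(null_sample, part, kconf).total
    return nulls


def run_test(sample: CISample, config: TestConfig | None = None) -> TestResult:
    """Run the full conditional-independence test on one sample.

    Fully reproducible from ``config.seed``; when the seed is absent one is
    drawn from OS entropy and recorded in the result (and in the log) so the
    run can be replayed.
    """
    config = config or TestConfig()
    n = sample.n
    if n < 4:
        warnings.warn(
            f"n={n} is very small for a bootstrap CI test", RuntimeWarning, stacklevel=2
        )

    if config.seed is None:
        seed = int(np.random.SeedSequence().generate_state(1)[0] % (2**31))
        logger.info("no seed supplied; drew seed=%d", seed)
    else:
        seed = int(config.seed)
    ss_kmeans, ss_boot = np.random.SeedSequence(seed).spawn(2)
    kmeans_seed = int(ss_kmeans.generate_state(1)[0] % (2**31))
    rng = np.random.default_rng(ss_boot)

    m = choose_cluster_count(
        n,
        config.avg_cluster_size_small,
        config.avg_cluster_size_large,
        config.size_threshold,
    )
    part = cluster_z(sample.z, m, kmeans_seed, standardize=config.standardize_z)
    breakdown = bhsic_statistic(sample, part, config.kernel)
    plan = build_plan(sample.z, config.k_nn, exclude_self=config.exclude_self)

    if config.bandwidth_refresh == "reuse_observed":
        nulls = _null_statistics_reuse(
            sample, part, breakdown, plan, rng, config.n_bootstrap
        )
    else:
        nulls = _null_statistics_recompute(
            sample, part, config.kernel, plan, rng, config.n_bootstrap
        )

    if not np.all(np.isfinite(nulls)) or not math.isfinite(breakdown.total):
        raise RuntimeError(
            "non-finite statistic encountered "
            f"(observed={breakdown.total}, nulls finite="
            f"{int(np.isfinite(nulls).sum())}/{nulls.size})"
        )

    p_value = compute_p_value(breakdown.total, nulls, config.add_one_correction)
    return TestResult(
        statistic=breakdown.total,
        null_statistics=nulls,
        p_value=p_value,
        reject=bool(p_value < config.alpha),
        partition=part,
        breakdown=breakdown,
        config=replace(config, seed=seed),
        seed=seed,
    )
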