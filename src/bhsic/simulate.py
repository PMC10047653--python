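"""Synthetic benchmark models and Type-I / Type-II error experiments.

Two data-generating models are provided, both with z-coordinates i.i.d.
standard Gaussian and independent standard Gaussian noise terms e1, e2 and
a shared confounder eb whose strength c switches the hypothesis:
c = 0 gives X ⫫ Y | Z (the null), c = 1 injects a common hidden cause
(the alternative).

Linear model:
    X = sum_i alpha_i Z_i + c*eb + e1,   Y = sum_i beta_i Z_i + c*eb + e2,
    alpha_i, beta_i ~ Uniform(-0.5/d_z, 0.5/d_z), redrawn per dataset.

Post-nonlinear model:
    X = g1(sum_i Z_i + c*eb + e1),       Y = g2(sum_i Z_i + c*eb + e2),
    g1, g2 drawn independently and uniformly from
    {identity, u^2, u^3, tanh(u), exp(-u^2)} per dataset.

``error_rate_experiment`` replicates generate + test with independent
per-replicate seeds and reports the rejection rate: the Type-I error rate
when c = 0, and one minus the Type-II error rate when c = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .citest import TestConfig, run_test
from .statistic import CISample

__all__ = [
    "SimConfig",
    "ExperimentResult",
    "G_FUNCTIONS",
    "generate",
    "error_rate_experiment",
    "grid_experiment",
]

MODELS = ("linear", "postnonlinear")

#: Post-nonlinear link functions, drawn uniformly per dataset.
G_FUNCTIONS = {
    "identity": lambda u: u,
    "square": lambda u: u**2,
    "cube": lambda u: u**3,
    "tanh": np.tanh,
    "neg_sq_exp": lambda u: np.exp(-(u**2)),
}
_G_NAMES = tuple(G_FUNCTIONS)


@dataclass(frozen=True)
class SimConfig:
    model: str = "postnonlinear"
    n: int = 400
    d_z: int = 1
    c: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}, got {self.model!r}")
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.d_z < 1:
            raise ValueError("d_z must be >= 1")


@dataclass(frozen=True)
class ExperimentResult:
    rejection_rate: float
    replications: int
    p_values: np.ndarray
    sim: SimConfig
    test_config: TestConfig
    g_choices: list[tuple[str, str]] = field(default_factory=list)


def generate(
    sim: SimConfig,
    rng: np.random.Generator | None = None,
    return_info: bool = False,
):
    """Draw one dataset; optionally also return the realised parameters.

    With ``return_info=True`` the second return value records the drawn
    coefficients (linear model) or link-function names (post-nonlinear
    model), so experiment logs can confirm coverage of all five g forms.
    """
    if rng is None:
        rng = np.random.default_rng(sim.seed)
    n, d_z, c = sim.n, sim.d_z, sim.c
    z = rng.standard_normal((n, d_z))
    e1 = rng.standard_normal(n)
    e2 = rng.standard_normal(n)
    eb = rng.standard_normal(n)

    if sim.model == "linear":
        half = 0.5 / d_z
        alpha = rng.uniform(-half, half, size=d_z)
        beta = rng.uniform(-half, half, size=d_z)
        x = z @ alpha + c * eb + e1
        y = z @ beta + c * eb + e2
        info = {"alpha": alpha, "beta": beta}
    else:
        g1_name, g2_name = rng.choice(_G_NAMES, size=2)
        s = z.sum(axis=1)
        x = G_FUNCTIONS[g1_name](s + c * eb + e1)
        y = G_FUNCTIONS[g2_name](s + c * eb + e2)
        info = {"g1": g1_name, "g2": g2_name}

    sample = CISample(x, y, z)
    return (sample, info) if return_info else sample


def error_rate_experiment(
    sim: SimConfig,
    test_config: TestConfig | None = None,
    replications: int = 100,
) -> ExperimentResult:
    """Rejection rate over independent replicates of generate + test.

    Each replicate gets its own data stream and test seed, both spawned
    deterministically from ``sim.seed`` (or the test seed when sim carries
    none), so the whole experiment replays from one integer.
    """
    test_config = test_config or TestConfig()
    if replications < 1:
        raise ValueError("replications must be >= 1")
    root = sim.seed if sim.seed is not None else test_config.seed
    streams = np.random.SeedSequence(root).spawn(replications)

    p_values = np.empty(replications)
    g_choices: list[tuple[str, str]] = []
    for r, stream in enumerate(streams):
        ss_data, ss_test = stream.spawn(2)
        out = generate(sim, np.random.default_rng(ss_data), return_info=True)
        sample, info = out
        if sim.model == "postnonlinear":
            g_choices.append((info["g1"], info["g2"]))
        rep_seed = int(ss_test.generate_state(1)[0] % (2**31))
        result = run_test(sample, replace(test_config, seed=rep_seed))
        p_values[r] = result.p_value

    rate = float(np.count_nonzero(p_values < test_config.alpha) / replications)
    return ExperimentResult(rate, replications, p_values, sim, test_config, g_choices)


def grid_experiment(
    cells: list[dict],
    test_config: TestConfig | None = None,
    replications: int = 100,
    base_seed: int | None = None,
) -> pd.DataFrame:
    """Run a grid of simulation cells and return a tidy result table.

    Each cell is a dict of :class:`SimConfig` field overrides.  Columns:
    model, n, d_z, c, m, replications, rejection_rate, mean_p, seed.
    """
    test_config = test_config or TestConfig()
    streams = np.random.SeedSequence(base_seed).spawn(len(cells))
    rows = []
    for cell, stream in zip(cells, streams):
        seed = int(stream.generate_state(1)[0] % (2**31))
        sim = SimConfig(seed=seed, **cell)
        res = error_rate_experiment(sim, test_config, replications)
        from .partition import choose_cluster_count

        rows.append(
            {
                "model": sim.model,
                "n": sim.n,
                "d_z": sim.d_z,
                "c": sim.c,
                "m": choose_cluster_count(
                    sim.n,
                    test_config.avg_cluster_size_small,
                    test_config.avg_cluster_size_large,
                    test_config.size_threshold,
                ),
                "replications": replications,
                "rejection_rate": res.rejection_rate,
                "mean_p": float(res.p_values.mean()),
                "seed": seed,
            }
        )
    return pd.DataFrame(rows)
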