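"""Synthetic benchmark generator.

Ground-truth networks are sparse random DBNs: adjacency entries are
independent Bernoulli(5/|V|) draws (so each vertex averages five parents,
roughly the sparsity of signaling pathways) and edge weights are
Normal(0, 1/|V|) — the 1/|V| variance keeps simulated trajectories from
diverging.  Time courses follow the linear-Gaussian recursion

    x_1 ~ N(0, I),    x_{t+1, j} = sum_i beta_ij x_{t, i} + eps,  eps ~ N(0, 1)

with M = 4 replicate courses of T = 8 timepoints by default, imitating
phosphoproteomic time-course dimensions.  Imperfect prior knowledge is
emulated by corrupting the true adjacency: a fraction ``r`` of true edges is
removed (false negatives) and ``a * |E0|`` spurious edges are added (false
positives).

The full benchmark grid crosses |V| in {40, 100, 200} with r and a each in
{0.1, 0.5, 0.75, 1.0}: 48 cells, 5 replicates per cell, 240 instances.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import PriorConfidences, TimeCourseSet

__all__ = [
    "SimulatedInstance",
    "sample_true_dbn",
    "simulate_time_courses",
    "corrupt_graph",
    "simulate_instance",
    "generate_grid",
    "GRID_V", "GRID_R", "GRID_A", "GRID_REPLICATES",
]

GRID_V = (40, 100, 200)
GRID_R = (0.1, 0.5, 0.75, 1.0)
GRID_A = (0.1, 0.5, 0.75, 1.0)
GRID_REPLICATES = 5
DEFAULT_M = 4
DEFAULT_T = 8
EXPECTED_PARENTS = 5.0  # Bernoulli rate is EXPECTED_PARENTS / |V|


@dataclass
class SimulatedInstance:
    """One synthetic benchmark dataset: truth, data, corrupted prior."""

    adjacency: np.ndarray = field(repr=False)
    weights: np.ndarray = field(repr=False)
    data: TimeCourseSet = field(repr=False)
    prior: PriorConfidences = field(repr=False)
    params: dict = field(default_factory=dict)


def sample_true_dbn(v: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Sample a ground-truth DBN: binary adjacency (diagonal included, a
    self-edge being plain autoregression) and Gaussian edge weights.

    Returns ``(A, beta)`` with ``A_ij ~ Bernoulli(min(1, 5/v))`` and
    ``beta_ij ~ N(0, 1/v)`` where ``A_ij = 1``, zero elsewhere.
    """
    if v < 2:
        raise ValueError("need at least 2 vertices")
    p = min(1.0, EXPECTED_PARENTS / v)
    a = (rng.random((v, v)) < p).astype(np.uint8)
    beta = np.where(a == 1, rng.normal(0.0, 1.0 / np.sqrt(v), size=(v, v)), 0.0)
    return a, beta


def simulate_time_courses(
    a: np.ndarray,
    beta: np.ndarray,
    m: int,
    t: int,
    rng: np.random.Generator,
    noise_sd: float = 1.0,
) -> TimeCourseSet:
    """Simulate ``m`` independent courses of length ``t`` from the DBN.

    ``x_1 ~ N(0, I)``; each later timepoint is the weighted sum of the
    previous timepoint over incoming edges plus N(0, noise_sd^2) noise.
    """
    if m < 1 or t < 2:
        raise ValueError("need m >= 1 courses of t >= 2 timepoints")
    v = a.shape[0]
    w = np.where(a == 1, beta, 0.0)  # w[i, j]: weight of edge i -> j
    courses = []
    for _ in range(m):
        x = np.empty((t, v))
        x[0] = rng.normal(size=v)
        for step in range(1, t):
            x[step] = x[step - 1] @ w + rng.normal(scale=noise_sd, size=v)
        if not np.all(np.isfinite(x)):
            raise FloatingPointError("simulated trajectory diverged")
        courses.append(x)
    variables = [f"v{j}" for j in range(v)]
    return TimeCourseSet(variables, courses)


def _round_half_even(x: float) -> int:
    return int(np.rint(x))


def corrupt_graph(a: np.ndarray, r: float, add: float, rng: np.random.Generator) -> np.ndarray:
    """Corrupt a true adjacency into imperfect binary prior knowledge.

    Removes ``round(r * |E0|)`` uniformly chosen true edges and adds
    ``round(add * |E0|)`` uniformly chosen spurious edges (``|E0|`` = original
    edge count; rounding is ties-to-even).  If fewer non-edges exist than
    requested additions, all non-edges are added with a warning.
    """
    if not (0 <= r <= 1 and 0 <= add <= 1):
        raise ValueError("corruption fractions must lie in [0, 1]")
    a = np.asarray(a, dtype=np.uint8)
    edges = np.argwhere(a == 1)
    n_edges = edges.shape[0]
    prior = a.copy()
    if n_edges == 0:
        return prior
    n_remove = _round_half_even(r * n_edges)
    n_add = _round_half_even(add * n_edges)
    if n_remove > 0:
        drop = rng.choice(n_edges, size=n_remove, replace=False)
        prior[edges[drop, 0], edges[drop, 1]] = 0
    non_edges = np.argwhere(a == 0)
    if n_add > non_edges.shape[0]:
        import warnings

        warnings.warn(
            f"requested {n_add} spurious edges but only {non_edges.shape[0]} "
            "non-edges exist; adding all of them",
            RuntimeWarning,
        )
        n_add = non_edges.shape[0]
    if n_add > 0:
        pick = rng.choice(non_edges.shape[0], size=n_add, replace=False)
        prior[non_edges[pick, 0], non_edges[pick, 1]] = 1
    return prior


def simulate_instance(
    v: int,
    r: float,
    a: float,
    seed: int,
    m: int = DEFAULT_M,
    t: int = DEFAULT_T,
    replicate: int = 0,
) -> SimulatedInstance:
    """Generate one complete benchmark instance from a single seed."""
    rng = np.random.Generator(np.random.Philox(seed))
    adj, beta = sample_true_dbn(v, rng)
    data = simulate_time_courses(adj, beta, m, t, rng)
    prior_mat = corrupt_graph(adj, r, a, rng)
    prior = PriorConfidences(data.variables, prior_mat.astype(float))
    params = {
        "V": v, "r": r, "a": a, "M": m, "T": t,
        "replicate": replicate, "seed": int(seed),
        "n_true_edges": int(adj.sum()),
    }
    return SimulatedInstance(adj, beta, data, prior, params)


def _instance_seed(base_seed: int, v: int, r: float, a: float, k: int) -> int:
    ss = np.random.SeedSequence(
        [int(base_seed), v, int(round(r * 100)), int(round(a * 100)), k]
    )
    return int(ss.generate_state(1)[0] % (2**31))


def generate_grid(
    out_dir,
    base_seed: int = 0,
    v_values=GRID_V,
    r_values=GRID_R,
    a_values=GRID_A,
    n_replicates: int = GRID_REPLICATES,
    m: int = DEFAULT_M,
    t: int = DEFAULT_T,
) -> pd.DataFrame:
    """Generate the full benchmark grid on disk and return its manifest.

    Each instance is written as a data CSV (long format: replicate, time,
    variables), a sparse edge-list prior CSV, a truth edge-list CSV and a
    JSON sidecar of parameters; ``manifest.csv`` ties them together.
    Deterministic per-cell seeds make repeated runs byte-identical.
    """
    from . import io as ssps_io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for v in v_values:
        for r in r_values:
            for a in a_values:
                for k in range(n_replicates):
                    seed = _instance_seed(base_seed, v, r, a, k)
                    inst = simulate_instance(v, r, a, seed, m=m, t=t, replicate=k)
                    stem = f"V{v}_r{r}_a{a}_rep{k}"
                    paths = {
                        "data": out / f"{stem}_data.csv",
                        "prior": out / f"{stem}_prior.csv",
                        "truth": out / f"{stem}_truth.csv",
                        "params": out / f"{stem}_params.json",
                    }
                    ssps_io.write_time_courses(paths["data"], inst.data)
                    ssps_io.write_edge_list(paths["prior"], inst.data.variables, inst.prior.conf)
                    ssps_io.write_edge_list(
                        paths["truth"], inst.data.variables, inst.adjacency.astype(float)
                    )
                    paths["params"].write_text(json.dumps(inst.params, indent=1))
                    rows.append(
                        {
                            "V": v, "r": r, "a": a, "replicate": k, "seed": seed,
                            "n_true_edges": inst.params["n_true_edges"],
                            **{f"{k2}_path": str(p) for k2, p in paths.items()},
                        }
                    )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
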