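"""Metropolis–Hastings sampler over DBN structures.

Each MCMC iteration sweeps the vertices in ascending order; for each vertex
``j`` it first updates the inverse temperature ``lambda_j`` (symmetric
Gaussian random walk) and then updates the parent set ``pa(j)`` with a
proposal purpose-built for sparse graphs.

The parent-set proposal chooses among three actions — add-parent,
remove-parent and swap-parent — with size-dependent probabilities.  With
``s = |pa(j)|``, reference size ``s_hat_j = sum_i c_ij`` and
``u = (s/|V|)^gamma(s_hat)`` where ``gamma(s_hat) = 1 / log2(|V| / s_hat)``,
the unnormalized action weights are ``(1 - u, u, 2u(1 - u))``.  These forms
are chosen for their boundary behavior: add is certain at ``s = 0``, remove
is certain at ``s = |V|``, and all three actions are equally likely at
``s = s_hat``.  Swap moves keep ``|pa(j)|`` fixed, which matters because the
marginal likelihood penalizes parent-set size steeply.

Each action is paired with its exact reverse (add <-> remove; swap is its own
reverse), so the reverse transition mass in the Metropolis–Hastings ratio is
available in closed form.
"""

from __future__ import annotations

import logging
import math
import time
import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import PriorConfidences, TimeCourseSet
from .model import (
    GraphState,
    MarginalLikelihood,
    ModelConfig,
    edge_prior_probability,
    log_prior_vertex,
)

__all__ = [
    "ProposalConfig",
    "TerminationPolicy",
    "ChainTrace",
    "action_probabilities",
    "propose_parent_update",
    "mh_update_parents",
    "mh_update_lambda",
    "run_chain",
    "run_chains",
]

_ADD, _REMOVE, _SWAP = "add", "remove", "swap"

logger = logging.getLogger("ssps.mcmc")


@dataclass
class ProposalConfig:
    """Tunables of the proposal distributions.

    xi:
        Standard deviation of the Gaussian lambda random walk.  The sampler
        is insensitive to it over a wide range; default 3.
    shat_floor / shat_ceil_frac:
        The reference size is clamped to ``[shat_floor, shat_ceil_frac * |V|]``
        before computing gamma, which requires ``|V| / s_hat > 1``; an empty
        prior column would otherwise leave gamma undefined.
    update_lambdas:
        Set False to freeze the inverse temperatures (used by exact-posterior
        comparisons where lambda is held fixed).
    """

    xi: float = 3.0
    shat_floor: float = 1.0
    shat_ceil_frac: float = 0.5
    update_lambdas: bool = True

    def __post_init__(self):
        if self.xi <= 0:
            raise ValueError("xi must be positive")
        if not (0 < self.shat_ceil_frac < 1):
            raise ValueError("shat_ceil_frac must lie in (0, 1)")


@dataclass
class TerminationPolicy:
    """When chains stop and how many of them run.

    A chain terminates when it reaches ``max_iterations`` or its wall time
    exceeds ``max_wall_seconds`` (checked at iteration boundaries, so traces
    always hold whole sweeps).  Defaults mirror an overnight-run budget:
    100,000 iterations or 12 hours, 4 chains, first half discarded as burnin.
    """

    max_iterations: int = 100_000
    max_wall_seconds: float = 43_200.0
    n_chains: int = 4
    burnin_fraction: float = 0.5

    def __post_init__(self):
        if self.max_iterations <= 0 or self.max_wall_seconds <= 0 or self.n_chains <= 0:
            raise ValueError("termination settings must be positive")
        if not (0 < self.burnin_fraction < 1):
            raise ValueError("burnin_fraction must lie in (0, 1)")


@dataclass
class ChainTrace:
    """Delta-encoded record of one chain.

    Only accepted changes are stored per iteration; replaying the deltas from
    ``initial state`` reconstructs the state at any iteration exactly.
    """

    n_vertices: int
    initial_parents: tuple[frozenset[int], ...]
    initial_lambdas: np.ndarray
    deltas: list[list[tuple]]
    seed: int
    accept_counts: dict[str, int] = field(default_factory=dict)
    propose_counts: dict[str, int] = field(default_factory=dict)
    elapsed_seconds: float = 0.0

    @property
    def iteration_count(self) -> int:
        return len(self.deltas)

    def acceptance_rates(self) -> dict[str, float]:
        return {
            k: self.accept_counts.get(k, 0) / n
            for k, n in self.propose_counts.items()
            if n > 0
        }

    def _initial_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        v = self.n_vertices
        z = np.zeros((v, v), dtype=np.uint8)
        for j, pa in enumerate(self.initial_parents):
            for i in pa:
                z[i, j] = 1
        return z, np.asarray(self.initial_lambdas, dtype=float).copy()

    @staticmethod
    def _apply(op: tuple, z: np.ndarray, lam: np.ndarray) -> None:
        kind = op[0]
        if kind == "lam":
            lam[op[1]] = op[2]
        elif kind == _ADD:
            z[op[2], op[1]] = 1
        elif kind == _REMOVE:
            z[op[2], op[1]] = 0
        elif kind == _SWAP:
            z[op[2], op[1]] = 0
            z[op[3], op[1]] = 1
        else:  # pragma: no cover
            raise ValueError(f"unknown delta op {kind!r}")

    def replay_dense(self) -> tuple[np.ndarray, np.ndarray]:
        """Dense replay: (z_seq, lambda_seq) with one entry per iteration,
        recorded after the full sweep."""
        z, lam = self._initial_arrays()
        n = self.iteration_count
        v = self.n_vertices
        z_seq = np.empty((n, v, v), dtype=np.uint8)
        lam_seq = np.empty((n, v), dtype=float)
        for t, ops in enumerate(self.deltas):
            for op in ops:
                self._apply(op, z, lam)
            z_seq[t] = z
            lam_seq[t] = lam
        return z_seq, lam_seq

    def state_at(self, iteration: int) -> GraphState:
        """State after ``iteration`` full sweeps (0 = initial state)."""
        if not 0 <= iteration <= self.iteration_count:
            raise IndexError("iteration out of range")
        z, lam = self._initial_arrays()
        for ops in self.deltas[:iteration]:
            for op in ops:
                self._apply(op, z, lam)
        parents = [set(np.flatnonzero(z[:, j]).tolist()) for j in range(self.n_vertices)]
        return GraphState(parents, lam)

    def final_state(self) -> GraphState:
        return self.state_at(self.iteration_count)


def _clamp_shat(shat: float, v_pool: int, floor: float, ceil_frac: float) -> float:
    hi = max(floor, ceil_frac * v_pool)
    return min(max(shat, floor), hi)


def action_probabilities(
    s: int,
    shat: float,
    v_pool: int,
    shat_floor: float = 1.0,
    shat_ceil_frac: float = 0.5,
) -> np.ndarray:
    """Normalized (add, remove, swap) probabilities at parent count ``s``.

    ``v_pool`` is the candidate-parent pool size (|V|, or |V|-1 when
    self-edges are excluded).  ``shat`` is clamped before use.
    """
    if v_pool < 2:
        raise ValueError("candidate pool must contain at least 2 vertices")
    if not 0 <= s <= v_pool:
        raise ValueError("parent count out of range")
    shat_c = _clamp_shat(float(shat), v_pool, shat_floor, shat_ceil_frac)
    gamma = 1.0 / math.log2(v_pool / shat_c)
    u = (s / v_pool) ** gamma
    w = np.array([1.0 - u, u, 2.0 * u * (1.0 - u)])
    return w / w.sum()


def _propose(parents: set[int], pool: np.ndarray, shat: float, cfg: ProposalConfig, rng):
    """Sample one parent-set action.  Returns
    (action, removed, added, new_parents, log_q_fwd, log_q_rev)."""
    v_pool = pool.shape[0]
    s = len(parents)
    probs = action_probabilities(s, shat, v_pool, cfg.shat_floor, cfg.shat_ceil_frac)
    r = rng.random()
    action_idx = 0 if r < probs[0] else (1 if r < probs[0] + probs[1] else 2)

    non_parents = [i for i in pool.tolist() if i not in parents]
    parent_list = sorted(parents)
    logp = np.log(np.maximum(probs, 1e-300))

    if action_idx == 0:  # add-parent
        added = non_parents[rng.integers(len(non_parents))]
        new_parents = parents | {added}
        log_q_fwd = logp[0] - math.log(len(non_parents))
        rev = action_probabilities(s + 1, shat, v_pool, cfg.shat_floor, cfg.shat_ceil_frac)
        log_q_rev = math.log(max(rev[1], 1e-300)) - math.log(s + 1)
        return _ADD, None, added, new_parents, log_q_fwd, log_q_rev
    if action_idx == 1:  # remove-parent
        removed = parent_list[rng.integers(s)]
        new_parents = parents - {removed}
        log_q_fwd = logp[1] - math.log(s)
        rev = action_probabilities(s - 1, shat, v_pool, cfg.shat_floor, cfg.shat_ceil_frac)
        log_q_rev = math.log(max(rev[0], 1e-300)) - math.log(v_pool - s + 1)
        return _REMOVE, removed, None, new_parents, log_q_fwd, log_q_rev
    # swap-parent: remove one parent and add one non-parent; self-inverse with
    # identical selection mass both ways.
    removed = parent_list[rng.integers(s)]
    added = non_parents[rng.integers(len(non_parents))]
    new_parents = (parents - {removed}) | {added}
    log_q = logp[2] - math.log(s) - math.log(v_pool - s)
    return _SWAP, removed, added, new_parents, log_q, log_q


def _candidate_pool(v: int, j: int, allow_self_edges: bool) -> np.ndarray:
    if allow_self_edges:
        return np.arange(v)
    return np.delete(np.arange(v), j)


def propose_parent_update(
    state: GraphState,
    j: int,
    prior: PriorConfidences,
    rng: np.random.Generator,
    proposal_config: ProposalConfig | None = None,
    allow_self_edges: bool = True,
):
    """Draw a candidate parent set for vertex ``j``.

    Returns ``(candidate_parents, log_q_forward, log_q_reverse, action)``.
    The reverse mass is evaluated under the paired reverse action at the
    candidate state (add <-> remove; swap is self-inverse).
    """
    cfg = proposal_config or ProposalConfig()
    pool = _candidate_pool(state.n_vertices, j, allow_self_edges)
    shat = float(prior.conf[pool, j].sum())
    action, _, _, new_parents, lqf, lqr = _propose(state.parents[j], pool, shat, cfg, rng)
    return new_parents, lqf, lqr, action


class _ChainRunner:
    """Mutable single-chain engine; caches per-vertex likelihood terms so a
    vertex update costs one small linear solve."""

    def __init__(
        self,
        data: TimeCourseSet,
        prior: PriorConfidences,
        state: GraphState,
        model_config: ModelConfig,
        proposal_config: ProposalConfig,
        rng: np.random.Generator,
    ):
        self.lik = MarginalLikelihood(data)
        self.conf = prior.conf
        self.state = state
        self.mc = model_config
        self.pc = proposal_config
        self.rng = rng
        v = state.n_vertices
        self.pools = [_candidate_pool(v, j, model_config.allow_self_edges) for j in range(v)]
        self.shats = [float(self.conf[self.pools[j], j].sum()) for j in range(v)]
        self.loglik = [self.lik.vertex(j, state.parents[j]) for j in range(v)]
        self.accept_counts = {k: 0 for k in (_ADD, _REMOVE, _SWAP, "lambda")}
        self.propose_counts = {k: 0 for k in (_ADD, _REMOVE, _SWAP, "lambda")}

    def _prior_term(self, j: int, lam: float) -> float:
        pool = self.pools[j]
        z = np.zeros(pool.shape[0])
        pa = self.state.parents[j]
        for k, i in enumerate(pool.tolist()):
            if i in pa:
                z[k] = 1.0
        return log_prior_vertex(z, self.conf[pool, j], lam)

    def update_lambda(self, j: int):
        self.propose_counts["lambda"] += 1
        lam = float(self.state.lambdas[j])
        lam_new = lam + self.pc.xi * self.rng.standard_normal()
        if not (self.mc.lambda_min <= lam_new <= self.mc.lambda_max):
            return None
        delta = self._prior_term(j, lam_new) - self._prior_term(j, lam)
        if delta >= 0 or math.log(self.rng.random()) < delta:
            self.state.lambdas[j] = lam_new
            self.accept_counts["lambda"] += 1
            return ("lam", j, lam_new)
        return None

    def update_parents(self, j: int):
        pa = self.state.parents[j]
        action, removed, added, new_pa, lqf, lqr = _propose(
            pa, self.pools[j], self.shats[j], self.pc, self.rng
        )
        self.propose_counts[action] += 1
        lam = float(self.state.lambdas[j])
        # Only the toggled entries contribute to the prior delta; the
        # Bernoulli normalizers cancel: log p1 - log p0 = (c_ij - 1) * lambda_j.
        dprior = 0.0
        if added is not None:
            dprior += (self.conf[added, j] - 1.0) * lam
        if removed is not None:
            dprior -= (self.conf[removed, j] - 1.0) * lam
        new_loglik = self.lik.vertex(j, new_pa)
        log_alpha = (new_loglik - self.loglik[j]) + dprior + lqr - lqf
        if log_alpha >= 0 or math.log(self.rng.random()) < log_alpha:
            self.state.parents[j] = new_pa
            self.loglik[j] = new_loglik
            self.accept_counts[action] += 1
            if action == _ADD:
                return (_ADD, j, added)
            if action == _REMOVE:
                return (_REMOVE, j, removed)
            return (_SWAP, j, removed, added)
        return None

    def sweep(self) -> list[tuple]:
        ops = []
        for j in range(self.state.n_vertices):
            if self.pc.update_lambdas:
                op = self.update_lambda(j)
                if op is not None:
                    ops.append(op)
            op = self.update_parents(j)
            if op is not None:
                ops.append(op)
        return ops


def mh_update_parents(
    state: GraphState,
    j: int,
    data: TimeCourseSet,
    prior: PriorConfidences,
    rng: np.random.Generator,
    model_config: ModelConfig | None = None,
    proposal_config: ProposalConfig | None = None,
) -> tuple[GraphState, bool]:
    """One Metropolis–Hastings parent-set update of vertex ``j`` (in place).

    Accepts with probability ``min(1, exp(dlik_j + dprior_j + lqr - lqf))``;
    only vertex j's terms are recomputed.  A rejected proposal leaves the
    state bit-identical.
    """
    runner = _ChainRunner(
        data, prior, state, model_config or ModelConfig(),
        proposal_config or ProposalConfig(), rng,
    )
    op = runner.update_parents(j)
    return state, op is not None


def mh_update_lambda(
    state: GraphState,
    j: int,
    prior: PriorConfidences,
    model_config: ModelConfig | None = None,
    proposal_config: ProposalConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[GraphState, bool]:
    """One Gaussian random-walk update of ``lambda_j`` (in place).

    Proposals outside ``[lambda_min, lambda_max]`` are rejected outright
    (zero prior mass); otherwise acceptance depends only on vertex j's prior
    term — the likelihood does not involve lambda.
    """
    if rng is None:
        rng = np.random.default_rng()
    mc = model_config or ModelConfig()
    pc = proposal_config or ProposalConfig()
    # Build a minimal runner without likelihood caches (lambda moves never
    # touch the likelihood).
    runner = _ChainRunner.__new__(_ChainRunner)
    runner.conf = prior.conf
    runner.state = state
    runner.mc = mc
    runner.pc = pc
    runner.rng = rng
    v = state.n_vertices
    runner.pools = [_candidate_pool(v, jj, mc.allow_self_edges) for jj in range(v)]
    runner.accept_counts = {"lambda": 0}
    runner.propose_counts = {"lambda": 0}
    op = runner.update_lambda(j)
    return state, op is not None


def _initial_state(
    prior: PriorConfidences, model_config: ModelConfig, rng: np.random.Generator
) -> GraphState:
    """Overdispersed start: lambda_j ~ Uniform(bounds), z_ij ~ Bernoulli of
    the prior edge probability at that lambda."""
    v = prior.n_variables
    lambdas = rng.uniform(model_config.lambda_min, model_config.lambda_max, size=v)
    parents: list[set[int]] = []
    for j in range(v):
        pool = _candidate_pool(v, j, model_config.allow_self_edges)
        p = edge_prior_probability(prior.conf[pool, j], lambdas[j])
        draws = rng.random(pool.shape[0]) < p
        parents.append(set(pool[draws].tolist()))
    return GraphState(parents, lambdas)


def run_chain(
    data: TimeCourseSet,
    prior: PriorConfidences,
    model_config: ModelConfig | None = None,
    proposal_config: ProposalConfig | None = None,
    termination: TerminationPolicy | None = None,
    seed: int = 0,
    initial_state: GraphState | None = None,
    log_interval: int = 10_000,
) -> ChainTrace:
    """Run one Markov chain and return its delta-encoded trace.

    Each iteration sweeps vertices in ascending order, updating ``lambda_j``
    then ``pa(j)``.  The chain stops at ``max_iterations`` or when wall time
    exceeds the budget (checked between iterations).  Same seed and inputs
    give a bit-identical trace.
    """
    mc = model_config or ModelConfig()
    pc = proposal_config or ProposalConfig()
    term = termination or TerminationPolicy()
    if data.n_variables != prior.n_variables or data.variables != prior.variables:
        raise ValueError("data and prior must share the same ordered variable set")
    rng = np.random.Generator(np.random.Philox(seed))
    state = initial_state.copy() if initial_state is not None else _initial_state(prior, mc, rng)
    init_parents = tuple(frozenset(p) for p in state.parents)
    init_lambdas = state.lambdas.copy()

    runner = _ChainRunner(data, prior, state, mc, pc, rng)
    deltas: list[list[tuple]] = []
    start = time.monotonic()
    for it in range(term.max_iterations):
        try:
            deltas.append(runner.sweep())
        except FloatingPointError as exc:  # pragma: no cover
            raise FloatingPointError(f"iteration {it}: {exc}") from exc
        if log_interval and (it + 1) % log_interval == 0:
            rates = {
                k: round(a / max(runner.propose_counts[k], 1), 3)
                for k, a in runner.accept_counts.items()
            }
            logger.info("chain seed=%d iteration=%d acceptance=%s", seed, it + 1, rates)
        if time.monotonic() - start > term.max_wall_seconds:
            break
    return ChainTrace(
        n_vertices=state.n_vertices,
        initial_parents=init_parents,
        initial_lambdas=init_lambdas,
        deltas=deltas,
        seed=seed,
        accept_counts=dict(runner.accept_counts),
        propose_counts=dict(runner.propose_counts),
        elapsed_seconds=time.monotonic() - start,
    )


def run_chains(
    data: TimeCourseSet,
    prior: PriorConfidences,
    model_config: ModelConfig | None = None,
    proposal_config: ProposalConfig | None = None,
    termination: TerminationPolicy | None = None,
    base_seed: int = 0,
) -> list[ChainTrace]:
    """Run ``n_chains`` independent chains with seeds ``base_seed + k``.

    A failing chain is reported as a warning without aborting the others; an
    error is raised only if every chain fails.
    """
    term = termination or TerminationPolicy()
    traces: list[ChainTrace] = []
    failures: list[str] = []
    for k in range(term.n_chains):
        seed = (int(base_seed) + k) % (2**31)
        try:
            traces.append(
                run_chain(data, prior, model_config, proposal_config, term, seed=seed)
            )
        except Exception as exc:  # noqa: BLE001 - per-chain isolation
            failures.append(f"chain {k} (seed {seed}): {exc}")
    if failures and traces:
        warnings.warn("some chains failed: " + "; ".join(failures), RuntimeWarning)
    if not traces:
        raise RuntimeError("all chains failed: " + "; ".join(failures))
    return traces
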