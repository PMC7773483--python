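"""The probabilistic model: marginalized Gaussian DBN likelihood and the
generalized edge prior.

The model decomposes per vertex.  For vertex ``j`` with parent set ``pa(j)``
and pooled transition count ``n`` (so ``T_eff = n + 1`` plays the role of the
single-course timepoint count ``T``), the marginal likelihood factor is

    P(X | pa(j))  ∝  T_eff^(-|pa(j)|/2) * ( y'y - (n/T_eff) * y'B beta_ols )^(-n/2)

with ``y`` the vertex-j response stacked over courses, ``B`` the lagged
parent design, and ``beta_ols`` the minimum-norm least-squares coefficient
estimate.  Regression coefficients and noise variances have been integrated
out under a Zellner-style g-prior and the improper 1/sigma^2 prior, leaving
structure as the only unknown.

The edge prior is a product of independent Bernoulli variables

    z_ij | c_ij, lambda_j  ~  Bernoulli( e^{-lambda_j} / (e^{-c_ij lambda_j} + e^{-lambda_j}) )

where ``c_ij`` is the prior edge confidence and the per-vertex inverse
temperature ``lambda_j ~ Uniform(lambda_min, lambda_max)`` controls how
strongly the prior constrains vertex j's parents.  Binary confidences recover
the classical reference-graph prior ``P(G | G', lambda) ∝ exp(-lambda |E(G) \\ E(G')|)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .data import PriorConfidences, TimeCourseSet

__all__ = [
    "ModelConfig",
    "GraphState",
    "DegenerateResponseError",
    "build_design",
    "log_marginal_likelihood_vertex",
    "log_prior_vertex",
    "log_posterior",
    "edge_prior_probability",
    "MarginalLikelihood",
]

# Relative floor for the likelihood's log argument; guards floating-point
# cancellation when an over-complete design interpolates y exactly.
_LOG_ARG_FLOOR = 1e-12


class DegenerateResponseError(ValueError):
    """Raised when a vertex's response vector is identically zero."""


@dataclass
class ModelConfig:
    """Bounds of the uniform prior on the inverse temperatures, plus the
    self-edge policy.

    ``lambda_min`` defaults to 3: much smaller values admit prior draws with
    very large numbers of edges, which is both implausible for signaling
    pathways and computationally hostile.  The model is insensitive to
    ``lambda_max`` as long as it is comfortably large (default 15).

    ``allow_self_edges=True`` keeps diagonal entries in play: a DBN edge runs
    from t-1 to t, so i -> i is plain autoregression.
    """

    lambda_min: float = 3.0
    lambda_max: float = 15.0
    allow_self_edges: bool = True

    def __post_init__(self):
        if not (0 < self.lambda_min < self.lambda_max):
            raise ValueError("require 0 < lambda_min < lambda_max")


@dataclass
class GraphState:
    """Current sampler state: per-vertex parent sets and inverse temperatures."""

    parents: list[set[int]]
    lambdas: np.ndarray = field(repr=False)

    def __post_init__(self):
        v = len(self.parents)
        self.parents = [set(int(i) for i in p) for p in self.parents]
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        if self.lambdas.shape != (v,):
            raise ValueError("lambdas must have one entry per vertex")
        for j, p in enumerate(self.parents):
            if p and (min(p) < 0 or max(p) >= v):
                raise ValueError(f"vertex {j} has parent index out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.parents)

    def adjacency(self) -> np.ndarray:
        """Binary |V| x |V| matrix Z with z_ij = 1 iff i is a parent of j."""
        v = self.n_vertices
        z = np.zeros((v, v), dtype=np.uint8)
        for j, pa in enumerate(self.parents):
            for i in pa:
                z[i, j] = 1
        return z

    def copy(self) -> "GraphState":
        return GraphState([set(p) for p in self.parents], self.lambdas.copy())


def build_design(
    data: TimeCourseSet, j: int, parents
) -> tuple[np.ndarray, np.ndarray]:
    """Response vector and lagged parent design for vertex ``j``.

    ``y`` stacks column ``j`` at timepoints ``2..T_m`` over courses (input
    order, time ascending); ``B`` stacks the parent columns at timepoints
    ``1..T_m-1``.  Parent columns appear in ascending index order.  An empty
    parent set yields a design with zero columns.
    """
    v = data.n_variables
    if not 0 <= j < v:
        raise IndexError(f"vertex index {j} out of range for {v} variables")
    pa = sorted(int(i) for i in parents)
    if pa and (pa[0] < 0 or pa[-1] >= v):
        raise IndexError(f"parent index out of range for {v} variables")
    x_minus, x_plus = data.stacked_pairs()
    y = x_plus[:, j]
    b = x_minus[:, pa] if pa else np.empty((y.shape[0], 0))
    return y, b


def _log_marginal_from_parts(yty: float, fit: float, n: int, n_parents: int) -> float:
    """Log marginal likelihood (up to the shared constant) from sufficient
    statistics: ``yty = y'y``, ``fit = y'B beta_ols``, ``n`` transitions."""
    if yty <= 0:
        raise DegenerateResponseError("response vector is identically zero (y'y = 0)")
    t_eff = n + 1
    arg = yty - (n / t_eff) * fit
    arg = max(arg, _LOG_ARG_FLOOR * yty)
    value = -0.5 * n_parents * np.log(t_eff) - 0.5 * n * np.log(arg)
    if not np.isfinite(value):
        raise FloatingPointError("non-finite log marginal likelihood")
    return float(value)


def log_marginal_likelihood_vertex(data: TimeCourseSet, j: int, parents) -> float:
    """Log of vertex ``j``'s marginal-likelihood factor, up to a constant
    shared by all parent sets of ``j``.

    Uses minimum-norm least squares (pseudo-inverse) so rank-deficient and
    over-complete designs are handled without any in-degree cap; the log
    argument stays positive because ``y'B beta_ols <= y'y`` (projection).
    """
    y, b = build_design(data, j, parents)
    n = y.shape[0]
    yty = float(y @ y)
    if b.shape[1] == 0:
        fit = 0.0
    else:
        beta = np.linalg.lstsq(b, y, rcond=None)[0]
        fit = float(y @ (b @ beta))
    return _log_marginal_from_parts(yty, fit, n, b.shape[1])


def edge_prior_probability(c, lam):
    """Bernoulli success probability of an edge under the generalized prior:
    ``e^{-lam} / (e^{-c lam} + e^{-lam})``, computed stably."""
    c = np.asarray(c, dtype=float)
    return expit(-(1.0 - c) * lam)


def log_prior_vertex(z_col, c_col, lambda_j: float) -> float:
    """Log prior mass of one vertex's parent-indicator column.

    Sum over candidate parents i of the Bernoulli log-mass with success
    probability ``edge_prior_probability(c_ij, lambda_j)``; evaluated in log
    space via ``logaddexp`` for stability at large ``lambda_j``.
    """
    z = np.asarray(z_col, dtype=float)
    c = np.asarray(c_col, dtype=float)
    if z.shape != c.shape:
        raise ValueError("indicator and confidence columns must have equal length")
    if lambda_j <= 0:
        raise ValueError("lambda_j must be positive")
    log_norm = np.logaddexp(-c * lambda_j, -lambda_j)
    log_p1 = -lambda_j - log_norm
    log_p0 = -c * lambda_j - log_norm
    return float(np.sum(z * log_p1 + (1.0 - z) * log_p0))


def log_posterior(
    data: TimeCourseSet,
    prior: PriorConfidences,
    state: GraphState,
    config: ModelConfig | None = None,
) -> float:
    """Full log posterior density (up to an additive constant).

    Decomposes per vertex: likelihood factor + prior factor for each j, plus
    the flat lambda prior (0 inside the bounds, -inf outside).  A change to
    one vertex's parents or lambda changes only that vertex's term.
    """
    config = config or ModelConfig()
    lam = state.lambdas
    if np.any(lam < config.lambda_min) or np.any(lam > config.lambda_max):
        return -np.inf
    v = data.n_variables
    if state.n_vertices != v:
        raise ValueError("state and data disagree on the number of vertices")
    z = state.adjacency()
    total = 0.0
    for j in range(v):
        total += log_marginal_likelihood_vertex(data, j, state.parents[j])
        mask = np.ones(v, dtype=bool)
        if not config.allow_self_edges:
            mask[j] = False
        total += log_prior_vertex(z[mask, j], prior.conf[mask, j], lam[j])
    return total


class MarginalLikelihood:
    """Cached per-vertex marginal-likelihood evaluator.

    Precomputes the Gram matrix ``G = X-' X-``, cross-products
    ``H[:, j] = X-' X+_j`` and ``y'y`` per vertex, so evaluating a parent set
    S costs one |S| x |S| solve: ``y'B beta_ols = H[S,j]' G[S,S]^+ H[S,j]``.
    Identical (to numerical precision) to :func:`log_marginal_likelihood_vertex`.
    """

    def __init__(self, data: TimeCourseSet):
        x_minus, x_plus = data.stacked_pairs()
        self.n = x_plus.shape[0]
        self.gram = x_minus.T @ x_minus
        self.cross = x_minus.T @ x_plus
        self.yty = np.einsum("ij,ij->j", x_plus, x_plus)
        if np.any(self.yty <= 0):
            bad = int(np.argmin(self.yty))
            raise DegenerateResponseError(
                f"variable index {bad} has identically zero response (y'y = 0)"
            )

    def vertex(self, j: int, parents) -> float:
        pa = sorted(parents)
        if not pa:
            return _log_marginal_from_parts(float(self.yty[j]), 0.0, self.n, 0)
        idx = np.asarray(pa, dtype=int)
        g = self.gram[np.ix_(idx, idx)]
        h = self.cross[idx, j]
        try:
            coef = np.linalg.solve(g, h)
        except np.linalg.LinAlgError:
            coef = np.linalg.lstsq(g, h, rcond=None)[0]
        fit = float(h @ coef)
        # solve() can silently amplify noise on ill-conditioned Gram blocks;
        # fall back to the pseudo-inverse if the fit is out of bounds.
        if not np.isfinite(fit) or fit > float(self.yty[j]) * (1 + 1e-8) or fit < 0:
            coef = np.linalg.lstsq(g, h, rcond=None)[0]
            fit = float(h @ coef)
            fit = min(max(fit, 0.0), float(self.yty[j]))
        return _log_marginal_from_parts(float(self.yty[j]), fit, self.n, len(pa))
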