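"""Convergence diagnostics and posterior summarization.

Edge posterior probabilities are the fraction of retained MCMC samples that
contain each edge, pooled over chains after discarding burnin.  Convergence
of each monitored scalar (every edge indicator and every lambda) is assessed
with the split-chain potential scale reduction factor (PSRF, a.k.a. R-hat)
and a multi-chain effective sample size (ESS); a quantity is flagged as
failed if PSRF >= 1.01 or ESS < 10.  Passing these checks does not guarantee
convergence, but failing them is a reliable red flag.

Binary indicator sequences are frequently constant, where the classical
formulas are 0/0; the conventions used here are: all chains constant and
equal -> PSRF = 1 and ESS = total retained count (e.g. a never-proposed edge
is "converged at zero"); chains constant but unequal -> PSRF = +inf and
ESS = number of chains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mcmc import ChainTrace

__all__ = ["EdgePosterior", "psrf", "effective_sample_size", "summarize"]

PSRF_THRESHOLD = 1.01
NEFF_THRESHOLD = 10.0


@dataclass
class EdgePosterior:
    """Posterior edge probabilities with per-edge convergence diagnostics."""

    variables: tuple[str, ...]
    prob: np.ndarray = field(repr=False)
    psrf: np.ndarray = field(repr=False)
    neff: np.ndarray = field(repr=False)
    converged: np.ndarray = field(repr=False)
    lambda_mean: np.ndarray = field(repr=False)
    lambda_psrf: np.ndarray = field(repr=False)
    lambda_neff: np.ndarray = field(repr=False)
    n_chains: int = 0
    n_retained: int = 0

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per ordered (parent, child) pair."""
        v = len(self.variables)
        ii, jj = np.meshgrid(np.arange(v), np.arange(v), indexing="ij")
        return pd.DataFrame(
            {
                "parent": np.asarray(self.variables)[ii.ravel()],
                "child": np.asarray(self.variables)[jj.ravel()],
                "probability": self.prob.ravel(),
                "psrf": self.psrf.ravel(),
                "neff": self.neff.ravel(),
                "converged": self.converged.ravel(),
            }
        )


def _as_stack(chains) -> np.ndarray:
    arrs = [np.asarray(c, dtype=float) for c in chains]
    if len({a.shape for a in arrs}) != 1:
        raise ValueError("chains must have equal lengths")
    return np.stack(arrs)


def _split_halves(x: np.ndarray) -> np.ndarray:
    """(m, n, ...) -> (2m, n//2, ...); drops one sample per chain if n is odd."""
    n = x.shape[1]
    half = n // 2
    return np.concatenate([x[:, :half], x[:, n - half :]], axis=0)


def _psrf_array(x: np.ndarray) -> np.ndarray:
    """Split-chain R-hat, vectorized over trailing axes.  x: (m, n, K)."""
    x = _split_halves(x)
    m, n = x.shape[0], x.shape[1]
    w = x.var(axis=1, ddof=1).mean(axis=0)
    means = x.mean(axis=1)
    b_over_n = means.var(axis=0, ddof=1)
    var_plus = (n - 1) / n * w + b_over_n
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.sqrt(var_plus / w)
    zero_w = w <= 0
    equal_means = b_over_n <= 0
    r = np.where(zero_w & equal_means, 1.0, r)
    r = np.where(zero_w & ~equal_means, np.inf, r)
    r = np.where(~zero_w & (var_plus <= w), 1.0, r)
    return r


def _autocov(x: np.ndarray) -> np.ndarray:
    """Per-chain biased autocovariance via FFT.  x: (m, n, K) -> (m, n, K)."""
    n = x.shape[1]
    xd = x - x.mean(axis=1, keepdims=True)
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xd, n=nfft, axis=1)
    acov = np.fft.irfft(f * np.conj(f), n=nfft, axis=1)[:, :n].real
    return acov / n


def _ess_array(x: np.ndarray) -> np.ndarray:
    """Multi-chain ESS with Geyer initial-monotone-positive-sequence
    truncation, vectorized over the trailing axis.  x: (m, n, K)."""
    m, n = x.shape[0], x.shape[1]
    total = float(m * n)
    w = x.var(axis=1, ddof=1)  # (m, K)
    w_mean = w.mean(axis=0)
    means = x.mean(axis=1)
    if m > 1:
        b_over_n = means.var(axis=0, ddof=1)
    else:
        b_over_n = np.zeros_like(w_mean)
    var_plus = (n - 1) / n * w_mean + b_over_n

    k = x.shape[2]
    ess = np.full(k, np.nan)
    zero_w = w_mean <= 0
    equal_means = b_over_n <= 0
    ess[zero_w & equal_means] = total
    ess[zero_w & ~equal_means] = float(m)
    active = ~zero_w
    if not np.any(active):
        return ess

    acov = _autocov(x[:, :, active]).mean(axis=0)  # (n, K_active)
    vp = var_plus[active]
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = 1.0 - (w_mean[active] - acov) / vp  # (n, K_active)

    # Geyer: sum pairs rho_{2t} + rho_{2t+1} while positive, enforcing
    # monotone non-increase; tau = -1 + 2 * sum of kept pairs.
    n_pairs = n // 2
    ka = rho.shape[1]
    pair_sum_total = np.zeros(ka)
    prev_pair = np.full(ka, np.inf)
    alive = np.ones(ka, dtype=bool)
    for t in range(n_pairs):
        pair = rho[2 * t] + (rho[2 * t + 1] if 2 * t + 1 < n else 0.0)
        pair = np.minimum(pair, prev_pair)
        alive &= pair > 0
        pair_sum_total += np.where(alive, pair, 0.0)
        prev_pair = np.where(alive, pair, prev_pair)
        if not alive.any():
            break
    tau = np.maximum(-1.0 + 2.0 * pair_sum_total, 1.0 / (m * n))
    ess_active = np.minimum(total / tau, total)
    ess[active] = ess_active
    return ess


def psrf(chains) -> float:
    """Split-chain potential scale reduction factor of one scalar quantity.

    ``chains``: sequence of >= 2 equal-length 1-D sample arrays.
    """
    x = _as_stack(chains)
    if x.shape[0] < 2:
        raise ValueError("psrf requires at least 2 chains")
    if x.shape[1] < 4:
        raise ValueError("psrf requires post-burnin chain length >= 4")
    return float(_psrf_array(x[:, :, None])[0])


def effective_sample_size(chains) -> float:
    """Multi-chain effective sample size of one scalar quantity."""
    x = _as_stack(chains)
    if x.shape[1] < 4:
        raise ValueError("effective sample size requires chain length >= 4")
    return float(_ess_array(x[:, :, None])[0])


def summarize(
    traces: list[ChainTrace],
    burnin_fraction: float = 0.5,
    variables: tuple[str, ...] | None = None,
) -> EdgePosterior:
    """Posterior summary from one or more chain traces.

    Replays each trace, drops the first ``burnin_fraction`` of each chain,
    truncates all chains to a common retained length (keeping the latest
    samples), and computes pooled edge frequencies plus per-edge and
    per-lambda PSRF / ESS.  With a single chain PSRF is NaN and nothing is
    flagged converged.
    """
    if not traces:
        raise ValueError("at least one trace is required")
    if not (0 < burnin_fraction < 1):
        raise ValueError("burnin_fraction must lie in (0, 1)")
    v = traces[0].n_vertices
    if any(t.n_vertices != v for t in traces):
        raise ValueError("traces disagree on the number of vertices")

    kept = [t.iteration_count - int(burnin_fraction * t.iteration_count) for t in traces]
    n_keep = min(kept)
    if n_keep < 1:
        raise ValueError("empty post-burnin segment")

    z_all, lam_all = [], []
    for t in traces:
        z_seq, lam_seq = t.replay_dense()
        z_all.append(z_seq[-n_keep:])
        lam_all.append(lam_seq[-n_keep:])
    z = np.stack(z_all).astype(float)  # (m, n, V, V)
    lam = np.stack(lam_all)  # (m, n, V)
    m = z.shape[0]

    prob = z.mean(axis=(0, 1))
    z_flat = z.reshape(m, n_keep, v * v)
    if m >= 2 and n_keep >= 4:
        edge_psrf = _psrf_array(z_flat).reshape(v, v)
        lam_psrf = _psrf_array(lam)
    else:
        edge_psrf = np.full((v, v), np.nan)
        lam_psrf = np.full(v, np.nan)
    if n_keep >= 4:
        edge_neff = _ess_array(z_flat).reshape(v, v)
        lam_neff = _ess_array(lam)
    else:
        edge_neff = np.full((v, v), np.nan)
        lam_neff = np.full(v, np.nan)

    with np.errstate(invalid="ignore"):
        converged = (edge_psrf < PSRF_THRESHOLD) & (edge_neff >= NEFF_THRESHOLD)
    converged = np.where(np.isnan(edge_psrf) | np.isnan(edge_neff), False, converged)

    if variables is None:
        variables = tuple(f"v{j}" for j in range(v))
    elif len(variables) != v:
        raise ValueError("variable names do not match the trace dimension")
    return EdgePosterior(
        variables=variables,
        prob=prob,
        psrf=edge_psrf,
        neff=edge_neff,
        converged=converged.astype(bool),
        lambda_mean=lam.mean(axis=(0, 1)),
        lambda_psrf=lam_psrf,
        lambda_neff=lam_neff,
        n_chains=m,
        n_retained=n_keep,
    )
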