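"""Differential-evolution Metropolis sampling (DE-MCMC), vectorized over chains.

Proposals are scaled differences of two other chains' states plus a small
uniform jitter:

    theta* = theta_i + gamma * (theta_j - theta_k) + Uniform(-jitter, jitter)

with j != k != i drawn uniformly.  The proposal is symmetric, so the
Metropolis acceptance ratio is just the posterior ratio.  All chains are
updated once per iteration from the ensemble's current generation (ter
Braak's DE-MC); no migration or crossover steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SamplerConfig", "de_propose", "run_de_mcmc"]


@dataclass(frozen=True)
class SamplerConfig:
    """DE-MCMC settings (defaults: 18 chains x 4000 iterations, 2000 burn-in)."""

    n_chains: int = 18
    n_iter: int = 4000
    burn_in: int = 2000
    gamma: float | None = None  # default 2.38/sqrt(2 d), filled at run time
    jitter: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if not self.burn_in < self.n_iter:
            raise ValueError("burn_in must be < n_iter")

    def resolved_gamma(self, d: int) -> float:
        return self.gamma if self.gamma is not None else 2.38 / np.sqrt(2.0 * d)


def _donor_pairs(n_chains: int, rng, shape=()):
    """Draw (j, k) per chain with j != k != i, vectorized.

    shape adds leading dimensions (e.g. one pair per participant block).
    """
    i = np.arange(n_chains)
    full = shape + (n_chains,)
    j = rng.integers(0, n_chains - 1, size=full)
    j = np.where(j >= i, j + 1, j)  # j != i
    k = rng.integers(0, n_chains - 2, size=full)
    k = np.where(k >= np.minimum(i, j), k + 1, k)
    k = np.where(k >= np.maximum(i, j), k + 1, k)  # k != i, k != j
    return j, k


def de_propose(current: np.ndarray, gamma: float, jitter: float, rng) -> np.ndarray:
    """One DE proposal per chain.

    current : (n_chains, d) or (n_chains, blocks, d); donors are drawn along
    the chain axis independently per block.
    """
    if current.ndim == 2:
        n, d = current.shape
        j, k = _donor_pairs(n, rng)
        diff = current[j] - current[k]
    else:
        n, nb, d = current.shape
        j, k = _donor_pairs(n, rng, shape=(nb,))
        cb = np.swapaxes(current, 0, 1)  # (blocks, chains, d)
        diff = np.take_along_axis(cb, j[..., None], axis=1) - np.take_along_axis(
            cb, k[..., None], axis=1
        )
        diff = np.swapaxes(diff, 0, 1)
    noise = rng.uniform(-jitter, jitter, size=current.shape)
    return current + gamma * diff + noise


def run_de_mcmc(log_post, init: np.ndarray, config: SamplerConfig, rng=None):
    """Sample a target with DE-MCMC.

    log_post maps an (n_chains, d) state array to (n_chains,) log-posterior
    values (vectorized over chains).  Returns (draws, accept_rate) where
    draws has shape (n_chains, n_iter - burn_in, d) and accept_rate is the
    post-burn-in acceptance fraction per chain.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    state = np.array(init, dtype=float, copy=True)
    n, d = state.shape
    gamma = config.resolved_gamma(d)
    lp = np.asarray(log_post(state), dtype=float)
    if not np.all(np.isfinite(lp)):
        raise ValueError("initial states must have finite log-posterior")

    kept = config.n_iter - config.burn_in
    draws = np.empty((n, kept, d))
    accepted = np.zeros(n)
    for it in range(config.n_iter):
        prop = de_propose(state, gamma, config.jitter, rng)
        lp_prop = np.asarray(log_post(prop), dtype=float)
        logu = np.log(rng.uniform(size=n))
        acc = logu < (lp_prop - lp)
        state[acc] = prop[acc]
        lp[acc] = lp_prop[acc]
        if it >= config.burn_in:
            draws[:, it - config.burn_in, :] = state
            accepted += acc
    return draws, accepted / kept
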