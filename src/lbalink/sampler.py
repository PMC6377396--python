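"""Non-hierarchical Bayesian estimation of LBA parameters per participant.

Each participant is fit independently (no hierarchical shrinkage: pooled
estimates are biased toward detecting effects in a second-stage correlation,
so the per-participant stage deliberately stays non-hierarchical).  Sampling
uses DE-MCMC with the defaults of 18 chains x 4000 iterations, the first
2000 discarded as burn-in.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd

from .demcmc import SamplerConfig, run_de_mcmc
from .lba import LbaParams, block_loglik, simulate_trials, urgency
from .priors import PriorSet, default_priors

__all__ = [
    "PosteriorDraws",
    "fit_participant",
    "median_urgency",
    "posterior_predictive_summary",
    "save_draws",
    "load_draws",
]

MAX_INIT_TRIES = 100


@dataclass(frozen=True)
class PosteriorDraws:
    """Post-burn-in draws for one participant.

    draws : (n_chains, n_kept, d) array on the sampled scale
    names : parameter names in column order
    accept_rate : per-chain post-burn-in acceptance fraction
    """

    draws: np.ndarray
    names: tuple
    burn_in: int
    accept_rate: np.ndarray
    s: float = 1.0

    @property
    def flat(self) -> np.ndarray:
        """(n_chains * n_kept, d) pooled draws."""
        return self.draws.reshape(-1, self.draws.shape[-1])

    def urgency_draws(self) -> np.ndarray:
        """Pooled decision-urgency draws b - A/2 = k + A/2."""
        return urgency(self.flat)

    def rhat(self) -> dict:
        """Split-chain rank-normalized R-hat per parameter."""
        ds = az.convert_to_dataset(
            {n: self.draws[..., i] for i, n in enumerate(self.names)}
        )
        rh = az.rhat(ds)
        return {n: float(rh[n].values) for n in self.names}

    def median_params(self) -> LbaParams:
        med = np.median(self.flat, axis=0)
        return LbaParams.from_array(med, s=self.s)


def median_urgency(draws: PosteriorDraws) -> float:
    """Posterior median of b - A/2 over all retained draws.

    The median is the robust point estimate used for plug-in correlation
    analyses; it ignores posterior uncertainty by construction, which is
    exactly the limitation the joint model addresses.
    """
    return float(np.median(draws.urgency_draws()))


def fit_participant(
    trials: pd.DataFrame,
    priors: PriorSet | None = None,
    config: SamplerConfig | None = None,
    s: float = 1.0,
) -> PosteriorDraws:
    """Fit one participant's LBA parameters by DE-MCMC.

    Chains initialize from independent prior draws, re-drawn (up to 100
    times per chain) until the log-posterior is finite.  Deterministic
    given ``config.seed``.
    """
    if len(trials) == 0:
        raise ValueError("participant has no trials")
    rt = np.ascontiguousarray(trials["rt"].to_numpy(dtype=float))
    correct = np.ascontiguousarray(trials["correct"].to_numpy(dtype=bool))
    if np.any(rt <= 0):
        raise ValueError("all response times must be positive")
    if priors is None:
        priors = default_priors(min_rt=float(rt.min()))
    config = config or SamplerConfig()
    if config.n_chains < priors.d + 2:
        raise ValueError("DE-MCMC needs at least d + 2 chains")
    rng = np.random.default_rng(config.seed)

    rt2d = rt[None, :]
    correct2d = correct[None, :]
    mask = np.ones_like(rt2d)

    def log_post(theta):
        ll = block_loglik(rt2d, correct2d, mask, theta[:, None, :], s=s)[:, 0]
        return priors.logpdf(theta) + ll

    init = priors.rvs(config.n_chains, rng)
    lp = log_post(init)
    for _ in range(MAX_INIT_TRIES):
        bad = ~np.isfinite(lp)
        if not bad.any():
            break
        redraw = priors.rvs(int(bad.sum()), rng)
        init[bad] = redraw
        lp[bad] = log_post(redraw)
    else:
        raise RuntimeError(
            "no finite log-posterior found from prior draws; data look pathological"
        )

    draws, accept = run_de_mcmc(log_post, init, config, rng=rng)
    return PosteriorDraws(
        draws=draws,
        names=tuple(priors.names),
        burn_in=config.burn_in,
        accept_rate=accept,
        s=s,
    )


def posterior_predictive_summary(
    draws: PosteriorDraws,
    trials: pd.DataFrame,
    quantiles=(0.1, 0.3, 0.5, 0.7, 0.9),
    n_draws: int = 100,
    trials_per_draw: int = 100,
    seed=0,
) -> pd.DataFrame:
    """Observed vs posterior-predicted defective-CDF summary.

    For a subsample of posterior draws, simulates trials and pools them,
    then tabulates RT quantiles and response proportions separately for
    correct and error responses — the numbers behind defective cumulative
    distribution goodness-of-fit plots.
    """
    rng = np.random.default_rng(seed)
    flat = draws.flat
    idx = rng.integers(0, flat.shape[0], size=min(n_draws, flat.shape[0]))
    sims = []
    for seed_i, row in zip(rng.integers(0, 2**31 - 1, size=len(idx)), flat[idx]):
        p = LbaParams.from_array(row, s=draws.s)
        sims.append(simulate_trials(p, trials_per_draw, seed=int(seed_i)))
    sim = pd.concat(sims, ignore_index=True)

    rows = []
    for label, frame in (("observed", trials), ("predicted", sim)):
        n_tot = len(frame)
        for resp, sub in (
            ("correct", frame[frame["correct"]]),
            ("error", frame[~frame["correct"]]),
        ):
            prop = len(sub) / n_tot
            qs = (
                np.quantile(sub["rt"].to_numpy(), quantiles)
                if len(sub)
                else np.full(len(quantiles), np.nan)
            )
            for q, v in zip(quantiles, qs):
                rows.append(
                    {
                        "source": label,
                        "response": resp,
                        "proportion": prop,
                        "quantile": q,
                        "rt": v,
                    }
                )
    return pd.DataFrame(rows)


def save_draws(draws: PosteriorDraws, csv_path, meta_path=None, config=None) -> None:
    """Persist draws as `chain,iteration,v_c,v_e,A,k,t0` plus a JSON sidecar."""
    n_chains, n_kept, d = draws.draws.shape
    chain = np.repeat(np.arange(n_chains), n_kept)
    iteration = np.tile(np.arange(n_kept) + draws.burn_in, n_chains)
    df = pd.DataFrame(draws.draws.reshape(-1, d), columns=list(draws.names))
    df.insert(0, "iteration", iteration)
    df.insert(0, "chain", chain)
    df.to_csv(csv_path, index=False)
    if meta_path is not None:
        meta = {
            "burn_in": int(draws.burn_in),
            "s": draws.s,
            "accept_rate": [float(a) for a in draws.accept_rate],
            "rhat": draws.rhat(),
        }
        if config is not None:
            meta["config"] = {
                "n_chains": config.n_chains,
                "n_iter": config.n_iter,
                "burn_in": config.burn_in,
                "jitter": config.jitter,
                "seed": config.seed,
            }
        with open(meta_path, "w") as fh:
            json.dump(meta, fh, indent=1)


def load_draws(csv_path, meta_path=None) -> PosteriorDraws:
    df = pd.read_csv(csv_path)
    names = tuple(c for c in df.columns if c not in ("chain", "iteration"))
    n_chains = df["chain"].nunique()
    arr = df[list(names)].to_numpy().reshape(n_chains, -1, len(names))
    burn_in = int(df["iteration"].min())
    s, accept = 1.0, np.full(n_chains, np.nan)
    if meta_path is not None:
        with open(meta_path) as fh:
            meta = json.load(fh)
        s = meta.get("s", 1.0)
        accept = np.asarray(meta.get("accept_rate", accept))
        burn_in = meta.get("burn_in", burn_in)
    return PosteriorDraws(
        draws=arr, names=names, burn_in=burn_in, accept_rate=accept, s=s
    )
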