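"""Prior distributions for per-participant LBA estimation.

Independent, weakly informative priors on (v_c, v_e, A, k, t0).  Truncation
enforces the parameter supports (k > 0, A > 0, t0 inside the plausible
non-decision range).  Log-densities are closed-form (the truncated-normal
normalization constant is precomputed) because the sampler evaluates them
once per chain per iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr
from scipy import stats

__all__ = ["NormalPrior", "TruncNormalPrior", "PriorSet", "default_priors"]

_LOG_SQRT2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass(frozen=True)
class NormalPrior:
    mu: float
    sigma: float

    def logpdf(self, x):
        z = (np.asarray(x, dtype=float) - self.mu) / self.sigma
        return -0.5 * z * z - _LOG_SQRT2PI - np.log(self.sigma)

    def rvs(self, size, rng):
        return rng.normal(self.mu, self.sigma, size=size)


@dataclass(frozen=True)
class TruncNormalPrior:
    """Normal(mu, sigma) truncated to (lo, hi); density renormalized."""

    mu: float
    sigma: float
    lo: float = -np.inf
    hi: float = np.inf
    _log_z: float = field(init=False, repr=False)

    def __post_init__(self):
        mass = float(
            ndtr((self.hi - self.mu) / self.sigma) - ndtr((self.lo - self.mu) / self.sigma)
        )
        if mass <= 0:
            raise ValueError("empty truncation interval")
        object.__setattr__(self, "_log_z", np.log(mass))

    def logpdf(self, x):
        x = np.asarray(x, dtype=float)
        z = (x - self.mu) / self.sigma
        out = -0.5 * z * z - _LOG_SQRT2PI - np.log(self.sigma) - self._log_z
        return np.where((x > self.lo) & (x < self.hi), out, -np.inf)

    def rvs(self, size, rng):
        a = (self.lo - self.mu) / self.sigma
        b = (self.hi - self.mu) / self.sigma
        return stats.truncnorm.rvs(
            a, b, loc=self.mu, scale=self.sigma, size=size, random_state=rng
        )


@dataclass(frozen=True)
class PriorSet:
    """Ordered priors matching the sampled parameter vector."""

    names: tuple
    priors: tuple

    def logpdf(self, theta):
        """Summed log-prior; theta has shape (..., d)."""
        theta = np.asarray(theta, dtype=float)
        out = self.priors[0].logpdf(theta[..., 0])
        for i, p in enumerate(self.priors[1:], start=1):
            out = out + p.logpdf(theta[..., i])
        return out

    def rvs(self, size, rng):
        cols = [p.rvs(size, rng) for p in self.priors]
        return np.stack(cols, axis=-1)

    @property
    def d(self):
        return len(self.priors)


def default_priors(min_rt: float = 1.0) -> PriorSet:
    """Default per-participant priors.

    v_c ~ N(3, 3); v_e ~ N(1, 3); A ~ N(1, 1) on (0, inf);
    k ~ N(0.5, 1) on (0, inf); t0 ~ N(0.3, 0.3) on (0.02, min_rt).

    ``min_rt`` should be the smallest observed response time so the
    non-decision time cannot exceed any datum.
    """
    t0_hi = max(float(min_rt), 0.03)
    return PriorSet(
        names=("v_c", "v_e", "A", "k", "t0"),
        priors=(
            NormalPrior(3.0, 3.0),
            NormalPrior(1.0, 3.0),
            TruncNormalPrior(1.0, 1.0, lo=0.0),
            TruncNormalPrior(0.5, 1.0, lo=0.0),
            TruncNormalPrior(0.3, 0.3, lo=0.02, hi=t0_hi),
        ),
    )
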