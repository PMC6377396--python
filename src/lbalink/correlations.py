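"""Point-estimate correlation analyses between adversity and decision urgency.

The directional hypothesis throughout is a *negative* correlation (more
adversity, more urgency, hence lower threshold), so frequentist p-values are
lower-tailed and Bayes factors compare H1: rho < 0 against H0: rho = 0.

The Pearson Bayes factor integrates the exact reduced likelihood of the
sample correlation r given rho (the sufficient-statistic likelihood used by
default Bayesian correlation tests) against a stretched-beta prior of width
1, restricted to negative values.  The Kendall Bayes factor uses the
asymptotic normal likelihood of the standardized tau with the same prior
mapped through tau = (2/pi) arcsin(rho); printed Kendall Bayes factors from
other software may therefore differ slightly even on identical data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats
from scipy.special import hyp2f1

__all__ = [
    "CorrelationResult",
    "SweepResult",
    "pearson_one_tailed",
    "kendall_one_tailed",
    "bf_pearson_negative",
    "bf_kendall_negative",
    "residualize",
    "posterior_sweep",
]


@dataclass(frozen=True)
class CorrelationResult:
    method: str  # "pearson" | "kendall"
    r: float
    p_one_tailed: float
    bf10: float
    n: int
    transform: str = "raw"
    partial: bool = False


@dataclass(frozen=True)
class SweepResult:
    """Per-draw correlations and Bayes factors across posterior samples."""

    r: np.ndarray
    bf10: np.ndarray

    @property
    def r_range(self):
        return float(self.r.min()), float(self.r.max())

    @property
    def bf_range(self):
        return float(self.bf10.min()), float(self.bf10.max())


def _check_xy(x, y, min_n=4):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and aligned")
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in input")
    for name, v in (("x", x), ("y", y)):
        if np.ptp(v) == 0:
            raise ValueError(f"variable {name} is constant")
    return x, y


def pearson_one_tailed(x, y, transform="raw", partial=False) -> CorrelationResult:
    """Pearson r with lower-tailed p and one-sided (rho < 0) Bayes factor."""
    x, y = _check_xy(x, y)
    r, p = stats.pearsonr(x, y, alternative="less")
    return CorrelationResult(
        method="pearson",
        r=float(r),
        p_one_tailed=float(p),
        bf10=bf_pearson_negative(float(r), len(x)),
        n=len(x),
        transform=transform,
        partial=partial,
    )


def kendall_one_tailed(x, y, transform="raw", partial=False) -> CorrelationResult:
    """Kendall tau-b with tie-corrected asymptotic lower-tailed p."""
    x, y = _check_xy(x, y)
    tau, p = stats.kendalltau(x, y, variant="b", alternative="less", method="asymptotic")
    return CorrelationResult(
        method="kendall",
        r=float(tau),
        p_one_tailed=float(p),
        bf10=bf_kendall_negative(float(tau), len(x)),
        n=len(x),
        transform=transform,
        partial=partial,
    )


def _log_reduced_likelihood_ratio(rho, r, n):
    """log [ p(r | rho, n) / p(r | 0, n) ] for the sample correlation r.

    Exact reduced likelihood: p(r|rho) proportional to
    (1-rho^2)^((n-1)/2) (1-rho r)^((3-2n)/2) 2F1(1/2, 1/2; n-1/2; (rho r+1)/2);
    r-only factors cancel in the ratio.
    """
    rho = np.asarray(rho, dtype=float)
    c = n - 0.5
    log_num = (
        0.5 * (n - 1) * np.log1p(-rho * rho)
        + (1.5 - n) * np.log1p(-rho * r)
        + np.log(hyp2f1(0.5, 0.5, c, (rho * r + 1.0) / 2.0))
    )
    log_den = np.log(hyp2f1(0.5, 0.5, c, 0.5))
    return log_num - log_den


def bf_pearson_negative(r: float, n: int, rtol: float = 1e-8) -> float:
    """BF10 for H1: rho < 0 (uniform prior on (-1, 0)) vs H0: rho = 0.

    The one-sided restriction of the width-1 stretched-beta prior is
    uniform on (-1, 0); the Bayes factor is the prior-averaged reduced
    likelihood ratio, computed by adaptive quadrature.
    """
    if np.abs(r) > 1:
        raise ValueError("need |r| <= 1")
    if n < 4:
        raise ValueError("need n >= 4")
    if r == -1.0:  # degenerate: the reduced likelihood is unbounded
        return np.inf
    if r == 1.0:
        return 0.0

    def integrand(rho):
        return np.exp(_log_reduced_likelihood_ratio(rho, r, n))

    val, err = integrate.quad(integrand, -1.0, 0.0, epsrel=rtol, limit=200)
    if not np.isfinite(val) or val <= 0 or (err > 1e-4 * max(val, 1.0)):
        raise RuntimeError(f"Pearson BF quadrature failed: value={val}, err={err}")
    return float(val)


def kendall_tau_sd(n: int) -> float:
    """Asymptotic null SD of tau-hat: sqrt(2(2n+5) / (9 n (n-1)))."""
    return float(np.sqrt(2.0 * (2 * n + 5) / (9.0 * n * (n - 1))))


def bf_kendall_negative(tau: float, n: int, rtol: float = 1e-8) -> float:
    """BF10 for H1: tau < 0 vs H0: tau = 0, asymptotic-likelihood version.

    tau-hat | tau ~ Normal(tau, sd(n)^2); the uniform (-1, 0) prior on rho
    maps through rho = sin(pi tau / 2) to density (pi/2) cos(pi tau / 2) on
    tau in (-1, 0).
    """
    if not np.abs(tau) < 1:
        raise ValueError("need |tau| < 1")
    sd = kendall_tau_sd(n)

    def integrand(t):
        lik = np.exp(-0.5 * ((tau - t) / sd) ** 2)
        return lik * (np.pi / 2.0) * np.cos(np.pi * t / 2.0)

    num, err = integrate.quad(integrand, -1.0, 0.0, epsrel=rtol, limit=200)
    den = 1.0  # likelihood at tau = 0, same unnormalized form
    val = num / np.exp(-0.5 * (tau / sd) ** 2)
    if not np.isfinite(val) or val <= 0:
        raise RuntimeError(f"Kendall BF quadrature failed: value={val}, err={err}")
    return float(val)


def residualize(y, covariate):
    """OLS residuals of y on a single covariate (with intercept).

    Correlating residualized x with residualized y gives the textbook
    partial correlation, removing variance linearly attributable to the
    covariate.
    """
    y = np.asarray(y, dtype=float)
    m = np.asarray(covariate, dtype=float)
    if len(y) != len(m) or y.ndim != 1:
        raise ValueError("y and covariate must be 1-D and aligned")
    if len(y) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(m) == 0:
        raise ValueError("covariate is constant")
    X = np.column_stack([np.ones_like(m), m])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def posterior_sweep(
    participant_draws,
    ela_log,
    n_draws: int = 500,
    seed: int = 0,
) -> SweepResult:
    """Correlation/Bayes-factor sweep across posterior urgency samples.

    Instead of the posterior median, each of ``n_draws`` iterations samples
    one urgency draw per participant (independently, uniformly over that
    participant's retained draws), log-transforms it, and recomputes the
    Pearson correlation and one-sided Bayes factor against ``ela_log``.
    The spread of the resulting histograms shows how strongly plug-in
    inference depends on the chosen point estimate.
    """
    ela_log = np.asarray(ela_log, dtype=float)
    urg = [np.asarray(d.urgency_draws() if hasattr(d, "urgency_draws") else d) for d in participant_draws]
    if len(urg) != len(ela_log):
        raise ValueError("one ELA value per participant required")
    rng = np.random.default_rng(seed)
    rs = np.empty(n_draws)
    bfs = np.empty(n_draws)
    for i in range(n_draws):
        sample = np.array([u[rng.integers(0, len(u))] for u in urg])
        r = float(np.corrcoef(np.log(sample), ela_log)[0, 1])
        rs[i] = r
        bfs[i] = bf_pearson_negative(r, len(ela_log))
    return SweepResult(r=rs, bf10=bfs)
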