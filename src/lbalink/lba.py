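"""Linear ballistic accumulator: analytic densities, trial likelihood, simulator.

The LBA models a two-alternative forced choice as a race between two
accumulators that gather evidence linearly and deterministically within a
trial.  Randomness enters only between trials: each accumulator starts at a
point drawn uniformly on [0, A] and accrues evidence at a rate drawn from
Normal(v_i, s).  The first accumulator to reach the threshold b determines
the response, and the response time is the crossing time plus a non-decision
offset t0.  Because within-trial accumulation is noiseless the first-passage
density has a closed form, which is what makes per-trial likelihood
evaluation cheap enough for MCMC.

The quantity of scientific interest here is the *decision urgency*
b - A/2 = k + A/2: the average evidence required to trigger a response,
averaging over the uniform start point.  Lower values mean faster, less
cautious responding.

Parameterization: we sample k = b - A > 0 instead of b so that b > A is
enforced by the support, and s is fixed (default 1) as the scaling
constraint that identifies the remaining parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy.special import ndtr

__all__ = [
    "LbaParams",
    "accumulator_pdf",
    "accumulator_cdf",
    "trial_loglik",
    "table_loglik",
    "simulate_trials",
    "urgency",
    "read_trial_table",
    "write_trial_table",
    "TRIAL_COLUMNS",
]

TRIAL_COLUMNS = ["participant", "trial", "stimulus", "response", "rt", "correct"]

_SQRT2PI = np.sqrt(2.0 * np.pi)
_TINY = 1e-300
_A_EPS = 1e-10  # below this, use the A -> 0 closed form


def _phi(x):
    return np.exp(-0.5 * np.square(x)) / _SQRT2PI


@dataclass(frozen=True)
class LbaParams:
    """One participant's LBA parameters.

    v_c : mean drift of the accumulator matching the stimulus (evidence/s)
    v_e : mean drift of the mismatching accumulator (evidence/s)
    A   : upper bound of the uniform start-point distribution (evidence, >= 0)
    k   : threshold offset b - A (evidence, > 0)
    t0  : non-decision time (s, > 0)
    s   : between-trial drift SD, fixed scaling constant (evidence/s, > 0)
    """

    v_c: float
    v_e: float
    A: float
    k: float
    t0: float
    s: float = 1.0

    def __post_init__(self):
        if not (self.k > 0):
            raise ValueError(f"k must be > 0, got {self.k}")
        if not (self.A >= 0):
            raise ValueError(f"A must be >= 0, got {self.A}")
        if not (self.t0 > 0):
            raise ValueError(f"t0 must be > 0, got {self.t0}")
        if not (self.s > 0):
            raise ValueError(f"s must be > 0, got {self.s}")

    @property
    def b(self) -> float:
        """Decision threshold b = A + k."""
        return self.A + self.k

    def to_array(self) -> np.ndarray:
        return np.array([self.v_c, self.v_e, self.A, self.k, self.t0])

    @classmethod
    def from_array(cls, x, s: float = 1.0) -> "LbaParams":
        v_c, v_e, A, k, t0 = (float(u) for u in x)
        return cls(v_c=v_c, v_e=v_e, A=A, k=k, t0=t0, s=s)


PARAM_NAMES = [f.name for f in fields(LbaParams)][:5]  # v_c, v_e, A, k, t0


def urgency(params) -> float:
    """Mean evidence required to respond, b - A/2 = k + A/2."""
    if isinstance(params, LbaParams):
        return params.k + params.A / 2.0
    arr = np.asarray(params, dtype=float)
    # array convention: columns ordered as PARAM_NAMES
    return arr[..., 3] + arr[..., 2] / 2.0


def accumulator_pdf(t, b, A, v, s):
    """First-passage density of a single LBA accumulator at decision time t.

    Standard closed form: with z1 = (b - A - v t)/(s t), z2 = (b - v t)/(s t),

        f(t) = (1/A) [ -v Phi(z1) + s phi(z1) + v Phi(z2) - s phi(z2) ]

    For A -> 0 the start point is fixed at 0 and the crossing time is b/V
    for V ~ Normal(v, s); the change of variables gives
    f(t) = b / (s t^2) * phi((b/t - v)/s).

    All arguments broadcast. Raises for t <= 0 or b <= A (scalar checks are
    vectorized: any offending element raises).
    """
    t = np.asarray(t, dtype=float)
    b, A, v, s = (np.asarray(x, dtype=float) for x in (b, A, v, s))
    if np.any(t <= 0):
        raise ValueError("decision time t must be > 0")
    if np.any(b <= A) or np.any(A < 0) or np.any(s <= 0):
        raise ValueError("require b > A >= 0 and s > 0")

    st = s * t
    z2 = (b - v * t) / st
    small_A = A < _A_EPS
    A_safe = np.where(small_A, 1.0, A)
    z1 = (b - A_safe - v * t) / st
    f_gen = (-v * ndtr(z1) + s * _phi(z1) + v * ndtr(z2) - s * _phi(z2)) / A_safe
    f_zero = b / (s * t * t) * _phi(z2)
    out = np.where(small_A, f_zero, f_gen)
    return np.maximum(out, 0.0)


def accumulator_cdf(t, b, A, v, s):
    """First-passage CDF companion to :func:`accumulator_pdf`.

        F(t) = 1 + ((b-A-vt)/A) Phi(z1) - ((b-vt)/A) Phi(z2)
                 + (st/A) [phi(z1) - phi(z2)]

    with the A -> 0 limit F(t) = Phi((v t - b)/(s t)).
    """
    t = np.asarray(t, dtype=float)
    b, A, v, s = (np.asarray(x, dtype=float) for x in (b, A, v, s))
    if np.any(t <= 0):
        raise ValueError("decision time t must be > 0")
    if np.any(b <= A) or np.any(A < 0) or np.any(s <= 0):
        raise ValueError("require b > A >= 0 and s > 0")

    st = s * t
    z2 = (b - v * t) / st
    small_A = A < _A_EPS
    A_safe = np.where(small_A, 1.0, A)
    z1 = (b - A_safe - v * t) / st
    F_gen = (
        1.0
        + (b - A_safe - v * t) / A_safe * ndtr(z1)
        - (b - v * t) / A_safe * ndtr(z2)
        + st / A_safe * (_phi(z1) - _phi(z2))
    )
    F_zero = ndtr(-z2)
    out = np.where(small_A, F_zero, F_gen)
    return np.clip(out, 0.0, 1.0)


def _defective_logpdf(dt, v_win, v_lose, A, k, s):
    """log of f_winner(dt) * (1 - F_loser(dt)) on the decision-time scale.

    Fused winner-pdf / loser-survivor evaluation (the samplers' hot path;
    shares intermediates instead of calling accumulator_pdf/cdf, which
    would validate and recompute).  Vectorized over everything; dt <= 0
    yields -inf.  Densities are clipped at 1e-300 before the log so
    off-range data give a large negative number, not -inf/NaN.
    """
    dt = np.asarray(dt, dtype=float)
    valid = dt > 0
    dt_safe = np.where(valid, dt, 1.0)
    b = A + k
    st = s * dt_safe
    small_A = A < _A_EPS
    A_safe = np.where(small_A, 1.0, A)

    vw_dt = v_win * dt_safe
    z1w = (b - A_safe - vw_dt) / st
    z2w = (b - vw_dt) / st
    phi_z2w = _phi(z2w)
    f_gen = (-v_win * ndtr(z1w) + s * _phi(z1w) + v_win * ndtr(z2w) - s * phi_z2w) / A_safe
    f_zero = b / (st * dt_safe) * phi_z2w
    f_win = np.maximum(np.where(small_A, f_zero, f_gen), 0.0)

    vl_dt = v_lose * dt_safe
    z1l = (b - A_safe - vl_dt) / st
    z2l = (b - vl_dt) / st
    F_gen = (
        1.0
        + (b - A_safe - vl_dt) / A_safe * ndtr(z1l)
        - (b - vl_dt) / A_safe * ndtr(z2l)
        + st / A_safe * (_phi(z1l) - _phi(z2l))
    )
    F_lose = np.clip(np.where(small_A, ndtr(-z2l), F_gen), 0.0, 1.0)

    ll = np.log(np.maximum(f_win, _TINY)) + np.log(np.maximum(1.0 - F_lose, _TINY))
    return np.where(valid, ll, -np.inf)


def trial_loglik(rt, correct, params: LbaParams):
    """Defective log-density of one (or an array of) trial outcome(s).

    The winning accumulator carries drift v_c for a correct response and
    v_e for an error; the other accumulator must not yet have finished.
    No renormalization is applied for the event that neither sampled drift
    is positive (standard defective-likelihood practice).  rt <= t0 gives
    -inf rather than raising, so samplers can reject such proposals.
    """
    rt = np.asarray(rt, dtype=float)
    correct = np.asarray(correct, dtype=bool)
    dt = rt - params.t0
    v_win = np.where(correct, params.v_c, params.v_e)
    v_lose = np.where(correct, params.v_e, params.v_c)
    out = _defective_logpdf(dt, v_win, v_lose, params.A, params.k, params.s)
    return out if out.ndim else float(out)


def table_loglik(trials: pd.DataFrame, params: LbaParams) -> float:
    """Participant log-likelihood: sum of trial_loglik over a trial table."""
    return float(
        np.sum(trial_loglik(trials["rt"].to_numpy(), trials["correct"].to_numpy(), params))
    )


def loglik_matrix(rt, correct, theta, s: float = 1.0):
    """Log-likelihood for a batch of parameter vectors on shared data.

    theta : array (..., 5) with columns (v_c, v_e, A, k, t0); rt/correct are
    1-D of length n_trials.  Returns array of shape theta.shape[:-1].  This
    is the hot path of the samplers: one call evaluates every chain (and,
    in the joint model, every chain x participant block) at once.
    """
    theta = np.asarray(theta, dtype=float)
    rt = np.asarray(rt, dtype=float)
    correct = np.asarray(correct, dtype=bool)
    lead = theta.shape[:-1]
    v_c, v_e, A, k, t0 = (theta[..., i][..., None] for i in range(5))
    bad = (k <= 0) | (A < 0) | (t0 <= 0)
    dt = rt - t0
    v_win = np.where(correct, v_c, v_e)
    v_lose = np.where(correct, v_e, v_c)
    A_safe = np.where(bad, 0.0, A)
    k_safe = np.where(bad, 1.0, k)
    ll = _defective_logpdf(dt, v_win, v_lose, A_safe, k_safe, s)
    total = np.sum(ll, axis=-1)
    return np.where(bad[..., 0], -np.inf, total).reshape(lead)


try:
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    _HAVE_NUMBA = False

if _HAVE_NUMBA:
    import math

    @_njit(cache=True, fastmath=True)
    def _block_loglik_numba(rt, correct, mask, theta, s):  # pragma: no cover
        C, N, _ = theta.shape
        T = rt.shape[1]
        out = np.empty((C, N))
        SQ2 = math.sqrt(2.0)
        LSQ2PI = 0.5 * math.log(2.0 * math.pi)
        for c in range(C):
            for n in range(N):
                v_c = theta[c, n, 0]
                v_e = theta[c, n, 1]
                A = theta[c, n, 2]
                k = theta[c, n, 3]
                t0 = theta[c, n, 4]
                if k <= 0.0 or A < 1e-8 or t0 <= 0.0:
                    out[c, n] = -np.inf
                    continue
                b = A + k
                tot = 0.0
                for t in range(T):
                    if mask[n, t] == 0.0:
                        continue
                    dt = rt[n, t] - t0
                    if dt <= 0.0:
                        tot = -np.inf
                        break
                    st = s * dt
                    if correct[n, t]:
                        vw = v_c
                        vl = v_e
                    else:
                        vw = v_e
                        vl = v_c
                    z1w = (k - vw * dt) / st
                    z2w = (b - vw * dt) / st
                    p1 = 0.5 * (1.0 + math.erf(z1w / SQ2))
                    p2 = 0.5 * (1.0 + math.erf(z2w / SQ2))
                    f1 = math.exp(-0.5 * z1w * z1w - LSQ2PI)
                    f2 = math.exp(-0.5 * z2w * z2w - LSQ2PI)
                    fw = (-vw * p1 + s * f1 + vw * p2 - s * f2) / A
                    z1l = (k - vl * dt) / st
                    z2l = (b - vl * dt) / st
                    q1 = 0.5 * (1.0 + math.erf(z1l / SQ2))
                    q2 = 0.5 * (1.0 + math.erf(z2l / SQ2))
                    g1 = math.exp(-0.5 * z1l * z1l - LSQ2PI)
                    g2 = math.exp(-0.5 * z2l * z2l - LSQ2PI)
                    F = 1.0 + (k - vl * dt) / A * q1 - (b - vl * dt) / A * q2 + st / A * (g1 - g2)
                    if F < 0.0:
                        F = 0.0
                    elif F > 1.0:
                        F = 1.0
                    sv = 1.0 - F
                    if fw < 1e-300:
                        fw = 1e-300
                    if sv < 1e-300:
                        sv = 1e-300
                    tot += math.log(fw) + math.log(sv)
                out[c, n] = tot
        return out


def block_loglik(rt2d, correct2d, mask, theta, s: float = 1.0):
    """Summed defective log-likelihood per (chain, participant) block.

    rt2d, correct2d, mask : (N, T) padded trial arrays; theta : (C, N, 5)
    with columns (v_c, v_e, A, k, t0).  This is the samplers' hot path;
    a compiled scalar kernel avoids the ~40 large temporaries the
    vectorized route allocates per call.  Falls back to the numpy path
    (bit-compatible up to ~1e-6 from fused arithmetic) without numba.
    """
    theta = np.ascontiguousarray(theta, dtype=float)
    if _HAVE_NUMBA:
        return _block_loglik_numba(
            np.ascontiguousarray(rt2d, dtype=float),
            np.ascontiguousarray(correct2d, dtype=bool),
            np.ascontiguousarray(mask, dtype=float),
            theta,
            float(s),
        )
    v_c, v_e, A, k, t0 = (theta[..., i][..., None] for i in range(5))
    bad = (k <= 0) | (A < 1e-8) | (t0 <= 0)
    dt = rt2d - t0
    v_win = np.where(correct2d, v_c, v_e)
    v_lose = np.where(correct2d, v_e, v_c)
    ll = _defective_logpdf(dt, v_win, v_lose, np.where(bad, 1.0, A), np.where(bad, 1.0, k), s)
    out = np.sum(np.where(mask > 0, ll, 0.0), axis=-1)
    return np.where(bad[..., 0], -np.inf, out)


def simulate_trials(
    params: LbaParams,
    n_trials: int,
    seed=None,
    participant="sim",
    max_resample: int = 1000,
) -> pd.DataFrame:
    """Simulate an LBA trial table.

    Per trial each accumulator draws start ~ Uniform[0, A] and drift ~
    Normal(v_i, s); trials where both drifts are nonpositive are resampled
    (the analytic defective densities are correspondingly renormalized by
    1/(1 - P(both <= 0)) when compared against simulation).  Stimulus sides
    are balanced and shuffled; the matching accumulator always carries v_c.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    b = params.b

    drifts = rng.normal([params.v_c, params.v_e], params.s, size=(n_trials, 2))
    for _ in range(max_resample):
        stuck = np.all(drifts <= 0, axis=1)
        if not stuck.any():
            break
        drifts[stuck] = rng.normal(
            [params.v_c, params.v_e], params.s, size=(int(stuck.sum()), 2)
        )
    else:  # pragma: no cover - requires pathological drift parameters
        raise RuntimeError("could not draw a positive drift pair")

    starts = rng.uniform(0.0, params.A, size=(n_trials, 2)) if params.A > 0 else np.zeros((n_trials, 2))
    with np.errstate(divide="ignore"):
        times = np.where(drifts > 0, (b - starts) / drifts, np.inf)
    winner = np.argmin(times, axis=1)  # 0 = matching accumulator
    rt = params.t0 + times[np.arange(n_trials), winner]

    stimulus = np.array(["left", "right"])[
        rng.permutation(np.arange(n_trials) % 2)
    ]
    correct = winner == 0
    other = np.where(stimulus == "left", "right", "left")
    response = np.where(correct, stimulus, other)

    return pd.DataFrame(
        {
            "participant": participant,
            "trial": np.arange(n_trials),
            "stimulus": stimulus,
            "response": response,
            "rt": rt,
            "correct": correct,
        }
    )


def read_trial_table(path, rt_in_ms: bool = False) -> pd.DataFrame:
    """Read a comma-separated trial table (header mandatory, rt in seconds).

    Set ``rt_in_ms=True`` to convert a millisecond rt column to seconds.
    ``correct`` is recomputed from stimulus/response and must agree with a
    provided column.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns and c != "correct"]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    if rt_in_ms:
        df["rt"] = df["rt"] / 1000.0
    if np.any(df["rt"].to_numpy() <= 0):
        raise ValueError("trial table contains nonpositive rt values")
    derived = df["stimulus"].to_numpy() == df["response"].to_numpy()
    if "correct" in df.columns:
        given = df["correct"].astype(bool).to_numpy()
        if not np.array_equal(given, derived):
            raise ValueError("correct column disagrees with stimulus/response")
    df["correct"] = derived
    return df[TRIAL_COLUMNS]


def write_trial_table(df: pd.DataFrame, path) -> None:
    df[TRIAL_COLUMNS].to_csv(path, index=False)
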