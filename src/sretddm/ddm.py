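"""Two-boundary Wiener diffusion: first-passage density, choice
probabilities and path simulation.

The decision process accumulates noisy evidence from a relative start point
``z`` (0-1 scale) between absorbing boundaries 0 and ``a`` with mean drift
``v`` and unit diffusion coefficient; the observed response time adds a
non-decision component ``t``.  The upper boundary is the "reject" response
(coded 1), the lower boundary the "endorse" response (coded 0).

The first-passage density is evaluated with the usual pair of series
expansions of the standardized density — a sum over mirrored Gaussian terms
that converges quickly at small normalized times and a trigonometric series
that converges quickly at large ones — choosing per evaluation whichever
needs fewer terms for the requested accuracy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

__all__ = [
    "DDMParameters",
    "wfpt_log_density",
    "choice_probability",
    "simulate",
    "simulate_path",
    "rt_quantiles",
]


@dataclass(frozen=True)
class DDMParameters:
    """Diffusion parameters (v, a, z, t) for one decision process."""

    v: float
    a: float
    z: float
    t: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.v):
            raise ValueError("v must be finite")
        if not (self.a > 0 and np.isfinite(self.a)):
            raise ValueError("a must be positive")
        if not 0.0 < self.z < 1.0:
            raise ValueError("z must lie in (0, 1)")
        if not (self.t >= 0 and np.isfinite(self.t)):
            raise ValueError("t must be >= 0")


_EPS = 1e-7  # series truncation tolerance for the standardized density


@njit(cache=False)
def _ftt_standardized(tt: float, w: float) -> float:
    """Standardized lower-boundary density f(tt|0,1,w) at normalized time tt.

    Chooses the small-time or large-time expansion by comparing the number
    of terms each needs to reach tolerance.
    """
    # number of terms for the small-time (Gaussian-mirror) series
    if 2.0 * math.sqrt(2.0 * math.pi * tt) * _EPS < 1.0:
        ks = 2.0 + math.sqrt(
            -2.0 * tt * math.log(2.0 * _EPS * math.sqrt(2.0 * math.pi * tt))
        )
        ks = max(ks, math.sqrt(tt) + 1.0)
    else:
        ks = 2.0
    # number of terms for the large-time (trigonometric) series
    if math.pi * tt * _EPS < 1.0:
        kl = math.sqrt(-2.0 * math.log(math.pi * tt * _EPS) / (math.pi**2 * tt))
        kl = max(kl, 1.0 / (math.pi * math.sqrt(tt)))
    else:
        kl = 1.0 / (math.pi * math.sqrt(tt))

    p = 0.0
    if ks < kl:
        K = int(math.ceil(ks))
        lo = -((K - 1) // 2)
        hi = (K - 1) // 2 + (K - 1) % 2
        for k in range(lo, hi + 1):
            wk = w + 2.0 * k
            p += wk * math.exp(-wk * wk / (2.0 * tt))
        p /= math.sqrt(2.0 * math.pi * tt**3)
    else:
        K = int(math.ceil(kl))
        for k in range(1, K + 1):
            p += k * math.exp(-(k**2) * math.pi**2 * tt / 2.0) * math.sin(
                k * math.pi * w
            )
        p *= math.pi
    return p


@njit(cache=False)
def _wfpt_logpdf(rt: float, upper: bool, v: float, a: float, z: float, t: float) -> float:
    """Log first-passage density at observed time ``rt`` for one boundary.

    Returns -inf for decision times <= 0 (rt at or below the non-decision
    time) and for numerically non-positive series values.
    """
    u = rt - t
    if u <= 0.0:
        return -np.inf
    if upper:
        # reflection: upper-boundary density with (v, z) equals the
        # lower-boundary density with (-v, 1-z)
        vv = -v
        w = 1.0 - z
    else:
        vv = v
        w = z
    tt = u / (a * a)
    f = _ftt_standardized(tt, w)
    if f <= 0.0:
        return -np.inf
    return math.log(f) - math.log(a * a) - vv * a * w - vv * vv * u / 2.0


def wfpt_log_density(rt, boundary, params: DDMParameters):
    """Log density of the Wiener first-passage time at one boundary.

    Parameters
    ----------
    rt : float or array-like
        Observed response time(s) in seconds (includes non-decision time).
    boundary : {"upper", "lower"}
        Which boundary absorbed the process ("upper" = reject).
    params : DDMParameters

    Returns
    -------
    float or ndarray of log densities; ``-inf`` where ``rt <= params.t``.
    """
    if boundary not in ("upper", "lower"):
        raise ValueError("boundary must be 'upper' or 'lower'")
    upper = boundary == "upper"
    rt_arr = np.atleast_1d(np.asarray(rt, dtype=float))
    if np.any(rt_arr <= 0):
        raise ValueError("rt must be > 0")
    out = np.empty(rt_arr.shape)
    for i in range(rt_arr.size):
        out.flat[i] = _wfpt_logpdf(
            rt_arr.flat[i], upper, params.v, params.a, params.z, params.t
        )
    return out[0] if np.isscalar(rt) or np.ndim(rt) == 0 else out


def choice_probability(params: DDMParameters) -> float:
    """Probability of absorption at the upper ("reject") boundary.

    For drift v, boundary separation a and relative start z the closed form
    is ``(1 - exp(-2 v a z)) / (1 - exp(-2 v a))``; at v = 0 it reduces to z.
    """
    v, a, z = params.v, params.a, params.z
    if abs(v) < 1e-12:
        return z
    x = -2.0 * v * a
    # guard the exp ratio for strong drifts
    if x < -700:
        return 1.0 if v > 0 else 0.0
    num = -math.expm1(x * z)
    den = -math.expm1(x)
    return num / den


@njit(cache=False)
def _simulate_paths(
    n: int, v: float, a: float, z: float, t: float, dt: float, seed: int,
    max_steps: int,
):
    np.random.seed(seed)
    rts = np.empty(n)
    upper = np.empty(n, dtype=np.bool_)
    sqdt = math.sqrt(dt)
    for i in range(n):
        x = z * a
        step = 0
        while 0.0 < x < a and step < max_steps:
            x += v * dt + sqdt * np.random.normal()
            step += 1
        upper[i] = x >= a
        rts[i] = t + step * dt
    return rts, upper


def simulate(
    params: DDMParameters,
    n: int,
    dt: float = 1e-3,
    seed: int | None = None,
    max_time: float = 30.0,
) -> pd.DataFrame:
    """Simulate first-passage samples by Euler-Maruyama integration.

    Returns a DataFrame with columns ``boundary`` ("upper"/"lower") and
    ``rt`` (seconds, includes non-decision time).  The integration step
    ``dt`` defaults to 1 ms; times are slightly discretized to multiples of
    ``dt`` and carry the usual small positive first-passage bias of
    discrete-time crossing checks.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 < dt <= 0.01:
        raise ValueError("dt must lie in (0, 0.01]")
    if seed is None:
        seed = np.random.SeedSequence().entropy % (2**31)
    max_steps = int(max_time / dt)
    rts, upper = _simulate_paths(
        int(n), params.v, params.a, params.z, params.t, dt, int(seed), max_steps
    )
    return pd.DataFrame(
        {"boundary": np.where(upper, "upper", "lower"), "rt": rts}
    )


def simulate_path(
    params: DDMParameters, dt: float = 1e-3, seed: int = 0, max_time: float = 30.0
) -> pd.DataFrame:
    """Simulate a single evidence path for plotting.

    Returns a DataFrame of (time, evidence) including the final crossing
    point; time starts after the non-decision period.
    """
    rng = np.random.default_rng(seed)
    x = params.z * params.a
    xs = [x]
    sqdt = math.sqrt(dt)
    max_steps = int(max_time / dt)
    for _ in range(max_steps):
        x = x + params.v * dt + sqdt * rng.standard_normal()
        xs.append(x)
        if x <= 0 or x >= params.a:
            break
    times = params.t + dt * np.arange(len(xs))
    return pd.DataFrame({"time": times, "evidence": xs})


def rt_quantiles(
    samples: pd.DataFrame,
    probs=(0.10, 0.30, 0.50, 0.70, 0.90),
    by_boundary: bool = False,
) -> pd.DataFrame:
    """Empirical RT quantiles of first-passage samples.

    ``samples`` needs an ``rt`` column and, when ``by_boundary`` is set, a
    ``boundary`` column.  Quantiles default to the five percentiles used in
    posterior-predictive displays (10/30/50/70/90).
    """
    if len(samples) == 0:
        raise ValueError("samples is empty")
    probs = list(probs)
    if by_boundary:
        rows = []
        for boundary, grp in samples.groupby("boundary", observed=True):
            q = np.quantile(grp["rt"].to_numpy(), probs)
            for p, val in zip(probs, q):
                rows.append({"boundary": boundary, "prob": p, "rt": val})
        return pd.DataFrame(rows)
    q = np.quantile(samples["rt"].to_numpy(), probs)
    return pd.DataFrame({"prob": probs, "rt": q})
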