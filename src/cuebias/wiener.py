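"""Wiener diffusion first-passage-time kernel.

Two-boundary Wiener diffusion with drift ``v`` (δ), boundary separation
``a`` (α), relative starting point ``w`` (β; upper boundary = correct
response under accuracy coding) and non-decision time ``tau`` (τ).  The
diffusion coefficient is fixed at 1, the Stan / Wabersich–Vandekerckhove
convention; parameter scales are 10× those of the Ratcliff s = 0.1
convention.

The density is evaluated through the small-time and large-time series
expansions with the Navarro–Fuss truncation rule, switching to whichever
series needs fewer terms at the requested tolerance.  All hot paths are
numba-compiled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "WienerParams",
    "fpt_density",
    "fpt_logdensity",
    "log_likelihood",
    "choice_probability",
    "sample_trials",
    "sample_trials_euler",
]

_SERIES_EPS = 1e-12  # raw truncation target for the dimensionless density


@dataclass(frozen=True)
class WienerParams:
    """Per-condition diffusion parameters (diffusion coefficient = 1)."""

    drift: float
    boundary: float
    ndt: float
    rel_start: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite([self.drift, self.boundary, self.ndt, self.rel_start])):
            raise ValueError("non-finite Wiener parameter")
        if self.boundary <= 0:
            raise ValueError(f"boundary separation must be > 0, got {self.boundary}")
        if not 0 < self.rel_start < 1:
            raise ValueError(f"relative start must be in (0, 1), got {self.rel_start}")
        if self.ndt < 0:
            raise ValueError(f"non-decision time must be >= 0, got {self.ndt}")


@njit(cache=True)
def _fw(u: float, w: float, eps: float) -> float:
    """Dimensionless lower-boundary FPT density f(u | v=0, a=1, w).

    Chooses the small-time or large-time expansion by comparing the
    number of terms each needs for truncation error below ``eps``.
    """
    if u <= 0.0:
        return 0.0
    # terms needed by the large-time series
    if np.pi * u * eps < 1.0:
        kl = np.sqrt(-2.0 * np.log(np.pi * u * eps) / (np.pi * np.pi * u))
        kl = max(kl, 1.0 / (np.pi * np.sqrt(u)))
    else:
        kl = 1.0 / (np.pi * np.sqrt(u))
    # terms needed by the small-time series
    if 2.0 * np.sqrt(2.0 * np.pi * u) * eps < 1.0:
        ks = 2.0 + np.sqrt(-2.0 * u * np.log(2.0 * np.sqrt(2.0 * np.pi * u) * eps))
        ks = max(ks, np.sqrt(u) + 1.0)
    else:
        ks = 2.0
    if ks < kl:
        K = int(np.ceil(ks))
        s = 0.0
        for k in range(-K, K + 1):
            x = w + 2.0 * k
            s += x * np.exp(-x * x / (2.0 * u))
        return s / np.sqrt(2.0 * np.pi * u * u * u)
    K = int(np.ceil(kl))
    s = 0.0
    for k in range(1, K + 1):
        s += k * np.exp(-k * k * np.pi * np.pi * u / 2.0) * np.sin(k * np.pi * w)
    return np.pi * s


@njit(cache=True)
def _logpdf(t: float, v: float, a: float, w: float, tau: float, upper: bool) -> float:
    """Log FPT density at clock time t for one boundary; -inf outside support."""
    dt = t - tau
    if dt <= 0.0:
        return -np.inf
    if upper:
        v = -v
        w = 1.0 - w
    u = dt / (a * a)
    fw = _fw(u, w, _SERIES_EPS)
    if fw <= 0.0:
        return -np.inf
    return -2.0 * np.log(a) - v * a * w - v * v * dt / 2.0 + np.log(fw)


@njit(cache=True)
def _loglik_conditions(rt, upper, cond, v3, a, w3, tau) -> float:
    """Sum of log densities for one participant; condition codes are 1..3."""
    s = 0.0
    for i in range(rt.size):
        c = cond[i] - 1
        lp = _logpdf(rt[i], v3[c], a, w3[c], tau, upper[i])
        if lp == -np.inf:
            return -np.inf
        s += lp
    return s


def fpt_logdensity(t, params: WienerParams, boundary: str = "upper"):
    """Log first-passage-time density at clock time(s) ``t``."""
    if boundary not in ("upper", "lower"):
        raise ValueError(f"boundary must be 'upper' or 'lower', got {boundary!r}")
    up = boundary == "upper"
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.empty_like(t_arr)
    for i, ti in enumerate(t_arr):
        out[i] = _logpdf(ti, params.drift, params.boundary, params.rel_start, params.ndt, up)
    return out if np.ndim(t) else float(out[0])


def fpt_density(t, params: WienerParams, boundary: str = "upper"):
    """First-passage-time density (per second) at clock time(s) ``t``.

    Zero for ``t <= ndt``; the series switch keeps the absolute error of
    the dimensionless density below ~1e-9 everywhere.
    """
    return np.exp(fpt_logdensity(t, params, boundary))


def log_likelihood(rt, correct, condition, params_by_condition) -> float:
    """Joint log likelihood of accuracy-coded trials.

    Parameters
    ----------
    rt, correct, condition
        Aligned arrays: RT in seconds, boolean correctness (upper
        boundary = correct), and condition codes in {1, 2, 3}.
    params_by_condition
        Mapping condition code -> :class:`WienerParams`, or a single
        ``WienerParams`` shared by all conditions.  Boundary separation
        and non-decision time must agree across conditions.

    Returns -inf when any trial's RT lies at or below the non-decision
    time, and 0.0 for an empty trial set.
    """
    rt = np.asarray(rt, dtype=float)
    correct = np.asarray(correct, dtype=np.bool_)
    condition = np.asarray(condition, dtype=np.int64)
    if rt.size == 0:
        return 0.0
    if isinstance(params_by_condition, WienerParams):
        params_by_condition = {c: params_by_condition for c in (1, 2, 3)}
    ref = next(iter(params_by_condition.values()))
    v3 = np.full(3, np.nan)
    w3 = np.full(3, np.nan)
    for c, p in params_by_condition.items():
        if not (p.boundary == ref.boundary and p.ndt == ref.ndt):
            raise ValueError("boundary separation and ndt must be shared across conditions")
        v3[c - 1] = p.drift
        w3[c - 1] = p.rel_start
    present = np.unique(condition)
    if np.any((present < 1) | (present > 3)) or np.any(np.isnan(v3[present - 1])):
        raise ValueError("trial condition without parameters")
    return float(_loglik_conditions(rt, correct, condition, v3, ref.boundary, w3, ref.ndt))


def choice_probability(params: WienerParams) -> float:
    """Probability of absorption at the upper (correct) boundary.

    Closed form ``(1 - exp(-2 v a w)) / (1 - exp(-2 v a))`` for v != 0
    and ``w`` for v = 0.
    """
    v, a, w = params.drift, params.boundary, params.rel_start
    if abs(v) < 1e-12:
        return w
    # expm1-based form is stable for small |v a|
    return float(np.expm1(-2.0 * v * a * w) / np.expm1(-2.0 * v * a))


def _decision_time_grid(params: WienerParams, n_grid: int) -> np.ndarray:
    """Quadratically spaced decision-time grid covering all but ~1e-12 mass."""
    v, a = params.drift, params.boundary
    lam1 = (v * v + np.pi * np.pi / (a * a)) / 2.0  # slowest decay rate
    t_max = min(45.0 / lam1 + 5.0 * a * a, 300.0)
    x = np.linspace(0.0, 1.0, n_grid)
    return t_max * x * x


def sample_trials(
    params: WienerParams,
    n: int,
    seed=None,
    method: str = "inverse_cdf",
    n_grid: int = 4097,
    euler_dt: float = 1e-4,
):
    """Draw ``n`` (correct, rt) pairs from the FPT distribution.

    The default draws the boundary from the closed-form choice
    probability and the decision time from the numerically inverted
    conditional CDF of the series density (grid tolerance ~1e-6).
    ``method='euler'`` instead simulates the diffusion path with an
    Euler–Maruyama step of ``euler_dt`` seconds.

    Returns
    -------
    correct : (n,) bool array
    rt : (n,) float array, all strictly greater than ``params.ndt``
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if method == "euler":
        return sample_trials_euler(params, n, rng, dt=euler_dt)
    if method != "inverse_cdf":
        raise ValueError(f"unknown sampling method {method!r}")
    p_up = choice_probability(params)
    t = _decision_time_grid(params, n_grid)
    shifted = WienerParams(params.drift, params.boundary, 0.0, params.rel_start)
    dens_up = fpt_density(t, shifted, "upper")
    dens_lo = fpt_density(t, shifted, "lower")
    correct = rng.random(n) < p_up
    rt = np.empty(n)
    for up, dens, mass in ((True, dens_up, p_up), (False, dens_lo, 1.0 - p_up)):
        idx = np.flatnonzero(correct == up)
        if idx.size == 0:
            continue
        cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2.0 * np.diff(t))])
        cdf /= cdf[-1]
        u = rng.random(idx.size)
        rt[idx] = np.interp(u, cdf, t) + params.ndt
    # inverse-CDF can land exactly on the grid origin; nudge into support
    np.maximum(rt, params.ndt + 1e-9, out=rt)
    return correct, rt


@njit(cache=True)
def _euler_paths(n, v, a, z0, dt, t_max, seeds):
    rts = np.empty(n)
    hit_upper = np.empty(n, dtype=np.bool_)
    sqdt = np.sqrt(dt)
    np.random.seed(seeds)
    for i in range(n):
        x = z0
        t = 0.0
        while t < t_max:
            x_new = x + v * dt + sqdt * np.random.randn()
            t += dt
            if x_new >= a:
                hit_upper[i] = True
                x = x_new
                break
            if x_new <= 0.0:
                hit_upper[i] = False
                x = x_new
                break
            # Brownian-bridge probability of an unobserved within-step
            # crossing; removes the O(sqrt(dt)) first-passage bias
            p_up = np.exp(-2.0 * (a - x) * (a - x_new) / dt)
            p_lo = np.exp(-2.0 * x * x_new / dt)
            u = np.random.random()
            if u < p_up:
                hit_upper[i] = True
                x = x_new
                t -= dt / 2.0
                break
            if u < p_up + p_lo:
                hit_upper[i] = False
                x = x_new
                t -= dt / 2.0
                break
            x = x_new
        else:
            hit_upper[i] = x >= a / 2.0
            t = t_max
        rts[i] = t
    return hit_upper, rts


def sample_trials_euler(params: WienerParams, n: int, rng, dt: float = 1e-4):
    """Euler–Maruyama path simulation with Brownian-bridge crossing
    correction (independent of the series density)."""
    seeds = int(rng.integers(0, 2**31 - 1))
    v, a, w = params.drift, params.boundary, params.rel_start
    lam1 = (v * v + np.pi * np.pi / (a * a)) / 2.0
    t_max = min(45.0 / lam1 + 5.0 * a * a, 300.0)
    correct, dts = _euler_paths(n, v, a, w * a, dt, t_max, seeds)
    return correct, dts + params.ndt
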