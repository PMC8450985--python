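"""Plausible-values correlation of model parameters with a trait score.

Rather than correlating posterior point estimates with the trait, each
posterior draw of the participant-parameter vector is treated as a
plausible realization: its sample Pearson correlation r_k with the
trait scores is computed, the exact posterior of the population
correlation rho given (r_k, n) under a stretched-beta prior is formed
analytically, and these single-draw posteriors are averaged.  The
result propagates both posterior uncertainty and sampling-to-population
uncertainty into one distribution, summarized by a 95% equal-tail
credible interval and a Bayesian p-value (posterior mass on the smaller
side of zero).

The sampling density of r given rho uses the exact hypergeometric form

    p(r | rho, n) = (n-2) Gamma(n-1) (1-rho^2)^((n-1)/2)
                    (1-r^2)^((n-4)/2) / (sqrt(2 pi) Gamma(n-1/2)
                    (1-rho r)^(n-3/2))
                    * 2F1(1/2, 1/2; n-1/2; (rho r + 1)/2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, hyp2f1, betaln

__all__ = [
    "PlausibleCorrelations",
    "CorrelationPosterior",
    "plausible_correlations",
    "correlation_posterior_single",
    "average_posteriors",
    "plausible_values_analysis",
    "default_rho_grid",
]


def default_rho_grid(n_points: int = 2001) -> np.ndarray:
    """Symmetric open grid on (-1, 1) including 0 (n_points must be odd)."""
    if n_points % 2 == 0:
        raise ValueError("n_points must be odd so that 0 is a grid point")
    return np.linspace(-1.0, 1.0, n_points + 2)[1:-1]


@dataclass
class PlausibleCorrelations:
    """Sample correlations r_k between draw-k parameters and the trait."""

    r: np.ndarray
    n_participants: int
    parameter: str
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 4:
            raise ValueError("need at least 4 participants")


@dataclass
class CorrelationPosterior:
    """Averaged posterior of the population correlation rho."""

    grid: np.ndarray
    density: np.ndarray
    ci_low: float
    ci_high: float
    bayes_p: float
    p_above_zero: float
    p_below_zero: float
    prior_width: float = 1.0

    def mean(self) -> float:
        return float(np.trapezoid(self.grid * self.density, self.grid))


def plausible_correlations(
    draws,
    parameter: str,
    trait,
    n_draws: int = 3000,
    seed: int | None = None,
) -> PlausibleCorrelations:
    """Pearson r between each retained draw's participant vector and the trait.

    ``draws`` is a :class:`~cuebias.hierarchical.PosteriorDraws`;
    ``parameter`` any name accepted by ``participant_matrix`` (e.g.
    ``start_effect``, ``alpha``, ``drift_effect``).  ``n_draws`` draws
    are subsampled without replacement (seeded); draws whose parameter
    vector has zero variance are dropped with a count reported.
    """
    mat = draws.participant_matrix(parameter)  # (n_retained, n_p)
    trait = np.asarray(trait, dtype=float)
    if trait.shape[0] != mat.shape[1]:
        raise ValueError(
            f"trait length {trait.shape[0]} != participants {mat.shape[1]}"
        )
    rng = np.random.default_rng(seed)
    k = min(n_draws, mat.shape[0])
    idx = np.sort(rng.choice(mat.shape[0], size=k, replace=False))
    sub = mat[idx]
    sd = sub.std(axis=1)
    ok = sd > 0
    centered = sub[ok] - sub[ok].mean(axis=1, keepdims=True)
    t_c = trait - trait.mean()
    denom = np.sqrt((centered**2).sum(axis=1) * (t_c**2).sum())
    r = centered @ t_c / denom
    return PlausibleCorrelations(
        r=r, n_participants=trait.shape[0], parameter=parameter, n_dropped=int((~ok).sum())
    )


def _log_prior_rho(rho, width: float):
    """Stretched-beta prior on (-1, 1): rho = 2*B - 1, B ~ Beta(1/w, 1/w)."""
    a = 1.0 / width
    return (a - 1.0) * np.log1p(-rho**2) - (betaln(a, a) + (2.0 * a - 1.0) * np.log(2.0))


def log_r_density(r: float, rho, n: int):
    """Exact log sampling density of the Pearson r given rho (bivariate normal)."""
    rho = np.asarray(rho, dtype=float)
    return (
        np.log(n - 2.0)
        + gammaln(n - 1.0)
        + ((n - 1.0) / 2.0) * np.log1p(-(rho**2))
        + ((n - 4.0) / 2.0) * np.log1p(-(r**2))
        - 0.5 * np.log(2.0 * np.pi)
        - gammaln(n - 0.5)
        - (n - 1.5) * np.log1p(-rho * r)
        + np.log(hyp2f1(0.5, 0.5, n - 0.5, (rho * r + 1.0) / 2.0))
    )


def correlation_posterior_single(
    r: float,
    n: int,
    grid: np.ndarray | None = None,
    prior_width: float = 1.0,
) -> np.ndarray:
    """Posterior density of rho given one sample correlation, on a grid.

    Exact bivariate-normal sampling density times a stretched-beta prior
    (uniform on (-1, 1) at the default width 1), trapezoid-normalized.
    """
    if not np.isfinite(r) or abs(r) > 1:
        raise ValueError(f"sample correlation must lie in [-1, 1], got {r}")
    if abs(r) == 1:
        raise ValueError("degenerate |r| = 1: posterior collapses to a point mass")
    if n < 4:
        raise ValueError("need n >= 4")
    g = default_rho_grid() if grid is None else np.asarray(grid, dtype=float)
    logd = log_r_density(r, g, n) + _log_prior_rho(g, prior_width)
    logd -= logd.max()
    dens = np.exp(logd)
    dens /= np.trapezoid(dens, g)
    return dens


def average_posteriors(
    singles, grid: np.ndarray, prior_width: float = 1.0, level: float = 0.95
) -> CorrelationPosterior:
    """Average single-draw rho posteriors into the plausible-values posterior.

    Pointwise arithmetic mean, renormalized; equal-tail CI from the
    averaged CDF; Bayesian p = min(P(rho > 0), P(rho < 0)).
    """
    singles = np.atleast_2d(np.asarray(singles, dtype=float))
    if singles.size == 0 or singles.shape[0] == 0:
        raise ValueError("no densities to average")
    if singles.shape[1] != grid.shape[0]:
        raise ValueError("densities and grid have mismatched lengths")
    dens = singles.mean(axis=0)
    dens = dens / np.trapezoid(dens, grid)

    # piecewise-linear CDF on the trapezoid rule
    seg = (dens[1:] + dens[:-1]) / 2.0 * np.diff(grid)
    cdf = np.concatenate([[0.0], np.cumsum(seg)])
    cdf /= cdf[-1]
    alpha = (1.0 - level) / 2.0
    ci_low = float(np.interp(alpha, cdf, grid))
    ci_high = float(np.interp(1.0 - alpha, cdf, grid))
    p_below = float(np.interp(0.0, grid, cdf))
    p_above = 1.0 - p_below
    return CorrelationPosterior(
        grid=grid,
        density=dens,
        ci_low=ci_low,
        ci_high=ci_high,
        bayes_p=min(p_above, p_below),
        p_above_zero=p_above,
        p_below_zero=p_below,
        prior_width=prior_width,
    )


def plausible_values_analysis(
    draws,
    parameter: str,
    trait,
    n_draws: int = 3000,
    grid: np.ndarray | None = None,
    prior_width: float = 1.0,
    seed: int | None = None,
):
    """End-to-end plausible-values run for one parameter/trait pair.

    Returns (PlausibleCorrelations, CorrelationPosterior).
    """
    g = default_rho_grid() if grid is None else np.asarray(grid, dtype=float)
    pc = plausible_correlations(draws, parameter, trait, n_draws=n_draws, seed=seed)
    n = pc.n_participants
    singles = np.stack([correlation_posterior_single(rk, n, g, prior_width) for rk in pc.r])
    post = average_posteriors(singles, g, prior_width=prior_width)
    return pc, post
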