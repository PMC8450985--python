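"""Hierarchical Bayesian Wiener diffusion models of the cueing effect.

Three model variants, mirroring the candidate explanations of the cue
effect:

``M1_start``
    Condition shifts the starting point: neutral trials have beta fixed
    at 0.5; on valid trials beta_p2 ~ TruncNormal(0.5 + theta*sigma_eps,
    sigma_eps) on (0.01, 0.99); invalid trials use 1 - beta_p2 exactly
    (symmetric effect).  Drift is shared across conditions.
``M2_drift``
    Condition shifts the drift rate: delta_pc ~ TruncNormal(mu_delta +
    x_c*theta*sigma_eps, sigma_delta) with x = (0, +1, -1) for
    (neutral, valid, invalid); beta = 0.5 everywhere.
``M3_both``
    Both effects, with separate (theta, sigma_eps) pairs.

Participant-level drift, boundary and non-decision time follow
truncated normals around population means (truncation bounds keep the
parameters plausible).  The condition effect uses the standardized
effect-size parameterization theta * sigma_eps of the Bayesian-ANOVA
convention, with a Cauchy(0, 1/sqrt(2)) prior on theta.

Sampling is blocked adaptive random-walk Metropolis in an unconstrained
parameterization (logit for interval-bounded parameters, log for
scales): all participant blocks update in parallel — the likelihood
factorizes over participants given the group level — followed by group
updates that touch only the hierarchical priors.  Proposal scales and
shapes adapt during burn-in only, so the retained chain is a valid
Markov chain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.special import ndtr, log_ndtr, expit, logit

from cuebias.data import StudyData
from cuebias.synthetic import ALPHA_BOUNDS, BETA_BOUNDS, DELTA_BOUNDS, TAU_BOUNDS
from cuebias.wiener import WienerParams, _logpdf, sample_trials

__all__ = [
    "MODEL_SPECS",
    "PriorConfig",
    "HierarchicalWienerModel",
    "PosteriorDraws",
    "build_model",
    "sample_posterior",
    "gelman_rubin",
    "posterior_predict",
]

MODEL_SPECS = ("M1_start", "M2_drift", "M3_both")
_COND_SIGN = np.array([0.0, 1.0, -1.0])  # neutral, valid, invalid


@dataclass(frozen=True)
class PriorConfig:
    """Group-level prior hyperparameters (weakly informative, s = 1 scale)."""

    mu_delta: tuple = (1.5, 2.0)
    mu_alpha: tuple = (1.5, 1.0)
    mu_tau: tuple = (0.3, 0.25)
    sigma_scale: float = 1.0          # half-normal scale for sigma_delta/alpha/tau
    theta_scale: float = 0.7071067811865476  # Cauchy scale 1/sqrt(2)
    sigma_eps_start_scale: float = 0.5
    sigma_eps_drift_scale: float = 1.0


# ---------------------------------------------------------------------------
# transforms

def _to_interval(x, lo, hi):
    return lo + (hi - lo) * expit(x)


def _from_interval(y, lo, hi):
    return logit((np.asarray(y, dtype=float) - lo) / (hi - lo))


def _interval_logjac(x, lo, hi):
    # log |d/dx (lo + (hi-lo) sigmoid(x))|, numerically stable
    x = np.asarray(x, dtype=float)
    return np.log(hi - lo) - np.logaddexp(0.0, -x) - np.logaddexp(0.0, x)


def _norm_logpdf(x, m, s):
    return -0.5 * np.log(2 * np.pi) - np.log(s) - 0.5 * ((x - m) / s) ** 2


def _truncnorm_logpdf(x, m, s, lo, hi):
    """Normalized truncated-normal log density; -inf outside [lo, hi]."""
    a = (np.asarray(lo) - m) / s
    b = (np.asarray(hi) - m) / s
    mass = ndtr(b) - ndtr(a)
    # tail-stable log mass: mirror into the lower tail when both points
    # sit far right, where ndtr saturates at 1
    a_m = np.where(a > 0, -b, a)
    b_m = np.where(a > 0, -a, b)
    la, lb = log_ndtr(a_m), log_ndtr(b_m)
    log_tail = lb + np.log1p(-np.exp(np.minimum(la - lb, -1e-300)))
    with np.errstate(divide="ignore"):
        logmass = np.where(mass > 1e-12, np.log(np.maximum(mass, 1e-300)), log_tail)
    out = _norm_logpdf(x, m, s) - logmass
    return np.where((x >= lo) & (x <= hi), out, -np.inf)


def _half_normal_logpdf(x, s):
    return np.where(x > 0, np.log(2.0) + _norm_logpdf(x, 0.0, s), -np.inf)


def _cauchy_logpdf(x, s):
    return -np.log(np.pi * s * (1.0 + (x / s) ** 2))


# ---------------------------------------------------------------------------
# likelihood kernel

@njit(cache=True)
def _loglik_all(rt, up, cond, starts, ends, V, A, W, T, out):
    for p in range(starts.size):
        s = 0.0
        for i in range(starts[p], ends[p]):
            c = cond[i] - 1
            lp = _logpdf(rt[i], V[p, c], A[p], W[p, c], T[p], up[i])
            if lp == -np.inf:
                s = -np.inf
                break
            s += lp
        out[p] = s


# ---------------------------------------------------------------------------

_GROUP_NAMES = {
    "M1_start": ["mu_delta", "mu_alpha", "mu_tau", "sigma_delta", "sigma_alpha",
                 "sigma_tau", "theta_start", "sigma_eps_start"],
    "M2_drift": ["mu_delta", "mu_alpha", "mu_tau", "sigma_delta", "sigma_alpha",
                 "sigma_tau", "theta_drift", "sigma_eps_drift"],
    "M3_both": ["mu_delta", "mu_alpha", "mu_tau", "sigma_delta", "sigma_alpha",
                "sigma_tau", "theta_start", "sigma_eps_start", "theta_drift",
                "sigma_eps_drift"],
}
_PART_NAMES = {
    "M1_start": ["delta", "alpha", "tau", "beta_2"],
    "M2_drift": ["delta_1", "delta_2", "delta_3", "alpha", "tau"],
    "M3_both": ["delta_1", "delta_2", "delta_3", "alpha", "tau", "beta_2"],
}


class HierarchicalWienerModel:
    """Log-posterior over (group, participant) parameters for one variant.

    Parameters are handled in an unconstrained vector
    ``[group, participants.ravel()]``; :meth:`log_posterior` includes
    all transform Jacobians, so its exponential integrates to the
    marginal likelihood over the unconstrained space.
    """

    def __init__(self, spec: str, data: StudyData, priors: PriorConfig | None = None,
                 use_likelihood: bool = True):
        if spec not in MODEL_SPECS:
            raise ValueError(f"unknown model spec {spec!r}; choose from {MODEL_SPECS}")
        self.spec = spec
        self.priors = priors or PriorConfig()
        self.data = data
        self.use_likelihood = use_likelihood

        trials = data.trials.sort_values("participant", kind="stable")
        self.participants = list(pd.unique(trials["participant"]))
        self.n_participants = len(self.participants)
        if self.n_participants == 0:
            raise ValueError("no trials")
        self._rt = trials["rt"].to_numpy(float)
        self._up = trials["correct"].to_numpy(bool)
        self._cond = trials["condition"].to_numpy(np.int64)
        sizes = trials.groupby("participant", sort=False).size().to_numpy()
        self._ends = np.cumsum(sizes)
        self._starts = self._ends - sizes
        min_rt = trials.groupby("participant", sort=False)["rt"].min().to_numpy()
        if use_likelihood:
            self.tau_hi = np.minimum(TAU_BOUNDS[1], min_rt - 1e-4)
        else:
            self.tau_hi = np.full(self.n_participants, TAU_BOUNDS[1])
        bad = self.tau_hi <= TAU_BOUNDS[0]
        if bad.any():
            who = [self.participants[i] for i in np.flatnonzero(bad)]
            raise ValueError(f"participants with min RT <= {TAU_BOUNDS[0]} s cannot be fit: {who}")

        self.group_names = list(_GROUP_NAMES[spec])
        self.part_names = list(_PART_NAMES[spec])
        self.d_group = len(self.group_names)
        self.d_part = len(self.part_names)
        self.dim = self.d_group + self.n_participants * self.d_part
        self.names = self.group_names + [
            f"{nm}[{p}]" for p in self.participants for nm in self.part_names
        ]

    # -- transforms ---------------------------------------------------------

    def group_constrain(self, g):
        """Unconstrained group vector(s) -> constrained array, plus log-Jacobian."""
        g = np.asarray(g, dtype=float)
        out = np.empty_like(g)
        lj = np.zeros(g.shape[:-1])
        bounds = [DELTA_BOUNDS, ALPHA_BOUNDS, TAU_BOUNDS]
        for i, b in enumerate(bounds):
            out[..., i] = _to_interval(g[..., i], *b)
            lj += _interval_logjac(g[..., i], *b)
        for i in range(3, self.d_group):
            if self.group_names[i].startswith("sigma"):
                out[..., i] = np.exp(g[..., i])
                lj += g[..., i]
            else:  # theta, unbounded
                out[..., i] = g[..., i]
        return out, lj

    def part_constrain(self, X):
        """Unconstrained participant matrix (..., n_p, d_p) -> constrained, log-Jac per participant."""
        X = np.asarray(X, dtype=float)
        out = np.empty_like(X)
        lj = np.zeros(X.shape[:-1])
        for j, nm in enumerate(self.part_names):
            if nm.startswith("delta"):
                b = DELTA_BOUNDS
                out[..., j] = _to_interval(X[..., j], *b)
                lj += _interval_logjac(X[..., j], *b)
            elif nm == "alpha":
                out[..., j] = _to_interval(X[..., j], *ALPHA_BOUNDS)
                lj += _interval_logjac(X[..., j], *ALPHA_BOUNDS)
            elif nm == "tau":
                out[..., j] = TAU_BOUNDS[0] + (self.tau_hi - TAU_BOUNDS[0]) * expit(X[..., j])
                lj += (np.log(self.tau_hi - TAU_BOUNDS[0])
                       - np.logaddexp(0.0, -X[..., j]) - np.logaddexp(0.0, X[..., j]))
            elif nm == "beta_2":
                out[..., j] = _to_interval(X[..., j], *BETA_BOUNDS)
                lj += _interval_logjac(X[..., j], *BETA_BOUNDS)
        return out, lj

    # -- densities ----------------------------------------------------------

    def group_logprior(self, gc):
        """Log prior of constrained group values (without Jacobians)."""
        pr = self.priors
        lp = _truncnorm_logpdf(gc[..., 0], *pr.mu_delta, *DELTA_BOUNDS)
        lp = lp + _truncnorm_logpdf(gc[..., 1], *pr.mu_alpha, *ALPHA_BOUNDS)
        lp = lp + _truncnorm_logpdf(gc[..., 2], *pr.mu_tau, *TAU_BOUNDS)
        for i in range(3, 6):
            lp = lp + _half_normal_logpdf(gc[..., i], pr.sigma_scale)
        for i in range(6, self.d_group):
            nm = self.group_names[i]
            if nm.startswith("theta"):
                lp = lp + _cauchy_logpdf(gc[..., i], pr.theta_scale)
            elif nm == "sigma_eps_start":
                lp = lp + _half_normal_logpdf(gc[..., i], pr.sigma_eps_start_scale)
            else:
                lp = lp + _half_normal_logpdf(gc[..., i], pr.sigma_eps_drift_scale)
        return lp

    def part_logprior(self, Xc, gc):
        """Log prior of constrained participant params given the group (per participant)."""
        idx = {nm: i for i, nm in enumerate(self.group_names)}
        mu_d, mu_a, mu_t = gc[..., 0:1], gc[..., 1:2], gc[..., 2:3]
        s_d, s_a, s_t = gc[..., 3:4], gc[..., 4:5], gc[..., 5:6]
        lp = 0.0
        if self.spec == "M1_start":
            lp = lp + _truncnorm_logpdf(Xc[..., 0], mu_d[..., 0], s_d[..., 0], *DELTA_BOUNDS)
        else:
            th = gc[..., idx["theta_drift"]:idx["theta_drift"] + 1]
            se = gc[..., idx["sigma_eps_drift"]:idx["sigma_eps_drift"] + 1]
            for j, sign in enumerate(_COND_SIGN):
                m = mu_d[..., 0] + sign * th[..., 0] * se[..., 0]
                lp = lp + _truncnorm_logpdf(Xc[..., j], m, s_d[..., 0], *DELTA_BOUNDS)
        ja, jt = self.part_names.index("alpha"), self.part_names.index("tau")
        lp = lp + _truncnorm_logpdf(Xc[..., ja], mu_a[..., 0], s_a[..., 0], *ALPHA_BOUNDS)
        lp = lp + _truncnorm_logpdf(Xc[..., jt], mu_t[..., 0], s_t[..., 0], *TAU_BOUNDS)
        if "beta_2" in self.part_names:
            jb = self.part_names.index("beta_2")
            th = gc[..., idx["theta_start"]:idx["theta_start"] + 1]
            se = gc[..., idx["sigma_eps_start"]:idx["sigma_eps_start"] + 1]
            m = 0.5 + th[..., 0] * se[..., 0]
            lp = lp + _truncnorm_logpdf(Xc[..., jb], m, se[..., 0], *BETA_BOUNDS)
        return lp

    def _vawt(self, Xc):
        """Constrained participant matrix -> per-participant (V, A, W, T) arrays."""
        n = Xc.shape[0]
        if self.spec == "M1_start":
            V = np.repeat(Xc[:, 0:1], 3, axis=1)
        else:
            V = Xc[:, 0:3].copy()
        A = Xc[:, self.part_names.index("alpha")].copy()
        T = Xc[:, self.part_names.index("tau")].copy()
        if "beta_2" in self.part_names:
            b2 = Xc[:, self.part_names.index("beta_2")]
            W = np.column_stack([np.full(n, 0.5), b2, 1.0 - b2])
        else:
            W = np.full((n, 3), 0.5)
        return V, A, W, T

    def loglik(self, Xc):
        """Per-participant Wiener log likelihoods for constrained params."""
        if not self.use_likelihood:
            return np.zeros(self.n_participants)
        V, A, W, T = self._vawt(Xc)
        out = np.empty(self.n_participants)
        _loglik_all(self._rt, self._up, self._cond, self._starts, self._ends,
                    V, A, W, T, out)
        return out

    def log_posterior(self, theta):
        """Unnormalized log posterior on the unconstrained space (Jacobians included)."""
        theta = np.asarray(theta, dtype=float)
        g = theta[: self.d_group]
        X = theta[self.d_group:].reshape(self.n_participants, self.d_part)
        gc, gj = self.group_constrain(g)
        glp = self.group_logprior(gc)
        if not np.isfinite(glp):
            return -np.inf
        Xc, xj = self.part_constrain(X)
        plp = self.part_logprior(Xc, gc)
        if not np.all(np.isfinite(plp)):
            return -np.inf
        lik = self.loglik(Xc)
        if not np.all(np.isfinite(lik)):
            return -np.inf
        return float(glp + gj + np.sum(plp) + np.sum(xj) + np.sum(lik))

    def log_posterior_batch(self, Theta):
        return np.array([self.log_posterior(t) for t in np.atleast_2d(Theta)])

    # -- initialization -----------------------------------------------------

    def initial_point(self, rng):
        """Uniform draws within admissible (plausible-subrange) parameter values."""
        g = np.empty(self.d_group)
        g[0] = _from_interval(rng.uniform(0.0, 3.0), *DELTA_BOUNDS)
        g[1] = _from_interval(rng.uniform(0.5, 2.5), *ALPHA_BOUNDS)
        tau_cap = min(0.6, float(self.tau_hi.min()) - 0.01)
        g[2] = _from_interval(rng.uniform(TAU_BOUNDS[0] + 0.01, max(tau_cap, 0.08)), *TAU_BOUNDS)
        g[3:6] = np.log(rng.uniform(0.1, 1.0, 3))
        for i in range(6, self.d_group):
            if self.group_names[i].startswith("theta"):
                g[i] = rng.uniform(-0.5, 0.5)
            else:
                g[i] = np.log(rng.uniform(0.05, 0.5))
        X = np.empty((self.n_participants, self.d_part))
        for j, nm in enumerate(self.part_names):
            if nm.startswith("delta"):
                X[:, j] = _from_interval(rng.uniform(0.0, 3.0, self.n_participants), *DELTA_BOUNDS)
            elif nm == "alpha":
                X[:, j] = _from_interval(rng.uniform(0.5, 2.5, self.n_participants), *ALPHA_BOUNDS)
            elif nm == "tau":
                hi = np.minimum(0.6, self.tau_hi - 0.01)
                lo = np.full_like(hi, TAU_BOUNDS[0] + 0.005)
                t0 = rng.uniform(lo, np.maximum(hi, lo + 0.01))
                X[:, j] = logit((t0 - TAU_BOUNDS[0]) / (self.tau_hi - TAU_BOUNDS[0]))
            elif nm == "beta_2":
                X[:, j] = _from_interval(rng.uniform(0.35, 0.65, self.n_participants), *BETA_BOUNDS)
        return g, X


def build_model(spec: str, data: StudyData, priors: PriorConfig | None = None,
                use_likelihood: bool = True) -> HierarchicalWienerModel:
    """Construct the log-posterior object for one model variant.

    ``use_likelihood=False`` keeps the data's structure (participants,
    trial counts) but samples the joint prior — useful for prior
    predictive and identifiability checks.
    """
    return HierarchicalWienerModel(spec, data, priors, use_likelihood=use_likelihood)


# ---------------------------------------------------------------------------
# posterior container

@dataclass
class PosteriorDraws:
    """Retained MCMC draws (unconstrained), with transforms to natural scale."""

    model: HierarchicalWienerModel
    draws: np.ndarray          # (n_chains, n_kept, dim), unconstrained
    seed: int | None
    n_iter: int
    burn_in: int
    accept_rates: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_retained(self) -> int:
        return self.draws.shape[0] * self.draws.shape[1]

    def flat(self) -> np.ndarray:
        """All retained unconstrained draws, (n_retained, dim)."""
        return self.draws.reshape(-1, self.draws.shape[-1])

    def group_samples(self, constrained: bool = True) -> pd.DataFrame:
        g = self.flat()[:, : self.model.d_group]
        if constrained:
            g, _ = self.model.group_constrain(g)
        return pd.DataFrame(g, columns=self.model.group_names)

    def extract(self, name: str) -> np.ndarray:
        """Group-level scalar as (n_chains, n_kept), constrained scale.

        Derived names: ``start_effect_group`` = theta_start*sigma_eps_start,
        ``drift_effect_group`` = theta_drift*sigma_eps_drift.
        """
        gc, _ = self.model.group_constrain(self.draws[..., : self.model.d_group])
        names = self.model.group_names
        if name in names:
            return gc[..., names.index(name)]
        if name == "start_effect_group":
            return gc[..., names.index("theta_start")] * gc[..., names.index("sigma_eps_start")]
        if name == "drift_effect_group":
            return gc[..., names.index("theta_drift")] * gc[..., names.index("sigma_eps_drift")]
        raise KeyError(name)

    def participant_matrix(self, param: str) -> np.ndarray:
        """Per-participant parameter per retained draw, (n_retained, n_p).

        ``param``: one of the participant parameter names, or the derived
        ``start_effect`` (beta_2 - 0.5) and ``drift_effect``
        ((delta_2 - delta_3)/2; zero under M1).
        """
        m = self.model
        X = self.flat()[:, m.d_group:].reshape(-1, m.n_participants, m.d_part)
        Xc, _ = m.part_constrain(X)
        names = m.part_names
        if param in names:
            return Xc[..., names.index(param)]
        if param == "start_effect":
            if "beta_2" not in names:
                return np.zeros(Xc.shape[:2])
            return Xc[..., names.index("beta_2")] - 0.5
        if param == "drift_effect":
            if "delta_2" not in names:
                return np.zeros(Xc.shape[:2])
            return (Xc[..., names.index("delta_2")] - Xc[..., names.index("delta_3")]) / 2.0
        if param == "delta" and "delta" not in names:
            return Xc[..., names.index("delta_1")]
        raise KeyError(param)

    def rhat(self, split: bool = False) -> pd.Series:
        """Gelman–Rubin statistic for every group-level parameter."""
        gc, _ = self.model.group_constrain(self.draws[..., : self.model.d_group])
        return pd.Series(
            {nm: gelman_rubin(gc[..., i], split=split) for i, nm in enumerate(self.model.group_names)}
        )

    def save(self, path) -> None:
        """Columnar draws file: chain, iteration, then every unconstrained
        parameter.  CSV by default; a ``.parquet`` suffix selects the
        compact binary format instead."""
        n_c, n_k, d = self.draws.shape
        df = pd.DataFrame(self.flat(), columns=self.model.names)
        df.insert(0, "iteration", np.tile(np.arange(n_k), n_c))
        df.insert(0, "chain", np.repeat(np.arange(n_c), n_k))
        if str(path).endswith(".parquet"):
            df.to_parquet(path, index=False)
        else:
            df.to_csv(path, index=False)


def load_draws(model: HierarchicalWienerModel, path) -> PosteriorDraws:
    """Rebuild a :class:`PosteriorDraws` from a saved draws file."""
    if str(path).endswith(".parquet"):
        df = pd.read_parquet(path)
    else:
        df = pd.read_csv(path)
    expected = ["chain", "iteration"] + model.names
    if list(df.columns) != expected:
        raise ValueError("draw file does not match this model's parameterization")
    n_c = df["chain"].nunique()
    arr = df[model.names].to_numpy(float).reshape(n_c, -1, model.dim)
    return PosteriorDraws(model=model, draws=arr, seed=None, n_iter=-1, burn_in=-1)


# ---------------------------------------------------------------------------
# sampler

def sample_posterior(
    model: HierarchicalWienerModel,
    n_chains: int = 3,
    n_iter: int = 15000,
    burn_in: int = 6000,
    thin: int = 1,
    seed: int | None = None,
    target_accept: float = 0.25,
) -> PosteriorDraws:
    """Blocked adaptive random-walk Metropolis sampling of the posterior.

    Defaults follow the study's schedule (3 chains x 15,000 iterations,
    6,000 burn-in -> 27,000 retained draws); tests use reduced
    schedules.  Initial values are uniform draws within admissible
    parameter ranges.  Adaptation (per-block scalar step sizes by
    Robbins–Monro, per-coordinate spreads from the running variance)
    happens during burn-in only.
    """
    if burn_in >= n_iter:
        raise ValueError("burn_in must be smaller than n_iter")
    ss = np.random.SeedSequence(seed)
    chains = []
    acc_stats = []
    for child in ss.spawn(n_chains):
        chains.append(_run_chain(model, n_iter, burn_in, thin, child, target_accept, acc_stats))
    draws = np.stack(chains)
    return PosteriorDraws(
        model=model, draws=draws, seed=seed, n_iter=n_iter, burn_in=burn_in,
        accept_rates={"chains": acc_stats},
    )


def _run_chain(model, n_iter, burn_in, thin, seedseq, target_accept, acc_stats):
    rng = np.random.default_rng(seedseq)
    n_p, d_p, d_g = model.n_participants, model.d_part, model.d_group

    for _ in range(200):
        g, X = model.initial_point(rng)
        gc, gj = model.group_constrain(g)
        Xc, xj = model.part_constrain(X)
        lik = model.loglik(Xc)
        ppri = model.part_logprior(Xc, gc) + xj
        gpri = model.group_logprior(gc) + gj
        if np.all(np.isfinite(lik)) and np.all(np.isfinite(ppri)) and np.isfinite(gpri):
            break
    else:  # pragma: no cover - initialization is essentially always feasible
        raise RuntimeError("could not find a feasible starting point")

    # adaptation state
    step_p = np.full(n_p, 0.15)
    step_g = 0.15
    sd_p = np.full((n_p, d_p), 0.5)
    sd_g = np.full(d_g, 0.3)
    mean_p, m2_p = X.copy(), np.zeros((n_p, d_p))
    mean_g, m2_g = g.copy(), np.zeros(d_g)

    # joint translation moves: shift a group-mean coordinate together with
    # the matching participant coordinates — decorrelates the centered
    # hierarchy, which plain one-block updates traverse very slowly
    delta_cols = [j for j, nm in enumerate(model.part_names) if nm.startswith("delta")]
    joint_specs = [
        ("shift", 0, delta_cols),
        ("shift", 1, [model.part_names.index("alpha")]),
        ("shift", 2, [model.part_names.index("tau")]),
        # scale moves: expand/contract participant spread together with the
        # group SD (deterministic stretch; Jacobian term in the ratio) —
        # needed to traverse the sigma funnel
        ("scale", 3, delta_cols),
        ("scale", 4, [model.part_names.index("alpha")]),
        ("scale", 5, [model.part_names.index("tau")]),
    ]
    step_j = np.full(len(joint_specs), 0.1)
    acc_j_n = np.zeros(len(joint_specs))
    acc_j_d = np.zeros(len(joint_specs))

    kept = []
    acc_p_n = acc_p_d = acc_g_n = acc_g_d = 0
    for it in range(n_iter):
        adapting = it < burn_in
        # --- participant blocks (vectorized accept/reject) ---
        prop = X + step_p[:, None] * sd_p * rng.standard_normal((n_p, d_p))
        Xc_new, xj_new = model.part_constrain(prop)
        lik_new = model.loglik(Xc_new)
        ppri_new = model.part_logprior(Xc_new, gc) + xj_new
        logr = (lik_new + ppri_new) - (lik + ppri)
        accept = np.log(rng.random(n_p)) < logr
        X[accept] = prop[accept]
        Xc[accept] = Xc_new[accept]
        lik[accept] = lik_new[accept]
        ppri[accept] = ppri_new[accept]
        xj[accept] = xj_new[accept]
        acc_p_n += accept.sum()
        acc_p_d += n_p

        # --- group block (prior-only, two sweeps for mixing) ---
        for _ in range(2):
            gprop = g + step_g * sd_g * rng.standard_normal(d_g)
            gc_new, gj_new = model.group_constrain(gprop)
            gpri_new = model.group_logprior(gc_new) + gj_new
            if np.isfinite(gpri_new):
                ppri_g = model.part_logprior(Xc, gc_new) + xj
                logr_g = gpri_new + ppri_g.sum() - gpri - ppri.sum()
                if np.log(rng.random()) < logr_g:
                    g, gc, gpri, ppri = gprop, gc_new, gpri_new, ppri_g
                    acc_g_n += 1
            acc_g_d += 1

        # --- joint hierarchy move (one rotating block per iteration) ---
        k = it % len(joint_specs)
        kind, gi, cols = joint_specs[k]
        eps = step_j[k] * rng.standard_normal()
        gprop = g.copy()
        gprop[gi] += eps
        Xprop = X.copy()
        log_jac_move = 0.0
        if kind == "shift":
            Xprop[:, cols] += eps
        else:
            center = g[gi - 3]  # matching group-mean coordinate
            Xprop[:, cols] = center + (Xprop[:, cols] - center) * np.exp(eps)
            log_jac_move = eps * n_p * len(cols)
        gc_new, gj_new = model.group_constrain(gprop)
        gpri_new = model.group_logprior(gc_new) + gj_new
        acc_j_d[k] += 1
        if np.isfinite(gpri_new):
            Xc_new, xj_new = model.part_constrain(Xprop)
            lik_new = model.loglik(Xc_new)
            ppri_new = model.part_logprior(Xc_new, gc_new) + xj_new
            logr_j = (gpri_new + np.sum(ppri_new + lik_new)
                      - gpri - np.sum(ppri + lik) + log_jac_move)
            if np.isfinite(logr_j) and np.log(rng.random()) < logr_j:
                g, gc, gpri = gprop, gc_new, gpri_new
                X, Xc, lik, ppri, xj = Xprop, Xc_new, lik_new, ppri_new, xj_new
                acc_j_n[k] += 1

        if adapting:
            t = it + 1
            gamma = t ** -0.6
            step_p *= np.exp(gamma * (accept.astype(float) - target_accept))
            step_g *= np.exp(gamma * (acc_g_n / max(acc_g_d, 1) - target_accept))
            step_j[k] *= np.exp(
                3.0 * gamma * (acc_j_n[k] / max(acc_j_d[k], 1) - target_accept)
            )
            # running spread estimates
            dX = X - mean_p
            mean_p += dX / t
            m2_p += dX * (X - mean_p)
            dg = g - mean_g
            mean_g += dg / t
            m2_g += dg * (g - mean_g)
            if t > 50:
                sd_p = np.sqrt(np.maximum(m2_p / t, 1e-6))
                sd_g = np.sqrt(np.maximum(m2_g / t, 1e-6))
        elif (it - burn_in) % thin == 0:
            kept.append(np.concatenate([g, X.ravel()]))

    acc_stats.append(
        {
            "participant": acc_p_n / max(acc_p_d, 1),
            "group": acc_g_n / max(acc_g_d, 1),
            "joint": (acc_j_n / np.maximum(acc_j_d, 1)).tolist(),
        }
    )
    return np.array(kept)


# ---------------------------------------------------------------------------
# diagnostics

def gelman_rubin(chains, split: bool = False) -> float:
    """Gelman–Rubin potential-scale-reduction statistic R-hat.

    ``chains`` is (n_chains, n_iterations).  The classic statistic is
    the default (matching the original diagnostic); ``split=True``
    halves each chain first.  Constant chains return 1.0 with a warning.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2:
        raise ValueError("chains must be 2-D (n_chains, n_iter)")
    if split:
        half = x.shape[1] // 2
        x = np.concatenate([x[:, :half], x[:, half: 2 * half]], axis=0)
    m, n = x.shape
    if m < 2:
        raise ValueError("need at least two chains (or split=True)")
    means = x.mean(axis=1)
    W = x.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W == 0:
        warnings.warn("zero within-chain variance; R-hat defined as 1.0" if B == 0
                      else "zero within-chain variance with nonzero between-chain variance",
                      stacklevel=2)
        return 1.0 if B == 0 else np.inf
    var_hat = (n - 1) / n * W + B / n
    return float(np.sqrt((var_hat + B / (m * n)) / W))


# ---------------------------------------------------------------------------
# posterior predictive checks

RT_QUANTILES = (0.1, 0.3, 0.5, 0.7, 0.9)


def _predictive_summary(trials: pd.DataFrame, quantiles) -> pd.DataFrame:
    rows = []
    for c in (1, 2, 3):
        sub = trials[trials["condition"] == c]
        acc = sub.groupby("participant")["correct"].mean()
        qs = (
            sub[sub["correct"]]
            .groupby("participant")["rt"]
            .quantile(list(quantiles))
            .groupby(level=1)
            .mean()
        )
        row = {"condition": c, "accuracy": float(acc.mean())}
        for q in quantiles:
            row[f"q{int(q * 100)}"] = float(qs.get(q, np.nan))
        rows.append(row)
    return pd.DataFrame(rows).set_index("condition")


def posterior_predict(
    draws: PosteriorDraws,
    data: StudyData,
    n_rep: int = 100,
    seed: int | None = None,
    quantiles=RT_QUANTILES,
    rt_window=(0.2, 1.5),
):
    """Posterior predictive accuracy and correct-RT quantiles per condition.

    For ``n_rep`` random retained draws, a full replicate dataset is
    simulated (same trial counts per participant x condition as
    observed, censored to the response window like the real data) and
    summarized; bands are the 2.5/97.5 predictive percentiles.

    Returns a dict with ``observed`` (DataFrame), ``replicates``
    (n_rep-long list of DataFrames), ``band_low``/``band_high``/``mean``
    DataFrames on the same layout.
    """
    rng = np.random.default_rng(seed)
    m = draws.model
    flat = draws.flat()
    idx = rng.choice(flat.shape[0], size=min(n_rep, flat.shape[0]), replace=False)
    obs = _predictive_summary(data.trials, quantiles)

    counts = data.trials.groupby(["participant", "condition"]).size()
    reps = []
    for k in idx:
        X = flat[k, m.d_group:].reshape(m.n_participants, m.d_part)
        Xc, _ = m.part_constrain(X)
        V, A, W, T = m._vawt(Xc)
        frames = []
        for p, pid in enumerate(m.participants):
            for c in (1, 2, 3):
                n_pc = int(counts.get((pid, c), 0))
                if n_pc == 0:
                    continue
                # oversample to offset window censoring, then trim
                params = WienerParams(V[p, c - 1], A[p], T[p], W[p, c - 1])
                cc, rr = sample_trials(params, int(n_pc * 1.4) + 8, seed=rng)
                ok = (rr >= rt_window[0]) & (rr <= rt_window[1])
                cc, rr = cc[ok][:n_pc], rr[ok][:n_pc]
                frames.append(
                    pd.DataFrame({"participant": pid, "condition": c, "correct": cc, "rt": rr})
                )
        reps.append(_predictive_summary(pd.concat(frames, ignore_index=True), quantiles))
    stack = np.stack([r.to_numpy() for r in reps])
    cols, index = reps[0].columns, reps[0].index
    return {
        "observed": obs,
        "replicates": reps,
        "mean": pd.DataFrame(stack.mean(axis=0), columns=cols, index=index),
        "band_low": pd.DataFrame(np.percentile(stack, 2.5, axis=0), columns=cols, index=index),
        "band_high": pd.DataFrame(np.percentile(stack, 97.5, axis=0), columns=cols, index=index),
    }
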