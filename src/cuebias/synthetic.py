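"""Synthetic-study generator with known ground truth.

Emulates the cued random-dot-motion design: each participant completes
``n_blocks`` x ``trials_per_block`` trials, half preceded by a neutral
cue and half by a directional cue of which 80% are valid.  Choices and
RTs come from the Wiener diffusion process with participant-level
parameters drawn from truncated normals around group means, and a trait
score (AQ-like, integer 0-50) can be linked to a chosen participant
parameter at a configurable population correlation.

Generating model variants mirror the fitted models: ``M1_start``
(condition shifts the starting point), ``M2_drift`` (condition shifts
the drift rate), ``M3_both``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from cuebias.data import StudyData
from cuebias.wiener import WienerParams, sample_trials

__all__ = ["GroupTruth", "SyntheticConfig", "generate_participants", "generate_trials", "generate_study"]

# participant-level plausibility bounds (shared with the fitted models)
DELTA_BOUNDS = (-5.0, 10.0)
ALPHA_BOUNDS = (0.1, 5.0)
TAU_BOUNDS = (0.05, 1.0)
BETA_BOUNDS = (0.01, 0.99)

CONDITION_SIGNS = {1: 0.0, 2: 1.0, 3: -1.0}  # neutral, valid, invalid


@dataclass
class GroupTruth:
    """Population-level generating parameters.

    Defaults reproduce the published behavioral profile: drift around
    1.33 with large between-participant spread, boundary separation near
    1.0 and non-decision time near 0.42 s give ~79% neutral accuracy and
    ~0.60 s median correct RTs; a positive starting-point effect
    (theta_start * sigma_start = 0.05) makes valid trials faster and
    more accurate and invalid trials least accurate.
    """

    mu_delta: float = 1.33
    sigma_delta: float = 0.8
    mu_alpha: float = 1.0
    sigma_alpha: float = 0.2
    mu_tau: float = 0.42
    sigma_tau: float = 0.06
    theta_start: float = 1.0      # standardized starting-point effect
    sigma_start: float = 0.05     # residual SD of beta_p2
    theta_drift: float = 0.0      # standardized drift effect
    sigma_drift: float = 0.3      # scale of the drift effect


@dataclass
class SyntheticConfig:
    """Design and linkage settings for one synthetic study."""

    n_participants: int = 222
    n_blocks: int = 5
    trials_per_block: int = 40
    p_neutral: float = 0.5
    cue_validity: float = 0.8
    model: str = "M1_start"  # generating model: M1_start / M2_drift / M3_both
    truth: GroupTruth = field(default_factory=GroupTruth)
    trait_correlation: float = 0.0
    trait_target: str = "start_effect"  # start_effect | boundary | drift_effect
    trait_mean: float = 17.0
    trait_sd: float = 6.77
    censor_misses: bool = True       # drop RTs beyond the 1.5 s response window
    exact_condition_counts: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_neutral", "cue_validity"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_participants", "n_blocks", "trials_per_block"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not -1 < self.trait_correlation < 1:
            raise ValueError("trait_correlation must be in (-1, 1)")
        if self.model not in ("M1_start", "M2_drift", "M3_both"):
            raise ValueError(f"unknown generating model {self.model!r}")
        if self.trait_target not in ("start_effect", "boundary", "drift_effect"):
            raise ValueError(f"unknown trait target {self.trait_target!r}")


def _truncnorm_rvs(mean, sd, lo, hi, size, rng):
    if sd == 0:
        if not lo <= mean <= hi:
            raise ValueError("degenerate truncated normal outside bounds")
        return np.full(size, float(mean))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    if stats.norm.cdf(b) - stats.norm.cdf(a) < 1e-6:
        raise ValueError(f"truncated normal has <1e-6 mass in [{lo}, {hi}]")
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_participants(config: SyntheticConfig, rng=None):
    """Draw participant-level parameters and linked trait scores.

    Returns a DataFrame indexed by participant with columns delta_1..3,
    alpha, tau, beta_1..3, start_effect, drift_effect, aq.  The trait is
    drawn jointly with the chosen target parameter from a bivariate
    normal on the latent (pre-truncation) scale at the configured
    population correlation, then rounded and clipped to [0, 50].
    """
    rng = np.random.default_rng(config.seed if rng is None else None) if rng is None else rng
    g, n = config.truth, config.n_participants
    model = config.model

    delta_base = _truncnorm_rvs(g.mu_delta, g.sigma_delta, *DELTA_BOUNDS, n, rng)
    alpha = _truncnorm_rvs(g.mu_alpha, g.sigma_alpha, *ALPHA_BOUNDS, n, rng)
    tau = _truncnorm_rvs(g.mu_tau, g.sigma_tau, *TAU_BOUNDS, n, rng)

    if model in ("M1_start", "M3_both"):
        beta2 = _truncnorm_rvs(
            0.5 + g.theta_start * g.sigma_start, g.sigma_start, *BETA_BOUNDS, n, rng
        )
    else:
        beta2 = np.full(n, 0.5)

    if model in ("M2_drift", "M3_both"):
        shift = g.theta_drift * g.sigma_drift
        delta = np.column_stack(
            [
                _truncnorm_rvs(g.mu_delta + s * shift, g.sigma_delta, *DELTA_BOUNDS, n, rng)
                for s in (0.0, 1.0, -1.0)
            ]
        )
    else:
        delta = np.column_stack([delta_base] * 3)

    df = pd.DataFrame(
        {
            "delta_1": delta[:, 0],
            "delta_2": delta[:, 1],
            "delta_3": delta[:, 2],
            "alpha": alpha,
            "tau": tau,
            "beta_1": 0.5,
            "beta_2": beta2,
            "beta_3": 1.0 - beta2,
        },
        index=pd.RangeIndex(1, n + 1, name="participant"),
    )
    df["start_effect"] = df["beta_2"] - 0.5
    df["drift_effect"] = (df["delta_2"] - df["delta_3"]) / 2.0

    # trait linked to the target parameter through a Gaussian copula-style
    # conditional draw on the standardized target
    target = df[{"start_effect": "start_effect", "boundary": "alpha", "drift_effect": "drift_effect"}[config.trait_target]].to_numpy()
    rho = config.trait_correlation
    sd_t = target.std(ddof=0)
    z_target = (target - target.mean()) / sd_t if sd_t > 0 else np.zeros(n)
    if sd_t == 0 and rho != 0:
        raise ValueError(f"trait target {config.trait_target!r} is constant; cannot induce correlation")
    z_trait = rho * z_target + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    aq = np.clip(np.rint(config.trait_mean + config.trait_sd * z_trait), 0, 50)
    df["aq"] = aq.astype(int)
    return df


def _condition_sequence(config: SyntheticConfig, n_trials: int, rng) -> np.ndarray:
    if config.exact_condition_counts:
        n_neutral = int(round(config.p_neutral * n_trials))
        n_cued = n_trials - n_neutral
        n_valid = int(round(config.cue_validity * n_cued))
        conds = np.concatenate(
            [
                np.full(n_neutral, 1, dtype=np.int64),
                np.full(n_valid, 2, dtype=np.int64),
                np.full(n_cued - n_valid, 3, dtype=np.int64),
            ]
        )
    else:
        u = rng.random(n_trials)
        conds = np.where(
            u < config.p_neutral,
            1,
            np.where(rng.random(n_trials) < config.cue_validity, 2, 3),
        ).astype(np.int64)
    rng.shuffle(conds)
    return conds


def generate_trials(participants: pd.DataFrame, config: SyntheticConfig, rng=None) -> StudyData:
    """Simulate the trial table for generated participants.

    RTs beyond the 1.5 s response window are treated as misses and
    omitted when ``censor_misses`` is on, emulating the task deadline.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    n_trials = config.n_blocks * config.trials_per_block
    frames = []
    for pid, row in participants.iterrows():
        conds = _condition_sequence(config, n_trials, rng)
        rt = np.empty(n_trials)
        correct = np.empty(n_trials, dtype=bool)
        for c in (1, 2, 3):
            mask = conds == c
            if not mask.any():
                continue
            params = WienerParams(row[f"delta_{c}"], row["alpha"], row["tau"], row[f"beta_{c}"])
            cc, rr = sample_trials(params, int(mask.sum()), seed=rng)
            correct[mask], rt[mask] = cc, rr
        block = 1 + np.arange(n_trials) // config.trials_per_block
        df = pd.DataFrame(
            {
                "participant": pid,
                "block": block,
                "condition": conds,
                "correct": correct,
                "rt": rt,
            }
        )
        if config.censor_misses:
            df = df[df["rt"] <= 1.5]
        frames.append(df)
    trials = pd.concat(frames, ignore_index=True)
    cov = participants[["aq"]].copy()
    return StudyData(trials=trials, covariates=cov)


def generate_study(config: SyntheticConfig):
    """Generate a complete study; returns (StudyData, participant truth table).

    Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    participants = generate_participants(config, rng)
    data = generate_trials(participants, config, rng)
    return data, participants


def config_dict(config: SyntheticConfig) -> dict:
    """JSON/YAML-serializable view of the configuration (seed included)."""
    return asdict(config)
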