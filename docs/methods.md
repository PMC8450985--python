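# Methods

## The model

Choices and response times in the cued motion-discrimination task are
modelled as a Wiener diffusion process: evidence accumulates from a
starting point `β·α` toward one of two boundaries at 0 and `α`, with
mean rate `δ` (drift) and unit diffusion coefficient; the response time
is the first passage time plus a non-decision component `τ`.  Under
accuracy coding the upper boundary is the correct response, collapsing
left/right stimuli.  The diffusion coefficient is fixed at **s = 1**
(the Stan / Wabersich–Vandekerckhove convention); parameter values are
10× those reported under the older s = 0.1 convention.

The first-passage-time density is evaluated by the small-time and
large-time series expansions with the Navarro–Fuss truncation rule,
switching to the series that needs fewer terms at a raw tolerance of
1e−12 (absolute density error well below 1e−9 over the plausible
parameter range).  The closed-form absorption probability
`P(upper) = (1 − e^{−2δαβ}) / (1 − e^{−2δα})` is used for trial
simulation and as an independent cross-check on the density.

### Trial simulation

The default sampler draws the boundary from the closed-form choice
probability and the decision time by numerically inverting the
conditional CDF of the series density on a quadratically spaced grid
(4097 points covering all but ~1e−12 of the mass) — deterministic given
the density and exact to grid tolerance.  An independent Euler–Maruyama
path simulator (default step 1e−4 s, with a Brownian-bridge
within-step crossing correction that removes the O(√dt) first-passage
bias) serves as the simulation oracle in tests; the two samplers agree
in distribution.

## Hierarchical structure

Three variants, differing in how the cue condition (neutral / valid /
invalid) acts:

- **M1 (starting point)** — neutral β fixed at 0.5; valid trials use
  `β_p2 ~ TruncNormal(0.5 + θ σ_ε, σ_ε)` on (0.01, 0.99); invalid
  trials use `1 − β_p2` exactly (symmetric effect).  One drift per
  participant.
- **M2 (drift)** — per-condition drifts
  `δ_pc ~ TruncNormal(μ_δ + x_c θ σ_ε, σ_δ)`, `x = (0, +1, −1)` for
  (neutral, valid, invalid); β = 0.5 everywhere.  The drift effect is
  symmetric in the population mean; the standardized-effect scale σ_ε
  is a hyperparameter of the effect, and only the product θσ_ε is
  strongly identified — the reported "drift effect" is that product.
- **M3 (both)** — both mechanisms with separate (θ, σ_ε) pairs.

Participant-level parameters follow truncated normals around
population means: δ ∈ (−5, 10), α ∈ (0.1, 5), τ ∈ (0.05, 1) s,
β ∈ (0.01, 0.99).  Group priors (weakly informative on the s = 1
scale, configurable):

| parameter | prior |
|---|---|
| μ_δ | Normal(1.5, 2) on (−5, 10) |
| μ_α | Normal(1.5, 1) on (0.1, 5) |
| μ_τ | Normal(0.3, 0.25) on (0.05, 1) |
| σ_δ, σ_α, σ_τ | half-Normal(1) |
| θ (either effect) | Cauchy(0, 1/√2) |
| σ_ε (start / drift) | half-Normal(0.5) / half-Normal(1) |

The Cauchy(0, 1/√2) scale on the standardized effect follows the
Bayesian-ANOVA convention for effect sizes.

## Sampling

No gradient-based probabilistic-programming backend is assumed: the
sampler is blocked adaptive random-walk Metropolis on an unconstrained
parameterization (scaled-logit for interval-bounded parameters, log
for scales; each participant's τ is additionally capped just below
that participant's minimum RT, where the posterior has all its mass).
Each iteration does:

1. **Participant blocks** — all participants propose and accept/reject
   simultaneously (the likelihood factorizes given the group level).
2. **Group block** — two Metropolis sweeps touching only the
   hierarchical priors (cheap: no likelihood evaluation).
3. **One joint hierarchy move** (rotating over six kinds): shift a
   group mean together with all matching participant coordinates, or
   stretch the participant spread together with the group SD (a
   deterministic scale move with the appropriate Jacobian).  These
   moves are what lets a random-walk sampler traverse the
   mean-coupling and σ-funnel of a centered hierarchy at a usable
   rate.

Proposal step sizes (Robbins–Monro toward 0.25 acceptance) and
per-coordinate spreads adapt during burn-in only, so retained draws
come from a fixed transition kernel.  Initial values are uniform draws
within plausible sub-ranges of the admissible values.  The reference
schedule is 3 chains × 15,000 iterations with 6,000 burn-in (27,000
retained); tests and the acceptance script use reduced schedules
(typically 2 chains × 700–3,600 iterations, chosen as the package's
desk-scale defaults) and verify convergence via the Gelman–Rubin
statistic (classic by default, split-chain optional).

## Model comparison

Log marginal likelihoods come from warp-III bridge sampling on the
unconstrained space (so transform Jacobians are part of the target,
and the estimated constant is the marginal likelihood over all sampled
parameters, group and participant).  Posterior draws are split in
half; the first half fixes the warp (mean + Cholesky whitening), the
second half enters the optimal-bridge fixed point together with fresh
standard-normal proposal draws; skew is symmetrized by mixing each
draw with its sign-flipped image.  The fixed point is iterated in log
space to a relative tolerance of 1e−10 (cap 20,000 iterations), with
the plain importance-sampling estimate as the starting value (running
zero iterations reproduces importance sampling exactly, which tests
exploit).  Six repetitions with fresh proposals are pooled by median
and their SD reported.  On a 20-dimensional conjugate-normal benchmark
the estimator is accurate to well under 0.01 log units.

## Plausible values

For a chosen participant-level parameter (change in starting point
`β_p2 − 0.5`, boundary separation α, or the drift effect), 3,000
retained draws are subsampled; each draw's participant vector is
correlated with the trait score, giving plausible correlations r_k.
For each r_k the exact posterior of the population correlation ρ under
a stretched-beta prior (uniform on (−1, 1) by default) is computed
analytically — the bivariate-normal sampling density of r via its
hypergeometric form — on a 2001-point grid, and the single-draw
posteriors are averaged pointwise and renormalized.  Reported: the 95%
equal-tail credible interval and the Bayesian p-value, defined as
min(P(ρ > 0), P(ρ < 0)) (both one-sided masses are also reported).
The averaged posterior is never narrower than the posterior implied by
the mean r alone, which is the point of the procedure: posterior
uncertainty propagates into the population-correlation inference.

## Synthetic studies

The generator reproduces the study design: 222 participants (default),
5 blocks × 40 trials, half neutral cues, directional cues 80% valid,
condition counts assigned exactly within participant (Bernoulli
assignment available by flag).  Participant parameters are drawn from
the truncated normals above with generator defaults chosen to match
the published behavioral profile: μ_δ = 1.33, σ_δ = 0.8, μ_α = 1.0,
σ_α = 0.2, μ_τ = 0.42 s, σ_τ = 0.06, and a positive starting-point
effect θσ_ε = 0.05 — giving ~79% neutral accuracy, ~0.55–0.6 s median
correct RTs, and the valid > neutral > invalid accuracy ordering.  The
trait score is integer-valued (AQ-like), mean 17, SD 6.77, clipped to
[0, 50], and can be linked to a chosen parameter (start effect,
boundary, drift effect) at a target population correlation through a
conditional Gaussian draw on the standardized parameter.

RTs beyond the 1.5 s response window are marked as misses and dropped
by default, emulating the task deadline; recovery and calibration
experiments disable this censoring so that they measure estimation
error, not deadline truncation (the fitted likelihood does not model
censoring — a known limitation, relevant mainly for slow, low-drift
participants).

### What the generator does not emulate

Stimulus rendering, the QUEST staircase (coherence is absorbed into
drift), sequential and learning effects, trial-by-trial parameter
variability, contaminant/lapse responses, and item-level trait
measurement.  Passing recovery and calibration tests therefore shows
the estimator chain is correct under the model's own assumptions, not
that real data meet those assumptions.

## Numerical choices and degenerate inputs

- RT filter bounds inclusive: trials with rt < 0.2 s or > 1.5 s are
  removed; filtering is idempotent and reported per participant.
- Correlation CIs in behavioral summaries use the Fisher-z transform
  with variance 1/(n−3); undefined correlations (zero variance, n < 4)
  are reported as NaN with a warning.
- Truncated-normal log densities keep their normalizing constants
  (they depend on sampled group parameters, and bridge sampling needs
  absolute densities); the log-mass is computed in the mirrored tail
  when both truncation points fall in one Gaussian tail.
- Zero within-chain variance makes the Gelman–Rubin statistic 1.0
  (with a warning) if chains agree and ∞ otherwise.
- A participant whose minimum RT is at or below the 0.05 s lower τ
  bound cannot be fit and is rejected with an explicit error;
  participants with zero retained trials are excluded with a warning.
- |r| = 1 makes the analytic ρ posterior degenerate and is rejected;
  zero-variance plausible draws are dropped and counted.

## Design choices left open by the problem

- Whether M3 shares its effect parameters across mechanisms: separate
  (θ, σ_ε) pairs here.
- The exact neutral-condition drift in M2/M3: neutral sits at the
  population mean, valid/invalid symmetric around it.
- Bayesian p side: the smaller of the two one-sided masses.
- The bridge iteration cap applies to the fixed point (not the
  proposal size).
- Plausible-value draws are subsampled uniformly without replacement
  from the pooled post-burn-in chains (seeded).

## Known limitations

- Random-walk MCMC needs the joint hierarchy moves to mix and still
  mixes more slowly than gradient-based samplers; short schedules can
  leave R̂ above 1.05 for variance parameters (the pipeline warns).
- No across-trial variability parameters (sv, st0, sz) and no
  contaminant mixture, by design.
- The deadline censoring in the generator is not mirrored in the
  likelihood (see above).
- θ and σ_ε are separately only weakly identified for the drift
  effect; inference should focus on θσ_ε.
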