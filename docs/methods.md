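# Methods

This note documents the models implemented in `collective_rescue`, the
defaults and numerical choices, and what the synthetic-data pipeline
does and does not establish.

## Learning model

Each agent maintains value estimates Q over the K options, initialised
at zero, updated only for the chosen option by the Rescorla–Wagner rule
`Q ← (1 − α)Q + απ` with learning rate α ∈ [0, 1] and realised payoff π.
Choice is softmax with inverse temperature β ≥ 0, computed in log space
with max subtraction so arbitrarily large β cannot overflow.

Social influence takes one of two forms:

- **Decision biasing** (the default): the net choice probability is
  `(1 − σ)·softmax + σ·S`, where the conformist term
  `S_i = (N_i + 0.1)^θ / Σ_j (N_j + 0.1)^θ` is built from the option
  choice counts N displayed from the previous trial. The smoothing
  constant 0.1 keeps options chosen by nobody in play and makes θ < 0
  (anti-conformity) favour them. θ = 0 makes S uniform — added
  exploration with no frequency information; θ > 1 is disproportionate
  majority attraction.
- **Value shaping**: choice is plain softmax, but after the RW update
  every option's value moves by `σ(S_i − 1/K)`. The increment is
  zero-mean across options, vanishes for uniform counts, and reduces to
  plain RW at σ = 0. This additive form is this package's documented
  variant of belief-level social influence, not a claim about any
  external implementation.

Whenever no social information exists — the first trial, a lone agent,
or all co-players dropped out — the choice is pure softmax. This
generalises the first-trial rule and makes a group of one exactly
asocial. Displayed counts exclude the focal agent's own previous choice
by default (`include_self` flips this); the choice is behaviourally
minor but the exclusive form gives the clean solo limit.

The *hot stove index* α(β + 1) summarises susceptibility to learnt risk
aversion; on the canonical Gaussian task the asocial indifference curve
is β = (2 − α)/α, i.e. index = 2.

## Tasks

Five presets. `gaussian_2arm`: safe pays 1 constantly, risky pays
Normal(1.5, 1), horizon 150. Four experiment-style tasks (horizon 70)
use two-point risky arms in points — positive-RP 1-risky-1-safe
(50/550 at 0.7/0.3, EV 200, vs safe 150), 1-risky-3-safe (50/425 at
0.6/0.4 vs 150/125/100), 2-risky-2-safe (adds a suboptimal 50/238 at
0.6/0.4 arm, exact EV 125.2), and negative-RP 1-risky-1-safe (50/220 at
0.7/0.3, EV 101). Safe arms in these tasks carry Gaussian noise with
s.d. 5 points. Gaussian payoffs are never truncated; negative draws are
allowed.

Point payoffs are divided by 100 (`payoff_scale = 0.01`) before they
enter learning, so value estimates stay O(1) and fitted β of order 3–5
are meaningful; the raw points are what session tables record. The scale
is configurable because the original scaling convention is not
documented anywhere authoritative.

## Simulation engine

All replicate groups and agents advance in lockstep, vectorised over
(replicate, agent); a cell of 1,000 groups × 150 trials runs in tens of
milliseconds. Reproducibility comes from a single numpy Generator
consumed in a fixed trial-major order: identical (task, composition,
seed) gives bit-identical output. The engine was deliberately not given
per-agent generator substreams — order-independence is unnecessary when
the update order is itself deterministic, and per-agent streams would
forfeit vectorisation.

Summary statistics use the second half of the horizon, trials
t > ⌊T/2⌋ (t > 75 at T = 150, t > 35 at T = 70). Sweeps default to
1,000 replicate groups per cell; heterogeneous-composition runs default
to 20,000 replications, reduced in tests. The example heterogeneous
compositions (groups of five, one focal parameter varied, group mean
matched to α = 0.5, β = 7, σ = 0.3, θ = 2) encode the documented
majority structures; the exact member values are package choices.

## Population dynamics

The reduced model tracks NR (choosing risky) and NS−, NS+ (choosing
safe with negative/positive attitude to risk); NR splits algebraically
as NR+ = e·NR, so the risk-premium proxy e is enforced by construction
and the state vector has exactly three equations with
NR + NS− + NS+ = N conserved. Transition probabilities mix asocial rates
(ph towards the preferred option, pl away; 0 ≤ pl ≤ ph ≤ 1) with the
conformist frequency term in raw densities (no +0.1 smoothing —
densities are continuous and the empty-population case is excluded).
The asocial system has the closed-form equilibrium bias

    NR* − NS* = −n(ph − pl){(1 − e)ph − e·pl} / [(ph + pl){(1 − e)ph + e·pl}]

used as the oracle for the integrator.

Integration uses LSODA in chunks of 200 time units with rtol = atol =
1e-10 until max |dN/dt| < 1e-8 (t_max = 1e4; non-convergence is flagged,
never silent). Bifurcation scans integrate from every initial
NR(0) ∈ {0, …, N} with the safe density split evenly between attitudes,
cluster endpoints on NR* with a 0.1-individual distinctness tolerance,
and confirm stability by re-integrating from ±0.5-individual
perturbations along NR (safe density redistributed proportionally).
Degenerate edge: at exactly σ = 1, θ = 1 the NR-dynamics vanish
identically (every NR is neutrally stable), so the scan reports zero
*stable* equilibria there; the bifurcation structure on either side is
unaffected.

At e ≤ 1/2 the asocial system is never risk seeking, and modest social
weight keeps it that way; strong conformity (large σ with θ > 1) can
still sustain a risk-seeking herding equilibrium from a risky-majority
start — that branch is the classic bistable conformism regime, not a
contradiction.

## Synthetic experiments

`ExperimentDesign` emulates the statistical structure of a group bandit
study: groups drawn uniformly from sizes 2–8 (configurable), an optional
solo condition (σ fixed at 0), 70 trials, an optional per-trial dropout
hazard independent of behaviour (a dropped subject's remaining trials
are missing, and the counts shown to others reflect only members who
completed the previous trial), and the inclusion rule that keeps
subjects with ≥ 35 completed rounds.

Individual parameters come from a non-centred hierarchy: logit-normal α
and σ, log-normal β, normal θ. The default locations are the fitted
group-condition globals of the positive-RP two-armed task
(μ_logitα = −2.2, μ_logβ = 1.4, μ_logitσ = −2.4, μ_θ = 1.4). Population
spreads are not reported anywhere, so the package defaults to 1.0 on
each transformed scale — the conventional weakly informative
individual-difference magnitude for hierarchical RL models. What the
generator does **not** emulate: lobby/waiting-room mechanics, payment,
instruction effects, behaviour-dependent attrition, or any within-
session drift in strategy. Passing tests therefore establish internal
consistency of the generative/inference pair under this design, not
fidelity to any particular human dataset.

## Hierarchical Bayesian inference

The likelihood replays each subject's own choices and payoffs through
the learning rule, scoring the observed choice each trial (first trial
and no-information trials use the asocial term). Probabilities are never
clipped: an impossible choice scores −inf and a non-finite probability
raises. The replay kernel is numba-compiled; a pure-numpy replica is
kept and cross-checked in the tests.

Priors: Normal(0, 2) on the transformed-scale locations,
half-Student-t(4, 0, 1) on the scales, standard-normal non-centred
subject effects. θ's support is unbounded. Group and solo conditions are
fitted separately; the solo model has no (σ, θ) block.

The sampler is adaptive random-walk Metropolis within Gibbs:

1. per-subject joint proposals on z (vectorised across subjects, who are
   conditionally independent given the globals), two repeats per sweep,
   Robbins–Monro adaptation to ~0.3 acceptance during warmup;
2. component-wise proposals on global locations and log-scales
   (~0.44 target);
3. an interweaving step in the centred parameterisation: holding the
   subject-level effects η_i = μ + s·z_i fixed, μ is redrawn exactly
   from its conjugate Normal conditional and log s by a likelihood-free
   Metropolis step, then z is recomputed. This decouples the globals
   from z and removes the random-walk drift that the non-centred moves
   alone suffer when the data pin down η.

Defaults are 4 chains × 1,000 warmup + 1,000 draws; reduced settings
(2 × 500 + 500) are used for recovery runs and tests with the
diagnostic thresholds unchanged. Convergence is summarised by
rank-normalised R̂ and ESS (arviz); a fit is flagged `converged` only if
every monitored parameter has R̂ < 1.01 and the globals have ESS ≥ 500.
Reduced runs often fail that bar and say so; posterior means remain
serviceable for recovery-style summaries.

Per-subject WAIC is computed on the deviance scale,
`−2(Σ_t lppd_t − Σ_t var_draws(log p_t))`, from the per-trial pointwise
log-likelihood draws. Model comparison uses the random-effects Bayesian
model selection of Stephan et al. (2009): per-subject log evidence
approximated by −WAIC/2, a variational Dirichlet fixed point for the
model frequencies, and Monte-Carlo exceedance probabilities over that
Dirichlet. Individual-parameter summaries ("mean α" style) are
posterior means of the per-subject natural-scale parameters.

## Known limitations

- Individual-level σ and θ are weakly identified at realistic copying
  weights (population mean σ ≈ 0.1): over 70 trials the social term
  touches ~10% of choice probability mass, so per-subject posteriors
  shrink hard towards the population mean. Parameter-recovery
  correlations reflect this — α and β recover well (~0.6–0.8), σ
  moderately (~0.3–0.65), θ poorly (~0.0–0.3) at 60 subjects in groups
  of six. Group-level (global) parameters recover well regardless, with
  95%-interval coverage at the nominal rate.
- Posterior-predictive credible bands for group trajectories saturate:
  with six members the per-trial risky fraction takes seven values, and
  wider individual heterogeneity does not widen group-level bands
  (extremes average out within groups).
- The ODE model is an approximation for qualitative regime analysis; it
  is not calibrated to the learning model's parameters, and e, pl, ph
  have no closed-form mapping onto α, β.
- The Metropolis-within-Gibbs sampler trades efficiency for having no
  gradient dependency; very large datasets (thousands of subjects)
  would want a gradient-based sampler instead.

## Problem sizes used in the shipped checks

Simulation checks use 2,000 learners × 5,000 trials (indifference
boundary and threshold location), 1,000 replicate groups of five
(collective rescue, risk-premium contrasts), 21 social-weight points ×
21 initial conditions (bifurcation scan), 500 random parameter draws
(ODE closed-form oracle), and 60 subjects with 2 × 500 + 500 MCMC
(recovery and model selection). These sizes were chosen to make the
Monte-Carlo error comfortably smaller than each check's tolerance.
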