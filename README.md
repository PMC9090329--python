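# collective-rescue

Tools for studying how conformist social learning reshapes learnt risk
preferences in repeated experience-based choice — for behavioural
ecologists, cognitive modellers, and anyone analysing group bandit
experiments.

## The problem

Trial-and-error learners in risky multi-armed bandits systematically
drift into risk aversion: one bad draw from a risky option suppresses
further sampling of it, so the error is never corrected (the *hot stove
effect*). A Rescorla–Wagner learner with learning rate α updates the
value of the chosen option i by

    Q_{i,t+1} = (1 − α) Q_{i,t} + α π_t

and chooses by softmax with inverse temperature β. Risk aversion is
expected whenever α(β + 1) > 2 for the canonical task (safe arm pays 1;
risky arm pays Normal(1.5, 1)); the indifference curve is β = (2 − α)/α.

Copying the majority sounds like it should amplify that bias. This
package implements the counter-intuitive result that it often does the
opposite. Under *decision biasing*, the net choice probability mixes the
asocial softmax A with a conformist weight of the option choice counts
N observed from the previous trial:

    P_i = (1 − σ) A_i + σ (N_i + 0.1)^θ / Σ_j (N_j + 0.1)^θ

where σ is the copying weight and θ the conformity exponent. Modest σ
injects exploration that weakens the self-reinforcing avoidance of the
risky arm (negative feedback); once the majority flips, conformity locks
the group into favourable risk taking (positive feedback). The package
provides:

- **Agent-based simulation** of synchronous group sessions, parameter
  sweeps, heterogeneous compositions, and horizon comparisons
  (`simulate`).
- **A reduced population ODE** for the same dynamics — compartments NR,
  NS−, NS+ with exploitation/exploration rates ph ≥ pl and a
  risk-premium proxy e — including the closed-form asocial equilibrium
  and numerical bifurcation scans over the social weight σ (`ode`).
- **Synthetic experiment generation** mirroring a group bandit study
  design (group sizes 2–8 plus a solo condition, 70 trials, dropout, a
  ≥ 35-completed-rounds inclusion rule) from a hierarchical generative
  model (`synth`).
- **Hierarchical Bayesian inference**: an adaptive
  Metropolis-within-Gibbs sampler with interweaving on the non-centred
  hierarchy (logit-normal α and σ, log-normal β, normal θ), per-subject
  WAIC, random-effects Bayesian model selection with exceedance
  probabilities, parameter/model recovery harnesses, and posterior
  predictive simulation (`mcmc`, `inference`, `likelihood`).

## Worked example: the collective rescue effect

Agents with α = 0.5, β = 7 sit deep in hot-stove territory
(α(β + 1) = 4 > 2). Asocial learners mostly avoid the optimal risky arm;
the same learners in conformist groups of five recover it:

```python
import collective_rescue as cr

task = cr.make_preset_task("gaussian_2arm")
social = cr.simulate_groups(task, 0.5, 7.0, 0.3, 2.0,
                            n_replicates=1000, group_size=5, seed=7,
                            record_counts=False)
asocial = cr.simulate_groups(task, 0.5, 7.0, variant="asocial",
                             n_replicates=1000, group_size=5, seed=8,
                             record_counts=False)
print(f"conformist groups : {cr.prop_risky_second_half(social, task):.3f}")
print(f"asocial learners  : {cr.prop_risky_second_half(asocial, task):.3f}")
```

prints

```
conformist groups : 0.489
asocial learners  : 0.218
```

i.e. the second-half risky-choice proportion more than doubles (0.218 →
0.489) with a copying weight of only σ = 0.3 and conformity exponent
θ = 2, even though every individual is biased towards risk aversion.

The same question in the reduced population model:

```python
import numpy as np
from collective_rescue.ode import stable_equilibria_scan

scan = stable_equilibria_scan(N=20, e=0.65, pl=0.2, ph=0.7, theta=2.0,
                              sigma_grid=np.linspace(0, 1, 21))
print(scan["n_stable"].max())   # -> 2: bistability beyond a critical sigma
```

A command-line interface (`collective-rescue simulate|sweep|
heterogeneous|horizons|ode|generate|fit|compare|recover|posthoc`) runs
each stage from a YAML/JSON config and writes tidy CSVs plus a manifest
(config echo, seed, package version) next to its outputs.

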