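# fishmot

Simulation and hierarchical Bayesian analysis of multiple-object-tracking
(MOT) experiments with fish-like motion.

In an MOT task, observers covertly track several moving targets among
identical distractors; after the motion stops, one object is queried and the
observer judges whether it was a target. This package models a complete
within-subject tracking study in which the stimuli are either real aquarium
fish (which alternate waiting at one spot with sudden dashes), standard
constant-speed circles, or circles whose motion mimics the fish. It is aimed
at visual-cognition researchers who want to generate such stimuli, enumerate
counterbalanced trial designs, simulate observers, and estimate tracking
sensitivity and response bias with the field's standard hierarchical
signal-detection model — or who want to run parameter-recovery studies of
that whole analysis chain.

## The model

Responses follow an equal-variance signal-detection probit regression. A
"target" response to a query occurs with probability

    P(resp = target) = Φ(−c + d′ · X)

where Φ is the standard normal CDF, X indicates that the queried object
really was a target, d′ is sensitivity, and c is the decision criterion
measured from the distractor-distribution mean (larger c = more conservative,
miss-prone). Both parameters are linear in tracking load n with
per-participant random intercepts and slopes:

    d′_pi = α_d + δ_d[g] + a_p + (β_d + b_p) · n_i + γ_d · z_i
    c_pi  = α_c + δ_c[g] + u_p + (β_c + v_p) · n_i + γ_c · z_i

with deviation-coded condition offsets δ[g] (plus condition × load
interactions), optional trial covariates z (e.g. the number of sudden target
motions), N(0, 1) priors on population intercepts and slopes, and
half-normal(1) priors on the random-effect SDs. The posterior is sampled by
an exact data-augmentation Gibbs sampler (truncated-normal latents, joint
Gaussian coefficient updates, slice updates for the SDs), diagnosed with
split-R̂ and ESS.

Around that core: trajectory segmentation into waiting/dash phases with
gamma maximum-likelihood motion models, event-exact ballistic and fish-like
stimulus simulators in a circular arena, trial-design enumeration and
counterbalancing, Savage–Dickey Bayes factors, closed-form per-participant
d′, cross-condition prediction models and Bayesian R².

## Worked example

Simulate ten observers responding to the 138-trial single-session design
(23 stimuli × set sizes {1, 3, 5} × two query types) and recover their
sensitivity and bias:

```python
from fishmot import design, observer, inference

videos = [f"v{i:02d}" for i in range(23)]
trials = design.build_design_exp1(videos, seed=0)
pop = observer.PopulationParams()          # α_d=3.58, β_d=−0.50, α_c=1.97, β_c=−0.22
observers = observer.sample_observers(pop, 10, seed=1)
responses = observer.simulate_responses(observers, trials, pop, seed=2)
print(f"{len(responses)} responses, accuracy {responses['correct'].mean():.3f}")

post = inference.fit_sdt_probit(responses, seed=3)
summary = inference.summarize_dprime_bias(post, at_loads=[1, 3, 5])
print(summary.round(2).to_string(index=False))
```

Output:

```
1380 responses, accuracy 0.794
 load condition measure  mean  ci_low  ci_high
    1      None  dprime  3.05    2.33     3.73
    1      None    bias  2.05    1.70     2.46
    3      None  dprime  1.90    1.23     2.46
    3      None    bias  1.52    1.29     1.79
    5      None  dprime  0.75    0.05     1.37
    5      None    bias  1.00    0.73     1.28
```

The generating population had d′ = 3.08 and c = 1.75 at load 1, falling by
0.50 and 0.22 per added target; the posterior means and 95% credible
intervals recover that load gradient from 1,380 simulated trials. Sensitivity
near 3 at one target corresponds to ~93% accuracy; by five targets d′ ≈ 1
predicts ~70% — the intermediate-difficulty regime tracking tasks aim for.

A command-line interface mirrors the library
(`fishmot build-design`, `simulate-stimuli`, `simulate-responses`,
`fit-sdt`, `contrast`, `predict`, `run-all`, `make-fixtures`, ...); see
`fishmot --help`.

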