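# Methods

This note documents the models, simulation conditions, numerical choices
and known limitations of `fishmot`. It states nothing the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Trajectory segmentation

A trajectory is a uniformly sampled 2-D path (default 30 Hz). The
segmentation formalises the observation that aquarium fish alternate
hovering with sudden relocations: a **waiting phase** is a maximal run of
samples all lying within `radius_px` of the run's first sample (the
anchor), committed only if it lasts at least `min_wait_s`; everything
between committed waits is a **movement phase** whose distance is the
sampled path length, mean velocity distance/duration, and direction the
atan2 of net displacement. Defaults: `radius_px = 60` (the radius used for
real fish, whose hovering jitter is large) and `min_wait_s = 0.2` s, which
suppresses spurious single-frame "waits" at 25–30 Hz sampling.

The greedy anchored scan was chosen over alternatives (change-point
detection, HMMs) because it is deterministic, has two interpretable
parameters, and is checkable against an exhaustive maximal-interval
oracle — the suite verifies exact agreement on random trajectories.

Two systematic properties of this rule matter when interpreting fits:

* **Dash clipping.** The first `radius_px` of travel of every dash still
  lies within the anchor radius, so it is booked to the preceding wait.
  Wait durations are overestimated by ≈ radius/velocity and dash
  distances underestimated by ≈ radius.
* **Slow-dash absorption.** Any movement slower than
  `radius_px / min_wait_s` (300 px/s at the defaults) is
  indistinguishable from waiting under this definition and is segmented
  as such.

Consequently the round-trip validation (generator → segmentation → gamma
MLE, asserted to within 3 asymptotic SEs) is run in a regime where both
effects are negligible: zero waiting jitter, a 0.5 px radius, 200 Hz
sampling, and dash velocities well above the absorption threshold. With
the 60 px radius and realistic jitter the recovery is qualitative only,
and the waiting-time-fraction check uses the generator's ground-truth
phase log rather than re-segmented phases.

## 2. Gamma motion models

Wait durations, dash distances and dash velocities are each fitted with a
two-parameter gamma law (location fixed at 0) by maximum likelihood. The
profiled shape equation `log k − ψ(k) = log(mean) − mean(log x)` is solved
by Newton iteration on the digamma function, initialised with Minka's
closed-form approximation and safeguarded by a bisection bracket; the
scale follows as `θ = mean/k`. Samples with (near-)zero log-spread raise a
degenerate-sample error rather than returning a divergent shape. The test
suite checks the score equations vanish at the optimum and that the fit
beats a 200 × 200 grid search.

## 3. Stimulus simulators

Both generators live in a circular arena, default diameter 800 px. The
800 px circle was sized to match the area covered by fish motion in
960 × 600 px video frames; since it is taller than the frame, the default
scene is the 1920 × 1200 px display on which circle stimuli are shown.
Default kinematics: 10 s trials, 200 px/s ballistic speed, 16 px object
radius (circles subtending about 1°).

**Ballistic (traditional MOT).** Constant speed, specular reflection at
the border, and — in the traditional condition — object–object bounces.
Integration is event-driven: wall-hit and pair-contact times are roots of
the quadratics of straight-line motion, the state advances exactly to
each event, and the dt grid is read off the piecewise-linear path, so
there is no integration error. At pair contact each object reflects its
own velocity about the contact tangent: the relative normal velocity
reverses (no interpenetration) and each object keeps its speed exactly,
which an elastic normal-component *swap* would not guarantee for unequal
approach speeds; for the symmetric head-on case the two rules coincide.
Simultaneous events resolve in object-index order. Initial positions are
uniform with rejection for overlap; a packing error is raised when object
area exceeds 60% of the arena. An independent replay checker re-derives
speed constancy, path continuity, continuous-time containment and minimum
pair distance from the emitted path alone.

**Fish-like.** Each object independently alternates WAIT phases (duration
from the wait gamma; position performs a Gaussian random walk with step
SD `jitter_radius/4`, clipped to the jitter disc — a bounded jitter, not a
calibrated diffusion) and straight DASH phases (distance and velocity
from their gammas, direction uniform on [0, 2π)). A dash whose endpoint
would leave the arena has its direction resampled up to 100 times, then
its distance truncated at the border; because any interior point can
reach the centre, distances below the arena radius are never truncated
and the marginal distance law is preserved. No collision handling, since
real fish pass freely by one another. The generator can return its
ground-truth phase log alongside the sampled trajectories.

**Reference motion law.** When no fitted model is supplied, the default
gammas are wait ~ Γ(2, 0.25 s), dash distance ~ Γ(2.5, 60 px), dash
velocity ~ Γ(4, 25 px/s), jitter 3 px. These were chosen once to emulate
the headline motion statistic of real aquarium fish — roughly a 20%/80%
waiting/moving time split (wait ≈ 0.5 s, movement ≈ 2 s per cycle) — at
dash speeds of order 100 px/s inside the arena. A bounded arena with
*straight* dashes cannot jointly reproduce the 20/80 split and very fast
dash speeds; the split was prioritised. Real movement phases are curved,
multi-second meanders, which is the main feature this generator does not
capture; passing tests therefore validate the analysis chain, not the
realism of any single trajectory.

## 4. Experimental designs

*Session design A*: 23 stimuli × set sizes {1, 3, 5} × {target-query,
distractor-query} = 138 trials, target queries exactly 50%. *Session
design B*: per condition, 23 stimuli × loads {2, 4} × two query types =
92 trials; the fish condition reuses the same video at both loads while
circle conditions get condition-unique trajectory sets. Target sets are
drawn uniformly without replacement, independently per trial, and the
queried distractor uniformly among non-targets (the natural default where
the procedure leaves this open). Block order is counterbalanced
round-robin over all 3! = 6 orderings; trial order is an independently
seeded permutation per participant. Cue (3 s), fixation (75 ms) and
tracking (10 s) durations are recorded as metadata constants only.

## 5. Generative observer

The observer answers "target" with probability Φ(−c + d′X). The criterion
c is the distance of the decision threshold from the distractor-
distribution mean, so c > d′/2 produces miss-prone behaviour. This sign
convention was fixed because it is the one under which the reported
sensitivity/bias pairs reproduce the reported accuracies via the normal
CDF (e.g. d′ = 3.08, c = 1.75 → 93.4% at 50% target queries; d′ = 1.07,
c = 0.86 → 69.4%); the suite asserts both within 4 points. Load enters
uncentered, so β_d is the change per added target. Default population
values (α_d, β_d, α_c, β_c) = (3.58, −0.50, 1.97, −0.22) are the load-0
intercepts implied by the load-1 values above and the per-target
decrements; random-effect SDs default to (0.5, 0.1, 0.3, 0.05), chosen as
plausible between-participant spread (participant d′ SD about 0.5) for
recovery studies. Condition-specific participant deviations can be drawn
with an exchangeable cross-condition correlation ρ.

## 6. Hierarchical probit estimation

The probit likelihood is exactly the observer model, so fitting it to
simulated data is a closed-loop recovery test. All location parameters
(population intercepts/slopes, deviation-coded condition offsets and
condition × load interactions, covariates, and four random-effect
deviations per participant) are stacked into one Gaussian-prior design
and sampled by Albert–Chib data augmentation: truncated-normal latent
utilities (tail-stable inverse-CDF forms), an exact multivariate-normal
coefficient draw per iteration, and univariate slice updates on log σ for
each half-normal(1) random-effect SD. Every update is an exact
conditional draw, so no step-size tuning exists. Defaults: 4 chains ×
1000 warmup + 1000 kept draws; split-R̂ and bulk ESS are computed for all
reported parameters, with an optional hard gate at R̂ < 1.01.

Internally load and covariates are centered so the N(0, 1) intercept
prior acts at the design mean — the convention of standard Bayesian
regression software; draws are mapped back to the uncentered reporting
scale. Slopes are unaffected. Perfectly separated participants trigger a
warning and are handled by the priors; fitting a single participant
collapses the random effects toward their priors rather than failing.

Covariates may enter d′, c, or both; both is the default, with Bayes
factors reported separately, since the analysis of sudden-motion effects
examines sensitivity and bias side by side. The "odds ratio" reading of a
covariate effect is the exponentiated probit coefficient; both the raw
and exponentiated forms can be derived from the draws.

Condition contrasts average the two load-specific values per condition
within each draw before differencing, so the pooled contrast inherits
full posterior dependence and is antisymmetric by construction.

**Savage–Dickey Bayes factors.** BF₁₀ = prior density at 0 / posterior
density at 0, the latter from a Gaussian KDE with Silverman bandwidth.
The estimate is flagged unstable when fewer than 50 draws lie within one
bandwidth of zero (far-from-null posteriors), where the KDE tail is
unreliable but the qualitative conclusion (BF ≫ 1) is not.

**Exclusion rule.** Participants whose accuracy in the reference cell
(traditional MOT, two targets) is strictly below 50% are excluded; a
participant missing that cell is flagged, never silently kept or
dropped. A pure guesser over 23 such trials is excluded with probability
P(Bin(23, .5) ≤ 11) ≈ 0.5, which the suite verifies.

**Closed-form d′.** Per participant × condition × load,
d′ = Φ⁻¹(hit) − Φ⁻¹(fa) and c = −Φ⁻¹(fa), with 0/1 rates continuity-
corrected to 1/(2N); with population heterogeneity switched off the
hierarchical model agrees with this estimator within 0.1 at 10⁴ trials.

**Cross-condition prediction.** A multilevel Gaussian regression of one
condition's per-participant d′ on another's, with a deviation-coded
(−½, +½) load factor, its interaction with the predictor, and a
per-participant random intercept; N(0, 1) priors on coefficients,
half-normal(1) on both SDs, sampled with the Gaussian analogue of the
same Gibbs scheme. Bayesian R² is computed per draw as
Var(fitted)/(Var(fitted) + σ²) with fitted values including the random
intercepts. Note the random intercept can absorb between-participant
predictor signal, attenuating the slope when the predictor varies mostly
between participants; recovery checks therefore use a generating design
whose predictor varies within participants as well.

## 7. Simulation scales and runtimes

Recovery studies use the two study scales: 10 participants × 138 trials
(20 replicates for CI calibration; coverage of the four population
parameters asserted at ≥ 16/20 against the nominal 95%) and
50 participants × 92 trials × 2 conditions for contrast recovery, plus
52 participants for prediction/R² recovery. Reduced but converged sampler
settings (2 chains × 400 + 600) keep each fit under a few seconds; the
round-trip motion validation uses 10 objects × 200 s at 200 Hz. These
sizes give the calibration checks adequate power while keeping the whole
suite interactive.

## 8. Reproducibility

Every stochastic component takes an explicit integer seed; the pipeline
derives per-stage seeds from one root seed via `SeedSequence`, and
`run-all` output is asserted byte-identical across repeated runs. CSV
round trips are lossless (`float_precision="round_trip"` on read).

## 9. Known limitations

* The fish-like generator uses straight constant-velocity dashes and
  uncalibrated bounded jitter; it does not model schooling, curved
  meanders, occlusion by scenery, or background-dependent detectability.
* The probit model assumes equal-variance SDT, linearity of d′ and c in
  load, and Gaussian random effects; no lapse/guessing mixture or
  reaction-time model is included.
* The Savage–Dickey KDE estimator is accurate near the null but only
  order-of-magnitude for posteriors far from zero (flagged).
* Real-data posterior values from human experiments are not reproduced
  here; the package validates the machinery by parameter recovery on
  synthetic cohorts drawn from the implied population values.
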