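# Methods

## Model overview

The core hypothesis implemented here is that contingency learning is
causal discovery: an agent infers which of its binary actions a^k
influence a scalar stochastic outcome m by comparing the outcome
distribution conditional on each action state against the marginal
outcome distribution.  Under Pearl's do-calculus with no confounders,
p(m|do(a)) = p(m|a) when a causal link exists and p(m|do(a)) = p(m) when
the variables are independent, so any divergence between p(m|a) and p(m)
is evidence of causal influence.  The divergence used is the
Wasserstein-2 distance, giving the causal action influence score (CAIS)
C(m|a) = W2(p(m|a), p(m)).  W2 is a true metric (symmetric, triangle
inequality) and, expressed through quantile functions, reduces to an L2
distance ∫(q1−q2)²dτ that needs no density estimation.

## Distribution learning

Every distribution — two conditionals per limb plus one shared marginal,
nine in the four-limb default — is a vector of 49 free quantile values on
the grid τ = 0.02, 0.04, …, 0.98 (grids of other sizes use the symmetric
interior rule τ_i = i/(n+1)).  Values are trained one observation at a
time with the asymmetric quantile Huber loss: the quantile error weights
over-prediction by τ and under-prediction by 1−τ, and the Huber envelope
(κ = 1, quadratic within κ, linear beyond) bounds gradients against
outliers.  Optimization is per-quantile Adam with the standard moment constants
(β1 = 0.9, β2 = 0.999, ε = 1e-8) and a one-cycle cosine-annealed
learning rate from 0.03 at step 0 to
exactly 0 at the episode horizon.  The annealing doubles as a model of
diminishing exploratory engagement and stabilizes late-phase behavior; a
constant-rate mode is available for ablations.

Numerical choices:

* **Initialization** — all quantile values start at 0, the baseline
  outcome mean: a neutral, reproducible start.
* **Quantile crossing** — independent per-quantile updates can cross
  transiently.  Readers that need an ordered quantile function (CAIS,
  surprise, entropy) sort at read time (`monotone_view`); the learnable
  parameters are never constrained, leaving the optimizer untouched.
* **Update cadence** — the marginal absorbs every outcome; each limb's
  conditional for the state actually taken absorbs that outcome, so
  exactly k+1 distributions update per step.
* **Tail behavior** — with κ = 1 and outcomes of scale 0.3, the loss
  operates in its quadratic regime, where its expected minimizer for a
  tail level τ is an expectile-like point with weight ratio (τ/(1−τ))²
  rather than the exact quantile; the extreme learned values therefore
  settle slightly beyond the true 2%/98% quantiles.  The unit tests check
  the tails against the analytic expected-loss minimizer; the median is
  recovered to high accuracy, and all downstream scores depend only on
  the sorted values.
* **W2 quadrature** — the τ-integral is a trapezoid rule over the grid
  normalized by the grid span, which keeps a pure location shift exact on
  any grid and agrees with an independent quadrature oracle to machine
  precision.

## Action selection, surprise, and smoothing

A limb's engagement score is the mean of its two state scores; the
baseline causal inertia is the mean over all 2k state-action pairs and
acts as the causal cost of inaction.  Movement probability is the sigmoid
of (engagement − inertia), so adding any constant to every score leaves
behavior unchanged and all-equal scores give p = 0.5.  Limbs are sampled
as independent Bernoulli draws.

Surprise is the width of the quantile interval of the learned
distribution into which the observed outcome falls — an inverse local
density, so no negation is needed.  Outcomes outside the learned range
clamp to the outermost interval, keeping the signal bounded.  The
surprise of each limb is read from the conditional of the state that limb
actually took (configurable to the marginal), weighted by α, and added to
the engagement before the inertia is recomputed as the mean of the
adjusted engagements — a uniform surprise across limbs therefore cancels
in the sigmoid.  Both engagements and inertia are smoothed by an
exponential moving average with ε = 0.03 from the third step on (the
paper-stated t > 1 condition); smoothing the inertia alongside the
engagements keeps their difference smooth.  α = 0 disables the mechanism;
α = 10 is the default for extinction-burst experiments and can be read as
an individual-differences parameter.

## Alternative agents

**Direct reinforcement (babybot)** — tabular movement probabilities
initialized at 0.2; a limb that moved and was followed by an outcome
above 2.5 gains 0.01, a limb that moved without such an outcome loses
0.005 (read as additive probability changes; a multiplicative mode exists
behind a flag).  Limbs that did not move are unchanged, and *any* moved
limb is reinforced on a suprathreshold outcome — this purely temporal
credit assignment is what produces spurious-correlation learning.
Probabilities clamp to [0.001, 1.0]; the nonzero floor avoids an
absorbing state that would freeze learning entirely.

**Controllability** — same distributional machinery, but the per-limb
score is the entropy change from acting, H(m) − H(m|a^k = 1), with H a
Vasicek-style estimator: the mean log-slope of the monotone quantile
function over the grid intervals (spacings floored at 1e-6 before the
log).  Scoring the *active* state is what gives the heuristic its
characteristic stability bias — averaging both states' entropy
differences would approximate a mutual information, which is positive
whenever the action changes the distribution and hence could not exhibit
the documented bimodal failure.  The general symmetric form
(1/|A|)Σ_a[H(m) − H(m|a)] remains available as `metrics.controllability_score`.

## Environments

One step represents 0.5 s.  The mobile paradigm runs baseline 200 /
connect 1000 / disconnect 800 steps; outside connect, outcomes are
baseline noise N(0, 0.3) regardless of actions.  During connect the
contingent law applies when the connected limb (chosen uniformly at
random per run and recorded in the trace header) is active — or, in the
inverted variant, when it is *inactive* (the mobile moves by itself and
halts on action).  Contingent laws: N(5, 0.3) standard; an equal mixture
of N(−2, 1) and N(2, 1) in the bimodal variant; N(μ, 0.3) in the mean
sweep.  Scale parameters are read as standard deviations; a `scale_is_variance`
flag flips the reading for sensitivity checks under the variance
interpretation.

The vocalization paradigm has a single binary action and four phases —
baseline 1 (partial feedback), social response (contingent feedback),
extinction (no feedback), baseline 2 — with a partial-feedback
probability of 0.7 for vocalizations in the baseline phases (matching a
typical caregiver response rate during familiarization).  Feedback
magnitudes reuse the mobile laws (N(5, 0.3) / N(0, 0.3)), and phases
default to 250 steps each (5 min at 50 steps/min), the order of magnitude
of the experimental protocol being emulated; both are configurable.  With one action the engagement equals the inertia, so
movement probability stays at 0.5; the scientifically meaningful output
is the per-phase mean engagement score, which rises in the social phase
and rises further during extinction (the vocal extinction burst).

## Experiments and aggregation

Episodes record, per step: phase, actions, outcome, per-limb movement
probability, raw and smoothed engagement, surprise, inertia, and learning
rate.  Replicates (default 5) run with consecutive seeds; per-limb series
are aligned by relabeling each run's connected limb to index 0 before
computing per-step means and standard deviations.  The mean sweep reports
the connected limb's movement probability at the final connect-phase step
per agent family and μ.  Burst and jump statistics use fixed windows
(last 100 connect steps vs first 100 disconnect steps for engagement;
50-step windows for surprise) — the window lengths are analysis choices
that make the transient burst a testable quantity.  `overlay_scale`
converts the step axis to minutes (steps-per-minute is a per-experiment
setting, since different overlays equate 100 or 120 steps with one
minute of infant behavior) and fits a
single least-squares magnitude factor against a user-supplied empirical
series; no infant data ship with the package.

## What the simulations do and do not show

The synthetic environments capture phase-switched stochastic
contingencies with scalar outcomes and binary ballistic actions.  They do
not model embodiment, high-dimensional perception, graded motor control,
non-contingent (experimenter-driven) stimulation, or social reciprocity
beyond a fixed feedback probability.  Passing tests therefore demonstrate
the internal coherence of the causal-discovery account and its
qualitative separation from the reinforcement and controllability
baselines under these idealized conditions — not quantitative fits to
infant data.

## Problem sizes

The default episode is 2000 steps with four limbs (nine learned
distributions) and runs in well under a second; the test suite and the
acceptance battery use five replicate seeds per condition, full-length
episodes throughout, and 10,000 draws for the distribution-recovery
check.
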