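# Models and methods

`metadelegate` simulates and fits the computational machinery of a social
decision-making study: a two-alternative dot-magnitude judgment performed
under personal (Self) or shared (Group) responsibility, with incentivized
confidence reports and, in one task variant, the option to delegate the
decision to experts of known accuracy. The scientific claims the machinery
supports are (i) that responsibility for others lowers decision confidence
through a metacognitive bias rather than through changed sensory evidence,
and (ii) that a confidence-based value comparison with a subjective
delegation preference explains who delegates and how often. Because no
human dataset ships with the package, everything is validated on synthetic
data generated by the package's own task and agent models: parameter
recovery, analytic oracles, and boundary identities take the place of
empirical replication. What passing tests show is that the estimators
recover what the generators planted at realistic trial counts — not that
any particular human population behaves this way.

## Task and synthetic data

The task presents two circles, one with 50 dots and one with 50 + c,
c ∈ {2, 4, …, 24} (12 difficulty levels). A session holds 10 trials per
level per condition — 120 trials per condition, 240 in all — arranged in
blocks of 10 trials of one condition, pseudo-randomly intermixed so that no
more than three consecutive blocks share a condition (found by rejection
sampling of block orders, which is fast because roughly half of all orders
already satisfy the constraint). The delegation variant crosses the same
structure with two expert accuracies (70% and 90%), giving 480 trials.
Confidence is reported on {50, 60, …, 100} percent. Dot layouts are drawn
uniformly inside 7.7 cm circles; the geometry is stored for fidelity but no
model consumes it.

Synthetic agents compose three generative stages:

* **Choice and RT** come from the collapsing-bound diffusion model below,
  with drift signed by the correct side (stimulus coding: the upper bound
  is the "left" response).
* **Confidence** comes from the metacognitive model. By default the
  confidence stage is *coupled* to the choice: the sensory decision value is
  drawn from the side of the DDM's response (a truncated normal), so choice
  and confidence share one evidence channel. An *independent* mode draws the
  decision value unconditionally. The study's models are fit to choices/RTs
  and to confidence separately, so either coupling is consistent with them;
  coupled is the default because a single-channel observer is the more
  parsimonious reading, and the flag documents that this was a free choice.
* **Delegation** applies the normative model's soft decision rule
  (logistic in the value difference) to an internally generated confidence.

Between-subject variability in `default_agents` is mild Gaussian jitter on
the DDM bound, drift, and nondecision time and on sensory noise (chosen so
simulated accuracy spans roughly 60–95% across difficulty, the usual
psychometric range for this stimulus family). Features of real data the
generator does not emulate: sequential dependencies (post-error slowing,
confidence drift), fatigue, and any direct effect of the block structure on
behavior.

## Collapsing-bound drift-diffusion model

Evidence x(t) starts at x0, accumulates with drift v = v0 + v1·ln c and
unit diffusion (the conventional scale fix), and is absorbed at ±u(t) with

    u(t) = max(B0 − ⌊t/l⌋·h, 0),

a staircase that drops h evidence units every l seconds. The typeset source
for this bound admits a linear reading (B0 − (t/l)·h); the staircase matches
the verbal definition of l and h as step length and step height and is the
default, with `collapse="linear"` available. RT is crossing time plus a
nondecision time; with 5% probability a trial instead comes from a uniform
non-DDM process (fair coin over responses, RT uniform over the response
window). Undecided trials at the horizon resolve by the sign of accumulated
evidence and are counted as a diagnostic.

Three backends must agree and are tested against each other:

1. a vectorized Euler–Maruyama simulator (default dt = 1 ms);
2. a transition-matrix propagation of the binned evidence density between
   the time-varying bounds. Bins straddling the bound stay active with
   their source point at the midpoint of their overlap with (−u, u), which
   conserves mass exactly; at each bound drop, stranded mass absorbs by its
   sign. Propagated at the same dt, this backend targets the same
   discrete-time law as the simulator (Kolmogorov–Smirnov distance < 0.02
   at 10⁵ simulations at dx = σ√dt/4);
3. the closed-form fixed-bound absorption probability
   P(upper) = (1 − e^(−2v(x0+B0)))/(1 − e^(−4vB0)) for the h = 0 limit.
   Discrete-time simulation overshoots the boundary by O(√dt), so oracle
   comparisons at dt = 0.5 ms carry about half a percentage point of
   systematic slack on top of Monte-Carlo error.

Fitting maximizes the lapse-mixture likelihood built from backend (2). Both
stimulus signs ride one propagation (a right-stimulus trial is the mirror
image of a left one with the starting point negated and the boundaries
swapped). Box bounds: B0 ∈ (0.3, 3], l ∈ [0.05, 1], h ∈ [0, 2],
v0 ∈ [−2, 2], v1 ∈ [0, 3], ndt ∈ [0.1, 1], x0 as a fraction (−0.9, 0.9) of
B0, lapse fixed at 0.05. The search has three stages: (1) differential
evolution at a coarse grid (dt = 20 ms), seeded with a data-driven start
(drift slope read off the accuracy psychometric at unit bound, nondecision
time just under the fastest 2% of RTs); (2) a profile grid over the
collapse parameters (l, h) with a simplex over the five smooth parameters —
the collapse profile sits on a likelihood ridge that free 7-dimensional
search localizes poorly; (3) an adaptive simplex polish of the best
candidates at a finer grid (dt = 10 ms). The final stage matters: the
coarse grid carries a resolution bias that drags the drift slope down along
the v0–v1 ridge (verified by comparing generating-parameter and fitted
likelihoods across grid resolutions). Even at the exact optimum the
v0–v1 trade-off leaves the drift slope noisy in a single 960-trial fit, so
recovery is asserted on the median error over seeded replicate subjects
(below 20% for v1 and ndt); the bound profile itself (B0, l, h) recovers
well once the fine polish is in place. For the same ridge reason the
sensitivity analysis swaps the collapsing-bound parameters jointly rather
than one at a time.

## Metacognitive process model

Five parameters: sensory noise σ_s and bias b_s (the psychometric stage),
report noise σ_m, and two evidence biases — multiplicative m (neutral 1)
and additive a (neutral 0), both acting on the absolute decision value
*after* the choice, so they can move confidence without touching accuracy.
The decision value is y ~ N(±ln c + b_s, σ_s); the choice is its sign;
metacognitive evidence is z = max(m·|y| + a, 0); the confidence link is the
ideal observer's posterior probability of being correct for a known
stimulus magnitude,

    conf = 1 / (1 + exp(−2·|ln c|·z / σ_s²)),

which maps to [0.5, 1] and yields the calibration identity — mean
confidence equals accuracy at every level — exactly when (m, a, σ_m) are
neutral, by the law of total expectation. Report noise is normal on the
confidence scale, censored to [0.5, 1], and rounded to the nearest of the
six report bins (edges at 0.55, 0.65, …, 0.95 with censoring mass at the
extremes). The cited modeling framework this simplifies leaves its link
function and bin treatment unspecified in the source; the choices above are
documented as this package's own and are not asserted to be bit-compatible
with any external implementation. Placing the dominant metacognitive noise
at the report stage follows the study's stated configuration.

The fit is maximum likelihood: a binomial choice term from the psychometric
function and a confidence term that integrates the binned report
distribution over the truncated decision-value density (Gauss–Legendre,
61 nodes), from multi-start L-BFGS-B within bounds. Wald intervals come
from the numerically observed information; they are approximate and used
only for coverage-style checks, not for inference on real data.

## Normative delegation model

Action values: delegating is worth the expert's accuracy (confidence in
others), leading is worth one's own confidence, rewards fixed at 1. The
decision variable is Δ = Q_delegate − Q_lead + ϕ_d with a subjective
preference ϕ_d; the trial-level rule is a hard step (delegate iff Δ > 0,
ties lead — consistent with the lead bias such data show, arbitrary but
fixed). Three fitted variants: constant ϕ_d = α; confidence-dependent
ϕ_d = −β·c_self with β ≥ 0 (the stated negative direction carried as a
nonnegative magnitude so the Uniform(0, 10) prior support and the sign
constraint coexist); and their combination. With only two expert levels no
variant is built on confidence-in-others; instead α posteriors are compared
across expert levels.

Fitting uses per-level aggregates — mean confidence and delegation
proportion per stimulus strength, subject, condition, and expert level —
with a binomial likelihood through a logistic in link_scale·Δ̄. The slope
link_scale is a free positive parameter (half-normal(10) prior): a
unit-slope logistic over Δ̄ ∈ [−1.5, 1.5] cannot reach the extreme
proportions aggregates display. Hierarchy: subject-level α (and β) normal
around population means with half-normal(1) scales, population priors
α ~ Uniform(−10, 10), β ~ Uniform(0, 10), sampled non-centered to avoid the
hierarchical funnel. Sampling is an affine-invariant ensemble MCMC with
differential-evolution moves (defaults: 8000 steps, half burn-in, thinned;
walkers-as-chains split-R̂ ≤ 1.05 flags convergence — a conservative
diagnostic for correlated walkers, so near-threshold values are reported
rather than hidden). The deviance trace over retained draws gives
DIC = D(θ̄) + 2·p_D with p_D = ½·Var[D(θ)].

A note on identifiability: with a 90% expert, a strongly negative α puts
every aggregate deep in the never-delegate regime and the likelihood goes
flat below a threshold; recovery scenarios therefore generate with a gentle
link slope (3) so that delegation events actually occur and the population
mean is informed by data rather than by the prior.

`expected_final_accuracy` evaluates the policy's overall correctness
(experts on delegated levels, own accuracy on led ones). Under calibrated
confidence the neutral preference ϕ_d = 0 attains the maximum,
mean(max(confidence, expert)) — the package's property tests verify this
over random confidence profiles. Leave-one-out prediction of final accuracy
from |ϕ_d| uses per-subject straight-line fits; note that under the null
(feature unrelated to accuracy) the LOO correlation is biased *negative*,
not zero — the held-out prediction approximates the training mean — so the
null check asserts absence of positive skill.

## Confidence incentive

The matching-probability rule draws n1 uniform on 1..100; a report above n1
pays on correctness, otherwise a second draw n2 pays iff n2 ≤ n1. The
continuous idealization of the expected reward is E = r·[p·s + (1 − p²)/2],
maximized uniquely at truthful p = s (∂E/∂p = r(s − p)). The discrete
lottery introduces an O(1/100) granularity gap that the Monte-Carlo
comparison tolerates explicitly. Reports below 50% are rejected at the
interface because the task's scale starts there, though the formula extends
lower.

## Statistical layer

Twelve Bayesian hierarchical (generalized) regressions cover accuracy,
confidence, log RT, and delegation on condition, standardized difficulty,
and design covariates (task variant, simulation type, trial index, recalled
responsibility, expert level, and stated interactions; one spec operates on
per-level change scores). Priors are N(0, 1) on intercepts and slopes with
N(0.5, 1) on the difficulty slope; subject-specific coefficients attach to
every regressor except difficulty; defaults are three chains of 2000
retained draws. Confidence enters standardized across the dataset's trials;
the trial index is standardized as well so its slope lives on the same
prior scale. Each effect reports the posterior median, the 95% credible
interval, and P_MCMC — one minus the posterior probability that the effect
lies on the side of zero of its point estimate.

The instrumental-variable model treats stimulus strength and condition as
instruments for confidence: a Student-t confidence stage on the instruments
and a Bernoulli-logit delegation stage on the *instrument-predicted*
confidence (the exclusion restriction — only instrument-driven confidence
variation reaches the delegation stage), fit jointly per expert level with
t3(0, 1) priors on intercepts and slopes, Exponential(1) on the confidence
scale, and Gamma(2, 0.1) on the degrees of freedom. Because the delegation
task elicits no confidence, trial confidence is merged from the matching
(subject, condition, difficulty) forced-choice cell mean, standardized.

All samplers in this layer are the same ensemble MCMC as the delegation
model's (the stated chain/draw counts are honored as retained-draw counts;
the underlying ensemble runs longer and is thinned). Whether stage-1
confidence should be standardized is not fixed by the source; the merge
helper standardizes, and the model accepts any fixed scale.

The parameter-swap sensitivity analysis transplants a named subset of
Group-fitted parameters into the Self parameter set, simulates a fresh
dataset (Self = Self fit, Group = hybrid), and re-runs the regression that
measured the original effect — log RT for the DDM, confidence for the
metacognitive model, delegation for the delegation model. Interdependent
parameters (the collapsing bound's B0, l, h) are swapped jointly. Two
identities hold by construction and are enforced in tests: swapping every
parameter reproduces the full simulated condition effect, and swapping none
yields a null effect.

## Problem sizes and numerical defaults

Desk-scale defaults used by the test suite and the acceptance script — the
package's own choice of sizes at which the checks are sharp: 960 trials per
DDM fit (two per-level replicates of the full design ×40), 1200 trials per
metacognitive fit, 40 subjects × 12 levels × 10 trials per delegation
stratum, 20 subjects × 36 trials for the IV model, 10–12 subjects for the
sensitivity simulations with single-chain reduced-draw regressions.
Tolerances follow the oracle structure: 3 Monte-Carlo standard errors
against closed forms (plus the stated discretization slack), ±20% on the
sharply identified DDM parameters, 95% credible-interval coverage for the
Bayesian recoveries. Degenerate inputs are flagged, not silently fit:
constant confidence pins the report noise at its bound, split-R̂ > 1.05
marks a sampler flag, a violated mass balance in the first-passage solver
raises.

## Known limitations

* The collapsing-bound likelihood is a discretized approximation; its
  resolution is chosen for the ±20% recovery targets, not for
  RT-distribution work at millisecond precision.
* The metacognitive link is one defensible choice among several; fitted
  bias parameters are comparable within this package, not across packages.
* The ensemble sampler mixes slowly in the flat all-delegate/all-lead
  regimes of the delegation posterior; the split-R̂ flag should be checked
  before trusting strata with few delegation events.
* Hierarchical regression R-hat is computed across independent chains (or
  split halves when a single chain is run); with the reduced settings used
  in tests it is a smoke check, not a publication-grade diagnostic.
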