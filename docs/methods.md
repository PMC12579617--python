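# Methods

This note documents the models, defaults, and numerical choices behind
`ensemble-ddm`, in the spirit of a package methods appendix.  It states no
empirical result that the test suite or `scripts/acceptance.py` do not
themselves compute.

## The task and its synthetic emulation

Each trial presents eight face morphs indexed by an integer emotion value
(EV) from 0 (anchoring fearful) to 100 (anchoring happy).  The generator
reproduces the design's stimulus structure exactly:

- **Neutral condition** — eight *distinct* integer EVs, each obtained by
  drawing a continuous Normal(50, 10), rejecting draws outside [30, 70],
  rounding to the nearest integer, and redrawing on collision with an EV
  already in the ensemble.  Distinctness is interpreted as distinct
  integers; since 41 integers are available the redraw loop always
  terminates.  The first accepted draw of each ensemble follows the
  truncated Gaussian exactly; later draws condition on distinctness, which
  leaves the mean at 50 by symmetry but slightly flattens the marginal —
  the distributional test therefore targets the first draw.
- **Fearful / happy conditions** — two uniformly chosen positions are
  replaced by the extreme pair {0, 10} or {90, 100}, with the assignment of
  the two values to the two positions randomised.
- **Sessions** — a general-attention phase with 100 trials per stimulus
  condition (300 total), followed by a specific-attention phase with twice
  as many trials split between alternating fear- and happy-attention
  blocks.  We use two blocks per attention condition when the counts divide
  evenly (the block count is not dictated by the design description) and
  randomise which attention condition leads, standing in for
  counterbalancing across subjects.  Orderings are uniform shuffles
  rejected until no (actor, stimulus-condition) pair runs longer than three
  consecutive trials; rejection keeps the distribution exactly uniform on
  the constrained set and fails loudly after a retry cap for degenerate
  inputs.

Behaviour is generated from a four-parameter DDM whose structure follows
the winning model specifications for this task family: drift depends on the
stimulus condition (bottom-up evidence), boundary separation on the
attention condition (top-down caution), midpoint start, one non-decision
time per subject.  Generating group values default to

| parameter | value | rationale |
| --- | --- | --- |
| v (fearful / neutral / happy stimuli) | +0.55 / +0.02 / −0.40 | published group estimates for the general task (fear-side-up coding) |
| a (general / fear / happy attention) | 1.46 / 1.55 / 1.40 | published condition estimates (the happy-arm analysis pairs 1.48 with 1.40) |
| t_er | 0.13 s | the value consistent with the published condition mean RTs once closed-form mean decision times at the parameters above are subtracted (0.12–0.13 s across conditions) |
| w | 0.5 | unbiased start; the task gives no reason for bias |
| between-subject SDs | 0.3 (v), 0.15 (log a), 0.05 (log t_er) | plausible heterogeneity at which desk-scale recovery runs finish; not estimated from data |

What the generator does *not* emulate: post-error slowing, fatigue or
learning drifts, fast guesses and other contaminant processes, and any
subject-level correlation between parameters.  Passing recovery tests
therefore demonstrates that the estimation machinery is correct and well
calibrated under the model, not that the model captures every feature of
real data.

**Centred cohorts.** In recovery studies the sampled between-subject
deviations are re-centred to mean zero on each transformed scale, so the
realised cohort average equals the generating group value.  The estimand of
a recovery study is the group location; without centring, a 20-subject
cohort's true mean differs from the nominal truth by ~SD/√20, which is
sampling noise of the cohort, not error of the estimator.  Set
`center=False` to emulate a fresh population draw.

## Diffusion kernel

The likelihood is the Wiener first-passage-time density of a unit-diffusion
drift process between absorbing boundaries, computed through the standard
dual series: a small-time expansion in images of the starting point and a
large-time eigenfunction expansion.  The branch and truncation order are
chosen per evaluation so the truncation error of the normalised density is
below `eps` (default 1e-10).  The upper-boundary density is evaluated as
the lower-boundary density of the sign-flipped process.  The noise
coefficient is fixed at 1, which sets the scale of `v` and `a`; no
across-trial variability parameters (sv, st, sz) are included — the model
family under study never invokes them, and the reaction-time ceiling is the
only robustness device.

**Simulation.** Paths advance by Euler–Maruyama steps
`x' = x + v·dt + sqrt(dt)·N(0,1)` (default `dt = 1e-4` s).  Plain Euler
systematically *misses* within-step boundary crossings, which biases
first-passage times upward by O(√dt) — measurably so against the analytic
density at any affordable step size.  We therefore add the Brownian-bridge
correction: after each non-crossing step the path is absorbed with the
bridge crossing probabilities `exp(−2(a−x)(a−x′)/dt)` (upper) and
`exp(−2xx′/dt)` (lower), reducing the bias to O(dt).  Observed crossings
interpolate the crossing instant linearly; bridge crossings use the step
midpoint.  With the correction, `dt = 1e-3` passes Kolmogorov–Smirnov
checks against the analytic distribution at n = 10⁵ and is used for bulk
cohort generation; a 30 s cap flags runaway paths, which callers resample
by default.

Closed forms used as oracles (and for initialisation): absorption
probability `P(upper) = (1 − e^{−2vaw}) / (1 − e^{−2va})` (limit `w` at
v = 0, evaluated piecewise to avoid overflow) and unconditional mean
decision time `(a·P(upper) − z)/v` (limit `z(a − z)`), derived from
optional stopping.

## Hierarchical model and sampler

Subject-level parameters are Normal on transformed scales — identity for
drifts, log for `a` and `t_er`, logit for `w` — around group means with
group SDs.  Group priors (weakly informative relative to the magnitudes
this task produces): means Normal(0, 5) for drifts, Normal(log 1.5, 1) for
log boundary, Normal(log 0.3, 1) for log non-decision time, Normal(0, 1)
for logit start; SDs Half-Normal(1).  Placing the boundary and
non-decision-time priors on the log-scale means keeps them conjugate with
the log-normal hierarchy; they are broad enough that the data dominate at
the trial counts used anywhere in the package.

The four specifications: Model 1 (general-attention trials, drift by
stimulus, `w = 0.5` fixed); Models 2–4 add one specific-attention condition
and let drift (2), starting point (3), or boundary separation (4) depend on
attention, all keeping the stimulus-dependent drift.  Model 2's drift
dependence defaults to the full stimulus × attention crossing (six cells);
an additive variant (stimulus cells plus one attention offset) is available
via `drift_structure="additive"` since the coarser description admits both
readings.  Models 2 and 4 keep the midpoint start fixed, matching the
one-parameter-per-mechanism design logic.  In the happy-attention analyses
the upper boundary is the happy decision; the recoding from the canonical
stored coding (fear side up) happens inside the model builder so drift
signs are never hand-flipped.

**Updates per iteration.**  Subject values: per-family Gaussian
random-walk proposals for all subjects at once, accepted subject-wise from
a single vectorised density call over the family's trials (per-trial
log-likelihoods are cached and patched on acceptance).  Group means: exact
conjugate Normal draws.  Group SDs: random-walk Metropolis on the log
scale.  Proposal scales adapt in batches of 25 iterations toward 44%
acceptance during burn-in and are frozen afterwards, so the retained chain
is a valid Markov chain.  Initial values come from per-subject heuristics
(boundary near 1.5, non-decision time below the subject's fastest response,
drifts from the choice fraction through the closed-form absorption
probability) with per-chain jitter so multiple chains start dispersed.

The reference protocol stores (5000 − 2500)/5 = 500 draws per chain; the
desk-scale protocol used by the recovery recipes and the acceptance script
(2 chains × 2000 iterations, burn-in 1000, thin 2) stores the same 500
draws per chain at roughly a quarter of the cost.  Two chains are run by
default so the Gelman-Rubin diagnostic is well defined; convergence is
declared when every stored parameter's R-hat ≤ 1.1.

## Model comparison and hypothesis testing

DIC uses the Spiegelhalter form: `D̄` is the mean stored deviance (−2 log
likelihood over all trials), `pD = D̄ − D(θ̄)` with `θ̄` the posterior mean
of the subject-level parameters on the sampling (transformed) scale, and
`DIC = D̄ + pD`.  Negative `pD` is reported with a warning, never hidden.
The winner is the DIC minimum.  R-hat is the classic potential-scale-
reduction statistic; the split-chain refinement is available but off by
default to match the classic definition.  Directional hypotheses use
`q = P(θ_A > θ_B | data)` over paired pooled draws, ties counting half
(unbiased under exchangeability), declared significant two-tailed when
`min(q, 1 − q) < .025`.  Published DIC magnitudes from the original
cohort anchor ordering logic only; they are not reproducible from
synthetic data and the package never targets them numerically.

## Validation layer

Posterior predictive checks simulate full replicate datasets (default 200)
from random joint posterior draws, apply the 4 s exclusion, and compare
observed condition-wise choice proportions and RT quantiles
{.1, .3, .5, .7, .9} per boundary against the predictive 95% intervals.
Recovery studies simulate a cohort from known group values (default 20
subjects), fit, and report per-parameter error and credible-interval
coverage; fits with any R-hat > 1.1 are flagged rather than silently
pooled.  The statistic set is configurable; the defaults are the
field-standard summaries.

## Behavioural statistics

Fear-side decision proportions count "Fearful" choices under general- and
fear-attention instructions and "Not Happy" choices under happy-attention
(each complementary to its opposing label); empty cells propagate NaN.
The 3×3 repeated-measures ANOVA is computed through `statsmodels`'
`AnovaRM` (each effect tested against its own subject-by-effect
interaction, no sphericity correction by default, matching the uncorrected
degrees of freedom convention); partial eta squared is
`F·df1 / (F·df1 + df2)` ≡ `SS_effect/(SS_effect + SS_error)`, with a 90%
CI from noncentral-F inversion.  Post hoc contrasts are paired t tests on
marginal means with Cohen's d from the SD of difference scores (the d
variant is not dictated by convention; both raw and Tukey-adjusted p are
emitted, the latter from the studentized range over the factor's three
levels).  The test suite checks the whole decomposition against an
independent from-first-principles sums-of-squares oracle.

## Problem sizes and tolerances

Recovery experiments run at 20 subjects × 100 trials per design cell
(Model 1: 300 trials/subject; Model 4: 600), the scale at which one fit
completes in well under a minute on a single core and group-mean recovery
error is dominated by subject-level estimation noise (empirically ~0.04 SD
for drifts).  The model-selection check runs one full-scale replicate plus
two at 12 subjects × 60 trials per cell.  Simulator-versus-closed-form
checks use 10⁵ paths per parameter point at `dt = 1e-3` against 3-binomial-
SE bounds; density normalisation is verified to 1e-6 by adaptive
quadrature.  Anxiety covariate analyses and image-level stimulus processing
are out of scope.

## Known limitations

- The sampler is single-site Metropolis within Gibbs; strongly correlated
  subject-level parameters (e.g. `a` with `t_er`) mix more slowly than a
  gradient-based sampler would, which is why convergence is always gated on
  R-hat rather than assumed.
- DIC is reported because it is the comparison statistic of record for
  this model family; no WAIC/LOO alternatives are provided.
- The generator's between-subject spreads are stipulated, not estimated;
  recovery calibration statements hold at those spreads.
- Reaction-time units are seconds throughout; parameter magnitudes assume
  the unit-diffusion scaling convention.
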