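# Methods

## Task generator

The simulator reproduces the horizon task's generative statistics.  Per
trial, each option's true mean is drawn independently and uniformly on
[3, 7] drops; draws closer than 0.05 drops (one observer-grid step) are
resampled so the options are always distinguishable in principle.  Outcomes
are Gaussian with SD 1.5 around the true mean, rounded half-up to the
nearest integer and clamped to [0, 10] — outcomes are displayed (and paid)
as whole drops of juice, and a finite integer support is what the
observer's summations assume.  The observation phase has 4 informative
samples; exactly half of a session's trials get the equal 2/2 split and
half the 3/1 split, assigned by shuffling a balanced label vector over the
session (the balance is exact per session, not Bernoulli), with the
3-sample side chosen uniformly.  Horizons (1 vs 4 choices) alternate in
blocks of 5 trials with a random starting block.  The feedback condition
(partial/complete) is a per-session constant.  Sessions must have a trial
count divisible by 2x the block length so both balances are exact; the
default is 150 trials, and the default dataset layout is 3 animals x 13
sessions per feedback condition, matching the scale of the kind of
experiment this pipeline is designed for.  Trial-event timings are carried
nowhere: they do not enter any computation.

Simulated choice-making agents invert the two choice models: at each choice
they build exactly the regressors the design builder would (the regressor
definitions live in one place, `design.py`, and are shared), apply their
coefficient vector, pass the linear predictor through a logistic, and mix
in an optional lapse (uniform random choice, default 0; the lapse exists to
stress-test fitting and is not part of the behavioral model).  Outcomes for
both sides are drawn every choice; the unchosen outcome is recorded, and
enters the agent's beliefs, only under complete feedback.

### Study-like agent defaults

The default generative coefficients (`study_agent_params`) encode the
qualitative behavioral pattern this paradigm is built to detect, at
ordinary logistic-regression scales: EV weight 0.8 (partial) vs 1.2
(complete); a positive EV-by-horizon interaction (0.25) in partial only, so
the EV weight is lower when information is useful and choice-contingent;
mild risk aversion (U weight -0.1); a repetition bias stronger in partial
(0.8 vs 0.5 on subsequent choices); equal chosen-update weights (0.6); and
a counterfactual-update weight (0.5) only where counterfactual feedback
exists.  These values are design constants of the synthetic study, chosen
once; recovery tests measure how well the pipeline retrieves them.

## Ideal observer

Beliefs about an option are a posterior over candidate means on a grid
(default 0 to 10 in steps of 0.05 — the full outcome range, because the
observer only knows what the screen can show, not the generative mean
range) with a uniform prior, likelihood given by a Gaussian kernel
evaluated at the integer outcome support and normalized per candidate mean.
Evaluating at support points (rather than integrating bins) keeps the
normalization exact and differs from bin integration only at second order
for sigma = 1.5.  Posteriors are computed in log space from outcome
multiplicities and renormalized via logsumexp; the posterior predictive is
the likelihood mixture; EV and U are the predictive's mean and variance.
The predictive is symmetric for symmetric evidence, so using its mean
rather than its mode changes nothing in those cases and is well defined in
all others.

Three belief *streams* are maintained along a trial, per side: (a) the
observation-phase baseline, (b) baseline plus own-choice outcomes revealed
so far, and (c) stream b plus counterfactual outcomes (complete feedback
only; under partial feedback b and c coincide).  Stream values at choice k
use only feedback revealed strictly before choice k.

Numerical checks backing the implementation: a naive direct-product
enumeration oracle agrees with the log-space path to 1e-8 on the posterior
mean; with a dense grid and a wide outcome support the predictive variance
after n identical observations matches the conjugate closed form
sigma^2 (1 + 1/n) to within 0.2%; on the bounded 0-10 support the deviation
from the closed form (0.5-5%, shrinking with n) is pure
truncation/discretization, shared exactly with the enumeration oracle.

## Design matrices

First-choice rows code: intercept (side bias), repetition bias RB (+1/-1
for the previous completed trial's last choice; 0 at a session's first
trial), horizon (+1 short / -1 long), right-minus-left EV and U differences
from stream (a), and the two horizon interactions.  An `info_count` variant
replaces the U difference by the right-minus-left informative-observation
count (uncertainty and information count are monotonically related on first
choices, so this is the model-free version of the same regressor).
Subsequent-choice rows (choices 2-4, long horizon only) code: intercept,
within-trial RB, a signed right-minus-left choice count, stream-(a)
baselines, chosen-feedback changes (stream b minus baseline) and
counterfactual changes (stream c minus stream b), all right-minus-left.
Regressors are left in natural units by default (coefficients are
interpretable per drop and per drop^2); recovery tests run unscaled.
Mirroring every trial left-right negates every non-intercept regressor and
flips the response — an exact antisymmetry the tests assert.

## Hierarchical fit

The likelihood is Bernoulli-logit.  Fixed effects: one coefficient vector
per animal-by-condition cell.  Random effects: per-session coefficient
vectors drawn, coefficient-wise, from Gaussians centered on the session's
cell fixed effect with per-animal, per-coefficient SDs (independent across
coefficients by default; a full covariance was deliberately left out — it
is rarely identifiable at 13 sessions per cell).  Priors are weakly
informative and fixed in the package rather than inherited from any
particular fitting framework: Student-t(3, 0, 2.5) on fixed effects,
half-Student-t(3, 0, 2.5) on random-effect SDs; inference is meant to be
likelihood-dominated and the recovery tests confirm that it is at the
default data scale.

Sampling is the package's own adaptive Hamiltonian Monte Carlo
(`horizontask.mcmc`): analytic gradients, non-centered random effects,
jittered leapfrog trajectories (target path length 1.2, capped at 32
steps), dual-averaging step-size adaptation targeting 0.8 acceptance, and a
diagonal mass matrix estimated from the middle warmup window with a
conservative step-size restart afterwards.  Energy errors above 1000 count
as divergences.  Chains are initialized at a per-cell ridge-logistic
solution.  Convergence is summarised with arviz split-R-hat and ESS per
fixed effect and random-effect SD; R-hat > 1.05, ESS < 400, or any
divergence raises a flag on the result (never silently passes).  With
truth-zero session variability the random-effect SDs sit in a funnel at
tau ~ 0 and their R-hat is often the flagged one; the group-level fixed
effects mix well, which is what the calibration tests measure.  The
paper-scale 12 chains x 1,000 draws is the `FitConfig` default; tests and
the acceptance script run 2 chains x 150-250 draws after 250-300 warmup,
which the recovery results show is enough for group-level inference at
these data sizes.

Non-identifiable designs are rejected up front: any non-intercept constant
column (e.g. the counterfactual columns in a partial-feedback-only design)
is named in the error, and single-column perfect separation is detected.
Multivariate separation is left to the divergence/R-hat flags.

Posterior-count inference: one-sided p = fraction of draws on the null
side of zero, with draws exactly at zero counted against the hypothesis;
p = 0 is reported as "< 1/N".  Group-level estimates average cell
posteriors per draw across animals (and conditions); arbitrary weighted
cell contrasts are supported, including the two headline contrasts —
complete-minus-partial on the EV weight, and the short-minus-long EV gap
within a condition, which under the +/-1 horizon coding equals twice the
EV-by-horizon coefficient.

## Behavioral metrics

Accuracy is model-defined: a choice is correct when the chosen side has the
strictly higher EV under the stream available at that moment (baseline for
first choices, full stream (c) thereafter).  EV gaps below 1e-6 drops are
ties — distinct evidence multisets can produce numerically equal EVs — and
are excluded from the denominator rather than scored 0.5.  Session-level
proportions are averaged across sessions; group tests are two-sided
one-sample t-tests over sessions.  Within-horizon trends z-score both the
choice index (1-4 for accuracy, 2-4 for repetition) and the session's
per-index means before taking the OLS slope; since both variables are
z-scored the slope is symmetric in which is called predictor.  Sessions
with a constant quantity have no slope and are dropped with a count
reported.  Psychometric curves bin first choices by the EV difference in
bins symmetric about zero, with binomial standard errors; empty bins are
reported missing, not zero.

## What the synthetic data do and do not show

The generator reproduces the task's marginal structure (outcome
distributions, information splits, horizon blocks, feedback contingencies)
and the agents are exactly the fitted model run generatively, so recovery
tests validate the *pipeline* — regressor construction, the hierarchy, the
contrasts, the posterior-count calibration — under correct model
specification.  They cannot detect model misspecification of real
behavior: real animals may lapse non-uniformly, drift across sessions, use
learning rules other than the ideal observer, or couple coefficients across
conditions.  Passing tests therefore mean the analysis retrieves what it
is pointed at, not that the model is true of any animal.

## Known limitations

- The HMC sampler uses fixed-length jittered trajectories, not dynamic
  (NUTS-style) ones; heavily correlated or funnel-shaped posteriors beyond
  the non-centered hierarchy used here may mix poorly.
- Random-effect correlations across coefficients are not modelled.
- The pipeline reads only its own CSV session format; converters for other
  log formats are out of scope.
- No reaction-time, eye-tracking, session-stability, or neural analyses.
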