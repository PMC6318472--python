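# Methods

This note documents the models implemented in `chokelab`, the choices made
where the design was genuinely open, and what the synthetic cohorts do and
do not establish about real data.

## The behavioral model

### Choking statistic

For one participant in one appraisal condition, let `p(I)` be the success
proportion at incentive `I ∈ {0, 25, 50, 75, 100}` dollars. The choking
score is

    C = 100 · ( max_I p(I) − p(100) )    [percentage points]

It is zero exactly when performance peaks at the maximum incentive and
positive otherwise, so its distribution has an atom at zero and a
continuous positive part — the reason the regression stage uses a censored
model rather than OLS. The statistic is invariant to permuting or
duplicating trials within cells (it depends only on proportions), never
decreases when failures are added at the $100 cell, and never increases
when successes are added there. Scores are expressed in percentage points
so regression coefficients are readable on the percent scale.

### Censored regression (Tobit) with a random participant intercept

Each participant contributes one score per condition. The latent-index
model is

    y*_it = x_it'β + u_i + ε_it,   u_i ~ N(0, τ²),  ε_it ~ N(0, σ²)
    y_it  = max(y*_it, 0)

with covariates: intercept, condition (baseline = 0, reappraisal = 1),
mean-corrected loss aversion `λ_i − λ̄`, and (by default, droppable) their
interaction. The marginal likelihood integrates `u_i` by Gauss–Hermite
quadrature, 32 nodes by default, doubled until the log-likelihood is
stable to 1e−6 (nodes capped at 256). Setting `random_intercept=False`
fits the pooled Tobit, which is the exact τ = 0 special case.

Numerics: σ and τ are optimised on log scale by BFGS; initialisation is
OLS on the uncensored rows (σ from their residual SD, τ from the
between-participant SD of mean residuals), with up to three seeded jitter
restarts on non-convergence; a still-unconverged fit is returned flagged
rather than raised. The covariance is the inverse observed information
(central-difference Hessian of the log-likelihood in the natural
parameters at the optimum), and inference is Wald with normal reference —
no small-sample correction. Degenerate inputs fail loudly: an all-censored
response or a rank-deficient design raises instead of returning NaNs.

Expected outcomes use the censored-normal mean

    E(y | x) = Φ(x'β/σ)·x'β + σ·φ(x'β/σ),

and the partial effect of reappraisal is `E(y | condition=0) −
E(y | condition=1)` at mean loss aversion. By default this is evaluated
conditional on `u_i = 0` (the average participant); a variant that
marginalises over the fitted `N(0, τ²)` by quadrature is available
(`marginalize=True`). The conditional version is the default because the
quantity of interest is phrased for an average individual, not a
population average of a nonlinear function.

### Loss aversion

Mixed 50/50 gambles (gain `g`, loss `l`) are accepted with probability
`logistic(0.5·(g − λ·l)/ν)`, where ν is a choice-noise temperature in
dollars. `(λ, ν)` are estimated by maximum likelihood on log scale with λ
constrained to [0.05, 10] (multi-start L-BFGS-B). All-accept or all-reject
choice sets are non-identifiable: the estimate is pinned at the relevant
bound and flagged, never raised. Estimates at a bound carry an exclusion
flag and such participants are dropped listwise from analyses involving
loss aversion; no imputation is attempted.

## The skin-conductance model

### Canonical response kernel

The canonical skin-conductance response function is a gamma density in
shifted time: shape k = 3, scale θ = 1.7 s, onset latency L = 0.5 s,
support 30 s, normalised to unit peak so fitted amplitudes read as
response sizes in microsiemens. The mode sits at L + (k−1)θ = 3.9 s, the
stereotyped time-to-peak of event-related electrodermal responses; the
tail at 30 s is below 1e−3 of peak. The first temporal derivative is
obtained analytically and scaled by the same normalisation constant;
including it absorbs small latency shifts. The parameters are exposed in
the API for sensitivity analyses.

### Convolution convention

Drivers are boxcars of height 1 over each event's duration, and the
discrete convolution carries the dt factor (integral convention); an
event shorter than one sample is a unit-area impulse. This makes
amplitudes invariant to the sampling rate and makes an amplitude-1
impulse produce a response whose maximum equals the kernel peak. The
generator and the design builder share one convolution routine, so a
noiseless generated trace is exactly representable by the GLM when the
generating amplitude model lies in the design span.

### Preprocessing

A causal (unidirectional, single-pass) Butterworth band-pass with
cut-offs 0.05 and 5 Hz is applied at the 100 Hz acquisition rate, before
downsampling — the 5 Hz upper cut-off equals the post-decimation Nyquist
bound, so the order of operations matters. Filter order defaults to 1
(gentle roll-off conventional for skin conductance), configurable.
Downsampling keeps every 20th sample (first sample kept, no
interpolation); non-integer rate ratios are rejected.

### Design matrix and GLM

Three epoch boxcars (incentive presentation with its per-trial 2–5 s
duration; motor task, 2 s; intertrial interval, 1–7 s) plus, at the
incentive and task epochs, parametric modulators for performance
(success = 1), condition (reappraisal = 1) and incentive (dollars/100),
their three two-way products and the three-way product: 17 drivers, each
convolved with the kernel and its derivative → 34 columns. Modulators are
mean-centered within participant before products are formed (centering is
standard practice for parametric interactions and keeps main effects
interpretable); the ITI boxcar carries no modulators. A modulator that is
constant within a schedule yields an all-zero centered driver and is
dropped with a warning. Per-participant fitting is ordinary least squares
with an intercept; rank deficiency raises with the offending columns
named.

The follow-up analysis recodes trials into the 8 cells of condition ×
outcome × incentive level (high = $100 by default; high = {$75, $100}
supported as a robustness variant) as 0/1 indicator drivers at the task
epoch (16 columns). The task boxcar is omitted from that design because
the cells partition the task trials; the incentive and ITI boxcars can be
prepended as nuisance drivers (the pipeline does).

### Group statistics

Group effects are two-tailed one-sample t-tests of per-participant
amplitudes against zero (df = n−1); cell comparisons are paired t-tests
on within-participant differences; the arousal–behavior coupling is a
simple regression of one per-participant difference score on another
(slope t-test with df = n−2, Pearson r reported). The headline tests use
the kernel (not derivative) amplitudes; derivative columns are treated as
nuisance. p-values are raw — no multiplicity correction — and degenerate
inputs (zero variance, n too small) raise errors rather than emitting
NaN.

## The synthetic cohort generator

The generator emulates the study conditions the analysis is designed
for: 38 participants, three runs of alternating baseline/reappraisal
blocks (10 trials per block), five incentive levels, 20 trials per
condition × incentive cell, incentive presentation 2–5 s, task 2 s, ITI
1–7 s, conductance at 100 Hz. All draws are namespaced per participant by
stable hashing of (seed, participant id, stream), so every generator is a
pure function of (config, seed) and adding a participant does not perturb
the others.

Success probability is

    p(I, cond) = clip( base_skill + facilitation · g(I) − choke(I, cond), 0, 1 )

where g(I) = min(I, 75)/75 − 1 rises from −1 at $0 to 0 at the $75
saturation point (so `base_skill` *is* the peak success probability and
facilitation is the $0→$75 gain), and the choke term equals `choke_depth`
at $100 in baseline and `choke_depth · reappraisal_attenuation` at $100
under reappraisal. Defaults: base_skill ~ U(0.55, 0.85) (thresholded
motor tasks are tuned to intermediate success rates), facilitation
~ U(0.05, 0.15), choke_depth ~ N(0.15, 0.05²) clipped to [0, base_skill]
and tilted by loss aversion (+0.03 per unit λ above the median — loss
aversion moderates choking), reappraisal_attenuation = 0.25 (an
approximately four-fold reduction of expected choking, the magnitude of
reduction the intervention is meant to produce). λ ~ lognormal(median 2,
σ = 0.4), never emitting the sentinel values 0 and 10 that mark excluded
estimates.

Conductance amplitudes (μS): incentive epoch 0.30 + 0.30·I/100, task
epoch 0.20 + 0.20·I/100, ITI 0.05. Failed trials at the $100 incentive
add a hyperarousal burst of 0.40 μS at the task epoch in the baseline
condition, abolished (attenuation 0) under reappraisal — selective to
high-incentive failures, so low-incentive failure cells stay null. The
burst is scaled by the participant's relative choke depth, coupling
sympathetic arousal to behavioral choking. All of a participant's
amplitudes are multiplied by a lognormal gain (σ = 0.8), reflecting the
large between-person heterogeneity of electrodermal responsiveness; white
noise SD is 0.10 μS at 100 Hz with a 0.001 μS/s tonic drift (removed by
the high-pass). Note the thresholded hyperarousal term is deliberately
*outside* the span of the linear parametric modulators: the GLM detects
its projection on the three-way interaction, as it would with a real
nonlinear effect.

The gamble generator uses the same logistic choice model as the
estimator, over a 140-gamble grid (gains $4–40, losses $2–28) with a $5
temperature — dense enough that λ is recovered to ~±10% at realistic
noise.

An optional mechanistic trial simulator integrates a damped mass-spring
(mass 1, stiffness (2π)² for a ~1 Hz natural frequency, damping ratio
0.2) coupled to a finger cursor driven by a noisy PD controller (10 ms
semi-implicit Euler steps, 2 s horizon; success requires both cursors
inside the target and slow at the horizon). It is not used to produce
outcomes by default — the downstream analyses consume only
success/failure, so Bernoulli sampling from the performance model is the
default mechanism — but it provides a physically grounded alternative for
experimentation.

### What the synthetic cohorts do not show

Passing tests on these cohorts demonstrate that the estimators and tests
are correct, calibrated and powerful *under the generating model*:
Bernoulli outcomes with a fixed per-cell probability, exactly
kernel-shaped conductance responses, Gaussian noise, no movement or
electrode artifacts, no non-stationarity beyond linear drift, no serial
dependence of performance (fatigue, learning), and loss aversion acting
only through the linear choke-depth tilt. Real recordings violate all of
these to some degree; results here bound what the pipeline can do under
favorable conditions, they do not certify field performance.

## Problem sizes used in the checks

The validation suite exercises: the choking oracle on 10⁴ random rows;
Tobit/OLS equivalence at n = 400 uncensored rows; parameter recovery on
25 cohorts of 200 participants (β = (14, −6, −1), σ = 10, τ = 5) with
type-I error over 200 pooled fits of 60 participants; the censored-mean
formula against 10⁶ Monte-Carlo draws; GLM recovery and calibration at
n = 38 with 20 power replicates and 2000 null replicates (the null
replicates reuse each participant's design and solve it against many
noise realisations at once — identical least-squares algebra, vectorised);
and 25 default plus 40 null end-to-end pipeline runs. These sizes were
chosen to give stable Monte-Carlo estimates of the rates being asserted
while keeping the default test run a desk-scale job.
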