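# Methods

`bartsim` simulates and analyzes a risk/reward-decoupled variant of the
Balloon Analog Risk Task (BART). This note documents the models the package
implements, the parameters that matter, the numerical choices behind them,
and what the synthetic-data machinery does and does not establish.

## Task model

A balloon inflates through `n_pictures = 128` discrete growth steps over a
`balloon_duration_ms = 6000` ms window, so each picture is on screen for
Δ = 46.875 ms; picture *k* covers the interval ((k−1)Δ, kΔ] and a response at
time *t* maps to picture ⌈t/Δ⌉. Each trial belongs to one cell of a 2×2
risk × reward design, announced by a 500 ms cue and followed by a 250 ms
fixation and a 2500 ms feedback phase.

Explosion probability is cumulative in the picture index:

- low risk: p(k) = k/128;
- high risk: p(k) = min(1.5·k/128, 0.99) for k < 128 and p(128) = 1.

The 1.5 multiplier saturates at the 0.99 plateau from picture 85 onward.
One consequence worth knowing: at picture 127 the low-risk ramp (127/128 =
0.9922) slightly exceeds the high-risk plateau (0.99). The schedules are
kept exactly as specified rather than patched for monotone ordering between
risk levels.

Reward is linear in the picture index: r(k) = 5k cents (low reward) or 25k
cents (high reward). Rewards attach to the *reward* level of the 2×2 design;
because the expected-value argmax is invariant to scaling r(k) by a
constant, both reward levels share one optimal cash-out per risk level
(`optimality_invariance_check` asserts this for any schedule).

A trial is resolved by a single uniform draw *u* at the response picture:
explosion iff u < p(k) (strict inequality, so p = 0 never explodes and p = 1
explodes almost surely). A cash-out pays r(k); an explosion pays nothing.
An agent that never responds is scored at picture 128 and therefore
explodes. Condition order is pseudorandom with exact per-condition counts
and no condition three times in a row, built by sequential sampling over the
still-available conditions with bounded restarts on (rare) dead ends.

## Expected value and outcome variance

With the single-draw rule, cashing out at picture *k* is a Bernoulli gamble,
so EV(k) = r(k)(1 − p(k)) and Var(k) = r(k)² p(k)(1 − p(k)). For the default
schedules the EV argmax is picture 64 (3000 ms) under low risk and picture
43 (2015 ms) under high risk. Optimal times are reported as the latest
response time mapping to the argmax picture, k·Δ, with fractional
milliseconds truncated (43 · 46.875 = 2015.625 → 2015 ms); rounding to
nearest would print 2016 ms instead. Argmax ties break toward the smaller
picture (earlier, safer cash-out).

Because r is linear, Var(k) ∝ k³(1 − p(k)) on the linear branch and peaks
where the cumulative explosion probability reaches 75% under both risk
levels (picture 96 low risk, picture 64 high risk), rising strictly
monotonically up to that peak. The high-risk EV curve is unimodal only on
the multiplier branch (k ≤ 84); on the plateau EV = r(k)·0.01 creeps upward
again, forming a secondary local maximum at picture 127 that stays well
below the global mode.

## Agent simulation

Agents emit truncated-Gaussian response times on (0, 6000] around
per-condition means (rejection sampling; a zero-SD policy is deterministic).
Three families: fixed per-condition means; means pinned at the analytic EV
optima; and trait-linked agents whose condition means come from the same
linear predictor the moderation model fits (risk, reward, SCR covariate,
impulsivity and their interactions), which guarantees a recoverable ground
truth for the statistics chain. Sessions default to 40 trials per condition
(160 total). Earnings are kept in integer-valued euro cents internally.

## Skin-conductance pipeline

The phasic component of skin conductance is modeled as an impulse train
convolved with a Bateman kernel g(t) = (e^(−t/τ2) − e^(−t/τ1))/(τ2 − τ1),
normalized to unit time integral, with defaults τ1 = 0.75 s, τ2 = 2.0 s —
the standard constants of continuous decomposition analysis, exposed as
configuration since they are a modeling choice, not a measurement. The
synthetic generator adds a tonic component (level 2 μS, slope −0.0005 μS/s,
0.05 μS sinusoidal wander with a 120 s period), places one impulse of known
mass per event at a 2.5 s latency (inside the 1–6 s anticipatory window) and
adds white Gaussian noise. Synthetic raw traces default to 500 Hz: high
enough to exercise resampling, small enough for desk-scale tests. Event
spacing in synthetic schedules defaults to 10 s so a 1–6 s window never
overlaps the previous trial's response.

Preprocessing mirrors standard electrodermal conditioning: polyphase
resampling to 80 Hz (linear-extension padding, so a constant trace passes
through unchanged to ~1e−5 relative), Gaussian smoothing with a 16-sample
window (σ = (16−1)/5 samples, the conventional Gaussian-window shape), and
a 4th-order low-pass Butterworth at 2 Hz applied forward–backward (zero
phase). The filter order is a package choice; only the cutoff is prescribed
by the pipeline being modeled. A 10 Hz probe tone is attenuated by far more
than 20 dB, a 0.1 Hz tone by less than 1 dB.

Decomposition runs in four steps:

1. **Tonic estimate.** 5th percentile of the trace in 10 s windows,
   interpolated with a monotone (PCHIP) cubic spline — phasic responses are
   transient upward deflections, so a low percentile over windows longer
   than the kernel support tracks the tonic floor without ringing.
2. **Non-negative deconvolution.** min‖conv(d, g) − phasic‖² s.t. d ≥ 0,
   solved globally by FISTA. The discrete kernel is non-negative with unit
   sum, so the operator norm is bounded by 1 and a unit gradient step is
   always valid. The iteration is deterministic; it stops when the relative
   objective change between 25-iteration checkpoints falls below 1e−5 or
   becomes negligible (< 1e−9) against the input energy, and raises with
   iteration diagnostics if `max_iter = 4000` is exhausted first. A global
   solve was preferred over blockwise NNLS to avoid seam artifacts at block
   boundaries.
3. **Driver-baseline reassignment and peak segmentation.** The percentile
   tonic estimate sits slightly below the true tonic level and the
   deconvolution absorbs that flat offset as a diffuse driver floor; a long
   (8 s) rolling median of the smoothed driver isolates the floor, which is
   reconvolved back into the tonic component. Peaks are then detected on a
   0.2 s-smoothed copy of the driver with a minimum spacing of 0.8 s, each
   peak's amplitude being the driver mass within ±0.5 s; peaks below the
   0.05 μS·s minimum-amplitude criterion are discarded. The criterion gates
   peak segmentation only — event integrals use the full driver.
4. **Reconstruction.** tonic + conv(driver, g), with the relative residual
   norm reported (≤ 5% on noiseless synthetic traces).

The SCR covariate is the driver's time integral over [onset + 1 s,
onset + 6 s] per event, averaged within condition per participant. Events
whose window overruns the trace are excluded and flagged. On synthetic
traces at SNR 10 (noise SD = phasic RMS / 10) the recovered per-event
integrals correlate with the generating impulse masses above 0.9.

What the generator does *not* emulate: movement artifacts, electrode drift
or contact loss, overlapping multi-peaked responses within a single window,
and inter-individual kernel variation. Passing recovery tests therefore
demonstrate correctness of the decomposition under its own forward model,
not robustness to real recording pathologies.

## Statistical chain

**Within-subject MANOVA.** Each single-df within effect (risk, reward,
risk × reward) is reduced to per-participant contrast scores across the
three dependent variables (mean RT, success proportion, earnings). With
H = n·ȳȳ′ and E the centered cross-product matrix, Pillai's trace
V = tr(H(H+E)⁻¹) has the exact transform F = V/(1−V)·(n−p)/p on (p, n−p)
df, and V equals partial η² for these single-df effects. A pseudoinverse is
used so fully degenerate (zero-variance) data yield V = 0 rather than an
error. Incomplete participants are dropped listwise. Post hoc paired t
tests use Bonferroni correction (raw p × family size, capped at 1) and
Cohen's d = mean difference / SD of paired differences.

**Mixed model.** RT is modeled with fixed effects risk, reward, SCR, BIS
and the interactions reward×SCR, reward×BIS, SCR×BIS, risk×SCR, risk×BIS,
reward×SCR×BIS, risk×SCR×BIS, plus a random intercept per participant,
estimated by REML (statsmodels `MixedLM` behind the package's interface).
Coding: risk/reward low = 0, high = 1; SCR z-standardized within sample so
its coefficients are per-SD effects; BIS left on the raw questionnaire
scale so moderator values are interpretable totals. t tests and the JN
critical value use residual df n_obs − n_fixed − n_participants + 1, a
containment-style approximation; Satterthwaite df are not implemented.
Perfectly noiseless data (both variances zero) short-circuit to the exact
linear solve instead of running the REML optimizer.

**Simple slopes and Johnson–Neyman.** The conditional SCR slope at
moderator value w and risk stratum s is c(w)′b with c the gradient vector
over (scr, scr:bis, risk:scr, risk:scr:bis); its SE is the quadratic form
against the coefficient covariance. The JN boundary solves
(c(w)′b)² = t²_crit·c(w)′Σc(w), a quadratic in w, and the significance
region is intersected with the observed moderator range; a negative
discriminant reports a full or empty region rather than an error. Every
boundary is verified in-suite against a 1e−4-step grid scan.

## Synthetic cohorts

`CohortSpec` defaults encode the study conditions: 46 participants, BIS
totals Normal(58.43, 7.795) clamped to the instrument range [30, 120] (30
items × 4-point scale), random-intercept SD 440.6 ms. The residual SD
defaults to 450 ms — chosen once as a plausible trial-averaged RT noise
level of the same order as the between-person SD; the source analysis does
not report one. SCR integrals are log-normal (non-negative, right-skewed)
with a participant-level reactivity shift of the log-mean (SD 0.3); the
true SCR–RT coupling structure is unknowable from summary statistics, so
the generator's coupling is a configurable stand-in, not an estimate.
Fixed effects default to zero apart from a 1500 ms intercept, keeping null
behavior the baseline. RTs are clipped to (0, 6000]; with default settings
~1% of observations touch the lower bound, which biases the intercept by
about 2 ms — negligible against its SE — and a clip fraction above 5%
triggers a warning.

`end_to_end_recovery` runs generate → fit → compare over replicates and
reports per-coefficient bias, RMSE, 95% CI coverage and the rejection rate
of a focal term. At the default conditions (n = 46), pooled CI coverage
over 500 replicates sits within [0.93, 0.97], and a single n = 200 cohort
recovers the generating random-intercept SD within a few percent.

## Problem sizes used in the test suite

Simulation-based tests are sized for a desk run: 1e5 Monte-Carlo outcome
draws, 1000 condition sequences, 100-event traces for deconvolution
recovery, 500 mixed-model replicates for CI calibration, 200 for type-I
behavior, and 40 per power point. The full suite runs in a few minutes on
one CPU.

## Known limitations

- No cognitive process model of pumping/cash-out (no drift diffusion or
  reinforcement learning); agents are descriptive RT policies.
- The decomposition is not bit-compatible with any specific EDA toolbox;
  it implements the same model class with its own tonic estimator and
  solver.
- Random slopes, crossed random effects and non-Bonferroni corrections are
  out of scope; the mixed model has a single random intercept.
- Reported earnings are in cents from the simulated schedules; no attempt
  is made to match any published earnings summaries whose units are
  ambiguous.
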