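# Methods

This note documents the models, numerical choices and defaults behind
`pupilbias`, and what the synthetic-data tests do and do not establish
about real data.

## Diffusion model and first-passage numerics

The decision variable follows `dX = μ dt + s dW` between absorbing bounds 0
and `a`, starting at `z_rel · a`, with `μ = ±v + v_bias` under stimulus
coding (signal trials drift at `+v`, noise trials at `−v`, both offset by
the drift bias). The within-trial noise convention is `s = 1`
(configurable); all other parameters are expressed relative to it.
Trial-to-trial drift variability `sv` adds `N(0, sv)` to each trial's
drift. RT = first-passage time + `t₀`.

**Analytic solution.** For constant bounds, the first-passage density at
each bound uses the two classical series representations of the
unit-variance Wiener process — the image-charge (small-time) expansion for
scaled times `t/a² < 0.35` and the spectral (large-time) expansion
otherwise, with 7 terms each, which is accurate far beyond the needs of the
quantile likelihood. Because the series part is drift-independent, drift
enters only through an exponential tilt; marginalising `sv` by
Gauss–Hermite quadrature (12 nodes) therefore costs almost nothing.
Defective CDFs are cumulative trapezoids on a nonuniform grid (1.5 ms cells
up to 1.5 s, 10 ms cells to 10 s).

**Path simulator.** Euler–Maruyama with a Brownian-bridge correction for
unobserved within-step crossings; for the Gaussian increments of a
constant-drift process the per-step crossing probabilities are exact, so
the step size (default `dt` = 1 ms) affects only the placement of the
crossing time inside a step. Crossing times are interpolated within the
step (linearly for exceedance crossings, uniformly for bridge-detected
ones) rather than recorded at step boundaries; recording at boundaries
leaves a visible `+dt`-scale bias in fitted non-decision time at large
trial counts. Collapsing bounds are evaluated per step; when bounds meet at
`τ`, unabsorbed paths terminate on the side of `a/2` they occupy, exact
ties randomised.

**Exact sampler.** For constant bounds and `sv = 0`, `sample_ddm_exact`
draws (choice, RT) by inverting the analytic defective CDFs on a fine grid
(0.3 ms resolution, linear interpolation within cells). The large
simulation experiments use it because it is orders of magnitude faster
than path simulation and free of discretisation error; the path simulator
is independently validated against closed-form choice probabilities
(`P(upper) = (1−e^{−2vz})/(1−e^{−2va})`) and the zero-drift mean decision
time `z(a−z)/s²` in the test suite.

## Quantile (G²) fitting

Observed RT distributions are summarised per (condition, stimulus) cell by
the 0.1/0.3/0.5/0.7/0.9 quantiles of each choice's RTs — six bins per
choice for yes/no data; six yes-bins plus one no-go-count bin for go/no-go
data, where no-go trials carry no RT. The objective is
`G² = 2 Σ O ln(O/(N·p))` summed over cells, with expected probabilities
floored at 1e−10 and `0·ln 0 = 0`. Minimisation uses adaptive Nelder–Mead
with box rejection, data-driven initialisation (`t₀` just under the 0.5th
RT percentile), seeded random restarts, and a final restart-at-solution
polish (restarting the simplex at the incumbent escapes degenerate simplex
geometry in flat directions). Expected proportions for collapsing-bound
models come from forward simulation with a fixed seed per fit (common
random numbers across optimizer iterations keep the objective smooth).
`BIC = G² + k ln n`, treating G² as a deviance surrogate; this supports the
model *ranking* used here, not absolute posterior statements.

A genuine statistical caveat found while validating: the quantile
likelihood is quartic in `sv` near `sv = 0`, so at 10⁵ trials/condition the
`sv` estimate from data generated with `sv = 0` has sampling spread up to
≈0.3 even with exact data. The drift-variability confound experiment
therefore defaults to 10⁶ trials per condition — the scale at which the
estimate concentrates below 0.03 — which the exact sampler makes cheap.

## Drift-variability confound experiment

Two conditions differing only in drift bias (−0.5 vs 0; `v = 1`, `a = 1`,
`t₀ = 0.3`, `sv = 0`; 50/50 signal/noise per condition). Fitting with
per-condition drift bias recovers `sv ≈ 0` and the generative biases;
forcing a shared drift bias inflates recovered `sv`, monotonically in the
bias disparity (sweep grid 0–1 in steps of 0.25). Ten seeded replicates;
medians reported. The 50/50 stimulus composition is what makes `v` and
`v_bias` jointly identifiable.

## Three-model comparison

Data generated with bin-varying drift bias (three bins, biases −0.6/−0.3/0)
are fitted by three equal-complexity models: *starting point* (`z_rel` per
bin, one drift bias, no urgency), *drift bias* (`v_bias` per bin, one
starting point), and *urgency* (`τ` per bin, one starting point, no drift
bias); `a`, `v`, `t₀` are bin-invariant and `sv` is fixed at 0 for speed.
Each fitted model is forward-simulated and scored by the sum of squared
differences between predicted and empirical per-bin SDT criterion. The
drift-bias model attains the smallest residual and the urgency model's
predicted bias is nearly flat across bins — collapsing bounds with no bias
parameter structurally cannot produce graded choice-bias changes.

## Pupil preprocessing

Defaults follow standard practice for fast-paced auditory detection:
blink-gap linear interpolation with 150 ms padding on both sides (edge gaps
held at the nearest valid sample; sessions >40 % missing are flagged);
zero-phase third-order Butterworth low-pass at 6 Hz (the zero-phase choice
means the realised amplitude response is the squared magnitude);
blink/saccade response removal by FIR deconvolution on a boxcar basis
(default 0.1 s bins over a 6 s epoch, sparse least squares with an
intercept) followed by subtraction of the fitted event-locked contribution;
conversion to percent signal change about the session mean; anti-aliased
decimation to 50 Hz. The derivative is the adjacent-sample difference
scaled to %/s (last sample repeated to preserve length) low-passed at 2 Hz;
units only matter up to rank for percentile binning. The phasic scalar is
the 95th percentile of the derivative in a configured window — stimulus-
locked 230–500 ms (humans) or 40–230 ms (mice) for go/no-go, the 500 ms
before the choice for yes/no — with the pre-trial baseline as the mean
normalised pupil in the 500 ms before onset. Go trials faster than the
window end + 50 ms (550 ms humans, 280 ms mice) are excluded, as are
mini-block cue trials; no-go trials are always retained. Bins are
equal-population within stratum (ranked stable on ties; populations differ
by ≤1).

Percentiles are taken on the 50 Hz (post-downsampling) derivative; the
extraction windows are fixed configuration, not adapted per session.

## Synthetic-data generator

The generator defines the study conditions: human go/no-go sessions of 660
trials in mini-blocks of 2–7 one-second trials (0.5 s inter-trial
interval), signal always on the final trial, block lengths drawn from a
linearly decreasing pmf on {2..7} so the marginal signal-position
probability declines linearly; mouse sessions of ~2974 trials with six
loudness levels; yes/no sessions of 1320 trials at signal probability 0.5
or 960 at 0.3/0.7 with exact stratified counts per 120-trial block;
recognition sessions of 300 trials split 150/150 old/new. Loudness levels
are balanced across mini-blocks.

Latent arousal is lognormal with unit median (shape 0.5). The coupling law
is multiplicative suppression `v_bias = bias_base · (1 − γ·ã)` with `ã`
the rank-normalised arousal; suppression beyond a configurable sign-flip
cap (25 %) is clamped with a warning. A multiplicative law is used because
the empirical phenomenon is suppression of biases of either sign, which an
additive (one-direction) law cannot produce; the law is a configurable
choice, since only the *estimated* arousal–bias relation, not the
generative one, is empirically constrained.

Traces are built at 1000 Hz (configurable) as baseline mean (1000 a.u.) +
slow drift (linear interpolation between 20 s random knots) + arousal-
scaled impulse responses at trial onsets + motor transients at responses +
blink-evoked dilations after blink gaps + Gaussian noise. The impulse
response is the standard gamma-family pupil IRF
`h(t) = (t/t_max)^w e^{−w(t/t_max−1)}` with `t_max = 0.93 s`, `w = 10.1`.
Blinks are Poisson (0.1 Hz) with 100–400 ms gaps masked as missing;
overlapping gaps merge.

Because the generator ties the arousal response to *trial onset*, the
pipeline's default scalar window for synthetic cohorts is stimulus-locked
over the IRF's rising flank (0.3–0.9 s). A choice-locked window on these
traces couples the scalar to RT (slow trials sample a later, steeper part
of the IRF), which distorts the bin–arousal mapping — a synthetic analogue
of the motor/timing confounds that motivate careful window choices on real
data. Choice-locking remains available in the configuration.

**What passing tests show — and don't.** The generator produces the
response features the pipeline consumes (event-locked dilations scaled by
a latent state, blinks, motor transients, baseline drift). It does not
emulate gaze-position artifacts, pupil foreshortening, luminance effects,
slow arousal (baseline) dynamics coupled to behavior, or any arousal
response whose timing varies with the decision itself. End-to-end recovery
here validates the pipeline's statistical machinery, not the physiological
assumptions of any particular experiment.

## Group statistics

The per-bin metric's dependence on pupil bin is classified by a sequential
mixed-model comparison: candidates add an intercept (plus loudness where
the design has one), a linear bin term, and a quadratic bin term, all with
the same random-effects structure (subject intercepts and bin slopes;
the quadratic term enters fixed effects only) so that BIC differences
reflect the fixed-effect order. Candidates are fitted by maximum
likelihood; BIC is computed as −2·llf + k·ln(n) with k = fixed effects +
random-effect (co)variances + residual scale. Selection is serial — a
higher order is adopted only if it improves on the current winner — and
the winner is refitted by REML. Degenerate random-effects fits fall back
to random intercepts with a warning.

Cluster-corrected time-course tests threshold pointwise one-sample
t-values at the two-sided α quantile, form contiguous same-sign clusters
scored by t-mass, and compare each observed cluster against the
permutation null of the maximum |mass| under subject sign-flips (default
10 000 permutations). Association tests are paired t-tests and Pearson
correlations with percentile-bootstrap CIs (60 % default, matching
individual-differences error-bar conventions).

## Problem sizes and determinism

Simulation experiments default to: confound experiment 10⁶
trials/condition × 10 replicates (exact sampler); three-model comparison
~10⁴ trials/bin with 10⁵ forward-simulated prediction trials; pipeline
demonstrations ~10 subjects × 600 trials. The test suite runs reduced but
qualitatively identical configurations. A single seed fans out to
per-stage substreams via `numpy.random.SeedSequence`, so every table,
trace and fit is reproducible bit-for-bit given (config, seed).

## Known limitations

- Per-subject (non-hierarchical) quantile fits replace hierarchical
  Bayesian estimation: parameter uncertainty is not quantified, and
  many-parameter-per-bin models can be ill-posed at small trial counts;
  per-parameter freeze flags (`ModelSpec.fixed`) are the mitigation.
- In go/no-go designs, starting point and drift bias cannot both vary by
  arousal bin (no RTs for no-go choices); the recovery suite demonstrates
  the trade-off.
- The `sv` estimate is softly identified near zero at moderate n (see
  above); treat small fitted `sv` values as upper bounds, not point
  estimates.
- BIC on the G² deviance surrogate is a ranking tool; absolute differences
  should not be over-interpreted.
- The composite-bias crossing can be undefined when all per-loudness
  sensitivities are ≤ 0; this raises an error rather than extrapolating.
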