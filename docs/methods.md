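# Methods

This note records the model equations, the tunable parameters with their
defaults and rationale, what the synthetic-data generator does and does not
emulate, numerical choices, and known limitations.

## Stimulus representation

Stimuli are sampled 1-D contrast modulations at 1 kHz (configurable). A
drifting grating seen through a local one-dimensional temporal filter is
equivalent to counterphase flicker at `speed × spatial frequency` Hz, so no
spatial dimension is modelled and direction reversals carry no signal of
their own: tests are `contrast·sin(2πf t)` in a rectangular envelope
(10 Hz, contrast 0.8), the flicker adaptor alternates 500 ms segments of
5 and 20 Hz at contrast 0.5 with exactly 50/50 occupancy. Carrier onset
phase is a fixed constant (0): the phase–envelope interaction is what
produces the small ripples in the read-out at brief durations, so it must
not vary covertly. Rectangular envelopes are assumed for targets; a
raised-cosine *envelope* is not provided (envelope shape is distinct from
the pooling-window shape below).

## Front-end filter

`h(t) = E(t) − I(t)` with `E` and `I` unit-area gamma densities
(`t^{n−1}e^{−t/τ}`): τ_exc = 8 ms × 9 stages, τ_inh = 10 ms × 10 stages.
Subtracting unit-area lobes zeroes the integral exactly (DC-balanced,
band-pass); the kernel is then normalized to unit peak. Peak sensitivity
lands near 5–8 Hz, between the 5/20 Hz adaptor components and the 10 Hz
test carrier. The inhibitory weight parameter only matters with DC-balance
off; requesting weight 0 with balance on is rejected because it would leave
a monophasic kernel. A low-pass variant (single exponential stage,
τ = 15 ms) exists because none of the package's qualitative conclusions
should depend on the filter family — the adaptation test-suite properties
are asserted under both filters. Rectification is full-wave by default
(drive proportional to contrast); squaring is available.

## Channel bank and transducer

61 channels with FWHH log-spaced 50–4000 ms (600 and 1200 ms sit well
inside the span; ≥ 8 channels are required for a usable derivative).
Pooling windows are causal, anchored at stimulus onset, unit peak.

**Window shape.** The default is a raised-cosine (Hann) window with support
`[0, 2W)` and FWHH exactly `W`; rectangular windows are available. This is
a deliberate design choice: with rectangular windows a channel's drive is
flat in `W` for every `W` beyond the stimulus duration, so a fixed-duration
adaptor adapts all wider channels *equally* and no repulsive expansion of
longer tests can arise. Raised-cosine windows make the per-channel drive a
tuned (bell-shaped) function of width — wide windows dilute a short
stimulus into their rising flank — which yields the notch-shaped gain
profile that bidirectional repulsion requires.

**Transducer.**

    R_i = (g_i L_i)^p / (z + (g_i L_i)^q + w·(g_N L_N)^q)

with defaults p = 2.4, q = 2.0, z = 10⁻³, w = 1, own-drive weight 1. The
`(g_N L_N)^q` term is divisive suppression from the widest mechanism; the
own-drive term is the standard self-saturation of divisive gain control.
The own-drive term matters for adaptation: without it the normalized
adaptor response is a pure power law of width, whose gradient *grows* with
width and would make flicker compression grow, rather than shrink, with
test duration. `z` sets where saturation engages on the drive scale
(drives are in amplitude·seconds; typical test drives span ~10⁻⁴–10⁻²).
p > q ≥ 1 is enforced so the population profile accelerates then saturates.

## Read-out and decoding

The population derivative `d_i = R_{i+1} − R_i` is assigned to the
geometric-mean width of each pair; the argmax (ties broken toward the
narrower width) is refined by 3-point parabolic interpolation in log-width
(edge peaks uninterpolated, interpolation clamped to one channel step).
Baseline calibration runs the unadapted model over a 100–3000 ms grid
(50 ms steps), isotonically smooths the peak-width curve in log-log space
(removing carrier-phase ripples; deviations beyond 0.05 log units indicate
a misconfigured bank and raise), strictifies flat runs with a 10⁻⁹ ramp,
and interpolates linearly in log-log in both directions. Decoding a peak
width outside the calibrated range raises with the offending width rather
than extrapolating.

## Adaptation

Gains are reduced according to the normalized adaptor response
`R̂_i = R_i / max_j R_j`:

    g_i = 1 − α[(1−b)·R̂_i + b·(1+s)·R̂_i/(s + R̂_i)]      (default)

with α = 0.8, semi-saturation s = 0.004, mix b = 0.6. The blend is
response-proportional for weakly driven channels and saturates for strongly
driven ones — the way adaptation depth saturates with drive physiologically.
The saturating component is what makes the flicker-compression gradient
*decline* with test duration (for `R̂ ≫ s` the gain gradient falls off as
`s·p/R̂`); the proportional component keeps gains strictly decreasing at the
widest channels so compression never flips sign at long durations. Strictly
linear (`g = 1 − αR̂`) and divisive (`g = 1/(1+αR̂)`) rules are provided
behind `adapt_rule`; both reproduce repulsion and all-negative flicker
compression, but not the sub-/supra-second ordering of the compression
magnitude, which is why they are not the default. Defaults were frozen by a
joint parameter scan requiring the monotone read-out, bidirectional
repulsion, and ordered compression to hold simultaneously under both the
biphasic and the low-pass front end.

**Adaptor responses.** A fixed-duration adaptor is a discrete, repeated
event with an onset, so its response is computed exactly like a test's
(onset-anchored windows). A prolonged flicker adaptor is modelled at steady
state: each channel's drive is the time-averaged rectified front-end output
times the window area (the sliding-window mean; for unit-peak windows of
either shape the area equals the FWHH). Onset-anchoring a multi-second
segmented adaptor instead imprints 500 ms segment-phase artifacts on the
gain profile (plateaus that can locally invert the effect), and makes the
result depend on an arbitrary exposure epoch; at steady state the exposure
duration drops out, consistent with treating the model as
exposure-duration-agnostic. The model path contains no randomness anywhere:
identical configuration gives bit-identical outputs.

## Psychometric fitting

Bernoulli maximum likelihood of
`P(longer) = λ/2 + (1−λ)Φ((x−μ)/σ)` over (μ, σ) with λ fixed (default 0;
the package does not fit lapses because the analyses it reproduces report
none). Trials are aggregated to per-level binomial counts; the NLL and its
analytic gradient feed L-BFGS-B with bounds μ within ±2 level-spans and
σ ∈ [0.5, 200] %, multi-started from a moment-based initializer plus σ
jitters. Bound hits (e.g. complete separation driving σ to its floor) and
optimizer failures are flagged on the fit, never silently returned;
degenerate cells (a single level, or all responses identical) raise. A
least-squares-on-pooled-proportions mode brackets the (unknown) objective
of legacy fitting code; in tests the MLE route is cross-checked against an
independent probit-GLM fit (statsmodels IRLS), which maximizes the same
likelihood by a different algorithm.

Estimator precision: at 7 levels × 20 repetitions and σ near 30% of the
standard, the Fisher information bounds the median absolute PSE error at
roughly 3 percentage points; the packaged estimator sits at that bound
(verified in the test suite), so recovery tolerances below it are not
achievable by any fitting method at these trial counts.

## Synthetic data

The population generator draws per-participant (PSE, JND) per
condition × standard cell from independent normals with the cell means and
between-participant SDs of the study conditions it emulates (SD recovered
from s.e.m. × √20): baseline PSEs +3.74/−0.127 % (600/1200 ms), adaptation
PSEs −12.75/−7.02 %, JNDs 23.24/19.3 % at 600 ms. The 1200 ms JND means are
not separately established and are set to the same Weber-like level (23 /
23.5 %). JNDs are truncated (by resampling) so σ stays above the fitting
floor. Two optional components mirror structure the analyses need: a
Gaussian-copula PSE–JND correlation in the baseline-600 cell (r ≈ 0.67),
and three planted extreme baseline-600 overestimators (+11.07, +15.73,
+21.73 %); with outliers on, the remaining participants follow the
post-exclusion statistics (mean +1.54 %, s.e.m. 1.02 at n = 17), so the
planted values are genuinely separated and the full-group mean returns to
~+3.74 %. Outliers are planted in z-space so their JNDs respect any
injected correlation.

Trials are Bernoulli draws from each observer's cumulative Gaussian at the
design's seven levels, exactly `min_reps` = 20 per level. The generator
does not model interval-order or position effects, sequential dependencies,
lapses, reaction times, or unbalanced repetition counts — so passing tests
show the pipeline recovers parameters under the design's idealized
statistical structure, not that real data are this clean. The model
observer closes the loop mechanistically: the standard (at the adapted
location) is decoded by the adapted model, the comparison by the unadapted
one, and the response compares the two decoded durations under Gaussian
decision noise.

All randomness uses `numpy.random.default_rng` (PCG64) with explicit seeds;
one stream per generator call, derived deterministically from the
user-supplied seed.

## Analysis pipeline

Group statistics always come from individual fits (pooled-trials fits are
for display only). s.e.m. = SD/√n with ddof = 1. Paired and one-sample
t-tests are classical (df = n−1, two-sided p; identical pairs define t = 0,
zero-variance differences with nonzero mean raise); no multiple-testing
correction is applied, and Bayes factors / repeated-measures ANOVA are
intentionally out of scope. "Stronger compression at 600 ms" means
effect(600) < effect(1200) (more negative). The exclusion re-analysis ranks
fitted baseline-600 PSEs and refuses ties at the cut boundary rather than
resolving them arbitrarily. The trial-table reader accepts a column map for
foreign layouts and auto-converts millisecond-valued comparisons to % of
the standard (values all-positive with any above 100 are treated as ms).

## Problem sizes

The packaged checks use: a 200–2000 ms grid in 50 ms steps for the
monotone-read-out property; 300–2000 ms in 100 ms steps for the two
adaptation curves; 200 observers for parameter recovery; and 200 replicate
populations of n = 20 for the effect-ordering rate. The full test suite
runs in ~3 minutes on one CPU; the acceptance script in ~3 minutes.

## Known limitations

* The model is a qualitative reconstruction: its parameter values are
  calibrated to reproduce behaviourally established *signs and orderings*
  (monotone read-out, bidirectional repulsion, duration-dependent
  compression), not to fit effect magnitudes; predicted percentages should
  be read as illustrative.
* Between-participant effects are independent across the two standards, so
  the synthetic paired t for 600-vs-1200 effects (~−2 to −3) is weaker than
  with correlated observers, and the expected stronger-compression count is
  ~15/20 rather than higher values that cross-standard correlation would
  produce; no such correlation is established cell-by-cell, so none is
  assumed.
* Perceived-speed after-effects, adaptation dynamics (build-up/decay,
  top-up schedules), directional signals, and neural localisation are out
  of scope.
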