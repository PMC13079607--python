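# Methods

`mmskit` characterizes two biorhythms — facial micro-movements extracted from
68-point landmark trajectories, and the heart's inter-beat-interval (IBI)
fluctuations — as Gamma stochastic processes, compares their noise regimes
between control and pain conditions, and quantifies directional
predictability between the two streams with transfer entropy. This note
records the model, the conventions that the numbers depend on, and the
design decisions taken where more than one reasonable choice existed.

## The micro-movement spike (MMS) transform

A raw series (landmark speed in pixels/s, or IBI in ms) is standardized in
three steps:

1. **Reference level.** Local maxima of the raw series are located; the
   continuous Gamma family is fitted to their magnitudes by maximum
   likelihood, and the fitted mean `a·b` is the empirical reference level.
2. **Deviations.** The series of absolute deviations from that mean is
   formed (a `deviations="positive"` flag restricts to upward deviations;
   the default keeps both signs, so both slowing and quickening excursions
   spike).
3. **Normalization.** At each local peak of the deviation series,

       MMS = Peak / (Peak + Avrg_min-to-min)

   where `Peak` is the deviation-peak magnitude and `Avrg` is the mean of
   the **raw** series over the closed window between the two valleys
   flanking the peak (both valley samples and the peak sample included).
   Every other frame carries 0 — the frame grid is preserved, and zeros mark
   motion at the mean level. Values lie in [0, 1).

Averaging the raw series (not the deviation series) in the denominator is
load-bearing: the window mean of the deviation series can never exceed the
deviation peak, which would confine every spike to [0.5, 1) and make small
spike magnitudes unrepresentable. With raw-series averaging, a small
deviation against a large baseline gives a small spike, and the transform is
exactly invariant under positive rescaling of the input (peak and average
scale together), which is the point of the allometric normalization: spike
magnitudes are comparable across faces and hearts of different size. The
deviation-window variant is retained behind `avg_on="deviation"`.

**Extrema conventions.** A peak is a forward-difference sign change from
positive to negative; a valley the reverse. A plateau (run of equal values
bounded by lower neighbors) is one extremum at the run's first index.
Boundary samples are valleys when the series moves up and away from them;
boundaries are never peaks, so every peak has two flanking valleys. These
rules are deterministic and are checked against an independent brute-force
scan in the tests.

**Smoothing and differentiation.** Landmark trajectories are smoothed with a
cubic smoothing spline whose residual budget defaults to `n·σ̂²`, with `σ̂²`
estimated from second differences — noise-free polynomial inputs pass
through unchanged, while unit-variance white noise is attenuated at least
tenfold. Speed is the Euclidean norm of central-difference derivatives
scaled by the frame rate (one-sided at the ends). The smoothing budget is a
config value (`RunConfig.smoothing`); it should reflect the measurement
noise actually present. For the synthetic recovery studies it is set to 0
(the generated positions are exact), because a noise-adaptive budget would
read the designed frame-scale excursions themselves as noise and flatten
them. The same sensitivity exists with real data: oversmoothing destroys
exactly the micro-structure the MMS transform measures.

## Gamma-process characterization

MMS spike magnitudes (nonzero values only — the zeros are bookkeeping, not
observations) are fitted with the Gamma family in shape-scale form,

    f(x; a, b) = x^(a-1) e^(-x/b) / (b^a Γ(a)),   x > 0,

by maximum likelihood without a location parameter. Derived quantities are
closed forms: mean `a·b`, variance `a·b²`, **noise-to-signal ratio
NSR = variance/mean = b** (the scale parameter itself), and skewness
`2/√a`. These identities are asserted for every fit the pipeline produces.
`a = 1` is the memoryless exponential regime; large `a` approaches Gaussian
symmetry — so an upward NSR shift with a downward shape shift reads as "more
dispersed and more random".

95% confidence intervals are Wald intervals from the observed-information
matrix (per-observation information `[[ψ′(a), 1/b], [1/b, a/b²]]`), the
standard asymptotic choice; their empirical coverage at n = 1000 is checked
to sit in 92–98%. A zero-variance sample is returned flagged `degenerate`
(scale 0) rather than raising, since heavy synthetic regimes can produce
near-constant windows. Normal, lognormal and Weibull fits are available for
likelihood ranking; only the ranking is reported, never an automatic
selection.

The cohort-level **shape-scale power law** is an ordinary least-squares fit
of log10(scale) on log10(shape) across per-record fits; slope, intercept,
R² and residual SD are reported. Face NSR values for the three trigeminal
regions form a vector whose Euclidean norm from the origin summarizes facial
noise; pain-minus-control deltas of NSR and skewness feed the cohort
statistics.

**Region table.** The 68 landmarks are partitioned into the trigeminal
territories V1 (ophthalmic: indices 17–30, 33, 36–47; 27 points), V2
(maxillary: 31, 32, 34, 35, 48–54, 60–64; 16 points) and V3 (mandibular:
0–16, 55–59, 65–67; 25 points), 0-based and ascending. Published listings
of these sets are not fully self-consistent (stated counts differ by one
from the ranges, and one range is printed descending), so membership is a
configuration table, not a constant, and the stated index sets are taken at
face value.

## HRV descriptors

R-peaks are detected by linear detrending, zero-phase band-pass filtering
(5–30 Hz Butterworth), and adaptive-threshold peak picking (threshold 0.4 of
the 99.9th-percentile filtered amplitude, 250 ms refractory period), with
each candidate refined to the argmax of the detrended raw trace within
±40 ms so peak times land on the R crest. Records are zero-padded by one
second per side so boundary beats are interior to the filter. On synthetic
ECG at default noise the detector's sensitivity exceeds 99% within ±1
sample.

Intervals outside 300–2000 ms are flagged as physiologically implausible
(retained raw, excluded from fits). Conventions the magnitudes depend on:

* **Poincaré.** With lag-1 pairs (x_t, x_{t+1}), SD1 = SD((x_{t+1}−x_t)/√2)
  and SD2 = SD((x_{t+1}+x_t)/√2), both with population (1/n) variance.
  These are exactly the standard deviations of the scatter projected on the
  ellipse axes (the identity line and its perpendicular) and match a
  rotation oracle to machine precision; the textbook form
  √(2·Var(x) − SD1²) differs only by O(1/n) edge terms.
* **Band powers.** The tachogram (interval i at the time of the beat
  completing it) is cubic-interpolated to a uniform 4 Hz grid; a Welch
  periodogram (60 s Hann segments, 50% overlap, constant detrend) is
  integrated over LF 0.04–0.15 Hz and HF 0.15–0.40 Hz. Total Welch power
  approximates the tachogram variance within 5% on stationary inputs.
  Records must cover at least 60 s.

The IBI MMS applies the identical transform to the beat-indexed interval
sequence. A constant rhythm yields an empty spike train by definition.

## Transfer entropy

For streams X (source) and Y (target) with history length L,

    T(X→Y) = H(Y_t | Y_{t−1:t−L}) − H(Y_t | Y_{t−1:t−L}, X_{t−1:t−L}),

in bits — the uncertainty about the target's present removed by the
source's recent past beyond the target's own past. Entropies use the
standard signed definition H = −Σ p log2 p. The conditional-MI and
entropy-difference formulations are numerically identical and tested as
such.

**Windowing.** The study constants are 50-frame windows with 10% of the
window as history (L = 5, ~167 ms at 30 Hz) over a 300-frame span. Windows
are non-overlapping and complete, and embedding vectors never cross a window
edge. By default the embedded samples of all windows are pooled into a
single estimate over the span, the way continuous-TE toolkits treat a
recording; `pooled=False` estimates per window and averages. The pooled
default is deliberate: a 50-frame window yields 45 transitions against an
11-regressor linear model (or a 4^11-state alphabet), so per-window
estimates are estimator-bias dominated and cannot rank directions reliably,
while the pooled estimate recovers an injected coupling direction
essentially always (see the acceptance tests).

**Estimators.**

* *binned* — equal-frequency discretization (quantile edges computed over
  the analysis span so all windows share one alphabet; `binarize=True`
  reduces to spike/no-spike) and a plug-in entropy estimate. Upward biased
  by ≈ df/(2N ln 2); validated against that band on independent streams and
  against the deterministic-copy limit, where T(X→Y) reaches the
  discretized-alphabet entropy.
* *gaussian* — ½ log2 of the residual-variance ratio of nested least-squares
  autoregressions (own lags vs own + source lags). Non-negative by
  construction and equal to the analytic closed form for linear-Gaussian
  coupling; this is the estimator used for direction comparisons, where the
  overfitting bias is shared by both directions.

The heart's beat-indexed MMS is mapped onto the 30 Hz frame grid by placing
each spike at the frame of the beat completing its interval and holding the
magnitude until the next spike (zero-order hold). Holding, rather than
leaving zeros, is what puts the sparsely sampled cardiac stream on a footing
where its recent past is visible to a frame-scale history. Cohort TE values
are presented as sorted curves: participants ordered by one direction's TE,
the other direction overlaid in that order, and per-participant differences
reported.

## Cohort statistics

All group comparisons are non-parametric: pairwise two-sided Wilcoxon
rank-sum (tie-corrected, no multiple-testing correction by default — raw
p-values are reported, a Benjamini–Hochberg pass can be applied downstream),
Kruskal–Wallis with a Tukey–Kramer-style follow-up on mean ranks (a pair is
flagged when the intervals `R̄ ± q·SE/2` are disjoint at the 5% family
level), and a tie-corrected Friedman test for complete participant ×
condition blocks (implemented in-house because the SciPy version rejects
two-condition blocks; cross-checked against SciPy for k ≥ 3).

Empirical spike-magnitude distributions are compared with the 1-D
Wasserstein-1 (earth mover's) distance on the raw samples — not on binned or
fitted densities, which would introduce a bin-width choice (a fitted-density
variant is a flag away). The distance matrix feeds average-linkage
agglomerative clustering cut at k = 8 groups by default, with per-cluster
control/pain composition percentages. The face–heart relationship is an OLS
fit of face ΔNSR on heart ΔNSR (pain minus control, per participant) with
R², adjusted R² and RMSE.

## The synthetic cohort generator

The generator exists so that every stage has a recoverable ground truth; its
defaults are the study conditions (21 participants, 30 Hz frame grid,
~800 ms resting IBI, control→pain NSR increases with face and heart shifts
linearly related at R² ≈ 0.84, a negative log-log shape-scale law).

**Inverse design.** The MMS transform is scale-invariant, so a target spike
magnitude is encoded in the *shape* of an excursion, not its amplitude.
Signals are a baseline `C` (per-segment jittered level so the raw-peak Gamma
fit is well posed) interrupted by downward excursions: linear ramps of
`h−1` interior samples to a floor `C−P`, a dwell of `L` samples, ramps
back. For the detector's window (previous gap's first sample through next
gap's first sample, W = G + 2h + L − 1 samples) the raw-series average is
`C − (h−1+L)·P/W`, so the depth solves in closed form:

    P = C / ((1−v)/v + (h−1+L)/W).

Large targets are reached by lengthening the dwell until the floor
constraint is met. Flat runs carry a tiny monotone tilt (2·10⁻⁵ of
baseline per sample) so that, after a signal is integrated into positions
and re-differentiated, float-level noise cannot split a plateau into
spurious micro-extrema; trailing padding extends the last gap seamlessly for
the same reason. For the face, speed is integrated under a slowly wandering
heading (turns confined to ramp samples), and the depth is refined by a
secant solve against the exact forward map through the central-difference
kernel, which rounds the corners of the piecewise-linear profile. The
measured per-spike error of the full round trip is ~0.1% ± 1%.

Generator-specific bounds: face excursions keep speed above 2% of baseline;
IBI excursions are floored at 40% of the base interval (intervals below
~300 ms are not physiological) with targets capped at 0.5, where the dwell
stays a few beats — heavier-tailed regimes than the defaults would truncate
visibly. IBI excursions occur every ~2–3 beats, comparable to real
beat-to-beat tachogram variability; face spikes every ~0.3 s.

**Cohort structure and coupling.** Per-participant (shape, scale) pairs are
drawn on the configured log-log law with adjustable spread and residual
noise; pain scales shift upward per participant, and face deltas are
`ratio·Δheart + noise` with the noise SD solved from the target R²
(`sd = sd(signal)·√(1/R² − 1)`). Coupling mixes the target stream's spike
magnitudes with the held source magnitude `lag` frames earlier:
`v = (1−s)·v_own + s·v_src` — linear and lagged, hence recoverable by the
Gaussian TE and analyzable in closed form. The ground-truth record carries
every injected parameter. All randomness flows from one seeded generator;
a fixed seed reproduces the cohort bit for bit.

**What the generator does not emulate.** Landmark measurement noise is off
by default (the recovery studies therefore run without smoothing);
photorealistic ECG morphology (P/T waves), respiration-IBI coupling, and
nonstationary drifts are absent; baselines between excursions are smooth
where real signals fluctuate everywhere. Passing the recovery studies shows
the analysis chain inverts its own assumptions faithfully — it does not show
robustness to artifacts real recordings contain (dropped frames, landmark
jitter, ectopic beats), which the pipeline only partially addresses
(artifact flags, smoothing config).

## Problem sizes and numerical choices

Test and acceptance runs use deliberately scaled studies: CI calibration at
400 fits × n = 1000; IBI recovery at 600 s across 50 seeds; face recovery
at 60 s × 27 landmarks across 50 seeds; TE direction recovery on 40 seeded
3-participant, 120 s cohorts; the end-to-end cohort at 20 participants ×
60 s. Tie-breaks and degenerate inputs follow the conventions above;
equal-frequency bin edges use sample quantiles (ties may merge bins);
Gaussian-TE windows with zero restricted residual return 0; constant-target
windows are skipped with a warning. Reported spike magnitudes are capped at
0.95 in the generator, where the profile inversion becomes ill-conditioned
(negligible mass under the regimes studied).

## Known limitations

* The binned plug-in TE is unusable at the 50/5 windowing without pooling;
  KSG-style continuous estimators are not implemented.
* Wald intervals undercover slightly for small samples (n ≲ 100) and skewed
  regimes; bootstrap CIs are not implemented.
* The IBI inversion's floor/cap truncates Gamma regimes with substantial
  mass above v = 0.5.
* ECG round trips attenuate the recovered NSR via R-time quantization and
  detection jitter (visible in `examples/02_heart_hrv.py`); guarantees are
  stated for the direct interval pipeline.
* Real-cohort quantities (published R² values, cluster compositions) depend
  on recordings this package does not ship; nothing here claims to
  reproduce them.
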