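# mmskit

Micro-movement spike analysis of facial and cardiac biorhythms.

`mmskit` is for researchers studying how physiological "noise" shifts with
state — for example between a pain-free baseline and an induced-pain
condition — using nothing more invasive than a webcam facial-landmark track
(OpenFace-style 68-point tables at 30 Hz) and a single-lead ECG. It turns
both signals into a common standardized data type, characterizes each as a
Gamma stochastic process, and asks whether one stream's recent past predicts
the other.

## The method

**Micro-movement spikes (MMS).** Landmark speed (or the inter-beat-interval
sequence) is reduced to a frame-preserving spike train: fit the Gamma family
to the raw peak magnitudes, form absolute deviations from the fitted mean
μ = a·b, and at each deviation peak emit

    MMS = Peak / (Peak + Avrg_min-to-min)  ∈ [0, 1),

where the local average runs over the raw signal between the valleys
flanking the peak. The normalization cancels anatomical scale exactly
(multiplying the signal by any k > 0 leaves every spike unchanged), so
fluctuation magnitudes are comparable across individuals.

**Gamma characterization.** Spike magnitudes are fitted with
Γ(a, b) by maximum likelihood (95% Wald CIs). The scale b is the
**noise-to-signal ratio** (NSR = variance/mean); skewness is 2/√a; a = 1 is
the memoryless exponential regime. Across a cohort, log₁₀ b falls on a
tight negatively sloped line in log₁₀ a — the shape–scale power law — so one
parameter predicts the other.

**HRV descriptors.** From ECG: R-peak detection → IBI series → Poincaré
SD1/SD2 (lag-1 ellipse axes) and Welch LF (0.04–0.15 Hz) / HF (0.15–0.40 Hz)
band powers of the tachogram.

**Transfer entropy.** T(X→Y) = H(Y_t | Y_past) − H(Y_t | Y_past, X_past) in
bits, with 50-frame windows and a 5-frame history on the shared 30 Hz grid
(heart spikes held between beats), estimated by a linear-Gaussian or a
binned plug-in estimator in both directions.

**Cohort statistics.** Rank-sum matrices, Kruskal–Wallis with mean-rank
follow-up, Friedman tests, earth-mover's-distance clustering of spike
distributions (average-linkage tree, k = 8), and OLS fits of face ΔNSR on
heart ΔNSR.

A synthetic-cohort generator (`mmskit.synth`) produces landmark tables, ECG
and IBI series with *known* Gamma signatures, a configurable shape–scale
law, control→pain NSR shifts, and lagged face–heart coupling — every stage
of the analysis is validated by recovering what the generator injected.

## Worked example

`examples/01_face_mms_pipeline.py` generates one minute of landmark data
whose ophthalmic (V1) region carries a Gamma(3, 0.1) spike signature, then
runs the full face pipeline:

```
$ python examples/01_face_mms_pipeline.py
landmark table: 1800 frames x 138 columns
pooled V1 spikes: n = 5026, mean magnitude = 0.299
Gamma shape: 3.102  (true 3.0; 95% CI 2.987-3.217)
Gamma scale (= NSR): 0.0964  (true 0.1; 95% CI 0.0926-0.1003)
skewness 2/sqrt(shape) = 1.136
```

The fitted shape and scale bracket the injected truth: the speed →
deviation → spike → Gamma chain inverts the generator. The NSR (= scale)
is the headline number — higher means noisier, more dispersed
micro-movements. The other examples cover the cardiac chain
(`02_heart_hrv.py`), the cohort power law (`03_shape_scale_law.py`),
directional transfer entropy (`04_transfer_entropy.py`) and the end-to-end
file pipeline (`05_full_cohort_pipeline.py`).

A thin CLI wraps the pipeline for shell use:

```bash
mmskit simulate --out data/ --participants 6 --duration 60 --level raw
mmskit analyze --in data/ --out results/
mmskit report --in results/
```

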