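"""Cardiac pipeline: ECG -> R-peaks -> IBI -> HRV descriptors -> IBI MMS.

Simulates ten minutes of inter-beat intervals with a Gamma(2, 0.05) spike
signature, renders an ECG, and runs the extraction chain: R-peak detection,
the Poincaré SD1/SD2 summary, LF/HF band powers of the tachogram, and the
Gamma fit of the standardized IBI spikes.
"""

from mmskit import (
    band_powers,
    build_ibi,
    detect_r_peaks,
    fit_gamma_mle,
    gen_ecg_from_ibi,
    gen_ibi_series,
    ibi_mms,
    poincare_sd,
)
from mmskit.synth import RegimeSpec

true = RegimeSpec(2.0, 0.05)
ibi_true = gen_ibi_series(base_ibi=800.0, spec=true, duration=600.0, seed=4)
ecg = gen_ecg_from_ibi(ibi_true, fs=250.0, seed=2)
print(f"ECG: {ecg.duration_s:.0f} s at {ecg.fs:.0f} Hz, "
      f"{len(ibi_true.r_times)} true beats")

r_times = detect_r_peaks(ecg)
ibi = build_ibi(r_times)
print(f"detected {len(r_times)} R-peaks "
      f"(mean interval {ibi.intervals.mean():.1f} ms)")

p = poincare_sd(ibi)
print(f"Poincaré SD1 = {p.sd1:.1f} ms (beat-to-beat), "
      f"SD2 = {p.sd2:.1f} ms (long-term)")

bands = band_powers(ibi)
print(f"LF power = {bands.lf_power:.0f} ms^2, HF power = {bands.hf_power:.0f} ms^2, "
      f"LF/HF = {bands.lf_hf_ratio:.2f}")

fit = fit_gamma_mle(ibi_mms(ibi).peak_values)
print(f"IBI MMS Gamma fit: shape {fit.shape:.2f}, NSR {fit.nsr:.4f} "
      f"(injected {true.shape}, {true.scale})")
fit_direct = fit_gamma_mle(ibi_mms(ibi_true).peak_values)
print(f"  on the true intervals (no ECG round trip): shape {fit_direct.shape:.2f}, "
      f"NSR {fit_direct.nsr:.4f}")
# SD1/SD2 summarize the lag-1 interval scatter; the Gamma NSR of the MMS
# spikes summarizes the dispersion of the standardized fluctuations.  R-time
# quantization at 250 Hz (4 ms) and detection jitter perturb the interval
# waveform, visibly attenuating the NSR relative to the direct-interval fit —
# the same sensitivity a real recording has to its sampling resolution.
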