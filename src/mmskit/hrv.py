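"""Heart-rate-variability descriptors: R-peak detection, IBI, Poincaré, bands.

From a single-lead ECG voltage trace the pipeline extracts R-peak times,
forms the inter-beat-interval (IBI) series (the tachogram), and summarizes
its variability two ways:

* time domain — the Poincaré plot of (IBI_t, IBI_{t+1}); the standard
  deviations along the minor and major ellipse axes, SD1 and SD2, index
  short-term (parasympathetic) and long-term (sympathetic) variability;
* frequency domain — Welch band power of the evenly resampled tachogram in
  the LF (0.04-0.15 Hz, sympathetic) and HF (0.15-0.40 Hz, parasympathetic)
  bands.

Conventions that the magnitudes depend on are fixed here and documented:
population (1/n) variance throughout the Poincaré computation; tachogram
resampled at 4 Hz by cubic interpolation; Welch with 60 s Hann segments and
50% overlap.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import interpolate, signal

from .mms import MMSSeries, mms_transform

logger = logging.getLogger(__name__)

__all__ = [
    "ECGRecord",
    "IBISeries",
    "PoincareSummary",
    "SpectralBands",
    "detect_r_peaks",
    "build_ibi",
    "poincare_sd",
    "band_powers",
    "ibi_mms",
]

#: physiologically plausible interval range in ms; values outside are flagged
ARTIFACT_BOUNDS_MS = (300.0, 2000.0)


@dataclass(frozen=True)
class ECGRecord:
    """Voltage samples (arbitrary units) at a fixed sampling rate."""

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        v = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", v)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if np.any(~np.isfinite(v)):
            raise ValueError("ECG samples must be finite")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


@dataclass(frozen=True)
class IBISeries:
    """R-peak times (ms, strictly increasing) and successive intervals (ms).

    ``artifact_mask`` marks intervals outside the physiologically plausible
    range; flagged intervals are retained in ``intervals`` but excluded by
    :meth:`clean_intervals`.
    """

    r_times: np.ndarray
    intervals: np.ndarray
    artifact_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        r = np.asarray(self.r_times, dtype=float)
        iv = np.asarray(self.intervals, dtype=float)
        object.__setattr__(self, "r_times", r)
        object.__setattr__(self, "intervals", iv)
        if len(r) >= 2 and not np.all(np.diff(r) > 0):
            raise ValueError("R-peak times must be strictly increasing")
        if len(iv) != max(len(r) - 1, 0):
            raise ValueError("interval count must be len(r_times) - 1")
        if self.artifact_mask is not None:
            m = np.asarray(self.artifact_mask, dtype=bool)
            object.__setattr__(self, "artifact_mask", m)
            if len(m) != len(iv):
                raise ValueError("artifact mask length mismatch")

    def clean_intervals(self) -> np.ndarray:
        if self.artifact_mask is None:
            return self.intervals
        return self.intervals[~self.artifact_mask]

    @property
    def duration_s(self) -> float:
        return float(self.r_times[-1] - self.r_times[0]) / 1000.0 if len(self.r_times) else 0.0


@dataclass(frozen=True)
class PoincareSummary:
    sd1: float  # ms, minor axis: beat-to-beat variability
    sd2: float  # ms, major axis: long-term variability


@dataclass(frozen=True)
class SpectralBands:
    lf_power: float  # ms^2, 0.04-0.15 Hz
    hf_power: float  # ms^2, 0.15-0.40 Hz

    @property
    def lf_hf_ratio(self) -> float:
        if self.hf_power <= 0:
            raise ZeroDivisionError("LF/HF ratio undefined: HF power is zero")
        return self.lf_power / self.hf_power


def detect_r_peaks(
    ecg: ECGRecord,
    *,
    band_hz: tuple[float, float] = (5.0, 30.0),
    refractory_s: float = 0.25,
    threshold_frac: float = 0.4,
    min_duration_s: float = 10.0,
) -> np.ndarray:
    """Locate R-peak times (ms) by band-pass + adaptive-threshold peak picking.

    The record is linearly detrended, zero-phase band-pass filtered, and peaks
    above ``threshold_frac`` of the robust (99.9th-percentile) filtered
    amplitude are picked with a refractory period.  Candidates are then
    refined to the argmax of the detrended raw signal within +-40 ms, so peak
    times land on the true R crest rather than a filter artifact.  A record
    with no suprathreshold peaks returns an empty array with a warning.
    """
    if ecg.duration_s < min_duration_s:
        raise ValueError(f"record shorter than {min_duration_s} s")
    fs = ecg.fs
    x = signal.detrend(ecg.samples)
    # zero-pad a second on each side so beats at the record boundaries are
    # interior to the filter and the peak picker
    npad = int(round(fs))
    xp = np.concatenate([np.zeros(npad), x, np.zeros(npad)])
    hi = min(band_hz[1], 0.45 * fs)
    sos = signal.butter(2, [band_hz[0], hi], btype="bandpass", fs=fs, output="sos")
    f = signal.sosfiltfilt(sos, xp)
    scale = np.percentile(f, 99.9)
    if scale <= 0 or np.ptp(f) == 0:
        warnings.warn("no R-peaks found (flat or non-positive filtered signal)")
        return np.array([], dtype=float)
    height = threshold_frac * scale
    idx, _ = signal.find_peaks(f, height=height, distance=max(1, int(refractory_s * fs)))
    if len(idx) == 0:
        warnings.warn("no R-peaks found above threshold")
        return np.array([], dtype=float)
    # refine on the padded detrended raw trace, then map back
    w = max(1, int(round(0.04 * fs)))
    refined = np.empty(len(idx), dtype=int)
    for k, i in enumerate(idx):
        lo = max(0, i - w)
        hi_i = min(len(xp), i + w + 1)
        refined[k] = lo + int(np.argmax(xp[lo:hi_i]))
    refined = np.unique(refined) - npad
    refined = refined[(refined >= 0) & (refined < len(x))]
    return refined / fs * 1000.0


def build_ibi(r_times: np.ndarray, *, flag_artifacts: bool = True) -> IBISeries:
    """Successive differences of R-peak times, with optional artifact flags.

    Intervals outside ``ARTIFACT_BOUNDS_MS`` are flagged (retained in the raw
    series, excluded by downstream fits via :meth:`IBISeries.clean_intervals`).
    """
    r = np.asarray(r_times, dtype=float)
    if len(r) < 2:
        raise ValueError("need at least 2 R-peaks to form intervals")
    if not np.all(np.diff(r) > 0):
        raise ValueError("R-peak times must be strictly increasing")
    iv = np.diff(r)
    mask = None
    if flag_artifacts:
        lo, hi = ARTIFACT_BOUNDS_MS
        mask = (iv < lo) | (iv > hi)
        if mask.any():
            logger.warning("flagged %d physiologically implausible intervals", int(mask.sum()))
    return IBISeries(r_times=r, intervals=iv, artifact_mask=mask)


def poincare_sd(ibi: IBISeries) -> PoincareSummary:
    """SD1/SD2 of the lag-1 Poincaré scatter (population variance).

    With pairs (x_t, x_{t+1}), SD1 = SD((x_{t+1}-x_t)/sqrt(2)) and
    SD2 = SD((x_{t+1}+x_t)/sqrt(2)) — exactly the standard deviations of the
    scatter projected on the ellipse axes (the identity line and its
    perpendicular).  SD2 equals the classic sqrt(2 Var(x) - SD1^2) form up to
    O(1/n) edge terms.
    """
    x = ibi.intervals
    if len(x) < 3:
        raise ValueError("need at least 3 intervals for a Poincaré summary")
    a, b = x[:-1], x[1:]
    sd1_sq = np.var(b - a) / 2.0
    sd2_sq = np.var(b + a) / 2.0
    if sd1_sq < 0 or sd2_sq < 0:  # numerically impossible, but clamp per contract
        warnings.warn("negative Poincaré radicand clamped to 0")
    return PoincareSummary(
        sd1=float(np.sqrt(max(sd1_sq, 0.0))),
        sd2=float(np.sqrt(max(sd2_sq, 0.0))),
    )


def band_powers(
    ibi: IBISeries,
    *,
    resample_hz: float = 4.0,
    lf_band: tuple[float, float] = (0.04, 0.15),
    hf_band: tuple[float, float] = (0.15, 0.40),
    segment_s: float = 60.0,
    min_duration_s: float = 60.0,
) -> SpectralBands:
    """LF/HF band powers of the tachogram via a Welch periodogram.

    The unevenly sampled tachogram (interval i located at the time of the beat
    completing it) is cubic-interpolated onto a uniform ``resample_hz`` grid;
    the Welch estimate uses Hann windows of ``segment_s`` with 50% overlap and
    constant detrending.  Band powers integrate the density over the stated
    bands (trapezoid rule).
    """
    if ibi.duration_s < min_duration_s:
        raise ValueError(
            f"record of {ibi.duration_s:.1f} s shorter than required {min_duration_s} s"
        )
    t = ibi.r_times[1:] / 1000.0
    v = ibi.intervals
    grid = np.arange(t[0], t[-1], 1.0 / resample_hz)
    tach = interpolate.CubicSpline(t, v)(grid)
    nperseg = min(len(tach), int(segment_s * resample_hz))
    freqs, psd = signal.welch(
        tach,
        fs=resample_hz,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend="constant",
    )

    def _band(lo: float, hi: float) -> float:
        m = (freqs >= lo) & (freqs <= hi)
        if m.sum() < 2:
            return 0.0
        return float(np.trapezoid(psd[m], freqs[m]))

    return SpectralBands(lf_power=_band(*lf_band), hf_power=_band(*hf_band))


def ibi_mms(ibi: IBISeries, *, min_peaks: int = 30, **kwargs) -> MMSSeries:
    """MMS standardization of the interval sequence.

    Identical pipeline to the facial-speed MMS, applied to the beat-indexed
    interval series: Gamma mean from the raw interval peaks, absolute
    deviations, local peak/average normalization.  Artifact-flagged intervals
    participate in the frame-preserving output, but callers fitting the spike
    distribution should rely on the flags upstream.
    """
    if len(ibi.intervals) < 3:
        raise ValueError("need at least 3 intervals for MMS standardization")
    if np.ptp(ibi.intervals) == 0:  # constant rhythm: no fluctuations, no spikes
        return MMSSeries(values=np.zeros(len(ibi.intervals)), fps=None)
    return mms_transform(ibi.intervals, fps=None, min_peaks=min_peaks, **kwargs)
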