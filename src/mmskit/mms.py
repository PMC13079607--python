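"""Micro-movement spike (MMS) standardization of positional and interval series.

The MMS transform converts a raw biorhythmic series (facial landmark speed in
pixels/s, or heart inter-beat intervals in ms) into a frame-preserving spike
train in [0, 1).  The steps are:

1. detect the local peaks of the raw series and fit the continuous Gamma family
   to their magnitudes; the fitted Gamma mean is the empirical reference level;
2. form the series of absolute deviations from that mean;
3. at each local peak of the deviation series, emit a spike

       MMS = Peak / (Peak + Avrg_{min-to-min})

   where ``Peak`` is the deviation-peak magnitude and ``Avrg`` is the local
   average of the raw series over the closed window bounded by the two valleys
   flanking the peak.  All other frames carry 0, which represents motion at the
   mean level.

The denominator's local averaging removes allometric (anatomical-scale)
effects: multiplying the raw series by any k > 0 leaves every spike value
unchanged, so fluctuation magnitudes are comparable across individuals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import UnivariateSpline

logger = logging.getLogger(__name__)

__all__ = [
    "SpeedSeries",
    "PeakSet",
    "MMSSeries",
    "smooth_positions",
    "speed_profile",
    "detect_extrema",
    "mms_from_series",
    "mms_transform",
    "pool_region_mms",
]


@dataclass(frozen=True)
class SpeedSeries:
    """Uniformly sampled speed magnitudes (pixels/s or ms, always >= 0)."""

    values: np.ndarray
    fps: float
    source_landmarks: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1:
            raise ValueError("speed values must be one-dimensional")
        if np.any(v < 0):
            raise ValueError("speed magnitudes must be non-negative")


@dataclass(frozen=True)
class PeakSet:
    """Local maxima of a series with their flanking valleys.

    ``left_valley[i] < peak_indices[i] < right_valley[i]`` for every peak.
    Valleys are positions where the forward difference changes sign from
    negative to positive; boundary samples count as valleys when the series
    moves away from them.  A plateau (run of equal values bounded by lower
    neighbours) is one extremum located at the run's first index.
    """

    peak_indices: np.ndarray
    left_valley: np.ndarray
    right_valley: np.ndarray
    valley_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        p = np.asarray(self.peak_indices, dtype=int)
        lv = np.asarray(self.left_valley, dtype=int)
        rv = np.asarray(self.right_valley, dtype=int)
        object.__setattr__(self, "peak_indices", p)
        object.__setattr__(self, "left_valley", lv)
        object.__setattr__(self, "right_valley", rv)
        object.__setattr__(self, "valley_indices", np.asarray(self.valley_indices, dtype=int))
        if not (len(p) == len(lv) == len(rv)):
            raise ValueError("peak and valley arrays must have equal length")
        if len(p) and not (np.all(lv < p) and np.all(p < rv)):
            raise ValueError("valleys must strictly flank their peaks")
        if len(p) > 1 and not np.all(np.diff(p) > 0):
            raise ValueError("peaks must be strictly increasing")

    def __len__(self) -> int:
        return len(self.peak_indices)


@dataclass(frozen=True)
class MMSSeries:
    """Frame-preserving standardized spike train.

    ``values`` has the same length as the source series; entries are in
    [0, 1), zero exactly at non-peak frames.  ``fps`` is None for series on a
    non-temporal index (e.g. beat-indexed inter-beat intervals).
    """

    values: np.ndarray
    fps: float | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if np.any(v < 0) or np.any(v >= 1):
            raise ValueError("MMS values must lie in [0, 1)")

    @property
    def peak_values(self) -> np.ndarray:
        """Spike magnitudes only (strictly positive entries)."""
        return self.values[self.values > 0]

    @property
    def spike_frames(self) -> np.ndarray:
        return np.flatnonzero(self.values > 0)

    def __len__(self) -> int:
        return len(self.values)


def _estimate_noise_variance(x: np.ndarray) -> float:
    # Second-difference estimator: for x = signal + white noise,
    # E[(d2 x)^2] = 6 sigma^2 + (signal curvature)^2, and the curvature term
    # is negligible for smooth signals at video frame rates.
    d2 = np.diff(x, n=2)
    if len(d2) == 0:
        return 0.0
    return float(np.mean(d2**2) / 6.0)


def smooth_positions(
    x: np.ndarray,
    y: np.ndarray,
    fps: float,
    smoothing: float | None = None,
    smooth_factor: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Cubic smoothing-spline fit of a pixel trajectory, on the original grid.

    ``smoothing`` is the spline residual budget ``s`` (see
    :class:`scipy.interpolate.UnivariateSpline`).  When None, it is set to
    ``smooth_factor * n * sigma^2`` with ``sigma^2`` estimated from second
    differences, so noise-free polynomial inputs are reproduced exactly while
    unit-variance white noise is attenuated at least tenfold.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be one-dimensional and equally long")
    if len(x) < 4:
        raise ValueError("need at least 4 samples for cubic spline smoothing")
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        raise ValueError("missing or non-finite values: fill gaps before smoothing")
    t = np.arange(len(x)) / float(fps)
    out = []
    for c in (x, y):
        s = smoothing
        if s is None:
            s = smooth_factor * len(c) * _estimate_noise_variance(c)
        spl = UnivariateSpline(t, c, k=3, s=s)
        out.append(spl(t))
    return out[0], out[1]


def speed_profile(
    x: np.ndarray,
    y: np.ndarray,
    fps: float,
    source_landmarks: tuple[int, ...] = (),
) -> SpeedSeries:
    """Per-frame speed magnitude (units/s) from a smoothed trajectory.

    Derivatives use central differences (one-sided at the ends) scaled by the
    frame rate; speed is the Euclidean norm of the velocity components.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    vx = np.gradient(x) * fps
    vy = np.gradient(y) * fps
    return SpeedSeries(values=np.hypot(vx, vy), fps=fps, source_landmarks=source_landmarks)


def detect_extrema(series: np.ndarray) -> PeakSet:
    """Locate local maxima and their flanking minima by slope sign changes.

    A peak is a sample where the forward difference changes sign from positive
    to negative; a valley, from negative to positive.  Plateaus count once at
    their first index.  Boundary samples are valleys when the series moves
    away (upward) from them; boundaries are never peaks, so every reported
    peak has both flanking valleys.  A monotone series yields an empty set.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("need a one-dimensional series of length >= 3")
    d = np.diff(x)
    s = np.sign(d)
    nz = np.flatnonzero(s)
    empty = np.array([], dtype=int)
    if len(nz) == 0:  # constant series
        return PeakSet(empty, empty, empty, empty)
    sn = s[nz]
    trans = np.flatnonzero(sn[1:] != sn[:-1]) + 1  # positions in nz where sign flips
    peaks = nz[trans[sn[trans] < 0] - 1] + 1 if len(trans) else empty
    valleys = nz[trans[sn[trans] > 0] - 1] + 1 if len(trans) else empty
    peaks = np.asarray(peaks, dtype=int)
    valleys = list(np.asarray(valleys, dtype=int))
    if sn[0] > 0:
        valleys.insert(0, 0)
    if sn[-1] < 0:
        valleys.append(len(x) - 1)
    valleys_arr = np.asarray(sorted(valleys), dtype=int)
    if len(peaks) == 0:
        return PeakSet(empty, empty, empty, valleys_arr)
    pos = np.searchsorted(valleys_arr, peaks)
    left = valleys_arr[pos - 1]
    right = valleys_arr[pos]
    return PeakSet(peaks, left, right, valleys_arr)


def mms_from_series(
    series: np.ndarray,
    gamma_mean: float,
    peaks: PeakSet | None = None,
    *,
    avg_on: str = "original",
    deviations: str = "absolute",
    fps: float | None = None,
) -> MMSSeries:
    """Standardize a raw series into micro-movement spikes.

    Parameters
    ----------
    series
        Raw positive-valued series (speed in pixels/s, or IBI in ms).
    gamma_mean
        Empirical Gamma mean of the raw peak magnitudes (shape * scale from a
        maximum-likelihood fit); use :func:`mms_transform` to run the full
        pipeline including this fit.
    peaks
        Extrema of the deviation series; computed here when omitted.  If
        supplied, they must have been computed on the same deviation series.
    avg_on
        Series on which the local min-to-min average is computed.  The default
        ``"original"`` averages the raw series between the flanking valleys,
        so deviation peaks that are small against the raw signal level produce
        small spikes.  ``"deviation"`` averages the deviation series itself
        (a stricter reading that confines spikes to [0.5, 1)).
    deviations
        ``"absolute"`` uses |series - mean|; ``"positive"`` keeps only upward
        deviations (downward excursions clipped to zero).
    """
    x = np.asarray(series, dtype=float)
    if avg_on not in ("original", "deviation"):
        raise ValueError(f"unknown avg_on mode {avg_on!r}")
    if deviations == "absolute":
        dev = np.abs(x - gamma_mean)
    elif deviations == "positive":
        dev = np.clip(x - gamma_mean, 0.0, None)
    else:
        raise ValueError(f"unknown deviations mode {deviations!r}")
    if peaks is None:
        peaks = detect_extrema(dev)
    base = x if avg_on == "original" else dev
    cs = np.concatenate([[0.0], np.cumsum(base)])
    values = np.zeros_like(x)
    p, lv, rv = peaks.peak_indices, peaks.left_valley, peaks.right_valley
    n_skipped = 0
    for i in range(len(p)):
        peak_mag = dev[p[i]]
        avg = (cs[rv[i] + 1] - cs[lv[i]]) / (rv[i] + 1 - lv[i])
        if peak_mag == 0.0 and avg == 0.0:
            n_skipped += 1
            continue
        values[p[i]] = peak_mag / (peak_mag + avg)
    if n_skipped:
        logger.warning("skipped %d degenerate flat spikes (Peak = Avg = 0)", n_skipped)
    return MMSSeries(values=values, fps=fps)


def mms_transform(
    series: np.ndarray,
    *,
    fps: float | None = None,
    min_peaks: int = 30,
    avg_on: str = "original",
    deviations: str = "absolute",
) -> MMSSeries:
    """Full MMS pipeline: raw peaks -> Gamma mean -> deviations -> spikes.

    Fits the Gamma family to the magnitudes of the raw-series peaks (requires
    at least ``min_peaks`` of them), then applies :func:`mms_from_series` with
    the fitted mean.
    """
    from .gamma import fit_gamma_mle  # local import: gamma depends on nothing here

    x = np.asarray(series, dtype=float)
    raw_peaks = detect_extrema(x)
    mags = x[raw_peaks.peak_indices]
    mags = mags[mags > 0]
    if len(mags) < min_peaks:
        raise ValueError(
            f"only {len(mags)} positive raw peaks; need >= {min_peaks} for the Gamma mean"
        )
    fit = fit_gamma_mle(mags, min_n=min_peaks)
    return mms_from_series(
        x, fit.mean, avg_on=avg_on, deviations=deviations, fps=fps
    )


def pool_region_mms(
    per_landmark_mms: dict[int, MMSSeries],
    region: str,
    regions: dict[str, tuple[int, ...]] | None = None,
) -> np.ndarray:
    """Concatenate spike magnitudes across a facial region's landmarks.

    The concatenation follows the region table's canonical landmark order,
    so the pooled vector does not depend on the mapping's insertion order.
    """
    from .regions import DEFAULT_REGIONS

    table = regions if regions is not None else DEFAULT_REGIONS
    if region not in table:
        raise ValueError(f"unknown region label {region!r}; expected one of {tuple(table)}")
    order = [i for i in table[region] if i in per_landmark_mms]
    if not order:
        raise ValueError(f"no landmarks supplied for region {region!r}")
    lengths = {len(per_landmark_mms[i]) for i in order}
    fpss = {per_landmark_mms[i].fps for i in order}
    if len(lengths) > 1 or len(fpss) > 1:
        raise ValueError("all landmark MMS series must share frame count and fps")
    return np.concatenate([per_landmark_mms[i].peak_values for i in order])
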