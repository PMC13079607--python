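"""Shannon entropy and windowed transfer entropy between MMS streams.

Transfer entropy (TE) from a source stream X to a target stream Y with
history length L is the conditional mutual information

    T(X -> Y) = H(Y_t | Y_{t-1:t-L}) - H(Y_t | Y_{t-1:t-L}, X_{t-1:t-L})
              = I(Y_t ; X_{t-1:t-L} | Y_{t-1:t-L}),

in bits: the reduction in uncertainty about the target's present provided by
the source's recent past beyond the target's own past.  Two estimators are
provided:

* ``binned`` — an equal-frequency discretized plug-in estimator.  Transparent
  and oracle-checkable, but upward biased by roughly df / (2 N ln 2) per
  window; it needs short histories (L = 1-2) and long windows to be
  informative, and degenerates when the joint alphabet dwarfs the window.
* ``gaussian`` — the linear-Gaussian TE, 1/2 log2 of the residual-variance
  ratio of nested least-squares autoregressions (target's own lags vs own
  plus source lags).  It is non-negative by construction, admits an analytic
  oracle under linear lagged coupling, and remains usable at the 50-frame /
  5-lag windowing because the comparison of the two directions shares the
  same overfitting bias.

Windows are non-overlapping and complete, and embedding vectors never cross a
window edge.  By default (``pooled=True``) the embedded samples from all
windows feed a single estimate over the analysis span, the way continuous TE
toolkits treat a recording; ``pooled=False`` instead estimates TE per window
and reports the mean.  Per-window estimation at the 50/5 setting is noisy (45
transitions against an 11-regressor model, or a 4^11-state alphabet) and is
retained for window-resolved exploration, not for direction inference.
Streams must share one uniform frame grid;
:func:`heart_mms_to_frames` maps a beat-indexed heart spike train onto the
30 Hz face grid (each spike placed at the frame of the beat completing its
interval, zeros elsewhere).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .hrv import IBISeries
from .mms import MMSSeries

logger = logging.getLogger(__name__)

__all__ = [
    "TEConfig",
    "TEResult",
    "TECurveSet",
    "shannon_entropy",
    "transfer_entropy",
    "te_both_directions",
    "build_te_curves",
    "heart_mms_to_frames",
    "source_amplitude_hold",
]


@dataclass(frozen=True)
class TEConfig:
    """Windowing and estimator settings for transfer entropy.

    Defaults mirror the study constants: 50-frame windows with 10% of the
    window as history (L = 5 frames, ~167 ms at 30 Hz) over a 300-frame
    (10 s) analysis span.  ``total_frames=None`` uses the full stream.
    """

    window: int = 50
    history_fraction: float = 0.10
    total_frames: int | None = 300
    estimator: str = "binned"
    n_bins: int = 4
    binarize: bool = False
    pooled: bool = True

    @property
    def history(self) -> int:
        """History length L in frames (at least 1)."""
        return max(1, int(round(self.window * self.history_fraction)))

    def __post_init__(self) -> None:
        if self.estimator not in ("binned", "gaussian"):
            raise ValueError(f"unknown estimator {self.estimator!r}")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if not 1 <= self.history < self.window:
            raise ValueError("need 1 <= history < window")
        if self.total_frames is not None and self.window > self.total_frames:
            raise ValueError("window exceeds the analysis span")


@dataclass(frozen=True)
class TEResult:
    """Windowed transfer entropy for one direction.

    ``per_window`` holds the per-window estimates (``pooled=False``) or a
    single pooled estimate; ``te_bits`` is always their mean.
    """

    direction: str
    te_bits: float
    per_window: np.ndarray
    config: TEConfig
    n_skipped: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "per_window", np.asarray(self.per_window, dtype=float))


@dataclass(frozen=True)
class TECurveSet:
    """Sorted-curve representation of cohort TE values.

    Participants are ordered by the TE of ``sort_direction`` (ascending, ties
    broken by participant id); ``matched_values`` carries the opposite
    direction in the same order and ``differences = matched - sorted``.
    """

    sort_direction: str
    participants: tuple
    sorted_values: np.ndarray
    matched_values: np.ndarray

    @property
    def differences(self) -> np.ndarray:
        return self.matched_values - self.sorted_values


def shannon_entropy(p: np.ndarray) -> float:
    """H(p) = -sum p log2 p in bits, with 0 log 0 = 0.

    The distribution must be non-negative and sum to 1 within 1e-9.  (The
    signed definition is used throughout; an unsigned variant sometimes seen
    in print is a typographical artifact.)
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("probabilities must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"distribution sums to {p.sum()!r}, not 1")
    nz = p[p > 0]
    return float(-np.sum(nz * np.log2(nz)))


def _entropy_from_counts(counts: np.ndarray) -> float:
    n = counts.sum()
    p = counts / n
    return float(-np.sum(p * np.log2(p)))


def _discretize(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency binning via sample quantiles (ties may merge bins)."""
    edges = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(edges, x, side="right")


def _embed(y: np.ndarray, x: np.ndarray, L: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rows (Y_t, Y_{t-1:t-L}, X_{t-1:t-L}) for t = L .. len-1."""
    t = np.arange(L, len(y))
    yt = y[t]
    yh = np.stack([y[t - k] for k in range(1, L + 1)], axis=1)
    xh = np.stack([x[t - k] for k in range(1, L + 1)], axis=1)
    return yt, yh, xh


def _joint_entropy(*cols: np.ndarray) -> float:
    rows = np.column_stack([np.atleast_2d(c.T).T for c in cols])
    _, counts = np.unique(rows, axis=0, return_counts=True)
    return _entropy_from_counts(counts)


def _binned_te_window(yt: np.ndarray, yh: np.ndarray, xh: np.ndarray) -> float:
    # H(Y_t | Y_hist) - H(Y_t | Y_hist, X_hist), each conditional entropy as a
    # difference of joint entropies.
    h_yyh = _joint_entropy(yt, yh)
    h_yh = _joint_entropy(yh)
    h_yhxh = _joint_entropy(yh, xh)
    h_all = _joint_entropy(yt, yh, xh)
    return (h_yyh - h_yh) - (h_all - h_yhxh)


def _gaussian_te_window(yt: np.ndarray, yh: np.ndarray, xh: np.ndarray) -> float:
    n = len(yt)
    ones = np.ones((n, 1))
    restricted = np.hstack([ones, yh])
    full = np.hstack([ones, yh, xh])
    rss_r = _rss(restricted, yt)
    rss_f = _rss(full, yt)
    if rss_f <= 0 or rss_r <= 0:
        return 0.0 if rss_r <= 0 else float(0.5 * np.log2(rss_r / max(rss_f, 1e-300)))
    return float(max(0.5 * np.log2(rss_r / rss_f), 0.0))


def _rss(design: np.ndarray, y: np.ndarray) -> float:
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return float(resid @ resid)


def _as_values(stream) -> np.ndarray:
    if isinstance(stream, MMSSeries):
        return stream.values
    return np.asarray(stream, dtype=float)


def transfer_entropy(source, target, config: TEConfig | None = None, *,
                     direction: str = "source->target") -> TEResult:
    """Windowed transfer entropy from ``source`` to ``target`` in bits.

    Both streams must live on the same uniform grid and have equal length at
    least one window.  For the binned estimator, values are discretized into
    equal-frequency bins computed over the whole analysis span (so windows
    share one alphabet); ``config.binarize`` instead reduces each stream to
    spike/no-spike.  Windows whose target is constant are skipped with a
    warning.
    """
    cfg = config or TEConfig()
    x = _as_values(source)
    y = _as_values(target)
    if len(x) != len(y):
        raise ValueError(f"stream lengths differ: {len(x)} vs {len(y)}")
    span = len(y) if cfg.total_frames is None else min(cfg.total_frames, len(y))
    if span < cfg.window:
        raise ValueError("streams shorter than one analysis window")
    x = x[:span]
    y = y[:span]
    if cfg.estimator == "binned":
        if cfg.binarize:
            xd, yd = (x > 0).astype(int), (y > 0).astype(int)
        else:
            xd, yd = _discretize(x, cfg.n_bins), _discretize(y, cfg.n_bins)
    else:
        xd, yd = x, y
    L = cfg.history
    estimate = _binned_te_window if cfg.estimator == "binned" else _gaussian_te_window
    embeddings = []
    n_skipped = 0
    for start in range(0, span - cfg.window + 1, cfg.window):
        yw = yd[start : start + cfg.window]
        xw = xd[start : start + cfg.window]
        if np.ptp(yw) == 0:
            n_skipped += 1
            continue
        embeddings.append(_embed(yw, xw, L))
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} constant-target windows")
    if not embeddings:
        warnings.warn("no usable windows: TE undefined, reporting NaN")
        return TEResult(direction, float("nan"), np.array([]), cfg, n_skipped)
    if cfg.pooled:
        yt = np.concatenate([e[0] for e in embeddings])
        yh = np.vstack([e[1] for e in embeddings])
        xh = np.vstack([e[2] for e in embeddings])
        per_window = [estimate(yt, yh, xh)]
    else:
        per_window = [estimate(yt, yh, xh) for yt, yh, xh in embeddings]
    pw = np.asarray(per_window)
    return TEResult(direction, float(pw.mean()), pw, cfg, n_skipped)


def te_both_directions(face, heart, config: TEConfig | None = None
                       ) -> tuple[TEResult, TEResult]:
    """TE in both directions with identical settings.

    Returns ``(heart->face, face->heart)``: the first asks whether the
    heart's recent past reduces uncertainty about the present face stream
    beyond the face's own past; the second reverses the roles.
    """
    cfg = config or TEConfig()
    hf = transfer_entropy(heart, face, cfg, direction="heart->face")
    fh = transfer_entropy(face, heart, cfg, direction="face->heart")
    return hf, fh


def build_te_curves(cohort: dict, sort_direction: str = "heart->face") -> TECurveSet:
    """Sorted/matched TE curves across participants.

    ``cohort`` maps participant id -> dict with keys ``"heart->face"`` and
    ``"face->heart"`` (floats or :class:`TEResult`).  Participants missing a
    direction are excluded with a warning; sorting is ascending in the chosen
    direction with ties broken by participant id.
    """
    other = "face->heart" if sort_direction == "heart->face" else "heart->face"
    if sort_direction not in ("heart->face", "face->heart"):
        raise ValueError(f"unknown direction {sort_direction!r}")
    rows = []
    for pid, vals in cohort.items():
        try:
            a = vals[sort_direction]
            b = vals[other]
        except (KeyError, TypeError):
            warnings.warn(f"participant {pid!r} missing a TE direction; excluded")
            continue
        a = a.te_bits if isinstance(a, TEResult) else float(a)
        b = b.te_bits if isinstance(b, TEResult) else float(b)
        if np.isnan(a) or np.isnan(b):
            warnings.warn(f"participant {pid!r} has undefined TE; excluded")
            continue
        rows.append((a, str(pid), pid, b))
    if len(rows) < 2:
        raise ValueError("need at least 2 participants with both TE directions")
    rows.sort(key=lambda r: (r[0], r[1]))
    return TECurveSet(
        sort_direction=sort_direction,
        participants=tuple(r[2] for r in rows),
        sorted_values=np.array([r[0] for r in rows]),
        matched_values=np.array([r[3] for r in rows]),
    )


def heart_mms_to_frames(
    ibi: IBISeries,
    mms: MMSSeries,
    fps: float = 30.0,
    n_frames: int | None = None,
    *,
    hold: bool = True,
) -> MMSSeries:
    """Map beat-indexed heart MMS spikes onto a uniform frame grid.

    Interval i's spike lands at the frame of the beat that completes it
    (``r_times[i+1]``).  With ``hold=True`` (the default) the magnitude is
    held until the next spike (zero-order hold), which puts the sparsely
    sampled cardiac stream on a footing comparable to the 30 Hz face stream
    for transfer-entropy estimation; ``hold=False`` keeps a sparse spike
    train (zeros between spikes).  Colliding spikes keep the larger
    magnitude.
    """
    if n_frames is None:
        n_frames = int(np.ceil(ibi.r_times[-1] / 1000.0 * fps)) + 1
    out = np.zeros(n_frames)
    spike_idx = np.flatnonzero(mms.values > 0)
    frames = np.round(ibi.r_times[spike_idx + 1] / 1000.0 * fps).astype(int)
    keep = frames < n_frames
    for fr, val in zip(frames[keep], mms.values[spike_idx][keep]):
        out[fr] = max(out[fr], val)
    if hold:
        out = source_amplitude_hold(out)
    return MMSSeries(values=out, fps=fps)


def source_amplitude_hold(values: np.ndarray) -> np.ndarray:
    """Zero-order hold of a spike train: each frame carries the most recent
    spike magnitude (0 before the first spike)."""
    v = np.asarray(values, dtype=float)
    out = np.zeros_like(v)
    last = 0.0
    for i, val in enumerate(v):
        if val > 0:
            last = val
        out[i] = last
    return out
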