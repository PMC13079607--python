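"""Synthetic face/heart cohorts with known Gamma signatures and coupling.

Every downstream stage of the analysis (MMS standardization, Gamma fitting,
HRV descriptors, transfer entropy, cohort statistics) can be validated
against this module because each generated signal carries a recoverable
ground truth:

* **Inverse-designed spike profiles.**  The MMS transform is scale invariant,
  so a target spike magnitude cannot be set by amplitude alone; it is set by
  the *shape* of the excursion.  Signals are built as a flat baseline ``C``
  (with a small per-segment level jitter so the raw-peak Gamma fit is well
  posed) interrupted by downward excursions: a linear ramp of ``h-1``
  interior samples down to a floor ``beta = C - P``, a dwell of ``L``
  samples, and a ramp back.  For the window running from the preceding gap's
  first sample to the following gap's first sample (exactly the valleys the
  extrema detector reports), the local average of the raw series is

      Avg = C - (h - 1 + L) * P / W,      W = G + 2h + L - 1,

  so the spike value v = P / (P + Avg) inverts in closed form:

      P = C / ((1 - v)/v + (h - 1 + L)/W).

  Small v needs only a shallow excursion; v near 1 is reached by lengthening
  the dwell L until the floor constraint beta >= beta_min C is met.  Target
  magnitudes are drawn i.i.d. from the requested Gamma(shape, scale) law
  (clipped at 0.95, where the inversion becomes ill-conditioned; for the
  regimes studied the clipped mass is negligible).

* **Cohort structure.**  Per-participant (shape, scale) pairs are drawn so
  log10(scale) follows a linear law in log10(shape) with configurable slope,
  intercept and residual noise; pain regimes shift the NSR (scale) upward,
  with the face and heart shifts linearly related at a tunable R^2.

* **Directional coupling.**  With direction ``heart->face`` the face spike
  magnitude at frame t mixes its own draw with the held magnitude of the most
  recent heart spike at t - lag:  v = (1 - strength) v_own + strength v_src.
  This linear lagged rule admits a Gaussian-limit transfer-entropy oracle and
  makes the injected direction recoverable.

All randomness flows through one :class:`numpy.random.Generator` derived from
the config seed; fixed seed implies bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hrv import IBISeries, ibi_mms
from .infodyn import heart_mms_to_frames, source_amplitude_hold
from .mms import MMSSeries
from .regions import DEFAULT_REGIONS, validate_regions

__all__ = [
    "RegimeSpec",
    "CouplingSpec",
    "SyntheticCohortConfig",
    "SyntheticCohort",
    "gen_gamma_mms_sample",
    "gen_ibi_series",
    "gen_ecg_from_ibi",
    "gen_face_landmarks",
    "gen_coupled_cohort",
]

V_MAX = 0.95  # spike-magnitude cap: the profile inversion degenerates above


@dataclass(frozen=True)
class RegimeSpec:
    """Gamma(shape, scale) regime for MMS spike magnitudes."""

    shape: float
    scale: float
    label: str = "control"

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("Gamma shape and scale must be positive")
        if self.label not in ("control", "pain"):
            raise ValueError(f"unknown condition label {self.label!r}")


@dataclass(frozen=True)
class CouplingSpec:
    """Lagged linear coupling between the heart and face spike streams."""

    direction: str = "none"
    lag: int = 1
    strength: float = 0.0

    def __post_init__(self) -> None:
        if self.direction not in ("heart->face", "face->heart", "none"):
            raise ValueError(f"unknown coupling direction {self.direction!r}")
        if self.lag < 1:
            raise ValueError("coupling lag must be >= 1 frame")
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("coupling strength must lie in [0, 1]")
        if self.direction == "none" and self.strength != 0.0:
            raise ValueError("direction 'none' forces strength = 0")


def _default_face_regimes() -> dict[str, RegimeSpec]:
    return {
        "control": RegimeSpec(4.0, 0.04, "control"),
        "pain": RegimeSpec(2.5, 0.08, "pain"),
    }


def _default_heart_regimes() -> dict[str, RegimeSpec]:
    return {
        "control": RegimeSpec(3.0, 0.05, "control"),
        "pain": RegimeSpec(2.0, 0.09, "pain"),
    }


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Study conditions for a synthetic cohort.

    Defaults emulate the study setting: 21 participants, 30 Hz video frame
    grid, ~800 ms resting inter-beat interval, control-to-pain NSR increases
    in both signals with the face and heart shifts linearly related at
    R^2 ~ 0.84, and a cohort-level log-log shape-scale law with negative
    slope.  ``level`` selects the materialization: ``"mms"`` yields paired
    spike trains on the common frame grid (exact ground truth, fast);
    ``"raw"`` additionally synthesizes landmark trajectory tables and ECG.
    """

    n_participants: int = 21
    duration: float = 120.0
    fps: float = 30.0
    face_regimes: dict[str, RegimeSpec] = field(default_factory=_default_face_regimes)
    heart_regimes: dict[str, RegimeSpec] = field(default_factory=_default_heart_regimes)
    coupling: CouplingSpec = field(default_factory=lambda: CouplingSpec("heart->face", 5, 0.5))
    loglog_slope: float = -1.2
    loglog_intercept: float = -0.675
    loglog_noise_sd: float = 0.02
    shape_log_spread: float = 0.1
    delta_r2_target: float = 0.84
    base_ibi: float = 800.0
    tasks: tuple[str, ...] = ("resting",)
    level: str = "mms"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")
        if self.fps <= 0 or self.duration <= 0:
            raise ValueError("fps and duration must be positive")
        if self.level not in ("mms", "raw"):
            raise ValueError(f"unknown level {self.level!r}")
        for regimes in (self.face_regimes, self.heart_regimes):
            if "pain" in regimes and "control" in regimes:
                if regimes["pain"].scale < regimes["control"].scale:
                    raise ValueError(
                        "pain regime scale below control: inconsistent NSR shift"
                    )


@dataclass
class SyntheticCohort:
    """Generated cohort: record table, per-record streams, and ground truth."""

    records: pd.DataFrame
    streams: dict
    truth: dict
    config: SyntheticCohortConfig


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def gen_gamma_mms_sample(spec: RegimeSpec, n: int, seed) -> np.ndarray:
    """n i.i.d. Gamma(shape, scale) draws of MMS spike magnitudes."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _as_rng(seed)
    return rng.gamma(spec.shape, spec.scale, size=n)


def _solve_spike(v: float, gap: int, h: int, l_min: int, beta_min_frac: float = 0.02
                 ) -> tuple[float, int]:
    """Invert a target spike magnitude into (excursion depth P/C, dwell L).

    Returns the depth as a fraction of the baseline; lengthens the dwell
    until the excursion floor stays above ``beta_min_frac`` of baseline.
    """
    v = min(v, V_MAX)
    L = l_min
    while True:
        W = gap + 2 * h + L - 1
        denom = (1.0 - v) / v + (h - 1 + L) / W
        p_frac = 1.0 / denom
        if p_frac <= 1.0 - beta_min_frac:
            return p_frac, L
        L += 1
        if L > 100_000:  # pragma: no cover - guarded by V_MAX
            raise RuntimeError("spike inversion failed to converge")


def _achieved_v_central(
    p_frac: float, gap_l: int, gap_r: int, h: int, L: int
) -> float:
    """Spike magnitude the analysis recovers after central differencing.

    Speed recomputed from integrated positions is the designed profile passed
    through the 2-tap kernel (s[t] + s[t-1]) / 2, which rounds the corners of
    the piecewise-linear excursion.  This helper builds one excursion flanked
    by its crests at unit baseline, applies the kernel, and evaluates the
    peak / (peak + local average) value the extrema detector will report.
    """
    depth = p_frac
    floor = 1.0 - depth
    seg = np.concatenate([
        np.ones(gap_l),
        1.0 - depth * np.arange(1, h) / h,
        np.full(L, floor),
        floor + depth * np.arange(1, h) / h,
        np.ones(gap_r),
    ])
    cd = 0.5 * (seg[1:] + seg[:-1])
    # the detector's window: the left crest run's first sample (plateau-first
    # valley) through the right crest run's first sample
    w = gap_l + 2 * h + L - 1
    avg = float(np.mean(cd[:w]))
    return float(depth / (depth + avg))


def _solve_spike_central(
    v: float, gap_l: int, gap_r: int, h: int, l_min: int, beta_min_frac: float = 0.02
) -> tuple[float, int]:
    """Invert a target magnitude against the central-difference kernel.

    Starts from the closed-form (flat-kernel) solution and refines the depth
    by the secant method on the kernel-exact forward map; lengthens the dwell
    when the floor constraint binds.
    """
    v = min(v, V_MAX)
    p0, L = _solve_spike(v, gap_l, h, l_min, beta_min_frac)
    p_hi = 1.0 - beta_min_frac
    while True:
        a, b = p0, min(p0 * 1.05, p_hi)
        fa = _achieved_v_central(a, gap_l, gap_r, h, L) - v
        for _ in range(40):
            fb = _achieved_v_central(b, gap_l, gap_r, h, L) - v
            if abs(fb) < 1e-9 or b == a:
                return b, L
            step = fb * (b - a) / (fb - fa) if fb != fa else 0.0
            a, fa = b, fb
            b = float(np.clip(b - step, 1e-9, p_hi))
        if _achieved_v_central(p_hi, gap_l, gap_r, h, L) >= v:
            return b, L
        L += 1  # target unreachable at this dwell: deepen via a longer floor
        p0 = min(p0, p_hi)


def _spike_profile(
    targets: np.ndarray,
    base: float,
    h: int,
    l_min: int,
    rng: np.random.Generator,
    gap_range: tuple[int, int] = (3, 9),
    n_samples: int | None = None,
    tilt: float = 0.0,
    kernel: str = "direct",
    beta_min_frac: float = 0.02,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Baseline-plus-excursion series whose MMS spikes equal ``targets``.

    Returns (series, spike_sample_indices, ramp_mask).  When ``n_samples``
    is given the series is padded/stopped at that length (a trailing partial
    excursion is dropped).  The mask marks ramp samples (used e.g. to
    confine heading changes to frames where the speed is changing anyway).

    ``tilt`` adds a per-sample monotone slope (fraction of ``base``) to gap
    and dwell runs.  Exactly flat runs survive direct analysis, but a series
    reconstructed from integrated positions carries float-level noise that
    would break plateaus into spurious micro-extrema; a tilt orders of
    magnitude above machine noise and below the designed excursions keeps
    every run's extremum unique without affecting the window averages.
    """
    jitter_sd = 0.002 * base * float(np.clip(np.mean(targets) / 0.05, 0.0, 1.0))
    slope = tilt * base
    segs: list[np.ndarray] = []
    spike_idx: list[int] = []
    bump_spans: list[tuple[int, int]] = []
    pos = 0

    def gap_block(g: int) -> np.ndarray:
        eps = rng.normal(0.0, jitter_sd) if jitter_sd > 0 else 0.0
        # ascending: the run's raw peak is its unique last sample
        return base + eps + slope * (np.arange(g) - (g - 1))

    g0 = int(rng.integers(gap_range[0], gap_range[1] + 1))
    segs.append(gap_block(g0))
    pos += g0
    for v in targets:
        g_next = int(rng.integers(gap_range[0], gap_range[1] + 1))
        if kernel == "central":
            p_frac, L = _solve_spike_central(float(v), g0, g_next, h, l_min, beta_min_frac)
        else:
            p_frac, L = _solve_spike(float(v), g0, h, l_min, beta_min_frac)
        depth = p_frac * base
        floor = base - depth
        ramp_down = base - depth * np.arange(1, h) / h
        # descending: the run's deviation peak is its unique last sample
        dwell = floor - slope * np.arange(L)
        ramp_up = floor + depth * np.arange(1, h) / h
        bump = np.concatenate([ramp_down, dwell, ramp_up])
        if n_samples is not None and pos + len(bump) + 1 > n_samples:
            break
        segs.append(bump)
        # the dev peak: the dwell's deepest sample (plateau-first rule when flat)
        spike_idx.append(pos + h - 1 + (L - 1 if slope > 0 else 0))
        # heading may turn on ramp samples only: dwell floors and baseline
        # crests must stay exact runs under downstream central differences
        bump_spans.append((pos, pos + h - 1))
        bump_spans.append((pos + h - 1 + L, pos + len(bump)))
        pos += len(bump)
        segs.append(gap_block(g_next))
        pos += g_next
        g0 = g_next
    series = np.concatenate(segs)
    if n_samples is not None:
        if len(series) < n_samples:
            # extend the last gap seamlessly (same level, continuing tilt):
            # a fresh jittered level would leave a junction step that the
            # analysis would read as a spurious micro-spike
            n_pad = n_samples - len(series)
            pad = series[-1] + slope * np.arange(1, n_pad + 1)
            series = np.concatenate([series, pad])
        else:
            series = series[:n_samples]
    mask = np.zeros(len(series), dtype=bool)
    for a, b in bump_spans:
        mask[a : min(b, len(series))] = True
    return series, np.asarray(spike_idx, dtype=int), mask


def gen_ibi_series(base_ibi: float, spec: RegimeSpec, duration: float, seed) -> IBISeries:
    """IBI sequence whose MMS spikes follow Gamma(shape, scale) approximately.

    The interval waveform alternates jittered baseline runs at ``base_ibi``
    with inverse-designed downward excursions (transiently faster heart
    rate); the excursion geometry reproduces the drawn target magnitudes
    under the IBI MMS pipeline.  Cumulative R-times are strictly increasing.
    """
    if base_ibi <= 0:
        raise ValueError("base_ibi must be positive")
    n_beats_nominal = duration * 1000.0 / base_ibi
    if n_beats_nominal < 10:
        raise ValueError("duration must cover at least 10 beats")
    rng = _as_rng(seed)
    # excursions shorten intervals, so nominal beat count is a lower bound
    n_beats = int(math.ceil(n_beats_nominal)) + 2
    # one excursion per ~2-3 beats: beat-to-beat variability comparable to a
    # real tachogram, and a heart MMS stream dense enough for windowed TE
    n_spikes = max(int(n_beats / 2) + 2, 3)
    # floor excursions at 40% of the baseline interval: intervals below
    # ~300 ms are not physiological, and targets beyond the reachable cap
    # (1 - floor fraction) are truncated (negligible mass for sane regimes)
    beta_min = 0.4
    # cap targets at 0.5: approaching the structural ceiling 1 - beta_min
    # requires excursion dwells spanning tens of beats
    targets = np.clip(gen_gamma_mms_sample(spec, n_spikes, rng), None, 0.5)
    intervals, _, _ = _spike_profile(
        targets, base_ibi, h=1, l_min=1, rng=rng, gap_range=(1, 2),
        n_samples=n_beats, beta_min_frac=beta_min,
    )
    r_times = np.concatenate([[0.0], np.cumsum(intervals)])
    keep = r_times <= duration * 1000.0 + base_ibi
    r_times = r_times[keep]
    if len(r_times) < 4:
        raise ValueError("duration too short to place at least 3 spikes")
    return IBISeries(r_times=r_times, intervals=np.diff(r_times))


def gen_ecg_from_ibi(
    ibi: IBISeries,
    fs: float,
    seed,
    *,
    noise_sd: float = 0.05,
    r_width_ms: float = 40.0,
) -> "ECGRecord":
    """Synthetic ECG: a unit Gaussian R deflection at each R-time plus noise.

    The template is a positive Gaussian of total width ``r_width_ms`` (sigma
    = width/4).  ``fs`` must resolve adjacent beats: the smallest interval
    must span at least two template widths.
    """
    from .hrv import ECGRecord

    if fs < 100:
        raise ValueError("sampling rate must be >= 100 Hz")
    min_iv = float(np.min(ibi.intervals))
    if min_iv < 2 * r_width_ms:
        raise ValueError("fs/template cannot separate adjacent beats")
    rng = _as_rng(seed)
    sigma_s = r_width_ms / 4.0 / 1000.0
    duration_s = (ibi.r_times[-1] + np.mean(ibi.intervals)) / 1000.0
    n = int(round(duration_s * fs))
    wave = np.zeros(n)
    half = int(math.ceil(4 * sigma_s * fs))
    t = np.arange(n) / fs
    for r_ms in ibi.r_times:
        c = r_ms / 1000.0
        i0 = max(0, int(math.floor((c - 4 * sigma_s) * fs)))
        i1 = min(n, int(math.ceil((c + 4 * sigma_s) * fs)) + 1)
        wave[i0:i1] += np.exp(-0.5 * ((t[i0:i1] - c) / sigma_s) ** 2)
    if noise_sd > 0:
        wave = wave + rng.normal(0.0, noise_sd, size=n)
    return ECGRecord(samples=wave, fs=fs)


def gen_face_landmarks(
    region_specs: dict[str, RegimeSpec],
    duration: float,
    fps: float = 30.0,
    seed=None,
    *,
    regions: dict[str, tuple[int, ...]] | None = None,
    base_speed: float = 40.0,
    amplitude_mixers: dict | None = None,
) -> pd.DataFrame:
    """68-point landmark trajectory table with region-wise Gamma signatures.

    Each landmark's speed profile is an inverse-designed excursion series
    drawn from its region's Gamma spec; positions integrate the speed under a
    slowly wandering heading, so the analysis pipeline (smoothing, central
    differences, Euclidean norm) recovers the designed speed to within
    discretization error.  Columns follow the OpenFace convention:
    ``frame, timestamp_s, x_0..x_67, y_0..y_67``.

    ``amplitude_mixers`` optionally maps a region name to a callable
    ``f(frame, v_own) -> v`` applied to each spike target before profile
    construction (used to inject cross-signal coupling).
    """
    table = regions if regions is not None else DEFAULT_REGIONS
    validate_regions(table)
    unknown = set(region_specs) - set(table)
    if unknown:
        raise ValueError(f"unknown region labels: {sorted(unknown)}")
    rng = _as_rng(seed)
    n_frames = int(round(duration * fps))
    h, l_min = 3, 2
    cols: dict[str, np.ndarray] = {
        "frame": np.arange(n_frames),
        "timestamp_s": np.arange(n_frames) / fps,
    }
    xs: dict[int, np.ndarray] = {}
    ys: dict[int, np.ndarray] = {}
    for region, spec in region_specs.items():
        mixer = (amplitude_mixers or {}).get(region)
        for lm in table[region]:
            # worst case one spike per ~(gap_min + bump_min) frames
            n_sp = n_frames // 8 + 2
            targets = np.clip(gen_gamma_mms_sample(spec, n_sp, rng), None, V_MAX)
            if mixer is not None:
                # approximate frame positions accrue during construction; mix
                # lazily inside the profile builder via a pre-pass
                targets = _mix_targets(targets, mixer, h, l_min, rng)
            # crests of 1-2 samples between excursions: short enough that
            # heading/smoothing wiggle cannot create spurious interior
            # deviation peaks on the baseline
            speed, _, moving = _spike_profile(
                targets, base_speed, h=h, l_min=l_min, rng=rng,
                gap_range=(2, 3), n_samples=n_frames, tilt=2e-5, kernel="central",
            )
            steps = np.where(moving, rng.normal(0.0, 0.02, size=n_frames), 0.0)
            heading = np.cumsum(steps)
            heading += rng.uniform(0, 2 * np.pi)
            step = speed / fps
            x0, y0 = rng.uniform(100, 500, size=2)
            xs[lm] = x0 + np.concatenate([[0.0], np.cumsum(step[:-1] * np.cos(heading[:-1]))])
            ys[lm] = y0 + np.concatenate([[0.0], np.cumsum(step[:-1] * np.sin(heading[:-1]))])
    for lm in range(68):
        if lm not in xs:  # regions not specced stay still
            x0, y0 = rng.uniform(100, 500, size=2)
            xs[lm] = np.full(n_frames, x0)
            ys[lm] = np.full(n_frames, y0)
    for lm in range(68):
        cols[f"x_{lm}"] = xs[lm]
    for lm in range(68):
        cols[f"y_{lm}"] = ys[lm]
    return pd.DataFrame(cols)


def _mix_targets(targets, mixer, h, l_min, rng) -> np.ndarray:
    """Apply a frame-aware amplitude mixer to spike targets.

    Frame positions are approximated by the expected spike spacing; the
    coupling ground truth remains exact at the mms level, and approximate at
    the raw level (documented).
    """
    spacing = 6 + 2 * h + l_min  # expected gap + bump extent
    out = np.empty_like(targets)
    for k, v in enumerate(targets):
        out[k] = min(max(mixer(k * spacing, float(v)), 1e-6), V_MAX)
    return out


def _participant_params(cfg: SyntheticCohortConfig, rng: np.random.Generator) -> dict:
    """Draw per-participant (shape, scale) pairs on the log-log law, with a
    pain-condition NSR shift whose face/heart deltas are linearly related."""
    n = cfg.n_participants
    out: dict[str, dict[str, np.ndarray]] = {}
    deltas: dict[str, np.ndarray] = {}
    for signal, regimes in (("face", cfg.face_regimes), ("heart", cfg.heart_regimes)):
        la = np.log10(regimes["control"].shape) + rng.normal(0, cfg.shape_log_spread, n)
        lb = cfg.loglog_intercept + cfg.loglog_slope * la + rng.normal(
            0, cfg.loglog_noise_sd, n
        )
        # recenter scales on the control regime value
        lb = lb - lb.mean() + np.log10(regimes["control"].scale)
        out[signal] = {"control": np.column_stack([10.0**la, 10.0**lb])}
        delta_regime = regimes["pain"].scale - regimes["control"].scale
        deltas[signal] = delta_regime * rng.uniform(0.5, 1.5, size=n)
    # calibrate face deltas against heart deltas at the target R^2
    dh = deltas["heart"]
    df_signal = deltas["face"].mean() / dh.mean() * dh if dh.mean() > 0 else deltas["face"]
    r2 = min(max(cfg.delta_r2_target, 1e-6), 1.0)
    noise_sd = float(np.std(df_signal) * math.sqrt(1.0 / r2 - 1.0))
    df = np.abs(df_signal + rng.normal(0, noise_sd, size=cfg.n_participants))
    deltas["face"] = df
    for signal in ("face", "heart"):
        ctrl = out[signal]["control"]
        b_pain = ctrl[:, 1] + deltas[signal]
        if cfg.loglog_slope != 0:
            la_pain = (np.log10(b_pain) - cfg.loglog_intercept) / cfg.loglog_slope
            # keep the pain shapes on the law but preserve participant offsets
            la_pain = la_pain - la_pain.mean() + np.mean(
                (np.log10(b_pain).mean() - cfg.loglog_intercept) / cfg.loglog_slope
            )
            a_pain = 10.0**la_pain
        else:
            a_pain = ctrl[:, 0]
        out[signal]["pain"] = np.column_stack([a_pain, b_pain])
    return {"params": out, "delta_face": deltas["face"], "delta_heart": deltas["heart"]}


def _face_stream_mms(
    spec_shape: float,
    spec_scale: float,
    n_frames: int,
    rng: np.random.Generator,
    coupling: CouplingSpec,
    source_hold: np.ndarray | None,
) -> MMSSeries:
    """Face spike train directly on the frame grid (mms level)."""
    h, l_min = 3, 2
    n_sp = n_frames // 8 + 2
    targets = np.clip(rng.gamma(spec_shape, spec_scale, n_sp), None, V_MAX)
    _, spike_frames, _ = _spike_profile(
        targets, 1.0, h=h, l_min=l_min, rng=rng, gap_range=(3, 9), n_samples=n_frames
    )
    values = np.zeros(n_frames)
    for k, fr in enumerate(spike_frames):
        v = float(targets[k])
        if (
            coupling.direction == "heart->face"
            and source_hold is not None
            and fr - coupling.lag >= 0
        ):
            v = (1 - coupling.strength) * v + coupling.strength * source_hold[fr - coupling.lag]
        values[fr] = min(max(v, 0.0), V_MAX)
    return MMSSeries(values=values, fps=None)


def gen_coupled_cohort(config: SyntheticCohortConfig) -> SyntheticCohort:
    """Paired face/heart MMS streams per participant with full ground truth.

    For each (participant, task, condition) record the heart stream comes
    from a generated IBI series passed through the MMS pipeline and mapped to
    the frame grid; the face stream is a frame-grid spike train with
    magnitudes drawn from the participant's face regime.  The configured
    coupling mixes the target stream's spike magnitudes with the held source
    magnitude ``lag`` frames earlier.
    """
    cfg = config
    rng = _as_rng(cfg.seed)
    pp = _participant_params(cfg, rng)
    n_frames = int(round(cfg.duration * cfg.fps))
    rows = []
    streams = {}
    for p in range(cfg.n_participants):
        pid = f"P{p:02d}"
        for task in cfg.tasks:
            for cond in ("control", "pain"):
                a_h, b_h = pp["params"]["heart"][cond][p]
                a_f, b_f = pp["params"]["face"][cond][p]
                ibi = gen_ibi_series(
                    cfg.base_ibi, RegimeSpec(a_h, b_h, cond), cfg.duration, rng
                )
                heart_beat_mms = ibi_mms(ibi, min_peaks=10)
                heart_sparse = heart_mms_to_frames(
                    ibi, heart_beat_mms, fps=cfg.fps, n_frames=n_frames, hold=False
                )
                heart_frames = MMSSeries(
                    values=source_amplitude_hold(heart_sparse.values), fps=cfg.fps
                )
                if cfg.coupling.direction == "heart->face":
                    hold = heart_frames.values
                    face = _face_stream_mms(a_f, b_f, n_frames, rng, cfg.coupling, hold)
                    heart_out = heart_frames
                elif cfg.coupling.direction == "face->heart":
                    face = _face_stream_mms(
                        a_f, b_f, n_frames, rng, CouplingSpec("none"), None
                    )
                    hold = source_amplitude_hold(face.values)
                    hv = heart_sparse.values.copy()
                    for fr in np.flatnonzero(hv > 0):
                        if fr - cfg.coupling.lag >= 0:
                            hv[fr] = (
                                (1 - cfg.coupling.strength) * hv[fr]
                                + cfg.coupling.strength * hold[fr - cfg.coupling.lag]
                            )
                    heart_out = MMSSeries(
                        values=source_amplitude_hold(np.clip(hv, 0.0, V_MAX)), fps=cfg.fps
                    )
                else:
                    face = _face_stream_mms(
                        a_f, b_f, n_frames, rng, CouplingSpec("none"), None
                    )
                    heart_out = heart_frames
                key = (pid, task, cond)
                streams[key] = {
                    "face_mms": face,
                    "heart_frames": heart_out,
                    "ibi": ibi,
                    "heart_beat_mms": heart_beat_mms,
                }
                rows.append(
                    {
                        "participant": pid,
                        "task": task,
                        "condition": cond,
                        "face_shape": a_f,
                        "face_scale": b_f,
                        "heart_shape": a_h,
                        "heart_scale": b_h,
                    }
                )
    records = pd.DataFrame(rows)
    truth = {
        "loglog_slope": cfg.loglog_slope,
        "loglog_intercept": cfg.loglog_intercept,
        "coupling": {
            "direction": cfg.coupling.direction,
            "lag": cfg.coupling.lag,
            "strength": cfg.coupling.strength,
        },
        "delta_face": pp["delta_face"].tolist(),
        "delta_heart": pp["delta_heart"].tolist(),
        "delta_r2_target": cfg.delta_r2_target,
        "params": {
            sig: {cond: arr.tolist() for cond, arr in d.items()}
            for sig, d in pp["params"].items()
        },
        "seed": cfg.seed,
    }
    return SyntheticCohort(records=records, streams=streams, truth=truth, config=cfg)
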