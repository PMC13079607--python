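"""End-to-end orchestration: simulate, load, analyze, report.

The pipeline runs the full analysis over a cohort of (participant, task,
condition) records: landmark trajectories -> per-region MMS -> Gamma fits and
NSR vectors; ECG -> IBI -> Poincaré / band powers / IBI MMS; face-heart
transfer entropy in both directions; then the cohort statistics (log-log
law, ΔNSR regression, rank tests, EMD clustering, TE curves).

Failures on one record never abort the cohort: the record is skipped and
logged, and the summary asserts records_in = completed + skipped.  A fixed
seed makes a simulate -> analyze -> report run byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .gamma import fit_gamma_mle, fit_loglog_law
from .hrv import ECGRecord, band_powers, build_ibi, detect_r_peaks, ibi_mms, poincare_sd
from .infodyn import TEConfig, build_te_curves, heart_mms_to_frames, te_both_directions
from .mms import mms_transform, pool_region_mms, smooth_positions, speed_profile
from .regions import DEFAULT_REGIONS
from .stats import cluster_tree, delta_linear_fit, emd_matrix, friedman_test, ranksum_matrix
from .synth import SyntheticCohort, SyntheticCohortConfig, gen_coupled_cohort, gen_ecg_from_ibi, gen_face_landmarks, RegimeSpec

logger = logging.getLogger(__name__)

TASKS = ("resting", "drawing", "pointing", "peg")
CONDITIONS = ("control", "pain", "post-pain")  # post-pain loaded, excluded from defaults

__all__ = ["RunConfig", "simulate", "load_inputs", "run_full_analysis", "write_report"]


@dataclass(frozen=True)
class RunConfig:
    """Validated analysis settings.

    ``smoothing`` is the spline residual budget for landmark trajectories:
    0.0 interpolates (appropriate for noise-free positions), None triggers
    the noise-adaptive default.  TE windowing defaults follow the study
    constants (50-frame windows, 10% history, 300-frame span).
    """

    mode: str = "synthetic"
    seed: int = 0
    fps: float = 30.0
    smoothing: float | None = 0.0
    min_peaks: int = 30
    te_window: int = 50
    te_history_fraction: float = 0.10
    te_total_frames: int | None = None
    te_estimator: str = "gaussian"
    te_n_bins: int = 4
    cluster_k: int = 8
    ecg_fs: float = 250.0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValueError(f"unknown input mode {self.mode!r}")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.cluster_k < 1:
            raise ValueError("cluster_k must be >= 1")
        TEConfig(
            window=self.te_window,
            history_fraction=self.te_history_fraction,
            total_frames=self.te_total_frames,
            estimator=self.te_estimator,
            n_bins=self.te_n_bins,
        )

    @property
    def te_config(self) -> TEConfig:
        return TEConfig(
            window=self.te_window,
            history_fraction=self.te_history_fraction,
            total_frames=self.te_total_frames,
            estimator=self.te_estimator,
            n_bins=self.te_n_bins,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _record_stem(pid: str, task: str, cond: str) -> str:
    return f"{pid}_{task}_{cond}"


def simulate(config: SyntheticCohortConfig, outdir: str | Path,
             run: RunConfig | None = None) -> pd.DataFrame:
    """Generate a cohort and write it to disk in the file dialects.

    ``level="raw"`` materializes landmark tables (OpenFace columns) and ECG
    per record; both levels write the IBI series, the ground-truth JSON and
    the cohort index.  Raw landmark files are regenerated from the
    per-record regimes; a configured face-heart coupling lives in the
    mms-level streams (the ground truth), not in the raw trajectories.
    Returns the cohort index table.
    """
    run = run or RunConfig(seed=config.seed)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = gen_coupled_cohort(config)
    rows = []
    rng = np.random.default_rng(config.seed + 1_000_003)
    for key, st in cohort.streams.items():
        pid, task, cond = key
        stem = _record_stem(pid, task, cond)
        rec = {"participant": pid, "task": task, "condition": cond}
        ibi = st["ibi"]
        ibi_path = out / f"ibi_{stem}.csv"
        pd.DataFrame(
            {"r_time_ms": ibi.r_times[1:], "ibi_ms": ibi.intervals}
        ).to_csv(ibi_path, index=False)
        rec["ibi_file"] = ibi_path.name
        if config.level == "raw":
            row = cohort.records[
                (cohort.records.participant == pid)
                & (cohort.records.task == task)
                & (cohort.records.condition == cond)
            ].iloc[0]
            face_df = gen_face_landmarks(
                {
                    "V1": RegimeSpec(row.face_shape, row.face_scale, cond),
                    "V2": RegimeSpec(row.face_shape, row.face_scale, cond),
                    "V3": RegimeSpec(row.face_shape, row.face_scale, cond),
                },
                duration=config.duration,
                fps=config.fps,
                seed=rng,
            )
            face_path = out / f"face_{stem}.csv"
            face_df.to_csv(face_path, index=False)
            rec["face_file"] = face_path.name
            ecg = gen_ecg_from_ibi(ibi, fs=run.ecg_fs, seed=rng)
            ecg_path = out / f"ecg_{stem}.csv"
            pd.DataFrame(
                {
                    "time_s": np.arange(len(ecg.samples)) / ecg.fs,
                    "voltage": ecg.samples,
                }
            ).to_csv(ecg_path, index=False)
            rec["ecg_file"] = ecg_path.name
        else:
            face_path = out / f"facemms_{stem}.csv"
            pd.DataFrame(
                {
                    "frame": np.arange(len(st["face_mms"])),
                    "value": st["face_mms"].values,
                }
            ).to_csv(face_path, index=False)
            rec["face_mms_file"] = face_path.name
        rows.append(rec)
    index = pd.DataFrame(rows).sort_values(
        ["participant", "task", "condition"]).reset_index(drop=True)
    index.to_csv(out / "cohort.csv", index=False)
    (out / "truth.json").write_text(json.dumps(cohort.truth, sort_keys=True, indent=1))
    return index


def load_inputs(indir: str | Path, config: RunConfig | None = None) -> pd.DataFrame:
    """Load and validate a cohort directory into a record table.

    Checks file existence, timestamp monotonicity and key uniqueness;
    errors name the offending record and row.
    """
    indir = Path(indir)
    index_path = indir / "cohort.csv"
    if not index_path.exists():
        raise FileNotFoundError(f"no cohort index at {index_path}")
    index = pd.read_csv(index_path)
    keys = list(zip(index.participant, index.task, index.condition))
    if len(keys) != len(set(keys)):
        raise ValueError("duplicate (participant, task, condition) keys in cohort index")
    for _, rec in index.iterrows():
        for col in ("face_file", "ecg_file", "ibi_file", "face_mms_file"):
            if col in rec and isinstance(rec[col], str):
                path = indir / rec[col]
                if not path.exists():
                    raise FileNotFoundError(f"record {tuple(rec[:3])}: missing {path.name}")
        if isinstance(rec.get("face_file"), str):
            ts = pd.read_csv(indir / rec["face_file"], usecols=["timestamp_s"])["timestamp_s"]
            bad = np.flatnonzero(np.diff(ts.to_numpy()) <= 0)
            if len(bad):
                raise ValueError(
                    f"record {tuple(rec[:3])}: non-monotone timestamp at row {bad[0] + 1}"
                )
        logger.info("loaded record %s", tuple(rec[:3]))
    return index


def _analyze_face_file(path: Path, cfg: RunConfig) -> dict:
    df = pd.read_csv(path)
    fits = {}
    pooled = {}
    for region, landmarks in DEFAULT_REGIONS.items():
        per = {}
        for lm in landmarks:
            x = df[f"x_{lm}"].to_numpy()
            y = df[f"y_{lm}"].to_numpy()
            if cfg.smoothing is None or cfg.smoothing > 0:
                x, y = smooth_positions(x, y, cfg.fps, smoothing=cfg.smoothing)
            sp = speed_profile(x, y, cfg.fps)
            per[lm] = mms_transform(sp.values, fps=cfg.fps, min_peaks=10)
        sample = pool_region_mms(per, region)
        pooled[region] = sample
        fits[region] = fit_gamma_mle(sample, min_n=cfg.min_peaks)
    return {"fits": fits, "pooled": pooled, "frames": len(df)}


def _face_stream_from_file(path: Path, cfg: RunConfig) -> np.ndarray:
    df = pd.read_csv(path)
    stream = None
    for lm in DEFAULT_REGIONS["V1"]:
        x = df[f"x_{lm}"].to_numpy()
        y = df[f"y_{lm}"].to_numpy()
        if cfg.smoothing is None or cfg.smoothing > 0:
            x, y = smooth_positions(x, y, cfg.fps, smoothing=cfg.smoothing)
        sp = speed_profile(x, y, cfg.fps)
        m = mms_transform(sp.values, fps=cfg.fps, min_peaks=10)
        stream = m.values if stream is None else np.maximum(stream, m.values)
    return stream


def run_full_analysis(
    cohort: pd.DataFrame | SyntheticCohort,
    config: RunConfig,
    indir: str | Path | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Execute the full pipeline over a cohort; returns the results bundle.

    Accepts either a loaded file-cohort table (with ``indir``) or an
    in-memory :class:`SyntheticCohort`.  Per-record failures are recorded
    under ``skipped`` with the reason; the cohort-level statistics use
    whatever records completed.  When ``outdir`` is given, all tables plus a
    ``summary.json`` are written there.
    """
    te_cfg = config.te_config
    fit_rows, te_rows, hrv_rows = [], [], []
    emd_samples: dict = {}
    conditions_by_record: dict = {}
    te_pairs: dict = {}
    skipped: list[dict] = []
    n_records = 0

    if isinstance(cohort, SyntheticCohort):
        iterator = [
            (key, {"streams": st}) for key, st in sorted(cohort.streams.items())
        ]
    else:
        if indir is None:
            raise ValueError("indir is required for a file-based cohort")
        indir = Path(indir)
        iterator = [
            ((r.participant, r.task, r.condition), {"record": r})
            for r in cohort.itertuples(index=False)
        ]

    for key, payload in iterator:
        pid, task, cond = key
        if cond == "post-pain":
            continue  # accepted in inputs, excluded from default comparisons
        n_records += 1
        try:
            if "streams" in payload:
                st = payload["streams"]
                face_stream = st["face_mms"].values
                face_sample = st["face_mms"].peak_values
                face_fit = fit_gamma_mle(face_sample, min_n=config.min_peaks)
                face_fits = {"V1": face_fit}
                ibi = st["ibi"]
                heart_frames = st["heart_frames"].values
                heart_mms = st["heart_beat_mms"]
            else:
                rec = payload["record"]
                if isinstance(getattr(rec, "face_file", None), str):
                    face_res = _analyze_face_file(indir / rec.face_file, config)
                    face_fits = face_res["fits"]
                    face_sample = face_res["pooled"]["V1"]
                    face_stream = _face_stream_from_file(indir / rec.face_file, config)
                else:
                    fdf = pd.read_csv(indir / rec.face_mms_file)
                    face_stream = fdf["value"].to_numpy()
                    face_sample = face_stream[face_stream > 0]
                    face_fits = {"V1": fit_gamma_mle(face_sample, min_n=config.min_peaks)}
                if isinstance(getattr(rec, "ecg_file", None), str):
                    edf = pd.read_csv(indir / rec.ecg_file)
                    ecg = ECGRecord(samples=edf["voltage"].to_numpy(), fs=config.ecg_fs)
                    r_times = detect_r_peaks(ecg)
                    ibi = build_ibi(r_times)
                else:
                    idf = pd.read_csv(indir / rec.ibi_file)
                    r0 = idf["r_time_ms"].to_numpy()
                    r_times = np.concatenate([[r0[0] - idf["ibi_ms"].iloc[0]], r0])
                    ibi = build_ibi(r_times)
                heart_mms = ibi_mms(ibi, min_peaks=10)
                heart_frames = heart_mms_to_frames(
                    ibi, heart_mms, fps=config.fps, n_frames=len(face_stream)
                ).values

            heart_fit = fit_gamma_mle(heart_mms.peak_values, min_n=10)
            poin = poincare_sd(ibi)
            try:
                bands = band_powers(ibi)
                lf, hf = bands.lf_power, bands.hf_power
            except ValueError:
                lf = hf = float("nan")
            hrv_rows.append(
                {
                    "participant": pid, "task": task, "condition": cond,
                    "sd1_ms": poin.sd1, "sd2_ms": poin.sd2,
                    "lf_power": lf, "hf_power": hf,
                    "n_beats": len(ibi.intervals) + 1,
                }
            )
            for region, f in face_fits.items():
                fit_rows.append(
                    {
                        "participant": pid, "task": task, "condition": cond,
                        "signal": "face", "region": region,
                        "shape": f.shape, "scale": f.scale,
                        "ci_shape_lo": f.ci_shape[0], "ci_shape_hi": f.ci_shape[1],
                        "ci_scale_lo": f.ci_scale[0], "ci_scale_hi": f.ci_scale[1],
                        "nsr": f.nsr, "skewness": f.skewness, "n": f.n,
                    }
                )
            fit_rows.append(
                {
                    "participant": pid, "task": task, "condition": cond,
                    "signal": "heart", "region": "IBI",
                    "shape": heart_fit.shape, "scale": heart_fit.scale,
                    "ci_shape_lo": heart_fit.ci_shape[0],
                    "ci_shape_hi": heart_fit.ci_shape[1],
                    "ci_scale_lo": heart_fit.ci_scale[0],
                    "ci_scale_hi": heart_fit.ci_scale[1],
                    "nsr": heart_fit.nsr, "skewness": heart_fit.skewness,
                    "n": heart_fit.n,
                }
            )
            n = min(len(face_stream), len(heart_frames))
            hf_res, fh_res = te_both_directions(
                face_stream[:n], heart_frames[:n], te_cfg
            )
            te_pairs.setdefault((task, cond), {})[pid] = {
                "heart->face": hf_res, "face->heart": fh_res,
            }
            for res in (hf_res, fh_res):
                te_rows.append(
                    {
                        "participant": pid, "task": task, "condition": cond,
                        "direction": res.direction, "te_bits": res.te_bits,
                        "n_windows": len(res.per_window),
                    }
                )
            emd_samples[(pid, task, cond)] = face_sample
            conditions_by_record[(pid, task, cond)] = cond
        except Exception as exc:  # noqa: BLE001 - skip-and-log policy
            logger.warning("record %s skipped: %s", key, exc)
            skipped.append({"record": list(key), "reason": str(exc)})

    fits = pd.DataFrame(fit_rows)
    results: dict = {
        "fits": fits,
        "hrv": pd.DataFrame(hrv_rows),
        "te": pd.DataFrame(te_rows),
        "skipped": skipped,
        "n_records": n_records,
    }

    completed = n_records - len(skipped)
    if completed >= 3 and len(fits):
        face_v1 = fits[(fits.signal == "face") & (fits.region == "V1")]
        from .gamma import GammaFit

        cohort_fits = [
            GammaFit(
                shape=r.shape, scale=r.scale,
                ci_shape=(r.ci_shape_lo, r.ci_shape_hi),
                ci_scale=(r.ci_scale_lo, r.ci_scale_hi),
                loglik=0.0, n=int(r.n),
            )
            for r in face_v1.itertuples()
        ]
        try:
            results["loglog_face_v1"] = fit_loglog_law(cohort_fits)
        except ValueError as exc:
            logger.warning("log-log law skipped: %s", exc)
        groups = {
            cond: face_v1[face_v1.condition == cond].nsr.to_numpy()
            for cond in face_v1.condition.unique()
        }
        if len(groups) >= 2:
            results["ranksum_v1_nsr"] = ranksum_matrix(groups)
        # pain-minus-control deltas per participant
        deltas = []
        heart = fits[fits.signal == "heart"]
        for pid in sorted(face_v1.participant.unique()):
            for task in sorted(face_v1.task.unique()):
                sel = lambda df, c: df[
                    (df.participant == pid) & (df.task == task) & (df.condition == c)
                ]
                fv_p, fv_c = sel(face_v1, "pain"), sel(face_v1, "control")
                hh_p, hh_c = sel(heart, "pain"), sel(heart, "control")
                if len(fv_p) and len(fv_c) and len(hh_p) and len(hh_c):
                    deltas.append(
                        {
                            "participant": pid, "task": task,
                            "dnsr_face": float(fv_p.nsr.iloc[0] - fv_c.nsr.iloc[0]),
                            "dnsr_heart": float(hh_p.nsr.iloc[0] - hh_c.nsr.iloc[0]),
                        }
                    )
        if len(deltas) >= 3:
            ddf = pd.DataFrame(deltas)
            results["deltas"] = ddf
            results["delta_fit"] = delta_linear_fit(
                ddf.dnsr_face.to_numpy(), ddf.dnsr_heart.to_numpy()
            )
        # Friedman over conditions for V1 NSR (complete blocks only)
        piv = face_v1.pivot_table(
            index="participant", columns="condition", values="nsr", aggfunc="mean"
        ).dropna()
        if piv.shape[0] >= 2 and piv.shape[1] >= 2:
            chi2, p = friedman_test(piv.to_numpy())
            results["friedman_v1"] = {"chi2": chi2, "p": p}
        if len(emd_samples) >= max(config.cluster_k, 2):
            emd = emd_matrix(
                {k: v for k, v in sorted(emd_samples.items())}, min_n=config.min_peaks
            )
            results["emd"] = emd
            results["clusters"] = cluster_tree(
                emd, k=min(config.cluster_k, len(emd.labels)),
                conditions={k: conditions_by_record[k] for k in emd.labels},
            )
        for (task, cond), pairs in te_pairs.items():
            if len(pairs) >= 2:
                results.setdefault("te_curves", {})[f"{task}_{cond}"] = build_te_curves(
                    pairs, sort_direction="heart->face"
                )
    else:
        logger.warning(
            "cohort-level statistics skipped: only %d completed records", completed
        )

    if outdir is not None:
        _write_results(results, Path(outdir), config)
    return results


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _write_results(results: dict, outdir: Path, config: RunConfig) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for name in ("fits", "hrv", "te", "deltas"):
        if name in results and len(results[name]):
            results[name].to_csv(outdir / f"{name}.csv", index=False)
    summary: dict = {
        "config": _jsonable(config),
        "version": __version__,
        "n_records": results["n_records"],
        "completed": results["n_records"] - len(results["skipped"]),
        "skipped": results["skipped"],
    }
    for name in ("loglog_face_v1", "delta_fit", "friedman_v1"):
        if name in results:
            summary[name] = _jsonable(results[name])
    if "ranksum_v1_nsr" in results:
        rs = results["ranksum_v1_nsr"]
        summary["ranksum_v1_nsr"] = {
            "labels": list(rs.labels), "p_values": rs.p_values.tolist()
        }
    if "clusters" in results:
        cl = results["clusters"]
        summary["clusters"] = {
            "k": cl.k, "labels": cl.labels.tolist(),
            "composition": _jsonable(cl.composition),
        }
    if "emd" in results:
        emd = results["emd"]
        pd.DataFrame(
            emd.distances, columns=[str(l) for l in emd.labels]
        ).to_csv(outdir / "emd.csv", index=False)
    if "te_curves" in results:
        summary["te_curves"] = {
            k: {
                "participants": [str(p) for p in c.participants],
                "sorted_values": c.sorted_values.tolist(),
                "matched_values": c.matched_values.tolist(),
                "differences": c.differences.tolist(),
            }
            for k, c in results["te_curves"].items()
        }
    (outdir / "summary.json").write_text(json.dumps(summary, sort_keys=True, indent=1))


def write_report(outdir: str | Path) -> dict:
    """Write a manifest of every artifact in ``outdir`` with SHA-256 checksums."""
    outdir = Path(outdir)
    if not outdir.is_dir():
        raise IOError(f"output directory {outdir} does not exist")
    files = sorted(
        p for p in outdir.iterdir() if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "version": __version__,
        "artifacts": [
            {
                "file": p.name,
                "sha256": hashlib.sha256(p.read_bytes()).hexdigest(),
                "bytes": p.stat().st_size,
            }
            for p in files
        ],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return manifest
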