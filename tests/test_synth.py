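"""Ground-truth recoverability and determinism of the synthetic generators."""

import numpy as np
import pandas as pd
import pytest

from mmskit import (
    detect_r_peaks,
    fit_gamma_mle,
    fit_loglog_law,
    gen_coupled_cohort,
    gen_ecg_from_ibi,
    gen_face_landmarks,
    gen_gamma_mms_sample,
    gen_ibi_series,
    ibi_mms,
    mms_transform,
    poincare_sd,
    pool_region_mms,
    speed_profile,
)
from mmskit.gamma import GammaFit
from mmskit.regions import DEFAULT_REGIONS
from mmskit.synth import CouplingSpec, RegimeSpec, SyntheticCohortConfig


def truth_fit(shape, scale):
    return GammaFit(shape=shape, scale=scale, ci_shape=(shape, shape),
                    ci_scale=(scale, scale), loglik=0.0, n=1)


class TestGammaSample:
    def test_moments_within_three_standard_errors(self):
        n = 100_000
        x = gen_gamma_mms_sample(RegimeSpec(4.0, 0.5), n, seed=0)
        se_mean = np.sqrt(4 * 0.5**2 / n)
        assert abs(x.mean() - 2.0) < 3 * se_mean
        # SE of the sample variance of a Gamma: sqrt((mu4 - var^2)/n)
        var, mu4 = 1.0, (3 + 6 / 4.0) * 1.0**2
        assert abs(x.var() - var) < 3 * np.sqrt((mu4 - var**2) / n)

    def test_exponential_skewness(self):
        x = gen_gamma_mms_sample(RegimeSpec(1.0, 1.0), 100_000, seed=1)
        m = x.mean()
        skew = np.mean((x - m) ** 3) / x.std() ** 3
        assert abs(skew - 2.0) < 3 * np.sqrt(15 / len(x)) * 3  # loose 3 SE bound

    def test_determinism_and_validation(self):
        a = gen_gamma_mms_sample(RegimeSpec(2, 0.1), 1000, seed=7)
        b = gen_gamma_mms_sample(RegimeSpec(2, 0.1), 1000, seed=7)
        np.testing.assert_array_equal(a, b)
        with pytest.raises(ValueError):
            gen_gamma_mms_sample(RegimeSpec(2, 0.1), 0, seed=0)
        with pytest.raises(ValueError):
            RegimeSpec(-1.0, 0.1)


class TestIBISeries:
    def test_parameter_recovery_across_seeds(self):
        # the full inverse-design round trip: generated intervals -> MMS ->
        # Gamma fit should cover the injected (shape, scale) ~95% of the time
        hits_a = hits_b = 0
        n_seeds = 50
        for seed in range(n_seeds):
            ibi = gen_ibi_series(800.0, RegimeSpec(2.0, 0.05), 600.0, seed)
            f = fit_gamma_mle(ibi_mms(ibi).peak_values)
            hits_a += f.ci_shape[0] <= 2.0 <= f.ci_shape[1]
            hits_b += f.ci_scale[0] <= 0.05 <= f.ci_scale[1]
        assert hits_a >= 0.9 * n_seeds
        assert hits_b >= 0.9 * n_seeds

    def test_zero_dispersion_limit(self):
        ibi = gen_ibi_series(800.0, RegimeSpec(2.0, 1e-9), 300.0, seed=0)
        assert np.allclose(ibi.intervals, 800.0, rtol=1e-3)
        p = poincare_sd(ibi)
        assert p.sd1 < 1.0 and p.sd2 < 1.0  # ms

    def test_strictly_increasing_r_times_and_determinism(self):
        a = gen_ibi_series(800.0, RegimeSpec(2, 0.05), 120.0, seed=5)
        b = gen_ibi_series(800.0, RegimeSpec(2, 0.05), 120.0, seed=5)
        assert np.all(np.diff(a.r_times) > 0)
        np.testing.assert_array_equal(a.r_times, b.r_times)

    def test_too_short_duration_rejected(self):
        with pytest.raises(ValueError, match="10 beats"):
            gen_ibi_series(800.0, RegimeSpec(2, 0.05), 5.0, seed=0)


class TestECG:
    def test_noiseless_round_trip_is_exact(self):
        r = np.arange(10) * 1000.0
        from mmskit.hrv import IBISeries

        ibi = IBISeries(r_times=r, intervals=np.diff(r))
        ecg = gen_ecg_from_ibi(ibi, fs=250.0, seed=0, noise_sd=0.0)
        np.testing.assert_array_equal(detect_r_peaks(ecg), r)

    def test_default_noise_count_within_one_percent(self):
        ibi = gen_ibi_series(800.0, RegimeSpec(2.0, 0.05), 600.0, seed=11)
        ecg = gen_ecg_from_ibi(ibi, fs=250.0, seed=12)
        detected = detect_r_peaks(ecg)
        assert abs(len(detected) - len(ibi.r_times)) <= 0.01 * len(ibi.r_times)

    def test_determinism_and_fs_validation(self):
        ibi = gen_ibi_series(800.0, RegimeSpec(2, 0.05), 60.0, seed=2)
        a = gen_ecg_from_ibi(ibi, fs=250.0, seed=3)
        b = gen_ecg_from_ibi(ibi, fs=250.0, seed=3)
        np.testing.assert_array_equal(a.samples, b.samples)
        with pytest.raises(ValueError, match=">= 100"):
            gen_ecg_from_ibi(ibi, fs=50.0, seed=0)


class TestFaceLandmarks:
    def test_column_contract_and_determinism(self):
        df1 = gen_face_landmarks({"V1": RegimeSpec(3, 0.1)}, 10.0, seed=4)
        df2 = gen_face_landmarks({"V1": RegimeSpec(3, 0.1)}, 10.0, seed=4)
        assert list(df1.columns[:2]) == ["frame", "timestamp_s"]
        assert list(df1.columns[2:70]) == [f"x_{i}" for i in range(68)]
        assert list(df1.columns[70:]) == [f"y_{i}" for i in range(68)]
        pd.testing.assert_frame_equal(df1, df2)

    def test_unknown_region_rejected(self):
        with pytest.raises(ValueError, match="unknown region"):
            gen_face_landmarks({"V9": RegimeSpec(3, 0.1)}, 10.0, seed=0)

    def test_static_landmark_contributes_no_spikes(self):
        # landmarks outside the specced regions stay still: zero speed, no peaks
        df = gen_face_landmarks({"V1": RegimeSpec(3, 0.1)}, 20.0, seed=1)
        lm_v3 = DEFAULT_REGIONS["V3"][0]
        sp = speed_profile(df[f"x_{lm_v3}"].to_numpy(), df[f"y_{lm_v3}"].to_numpy(), 30)
        assert np.all(sp.values == 0.0)

    def test_region_scale_recovery_across_seeds(self):
        # pooled V1 spikes from the full speed pipeline recover the injected
        # scale within its 95% CI in >= 90% of seeds
        hits_b = 0
        n_seeds = 50
        for seed in range(n_seeds):
            df = gen_face_landmarks({"V1": RegimeSpec(3.0, 0.1)}, 60.0, seed=seed)
            per = {}
            for lm in DEFAULT_REGIONS["V1"]:
                sp = speed_profile(df[f"x_{lm}"].to_numpy(), df[f"y_{lm}"].to_numpy(), 30)
                per[lm] = mms_transform(sp.values, fps=30)
            f = fit_gamma_mle(pool_region_mms(per, "V1"))
            hits_b += f.ci_scale[0] <= 0.1 <= f.ci_scale[1]
        assert hits_b >= 0.9 * n_seeds


class TestCoupledCohort:
    def test_inconsistent_pain_regime_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            SyntheticCohortConfig(
                face_regimes={
                    "control": RegimeSpec(3, 0.1, "control"),
                    "pain": RegimeSpec(3, 0.05, "pain"),
                }
            )

    def test_none_direction_forces_zero_strength(self):
        with pytest.raises(ValueError, match="forces strength"):
            CouplingSpec("none", 1, 0.5)

    def test_determinism(self):
        cfg = SyntheticCohortConfig(n_participants=2, duration=60, seed=9)
        c1, c2 = gen_coupled_cohort(cfg), gen_coupled_cohort(cfg)
        pd.testing.assert_frame_equal(c1.records, c2.records)
        for key in c1.streams:
            np.testing.assert_array_equal(
                c1.streams[key]["face_mms"].values, c2.streams[key]["face_mms"].values
            )
        assert c1.truth == c2.truth

    def test_zero_noise_law_is_exact_on_truth(self):
        cfg = SyntheticCohortConfig(
            n_participants=12, duration=60, seed=1,
            loglog_slope=-1.0, loglog_noise_sd=0.0, shape_log_spread=0.2,
        )
        cohort = gen_coupled_cohort(cfg)
        pars = np.array(cohort.truth["params"]["face"]["control"])
        fits = [truth_fit(a, b) for a, b in pars]
        law = fit_loglog_law(fits)
        assert law.slope == pytest.approx(-1.0, abs=1e-9)
        assert law.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_pain_shifts_nsr_upward(self):
        cfg = SyntheticCohortConfig(n_participants=6, duration=60, seed=3)
        cohort = gen_coupled_cohort(cfg)
        for sig in ("face", "heart"):
            ctrl = np.array(cohort.truth["params"][sig]["control"])[:, 1]
            pain = np.array(cohort.truth["params"][sig]["pain"])[:, 1]
            assert np.all(pain > ctrl)

    def test_uncoupled_streams_have_symmetric_te(self):
        from mmskit import TEConfig, te_both_directions

        cfg = SyntheticCohortConfig(
            n_participants=3, duration=120, seed=21, coupling=CouplingSpec("none")
        )
        cohort = gen_coupled_cohort(cfg)
        te_cfg = TEConfig(estimator="gaussian", total_frames=None)
        diffs = []
        for key, st in sorted(cohort.streams.items()):
            n = min(len(st["face_mms"]), len(st["heart_frames"]))
            hf, fh = te_both_directions(
                st["face_mms"].values[:n], st["heart_frames"].values[:n], te_cfg
            )
            diffs.append(hf.te_bits - fh.te_bits)
        # independence: mean directional difference sits near zero
        assert abs(np.mean(diffs)) < 0.02
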