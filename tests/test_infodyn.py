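"""Entropy, transfer entropy (both estimators), and TE curve analyses."""

import numpy as np
import pytest

from mmskit import (
    TEConfig,
    build_te_curves,
    shannon_entropy,
    te_both_directions,
    transfer_entropy,
)
from mmskit.infodyn import _discretize, _embed


def cmi_identity_te(source, target, L, n_bins):
    """Independent route: TE as the conditional-mutual-information sum
    I(Y_t; X_hist | Y_hist) = H(Y_t,Yh) + H(Yh,Xh) - H(Yh) - H(Y_t,Yh,Xh)."""
    xd, yd = _discretize(source, n_bins), _discretize(target, n_bins)
    yt, yh, xh = _embed(yd, xd, L)

    def H(*cols):
        rows = np.column_stack([np.atleast_2d(c.T).T for c in cols])
        _, counts = np.unique(rows, axis=0, return_counts=True)
        p = counts / counts.sum()
        return float(-np.sum(p * np.log2(p)))

    return H(yt, yh) + H(yh, xh) - H(yh) - H(yt, yh, xh)


class TestShannonEntropy:
    @pytest.mark.parametrize(
        "p, h",
        [
            ([0.25] * 4, 2.0),
            ([1.0], 0.0),
            ([0.5, 0.25, 0.25], 1.5),
        ],
    )
    def test_closed_forms(self, p, h):
        assert shannon_entropy(np.array(p)) == pytest.approx(h, abs=1e-12)

    def test_rejects_invalid_distributions(self):
        with pytest.raises(ValueError, match="negative"):
            shannon_entropy(np.array([1.2, -0.2]))
        with pytest.raises(ValueError, match="sums"):
            shannon_entropy(np.array([0.5, 0.4]))


class TestTransferEntropy:
    def test_deterministic_lagged_copy(self, rng):
        # Y_t = X_{t-2}: knowing the source past makes the target certain,
        # so TE(X->Y) approaches the discretized-alphabet entropy (2 bits at
        # 4 equal-frequency bins) while TE(Y->X) stays near zero.
        n = 20_000
        x = rng.gamma(2.0, 0.1, size=n)
        y = np.roll(x, 2)
        cfg = TEConfig(window=n, history_fraction=2 / n, total_frames=None,
                       estimator="binned", n_bins=4)
        fwd = transfer_entropy(x, y, cfg).te_bits
        rev = transfer_entropy(y, x, cfg).te_bits
        assert fwd == pytest.approx(2.0, abs=0.1)
        assert rev < 0.2
        assert fwd > 5 * rev

    def test_independent_streams_sit_in_bias_band(self, rng):
        # plug-in CMI bias ~ df / (2 N ln 2) with df = (|Y|-1)(|Xh|-1)|Yh|
        n, n_bins, L = 1000, 2, 1
        cfg = TEConfig(window=n, history_fraction=1 / n, total_frames=None,
                       estimator="binned", n_bins=n_bins)
        vals = [
            transfer_entropy(rng.normal(size=n), rng.normal(size=n), cfg).te_bits
            for _ in range(100)
        ]
        df = (n_bins - 1) * (n_bins - 1) * n_bins
        bias = df / (2 * (n - L) * np.log(2))
        mean, se = np.mean(vals), np.std(vals) / 10
        assert abs(mean - bias) < 3 * se + 0.5 * bias

    def test_gaussian_estimator_matches_fitted_ar_oracle(self, rng):
        n, L = 4000, 1
        x = rng.normal(size=n)
        e = rng.normal(scale=0.6, size=n)
        y = 0.8 * np.roll(x, 1) + e
        cfg = TEConfig(window=n, history_fraction=1 / n, total_frames=None,
                       estimator="gaussian")
        te = transfer_entropy(x, y, cfg).te_bits
        # oracle: fit the two nested autoregressions independently
        yt, yh, xh = _embed(y, x, L)
        ones = np.ones((len(yt), 1))

        def rss(design):
            coef, *_ = np.linalg.lstsq(design, yt, rcond=None)
            r = yt - design @ coef
            return float(r @ r)

        oracle = 0.5 * np.log2(rss(np.hstack([ones, yh])) / rss(np.hstack([ones, yh, xh])))
        assert te == pytest.approx(oracle, abs=1e-3)
        # population value 0.5 log2(1 + 0.64/0.36) as a sanity anchor
        assert te == pytest.approx(0.5 * np.log2(1 + 0.64 / 0.36), rel=0.1)

    def test_gaussian_te_nonnegative(self, rng):
        cfg = TEConfig(estimator="gaussian", total_frames=None)
        for _ in range(20):
            x, y = rng.normal(size=300), rng.normal(size=300)
            assert transfer_entropy(x, y, cfg).te_bits >= 0.0

    def test_matches_cmi_identity_route(self, rng):
        # entropy-difference and conditional-MI formulations coincide
        n, L, bins = 600, 2, 3
        x = rng.gamma(2, 0.1, size=n)
        y = 0.5 * np.roll(x, 1) + 0.5 * rng.gamma(2, 0.1, size=n)
        cfg = TEConfig(window=n, history_fraction=L / n, total_frames=None,
                       estimator="binned", n_bins=bins)
        te = transfer_entropy(x, y, cfg).te_bits
        assert te == pytest.approx(cmi_identity_te(x, y, L, bins), abs=1e-10)

    def test_shuffled_source_collapses_te(self, rng):
        # data-processing sanity: permuting the source destroys the coupling
        n = 3000
        cfg = TEConfig(window=n, history_fraction=1 / n, total_frames=None,
                       estimator="gaussian")
        collapsed = 0
        for _ in range(20):
            x = rng.normal(size=n)
            y = 0.9 * np.roll(x, 1) + 0.3 * rng.normal(size=n)
            coupled = transfer_entropy(x, y, cfg).te_bits
            xs = rng.permutation(x)
            shuffled = transfer_entropy(xs, y, cfg).te_bits
            collapsed += shuffled < 0.05 * coupled
        assert collapsed >= 19

    def test_length_mismatch_and_short_stream_errors(self):
        with pytest.raises(ValueError, match="lengths differ"):
            transfer_entropy(np.zeros(100), np.zeros(99))
        with pytest.raises(ValueError, match="shorter"):
            transfer_entropy(np.zeros(10), np.zeros(10), TEConfig(total_frames=None))

    def test_constant_target_windows_skipped(self, rng):
        x = rng.normal(size=100)
        y = np.zeros(100)
        y[60:] = rng.normal(size=40)
        cfg = TEConfig(window=50, total_frames=None, estimator="gaussian")
        with pytest.warns(UserWarning, match="constant-target"):
            res = transfer_entropy(x, y, cfg)
        assert res.n_skipped == 1


class TestBothDirections:
    def test_role_swap_symmetry(self, rng):
        f, h = rng.normal(size=400), rng.normal(size=400)
        cfg = TEConfig(estimator="gaussian", total_frames=None)
        hf, fh = te_both_directions(f, h, cfg)
        hf2, fh2 = te_both_directions(h, f, cfg)
        assert hf.te_bits == fh2.te_bits
        assert fh.te_bits == hf2.te_bits

    def test_independent_streams_small_both_ways(self, rng):
        cfg = TEConfig(estimator="gaussian", total_frames=None)
        hf, fh = te_both_directions(rng.normal(size=3000), rng.normal(size=3000), cfg)
        assert hf.te_bits < 0.02 and fh.te_bits < 0.02


class TestTECurves:
    def _cohort(self, pairs):
        return {
            pid: {"heart->face": a, "face->heart": b} for pid, (a, b) in pairs.items()
        }

    def test_identical_directions_zero_differences(self):
        cohort = self._cohort({f"P{i}": (0.1 * i, 0.1 * i) for i in range(5)})
        c = build_te_curves(cohort)
        assert np.all(c.differences == 0)

    def test_sorted_curve_nondecreasing(self, rng):
        cohort = self._cohort(
            {f"P{i}": (rng.random(), rng.random()) for i in range(10)}
        )
        for direction in ("heart->face", "face->heart"):
            c = build_te_curves(cohort, sort_direction=direction)
            assert np.all(np.diff(c.sorted_values) >= 0)

    def test_missing_direction_excluded_with_warning(self):
        cohort = self._cohort({"P0": (0.1, 0.2), "P1": (0.3, 0.1)})
        cohort["P2"] = {"heart->face": 0.5}
        with pytest.warns(UserWarning, match="missing"):
            c = build_te_curves(cohort)
        assert len(c.participants) == 2

    def test_coupled_cohort_favors_matched_direction(self, small_coupled_cohort):
        # ground truth drives heart->face: sorting by the weaker direction,
        # the matched (heart->face) curve should sit above on average
        cfg = TEConfig(estimator="gaussian", total_frames=None)
        pairs = {}
        for (pid, task, cond), st in sorted(small_coupled_cohort.streams.items()):
            n = min(len(st["face_mms"]), len(st["heart_frames"]))
            hf, fh = te_both_directions(
                st["face_mms"].values[:n], st["heart_frames"].values[:n], cfg
            )
            pairs[f"{pid}_{cond}"] = {"heart->face": hf, "face->heart": fh}
        c = build_te_curves(pairs, sort_direction="face->heart")
        assert c.matched_values.mean() > c.sorted_values.mean()
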