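import numpy as np
import pytest
from hypothesis import given, strategies as st

import cbfmap as cm
from cbfmap.preprocess import MAD_TO_SIGMA, smooth_stack_frames

from conftest import classic_gamma


def make_trace(I, dt=1.0, t0=0.0):
    I = np.asarray(I, dtype=float)
    return cm.Trace(t0 + np.arange(len(I)) * dt, I)


class TestAnalysisWindow:
    def test_default_keeps_initial_40_frames(self):
        frames = np.zeros((300, 4, 4), dtype=np.uint16)
        stack = cm.AcquisitionStack(frames, 0.58)
        win = cm.select_analysis_window(stack, 40)
        assert win.n_frames == 40

    def test_short_stack_clamped_with_warning(self):
        stack = cm.AcquisitionStack(np.zeros((30, 4, 4), np.uint16), 0.58)
        with pytest.warns(UserWarning, match="only 30 frames"):
            win = cm.select_analysis_window(stack, 40)
        assert win.n_frames == 30

    def test_degenerate_count_rejected(self):
        stack = cm.AcquisitionStack(np.zeros((30, 4, 4), np.uint16), 0.58)
        with pytest.raises(ValueError):
            cm.select_analysis_window(stack, 1)


def sliding_lsq_oracle(I, window, order):
    """Brute-force per-point polynomial least squares (interior points)."""
    n = len(I)
    half = window // 2
    out = np.full(n, np.nan)
    x = np.arange(-half, half + 1)
    for i in range(half, n - half):
        coef = np.polynomial.polynomial.polyfit(x, I[i - half : i + half + 1], order)
        out[i] = coef[0]  # evaluation at the window center
    return out


class TestSavitzkyGolay:
    def test_constant_series_unchanged(self):
        tr = make_trace([5.0] * 7)
        out = cm.smooth_trace(tr, window=7, order=3)
        np.testing.assert_allclose(out.I, 5.0)

    def test_cubic_reproduced_to_machine_precision(self):
        t = np.linspace(0, 2, 9)
        tr = cm.Trace(t, t**3)
        out = cm.smooth_trace(tr, window=7, order=3)
        np.testing.assert_allclose(out.I, t**3, atol=1e-12)

    def test_matches_sliding_least_squares_oracle_on_noise(self):
        rng = np.random.default_rng(42)
        I = rng.normal(0, 1, size=200)
        out = cm.smooth_trace(make_trace(I), window=7, order=3)
        oracle = sliding_lsq_oracle(I, 7, 3)
        interior = ~np.isnan(oracle)
        assert np.max(np.abs(out.I[interior] - oracle[interior])) < 1e-10

    @pytest.mark.parametrize(
        "window,order,match",
        [(6, 3, "odd"), (3, 3, "exceed"), (41, 3, "length")],
    )
    def test_bad_window_rejected(self, window, order, match):
        tr = make_trace(np.arange(40.0))
        with pytest.raises(ValueError, match=match):
            cm.smooth_trace(tr, window=window, order=order)

    def test_stackwise_smoothing_equals_traces(self):
        rng = np.random.default_rng(0)
        frames = rng.normal(100, 5, size=(40, 3, 2))
        sm = smooth_stack_frames(frames, 7, 3)
        for r in range(3):
            for c in range(2):
                tr = cm.smooth_trace(make_trace(frames[:, r, c]), 7, 3)
                np.testing.assert_allclose(sm[:, r, c], tr.I, atol=1e-12)

    def test_length_and_timebase_preserved(self):
        tr = make_trace(np.sin(np.arange(40.0)), dt=0.58)
        out = cm.smooth_trace(tr, 7, 3)
        assert len(out) == len(tr)
        np.testing.assert_array_equal(out.t, tr.t)


class TestInterpolation:
    def test_default_resamples_580ms_to_11_6ms(self):
        tr = make_trace(np.arange(40.0) ** 2, dt=0.58)
        out = cm.interpolate_trace(tr, 0.0116)
        assert out.dt == pytest.approx(0.0116, rel=1e-12)
        assert out.t[0] == tr.t[0]
        assert out.t[-1] == pytest.approx(tr.t[-1], abs=1e-9)

    def test_linear_data_reproduced_exactly(self):
        tr = make_trace(3.0 * np.arange(20.0) + 1.0, dt=0.5)  # I = 6 t + 1
        out = cm.interpolate_trace(tr, 0.1)
        np.testing.assert_allclose(out.I, 6.0 * out.t + 1.0, atol=1e-9)

    def test_passes_through_original_samples(self):
        rng = np.random.default_rng(5)
        tr = make_trace(rng.normal(size=15), dt=0.5)
        out = cm.interpolate_trace(tr, 0.1)
        np.testing.assert_allclose(out.I[::5], tr.I, atol=1e-12)

    def test_identity_at_native_step(self):
        rng = np.random.default_rng(6)
        tr = make_trace(rng.normal(size=15), dt=0.58)
        out = cm.interpolate_trace(tr, 0.58)
        np.testing.assert_allclose(out.I, tr.I, atol=1e-12)

    def test_invalid_step_rejected(self):
        tr = make_trace(np.arange(10.0))
        with pytest.raises(ValueError):
            cm.interpolate_trace(tr, 0.0)
        with pytest.raises(ValueError):
            cm.interpolate_trace(tr, 2.0)


class TestEquivarianceProperties:
    @given(
        shift=st.floats(-50, 50),
        seed=st.integers(0, 2**16),
    )
    def test_smoothing_is_time_shift_equivariant(self, shift, seed):
        rng = np.random.default_rng(seed)
        I = rng.normal(100, 10, size=40)
        base = cm.smooth_trace(make_trace(I, dt=0.58), 7, 3)
        shifted = cm.smooth_trace(make_trace(I, dt=0.58, t0=shift), 7, 3)
        np.testing.assert_allclose(shifted.t, base.t + shift, atol=1e-9)
        np.testing.assert_allclose(shifted.I, base.I, atol=1e-9)

    @given(
        shift=st.floats(-50, 50),
        seed=st.integers(0, 2**16),
    )
    def test_interpolation_is_time_shift_equivariant(self, shift, seed):
        rng = np.random.default_rng(seed)
        I = rng.normal(100, 10, size=20)
        base = cm.interpolate_trace(make_trace(I, dt=0.58, t0=0.0), 0.0116)
        shifted = cm.interpolate_trace(make_trace(I, dt=0.58, t0=shift), 0.0116)
        np.testing.assert_allclose(shifted.I, base.I, atol=1e-8)

    @given(
        k=st.floats(1e-3, 1e3),
        seed=st.integers(0, 2**16),
    )
    def test_both_stages_linear_in_intensity(self, k, seed):
        rng = np.random.default_rng(seed)
        I = rng.normal(100, 10, size=20)
        out1 = cm.interpolate_trace(cm.smooth_trace(make_trace(I), 7, 3), 0.2)
        out2 = cm.interpolate_trace(
            cm.smooth_trace(make_trace(k * I), 7, 3), 0.2
        )
        np.testing.assert_allclose(out2.I, k * out1.I, rtol=1e-9, atol=1e-9)


class TestBaseline:
    def test_constant_pre_arrival_mean(self):
        I = np.concatenate([np.full(10, 100.0), [200, 300, 250, 150]])
        tr = make_trace(I, dt=0.2)
        assert cm.estimate_baseline(tr, t_arrival=2.0) == pytest.approx(100.0)

    def test_degenerate_pre_arrival_falls_back_to_minimum(self):
        tr = make_trace([50.0, 120.0, 300.0, 200.0, 80.0])
        with pytest.warns(UserWarning, match="fewer than 3"):
            base = cm.estimate_baseline(tr, t_arrival=1.0)
        assert base == pytest.approx(50.0)

    def test_noisy_pre_arrival_matches_direct_mean(self):
        rng = np.random.default_rng(11)
        pre = 50.0 + rng.normal(0, 1, size=500)
        post = classic_gamma(np.arange(100) * 0.01, 0.0, 2, 1, 400.0) + 50.0
        I = np.concatenate([pre, post])
        tr = make_trace(I, dt=0.01)
        base = cm.estimate_baseline(tr, t_arrival=5.0)
        assert base == pytest.approx(np.mean(pre), abs=1e-12)

    def test_without_arrival_uses_minimum(self):
        tr = make_trace([5.0, 3.0, 8.0, 9.0])
        assert cm.estimate_baseline(tr) == 3.0


class TestQcMask:
    @staticmethod
    def qc_oracle(frames, threshold, window=7, order=3):
        """Per-pixel direct evaluation of the QC rule."""
        from cbfmap.preprocess import _sg_matrix

        n_t, rows, cols = frames.shape
        m = _sg_matrix(n_t, window, order)
        mid = n_t // 2
        atten = np.sqrt(1 - 2 * m[mid, mid] + (m[mid] ** 2).sum())
        sel = slice(window // 2, n_t - window // 2)
        out = np.zeros((rows, cols), dtype=bool)
        for r in range(rows):
            for c in range(cols):
                raw = frames[:, r, c].astype(float)
                sm = cm.smooth_trace(
                    cm.Trace(np.arange(n_t, dtype=float), raw), window, order
                ).I
                resid = (raw - sm)[sel]
                med = np.median(resid)
                noise = (
                    MAD_TO_SIGMA * np.median(np.abs(resid - med)) / atten
                )
                amp = sm[sel].max() - np.median(sm[sel])
                out[r, c] = amp > 0 and amp >= threshold * noise
        return out

    def test_pure_noise_pixel_fails(self):
        rng = np.random.default_rng(1)
        frames = 100 + rng.normal(0, 1, size=(40, 6, 6))
        stack = cm.AcquisitionStack(frames, 0.58)
        mask = cm.qc_mask(stack, snr_threshold=5.0)
        assert mask.sum() == 0

    def test_noiseless_bolus_passes_any_threshold(self):
        t = np.arange(40) * 0.58
        curve = classic_gamma(t, 4.0, 2, 1.35, 100.0) + 100.0
        frames = np.tile(curve[:, None, None], (1, 3, 3))
        stack = cm.AcquisitionStack(frames, 0.58)
        assert cm.qc_mask(stack, snr_threshold=1000.0).all()

    def test_amplitude_gradient_matches_per_pixel_oracle(self):
        rng = np.random.default_rng(9)
        t = np.arange(40) * 0.58
        shape_curve = classic_gamma(t, 4.0, 2, 1.35, 1.0)
        shape_curve /= shape_curve.max()
        amps = np.linspace(0, 100, 64).reshape(8, 8)
        frames = (
            100.0
            + shape_curve[:, None, None] * amps[None]
            + rng.normal(0, 2.0, size=(40, 8, 8))
        )
        stack = cm.AcquisitionStack(frames, 0.58)
        mask = cm.qc_mask(stack, snr_threshold=5.0)
        oracle = self.qc_oracle(frames, 5.0)
        np.testing.assert_array_equal(mask, oracle)
        assert 0 < mask.sum() < mask.size  # threshold actually separates
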