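import numpy as np
import pytest
from hypothesis import given, strategies as st

import fnirsdpf as f
from fnirsdpf import HRFParams, StimulusTrain, TimeSeries


class TestCanonicalKernel:
    def test_zero_at_origin(self, canonical):
        h = f.canonical_kernel(canonical, dt=0.01)
        assert h.values[0] == 0.0

    def test_peak_at_gamma_mode(self, canonical):
        # mode of the main gamma term: (alpha1 - 1) / beta1 = 5 s
        h = f.canonical_kernel(canonical, dt=0.01)
        assert h.times[np.argmax(h.values)] == pytest.approx(5.0, abs=0.05)

    @pytest.mark.parametrize("alpha1, beta1", [(6.0, 1.0), (3.0, 0.7), (8.0, 1.8)])
    def test_main_term_integrates_to_one(self, alpha1, beta1):
        # beta2 = 0 switches the undershoot term off, leaving a gamma density
        h = f.canonical_kernel(HRFParams(alpha1, 16.0, beta1, 0.0), dt=0.01, length=60.0)
        assert np.sum(h.values) * h.dt == pytest.approx(1.0, abs=1e-3)

    def test_rejects_nonpositive_grid(self, canonical):
        with pytest.raises(ValueError):
            f.canonical_kernel(canonical, dt=0.0)
        with pytest.raises(ValueError):
            f.canonical_kernel(canonical, dt=0.01, length=-1.0)


class TestConvolution:
    def test_unit_impulse_identity(self, canonical):
        dt = 0.01
        h = f.canonical_kernel(canonical, dt=dt)
        u = TimeSeries(np.zeros(4000), fs=1 / dt)
        u.values[0] = 1.0 / dt
        out = f.convolve_hrf(u, h)
        n = min(len(out), len(h))
        np.testing.assert_allclose(out.values[:n], h.values[:n], atol=1e-12)

    def test_zero_input_gives_zero(self, canonical):
        h = f.canonical_kernel(canonical, dt=0.01)
        u = TimeSeries(np.zeros(1000), fs=100.0)
        assert np.allclose(f.convolve_hrf(u, h).values, 0.0)

    def test_matches_direct_convolution(self, canonical, paradigm_st1):
        """fft-based path agrees with the quadratic-time definition."""
        dt = 0.05
        h = f.canonical_kernel(canonical, dt=dt)
        u = f.encode_stimulus(paradigm_st1, fs=1 / dt)
        expected = np.convolve(u.values, h.values)[: len(u)] * dt
        np.testing.assert_allclose(f.convolve_hrf(u, h).values, expected, atol=1e-10)

    def test_boxcar_peak_later_and_wider_than_kernel(self, canonical, paradigm_st1):
        dt = 0.01
        h = f.canonical_kernel(canonical, dt=dt)
        u = f.encode_stimulus(paradigm_st1, fs=1 / dt)
        out = f.convolve_hrf(u, h)
        t_peak_kernel = h.times[np.argmax(h.values)]
        t_peak_out = out.times[np.argmax(out.values)] - paradigm_st1.onsets[0]
        assert t_peak_out > t_peak_kernel
        attrs_h = f.extract_attributes(h, (0.0, 1.0))
        attrs_out = f.extract_attributes(out, paradigm_st1.task_window)
        assert attrs_out.fwhm_s > attrs_h.fwhm_s

    def test_linearity(self, canonical):
        dt = 0.02
        h = f.canonical_kernel(canonical, dt=dt)
        rng = np.random.default_rng(11)
        u1 = TimeSeries(rng.uniform(0, 1, 2000), fs=1 / dt)
        u2 = TimeSeries(rng.uniform(0, 1, 2000), fs=1 / dt)
        both = u1.copy_with(u1.values + u2.values)
        lhs = f.convolve_hrf(both, h).values
        rhs = f.convolve_hrf(u1, h).values + f.convolve_hrf(u2, h).values
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_mismatched_dt_rejected(self, canonical):
        h = f.canonical_kernel(canonical, dt=0.01)
        u = TimeSeries(np.zeros(100), fs=50.0)
        with pytest.raises(ValueError, match="step"):
            f.convolve_hrf(u, h)


class TestStimulusTrain:
    def test_overlapping_blocks_rejected(self):
        with pytest.raises(ValueError):
            StimulusTrain(onsets=(0.0, 5.0), durations=(10.0, 5.0), total_length=30.0)

    def test_blocks_past_end_rejected(self):
        with pytest.raises(ValueError):
            StimulusTrain(onsets=(25.0,), durations=(10.0,), total_length=30.0)


class TestExtractAttributes:
    def test_canonical_impulse_response(self, canonical):
        h = f.canonical_kernel(canonical, dt=0.01)
        attrs = f.extract_attributes(h, (0.0, 1.0))
        assert attrs.time_to_peak_s == pytest.approx(5.0, abs=0.1)
        assert attrs.fwhm_s > 0
        assert attrs.undershoot_depth > 0
        assert attrs.baseline_offset == pytest.approx(0.0, abs=1e-6)

    def test_constant_series(self):
        series = TimeSeries(np.full(5000, 3.7), fs=100.0)
        attrs = f.extract_attributes(series, (10.0, 20.0))
        assert attrs.peak_value - attrs.baseline_offset == pytest.approx(0.0, abs=1e-12)
        assert attrs.undershoot_depth == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(attrs.fwhm_s)

    @given(shift=st.floats(-10.0, 10.0))
    def test_translation_equivariance(self, shift):
        paradigm = f.simulated_paradigm(10, "St1")
        h = f.generate_signal(
            f.HRFParams(), f.NuisanceParams(a1=3.0, noise_sd=0.0), paradigm, fs=100.0
        )
        base = f.extract_attributes(h, paradigm.task_window)
        moved = f.extract_attributes(h.copy_with(h.values + shift), paradigm.task_window)
        assert moved.baseline_offset == pytest.approx(base.baseline_offset + shift, abs=1e-9)
        assert moved.peak_value == pytest.approx(base.peak_value + shift, abs=1e-9)
        assert moved.time_to_peak_s == base.time_to_peak_s
        assert moved.fwhm_s == pytest.approx(base.fwhm_s, abs=1e-9)
        assert moved.undershoot_depth == pytest.approx(base.undershoot_depth, abs=1e-9)

    def test_window_outside_series_rejected(self):
        series = TimeSeries(np.zeros(100), fs=10.0)
        with pytest.raises(ValueError, match="span"):
            f.extract_attributes(series, (5.0, 60.0))
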