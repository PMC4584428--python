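"""Power spectra, whitening, block sums, circular averages, backgrounds."""

import numpy as np
import pytest

from icemotion import detector, spectra
from icemotion.detector import NPSSurface


def _flat_nps(shape):
    return NPSSurface(values=np.ones(shape))


class TestPowerSpectrum:
    def test_constant_image(self):
        img = np.full((16, 16), 3.0)
        s = spectra.power_spectrum(img, 1.0)
        assert s.values[0, 0] == pytest.approx(16 * 16 * 9.0)
        off_dc = s.values.copy()
        off_dc[0, 0] = 0.0
        assert np.allclose(off_dc, 0.0, atol=1e-18)

    def test_single_cosine_two_symmetric_peaks(self):
        n, a, k = 32, 0.7, 5
        x = np.arange(n)
        img = a * np.cos(2 * np.pi * k * x / n)[None, :] * np.ones((n, 1))
        s = spectra.power_spectrum(img, 1.0)
        expected = n * n * a * a / 4.0
        assert s.values[0, k] == pytest.approx(expected, rel=1e-9)
        assert s.values[0, n - k] == pytest.approx(expected, rel=1e-9)
        rest = s.values.copy()
        rest[0, k] = rest[0, n - k] = 0.0
        assert np.max(rest) < 1e-12 * expected

    def test_parseval(self, rng):
        img = rng.normal(size=(24, 24))
        s = spectra.power_spectrum(img, 1.0)
        assert s.values.sum() == pytest.approx(np.sum(img**2), rel=1e-12)

    def test_translation_invariant(self, rng):
        img = rng.normal(size=(32, 32))
        s0 = spectra.power_spectrum(img, 1.0).values
        s1 = spectra.power_spectrum(np.roll(img, (5, -3), axis=(0, 1)), 1.0).values
        assert np.max(np.abs(s0 - s1)) < 1e-9 * np.max(s0)

    def test_rejects_nonfinite(self):
        img = np.ones((8, 8))
        img[3, 3] = np.nan
        with pytest.raises(ValueError):
            spectra.power_spectrum(img, 1.0)


class TestNoiseWhiten:
    def test_unit_nps_is_identity(self, rng):
        s = spectra.power_spectrum(rng.normal(size=(16, 16)), 1.0)
        w = spectra.noise_whiten(s, _flat_nps((16, 16)))
        np.testing.assert_array_equal(w.values, s.values)
        assert w.kind == "whitened"

    def test_grid_mismatch_rejected(self, rng):
        s = spectra.power_spectrum(rng.normal(size=(16, 16)), 1.0)
        with pytest.raises(ValueError, match="mismatch"):
            spectra.noise_whiten(s, _flat_nps((8, 8)))


class TestBlockSums:
    def _movie(self, rng, m=6, n=32):
        frames = rng.normal(2.0, 0.3, size=(m, n, n))
        return spectra.MovieStack(frames=frames, pixel_size=1.04, dose_per_frame=2.0)

    def test_m_equals_M_is_spectrum_of_sum(self, rng):
        movie = self._movie(rng)
        nps = _flat_nps((32, 32))
        got = spectra.block_sum_nwps(movie, movie.n_frames, nps)
        want = spectra.power_spectrum(movie.frames.sum(axis=0), 1.04)
        assert np.allclose(got.values, want.values)

    def test_m_1_is_sum_of_frame_spectra(self, rng):
        movie = self._movie(rng)
        nps = _flat_nps((32, 32))
        got = spectra.block_sum_nwps(movie, 1, nps)
        want = sum(
            spectra.power_spectrum(f, 1.04).values for f in movie.frames
        )
        assert np.allclose(got.values, want)

    def test_invalid_m_lists_divisors(self, rng):
        movie = self._movie(rng, m=6)
        with pytest.raises(ValueError, match=r"\[1, 2, 3, 6\]"):
            spectra.block_sum_nwps(movie, 4, _flat_nps((32, 32)))

    def test_background_mean_independent_of_m_and_noise_grows_sqrt_m(
        self, noise_movie_256, nps_256
    ):
        movie, cfg = noise_movie_256
        big_m = movie.n_frames
        gamma_m = spectra.predicted_background(big_m, cfg.dose_per_frame, 0.5)
        for m in (1, 2, 4, 8, 24):
            w = spectra.block_sum_nwps(movie, m, nps_256)
            vals = w.values.ravel()[1:]  # drop DC
            se = spectra.predicted_noise(big_m, cfg.dose_per_frame, 0.5, m) / np.sqrt(
                vals.size
            )
            assert abs(vals.mean() - gamma_m) < 3 * se
            # empirical SD tracks the sqrt(m) prediction within 10%
            predicted_sd = spectra.predicted_noise(big_m, cfg.dose_per_frame, 0.5, m)
            assert vals.std() == pytest.approx(predicted_sd, rel=0.10)


class TestPredictions:
    def test_reference_background(self):
        assert spectra.predicted_background(120, 2.33, 0.5) == pytest.approx(559.2)
        assert round(spectra.predicted_background(120, 2.33, 0.5), -1) == 560

    def test_single_frame_background_near_measured_value(self):
        # the reported measured per-frame background was within 5% of this
        gamma1 = spectra.predicted_background(1, 2.33, 0.5)
        assert gamma1 == pytest.approx(4.66)
        assert abs(4.91 - gamma1) / gamma1 < 0.055

    def test_background_linear_in_M(self):
        assert spectra.predicted_background(240, 2.33, 0.5) == pytest.approx(
            2 * spectra.predicted_background(120, 2.33, 0.5)
        )

    def test_noise_coefficient_and_scalings(self):
        n1 = spectra.predicted_noise(120, 2.33, 0.5, 1)
        assert n1 == pytest.approx(51.05, abs=0.05)
        assert spectra.predicted_noise(120, 2.33, 0.5, 120) == pytest.approx(
            spectra.predicted_background(120, 2.33, 0.5)
        )
        assert spectra.predicted_noise(120, 2.33, 0.5, 4) / n1 == pytest.approx(2.0)

    def test_noise_rejects_nondivisor(self):
        with pytest.raises(ValueError):
            spectra.predicted_noise(120, 2.33, 0.5, 7)


class TestRadialAverage:
    def test_flat_surface(self):
        s = spectra.Spectrum2D(
            values=np.full((64, 64), 3.5), pixel_size=1.0, n_pixels_total=64 * 64
        )
        curve = spectra.radial_average(s)
        assert np.allclose(curve.value, 3.5)

    def test_ring_is_maximal_at_ring_radius(self):
        r = np.hypot(np.fft.fftfreq(64)[:, None], np.fft.fftfreq(64)[None, :])
        vals = 1.0 + 10.0 * np.exp(-((r - 0.3) ** 2) / 1e-4)
        s = spectra.Spectrum2D(values=vals, pixel_size=1.0, n_pixels_total=64 * 64)
        curve = spectra.radial_average(s)
        assert curve.u[np.argmax(curve.value)] == pytest.approx(0.3, abs=0.02)

    def test_predicted_noise_falls_with_radius(self):
        s = spectra.Spectrum2D(
            values=np.ones((64, 64)), pixel_size=1.0, n_pixels_total=64 * 64
        )
        curve = spectra.radial_average(s, noise_level=10.0)
        # more samples per annulus at higher radius -> smaller error
        assert curve.noise[-1] < curve.noise[1]
        assert np.allclose(curve.noise, 10.0 / np.sqrt(curve.count))


class TestBackgroundStats:
    def test_exponential_background(self, rng):
        gamma_true = 4.66
        vals = rng.exponential(gamma_true, size=(384, 384))
        s = spectra.Spectrum2D(
            values=vals, pixel_size=1.0, n_pixels_total=vals.size, kind="whitened"
        )
        st = spectra.background_stats(s)
        se = gamma_true / np.sqrt(st.n)
        assert abs(st.gamma - gamma_true) < 3 * se
        assert 0.97 < st.cv < 1.03
        assert st.ks_distance < 0.01
        assert st.is_exponential()

    def test_constant_surface_fails_goodness_of_fit(self):
        s = spectra.Spectrum2D(
            values=np.full((32, 32), 2.0),
            pixel_size=1.0,
            n_pixels_total=1024,
            kind="whitened",
        )
        st = spectra.background_stats(s)
        assert st.sd == 0.0
        assert not st.is_exponential()

    def test_empty_after_exclusion_rejected(self):
        s = spectra.Spectrum2D(
            values=np.ones((16, 16)),
            pixel_size=1.0,
            n_pixels_total=256,
            kind="whitened",
        )
        with pytest.raises(ValueError):
            spectra.background_stats(s, exclusion=(0.0, 10.0))


class TestAnchorShift:
    def _curve(self, value):
        u = np.linspace(0.01, 0.48, 48)
        return spectra.RadialCurve(
            u=u,
            value=np.full_like(u, value),
            count=np.full(48, 100),
            noise=np.full(48, 0.1),
        )

    def test_already_anchored_gives_zero_shifts(self):
        curves = {1: self._curve(100.0), 4: self._curve(100.0)}
        shifted, report = spectra.anchor_shift(curves)
        assert report["shifts"][4] == 0.0
        assert report["ok"]

    def test_offset_recovered(self):
        curves = {1: self._curve(100.0), 120: self._curve(105.0)}
        shifted, report = spectra.anchor_shift(curves)
        assert report["shifts"][120] == pytest.approx(-5.0)
        assert report["max_shift_fraction"] == pytest.approx(0.05)
        assert report["ok"]
        assert np.allclose(shifted[120].value, 100.0)

    def test_large_shift_flagged(self):
        curves = {1: self._curve(100.0), 8: self._curve(110.0)}
        _, report = spectra.anchor_shift(curves)
        assert not report["ok"]

    def test_requires_m1(self):
        with pytest.raises(ValueError):
            spectra.anchor_shift({2: self._curve(1.0)})


class TestRingSignal:
    def _noise_curve(self, rng, level=100.0, noise=1.0):
        u = np.linspace(0.01, 0.48, 48)
        return spectra.RadialCurve(
            u=u,
            value=level + rng.normal(0, noise, 48),
            count=np.full(48, 400),
            noise=np.full(48, noise),
        )

    def test_flat_curve_gives_zero_within_error(self, rng):
        curve = self._noise_curve(rng)
        val, err = spectra.ring_signal_at(curve, 0.27, background=100.0)
        assert abs(val) < 3 * err

    def test_bump_height_recovered(self, rng):
        u = np.linspace(0.01, 0.48, 96)
        h = 25.0
        vals = 50.0 + h * np.exp(-((u - 0.27) ** 2) / (2 * 0.03**2))
        curve = spectra.RadialCurve(
            u=u, value=vals, count=np.full(96, 400), noise=np.full(96, 0.5)
        )
        val, err = spectra.ring_signal_at(curve, 0.27, background=50.0)
        assert val == pytest.approx(h, rel=0.02)

    def test_annulus_background(self, rng):
        curve = self._noise_curve(rng)
        val, err = spectra.ring_signal_at(
            curve, 0.27, background_band=(0.38, 0.46)
        )
        assert abs(val) < 4 * err

    def test_overlapping_background_band_rejected(self, rng):
        curve = self._noise_curve(rng)
        with pytest.raises(ValueError, match="overlap"):
            spectra.ring_signal_at(
                curve, 0.27, background_band=(0.25, 0.30), band=0.02
            )


class TestModulation:
    def _curve(self, vals, u):
        return spectra.RadialCurve(
            u=u, value=vals, count=np.full(len(u), 10), noise=np.ones(len(u))
        )

    def test_pure_background_is_zero(self):
        u = np.linspace(0.2, 0.35, 50)
        curve = self._curve(np.full(50, 7.0), u)
        assert spectra.measure_modulation(curve, (0.2, 0.35), background=7.0) == 0.0

    def test_sinusoid_on_pedestal(self):
        u = np.linspace(0.2, 0.35, 600)
        b, pedestal, a = 100.0, 20.0, 1.8
        vals = b + pedestal + a * np.sin(2 * np.pi * (u - 0.2) / 0.03)
        curve = self._curve(vals, u)
        mod = spectra.measure_modulation(curve, (0.2, 0.35), background=b)
        assert mod == pytest.approx(a / pedestal, rel=0.02)
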