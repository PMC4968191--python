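import numpy as np
import pytest
from hypothesis import given, strategies as st

import spidiff as sp
from spidiff.calibration import RawFrame, read_mask
from spidiff.errors import (
    InsufficientDarksError,
    InsufficientStatisticsError,
    InvalidGainError,
    NoBackgroundFramesError,
)


class TestPedestal:
    def test_constant_darks(self):
        darks = np.full((5, 4, 4), 10.0)
        ped, noise = sp.estimate_pedestal(darks)
        np.testing.assert_array_equal(ped, 10.0)
        np.testing.assert_array_equal(noise, 0.0)

    def test_two_point_sample_sd(self):
        darks = np.stack([np.full((2, 2), 9.0), np.full((2, 2), 11.0)])
        ped, noise = sp.estimate_pedestal(darks)
        np.testing.assert_allclose(ped, 10.0)
        np.testing.assert_allclose(noise, np.sqrt(2.0))

    def test_single_dark_rejected(self):
        with pytest.raises(InsufficientDarksError):
            sp.estimate_pedestal(np.zeros((1, 4, 4)))

    def test_monte_carlo_accuracy(self, rng):
        """500 noisy darks: pedestal errors within 3 sigma/sqrt(N) on
        at least 99% of pixels."""
        true_ped, sigma, n = 20.0, 3.0, 500
        darks = rng.normal(true_ped, sigma, size=(n, 40, 40))
        ped, noise = sp.estimate_pedestal(darks)
        tol = 3.0 * sigma / np.sqrt(n)
        assert np.mean(np.abs(ped - true_ped) <= tol) >= 0.99
        assert abs(noise.mean() - sigma) < 0.1


class TestCommonMode:
    def test_uniform_offset_removed(self):
        cal = sp.CalibrationSet.uniform((8, 8), gain=33.0)
        frame = RawFrame(np.full((8, 8), 5.0))
        out = sp.common_mode_correct(frame, cal)
        np.testing.assert_allclose(out.data, 0.0)
        assert out.cm_flags == ()

    def test_bright_pixel_does_not_bias_median(self):
        cal = sp.CalibrationSet.uniform((8, 8), gain=33.0)
        data = np.zeros((8, 8))
        data[3, 3] = 1000.0
        out = sp.common_mode_correct(RawFrame(data), cal)
        np.testing.assert_array_equal(out.data, data)  # median of zeros is 0

    def test_panel_with_no_noise_pixels_flagged(self):
        cal = sp.CalibrationSet.uniform((4, 8), gain=33.0)
        data = np.full((4, 8), 100.0)  # everything above the 16.5 ADU cut
        panels = np.repeat([[0, 1]], 4, axis=0).repeat(4, axis=1)
        out = sp.common_mode_correct(RawFrame(data, panel_id=panels), cal)
        np.testing.assert_array_equal(out.data, data)
        assert set(out.cm_flags) == {0, 1}

    def test_recovers_injected_panel_offsets(self, rng):
        """Per-panel offsets uniform(-4, 4) over >=1e4 noise pixels each
        are recovered to 0.2 ADU by the sub-threshold median."""
        shape = (200, 200)
        cal = sp.CalibrationSet.uniform(shape, read_noise=3.0, gain=33.0)
        panels = (np.arange(200)[:, None] // 100) * 2 + np.arange(200)[None, :] // 100
        offsets = rng.uniform(-4, 4, size=4)
        data = rng.normal(0.0, 3.0, size=shape) + offsets[panels]
        out = sp.common_mode_correct(RawFrame(data, panel_id=panels), cal)
        for p in range(4):
            residual = np.median(out.data[panels == p])
            assert abs(residual) < 0.2


class TestGain:
    def test_noiseless_two_delta_histogram_exact(self, rng):
        """Flat-fields taking only the values 0 and 33 ADU give gamma = 33
        exactly (degenerate two-peak histogram)."""
        photons = rng.random(size=(400, 4, 4)) < 0.2
        flats = photons * 33.0
        cal = sp.CalibrationSet.uniform((4, 4), read_noise=0.0, gain=1.0)
        gain = sp.estimate_gain(flats, cal, gamma_guess=30.0)
        np.testing.assert_allclose(gain, 33.0)

    def test_monte_carlo_recovery(self, rng):
        """True gamma 33, read noise 4, occupancy 0.2, 2000 frames:
        per-pixel estimates within 5% on >= 95% of pixels."""
        shape = (6, 6)
        n_frames, gamma, sigma = 2000, 33.0, 4.0
        photons = rng.poisson(0.2, size=(n_frames, *shape))
        flats = photons * gamma + rng.normal(0, sigma, size=(n_frames, *shape))
        cal = sp.CalibrationSet.uniform(shape, read_noise=sigma, gain=gamma)
        gain = sp.estimate_gain(flats, cal, gamma_guess=30.0)
        ok = np.isfinite(gain) & (np.abs(gain - gamma) / gamma < 0.05)
        assert ok.mean() >= 0.95

    def test_all_zero_frames_masked(self):
        flats = np.zeros((100, 4, 4))
        cal = sp.CalibrationSet.uniform((4, 4), read_noise=1.0, gain=33.0)
        gain = sp.estimate_gain(flats, cal)
        assert np.all(np.isnan(gain))

    def test_too_few_frames_rejected(self):
        cal = sp.CalibrationSet.uniform((4, 4), gain=33.0)
        with pytest.raises(InsufficientStatisticsError):
            sp.estimate_gain(np.zeros((10, 4, 4)), cal)


class TestPhotonize:
    @pytest.mark.parametrize("adu, expected", [
        (16.4, 0), (17.0, 1), (49.5, 1), (50.0, 2), (-100.0, 0), (16.5, 0),
    ])
    def test_ceil_rule_thresholds(self, adu, expected):
        frame = sp.photonize(np.array([[adu]]), 33.0)
        assert frame.counts[0, 0] == expected

    def test_nonpositive_gain_rejected(self):
        with pytest.raises(InvalidGainError):
            sp.photonize(np.zeros((2, 2)), 0.0)

    def test_mask_propagates(self):
        mask = np.array([[True, False]])
        frame = sp.photonize(np.array([[1e9, 40.0]]), 33.0, mask=mask)
        np.testing.assert_array_equal(frame.mask, mask)
        assert frame.counts[0, 1] == 1

    @given(st.floats(-500, 500), st.floats(-500, 500),
           st.floats(1.0, 100.0), st.floats(0.1, 10.0))
    def test_monotone_and_scale_covariant(self, a1, a2, gamma, c):
        from hypothesis import assume

        # ceil is discontinuous: stay clear of the photon thresholds where
        # float rounding of c*A / c*gamma can legitimately flip the count
        for a in (a1, a2):
            frac = (a / gamma - 0.5) % 1.0
            assume(min(frac, 1.0 - frac) > 1e-6)
        lo, hi = sorted((a1, a2))
        k = sp.photonize(np.array([[lo, hi]]), gamma).counts
        assert k[0, 0] <= k[0, 1]
        k_scaled = sp.photonize(np.array([[c * lo, c * hi]]), c * gamma).counts
        np.testing.assert_array_equal(k, k_scaled)

    def test_full_chain_identity_zero_noise(self, rng):
        """Zero read noise and exact gain: photonization recovers the
        generator's photon counts bit-exactly."""
        geom = sp.back_detector(64, 64)
        cfg = sp.ShotConfig(read_noise=0.0, seed=3)
        raw, truth = sp.simulate_shot(cfg, sp.SphereModel(71.0), geom,
                                      np.random.default_rng(3),
                                      frame_class="hit")
        k = sp.photonize(raw.data - cfg.pedestal, cfg.gain)
        np.testing.assert_array_equal(k.counts, truth.photons)


class TestBackground:
    def test_identical_blanks_returned_exactly(self):
        frame = np.arange(16.0).reshape(4, 4)
        stack = np.stack([frame] * 3)
        out = sp.average_background(stack, ["blank"] * 3)
        np.testing.assert_array_equal(out, frame)

    def test_mean_of_blanks_only(self):
        stack = np.stack([np.zeros((2, 2)), np.full((2, 2), 2.0),
                          np.full((2, 2), 99.0), np.full((2, 2), 77.0)])
        out = sp.average_background(stack, ["blank", "blank", "hit", "dark"])
        np.testing.assert_array_equal(out, 1.0)

    def test_no_blanks_rejected(self):
        with pytest.raises(NoBackgroundFramesError):
            sp.average_background(np.zeros((2, 3, 3)), ["hit", "dark"])

    def test_poisson_background_recovered(self, rng):
        """1000 Poisson(0.05) blanks: averaged rate within 5% of truth."""
        stack = rng.poisson(0.05, size=(1000, 32, 32)).astype(float)
        out = sp.average_background(stack, ["blank"] * 1000)
        assert abs(out.mean() - 0.05) / 0.05 < 0.05


class TestCalibrationSet:
    def test_hdf5_round_trip(self, tmp_path, rng):
        shape = (8, 8)
        cal = sp.CalibrationSet(
            pedestal=rng.normal(20, 1, shape),
            read_noise=rng.uniform(2, 4, shape),
            gain=rng.uniform(30, 36, shape),
            bad_pixel=rng.random(shape) < 0.1,
        )
        path = tmp_path / "cal.h5"
        cal.to_hdf5(path)
        again = sp.CalibrationSet.from_hdf5(path)
        np.testing.assert_array_equal(again.pedestal, cal.pedestal)
        np.testing.assert_array_equal(again.gain, cal.gain)
        np.testing.assert_array_equal(again.bad_pixel, cal.bad_pixel)

    def test_nonpositive_gain_rejected(self):
        with pytest.raises(InvalidGainError):
            sp.CalibrationSet(pedestal=np.zeros((2, 2)),
                              read_noise=np.zeros((2, 2)),
                              gain=np.zeros((2, 2)),
                              bad_pixel=np.zeros((2, 2), bool))

    def test_standalone_mask_nonzero_is_bad(self, tmp_path):
        import h5py

        path = tmp_path / "mask.h5"
        grid = np.array([[0, 2], [1, 0]], dtype=np.int32)
        with h5py.File(path, "w") as fh:
            fh.create_dataset("data/data", data=grid)
        m1 = read_mask(path)
        m2 = read_mask(path)
        np.testing.assert_array_equal(m1, grid != 0)
        np.testing.assert_array_equal(m1, m2)
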