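import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.stats import kstest

import spidiff as sp
from spidiff.errors import InvalidOrientationError
from spidiff.simulator import (
    CLASSICAL_ELECTRON_RADIUS_UM,
    _solid_angle,
    random_quaternion,
    read_truth,
)


class TestSphereModel:
    def test_forward_scattering_limit(self, back_map):
        """At q = 0 the form factor is exactly 1, so the central pixel sees
        Phi * r_e^2 * dOmega * N_e^2 photons."""
        geom = sp.back_detector(65, 65, beam_center=(32.0, 32.0))
        pm = sp.build_pixel_map(geom)
        model = sp.SphereModel(71.0)
        n = sp.sphere_expected_photons(model, 1e11, pm)
        expected = (1e11 * CLASSICAL_ELECTRON_RADIUS_UM ** 2
                    * _solid_angle(geom) * model.n_electrons ** 2)
        assert n[32, 32] == pytest.approx(expected, rel=1e-12)

    def test_linear_in_fluence(self, back_map):
        model = sp.SphereModel(71.0)
        n1 = sp.sphere_expected_photons(model, 1e11, back_map)
        n2 = sp.sphere_expected_photons(model, 2e11, back_map)
        np.testing.assert_allclose(n2, 2.0 * n1, rtol=1e-12)

    def test_first_fringe_minimum_position(self):
        """The first zero of 3(sin u - u cos u)/u^3 sits at u = 4.4934;
        for a 71 nm sphere on the 2.4 m geometry that is r ~ 77.8 px."""
        f = lambda u: 3.0 * (np.sin(u) - u * np.cos(u)) / u ** 3
        u_star = brentq(f, 4.0, 5.0, xtol=1e-12)
        assert u_star == pytest.approx(4.4934, abs=1e-4)

        geom = sp.back_detector(512, 512)
        model = sp.SphereModel(71.0)
        lam = geom.wavelength
        q_star = u_star / model.radius_angstrom
        alpha = 2.0 * np.arcsin(q_star * lam / (4.0 * np.pi))
        r_oracle = geom.distance * np.tan(alpha) / (geom.pixel_size * 1e-3)
        assert r_oracle == pytest.approx(77.8, abs=0.5)

        pm = sp.build_pixel_map(geom)
        n = sp.sphere_expected_photons(model, 1.0, pm)
        prof = sp.radial_average(n, pm, bin_width=0.25)
        c = prof.bin_centers
        window = (c > 60) & (c < 95)
        r_min = c[window][np.nanargmin(prof.mean[window])]
        assert abs(r_min - r_oracle) < 0.5

    def test_total_signal_monotone_in_diameter(self, back_map):
        totals = [sp.sphere_expected_photons(sp.SphereModel(d), 1e11,
                                             back_map).sum()
                  for d in (50, 60, 70, 80, 90)]
        assert np.all(np.diff(totals) > 0)

    def test_radially_symmetric_about_true_center(self):
        geom = sp.back_detector(65, 65, beam_center=(32.0, 32.0))
        pm = sp.build_pixel_map(geom)
        n = sp.sphere_expected_photons(sp.SphereModel(71.0), 1e11, pm)
        np.testing.assert_allclose(n, n[::-1, :], rtol=1e-9)
        np.testing.assert_allclose(n, n[:, ::-1], rtol=1e-9)
        np.testing.assert_allclose(n, n.T, rtol=1e-9)


class TestIcosaModel:
    @pytest.fixture(scope="class")
    def model(self):
        return sp.IcosaBlobModel(blob_radius=15.0, circum_radius=30.0,
                                 n_electrons=8e7)

    @pytest.fixture(scope="class")
    def small_map(self):
        return sp.build_pixel_map(sp.back_detector(96, 96))

    def test_icosahedral_symmetry(self, model, small_map):
        """A 72-degree rotation about a vertex axis maps the blob set onto
        itself, so the pattern is unchanged."""
        from scipy.spatial.transform import Rotation

        phi = (1.0 + np.sqrt(5.0)) / 2.0
        axis = np.array([0.0, 1.0, phi])
        axis /= np.linalg.norm(axis)
        rot = Rotation.from_rotvec(axis * 2.0 * np.pi / 5.0)
        x, y, z, w = rot.as_quat()
        n0 = sp.icosa_expected_photons(model, 1e11, (1, 0, 0, 0), small_map)
        n1 = sp.icosa_expected_photons(model, 1e11, (w, x, y, z), small_map)
        np.testing.assert_allclose(n1, n0, rtol=1e-9)

    def test_degenerate_point_cluster_is_orientation_free(self, small_map):
        """With a vanishing circumradius all blobs coincide and the pattern
        reduces to a spherical (orientation-independent) profile."""
        tiny = sp.IcosaBlobModel(blob_radius=15.0, circum_radius=1e-9,
                                 n_electrons=8e7)
        rng = np.random.default_rng(0)
        n0 = sp.icosa_expected_photons(tiny, 1e11, random_quaternion(rng),
                                       small_map)
        n1 = sp.icosa_expected_photons(tiny, 1e11, random_quaternion(rng),
                                       small_map)
        np.testing.assert_allclose(n0, n1, rtol=1e-9)

    def test_distinct_orientations_differ(self, model, small_map, rng):
        n0 = sp.icosa_expected_photons(model, 1e11, random_quaternion(rng),
                                       small_map)
        n1 = sp.icosa_expected_photons(model, 1e11, random_quaternion(rng),
                                       small_map)
        outer = small_map.r_px > 30
        rel = np.abs(n0 - n1)[outer] / n0[outer].max()
        assert rel.max() > 0.01

    def test_unnormalized_quaternion_rejected(self, model, small_map):
        with pytest.raises(InvalidOrientationError):
            sp.icosa_expected_photons(model, 1.0, (2.0, 0, 0, 0), small_map)


class TestSimulateShot:
    def test_noise_free_hit_renders_exactly(self):
        cfg = sp.ShotConfig(fluence_sigma=0.0, center_drift_px=0.0,
                            background_rate=0.0, read_noise=0.0, seed=1)
        geom = sp.back_detector(64, 64)
        raw, truth = sp.simulate_shot(cfg, sp.SphereModel(71.0), geom,
                                      np.random.default_rng(1),
                                      frame_class="hit")
        np.testing.assert_array_equal(
            raw.data, truth.photons * cfg.gain + cfg.pedestal)
        assert truth.fluence == cfg.fluence_median

    def test_dark_frame_has_no_photons(self):
        cfg = sp.ShotConfig(seed=2)
        geom = sp.back_detector(64, 64)
        raw, truth = sp.simulate_shot(cfg, sp.SphereModel(71.0), geom,
                                      np.random.default_rng(2),
                                      frame_class="dark")
        assert truth.photons.sum() == 0
        assert abs(raw.data.mean() - cfg.pedestal) < 1.0

    def test_fluence_distribution_is_lognormal(self):
        from scipy.stats import lognorm

        cfg = sp.ShotConfig(seed=3)
        geom = sp.back_detector(16, 16)
        fluences = []
        for i in range(1000):
            _, t = sp.simulate_shot(cfg, sp.SphereModel(71.0), geom,
                                    np.random.default_rng([3, i]),
                                    frame_class="blank")
            fluences.append(t.fluence)
        stat = kstest(fluences, lognorm(s=cfg.fluence_sigma,
                                        scale=cfg.fluence_median).cdf).statistic
        assert stat < 1.628 / np.sqrt(1000)  # 1% critical value

    def test_center_of_intensity_tracks_drift(self):
        """The centre of intensity of a noise-free pattern moves
        one-for-one with the injected beam-centre drift."""
        geom = sp.back_detector(257, 257, beam_center=(128.0, 128.0))
        drifts = np.linspace(0.0, 2.0, 5)
        recovered = []
        for drift in drifts:
            shifted = sp.DetectorGeometry(
                geom.n_rows, geom.n_cols, geom.pixel_size, geom.distance,
                (128.0 + drift, 128.0), geom.photon_energy)
            pm = sp.build_pixel_map(shifted)
            n = sp.sphere_expected_photons(sp.SphereModel(71.0), 5e11, pm)
            recovered.append(sp.center_of_intensity(n)[0] - 128.0)
        slope = np.polyfit(drifts, recovered, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.02)


class TestSimulateRun:
    def test_empty_run_is_valid(self, tmp_path):
        cfg = sp.ShotConfig(seed=4)
        geom = sp.back_detector(16, 16)
        path = tmp_path / "empty.cxi"
        sp.simulate_run(cfg, sp.SphereModel(71.0), geom, 0, path)
        with sp.cxi_io.read_cxi(path) as data:
            assert data.n_frames == 0

    def test_same_seed_reproduces_run(self, tmp_path):
        import h5py

        cfg = sp.ShotConfig(seed=5)
        geom = sp.back_detector(32, 32)
        paths = [tmp_path / f"run{i}.cxi" for i in (0, 1)]
        tpaths = [tmp_path / f"truth{i}.h5" for i in (0, 1)]
        for p, t in zip(paths, tpaths):
            sp.simulate_run(cfg, sp.SphereModel(71.0), geom, 25, p,
                            truth_path=t)
        with h5py.File(paths[0]) as f0, h5py.File(paths[1]) as f1:
            names = []
            f0.visit(lambda n: names.append(n))
            for name in names:
                if hasattr(f0[name], "shape"):
                    np.testing.assert_array_equal(f0[name][...], f1[name][...])
        t0, t1 = read_truth(tpaths[0]), read_truth(tpaths[1])
        np.testing.assert_array_equal(t0["photons"], t1["photons"])
        np.testing.assert_array_equal(t0["fluence"], t1["fluence"])

    def test_hit_count_matches_binomial(self, tmp_path):
        cfg = sp.ShotConfig(seed=6)
        geom = sp.back_detector(16, 16)
        truths = sp.simulate_run(cfg, sp.SphereModel(71.0), geom, 2000,
                                 tmp_path / "big.cxi")
        n_hits = sum(t.frame_class == "hit" for t in truths)
        expected = 2000 * cfg.hit_fraction
        bound = 3.0 * np.sqrt(2000 * cfg.hit_fraction * (1 - cfg.hit_fraction))
        assert abs(n_hits - expected) <= bound
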