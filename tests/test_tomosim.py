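import numpy as np
import pytest

import graphtomo as gt


class TestTiltScheme:
    @pytest.mark.parametrize("scheme,n", [
        (gt.FULL_SCHEME, 361),
        (gt.MISSING_WEDGE_SCHEME, 241),
        (gt.TiltScheme(-90, 90, 15), 13),
    ])
    def test_angle_counts(self, scheme, n):
        a = scheme.angles()
        assert len(a) == n
        assert a[0] == scheme.angle_min and a[-1] == scheme.angle_max

    def test_invalid_schemes_rejected(self):
        with pytest.raises(ValueError):
            gt.TiltScheme(60, -60, 0.5)
        with pytest.raises(ValueError):
            gt.TiltScheme(-60, 60, 0.0)


class TestRasterize:
    def test_single_atom_peak_at_center(self):
        cloud = gt.AtomCloud(positions=[[0.0, 0.0, 0.0]])
        vol = gt.rasterize(cloud, box_size=33)
        peak = np.unravel_index(np.argmax(vol.grid), vol.shape)
        assert peak == (16, 16, 16)
        assert vol.grid.sum() == pytest.approx(1.0, abs=1e-3)

    def test_linearity_of_deposits(self):
        one = gt.rasterize(gt.AtomCloud(positions=[[0, 0, 0]]), box_size=32)
        two = gt.rasterize(gt.AtomCloud(positions=[[0, 0, 0], [0, 0, 0]]),
                           box_size=32)
        assert two.grid.sum() == pytest.approx(2 * one.grid.sum(), rel=1e-6)

    def test_total_mass_matches_analytic_gaussian_integral(self):
        rng = np.random.default_rng(5)
        cloud = gt.AtomCloud(positions=rng.uniform(-10, 10, size=(100, 3)))
        vol = gt.rasterize(cloud, sigma=1.0, voxel_size=1.0)
        assert vol.grid.sum() / 100.0 == pytest.approx(1.0, abs=1e-3)

    def test_atom_outside_box_rejected(self):
        cloud = gt.AtomCloud(positions=[[0, 0, 0], [100, 0, 0]])
        with pytest.raises(ValueError, match="box"):
            gt.rasterize(cloud, box_size=16)


class TestRotations:
    def test_rotation_matrix_is_special_orthogonal(self):
        for seed in range(5):
            R = gt.random_rotation(seed)
            assert np.allclose(R @ R.T, np.eye(3), atol=1e-10)
            assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-10)

    def test_seed_determinism(self):
        assert np.array_equal(gt.random_rotation(42), gt.random_rotation(42))
        assert not np.array_equal(gt.random_rotation(42), gt.random_rotation(43))

    def test_isotropy_of_rotated_unit_vectors(self):
        z = np.array([0.0, 0.0, 1.0])
        mean = np.mean([gt.random_rotation(s) @ z for s in range(10_000)], axis=0)
        assert np.linalg.norm(mean) < 0.05

    def test_apply_rotation_identity_and_isometry(self):
        rng = np.random.default_rng(1)
        cloud = gt.AtomCloud(positions=rng.uniform(0, 10, size=(30, 3)))
        same = gt.apply_rotation(cloud, np.eye(3))
        assert np.allclose(same.positions, cloud.positions)
        R = gt.random_rotation(9)
        rot = gt.apply_rotation(cloud, R)
        d0 = np.linalg.norm(cloud.positions[:, None] - cloud.positions[None], axis=-1)
        d1 = np.linalg.norm(rot.positions[:, None] - rot.positions[None], axis=-1)
        assert np.allclose(d0, d1, atol=1e-9)
        back = gt.apply_rotation(rot, R.T)
        assert np.allclose(back.positions, cloud.positions, atol=1e-9)


class TestProjection:
    def test_zero_volume_projects_to_zero(self):
        vol = gt.DensityVolume(grid=np.zeros((16, 16, 16)))
        ts = gt.project_tilt_series(vol, gt.TiltScheme(-90, 90, 30))
        assert np.all(ts.images == 0)

    def test_mass_conserved_per_angle(self):
        # a smooth random density well inside the box (density maps are
        # smooth at the voxel scale; white noise is not a valid map)
        from scipy.ndimage import gaussian_filter
        rng = np.random.default_rng(2)
        grid = np.zeros((32, 32, 32), dtype=np.float32)
        grid[8:24, 8:24, 8:24] = rng.random((16, 16, 16))
        vol = gt.DensityVolume(grid=gaussian_filter(grid, 1.5))
        ts = gt.project_tilt_series(vol, gt.TiltScheme(-90, 90, 7.5))
        total = grid.sum()
        assert np.all(np.abs(ts.images.sum(axis=(1, 2)) - total) <= 0.005 * total)

    def test_analytic_atom_projection_matches_volume_projection(self):
        cloud = gt.make_helix(20).as_atom_cloud()
        scheme = gt.TiltScheme(-90, 90, 22.5)
        from_volume = gt.project_tilt_series(gt.rasterize(cloud), scheme)
        from_atoms = gt.project_atoms_tilt_series(cloud, scheme)
        assert from_volume.images.shape == from_atoms.images.shape
        for a, b in zip(from_volume.images, from_atoms.images):
            r = np.corrcoef(a.ravel(), b.ravel())[0, 1]
            assert r > 0.99


class TestBackProjection:
    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            gt.back_project(gt.TiltSeries(images=np.empty((0, 8, 8)),
                                          angles=np.empty(0)))

    def test_zero_series_gives_zero_volume(self):
        ts = gt.TiltSeries(images=np.zeros((5, 8, 8)),
                           angles=np.arange(5, dtype=float))
        assert np.all(gt.back_project(ts).grid == 0)

    def test_impulse_round_trip_peaks_at_origin(self):
        grid = np.zeros((32, 32, 32), dtype=np.float32)
        grid[16, 16, 16] = 1.0
        ts = gt.project_tilt_series(gt.DensityVolume(grid=grid), gt.FULL_SCHEME)
        rec = gt.back_project(ts, filter="ramp")
        assert np.unravel_index(np.argmax(rec.grid), rec.shape) == (16, 16, 16)

    def test_helix_round_trip_correlates(self):
        cloud = gt.make_helix(20).as_atom_cloud()
        vol = gt.rasterize(cloud)
        rec = gt.back_project(gt.project_tilt_series(vol, gt.FULL_SCHEME))
        r = np.corrcoef(vol.grid.ravel().astype(float),
                        rec.grid.ravel().astype(float))[0, 1]
        assert r > 0.9

    def test_unknown_filter_rejected(self):
        ts = gt.TiltSeries(images=np.zeros((2, 8, 8)), angles=np.array([0.0, 1.0]))
        with pytest.raises(ValueError):
            gt.back_project(ts, filter="hann")


class TestSimulateTomogram:
    def test_full_regime_is_deterministic(self):
        cloud = gt.make_helix(12).as_atom_cloud()
        a = gt.simulate_tomogram(cloud, regime="full")
        b = gt.simulate_tomogram(cloud, regime="full")
        assert np.array_equal(a.grid, b.grid)

    def test_tumbled_reproducible_for_equal_seeds(self):
        cloud = gt.make_helix(12).as_atom_cloud()
        a = gt.simulate_tomogram(cloud, regime="tumbled", seed=5)
        b = gt.simulate_tomogram(cloud, regime="tumbled", seed=5)
        c = gt.simulate_tomogram(cloud, regime="tumbled", seed=6)
        assert np.array_equal(a.grid, b.grid)
        assert not np.array_equal(a.grid, c.grid)

    def test_unknown_regime_rejected(self):
        with pytest.raises(ValueError):
            gt.simulate_tomogram(gt.make_helix(5).as_atom_cloud(), regime="noisy")

    def test_missing_wedge_elongates_sphere_along_beam(self):
        n = 48
        x, y, z = np.indices((n, n, n))
        c = (n - 1) / 2
        grid = ((x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2 < 8**2).astype(np.float32)
        ts = gt.project_tilt_series(gt.DensityVolume(grid=grid),
                                    gt.MISSING_WEDGE_SCHEME)
        rec = gt.back_project(ts).grid
        half = rec.max() / 2
        kept = np.argwhere(rec >= half)
        extent = lambda ax: np.ptp(kept[:, ax])
        assert extent(2) / extent(0) > 1.05  # z is the beam axis
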