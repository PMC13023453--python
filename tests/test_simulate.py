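import numpy as np
import pytest
from scipy.stats import chi

from chromadist import (
    AffineTransform3D,
    SceneSpec,
    compose_affine,
    generate_scene,
    render_nuclei,
    render_spots,
)


def make_spec(**kwargs):
    defaults = dict(n_spots=50, seed=7)
    defaults.update(kwargs)
    return SceneSpec(**defaults)


class TestGenerateScene:
    def test_colocalization_control_is_identical_point_lists(self):
        scene = generate_scene(make_spec(true_separation_nm=0.0))
        assert np.array_equal(scene.a, scene.b)
        assert np.array_equal(scene.true_a, scene.true_b_pre)

    @pytest.mark.parametrize("L", [120.0, 160.0])
    def test_nanoruler_separation_exact(self, L):
        scene = generate_scene(make_spec(true_separation_nm=L))
        d = np.linalg.norm(scene.true_b_pre - scene.true_a, axis=1)
        assert np.allclose(d, L, rtol=1e-12)
        # zero noise, identity aberration: observed = true
        assert np.allclose(np.linalg.norm(scene.b - scene.a, axis=1), L)

    def test_noise_floor_median_matches_chi_closed_form(self):
        # colocalized pairs with per-axis sigma 20 nm in each channel: the
        # pair difference is isotropic Gaussian with per-axis s.d. 20*sqrt(2),
        # so the 3D distance is (20*sqrt(2)) * chi(3).
        sigma = 20.0
        scene = generate_scene(
            make_spec(n_spots=20000, true_separation_nm=0.0, noise_sigma_nm=(sigma,) * 3)
        )
        med = np.median(np.linalg.norm(scene.b - scene.a, axis=1))
        expected = sigma * np.sqrt(2) * chi(3).median()
        assert med == pytest.approx(expected, rel=0.01)

    def test_squared_distance_mean_follows_distance_law(self):
        # E[d^2] = L^2 + 2 * sum_k sigma_k^2 (both channels add noise)
        L, sigmas = 120.0, (15.0, 15.0, 40.0)
        scene = generate_scene(
            make_spec(n_spots=20000, true_separation_nm=L, noise_sigma_nm=sigmas)
        )
        mean_sq = np.mean(np.sum((scene.b - scene.a) ** 2, axis=1))
        expected = L**2 + 2 * sum(s**2 for s in sigmas)
        assert mean_sq == pytest.approx(expected, rel=0.02)

    def test_orientation_isotropy(self):
        scene = generate_scene(make_spec(n_spots=20000, true_separation_nm=120.0))
        u = (scene.true_b_pre - scene.true_a) / 120.0
        assert np.all(np.abs(u.mean(axis=0)) < 3.0 / np.sqrt(20000))

    def test_aberration_applied_to_b_only(self):
        t = compose_affine(translation_nm=(30.0, 27.0, 162.5))
        scene = generate_scene(make_spec(true_separation_nm=0.0, aberration=t))
        assert np.allclose(scene.b - scene.a, (30.0, 27.0, 162.5))

    def test_seed_determinism(self):
        spec = make_spec(true_separation_nm=120.0, noise_sigma_nm=(20.0,) * 3)
        s1, s2 = generate_scene(spec), generate_scene(spec)
        assert np.array_equal(s1.a, s2.a) and np.array_equal(s1.b, s2.b)

    def test_min_separation_enforced(self):
        scene = generate_scene(make_spec(n_spots=30, min_separation_nm=2000.0))
        d = np.linalg.norm(scene.true_a[:, None] - scene.true_a[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 2000.0

    def test_infeasible_packing_raises(self):
        spec = make_spec(
            n_spots=100,
            bounds_nm=((0, 1000), (0, 1000), (0, 1000)),
            min_separation_nm=900.0,
        )
        with pytest.raises(RuntimeError, match="could not place"):
            generate_scene(spec)

    def test_spec_json_round_trip(self, tmp_path):
        spec = make_spec(
            true_separation_nm=120.0,
            aberration=compose_affine(translation_nm=(30, 27, 160), scales=(1.002, 0.998, 1.005)),
            noise_sigma_nm=(15.0, 15.0, 40.0),
        )
        spec.to_json(tmp_path / "spec.json")
        back = SceneSpec.from_json(tmp_path / "spec.json")
        assert back.n_spots == spec.n_spots
        assert np.array_equal(back.aberration.matrix, spec.aberration.matrix)
        assert generate_scene(back).a == pytest.approx(generate_scene(spec).a)


class TestRenderSpots:
    def test_single_spot_at_voxel_center_peaks_there(self, voxel_size):
        vx, vy, vz = voxel_size
        pos = [[20 * vx, 30 * vy, 8 * vz]]
        grid = render_spots(pos, shape=(16, 64, 64), amplitude=500.0, background=50.0)
        peak = np.unravel_index(np.argmax(grid.intensities), grid.shape)
        assert peak == (8, 30, 20)
        assert grid.intensities[peak] == pytest.approx(550.0)

    def test_zero_spots_constant_background(self):
        grid = render_spots(np.empty((0, 3)), shape=(4, 16, 16), background=77.0)
        assert np.all(grid.intensities == 77.0)

    def test_total_mass_matches_gaussian_integral(self, voxel_size):
        vx, vy, vz = voxel_size
        sxy, sz, amp, bg = 130.0, 300.0, 1000.0, 10.0
        pos = [[32 * vx, 32 * vy, 10 * vz]]
        grid = render_spots(
            pos, shape=(21, 64, 64), sigma_xy_nm=sxy, sigma_z_nm=sz, amplitude=amp, background=bg
        )
        mass = (grid.intensities - bg).sum()
        expected = amp * (2 * np.pi) ** 1.5 * sxy**2 * sz / (vx * vy * vz)
        assert mass == pytest.approx(expected, rel=0.01)

    def test_spot_outside_margin_rejected(self, voxel_size):
        with pytest.raises(ValueError, match="3 sigma"):
            render_spots([[100.0, 100.0, 100.0]], shape=(16, 64, 64))

    def test_poisson_noise_deterministic_given_seed(self, voxel_size):
        vx, vy, vz = voxel_size
        pos = [[30 * vx, 30 * vy, 8 * vz]]
        g1 = render_spots(pos, shape=(16, 64, 64), noise_model="poisson", seed=5)
        g2 = render_spots(pos, shape=(16, 64, 64), noise_model="poisson", seed=5)
        assert np.array_equal(g1.intensities, g2.intensities)


class TestRenderNuclei:
    def test_single_ellipsoid_single_label(self, voxel_size):
        _, labels = render_nuclei([[3000, 3000, 2000]], [[1500, 1200, 1000]], shape=(17, 64, 64))
        assert set(np.unique(labels)) == {0, 1}

    def test_two_disjoint_ellipsoids_volumes(self, voxel_size):
        vx, vy, vz = voxel_size
        centers = [[1800, 1800, 2000], [4800, 4800, 2000]]
        radii = [[1200, 1200, 900], [1000, 1400, 1100]]
        _, labels = render_nuclei(centers, radii, shape=(17, 64, 64))
        assert labels.max() == 2
        for i, r in enumerate(radii, start=1):
            vol = (labels == i).sum() * vx * vy * vz
            analytic = 4.0 / 3.0 * np.pi * r[0] * r[1] * r[2]
            assert vol == pytest.approx(analytic, rel=0.05)

    def test_zero_ellipsoids_all_background(self):
        _, labels = render_nuclei(np.empty((0, 3)), np.empty((0, 3)), shape=(4, 16, 16))
        assert np.all(labels == 0)
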