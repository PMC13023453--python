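import numpy as np
import pandas as pd
import pytest
from scipy.optimize import least_squares
from scipy.stats import chi

from chromadist import (
    AffineChromaticCorrection,
    AffineTransform3D,
    LinearChromaticCorrection,
    SceneSpec,
    apply_lcc,
    apply_transform_to_pairs,
    compose_affine,
    correction_agreement,
    fit_acc,
    fit_lcc,
    generate_scene,
    load_transform,
    save_transform,
)
from chromadist.io import PAIR_COLUMNS


def pairs_from_arrays(a, b, image_id="img0"):
    df = pd.DataFrame(
        {
            "image_id": image_id,
            "ax_nm": a[:, 0], "ay_nm": a[:, 1], "az_nm": a[:, 2],
            "bx_nm": b[:, 0], "by_nm": b[:, 1], "bz_nm": b[:, 2],
            "raw_distance_nm": np.linalg.norm(b - a, axis=1),
            "nucleus_label": 0,
        }
    )
    return df[PAIR_COLUMNS]


def random_points(n, seed, span=40000.0):
    rng = np.random.default_rng(seed)
    pts = rng.uniform(0, 1, (n, 3)) * [span, span, span / 4]
    return pts


def brute_force_affine(a, b):
    """Independent oracle: generic iterative optimizer over the 12 affine dof.

    Coordinates are centered and scaled to O(1) inside the oracle so the
    optimizer converges to the double-precision floor; the result is mapped
    back to the raw frame afterwards."""
    mu_a, mu_b = a.mean(axis=0), b.mean(axis=0)
    s = max(b.std(axis=0).max(), 1.0)
    a_c, b_c = (a - mu_a) / s, (b - mu_b) / s

    def residuals(p):
        m = p.reshape(3, 4)
        return (b_c @ m[:, :3].T + m[:, 3] - a_c).ravel()

    p = np.eye(3, 4).ravel()
    for _ in range(3):  # restarts reset the trust region (pure Gauss-Newton step)
        p = least_squares(residuals, p, method="trf", tr_solver="exact",
                          xtol=2.3e-16, ftol=None, gtol=None).x
    m = p.reshape(3, 4)
    out = np.eye(4)
    out[:3, :3] = m[:, :3]
    out[:3, 3] = s * m[:, 3] + mu_a - m[:, :3] @ mu_b
    return out


class TestLCC:
    def test_identical_channels_give_identity_correction(self):
        a = random_points(100, 0)
        model = fit_lcc(pairs_from_arrays(a, a))
        assert np.allclose(model.mean_diff_, 0, atol=1e-9)
        assert np.allclose(model.slope_, 0, atol=1e-12)
        assert np.allclose(model.intercept_, 0, atol=1e-9)

    def test_constant_offset_fully_removed(self):
        # offsets of the magnitude a confocal system actually shows
        a = random_points(200, 1)
        b = a + np.array([29.7, 27.3, 162.5])
        corrected = apply_lcc(fit_lcc(pairs_from_arrays(a, b)), pairs_from_arrays(a, b))
        d = corrected[["bx_nm", "by_nm", "bz_nm"]].to_numpy() - a
        assert np.allclose(d, 0, atol=1e-9)

    def test_scaling_bias_recovered_closed_form(self):
        # noiseless b = 1.01 a: OLS slope must be exactly 0.01
        a = random_points(500, 2)
        model = fit_lcc(pairs_from_arrays(a, 1.01 * a))
        assert np.allclose(model.slope_, 0.01, atol=1e-9)

    def test_zero_mean_postcondition_on_training_data(self):
        rng = np.random.default_rng(3)
        a = random_points(300, 3)
        b = a @ np.diag([1.003, 0.997, 1.01]) + [30, 27, 160] + rng.normal(0, 25, a.shape)
        model = fit_lcc(pairs_from_arrays(a, b))
        assert np.allclose(model.residual_mean_, 0, atol=1e-9)
        corrected = apply_lcc(model, pairs_from_arrays(a, b))
        d = corrected[["bx_nm", "by_nm", "bz_nm"]].to_numpy() - a
        assert np.allclose(d.mean(axis=0), 0, atol=1e-9)

    def test_reference_channel_untouched(self):
        a = random_points(50, 4)
        pairs = pairs_from_arrays(a, a + 100.0)
        corrected = apply_lcc(fit_lcc(pairs), pairs)
        assert np.array_equal(corrected[["ax_nm", "ay_nm", "az_nm"]].to_numpy(), a)

    def test_double_application_is_not_idempotent_but_refit_is_identity(self):
        a = random_points(100, 5)
        pairs = pairs_from_arrays(a, a + np.array([10.0, 0.0, 0.0]))
        model = fit_lcc(pairs)
        once = apply_lcc(model, pairs)
        twice = apply_lcc(model, once)
        # translation applied twice overshoots by the offset
        assert np.allclose(
            twice["bx_nm"].to_numpy() - once["bx_nm"].to_numpy(), -10.0, atol=1e-9
        )
        # but refitting on corrected data is the identity correction
        refit = fit_lcc(once)
        assert np.allclose(refit.mean_diff_, 0, atol=1e-9)
        assert np.allclose(refit.slope_, 0, atol=1e-12)

    def test_works_for_distant_pairs_without_biasing_separation(self):
        # the self-calibration premise: isotropically oriented separated pairs
        # have zero mean difference, so LCC fitted on them removes the
        # aberration without shrinking the true separation
        L, sigma = 120.0, 15.0
        ab = compose_affine(translation_nm=(30, 27, 160), scales=(1.002, 0.998, 1.005))
        spec = SceneSpec(
            n_spots=8000, true_separation_nm=L, aberration=ab,
            noise_sigma_nm=(sigma,) * 3, seed=11,
        )
        pairs = generate_scene(spec).to_pairs()
        corrected = apply_lcc(fit_lcc(pairs), pairs)
        # Monte-Carlo oracle under the same noise model, no aberration
        rng = np.random.default_rng(99)
        u = rng.standard_normal((200000, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        d_oracle = np.linalg.norm(L * u + rng.normal(0, sigma * np.sqrt(2), u.shape), axis=1)
        med = np.median(corrected["raw_distance_nm"])
        # 99% order-statistic CI half-width for the median at n=8000 is ~1 nm here
        assert med == pytest.approx(np.median(d_oracle), abs=2.5)

    def test_too_few_pairs_and_degenerate_axis_rejected(self):
        a = random_points(5, 6)
        with pytest.raises(ValueError, match=">= 10"):
            fit_lcc(pairs_from_arrays(a, a))
        a = random_points(50, 7)
        a[:, 2] = 1000.0  # zero variance in z
        with pytest.raises(ValueError, match="degenerate"):
            fit_lcc(pairs_from_arrays(a, a))


class TestACC:
    def test_identity_on_identical_channels(self):
        a = random_points(50, 8)
        t = fit_acc(pairs_from_arrays(a, a))
        assert np.allclose(t.matrix, np.eye(4), atol=1e-10)

    def test_pure_translation_recovered_exactly(self):
        a = random_points(50, 9)
        b = a + np.array([30.0, 27.0, 160.0])
        t = fit_acc(pairs_from_arrays(a, b))
        assert np.allclose(t.matrix[:3, :3], np.eye(3), atol=1e-9)
        assert np.allclose(t.matrix[:3, 3], [-30.0, -27.0, -160.0], atol=1e-6)

    def test_noiseless_full_affine_exact_recovery(self):
        # translation + anisotropic scale + rotation + shear, no noise
        ab = compose_affine(
            translation_nm=(30, 27, 160),
            scales=(1.01, 0.99, 1.02),
            rotation_deg=(0.3, -0.2, 0.5),
            shear=(0.002, -0.001, 0.003),
        )
        a = random_points(50, 10)
        b = ab.apply(a)
        t = fit_acc(pairs_from_arrays(a, b))
        assert np.max(np.abs(t.apply(b) - a)) < 1e-6

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_generic_optimizer_oracle_on_noisy_pairs(self, seed):
        rng = np.random.default_rng(100 + seed)
        a = random_points(10, 200 + seed, span=10000.0)
        ab = compose_affine(
            translation_nm=rng.uniform(-200, 200, 3),
            scales=1 + rng.uniform(-0.01, 0.01, 3),
            rotation_deg=rng.uniform(-1, 1, 3),
        )
        b = ab.apply(a) + rng.normal(0, 20, a.shape)
        t = fit_acc(pairs_from_arrays(a, b), min_pairs=10)
        oracle = brute_force_affine(a, b)
        assert np.allclose(t.matrix, oracle, atol=1e-6)

    def test_reference_channel_untouched(self):
        a = random_points(30, 12)
        pairs = pairs_from_arrays(a, a + 50.0)
        corrected = apply_transform_to_pairs(fit_acc(pairs), pairs)
        assert np.array_equal(corrected[["ax_nm", "ay_nm", "az_nm"]].to_numpy(), a)

    def test_coplanar_geometry_rejected(self):
        a = random_points(30, 13)
        b = a.copy()
        b[:, 2] = 0.0  # moving points coplanar
        with pytest.raises(ValueError, match="coplanar"):
            fit_acc(pairs_from_arrays(a, b))

    def test_too_few_pairs_rejected(self):
        a = random_points(10, 14)
        with pytest.raises(ValueError, match=">= 20"):
            fit_acc(pairs_from_arrays(a, a))

    def test_estimator_interface(self):
        est = AffineChromaticCorrection(min_pairs=25)
        assert est.get_params()["min_pairs"] == 25
        a = random_points(30, 15)
        est.set_params(min_pairs=20).fit(pairs_from_arrays(a, a + 10.0))
        assert est.n_pairs_ == 30
        assert est.rms_residual_nm_ < 1e-9
        assert np.allclose(est.transform(a + 10.0), a, atol=1e-6)


class TestAffineTransform:
    def test_apply_translation(self):
        t = compose_affine(translation_nm=(10, 20, 30))
        assert np.allclose(t.apply(np.zeros(3)), (10, 20, 30))

    def test_inverse_round_trip(self):
        t = compose_affine(
            translation_nm=(30, 27, 160), scales=(1.01, 0.99, 1.02), rotation_deg=(1, 2, 3)
        )
        pts = random_points(20, 16)
        assert np.allclose(t.inverse().apply(t.apply(pts)), pts, atol=1e-9)

    def test_invalid_matrices_rejected(self):
        bad = np.eye(4)
        bad[3, 0] = 1.0
        with pytest.raises(ValueError, match="last row"):
            AffineTransform3D(matrix=bad)
        singular = np.eye(4)
        singular[0, 0] = 0.0
        with pytest.raises(ValueError, match="singular"):
            AffineTransform3D(matrix=singular)


class TestPersistence:
    def test_json_round_trip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(17)
        m = np.eye(4)
        m[:3, :4] = np.eye(3, 4) + rng.normal(0, 0.01, (3, 4))
        t = AffineTransform3D(m, reference_channel="A", moving_channel="B", n_pairs=123)
        path = tmp_path / "t.json"
        save_transform(t, path)
        back = load_transform(path)
        assert np.array_equal(back.matrix, t.matrix)
        assert (back.reference_channel, back.moving_channel, back.n_pairs) == ("A", "B", 123)
        assert back.created == t.created

    def test_wrong_schema_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"schema": "something-else/9", "matrix": []}')
        with pytest.raises(ValueError, match="schema"):
            load_transform(path)

    def test_corrupted_last_row_rejected(self, tmp_path):
        t = AffineTransform3D.identity()
        path = tmp_path / "t.json"
        save_transform(t, path)
        text = path.read_text().replace('[\n      0.0,\n      0.0,\n      0.0,\n      1.0\n    ]',
                                        '[\n      0.5,\n      0.0,\n      0.0,\n      1.0\n    ]')
        path.write_text(text)
        with pytest.raises(ValueError, match="last row"):
            load_transform(path)


class TestAgreement:
    def test_translation_plus_scaling_gives_identical_corrections(self):
        # both models express translation + axis-aligned scaling exactly
        ab = compose_affine(translation_nm=(30, 27, 160), scales=(1.002, 0.998, 1.005))
        a = random_points(500, 18)
        pairs = pairs_from_arrays(a, ab.apply(a))
        report = correction_agreement(pairs, fit_lcc(pairs), fit_acc(pairs))
        assert report["median_abs_difference_nm"] < 1e-6
        assert not report["diverged"]

    def test_rotation_favors_affine_model(self):
        # LCC has no rotation term; ACC must fit strictly better
        ab = compose_affine(translation_nm=(30, 27, 160), rotation_deg=(0, 0, 2.0))
        a = random_points(500, 19)
        pairs = pairs_from_arrays(a, ab.apply(a))
        lcc_resid = np.median(apply_lcc(fit_lcc(pairs), pairs)["raw_distance_nm"])
        acc_resid = np.median(
            apply_transform_to_pairs(fit_acc(pairs), pairs)["raw_distance_nm"]
        )
        assert acc_resid < lcc_resid
        report = correction_agreement(pairs, fit_lcc(pairs), fit_acc(pairs))
        assert report["diverged"]

    def test_parameter_recovery_under_noise(self):
        # realistic aberration + localization noise: corrected median sits on
        # the noise floor and the linear block is recovered to 1e-3
        ab = compose_affine(
            translation_nm=(30, 27, 160), scales=(1.002, 0.998, 1.005), rotation_deg=(0, 0, 0.5)
        )
        sigmas = np.array([15.0, 15.0, 40.0])
        spec = SceneSpec(
            n_spots=1000, true_separation_nm=0.0, aberration=ab,
            noise_sigma_nm=tuple(sigmas), seed=20,
        )
        pairs = generate_scene(spec).to_pairs()
        t = fit_acc(pairs)
        assert np.allclose(t.matrix[:3, :3], np.linalg.inv(ab.matrix[:3, :3]), atol=1e-3)
        corrected = apply_transform_to_pairs(t, pairs)
        rng = np.random.default_rng(77)
        noise = rng.normal(0, sigmas * np.sqrt(2), (200000, 3))
        floor = np.median(np.linalg.norm(noise, axis=1))
        assert np.median(corrected["raw_distance_nm"]) == pytest.approx(floor, rel=0.05)
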