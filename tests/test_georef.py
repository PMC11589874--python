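"""Rotation, scan-attribute, and Helmert-transform behaviour.

The default-pose rotation matrix is checked against a symbolically derived
value (Rz(90°)·Ry(60°)·Rx(0°) worked out by hand from the axis-rotation
matrices and frozen here), independent of the implementation.
"""

import numpy as np
import pytest

from plstk.cloud import ControlPointPair
from plstk.georef import (EulerAngles, HelmertTransform, apply_helmert,
                          compute_scan_attributes, euler_from_matrix,
                          fit_helmert, rectify, rotation_matrix)

from conftest import random_cloud

SQ3 = np.sqrt(3.0)
# symbolic composition for (omega, phi, kappa) = (0, 60, 90)
R_DEFAULT = np.array([
    [0.0, -1.0, 0.0],
    [0.5, 0.0, SQ3 / 2],
    [-SQ3 / 2, 0.0, 0.5],
])


class TestRotation:
    def test_zero_angles_identity(self):
        assert np.allclose(rotation_matrix(EulerAngles(0, 0, 0)), np.eye(3))

    def test_default_pose_matches_symbolic_composition(self):
        r = rotation_matrix(EulerAngles(0, 60, 90))
        assert np.allclose(r, R_DEFAULT, atol=1e-12)
        assert np.linalg.det(r) == pytest.approx(1.0)

    def test_rotation_is_isometry(self, rng):
        r = rotation_matrix(EulerAngles(*rng.uniform(-180, 180, 3)))
        v = rng.normal(size=(50, 3))
        assert np.allclose(np.linalg.norm(v @ r.T, axis=1),
                           np.linalg.norm(v, axis=1), rtol=1e-12)
        assert np.allclose(r.T @ r, np.eye(3), atol=1e-9)

    def test_euler_extraction_round_trip(self, rng):
        for _ in range(20):
            a = EulerAngles(*rng.uniform(-80, 80, 3))
            b = euler_from_matrix(rotation_matrix(a))
            assert np.allclose([a.omega, a.phi, a.kappa],
                               [b.omega, b.phi, b.kappa], atol=1e-9)

    def test_gimbal_lock_convention(self):
        a = euler_from_matrix(rotation_matrix(EulerAngles(10, 90, 25)))
        assert a.kappa == 0.0
        assert np.allclose(rotation_matrix(a), rotation_matrix(EulerAngles(10, 90, 25)),
                           atol=1e-9)


class TestRectify:
    def test_identity_angles_leave_cloud_unchanged(self, rng):
        c = random_cloud(rng, 30)
        r = rectify(c, EulerAngles(0, 0, 0))
        assert np.allclose(r.xyz, c.xyz)

    def test_pairwise_distances_preserved(self, rng):
        c = random_cloud(rng, 40)
        r = rectify(c, EulerAngles(12.0, 60.0, 90.0))
        d0 = np.linalg.norm(c.xyz[:, None] - c.xyz[None, :], axis=2)
        d1 = np.linalg.norm(r.xyz[:, None] - r.xyz[None, :], axis=2)
        assert np.allclose(d0, d1, rtol=1e-9, atol=1e-9)

    def test_attributes_ride_along(self, rng):
        c = random_cloud(rng, 20)
        r = rectify(c)
        assert np.array_equal(r["label"], c["label"])

    def test_default_pose_levels_synthetic_ground(self, desk_scene):
        cloud, _ = desk_scene
        rect = rectify(cloud)
        gz = rect.z[cloud["label"] == 0]
        frac = np.mean((gz > -31.0) & (gz < -29.0))
        assert frac >= 0.99


class TestScanAttributes:
    def test_nadir_point(self):
        c = compute_scan_attributes(PointCloudXYZ(0.0, 0.0, -30.0))
        assert c["range"][0] == pytest.approx(30.0)
        assert c["theta"][0] == pytest.approx(180.0)
        assert c["phi_az"][0] == pytest.approx(0.0)

    def test_horizontal_point_hand_trigonometry(self):
        c = compute_scan_attributes(PointCloudXYZ(3.0, 4.0, 0.0))
        assert c["range"][0] == pytest.approx(5.0)
        assert c["theta"][0] == pytest.approx(90.0)
        assert c["phi_az"][0] == pytest.approx(np.degrees(np.arctan2(4, 3)), abs=1e-9)
        assert c["phi_az"][0] == pytest.approx(53.1301, abs=1e-3)

    def test_origin_point_degenerate(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING):
            c = compute_scan_attributes(PointCloudXYZ(0.0, 0.0, 0.0))
        assert c["range"][0] == 0.0 and c["theta"][0] == 0.0 and c["phi_az"][0] == 0.0
        assert "origin" in caplog.text

    def test_ranges_invariant_under_rectify(self, rng):
        c = random_cloud(rng, 50)
        r_before = compute_scan_attributes(c)["range"]
        r_after = compute_scan_attributes(rectify(c))["range"]
        assert np.allclose(r_before, r_after, rtol=1e-12)


def PointCloudXYZ(x, y, z):
    from plstk.cloud import PointCloud
    return PointCloud([x], [y], [z])


def _known_transform():
    rot = rotation_matrix(EulerAngles(0.3, -0.7, 1.2))
    return 1.0005, rot, np.array([105.0, 220.0, 5.5])


class TestHelmert:
    def test_identity_pairs(self, rng):
        src = rng.uniform(0, 50, (8, 3))
        h = HelmertTransform().fit(src, src)
        assert np.allclose(h.translation_, 0, atol=1e-9)
        assert np.allclose(h.rotation_matrix_, np.eye(3), atol=1e-9)
        assert h.scale_ == pytest.approx(1.0, abs=1e-12)
        assert h.rmse_ == pytest.approx(0.0, abs=1e-12)

    def test_parameter_recovery_noise_free(self, rng):
        mu, rot, t = _known_transform()
        src = rng.uniform(0, 100, (8, 3))
        tgt = t + mu * src @ rot.T
        h = HelmertTransform().fit(src, tgt)
        assert np.allclose(h.translation_, t, rtol=1e-9, atol=1e-9)
        assert np.allclose(h.rotation_matrix_, rot, atol=1e-12)
        assert h.scale_ == pytest.approx(mu, rel=1e-12)
        assert h.rmse_ <= 1e-9

    def test_held_out_pair_reproduced(self, rng):
        mu, rot, t = _known_transform()
        src = rng.uniform(0, 100, (9, 3))
        tgt = t + mu * src @ rot.T
        h = HelmertTransform().fit(src[:8], tgt[:8])
        assert np.allclose(h.transform(src[8:]), tgt[8:], atol=1e-9)

    def test_noise_rmse_bracket_monte_carlo(self):
        """Mean fitted RMSE over 100 seeds sits in [0.5 sigma, 2 sigma]
        under 1 cm Gaussian noise on the targets."""
        mu, rot, t = _known_transform()
        sigma = 0.01
        rmses = []
        for seed in range(100):
            r = np.random.default_rng(seed)
            src = r.uniform(0, 100, (8, 3))
            tgt = t + mu * src @ rot.T + r.normal(0, sigma, (8, 3))
            rmses.append(HelmertTransform().fit(src, tgt).rmse_)
        assert 0.5 * sigma <= np.mean(rmses) <= 2 * sigma

    def test_apply_then_inverse_is_identity(self, rng):
        mu, rot, t = _known_transform()
        h = HelmertTransform()
        h.rotation_matrix_, h.scale_, h.translation_ = rot, mu, t
        x = rng.uniform(-50, 50, (30, 3))
        assert np.allclose(h.inverse_transform(h.transform(x)), x, atol=1e-9)

    def test_apply_helmert_keeps_attributes(self, rng):
        c = random_cloud(rng, 10)
        src = rng.uniform(0, 50, (5, 3))
        h = HelmertTransform().fit(src, src + 3.0)
        out = apply_helmert(c, h)
        assert np.allclose(out.xyz, c.xyz + 3.0, atol=1e-9)
        assert np.array_equal(out["label"], c["label"])

    def test_too_few_pairs(self, rng):
        with pytest.raises(ValueError, match=">= 3"):
            HelmertTransform().fit(rng.uniform(0, 1, (2, 3)), rng.uniform(0, 1, (2, 3)))

    def test_collinear_pairs_rejected(self):
        src = np.array([[float(i), 0.0, 0.0] for i in range(6)])
        with pytest.raises(ValueError, match="degenerate|collinear"):
            HelmertTransform().fit(src, src + 1.0)

    def test_fit_helmert_from_pairs(self, rng):
        src = rng.uniform(0, 50, (8, 3))
        pairs = [ControlPointPair(s, s * 2.0) for s in src]
        h = fit_helmert(pairs)
        assert h.scale_ == pytest.approx(2.0, rel=1e-9)

    def test_unbiased_under_noise(self):
        """Mean parameter error shrinks toward zero over many noise draws."""
        mu, rot, t = _known_transform()
        errs = []
        for seed in range(60):
            r = np.random.default_rng(1000 + seed)
            src = r.uniform(0, 100, (8, 3))
            tgt = t + mu * src @ rot.T + r.normal(0, 0.01, (8, 3))
            h = HelmertTransform().fit(src, tgt)
            errs.append(h.scale_ - mu)
        assert abs(np.mean(errs)) < 5e-5
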