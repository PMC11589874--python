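"""Stem-point classification, cylinder fitting, clustering and normalization."""

import numpy as np
import pytest

from plstk.cloud import PointCloud, TerrainModel
from plstk.stems import (StemDetectionConfig, classify_stem_points, cluster_stems,
                         coarse_segment, fit_cylinder, normalize_heights)
from plstk.validate import match_stems


def flat_dtm(extent=20.0, z=0.0, res=0.5):
    xs, ys = np.meshgrid(np.arange(-extent, extent, res), np.arange(-extent, extent, res))
    return TerrainModel(np.column_stack([xs.ravel(), ys.ravel(),
                                         np.full(xs.size, z)]), resolution=res)


def vertical_line(rng, x=0.0, y=0.0, z0=0.0, height=2.0, spacing=0.01, jitter=0.002):
    n = int(height / spacing)
    z = z0 + np.arange(n) * spacing
    return np.column_stack([x + rng.normal(0, jitter, n),
                            y + rng.normal(0, jitter, n), z])


def sampled_cylinder(rng, center=(0.0, 0.0), radius=0.10, height=3.0, n=600,
                     noise=0.0, tilt=(0.0, 0.0, 1.0)):
    theta = rng.uniform(0, 2 * np.pi, n)
    h = rng.uniform(0, height, n)
    r = radius + (rng.normal(0, noise, n) if noise else 0.0)
    d = np.asarray(tilt, float)
    d = d / np.linalg.norm(d)
    ex = np.cross([0, 1, 0], d)
    ex /= np.linalg.norm(ex)
    ey = np.cross(d, ex)
    pts = (np.array([center[0], center[1], 0.0]) + np.outer(h, d)
           + np.outer(r * np.cos(theta), ex) + np.outer(r * np.sin(theta), ey))
    return pts


class TestClassify:
    def test_vertical_line_flagged(self, rng):
        pts = vertical_line(rng)
        cloud = PointCloud(pts[:, 0], pts[:, 1], pts[:, 2])
        cfg = StemDetectionConfig(search_z_band=None)
        mask = classify_stem_points(cloud, flat_dtm(), cfg)
        # points with a full (two-sided) neighbourhood must all be flagged
        interior = (pts[:, 2] > 0.5) & (pts[:, 2] < 1.5)
        assert mask[interior].all()

    def test_horizontal_line_not_flagged(self, rng):
        pts = vertical_line(rng)
        cloud = PointCloud(pts[:, 2], pts[:, 1], pts[:, 0] + 1.0)  # laid flat at z=1
        cfg = StemDetectionConfig(search_z_band=None)
        mask = classify_stem_points(cloud, flat_dtm(), cfg)
        assert mask.sum() == 0

    def test_isotropic_blob_not_flagged(self, rng):
        pts = rng.normal(0, 0.3, (500, 3)) + [0, 0, 1.5]
        cloud = PointCloud(pts[:, 0], pts[:, 1], pts[:, 2])
        cfg = StemDetectionConfig(search_z_band=None)
        mask = classify_stem_points(cloud, flat_dtm(), cfg)
        assert mask.sum() == 0

    def test_disjoint_frames_error(self, rng):
        pts = vertical_line(rng, x=500.0, y=500.0)
        cloud = PointCloud(pts[:, 0], pts[:, 1], pts[:, 2])
        with pytest.raises(ValueError, match="disjoint"):
            classify_stem_points(cloud, flat_dtm(), StemDetectionConfig())


class TestFitCylinder:
    def test_noise_free_recovery(self, rng):
        pts = sampled_cylinder(rng, center=(2.0, -1.0), radius=0.10)
        cyl = fit_cylinder(pts)
        assert cyl.radius == pytest.approx(0.10, abs=1e-6)
        angle = np.degrees(np.arccos(np.clip(cyl.axis_direction[2], -1, 1)))
        assert angle < 0.01
        assert np.allclose(cyl.xy_at(0.0), [2.0, -1.0], atol=1e-6)

    def test_tilted_axis_recovery(self, rng):
        tilt = np.array([0.1, -0.05, 1.0])
        pts = sampled_cylinder(rng, radius=0.15, tilt=tilt)
        cyl = fit_cylinder(pts, init_direction=(0, 0, 1))
        cosang = abs(cyl.axis_direction @ (tilt / np.linalg.norm(tilt)))
        assert np.degrees(np.arccos(min(cosang, 1.0))) < 0.01
        assert cyl.radius == pytest.approx(0.15, abs=1e-6)

    def test_radius_under_noise_monte_carlo(self):
        radii = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            pts = sampled_cylinder(r, radius=0.10, noise=0.005)
            radii.append(fit_cylinder(pts).radius)
        assert np.all(np.abs(np.array(radii) - 0.10) < 0.01)

    def test_consistency_error_shrinks_with_noise(self):
        errs = []
        for noise in (0.01, 0.001, 0.0001):
            r = np.random.default_rng(5)
            pts = sampled_cylinder(r, radius=0.12, noise=noise)
            errs.append(abs(fit_cylinder(pts).radius - 0.12))
        assert errs[2] < errs[0]

    def test_too_few_points(self, rng):
        with pytest.raises(ValueError, match=">= 6"):
            fit_cylinder(rng.normal(size=(5, 3)))


class TestClusterStems:
    def _scene(self, rng, centers):
        pts = np.vstack([sampled_cylinder(rng, center=c, radius=0.12, height=4.0,
                                          n=800, noise=0.002) for c in centers])
        return PointCloud(pts[:, 0], pts[:, 1], pts[:, 2])

    def test_single_stem_position(self, rng):
        cloud = self._scene(rng, [(3.0, 4.0)])
        cfg = StemDetectionConfig(search_z_band=(0.0, 10.0))
        mask = classify_stem_points(cloud, flat_dtm(), cfg)
        sm = cluster_stems(cloud, mask, flat_dtm(), cfg)
        assert len(sm) == 1
        assert np.linalg.norm(sm.positions()[0, :2] - [3.0, 4.0]) < 0.25

    def test_two_stems_five_metres_apart(self, rng):
        cloud = self._scene(rng, [(0.0, 0.0), (5.0, 0.0)])
        cfg = StemDetectionConfig(search_z_band=(0.0, 10.0))
        mask = classify_stem_points(cloud, flat_dtm(), cfg)
        sm = cluster_stems(cloud, mask, flat_dtm(), cfg)
        assert len(sm) == 2

    def test_stem_beyond_max_range_excluded(self, rng):
        cloud = self._scene(rng, [(0.0, 10.0)])
        cfg = StemDetectionConfig(search_z_band=(0.0, 10.0), max_range=8.0)
        mask = classify_stem_points(cloud, flat_dtm(), cfg)
        sm = cluster_stems(cloud, mask, flat_dtm(), cfg,
                           scanner_position=(0.0, 0.0, 0.0))
        assert len(sm) == 0

    def test_no_stems_on_empty_mask(self, rng):
        cloud = self._scene(rng, [(0.0, 0.0)])
        sm = cluster_stems(cloud, np.zeros(len(cloud), bool), flat_dtm(),
                           StemDetectionConfig())
        assert len(sm) == 0


class TestCoarseSegment:
    def _map_at_origin(self, rng):
        cloud = PointCloud(*sampled_cylinder(rng, radius=0.1).T)
        cfg = StemDetectionConfig(search_z_band=(0.0, 10.0), min_cluster_points=20)
        mask = classify_stem_points(cloud, flat_dtm(), cfg)
        return cluster_stems(cloud, mask, flat_dtm(), cfg)

    def test_boundary_inclusive(self, rng):
        sm = self._map_at_origin(rng)
        probe = PointCloud([3.0, 3.5, 4.0], [0.0] * 3, [1.0] * 3)
        bufs = coarse_segment(probe, sm, StemDetectionConfig())
        xs = sorted(bufs[1].x)
        assert len(xs) == 2 and xs == [3.0, 3.5]

    def test_empty_stem_map(self, rng):
        from plstk.stems import StemMap
        probe = PointCloud([0.0], [0.0], [0.0])
        assert coarse_segment(probe, StemMap(), StemDetectionConfig()) == {}

    def test_overlapping_buffers_share_points(self, rng):
        from plstk.stems import CylinderModel, StemMap
        cyl = CylinderModel([0, 0, 0], [0, 0, 1], 0.1, (0.0, 2.0), 0.0)
        sm = StemMap([(1, np.array([0.0, 0.0, 0.0]), cyl),
                      (2, np.array([4.0, 0.0, 0.0]), cyl)])
        probe = PointCloud([2.0], [0.0], [1.0])
        bufs = coarse_segment(probe, sm, StemDetectionConfig())
        assert len(bufs[1]) == 1 and len(bufs[2]) == 1

    def test_membership_matches_brute_force(self, rng):
        sm = self._map_at_origin(rng)
        pts = rng.uniform(-6, 6, (300, 3))
        probe = PointCloud(pts[:, 0], pts[:, 1], pts[:, 2])
        bufs = coarse_segment(probe, sm, StemDetectionConfig())
        pos = sm.positions()[0, :2]
        expected = np.flatnonzero(np.linalg.norm(pts[:, :2] - pos, axis=1) <= 3.5)
        got = np.flatnonzero(np.isin(np.round(pts[:, 0], 9),
                                     np.round(bufs[1].x, 9)))
        assert np.array_equal(expected, got)


class TestNormalizeHeights:
    def test_flat_offset(self):
        dtm = flat_dtm(z=100.0)
        c = PointCloud([0.0], [0.0], [105.0])
        out = normalize_heights(c, dtm)
        assert out.z[0] == pytest.approx(5.0)
        assert (out.x[0], out.y[0]) == (0.0, 0.0)

    def test_round_trip_inverse(self, rng):
        dtm = flat_dtm(z=77.0)
        pts = rng.uniform(-10, 10, (50, 3))
        c = PointCloud(pts[:, 0], pts[:, 1], pts[:, 2] + 77.0)
        norm = normalize_heights(c, dtm)
        gz, _ = dtm.ground_at(norm.xyz[:, :2])
        back = norm.with_coords(np.column_stack([norm.x, norm.y, norm.z + gz]))
        assert np.allclose(back.z, c.z, atol=1e-9)

    def test_sloped_dtm_grounds_surface_points(self, rng):
        res = 0.2
        xs, ys = np.meshgrid(np.arange(-10, 10, res), np.arange(-10, 10, res))
        gz = 0.05 * xs + 0.02 * ys
        dtm = TerrainModel(np.column_stack([xs.ravel(), ys.ravel(), gz.ravel()]),
                           resolution=res)
        px = rng.uniform(-9, 9, 300)
        py = rng.uniform(-9, 9, 300)
        pz = 0.05 * px + 0.02 * py
        out = normalize_heights(PointCloud(px, py, pz), dtm)
        assert np.abs(out.z).max() <= 0.05

    def test_gap_listed_in_error(self):
        dtm = flat_dtm(extent=1.0, res=0.2)
        c = PointCloud([50.0], [50.0], [0.0])
        with pytest.raises(ValueError, match="1 locations"):
            normalize_heights(c, dtm)
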