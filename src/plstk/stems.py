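"""Stem detection, coarse cylindrical-buffer segmentation and DTM normalization.

Stems are found in two steps.  First, each candidate point's local
neighbourhood (radius ball) is analysed with PCA: a point is a stem point
when the neighbourhood is sufficiently linear — linearity
``(l1 - l2)/l1`` of the sorted eigenvalues above a threshold — and its
dominant eigenvector is close to the local terrain normal (vertical on flat
ground).  Second, stem points are clustered by planimetric connectivity and
each cluster is fitted with a 3-D cylinder; clusters whose fitted axes land
within the merge distance are merged and refitted, which restores the
coupling between clustering and cylinder reconstruction.

By default, candidate points are taken from a normalized-height band above
the ground (0.3–10 m): the ground sheet and the upper canopy cannot pass the
verticality/linearity gates, and skipping them keeps neighbourhood analysis
tractable on full scenes of millions of points.  Set ``search_z_band=None``
to evaluate every point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import cKDTree
from sklearn.cluster import DBSCAN

from .cloud import PointCloud, TerrainModel

__all__ = [
    "StemDetectionConfig",
    "CylinderModel",
    "StemMap",
    "classify_stem_points",
    "fit_cylinder",
    "cluster_stems",
    "coarse_segment",
    "normalize_heights",
]

log = logging.getLogger(__name__)


@dataclass
class StemDetectionConfig:
    neighborhood_radii: tuple[float, ...] = (0.5, 1.0)  # m, PCA ball radii;
    # multi-scale: dense near-range stems are linear at the small radius,
    # sparsely sampled distant stems need several scan rows (large radius)
    verticality_max_angle: float = 15.0    # deg, dominant eigvec vs local up
    linearity_min: float = 0.6             # (l1-l2)/l1
    min_neighbors: int = 5                 # full-neighbourhood requirement
    min_cluster_points: int = 50
    stem_merge_xy: float = 0.5             # m, planimetric link/merge distance
    max_range: float = 200.0               # m, 3-D gate to the scanner
    buffer_radius: float = 3.5             # m, coarse segmentation cylinder
    max_stem_radius: float = 0.5           # m, plausibility gate on fitted stems
    max_fit_rmse: float = 0.05             # m, plausibility gate on fit residuals
    search_z_band: tuple[float, float] | None = (0.3, 10.0)  # m above ground

    def __post_init__(self):
        for name in ("verticality_max_angle", "min_cluster_points",
                     "stem_merge_xy", "max_range", "buffer_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.neighborhood_radii or min(self.neighborhood_radii) <= 0:
            raise ValueError("neighborhood_radii must be positive")
        if not 0.0 <= self.linearity_min <= 1.0:
            raise ValueError("linearity_min must be in [0, 1]")


@dataclass
class CylinderModel:
    """Finite cylinder: a point on the axis, unit direction, radius, z span."""

    axis_point: np.ndarray
    axis_direction: np.ndarray
    radius: float
    z_extent: tuple[float, float]
    inlier_rmse: float

    def __post_init__(self):
        self.axis_point = np.asarray(self.axis_point, dtype=np.float64)
        self.axis_direction = np.asarray(self.axis_direction, dtype=np.float64)
        nrm = np.linalg.norm(self.axis_direction)
        if not np.isclose(nrm, 1.0, atol=1e-6):
            raise ValueError("axis_direction must be a unit vector")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.z_extent[0] >= self.z_extent[1]:
            raise ValueError("z_extent must be increasing")

    def xy_at(self, z: float) -> np.ndarray:
        """Planimetric axis position at height z."""
        p, d = self.axis_point, self.axis_direction
        if abs(d[2]) < 1e-9:
            return p[:2]
        t = (z - p[2]) / d[2]
        return (p + t * d)[:2]


@dataclass
class StemMap:
    """Detected stems: (stem_id, ground position E/N/h, cylinder model)."""

    stems: list[tuple[int, np.ndarray, CylinderModel]] = field(default_factory=list)

    def __len__(self):
        return len(self.stems)

    def positions(self) -> np.ndarray:
        if not self.stems:
            return np.empty((0, 3))
        return np.vstack([p for _, p, _ in self.stems])

    def to_geojson(self) -> dict:
        feats = []
        for sid, pos, cyl in self.stems:
            feats.append({
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [round(v, 4) for v in pos]},
                "properties": {
                    "stem_id": int(sid),
                    "radius_m": round(cyl.radius, 4),
                    "axis_point": [round(v, 4) for v in cyl.axis_point],
                    "axis_direction": [round(v, 6) for v in cyl.axis_direction],
                    "z_extent": [round(v, 4) for v in cyl.z_extent],
                    "inlier_rmse_m": round(cyl.inlier_rmse, 5),
                },
            })
        return {"type": "FeatureCollection", "features": feats}


def _check_frames(cloud: PointCloud, dtm: TerrainModel) -> None:
    """Cheap frame-mismatch guard: planimetric bounding boxes must overlap."""
    if len(cloud) == 0:
        return
    cmin, cmax = cloud.xyz[:, :2].min(axis=0), cloud.xyz[:, :2].max(axis=0)
    dmin, dmax = dtm.support[:, :2].min(axis=0), dtm.support[:, :2].max(axis=0)
    if np.any(cmax < dmin) or np.any(cmin > dmax):
        raise ValueError("cloud and DTM planimetric bounding boxes are disjoint "
                         "(frame mismatch?)")


def classify_stem_points(cloud: PointCloud, dtm: TerrainModel,
                         config: StemDetectionConfig = StemDetectionConfig()) -> np.ndarray:
    """Boolean mask flagging points whose neighbourhood is linear and vertical."""
    _check_frames(cloud, dtm)
    n = len(cloud)
    mask = np.zeros(n, dtype=bool)
    if n == 0:
        return mask
    xyz = cloud.xyz

    if config.search_z_band is not None:
        gz, _ = dtm.ground_at(xyz[:, :2])
        hn = xyz[:, 2] - gz
        cand = np.flatnonzero((hn >= config.search_z_band[0])
                              & (hn <= config.search_z_band[1]))
    else:
        cand = np.arange(n)
    if cand.size == 0:
        return mask

    flat = np.ptp(dtm.support[:, 2]) < 1e-9
    tree = cKDTree(xyz[cand])
    pts = xyz[cand]

    for radius in config.neighborhood_radii:
        todo = np.flatnonzero(~mask[cand])      # already-flagged points are done
        if todo.size == 0:
            break
        neighbors = tree.query_ball_point(pts[todo], radius, workers=-1)
        covs = np.empty((todo.size, 3, 3))
        valid = np.zeros(todo.size, dtype=bool)
        for i, nb in enumerate(neighbors):
            if len(nb) < config.min_neighbors:
                continue
            q = pts[nb]
            q = q - q.mean(axis=0)
            covs[i] = q.T @ q / len(nb)
            valid[i] = True
        if not valid.any():
            continue
        w, v = np.linalg.eigh(covs[valid])      # ascending eigenvalues
        l1, l2 = w[:, 2], w[:, 1]
        with np.errstate(invalid="ignore", divide="ignore"):
            linearity = np.where(l1 > 0, (l1 - l2) / l1, 0.0)
        dominant = v[:, :, 2]                   # eigenvector of largest eigenvalue

        sel = cand[todo[valid]]
        if flat:
            up = np.tile([0.0, 0.0, 1.0], (sel.size, 1))
        else:
            up = np.vstack([dtm.normal_at(xyz[j, :2]) for j in sel])
        cosang = np.abs(np.sum(dominant * up, axis=1))
        angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))

        ok = (linearity >= config.linearity_min) & (angle <= config.verticality_max_angle)
        mask[sel[ok]] = True
    return mask


def _cylinder_residuals(params, pts):
    tx, ty, cx, cy, r = params
    d = np.array([np.sin(tx), -np.cos(tx) * np.sin(ty), np.cos(tx) * np.cos(ty)])
    p0 = np.array([cx, cy, 0.0])
    diff = pts - p0
    cross = np.cross(diff, d)
    dist = np.linalg.norm(cross, axis=1)
    return dist - r


def fit_cylinder(points: PointCloud | np.ndarray,
                 init_direction=(0.0, 0.0, 1.0)) -> CylinderModel:
    """Least-squares cylinder: minimizes sum((dist_to_axis - r)^2).

    Parameterized by two axis tilt angles, the planimetric axis intercept at
    z = 0 (of the centred points) and the radius; Gauss-Newton refinement via
    :func:`scipy.optimize.least_squares`, initialized from ``init_direction``
    and an algebraic circle fit of the axis-aligned projection.
    """
    pts = points.xyz if isinstance(points, PointCloud) else np.asarray(points, float)
    if pts.shape[0] < 6:
        raise ValueError(f"cylinder fit needs >= 6 points, got {pts.shape[0]}")
    center = pts.mean(axis=0)
    q = pts - center

    d0 = np.asarray(init_direction, dtype=np.float64)
    d0 = d0 / np.linalg.norm(d0)
    if d0[2] < 0:
        d0 = -d0
    # initial tilt angles from the direction (inverse of the parameterization)
    tx0 = np.arcsin(np.clip(d0[0], -1, 1))
    ty0 = np.arctan2(-d0[1], d0[2]) if abs(np.cos(tx0)) > 1e-9 else 0.0

    # algebraic (Kasa) circle fit in the plane orthogonal to d0
    ez = d0
    ex = np.cross([0.0, 1.0, 0.0] if abs(ez[0]) > 0.9 else [1.0, 0.0, 0.0], ez)
    ex /= np.linalg.norm(ex)
    ey = np.cross(ez, ex)
    u, v = q @ ex, q @ ey
    a_mat = np.column_stack([u, v, np.ones_like(u)])
    b_vec = u ** 2 + v ** 2
    try:
        sol, *_ = np.linalg.lstsq(a_mat, b_vec, rcond=None)
    except np.linalg.LinAlgError as exc:
        raise ValueError("degenerate cylinder geometry") from exc
    uc, vc = sol[0] / 2.0, sol[1] / 2.0
    r0 = float(np.sqrt(max(sol[2] + uc ** 2 + vc ** 2, 1e-8)))
    c0 = uc * ex + vc * ey   # axis point offset in the centred frame
    if not np.all(np.isfinite([uc, vc, r0])):
        raise ValueError("degenerate cylinder geometry")

    x0 = np.array([tx0, ty0, c0[0], c0[1], r0])
    res = least_squares(_cylinder_residuals, x0, args=(q,),
                        method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14,
                        max_nfev=500)
    tx, ty, cx, cy, r = res.x
    if r <= 0 or not np.all(np.isfinite(res.x)):
        raise ValueError("cylinder fit did not converge to a valid model")
    d = np.array([np.sin(tx), -np.cos(tx) * np.sin(ty), np.cos(tx) * np.cos(ty)])
    d /= np.linalg.norm(d)
    if d[2] < 0:
        d = -d
    axis_point = center + np.array([cx, cy, 0.0])
    rmse = float(np.sqrt(np.mean(res.fun ** 2)))
    z_extent = (float(pts[:, 2].min()), float(pts[:, 2].max()))
    return CylinderModel(axis_point, d, float(abs(r)), z_extent, rmse)


def _ground_position(cyl: CylinderModel, dtm: TerrainModel) -> np.ndarray:
    """Axis ∩ DTM surface, by one fixed-point refinement of the ground height."""
    xy = cyl.xy_at(cyl.z_extent[0])
    for _ in range(3):
        gz, _ = dtm.ground_at(xy)
        xy = cyl.xy_at(float(gz[0]))
    gz, _ = dtm.ground_at(xy)
    return np.array([xy[0], xy[1], float(gz[0])])


def cluster_stems(cloud: PointCloud, stem_mask: np.ndarray, dtm: TerrainModel,
                  config: StemDetectionConfig = StemDetectionConfig(),
                  scanner_position=(0.0, 0.0, 0.0)) -> StemMap:
    """Group stem points into trees and fit per-tree cylinder models.

    3-D single-linkage connectivity at ``stem_merge_xy`` replaces the
    original coupled clustering/fitting; a merge-and-refit pass on fitted
    axes restores the coupling.  Connectivity is deliberately 3-D: crown
    silhouettes project planimetrically onto the stem axis and would fuse
    with the stem in 2-D, whereas in 3-D they stay on the crown shell, well
    separated.  Stems farther than ``max_range`` (3-D, from
    ``scanner_position``) are discarded.
    """
    idx = np.flatnonzero(stem_mask)
    if idx.size == 0:
        return StemMap()
    xyz = cloud.xyz[idx]

    # 3-D single-linkage connectivity == DBSCAN(eps=link, min_samples=1)
    labels = DBSCAN(eps=config.stem_merge_xy, min_samples=1).fit_predict(xyz)
    groups = [np.flatnonzero(labels == g) for g in np.unique(labels)]
    groups = [g for g in groups if g.size >= config.min_cluster_points]

    fitted = []
    for g in groups:
        try:
            cyl = fit_cylinder(xyz[g])
        except ValueError:
            log.info("dropping degenerate stem cluster of %d points", g.size)
            continue
        # only stem-like cylinders survive: crown silhouettes and other
        # vertical structures fit with implausible radius or residuals
        if cyl.radius > config.max_stem_radius or cyl.inlier_rmse > config.max_fit_rmse:
            log.info("dropping non-stem cluster (r=%.2f m, rmse=%.3f m)",
                     cyl.radius, cyl.inlier_rmse)
            continue
        fitted.append((g, cyl))

    # merge clusters whose fitted axes are planimetrically close, then refit
    merged = True
    while merged and len(fitted) > 1:
        merged = False
        for i in range(len(fitted)):
            zi = fitted[i][1].z_extent[0]
            for j in range(i + 1, len(fitted)):
                dxy = np.linalg.norm(fitted[i][1].xy_at(zi) - fitted[j][1].xy_at(zi))
                if dxy < config.stem_merge_xy:
                    g = np.concatenate([fitted[i][0], fitted[j][0]])
                    try:
                        cyl = fit_cylinder(xyz[g])
                    except ValueError:
                        continue
                    if (cyl.radius > config.max_stem_radius
                            or cyl.inlier_rmse > config.max_fit_rmse):
                        continue
                    fitted[i] = (g, cyl)
                    del fitted[j]
                    merged = True
                    break
            if merged:
                break

    scanner = np.asarray(scanner_position, dtype=np.float64)
    stems = []
    sid = 1
    for _, cyl in sorted(fitted, key=lambda t: tuple(t[1].xy_at(t[1].z_extent[0]))):
        pos = _ground_position(cyl, dtm)
        if np.linalg.norm(pos - scanner) > config.max_range:
            continue
        stems.append((sid, pos, cyl))
        sid += 1
    return StemMap(stems)


def coarse_segment(cloud: PointCloud, stem_map: StemMap,
                   config: StemDetectionConfig = StemDetectionConfig()) -> dict[int, PointCloud]:
    """Per-stem cylindrical buffers: planimetric distance <= buffer_radius
    (boundary inclusive), full z extent; overlapping buffers share points."""
    out: dict[int, PointCloud] = {}
    if len(stem_map) == 0:
        return out
    tree = cKDTree(cloud.xyz[:, :2])
    for sid, pos, _ in stem_map.stems:
        idx = tree.query_ball_point(pos[:2], config.buffer_radius)
        idx = np.sort(np.asarray(idx, dtype=np.int64))
        out[sid] = cloud.select(idx)
    return out


def normalize_heights(cloud: PointCloud, dtm: TerrainModel) -> PointCloud:
    """Subtract the ground elevation of the nearest DTM support point.

    Errors (listing the count) when points sit farther than 5x the DTM
    resolution from any support.  Invertible given the same DTM.
    """
    if len(cloud) == 0:
        return cloud
    gz, _ = dtm.ground_at(cloud.xyz[:, :2], max_dist=5.0 * dtm.resolution)
    xyz = cloud.xyz
    xyz[:, 2] -= gz
    return cloud.with_coords(xyz)
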