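"""Seed-reproducible synthetic permanent-laser-scanner forest scenes.

Emulates the acquisition geometry of a mast-mounted scanner: instrument 30 m
above ground, boresight tilted 60° down, an 87° x 151° scan window sampled
on a regular angular grid, and a maximum usable range of 200 m.  Trees are
analytic primitives — a vertical stem cylinder topped by a conifer cone or a
birch crown ellipsoid — standing on a flat or uniformly sloped ground plane.
Each grid direction is ray-cast against the primitives; with occlusion on
only the first intersection survives, so the far side of stems and anything
shadowed by a nearer crown is never sampled, matching the single-view
perspective of a fixed installation.  Gaussian range noise, crown
penetration jitter, and a small fraction of atmospheric outliers complete
the cloud.  Every point carries a ground-truth tree label (0 = ground or
noise) and class-dependent synthetic reflectance/deviation/amplitude.

The instrument's native angular resolution (0.006°) would produce ~10^8
rays; the generator defaults to 0.05°, which preserves the geometry at desk
scale.

Frames: the generated cloud is in the *scanner frame* (what the instrument
would record); the truth tables and DTM are in the *rectified frame* (origin
at the scanner, +Z up, ground near z = -mast height), i.e. what
``rectify`` with the default pose angles produces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cloud import PointCloud, TerrainModel
from .georef import EulerAngles, rotation_matrix

__all__ = [
    "ScannerPose",
    "SceneConfig",
    "SceneTruth",
    "TreeTruth",
    "generate_scene",
    "simulate_scan",
    "Plane",
    "VerticalCylinder",
    "VerticalCone",
    "Ellipsoid",
]


@dataclass(frozen=True)
class ScannerPose:
    position: tuple[float, float, float] = (0.0, 0.0, 30.0)  # world frame, m
    tilt_deg: float = 60.0
    heading_deg: float = 0.0
    fov_v_deg: float = 87.0
    fov_h_deg: float = 151.0
    upper_edge_deg: float = 1.5     # depression of the shallowest ray
    angular_res_deg: float = 0.05   # instrument native: 0.006
    max_range_m: float = 200.0

    @property
    def euler(self) -> EulerAngles:
        return EulerAngles(0.0, self.tilt_deg, 90.0 + self.heading_deg)

    def grid_directions(self) -> np.ndarray:
        """(n, 3) unit ray directions in the *world* frame, row-major over
        the (vertical, horizontal) angular grid.

        The vertical window spans depressions ``[upper_edge, upper_edge +
        fov_v]``: a long-range line scanner covers well above its tilted
        boresight, so the usable window reaches almost to the horizon —
        otherwise distant crown tops could never be observed.
        """
        nv = int(round(self.fov_v_deg / self.angular_res_deg)) + 1
        nh = int(round(self.fov_h_deg / self.angular_res_deg)) + 1
        v = np.deg2rad(np.linspace(self.tilt_deg - self.upper_edge_deg - self.fov_v_deg,
                                   self.tilt_deg - self.upper_edge_deg, nv))
        h = np.deg2rad(np.linspace(-self.fov_h_deg / 2, self.fov_h_deg / 2, nh))
        cv, sv = np.cos(v), np.sin(v)
        ch, sh = np.cos(h), np.sin(h)
        # scanner frame: boresight +X, h about +Z, v elevation
        d = np.empty((nv, nh, 3))
        d[:, :, 0] = cv[:, None] * ch[None, :]
        d[:, :, 1] = cv[:, None] * sh[None, :]
        d[:, :, 2] = sv[:, None]
        r = rotation_matrix(self.euler)
        return d.reshape(-1, 3) @ r.T


# species index -> (height range, crown-base fraction, crown radius range,
#                   stem radius range, crown kind)
_SPECIES_PARAMS = {
    1: ((14.0, 22.0), 0.45, (1.3, 2.2), (0.10, 0.25), "cone"),      # Scots pine
    2: ((10.0, 20.0), 0.15, (1.2, 2.0), (0.10, 0.22), "cone"),      # Norway spruce
    3: ((8.0, 18.0), 0.50, (1.5, 2.5), (0.08, 0.18), "ellipsoid"),  # silver birch
    4: ((5.0, 12.0), 1.00, (0.0, 0.0), (0.08, 0.20), "none"),       # dead, stem only
}


@dataclass
class SceneConfig:
    n_trees: int = 10
    species_mix: tuple[float, float, float, float] = (0.6, 0.2, 0.2, 0.0)
    area: tuple[float, float, float, float] = (-25.0, 25.0, 15.0, 65.0)  # x0,x1,y0,y1 world
    tree_positions: tuple | None = None   # explicit (x, y) pairs override placement
    tree_overrides: tuple | None = None   # per-tree dicts: species_index,
    #   height_m, crown_radius_m, stem_radius_m (any subset; rest sampled)
    min_spacing: float = 2.0
    terrain: str = "flat"                       # "flat" | "sloped"
    slope: tuple[float, float] = (0.03, 0.01)   # dz/dx, dz/dy when sloped
    range_noise_sigma_m: float = 0.005
    crown_jitter_sigma_m: float = 0.3
    crown_porosity: float = 0.3   # fraction of rays passing through foliage
    outlier_fraction: float = 0.001
    occlusion: bool = True
    dtm_resolution: float = 0.20
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.species_mix) - 1.0) > 1e-9:
            raise ValueError("species_mix proportions must sum to 1")
        if self.min_spacing <= 0 or self.range_noise_sigma_m < 0:
            raise ValueError("scales must be positive")
        if self.terrain not in ("flat", "sloped"):
            raise ValueError("terrain must be flat or sloped")


@dataclass
class TreeTruth:
    tree_id: int
    species_index: int
    stem_xy: tuple[float, float]       # rectified frame
    ground_z: float                    # rectified frame
    height_m: float
    crown_apex: tuple[float, float, float]
    stem_radius_m: float
    crown_radius_m: float


@dataclass
class SceneTruth:
    trees: list[TreeTruth]
    dtm: TerrainModel
    scanner_position: tuple[float, float, float] = (0.0, 0.0, 0.0)  # rectified

    def stem_positions(self) -> np.ndarray:
        if not self.trees:
            return np.empty((0, 3))
        return np.array([[t.stem_xy[0], t.stem_xy[1], t.ground_z] for t in self.trees])


# ---------------------------------------------------------------------------
# analytic primitives (world frame)
# ---------------------------------------------------------------------------

@dataclass
class Plane:
    """Ground plane z = z0 + gx*x + gy*y."""
    z0: float = 0.0
    gx: float = 0.0
    gy: float = 0.0

    def intersect(self, origin, dirs):
        o = origin
        denom = dirs[:, 2] - self.gx * dirs[:, 0] - self.gy * dirs[:, 1]
        num = self.z0 + self.gx * o[0] + self.gy * o[1] - o[2]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = num / denom
        t = np.where((np.abs(denom) > 1e-12) & (t > 0), t, np.inf)
        return t


@dataclass
class VerticalCylinder:
    cx: float
    cy: float
    radius: float
    z0: float
    z1: float

    def intersect(self, origin, dirs):
        o = origin
        fx, fy = o[0] - self.cx, o[1] - self.cy
        a = dirs[:, 0] ** 2 + dirs[:, 1] ** 2
        b = 2 * (fx * dirs[:, 0] + fy * dirs[:, 1])
        c = fx * fx + fy * fy - self.radius ** 2
        return _near_root(a, b, c, o, dirs, self.z0, self.z1)


@dataclass
class VerticalCone:
    """Downward-opening cone: apex at (cx, cy, z_apex), radius growing
    linearly to ``base_radius`` at ``z_base`` (< z_apex)."""
    cx: float
    cy: float
    z_apex: float
    z_base: float
    base_radius: float

    def intersect(self, origin, dirs):
        o = origin
        k = self.base_radius / (self.z_apex - self.z_base)
        fx, fy = o[0] - self.cx, o[1] - self.cy
        w = self.z_apex - o[2]
        a = dirs[:, 0] ** 2 + dirs[:, 1] ** 2 - (k * dirs[:, 2]) ** 2
        b = 2 * (fx * dirs[:, 0] + fy * dirs[:, 1] + k * k * w * dirs[:, 2])
        c = fx * fx + fy * fy - (k * w) ** 2
        return _near_root(a, b, c, o, dirs, self.z_base, self.z_apex)


@dataclass
class Ellipsoid:
    """Axis-aligned spheroid: horizontal semi-axis a, vertical semi-axis b."""
    cx: float
    cy: float
    cz: float
    a: float
    b: float

    def intersect(self, origin, dirs):
        o = origin
        f = np.array([(o[0] - self.cx) / self.a, (o[1] - self.cy) / self.a,
                      (o[2] - self.cz) / self.b])
        d = np.column_stack([dirs[:, 0] / self.a, dirs[:, 1] / self.a,
                             dirs[:, 2] / self.b])
        a = np.sum(d * d, axis=1)
        b = 2 * d @ f
        c = float(f @ f) - 1.0
        return _near_root(a, b, c, o, dirs, -np.inf, np.inf)


def _near_root(a, b, c, origin, dirs, zlo, zhi):
    """Smaller positive quadratic root whose hit height lies in [zlo, zhi]."""
    disc = b * b - 4 * a * c
    ok = (disc >= 0) & (np.abs(a) > 1e-15)
    t = np.full(dirs.shape[0], np.inf)
    if not np.any(ok):
        return t
    sq = np.sqrt(disc[ok])
    a_ok, b_ok = a[ok], b[ok]
    t1 = (-b_ok - sq) / (2 * a_ok)
    t2 = (-b_ok + sq) / (2 * a_ok)
    lo = np.where(t1 > 1e-9, t1, np.where(t2 > 1e-9, t2, np.inf))
    z = origin[2] + lo * dirs[ok, 2]
    lo = np.where((z >= zlo) & (z <= zhi), lo, np.inf)
    # the far root may still be valid when the near one exits the z window
    z2 = origin[2] + t2 * dirs[ok, 2]
    far_ok = (~np.isfinite(lo)) & (t2 > 1e-9) & (z2 >= zlo) & (z2 <= zhi)
    lo = np.where(far_ok, t2, lo)
    t[ok] = lo
    return t


def simulate_scan(surfaces, pose: ScannerPose, rng=None,
                  range_noise_sigma: float = 0.0, occlusion: bool = True):
    """Ray-cast the pose's angular grid against ``surfaces``.

    ``surfaces`` is a list of ``(primitive, label, cls)`` or
    ``(primitive, label, cls, porosity)``; a porous surface lets each ray
    pass straight through with that probability (canopy gap fraction).
    Returns ``(points (n,3) world frame, labels, classes, ray_index)``.
    With occlusion on, only the nearest intersection per grid direction is
    kept.
    """
    rng = rng or np.random.default_rng(0)
    origin = np.asarray(pose.position, dtype=np.float64)
    dirs = pose.grid_directions()
    n = dirs.shape[0]
    surfaces = [(s + (0.0,) if len(s) == 3 else s) for s in surfaces]

    if occlusion:
        t_best = np.full(n, np.inf)
        lab_best = np.zeros(n, dtype=np.int64)
        cls_best = np.zeros(n, dtype=np.int64)
        for prim, lab, cls, porosity in surfaces:
            t = prim.intersect(origin, dirs)
            if porosity > 0:
                t = np.where(rng.random(n) < porosity, np.inf, t)
            win = t < t_best
            t_best[win] = t[win]
            lab_best[win] = lab
            cls_best[win] = cls
        hit = np.isfinite(t_best) & (t_best <= pose.max_range_m)
        t = t_best[hit]
        if range_noise_sigma > 0:
            t = t + rng.normal(0.0, range_noise_sigma, t.size)
        pts = origin + t[:, None] * dirs[hit]
        return pts, lab_best[hit], cls_best[hit], np.flatnonzero(hit)

    pts_all, lab_all, cls_all, ray_all = [], [], [], []
    for prim, lab, cls, porosity in surfaces:
        t = prim.intersect(origin, dirs)
        if porosity > 0:
            t = np.where(rng.random(n) < porosity, np.inf, t)
        hit = np.isfinite(t) & (t <= pose.max_range_m)
        tt = t[hit]
        if range_noise_sigma > 0:
            tt = tt + rng.normal(0.0, range_noise_sigma, tt.size)
        pts_all.append(origin + tt[:, None] * dirs[hit])
        lab_all.append(np.full(tt.size, lab, dtype=np.int64))
        cls_all.append(np.full(tt.size, cls, dtype=np.int64))
        ray_all.append(np.flatnonzero(hit))
    return (np.vstack(pts_all) if pts_all else np.empty((0, 3)),
            np.concatenate(lab_all) if lab_all else np.empty(0, dtype=np.int64),
            np.concatenate(cls_all) if cls_all else np.empty(0, dtype=np.int64),
            np.concatenate(ray_all) if ray_all else np.empty(0, dtype=np.int64))


# ---------------------------------------------------------------------------
# scene assembly
# ---------------------------------------------------------------------------

def _place_trees(cfg: SceneConfig, rng) -> np.ndarray:
    if cfg.tree_positions is not None:
        pos = np.asarray(cfg.tree_positions, dtype=np.float64).reshape(-1, 2)
        if pos.shape[0] != cfg.n_trees:
            raise ValueError("tree_positions length must equal n_trees")
        return pos
    x0, x1, y0, y1 = cfg.area
    placed = np.empty((0, 2))
    tries = 0
    while placed.shape[0] < cfg.n_trees:
        cand = np.array([rng.uniform(x0, x1), rng.uniform(y0, y1)])
        if placed.size == 0 or np.min(np.linalg.norm(placed - cand, axis=1)) >= cfg.min_spacing:
            placed = np.vstack([placed, cand])
        tries += 1
        if tries > 200 * max(cfg.n_trees, 1):
            raise ValueError(
                f"cannot place {cfg.n_trees} trees with {cfg.min_spacing} m spacing "
                f"in area {cfg.area}")
    return placed


_CLS_GROUND, _CLS_STEM, _CLS_FOLIAGE, _CLS_OUTLIER = 0, 1, 2, 3

# per-class synthetic attribute models: (reflectance mean/sd, deviation mean/sd)
_CLASS_ATTRS = {
    _CLS_GROUND: ((-8.0, 1.5), (3.0, 2.0)),
    _CLS_STEM: ((-6.0, 1.5), (2.0, 1.5)),
    _CLS_FOLIAGE: ((-14.0, 2.5), (15.0, 8.0)),
    _CLS_OUTLIER: ((-22.0, 3.0), (60.0, 30.0)),
}


def _ground_fn(cfg: SceneConfig):
    if cfg.terrain == "flat":
        return Plane(0.0, 0.0, 0.0)
    return Plane(0.0, cfg.slope[0], cfg.slope[1])


def generate_scene(cfg: SceneConfig = SceneConfig(),
                   pose: ScannerPose = ScannerPose()):
    """Build a labelled synthetic scene.

    Returns ``(cloud, truth)``: the cloud in the scanner frame with per-point
    label/reflectance/deviation/intensity/return columns, and the truth
    (tree table + DTM + scanner position) in the rectified frame.
    """
    rng = np.random.default_rng(cfg.seed)
    origin = np.asarray(pose.position, dtype=np.float64)
    ground = _ground_fn(cfg)

    species = rng.choice([1, 2, 3, 4], size=cfg.n_trees, p=list(cfg.species_mix))
    xy = _place_trees(cfg, rng) if cfg.n_trees else np.empty((0, 2))

    surfaces: list[tuple[object, int, int]] = [(ground, 0, _CLS_GROUND)]
    trees: list[TreeTruth] = []
    for i in range(cfg.n_trees):
        over = (cfg.tree_overrides[i] if cfg.tree_overrides is not None else {}) or {}
        sp = int(over.get("species_index", species[i]))
        (hlo, hhi), cb_frac, (rclo, rchi), (rslo, rshi), kind = _SPECIES_PARAMS[sp]
        h = float(over.get("height_m", rng.uniform(hlo, hhi)))
        rc = float(over.get("crown_radius_m", rng.uniform(rclo, rchi)))
        rs = float(over.get("stem_radius_m", rng.uniform(rslo, rshi)))
        gz = ground.z0 + ground.gx * xy[i, 0] + ground.gy * xy[i, 1]
        crown_base = gz + cb_frac * h
        top = gz + h
        tid = i + 1
        stem_top = top if kind == "none" else min(crown_base + 1.0, top)
        surfaces.append((VerticalCylinder(xy[i, 0], xy[i, 1], rs, gz, stem_top),
                         tid, _CLS_STEM))
        if kind == "cone":
            surfaces.append((VerticalCone(xy[i, 0], xy[i, 1], top, crown_base, rc),
                             tid, _CLS_FOLIAGE, cfg.crown_porosity))
        elif kind == "ellipsoid":
            cz = (crown_base + top) / 2.0
            surfaces.append((Ellipsoid(xy[i, 0], xy[i, 1], cz, rc, (top - crown_base) / 2.0),
                             tid, _CLS_FOLIAGE, cfg.crown_porosity))
        trees.append(TreeTruth(
            tree_id=tid, species_index=sp,
            stem_xy=(xy[i, 0] - origin[0], xy[i, 1] - origin[1]),
            ground_z=gz - origin[2], height_m=h,
            crown_apex=(xy[i, 0] - origin[0], xy[i, 1] - origin[1], top - origin[2]),
            stem_radius_m=rs, crown_radius_m=rc))

    pts, labels, classes, _ = simulate_scan(surfaces, pose, rng=rng,
                                            range_noise_sigma=0.0,
                                            occlusion=cfg.occlusion)

    # crown penetration jitter: foliage hits slide a little deeper along the ray
    vec = pts - origin
    rng_hit = np.linalg.norm(vec, axis=1)
    unit = vec / np.maximum(rng_hit[:, None], 1e-12)
    fol = classes == _CLS_FOLIAGE
    depth = np.zeros(pts.shape[0])
    depth[fol] = np.abs(rng.normal(0.0, cfg.crown_jitter_sigma_m, int(fol.sum())))
    depth += rng.normal(0.0, cfg.range_noise_sigma_m, pts.shape[0])
    pts = pts + depth[:, None] * unit

    # atmospheric outliers, uniform in the sampled frustum
    n_out = int(round(cfg.outlier_fraction * pts.shape[0]))
    if n_out:
        dirs = pose.grid_directions()
        pick = rng.integers(0, dirs.shape[0], n_out)
        t_out = rng.uniform(2.0, 0.8 * pose.max_range_m, n_out)
        out_pts = origin + t_out[:, None] * dirs[pick]
        pts = np.vstack([pts, out_pts])
        labels = np.concatenate([labels, np.zeros(n_out, dtype=np.int64)])
        classes = np.concatenate([classes, np.full(n_out, _CLS_OUTLIER, dtype=np.int64)])

    n = pts.shape[0]
    refl = np.empty(n)
    dev = np.empty(n)
    for cls, ((rm, rsd), (dm, dsd)) in _CLASS_ATTRS.items():
        m = classes == cls
        k = int(m.sum())
        refl[m] = rng.normal(rm, rsd, k)
        dev[m] = np.abs(rng.normal(dm, dsd, k))
    intensity = np.clip(np.round(1800 + 60 * refl + rng.normal(0, 30, n)), 0, 65535)

    # instrument output: scanner-frame coordinates
    r = rotation_matrix(pose.euler)
    pts_scan = (pts - origin) @ r

    ones = np.ones(n, dtype=np.int64)
    cloud = PointCloud(pts_scan[:, 0], pts_scan[:, 1], pts_scan[:, 2],
                       intensity=intensity, reflectance=refl, deviation=dev,
                       return_number=ones, number_of_returns=ones, label=labels)

    # DTM over the area footprint plus margin, rectified frame
    x0, x1, y0, y1 = cfg.area
    margin = 6.0
    gx = np.arange(x0 - margin, x1 + margin + 1e-9, cfg.dtm_resolution)
    gy = np.arange(y0 - margin, y1 + margin + 1e-9, cfg.dtm_resolution)
    gxx, gyy = np.meshgrid(gx, gy)
    gzz = ground.z0 + ground.gx * gxx + ground.gy * gyy
    support = np.column_stack([
        gxx.ravel() - origin[0], gyy.ravel() - origin[1], gzz.ravel() - origin[2]])
    dtm = TerrainModel(support, resolution=cfg.dtm_resolution)

    truth = SceneTruth(trees=trees, dtm=dtm, scanner_position=(0.0, 0.0, 0.0))
    return cloud, truth


def adjoining_pair_config(seed: int) -> tuple[SceneConfig, ScannerPose]:
    """Preset: two conifers 2.8 m apart whose crowns just touch.

    The crown radii are pinned at 1.4 m each so the canonical
    adjoining-crowns segmentation condition is geometric, not a draw; seed
    only drives sampling noise and attribute synthesis.  The pose restricts
    the scan window to the pair's neighbourhood at the default desk-scale
    angular resolution.
    """
    cfg = SceneConfig(
        n_trees=2, species_mix=(0.7, 0.3, 0.0, 0.0),
        tree_positions=((-1.4, 32.0), (1.4, 32.0)),
        tree_overrides=({"species_index": 1, "height_m": 16.0, "crown_radius_m": 1.4},
                        {"species_index": 2, "height_m": 13.5, "crown_radius_m": 1.4}),
        area=(-4.0, 4.0, 28.0, 36.0), seed=seed)
    pose = ScannerPose(fov_v_deg=60.0, fov_h_deg=30.0, angular_res_deg=0.05)
    return cfg, pose


def truth_to_json(truth: SceneTruth) -> dict:
    """JSON-serializable truth table (per-tree rows + scanner position)."""
    return {
        "scanner_position": list(truth.scanner_position),
        "trees": [{
            "tree_id": t.tree_id,
            "species_index": t.species_index,
            "stem_xy": [t.stem_xy[0], t.stem_xy[1]],
            "ground_z": t.ground_z,
            "height_m": t.height_m,
            "crown_apex": list(t.crown_apex),
            "stem_radius_m": t.stem_radius_m,
            "crown_radius_m": t.crown_radius_m,
        } for t in truth.trees],
    }
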