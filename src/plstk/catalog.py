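"""Per-tree attributes, quality flags, scan selection, filenames, catalogue.

Quality levels follow the completeness convention: level 4 = no commission
and no omission; 3 = commission only; 2 = omission only; 1 = both; 0 = the
fine segmentation failed outright.  Species indices: 1 Scots pine, 2 Norway
spruce, 3 silver birch, 4 unidentified.  Tree height is the 99.95th
percentile of the heights (linear interpolation between order statistics)
minus the ground elevation of the nearest DTM support at the tree location.
Scans are usable when the weather record shows wind < 3 m/s (strict), no
precipitation, no snow, and relative humidity < 90 % (strict).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
import json
import re

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .cloud import PointCloud, TerrainModel

__all__ = [
    "SPECIES_NAMES",
    "QualityLevel",
    "TreeRecord",
    "ScanSelectionCriteria",
    "assign_quality",
    "estimate_tree_height",
    "scanner_distances",
    "point_density",
    "select_scans",
    "make_filename",
    "parse_filename",
    "build_catalog",
    "validate_catalog",
]

SPECIES_NAMES = {1: "Scots pine", 2: "Norway spruce", 3: "silver birch", 4: "unidentified"}

HEIGHT_PERCENTILE = 99.95


@dataclass(frozen=True)
class QualityLevel:
    level: int
    commission: bool
    omission: bool
    seg_failed: bool


def assign_quality(commission: bool, omission: bool, seg_failed: bool) -> QualityLevel:
    """Map completeness findings to the 0–4 quality scale (total, exact)."""
    if seg_failed:
        level = 0
    elif commission and omission:
        level = 1
    elif omission:
        level = 2
    elif commission:
        level = 3
    else:
        level = 4
    return QualityLevel(level, bool(commission), bool(omission), bool(seg_failed))


@dataclass
class TreeRecord:
    tree_id: int
    species_index: int
    location: tuple[float, float, float]      # E, N, h (m)
    height_m: float
    quality: int
    dist_crown_top_m: float | None = None
    dist_stem_base_m: float | None = None
    point_density_per_m2: float | None = None
    timestamp: datetime | None = None
    files: tuple[str, ...] = ()

    def __post_init__(self):
        if self.species_index not in SPECIES_NAMES:
            raise ValueError(f"species_index must be 1..4, got {self.species_index}")
        if not 0 <= self.quality <= 4:
            raise ValueError(f"quality must be 0..4, got {self.quality}")
        if self.height_m < 0:
            raise ValueError("height_m must be >= 0")


@dataclass(frozen=True)
class ScanSelectionCriteria:
    wind_max: float = 3.0          # m/s, exclusive
    rh_max: float = 90.0           # %, exclusive
    precipitation_allowed: bool = False
    snow_allowed: bool = False


def estimate_tree_height(tree_cloud: PointCloud, dtm: TerrainModel,
                         location) -> float:
    """Crown-top height above ground at the tree location.

    Top = 99.95th percentile of z (linear interpolation); ground = nearest
    DTM support to ``location``.  Clamped at 0 (a warning-worthy geometry).
    """
    if len(tree_cloud) == 0:
        raise ValueError("empty tree cloud")
    top = float(np.percentile(tree_cloud.z, HEIGHT_PERCENTILE, method="linear"))
    gz, _ = dtm.ground_at(np.asarray(location, float)[:2])
    h = top - float(gz[0])
    return max(h, 0.0)


def scanner_distances(tree_cloud: PointCloud, scanner_position, location,
                      dtm: TerrainModel) -> tuple[float, float]:
    """(crown-top, stem-base) 3-D distances from the scanner position."""
    if len(tree_cloud) == 0:
        raise ValueError("empty tree cloud")
    scanner = np.asarray(scanner_position, dtype=np.float64)
    zcut = np.percentile(tree_cloud.z, HEIGHT_PERCENTILE, method="linear")
    retained = tree_cloud.z <= zcut
    idx = int(np.argmax(np.where(retained, tree_cloud.z, -np.inf))) if retained.any() \
        else int(np.argmax(tree_cloud.z))
    crown = tree_cloud.xyz[idx]
    gz, _ = dtm.ground_at(np.asarray(location, float)[:2])
    base = np.array([location[0], location[1], float(gz[0])])
    return (float(np.linalg.norm(crown - scanner)),
            float(np.linalg.norm(base - scanner)))


def point_density(tree_cloud: PointCloud) -> float | None:
    """Points per square metre of the planimetric convex-hull footprint.

    ``None`` (missing) when the footprint is degenerate (< 3 points or
    collinear).
    """
    if len(tree_cloud) < 3:
        return None
    xy = tree_cloud.xyz[:, :2]
    try:
        hull = ConvexHull(xy)
    except QhullError:
        return None
    if hull.volume <= 0:   # 2-D "volume" is the area
        return None
    return len(tree_cloud) / hull.volume


def select_scans(weather: pd.DataFrame,
                 criteria: ScanSelectionCriteria = ScanSelectionCriteria()) -> list:
    """Timestamps of weather rows meeting the scan-selection criteria.

    Expects columns (case-insensitive): timestamp, wind (m/s), precipitation
    (amount or flag), snow (flag), rh (%).
    """
    cols = {c.lower().strip(): c for c in weather.columns}
    for need in ("timestamp", "wind", "precipitation", "snow", "rh"):
        if need not in cols:
            raise ValueError(f"weather table lacks column {need!r}")
    ok = weather[cols["wind"]].astype(float) < criteria.wind_max
    ok &= weather[cols["rh"]].astype(float) < criteria.rh_max
    if not criteria.precipitation_allowed:
        ok &= ~(weather[cols["precipitation"]].astype(float) > 0)
    if not criteria.snow_allowed:
        snow = weather[cols["snow"]]
        if snow.dtype == bool:
            ok &= ~snow
        else:
            ok &= ~snow.astype(str).str.strip().str.lower().isin(
                ("1", "true", "yes", "y", "snow")) & ~(
                pd.to_numeric(snow, errors="coerce").fillna(0) > 0)
    return weather.loc[ok, cols["timestamp"]].tolist()


_FILENAME_RE = re.compile(
    r"^(\d{6})_(\d{6})_(\d+)_(\d)\.(las|laz)$")


def make_filename(timestamp: datetime, tree_id: int, quality: int,
                  ext: str = ".laz") -> str:
    """``YYMMDD_HHMMSS_treeID_Quality`` + extension."""
    if not 0 <= quality <= 4:
        raise ValueError("quality must be 0..4")
    return f"{timestamp:%y%m%d_%H%M%S}_{int(tree_id)}_{int(quality)}{ext}"


def parse_filename(name: str) -> tuple[datetime, int, int]:
    """Inverse of :func:`make_filename`: (timestamp, tree_id, quality)."""
    m = _FILENAME_RE.match(name)
    if not m:
        raise ValueError(f"filename {name!r} does not match YYMMDD_HHMMSS_id_q pattern")
    ts = datetime.strptime(m.group(1) + m.group(2), "%y%m%d%H%M%S")
    return ts, int(m.group(3)), int(m.group(4))


def build_catalog(records: list[TreeRecord]) -> dict:
    """GeoJSON-style catalogue, one point feature per tree (stable key order)."""
    ids = [r.tree_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate tree_ids in catalogue records")
    feats = []
    for r in sorted(records, key=lambda r: r.tree_id):
        props = {
            "id": int(r.tree_id),
            "species_index": int(r.species_index),
            "species_name": SPECIES_NAMES[r.species_index],
            "height_m": round(float(r.height_m), 3),
            "quality": int(r.quality),
            "dist_crown_top_m": None if r.dist_crown_top_m is None
            else round(float(r.dist_crown_top_m), 3),
            "dist_stem_base_m": None if r.dist_stem_base_m is None
            else round(float(r.dist_stem_base_m), 3),
            "point_density_per_m2": None if r.point_density_per_m2 is None
            else round(float(r.point_density_per_m2), 2),
            "timestamp": None if r.timestamp is None
            else r.timestamp.strftime("%Y-%m-%dT%H:%M:%S"),
            "files": list(r.files),
            "crs": "EPSG:3067",
        }
        feats.append({
            "type": "Feature",
            "geometry": {"type": "Point",
                         "coordinates": [round(float(v), 4) for v in r.location]},
            "properties": props,
        })
    return {"type": "FeatureCollection", "features": feats}


def validate_catalog(catalog: dict) -> None:
    """Structural check of the catalogue (point features with required props)."""
    if catalog.get("type") != "FeatureCollection":
        raise ValueError("catalogue must be a FeatureCollection")
    if not isinstance(catalog.get("features"), list):
        raise ValueError("catalogue lacks a features list")
    seen = set()
    for f in catalog["features"]:
        if f.get("type") != "Feature":
            raise ValueError("catalogue entry is not a Feature")
        geom = f.get("geometry", {})
        if geom.get("type") != "Point" or len(geom.get("coordinates", [])) != 3:
            raise ValueError("catalogue feature needs a 3-D Point geometry")
        props = f.get("properties", {})
        for key in ("id", "species_index", "species_name", "height_m", "quality"):
            if key not in props:
                raise ValueError(f"catalogue feature lacks property {key!r}")
        if props["id"] in seen:
            raise ValueError(f"duplicate catalogue id {props['id']}")
        seen.add(props["id"])


def dump_catalog(catalog: dict) -> str:
    """Deterministic serialization (sorted keys, fixed separators)."""
    return json.dumps(catalog, sort_keys=True, separators=(",", ":"),
                      ensure_ascii=True)
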