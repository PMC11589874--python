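"""Core in-memory containers for the processing chain.

A :class:`PointCloud` is a column store: three mandatory coordinate columns in
metres plus any subset of the per-point attributes a permanent laser scanner
produces (amplitude/intensity, calibrated reflectance in dB, pulse-shape
deviation, return counters, scan angles, range, and an integer tree label).
Absent columns stay absent — they are never silently zero-filled, so every
downstream stage can tell "not measured" from "measured zero".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["PointCloud", "TerrainModel", "ControlPointPair", "stack_pairs"]

#: optional per-point attribute columns and their storage dtype
OPTIONAL_ATTRS = {
    "intensity": np.float64,
    "reflectance": np.float64,
    "deviation": np.float64,
    "return_number": np.int64,
    "number_of_returns": np.int64,
    "theta": np.float64,
    "phi_az": np.float64,
    "range": np.float64,
    "label": np.int64,
}


class PointCloud:
    """Columnar point cloud with validated per-point attributes.

    Parameters
    ----------
    x, y, z
        Coordinates in metres. Must be finite and of equal length.
    **attrs
        Optional columns from :data:`OPTIONAL_ATTRS`, each of the same
        length as the coordinates.
    """

    def __init__(self, x, y, z, **attrs):
        self.x = np.asarray(x, dtype=np.float64).ravel()
        self.y = np.asarray(y, dtype=np.float64).ravel()
        self.z = np.asarray(z, dtype=np.float64).ravel()
        self._attrs: dict[str, np.ndarray] = {}
        for name, values in attrs.items():
            if values is None:
                continue
            if name not in OPTIONAL_ATTRS:
                raise ValueError(f"unknown point attribute {name!r}")
            self._attrs[name] = np.asarray(values, dtype=OPTIONAL_ATTRS[name]).ravel()
        self.validate()

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return self.x.size

    def __repr__(self) -> str:
        cols = ",".join(self._attrs)
        return f"PointCloud(n={len(self)}, attrs=[{cols}])"

    def has(self, name: str) -> bool:
        return name in self._attrs

    @property
    def attributes(self) -> Mapping[str, np.ndarray]:
        return dict(self._attrs)

    def __getitem__(self, name: str) -> np.ndarray:
        if name in ("x", "y", "z"):
            return getattr(self, name)
        try:
            return self._attrs[name]
        except KeyError:
            raise KeyError(f"point cloud has no attribute column {name!r}") from None

    @property
    def xyz(self) -> np.ndarray:
        """(n, 3) coordinate array (a copy)."""
        return np.column_stack([self.x, self.y, self.z])

    # -- validation ----------------------------------------------------------
    def validate(self) -> None:
        n = self.x.size
        if self.y.size != n or self.z.size != n:
            raise ValueError("coordinate columns differ in length")
        for c in (self.x, self.y, self.z):
            if not np.all(np.isfinite(c)):
                raise ValueError("non-finite coordinates")
        for name, col in self._attrs.items():
            if col.size != n:
                raise ValueError(
                    f"attribute {name!r} has length {col.size}, expected {n}"
                )
        if "range" in self._attrs and n and self._attrs["range"].min() < 0:
            raise ValueError("negative range values")
        if "return_number" in self._attrs and "number_of_returns" in self._attrs and n:
            rn = self._attrs["return_number"]
            nr = self._attrs["number_of_returns"]
            ok = (1 <= rn) & (rn <= nr) & (nr <= 15)
            if not np.all(ok):
                bad = int(np.sum(~ok))
                raise ValueError(
                    f"{bad} points violate 1 <= return_number <= number_of_returns <= 15"
                )

    # -- functional updates --------------------------------------------------
    def copy(self) -> "PointCloud":
        return PointCloud(
            self.x.copy(), self.y.copy(), self.z.copy(),
            **{k: v.copy() for k, v in self._attrs.items()},
        )

    def with_coords(self, xyz: np.ndarray) -> "PointCloud":
        """Same attributes, new coordinates (isometries, normalization...)."""
        xyz = np.asarray(xyz, dtype=np.float64)
        return PointCloud(xyz[:, 0], xyz[:, 1], xyz[:, 2], **self._attrs)

    def with_columns(self, **attrs) -> "PointCloud":
        merged = dict(self._attrs)
        merged.update({k: v for k, v in attrs.items() if v is not None})
        return PointCloud(self.x, self.y, self.z, **merged)

    def select(self, index) -> "PointCloud":
        """Subset by boolean mask or integer index array (order-preserving)."""
        return PointCloud(
            self.x[index], self.y[index], self.z[index],
            **{k: v[index] for k, v in self._attrs.items()},
        )

    @staticmethod
    def empty(attrs: Iterable[str] = ()) -> "PointCloud":
        z = np.empty(0)
        return PointCloud(z, z, z, **{a: np.empty(0) for a in attrs})


@dataclass
class TerrainModel:
    """Digital terrain model as scattered/gridded ground support points.

    ``support`` is an (n, 3) array of (x, y, ground elevation) in metres;
    ``resolution`` is the nominal planimetric support spacing (0.20 m for
    a 20 cm DTM).
    """

    support: np.ndarray
    resolution: float = 0.20
    _tree: cKDTree | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.support = np.asarray(self.support, dtype=np.float64)
        if self.support.ndim != 2 or self.support.shape[1] != 3:
            raise ValueError("DTM support must be an (n, 3) array")
        if self.support.shape[0] == 0:
            raise ValueError("empty DTM")
        if not np.all(np.isfinite(self.support)):
            raise ValueError("non-finite DTM support")
        if self.resolution <= 0:
            raise ValueError("DTM resolution must be positive")

    @property
    def kdtree(self) -> cKDTree:
        if self._tree is None:
            self._tree = cKDTree(self.support[:, :2])
        return self._tree

    def ground_at(self, xy: np.ndarray, max_dist: float | None = None):
        """Ground elevation at planimetric locations by nearest support point.

        Returns ``(ground_z, dist)``; if ``max_dist`` is given, locations whose
        nearest support is farther raise with the offending count.
        """
        xy = np.atleast_2d(np.asarray(xy, dtype=np.float64))
        dist, idx = self.kdtree.query(xy, k=1)
        if max_dist is not None:
            n_far = int(np.sum(dist > max_dist))
            if n_far:
                raise ValueError(
                    f"{n_far} locations farther than {max_dist:.3f} m from any DTM support"
                )
        return self.support[idx, 2], dist

    def normal_at(self, xy, radius: float = 1.0) -> np.ndarray:
        """Local terrain unit normal from a plane fit to support within ``radius``."""
        xy = np.asarray(xy, dtype=np.float64).ravel()
        idx = self.kdtree.query_ball_point(xy, radius)
        pts = self.support[idx]
        if len(pts) < 3:
            return np.array([0.0, 0.0, 1.0])
        c = pts.mean(axis=0)
        d = pts - c
        # smallest right-singular vector of the centred support = plane normal
        _, _, vt = np.linalg.svd(d, full_matrices=False)
        n = vt[-1]
        if np.allclose(n[:2], 0.0, atol=1e-12) or abs(n[2]) < 1e-9:
            # degenerate (collinear support): fall back to vertical
            if abs(n[2]) < 1e-9:
                return np.array([0.0, 0.0, 1.0])
        return n if n[2] > 0 else -n


@dataclass(frozen=True)
class ControlPointPair:
    """One ground-control correspondence: local frame -> reference frame."""

    source: np.ndarray
    target: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "source", np.asarray(self.source, dtype=np.float64).ravel())
        object.__setattr__(self, "target", np.asarray(self.target, dtype=np.float64).ravel())
        for v in (self.source, self.target):
            if v.shape != (3,) or not np.all(np.isfinite(v)):
                raise ValueError("control point triplets must be finite 3-vectors")


def stack_pairs(pairs: Iterable[ControlPointPair]):
    """Split a pair list into (n,3) source and target arrays."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no control point pairs")
    src = np.vstack([p.source for p in pairs])
    tgt = np.vstack([p.target for p in pairs])
    return src, tgt
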