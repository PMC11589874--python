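"""Rectification, scan-attribute derivation and Helmert georeferencing.

The scanner hangs 30 m above ground on a mast, tilted 60° down, so raw scans
arrive in a tilted instrument frame.  :func:`rectify` applies a passive 3-D
rotation ``R = Rz(kappa) @ Ry(phi) @ Rx(omega)`` (right-handed axis rotations,
angles in degrees; default pose omega=0, phi=60, kappa=90) that turns the
scene into a local right-handed frame with the origin still at the scanner
and +Z up — the ground then sits near z = -(mast height).

:class:`HelmertTransform` is the 7-parameter similarity transform
``p' = t + mu * R @ p`` (3 translations, 3 rotations, 1 scale) fitted to
ground-control pairs by the closed-form least-squares solution
(centroid alignment + orthogonal Procrustes + ratio scale), which attains the
global optimum of the squared-residual loss without initialization.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .cloud import ControlPointPair, PointCloud, stack_pairs

__all__ = [
    "EulerAngles",
    "rotation_matrix",
    "rectify",
    "compute_scan_attributes",
    "HelmertTransform",
    "fit_helmert",
    "apply_helmert",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EulerAngles:
    """Rectification Euler angles in degrees (default: the mast pose)."""

    omega: float = 0.0
    phi: float = 60.0
    kappa: float = 90.0

    def __post_init__(self):
        if not all(np.isfinite([self.omega, self.phi, self.kappa])):
            raise ValueError("Euler angles must be finite")


def _rx(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _ry(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rz(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def rotation_matrix(angles: EulerAngles) -> np.ndarray:
    """Composition ``Rz(kappa) @ Ry(phi) @ Rx(omega)`` (angles in degrees)."""
    o, p, k = np.deg2rad([angles.omega, angles.phi, angles.kappa])
    return _rz(k) @ _ry(p) @ _rx(o)


def euler_from_matrix(r: np.ndarray) -> EulerAngles:
    """Invert :func:`rotation_matrix`; at gimbal lock (|phi| = 90°) kappa := 0."""
    phi = np.arcsin(np.clip(-r[2, 0], -1.0, 1.0))
    if abs(abs(r[2, 0]) - 1.0) < 1e-12:
        kappa = 0.0
        # at |phi| = 90 only (kappa -+ omega) is determined; with kappa := 0
        # the sign of the recoverable angle flips with the sign of phi
        omega = np.arctan2(r[0, 1], r[1, 1]) if r[2, 0] < 0 \
            else np.arctan2(-r[0, 1], r[1, 1])
    else:
        omega = np.arctan2(r[2, 1], r[2, 2])
        kappa = np.arctan2(r[1, 0], r[0, 0])
    return EulerAngles(*np.rad2deg([omega, phi, kappa]))


def rectify(cloud: PointCloud, angles: EulerAngles = EulerAngles()) -> PointCloud:
    """Rotate a scanner-frame cloud into the ground-normalized local frame.

    The origin (the scanner) is unchanged and all attributes ride along.
    """
    r = rotation_matrix(angles)
    return cloud.with_coords(cloud.xyz @ r.T)


def compute_scan_attributes(cloud: PointCloud) -> PointCloud:
    """Add range/theta/phi_az columns derived from scanner-frame coordinates.

    range = sqrt(x^2+y^2+z^2) [m]; theta = polar angle from +Z in [0, 180]°;
    phi_az = azimuth from +X toward +Y in [0, 360)°.  A point at the exact
    origin gets (0, 0, 0) and is flagged in the log.
    """
    xyz = cloud.xyz
    rng = np.linalg.norm(xyz, axis=1)
    at_origin = rng == 0.0
    if np.any(at_origin):
        log.warning("%d points at the scanner origin: angles set to 0", at_origin.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.degrees(np.arccos(np.clip(np.divide(xyz[:, 2], rng,
                                                       out=np.zeros_like(rng),
                                                       where=~at_origin), -1, 1)))
        phi = np.degrees(np.arctan2(xyz[:, 1], xyz[:, 0])) % 360.0
    theta[at_origin] = 0.0
    phi[at_origin] = 0.0
    return cloud.with_columns(range=rng, theta=theta, phi_az=phi)


class HelmertTransform(BaseEstimator, TransformerMixin):
    """7-parameter 3-D similarity transform ``p' = t + mu * R @ p``.

    Follows the scikit-learn estimator protocol: :meth:`fit` takes matched
    (n, 3) source and target coordinate arrays and solves the least-squares
    problem in closed form; :meth:`transform` / :meth:`inverse_transform`
    apply the fitted mapping.

    Attributes (after fit)
    ----------------------
    translation_ : (3,) metres
    rotation_matrix_ : (3, 3) orthonormal, det +1
    scale_ : float, > 0
    angles_deg_ : :class:`EulerAngles` pitch/roll/yaw equivalent of the matrix
    rmse_ : float, overall fit RMSE in metres
    per_axis_rmse_ : (3,) per-axis RMSE in metres
    """

    def __init__(self):
        pass

    def fit(self, X, y):
        src = np.asarray(X, dtype=np.float64)
        tgt = np.asarray(y, dtype=np.float64)
        if src.ndim != 2 or src.shape[1] != 3 or src.shape != tgt.shape:
            raise ValueError("expected matched (n, 3) source and target arrays")
        n = src.shape[0]
        if n < 3:
            raise ValueError(f"need >= 3 control point pairs, got {n}")
        sc, tc = src.mean(axis=0), tgt.mean(axis=0)
        ds, dt = src - sc, tgt - tc
        denom = np.sum(ds * ds)
        if denom == 0:
            raise ValueError("degenerate control points: zero source spread")
        h = ds.T @ dt
        u, s, vt = np.linalg.svd(h)
        if s[1] < 1e-12 * max(s[0], 1.0):
            raise ValueError("degenerate (collinear) control point configuration")
        d = np.sign(np.linalg.det(vt.T @ u.T))
        rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
        mu = float(np.trace(np.diag(s) @ np.diag([1.0, 1.0, d])) / denom)
        if mu <= 0:
            raise ValueError("non-positive fitted scale")
        t = tc - mu * rot @ sc
        self.rotation_matrix_ = rot
        self.scale_ = mu
        self.translation_ = t
        self.angles_deg_ = euler_from_matrix(rot)
        res = tgt - self.transform(src)
        self.per_axis_rmse_ = np.sqrt(np.mean(res ** 2, axis=0))
        self.rmse_ = float(np.sqrt(np.mean(np.sum(res ** 2, axis=1))))
        return self

    def _check_fitted(self):
        if not hasattr(self, "rotation_matrix_"):
            raise ValueError("HelmertTransform is not fitted")

    def transform(self, X):
        self._check_fitted()
        X = np.asarray(X, dtype=np.float64)
        return self.translation_ + self.scale_ * X @ self.rotation_matrix_.T

    def inverse_transform(self, X):
        self._check_fitted()
        X = np.asarray(X, dtype=np.float64)
        return (X - self.translation_) @ self.rotation_matrix_ / self.scale_

    def to_dict(self) -> dict:
        self._check_fitted()
        a = self.angles_deg_
        return {
            "translation_m": self.translation_.tolist(),
            "rotation_deg": {"omega": a.omega, "phi": a.phi, "kappa": a.kappa},
            "scale": self.scale_,
            "fit_rmse_m": self.rmse_,
            "per_axis_rmse_m": self.per_axis_rmse_.tolist(),
        }


def fit_helmert(pairs: list[ControlPointPair]) -> HelmertTransform:
    """Fit the similarity transform to ground-control pairs."""
    src, tgt = stack_pairs(pairs)
    return HelmertTransform().fit(src, tgt)


def apply_helmert(cloud: PointCloud, transform: HelmertTransform) -> PointCloud:
    """Georeference a cloud; per-point attributes are untouched."""
    return cloud.with_coords(transform.transform(cloud.xyz))
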