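"""Quality metrics: stem positional accuracy, cloud-to-cloud consistency,
and automatic completeness scoring against ground truth.

These reimplement the standard geographic data-quality checks (ISO 19157
language: positional accuracy, completeness) as reusable operations so a
processing run can be scored against a reference stem map or a labelled
synthetic scene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .catalog import QualityLevel, assign_quality
from .cloud import PointCloud
from .stems import StemMap

__all__ = [
    "AccuracyReport",
    "C2CReport",
    "match_stems",
    "planimetric_accuracy",
    "cloud_to_cloud",
    "score_completeness",
]


@dataclass
class AccuracyReport:
    n_matched: int
    mean_planimetric_m: float
    rmse_e_m: float
    rmse_n_m: float
    unmatched_detected: int
    unmatched_reference: int

    def to_dict(self) -> dict:
        return {
            "n_matched": self.n_matched,
            "mean_planimetric_m": self.mean_planimetric_m,
            "rmse_e_m": self.rmse_e_m,
            "rmse_n_m": self.rmse_n_m,
            "unmatched_detected": self.unmatched_detected,
            "unmatched_reference": self.unmatched_reference,
        }


@dataclass
class C2CReport:
    mean_distance_m: float
    fraction_within_threshold: float
    threshold_m: float = 0.15

    def to_dict(self) -> dict:
        return {
            "mean_distance_m": self.mean_distance_m,
            "fraction_within_threshold": self.fraction_within_threshold,
            "threshold_m": self.threshold_m,
        }


def _positions(stem_map) -> np.ndarray:
    if isinstance(stem_map, StemMap):
        return stem_map.positions()[:, :2]
    arr = np.asarray(stem_map, dtype=np.float64)
    return arr[:, :2]


def match_stems(detected, reference, gate_m: float = 2.0):
    """Greedy mutually-nearest planimetric pairing within a gate.

    Candidate pairs are taken in ascending distance; each stem is matched at
    most once, so every accepted pair is mutually nearest among the stems
    still unmatched.  Returns a list of ``(detected_idx, reference_idx,
    de, dn, distance)`` tuples with signed disparities detected - reference.
    """
    det = _positions(detected)
    ref = _positions(reference)
    if det.shape[0] == 0 or ref.shape[0] == 0:
        return []
    diff = det[:, None, :] - ref[None, :, :]
    dist = np.linalg.norm(diff, axis=2)
    order = np.argsort(dist, axis=None, kind="stable")
    used_d, used_r, pairs = set(), set(), []
    for flat in order:
        i, j = np.unravel_index(flat, dist.shape)
        if dist[i, j] > gate_m:
            break
        if i in used_d or j in used_r:
            continue
        used_d.add(int(i))
        used_r.add(int(j))
        pairs.append((int(i), int(j), float(diff[i, j, 0]), float(diff[i, j, 1]),
                      float(dist[i, j])))
    return pairs


def planimetric_accuracy(pairs, n_detected: int | None = None,
                         n_reference: int | None = None) -> AccuracyReport:
    """Mean planimetric distance and per-axis RMSE of matched stem pairs."""
    if not pairs:
        raise ValueError("no matched pairs")
    de = np.array([p[2] for p in pairs])
    dn = np.array([p[3] for p in pairs])
    d = np.array([p[4] for p in pairs])
    n = len(pairs)
    return AccuracyReport(
        n_matched=n,
        mean_planimetric_m=float(d.mean()),
        rmse_e_m=float(np.sqrt(np.mean(de ** 2))),
        rmse_n_m=float(np.sqrt(np.mean(dn ** 2))),
        unmatched_detected=(0 if n_detected is None else n_detected - n),
        unmatched_reference=(0 if n_reference is None else n_reference - n),
    )


def cloud_to_cloud(a: PointCloud, b: PointCloud, threshold_m: float = 0.15,
                   symmetric: bool = False) -> C2CReport:
    """Nearest-neighbour point-to-point distances from ``a`` to ``b``.

    Asymmetric by design (direction a -> b); with ``symmetric=True`` the
    report takes the worse (max) of both directions for each summary.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("cloud_to_cloud requires two non-empty clouds")
    d_ab, _ = cKDTree(b.xyz).query(a.xyz, k=1)
    mean = float(np.mean(d_ab))
    frac = float(np.mean(d_ab <= threshold_m))
    if symmetric:
        d_ba, _ = cKDTree(a.xyz).query(b.xyz, k=1)
        mean = max(mean, float(np.mean(d_ba)))
        frac = min(frac, float(np.mean(d_ba <= threshold_m)))
    return C2CReport(mean, frac, threshold_m)


def score_completeness(assigned_labels, truth_labels, tree_id: int,
                       commission_tol: float = 0.05,
                       omission_tol: float = 0.10) -> QualityLevel:
    """Automatic commission/omission scoring of one segmented tree.

    commission: fraction of points assigned to ``tree_id`` whose true label
    differs, above ``commission_tol``; omission: fraction of true tree
    points not assigned to it, above ``omission_tol``.  No assigned points
    at all means the segmentation failed (level 0).  With both tolerances at
    0 this reduces to strict set equality.
    """
    assigned = np.asarray(assigned_labels)
    truth = np.asarray(truth_labels)
    if assigned.shape != truth.shape:
        raise ValueError("label arrays differ in length")
    if not np.any(truth == tree_id):
        raise ValueError(f"tree_id {tree_id} absent from truth labels")
    got = assigned == tree_id
    if not got.any():
        return assign_quality(False, False, seg_failed=True)
    foreign = float(np.sum(got & (truth != tree_id))) / float(np.sum(got))
    missing = float(np.sum((truth == tree_id) & ~got)) / float(np.sum(truth == tree_id))
    return assign_quality(foreign > commission_tol, missing > omission_tol,
                          seg_failed=False)
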