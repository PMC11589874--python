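"""Fine segmentation of a coarse buffer: layers, DBSCAN, seeds, fuzzy k-NN.

The height-normalized buffer is sliced into horizontal layers of fixed
thickness; DBSCAN clusters each layer on the planimetric (x, y) projection.
Cluster centroids stacked across layers are grouped by planimetric
proximity; a group supported by enough layers, whose least-squares 3-D line
is near-vertical, becomes a tree seed (the local z-maximum of the stack is
its apex).  Seed points initialize an iterative sweep that classifies every
remaining point with a fuzzy k-nearest-neighbour rule, layer by layer, using
all points labelled so far as evidence; points farther than a cut-off from
any labelled point stay unassigned (label 0).

:class:`FuzzyKNN` is a scikit-learn compatible classifier: membership of a
query in class c is ``u_c = sum_{j: y_j=c} w_j / sum_j w_j`` over the k
nearest training points with weights ``w_j = d_j^(-2/(m-1))``; the
fuzzifier m > 1 controls how fast influence decays (m = 2: inverse-square
weighting).  A query coinciding with a training point takes that point's
label with membership 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.cluster import DBSCAN

from .cloud import PointCloud

__all__ = [
    "LayerSegConfig",
    "TreeSeed",
    "slice_layers",
    "cluster_layer",
    "detect_trees",
    "FuzzyKNN",
    "fknn_membership",
    "segment_layers",
]


@dataclass
class LayerSegConfig:
    layer_thickness: float = 0.5
    dbscan_eps: float = 0.4
    dbscan_min_samples: int = 5
    line_xy_tolerance: float = 0.5
    min_layers_per_tree: int = 4
    fknn_k: int = 10
    fuzzifier_m: float = 2.0
    max_assign_dist: float = 1.5
    sweep_direction: str = "bottom_up"     # or "top_down"
    fknn_2d: bool = False                  # classify on (x, y) only
    max_line_angle: float = 15.0           # deg off vertical for seed lines
    apex_localmax_radius: float = 1.0      # m, canopy local-maximum check
    apex_localmax_margin: float = 0.5      # m, height slack for that check

    def __post_init__(self):
        for name in ("layer_thickness", "dbscan_eps", "dbscan_min_samples",
                     "line_xy_tolerance", "min_layers_per_tree", "fknn_k",
                     "max_assign_dist"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.fuzzifier_m <= 1:
            raise ValueError("fuzzifier_m must be > 1")
        if self.sweep_direction not in ("bottom_up", "top_down"):
            raise ValueError("sweep_direction must be bottom_up or top_down")


@dataclass
class TreeSeed:
    tree_id: int
    apex_xy: np.ndarray
    line_point: np.ndarray
    line_direction: np.ndarray
    seed_point_indices: np.ndarray


def slice_layers(cloud: PointCloud, thickness: float) -> list[tuple[int, np.ndarray]]:
    """Half-open horizontal slabs ``[j*t, (j+1)*t)``, ordered by j ascending."""
    if thickness <= 0:
        raise ValueError("layer thickness must be positive")
    j = np.floor(cloud.z / thickness).astype(np.int64)
    order = np.argsort(j, kind="stable")
    js, starts = np.unique(j[order], return_index=True)
    return [(int(jj), np.sort(order[s:e]))
            for jj, s, e in zip(js, starts, list(starts[1:]) + [len(j)])]


def cluster_layer(xy: np.ndarray, eps: float, min_samples: int) -> np.ndarray:
    """DBSCAN on the planimetric projection; -1 marks noise."""
    xy = np.asarray(xy, dtype=np.float64)[:, :2]
    if xy.shape[0] == 0:
        return np.empty(0, dtype=np.int64)
    return DBSCAN(eps=eps, min_samples=min_samples).fit_predict(xy)


def detect_trees(cloud: PointCloud,
                 config: LayerSegConfig = LayerSegConfig()) -> list[TreeSeed]:
    """Find tree seeds by stacking per-layer DBSCAN centroids into vertical lines.

    A candidate stack only becomes a tree when its apex is a local maximum of
    the canopy height: no buffer point within ``apex_localmax_radius``
    (planimetric) may rise more than ``apex_localmax_margin`` above the
    stack's topmost centroid.  Where two adjoining crowns merge into a single
    mid-air cluster, the resulting stack has canopy above it and is rejected;
    its points are later distributed by the fuzzy classifier.

    Tree ids are assigned in decreasing apex-height order, starting at 1.
    """
    layers = slice_layers(cloud, config.layer_thickness)
    cents, cent_members = [], []
    for _, idx in layers:
        labels = cluster_layer(cloud.xyz[idx], config.dbscan_eps,
                               config.dbscan_min_samples)
        for lab in np.unique(labels):
            if lab < 0:
                continue
            members = idx[labels == lab]
            cents.append(cloud.xyz[members].mean(axis=0))
            cent_members.append(members)
    if not cents:
        return []
    cents = np.vstack(cents)

    groups = DBSCAN(eps=config.line_xy_tolerance, min_samples=1).fit_predict(cents[:, :2])
    xy_tree = cKDTree(cloud.xyz[:, :2])
    seeds = []
    for g in np.unique(groups):
        rows = np.flatnonzero(groups == g)
        layer_ids = np.unique(np.floor(cents[rows, 2] / config.layer_thickness))
        if layer_ids.size < config.min_layers_per_tree:
            continue
        pts = cents[rows]
        c = pts.mean(axis=0)
        if rows.size >= 2:
            _, _, vt = np.linalg.svd(pts - c, full_matrices=False)
            d = vt[0]
            d = d if d[2] >= 0 else -d
        else:
            d = np.array([0.0, 0.0, 1.0])
        angle = np.degrees(np.arccos(np.clip(d[2], -1.0, 1.0)))
        if angle > config.max_line_angle:
            continue
        top = rows[np.argmax(cents[rows, 2])]
        topmost_layer = np.floor(cents[top, 2] / config.layer_thickness)
        in_top = rows[np.floor(cents[rows, 2] / config.layer_thickness) == topmost_layer]
        apex_xy = cents[in_top, :2].mean(axis=0)
        apex_z = cents[top, 2]
        near = xy_tree.query_ball_point(apex_xy, config.apex_localmax_radius)
        n_above = int(np.sum(cloud.z[near] > apex_z + config.apex_localmax_margin))
        if n_above >= config.dbscan_min_samples:
            continue  # canopy rises above this stack: merged-crown artifact
            # (a handful of points is tolerated as atmospheric noise)
        members = np.sort(np.concatenate([cent_members[r] for r in rows]))
        seeds.append((float(cloud.z[members].max()), apex_xy, c, d, members))

    seeds.sort(key=lambda s: -s[0])
    return [TreeSeed(i + 1, apex, lp, ld, m)
            for i, (_, apex, lp, ld, m) in enumerate(seeds)]


class FuzzyKNN(BaseEstimator, ClassifierMixin):
    """Fuzzy k-nearest-neighbour classifier (inverse-distance fuzzy votes).

    Parameters
    ----------
    k : neighbours considered (capped at the training size).
    m : fuzzifier, > 1; weights are ``d**(-2/(m-1))``.
    """

    def __init__(self, k: int = 10, m: float = 2.0):
        self.k = k
        self.m = m

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.shape[0] == 0:
            raise ValueError("empty labelled set")
        if self.m <= 1:
            raise ValueError("fuzzifier m must be > 1")
        self.X_ = X
        self.classes_, self.y_ = np.unique(y, return_inverse=True)
        self.tree_ = cKDTree(X)
        return self

    def membership(self, X):
        """Per-class membership matrix, rows summing to 1."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        k = min(self.k, self.X_.shape[0])
        dist, idx = self.tree_.query(X, k=k)
        dist = dist.reshape(X.shape[0], k)
        idx = idx.reshape(X.shape[0], k)
        return self._membership_from_neighbors(dist, self.y_[idx])

    def _membership_from_neighbors(self, dist, enc_labels):
        n, k = dist.shape
        u = np.zeros((n, len(self.classes_)))
        exact = dist <= 0.0
        has_exact = exact.any(axis=1)
        with np.errstate(divide="ignore"):
            w = dist ** (-2.0 / (self.m - 1.0))
        w[~np.isfinite(w)] = 0.0
        w[has_exact] = exact[has_exact].astype(float)  # coincident points dominate
        rows = np.repeat(np.arange(n), k)
        np.add.at(u, (rows, enc_labels.ravel()), w.ravel())
        total = u.sum(axis=1, keepdims=True)
        total[total == 0] = 1.0
        return u / total

    def predict_proba(self, X):
        return self.membership(X)

    def predict(self, X):
        u = self.membership(X)
        return self.classes_[np.argmax(u, axis=1)]


def fknn_membership(query, labeled_positions, labels, k: int = 10, m: float = 2.0):
    """Membership of one query point per distinct label (dict label -> u)."""
    clf = FuzzyKNN(k=k, m=m).fit(np.asarray(labeled_positions, float),
                                 np.asarray(labels))
    u = clf.membership(np.atleast_2d(np.asarray(query, float)))[0]
    return dict(zip(clf.classes_.tolist(), u.tolist()))


def segment_layers(cloud: PointCloud, seeds: list[TreeSeed],
                   config: LayerSegConfig = LayerSegConfig()) -> PointCloud:
    """Label every buffer point by an iterative layer-by-layer fuzzy k-NN sweep.

    Seed points are pre-labelled.  Layers are processed bottom-up (or
    top-down); within a layer, unlabelled points are processed in ascending
    input index, each classified against *all* points labelled so far —
    seeds, previous layers, and earlier points of the current layer — unless
    its nearest labelled neighbour is farther than ``max_assign_dist``
    (then label 0).  Deterministic for a fixed config.
    """
    if not seeds:
        raise ValueError("segmentation requires at least one tree seed")
    n = len(cloud)
    labels = np.zeros(n, dtype=np.int64)
    for s in seeds:
        labels[s.seed_point_indices] = s.tree_id

    dims = slice(0, 2) if config.fknn_2d else slice(0, 3)
    xyz = cloud.xyz[:, dims]
    inv_exp = -2.0 / (config.fuzzifier_m - 1.0)
    classes = np.array([s.tree_id for s in seeds])

    layers = slice_layers(cloud, config.layer_thickness)
    if config.sweep_direction == "top_down":
        layers = layers[::-1]

    for _, idx in layers:
        todo = idx[labels[idx] == 0]
        if todo.size == 0:
            continue
        evidence = np.flatnonzero(labels > 0)
        if evidence.size == 0:
            continue
        k = min(config.fknn_k, evidence.size)
        tree = cKDTree(xyz[evidence])
        dist0, nb0 = tree.query(xyz[todo], k=k)
        dist0 = dist0.reshape(todo.size, k)
        nb0 = nb0.reshape(todo.size, k)
        lab0 = labels[evidence][nb0]

        buf = np.empty((todo.size, xyz.shape[1]))
        buf_lab = np.empty(todo.size, dtype=np.int64)
        nnew = 0
        for i, p in enumerate(todo):
            d_static, l_static = dist0[i], lab0[i]
            if nnew:
                d_new = np.linalg.norm(buf[:nnew] - xyz[p], axis=1)
                d_all = np.concatenate([d_static, d_new])
                l_all = np.concatenate([l_static, buf_lab[:nnew]])
                if d_all.size > config.fknn_k:
                    part = np.argpartition(d_all, config.fknn_k - 1)[:config.fknn_k]
                    d_all, l_all = d_all[part], l_all[part]
            else:
                d_all, l_all = d_static, l_static
            if d_all.min() > config.max_assign_dist:
                continue  # stays 0
            zero = d_all <= 0.0
            if zero.any():
                w = zero.astype(float)
            else:
                w = d_all ** inv_exp
            votes = np.zeros(classes.size)
            for c_i, c in enumerate(classes):
                votes[c_i] = w[l_all == c].sum()
            lab = int(classes[np.argmax(votes)])
            labels[p] = lab
            buf[nnew] = xyz[p]
            buf_lab[nnew] = lab
            nnew += 1

    return cloud.with_columns(label=labels)
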