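"""Layer slicing, DBSCAN vs a brute-force reachability oracle, fuzzy k-NN,
seed detection and the iterative sweep."""

import numpy as np
import pytest

from plstk.cloud import PointCloud
from plstk.layerseg import (FuzzyKNN, LayerSegConfig, cluster_layer, detect_trees,
                            fknn_membership, segment_layers, slice_layers)


def brute_force_dbscan(xy, eps, min_samples):
    """Independent O(n^2) reachability oracle.

    Returns (core mask, component id per core point, per-point allowed label
    sets for border points)."""
    n = len(xy)
    d = np.linalg.norm(xy[:, None] - xy[None, :], axis=2)
    neighbor = d <= eps
    core = neighbor.sum(axis=1) >= min_samples
    comp = -np.ones(n, dtype=int)
    cid = 0
    for i in range(n):
        if not core[i] or comp[i] >= 0:
            continue
        stack = [i]
        comp[i] = cid
        while stack:
            j = stack.pop()
            for k in np.flatnonzero(neighbor[j] & core):
                if comp[k] < 0:
                    comp[k] = cid
                    stack.append(k)
        cid += 1
    allowed = []
    for i in range(n):
        if core[i]:
            allowed.append({comp[i]})
        else:
            labs = {comp[j] for j in np.flatnonzero(neighbor[i] & core)}
            allowed.append(labs or {-1})
    return core, comp, allowed


class TestSliceLayers:
    def test_one_point_per_layer(self):
        c = PointCloud([0, 0, 0], [0, 0, 0], [0.1, 0.6, 1.1])
        layers = slice_layers(c, 0.5)
        assert [j for j, _ in layers] == [0, 1, 2]
        assert all(len(idx) == 1 for _, idx in layers)

    def test_boundary_goes_to_upper_layer(self):
        c = PointCloud([0], [0], [0.5])
        layers = slice_layers(c, 0.5)
        assert layers[0][0] == 1

    def test_layers_partition_cloud(self, rng):
        c = PointCloud(rng.normal(size=300), rng.normal(size=300),
                       rng.uniform(0, 20, 300))
        layers = slice_layers(c, 0.5)
        all_idx = np.concatenate([idx for _, idx in layers])
        assert np.array_equal(np.sort(all_idx), np.arange(300))

    def test_nonpositive_thickness(self):
        with pytest.raises(ValueError, match="positive"):
            slice_layers(PointCloud([0], [0], [0]), 0.0)


class TestClusterLayer:
    def test_two_blobs(self, rng):
        xy = np.vstack([rng.normal(0, 0.1, (40, 2)), rng.normal(5, 0.1, (40, 2))])
        labels = cluster_layer(xy, eps=0.4, min_samples=5)
        assert len(set(labels[:40])) == 1 and len(set(labels[40:])) == 1
        assert labels[0] != labels[40]

    def test_isolated_point_is_noise(self, rng):
        xy = np.vstack([rng.normal(0, 0.05, (20, 2)), [[50.0, 50.0]]])
        labels = cluster_layer(xy, eps=0.4, min_samples=5)
        assert labels[-1] == -1

    def test_duplicated_point_is_dense_core(self):
        xy = np.tile([[1.0, 2.0]], (6, 1))
        labels = cluster_layer(xy, eps=0.4, min_samples=5)
        assert set(labels) == {0}

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_agrees_with_brute_force_reachability(self, seed):
        rng = np.random.default_rng(seed)
        centers = rng.uniform(-5, 5, (4, 2))
        xy = np.vstack([c + rng.normal(0, 0.15, (40, 2)) for c in centers])
        eps, ms = 0.4, 5
        got = cluster_layer(xy, eps, ms)
        core, comp, allowed = brute_force_dbscan(xy, eps, ms)
        # noise must agree exactly
        assert np.array_equal(got == -1, np.array([a == {-1} for a in allowed]))
        # core partition must agree up to relabelling
        for c_id in set(comp[core]):
            members = np.flatnonzero(core & (comp == c_id))
            assert len(set(got[members])) == 1
        # border points must take a label of a reachable component
        for i in np.flatnonzero(~core):
            if allowed[i] == {-1}:
                continue
            ref = {comp[j] for j in range(len(xy))
                   if core[j] and got[j] == got[i]}
            assert ref & allowed[i]


class TestFuzzyKNN:
    def test_equidistant_split(self):
        u = fknn_membership([0.0, 0.0, 0.0], [[1, 0, 0], [-1, 0, 0]], [1, 2],
                            k=2, m=2.0)
        assert u[1] == pytest.approx(0.5) and u[2] == pytest.approx(0.5)

    def test_inverse_square_hand_case(self):
        """d=(1,2), m=2 -> weights (1, 0.25) -> memberships (0.8, 0.2)."""
        u = fknn_membership([0.0, 0.0, 0.0], [[1, 0, 0], [0, 2, 0]], [1, 2],
                            k=2, m=2.0)
        assert u[1] == pytest.approx(0.8)
        assert u[2] == pytest.approx(0.2)

    def test_coincident_point_wins(self):
        u = fknn_membership([1.0, 1.0, 1.0], [[1, 1, 1], [0, 0, 0]], [3, 1],
                            k=2, m=2.0)
        assert u[3] == pytest.approx(1.0) and u[1] == pytest.approx(0.0)

    def test_memberships_sum_to_one(self, rng):
        X = rng.normal(size=(100, 3))
        y = rng.integers(1, 5, 100)
        clf = FuzzyKNN(k=7, m=1.8).fit(X, y)
        u = clf.membership(rng.normal(size=(50, 3)))
        assert np.allclose(u.sum(axis=1), 1.0, atol=1e-12)

    def test_label_permutation_equivariance(self, rng):
        X = rng.normal(size=(60, 3))
        y = rng.integers(0, 3, 60)
        q = rng.normal(size=(20, 3))
        u1 = FuzzyKNN(k=5).fit(X, y).membership(q)
        perm = {0: 2, 1: 0, 2: 1}
        u2 = FuzzyKNN(k=5).fit(X, np.vectorize(perm.get)(y)).membership(q)
        # class c columns follow the permutation
        for c_old, c_new in perm.items():
            assert np.allclose(u1[:, c_old], u2[:, c_new], atol=1e-12)

    def test_sklearn_protocol(self, rng):
        from sklearn.base import clone
        clf = FuzzyKNN(k=3, m=2.5)
        assert clone(clf).get_params() == {"k": 3, "m": 2.5}
        X = rng.normal(size=(30, 3))
        y = rng.integers(0, 2, 30)
        proba = clf.fit(X, y).predict_proba(X[:5])
        assert proba.shape == (5, 2)
        assert (clf.predict(X) == y).mean() == 1.0  # coincident queries

    def test_empty_labeled_set(self):
        with pytest.raises(ValueError, match="empty"):
            FuzzyKNN().fit(np.empty((0, 3)), np.empty(0))


def synthetic_buffer(rng, centers, height=10.0, n_stem=400, n_crown=1500):
    """Analytic two-tree buffer: vertical stems plus conical crowns."""
    pts, labels = [], []
    for tid, (cx, cy) in enumerate(centers, start=1):
        z = rng.uniform(0.0, height, n_stem)
        theta = rng.uniform(0, 2 * np.pi, n_stem)
        pts.append(np.column_stack([cx + 0.1 * np.cos(theta),
                                    cy + 0.1 * np.sin(theta), z]))
        zc = rng.uniform(0.4 * height, height, n_crown)
        rad = 1.5 * (height - zc) / (0.6 * height)
        theta = rng.uniform(0, 2 * np.pi, n_crown)
        pts.append(np.column_stack([cx + rad * np.cos(theta),
                                    cy + rad * np.sin(theta), zc]))
        labels += [tid] * (n_stem + n_crown)
    pts = np.vstack(pts)
    return PointCloud(pts[:, 0], pts[:, 1], pts[:, 2]), np.array(labels)


class TestDetectTrees:
    def test_single_tree_seed_at_location(self, rng):
        cloud, _ = synthetic_buffer(rng, [(1.0, 2.0)])
        seeds = detect_trees(cloud, LayerSegConfig())
        assert len(seeds) == 1
        assert np.linalg.norm(seeds[0].apex_xy - [1.0, 2.0]) < 0.25

    def test_two_trees_four_metres_apart(self, rng):
        cloud, _ = synthetic_buffer(rng, [(0.0, 0.0), (4.0, 0.0)])
        seeds = detect_trees(cloud, LayerSegConfig())
        assert len(seeds) == 2

    def test_single_layer_blob_gated_out(self, rng):
        pts = rng.normal(0, 0.1, (200, 3)) * [1, 1, 0.05] + [0, 0, 0.2]
        cloud = PointCloud(pts[:, 0], pts[:, 1], pts[:, 2])
        assert detect_trees(cloud, LayerSegConfig()) == []

    def test_ids_ordered_by_decreasing_apex(self, rng):
        c1, _ = synthetic_buffer(rng, [(0.0, 0.0)], height=8.0)
        c2, _ = synthetic_buffer(rng, [(4.0, 0.0)], height=12.0)
        xyz = np.vstack([c1.xyz, c2.xyz])
        cloud = PointCloud(xyz[:, 0], xyz[:, 1], xyz[:, 2])
        seeds = detect_trees(cloud, LayerSegConfig())
        assert len(seeds) == 2
        assert np.linalg.norm(seeds[0].apex_xy - [4.0, 0.0]) < 0.5  # taller first


class TestSegmentLayers:
    def test_single_tree_fully_labelled(self, rng):
        cloud, _ = synthetic_buffer(rng, [(0.0, 0.0)])
        seeds = detect_trees(cloud, LayerSegConfig())
        seg = segment_layers(cloud, seeds, LayerSegConfig())
        lab = seg["label"]
        assert np.mean(lab == 0) < 0.01
        assert set(lab[lab != 0]) == {seeds[0].tree_id}

    def test_two_tree_accuracy(self, rng):
        cloud, truth = synthetic_buffer(rng, [(0.0, 0.0), (2.5, 0.0)])
        seeds = detect_trees(cloud, LayerSegConfig())
        assert len(seeds) == 2
        seg = segment_layers(cloud, seeds, LayerSegConfig())
        lab = seg["label"]
        # map segment ids to truth ids by majority overlap
        mapping = {}
        for s in seeds:
            m = lab == s.tree_id
            mapping[s.tree_id] = np.bincount(truth[m]).argmax()
        mapped = np.array([mapping.get(l, 0) for l in lab])
        assert np.mean(mapped == truth) >= 0.95

    def test_far_point_stays_unassigned(self, rng):
        cloud, _ = synthetic_buffer(rng, [(0.0, 0.0)])
        xyz = np.vstack([cloud.xyz, [[50.0, 50.0, 3.0]]])
        cloud2 = PointCloud(xyz[:, 0], xyz[:, 1], xyz[:, 2])
        seeds = detect_trees(cloud2, LayerSegConfig())
        seg = segment_layers(cloud2, seeds, LayerSegConfig(max_assign_dist=1.5))
        assert seg["label"][-1] == 0

    def test_partition_property(self, rng):
        cloud, _ = synthetic_buffer(rng, [(0.0, 0.0), (3.0, 0.0)])
        seeds = detect_trees(cloud, LayerSegConfig())
        seg = segment_layers(cloud, seeds, LayerSegConfig())
        lab = seg["label"]
        valid = {0} | {s.tree_id for s in seeds}
        assert set(np.unique(lab)).issubset(valid)
        assert len(lab) == len(cloud)

    def test_deterministic_across_runs(self, rng):
        cloud, _ = synthetic_buffer(rng, [(0.0, 0.0), (2.5, 0.0)])
        seeds = detect_trees(cloud, LayerSegConfig())
        a = segment_layers(cloud, seeds, LayerSegConfig())["label"]
        b = segment_layers(cloud, seeds, LayerSegConfig())["label"]
        assert np.array_equal(a, b)

    def test_no_seeds_is_error(self, rng):
        cloud, _ = synthetic_buffer(rng, [(0.0, 0.0)])
        with pytest.raises(ValueError, match="seed"):
            segment_layers(cloud, [], LayerSegConfig())
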