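"""Shared fixtures: random clouds and session-scoped synthetic scenes.

The survey-scale scene (0.05° angular grid, 10 trees) is expensive, so it is
generated once per session and shared by the stem-detection and end-to-end
tests.
"""

import json

import numpy as np
import pandas as pd
import pytest

from plstk.cloud import PointCloud
from plstk.io import write_point_cloud
from plstk.simulate import SceneConfig, ScannerPose, generate_scene, truth_to_json

SCENE_SEED = 3


def random_cloud(rng, n=200, attrs=True) -> PointCloud:
    kw = {}
    if attrs:
        kw = dict(
            intensity=rng.integers(0, 65536, n),
            reflectance=rng.normal(-10, 3, n),
            deviation=np.abs(rng.normal(5, 3, n)),
            return_number=np.ones(n, dtype=np.int64),
            number_of_returns=np.ones(n, dtype=np.int64),
            label=rng.integers(0, 5, n),
        )
    return PointCloud(rng.uniform(-60, 60, n), rng.uniform(-60, 60, n),
                      rng.uniform(-35, 5, n), **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def survey_scene():
    """Default-condition scene: 10 trees, occlusion on, 0.05° grid."""
    cloud, truth = generate_scene(SceneConfig(n_trees=10, seed=SCENE_SEED),
                                  ScannerPose())
    return cloud, truth


@pytest.fixture(scope="session")
def desk_scene():
    """Coarse (0.15°) small scene for fast structural tests."""
    cloud, truth = generate_scene(SceneConfig(n_trees=5, seed=7),
                                  ScannerPose(angular_res_deg=0.15))
    return cloud, truth


@pytest.fixture(scope="session")
def two_tree_buffer():
    """Two conifers 2.8 m apart, crowns touching, as a ground-free buffer
    with per-point truth labels."""
    from plstk.georef import rectify
    from plstk.stems import normalize_heights

    from plstk.simulate import adjoining_pair_config

    cfg, pose = adjoining_pair_config(seed=5)
    cloud, truth = generate_scene(cfg, pose)
    rect = rectify(cloud)
    mid = np.array([0.0, 32.0])
    near = np.linalg.norm(rect.xyz[:, :2] - mid, axis=1) <= 4.5
    norm = normalize_heights(rect.select(near), truth.dtm)
    buf = norm.select(norm.z >= 0.3)
    return buf, buf["label"]


@pytest.fixture(scope="session")
def tall_tree_scene():
    """One birch at close range on a near-instrument-resolution grid, for
    crown-top height accuracy (its blunt ellipsoid crown top is densely
    sampled; a cone apex is intrinsically percentile-hostile)."""
    cfg = SceneConfig(n_trees=1, species_mix=(0.0, 0.0, 1.0, 0.0),
                      tree_positions=((0.0, 24.0),), area=(-4.0, 4.0, 20.0, 28.0),
                      seed=9)
    pose = ScannerPose(fov_v_deg=45.0, fov_h_deg=30.0, angular_res_deg=0.02)
    return generate_scene(cfg, pose)


@pytest.fixture(scope="session")
def scene_files(tmp_path_factory, survey_scene):
    """Survey scene written to disk as the pipeline expects its inputs."""
    d = tmp_path_factory.mktemp("scene")
    cloud, truth = survey_scene
    write_point_cloud(cloud, d / "scene.las")
    (d / "truth.json").write_text(json.dumps(truth_to_json(truth)))
    pd.DataFrame(truth.dtm.support, columns=["x", "y", "z"]).to_csv(
        d / "dtm.csv", index=False)
    return d
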