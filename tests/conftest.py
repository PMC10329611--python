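import numpy as np
import pytest

from disguisor.geometry import CameraModel, RigidTransform
from disguisor.pipeline import PipelineConfig, run_pipeline
from disguisor.synthetic import (
    NoiseParams,
    PersonSpec,
    SceneConfig,
    generate,
    preset_config,
)


def rotation(axis, degrees):
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    a = np.deg2rad(degrees)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * K @ K


def head_lattice(n_u=24, n_v=20):
    """Deterministic head-shaped ellipsoid lattice (no duplicate points)."""
    u = np.linspace(0, 2 * np.pi, n_u, endpoint=False)
    v = np.linspace(0.15, np.pi - 0.15, n_v)
    uu, vv = np.meshgrid(u, v)
    return np.stack(
        [
            0.09 * np.cos(uu) * np.sin(vv),
            0.11 * np.sin(uu) * np.sin(vv),
            0.12 * np.cos(vv),
        ],
        axis=-1,
    ).reshape(-1, 3)


@pytest.fixture
def simple_camera():
    return CameraModel(
        id="cam0", fx=100.0, fy=100.0, cx=50.0, cy=50.0, width=100, height=100
    )


@pytest.fixture(scope="session")
def tiny_scene():
    """Two static mannequins, two frames — quick input for unit tests."""
    cfg = SceneConfig(
        persons=[
            PersonSpec([(0.5, 0.3)], yaw=np.pi, height=1.65),
            PersonSpec([(-0.5, 0.3)], yaw=np.pi, height=1.8),
        ],
        n_frames=2,
        seed=11,
        name="tiny",
    )
    return generate(cfg)


@pytest.fixture(scope="session")
def hard_scene():
    """The challenging evaluation scenario: four persons, occluder panels in
    front of both surgical cameras, 20 noise-free frames."""
    return generate(preset_config("hard", seed=0, n_frames=20))


@pytest.fixture(scope="session")
def hard_result(hard_scene):
    return run_pipeline(
        hard_scene.cameras,
        hard_scene.frames,
        hard_scene.detections,
        gt=hard_scene.gt_faces,
        config=PipelineConfig(seed=0),
    )
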