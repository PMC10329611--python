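"""Pinhole camera model, rigid transforms, and multi-view RGB-D point-cloud fusion.

Conventions (used everywhere in the package):

* pixels are 0-based ``(u, v) = (column, row)`` with pixel centers at integer
  coordinates;
* depth is the z-distance along the optical axis in meters, not the ray length;
* extrinsics are stored world → camera;
* stored depth maps are 16-bit integers; ``depth_scale`` converts stored units
  to meters (default ``0.001``, i.e. millimeters).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

__all__ = [
    "RigidTransform",
    "CameraModel",
    "RGBDFrame",
    "PointCloud",
    "NotProjectableError",
    "project",
    "unproject",
    "fuse_point_cloud",
    "load_calibration",
    "save_calibration",
    "save_point_cloud",
    "load_point_cloud",
]

_ORTHO_TOL = 1e-8
_Z_EPS = 1e-6  # meters; points nearer than this are "behind" the camera
MAX_DEPTH_M = 20.0


class NotProjectableError(ValueError):
    """Point lies at or behind the camera's principal plane."""


def _check_rotation(R: np.ndarray, tol: float = _ORTHO_TOL) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValueError(f"rotation must be 3x3, got {R.shape}")
    if np.abs(R.T @ R - np.eye(3)).max() > tol:
        raise ValueError("rotation matrix is not orthonormal")
    if abs(np.linalg.det(R) - 1.0) > tol:
        raise ValueError("rotation matrix determinant is not +1 (improper rotation)")
    return R


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> R @ x + t`` (meters)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", _check_rotation(self.rotation))
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (..., 3) array of points."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ other`` (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix."""
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation
        return M


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    return a.compose(b)


def invert(t: RigidTransform) -> RigidTransform:
    return t.inverse()


@dataclass(frozen=True)
class CameraModel:
    """Calibrated pinhole RGB-D camera.

    ``extrinsic`` maps world coordinates into the camera frame; ``depth_scale``
    is meters per stored depth unit.
    """

    id: str
    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int
    extrinsic: RigidTransform = field(default_factory=RigidTransform.identity)
    depth_scale: float = 0.001

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ValueError("principal point must lie inside the image")

    @property
    def intrinsic_matrix(self) -> np.ndarray:
        return np.array(
            [[self.fx, 0.0, self.cx], [0.0, self.fy, self.cy], [0.0, 0.0, 1.0]]
        )

    @property
    def projection_matrix(self) -> np.ndarray:
        """3x4 matrix ``K [R | t]`` mapping homogeneous world points to pixels."""
        E = np.hstack([self.extrinsic.rotation, self.extrinsic.translation[:, None]])
        return self.intrinsic_matrix @ E

    @property
    def center(self) -> np.ndarray:
        """Camera center in world coordinates."""
        return self.extrinsic.inverse().translation


@dataclass
class RGBDFrame:
    """One synchronized color + depth acquisition from a single camera."""

    camera_id: str
    frame_index: int
    color: np.ndarray  # H x W x 3, uint8
    depth: np.ndarray  # H x W, stored depth units; 0 = invalid

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")
        if self.color.ndim != 3 or self.color.shape[2] != 3:
            raise ValueError("color must be HxWx3")
        if self.depth.shape != self.color.shape[:2]:
            raise ValueError("depth and color dimensions disagree")
        if np.any(self.depth < 0):
            raise ValueError("depth values must be nonnegative")


@dataclass
class PointCloud:
    """World-frame point cloud, optionally colored."""

    points: np.ndarray  # N x 3, meters
    colors: np.ndarray | None = None  # N x 3, uint8

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.points)):
            raise ValueError("point cloud contains NaN/Inf")
        if self.colors is not None:
            self.colors = np.asarray(self.colors).reshape(-1, 3)
            if len(self.colors) != len(self.points):
                raise ValueError("colors must align 1:1 with points")

    def __len__(self) -> int:
        return len(self.points)


# ---------------------------------------------------------------------------
# projection


def project(camera: CameraModel, point_world) -> tuple[np.ndarray, float]:
    """Project a world point; returns continuous ``(u, v)`` and depth (m).

    Raises :class:`NotProjectableError` for points at or behind the camera.
    """
    pc = camera.extrinsic.apply(np.asarray(point_world, dtype=float).reshape(3))
    z = pc[2]
    if z <= _Z_EPS:
        raise NotProjectableError(f"point has camera-frame depth {z:.3g} <= {_Z_EPS}")
    u = camera.fx * pc[0] / z + camera.cx
    v = camera.fy * pc[1] / z + camera.cy
    return np.array([u, v]), float(z)


def project_many(camera: CameraModel, points_world: np.ndarray):
    """Vectorized projection. Returns ``(uv, depth, in_front)``; rows of ``uv``
    for points behind the camera are NaN."""
    pc = camera.extrinsic.apply(np.asarray(points_world, dtype=float).reshape(-1, 3))
    z = pc[:, 2]
    ok = z > _Z_EPS
    uv = np.full((len(pc), 2), np.nan)
    uv[ok, 0] = camera.fx * pc[ok, 0] / z[ok] + camera.cx
    uv[ok, 1] = camera.fy * pc[ok, 1] / z[ok] + camera.cy
    return uv, z, ok


def unproject(camera: CameraModel, pixel, depth: float) -> np.ndarray:
    """Inverse of :func:`project`: pixel + metric depth → world point."""
    if depth <= 0:
        raise ValueError(f"depth must be positive, got {depth}")
    u, v = np.asarray(pixel, dtype=float).reshape(2)
    x = (u - camera.cx) / camera.fx * depth
    y = (v - camera.cy) / camera.fy * depth
    return camera.extrinsic.inverse().apply(np.array([x, y, depth]))


def fuse_point_cloud(
    frames: list[RGBDFrame],
    cameras: list[CameraModel],
    stride: int = 2,
) -> PointCloud:
    """Fuse per-camera depth maps into one colored world-frame cloud.

    Valid-depth pixels are subsampled by ``stride`` along both axes, unprojected
    through each camera's calibration and concatenated; pixel colors ride along.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    cam_by_id = {c.id: c for c in cameras}
    indices = {f.frame_index for f in frames}
    if len(indices) > 1:
        raise ValueError(f"frames span multiple frame indices: {sorted(indices)}")
    pts, cols = [], []
    for frame in frames:
        cam = cam_by_id.get(frame.camera_id)
        if cam is None:
            raise KeyError(f"unknown camera_id {frame.camera_id!r}")
        depth = frame.depth[::stride, ::stride].astype(float) * cam.depth_scale
        color = frame.color[::stride, ::stride]
        vs, us = np.nonzero(depth > 0)
        if len(vs) == 0:
            continue
        z = depth[vs, us]
        u = us * stride
        v = vs * stride
        x = (u - cam.cx) / cam.fx * z
        y = (v - cam.cy) / cam.fy * z
        cam_pts = np.column_stack([x, y, z])
        pts.append(cam.extrinsic.inverse().apply(cam_pts))
        cols.append(color[vs, us])
    if not pts:
        return PointCloud(np.empty((0, 3)), np.empty((0, 3), dtype=np.uint8))
    return PointCloud(np.vstack(pts), np.vstack(cols))


def kabsch(source: np.ndarray, target: np.ndarray, weights=None) -> RigidTransform:
    """Closed-form least-squares rigid motion mapping ``source`` onto ``target``.

    Solves ``argmin_{R,t} Σ w_i ||R s_i + t - q_i||²`` (SVD with a proper-rotation
    sign fix). Degenerate geometry (covariance rank < 2) raises ``ValueError``.
    """
    P = np.asarray(source, dtype=float).reshape(-1, 3)
    Q = np.asarray(target, dtype=float).reshape(-1, 3)
    w = np.ones(len(P)) if weights is None else np.asarray(weights, dtype=float)
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("weights must have positive sum")
    w = w / wsum
    pc = (w[:, None] * P).sum(axis=0)
    qc = (w[:, None] * Q).sum(axis=0)
    H = (w[:, None] * (P - pc)).T @ (Q - qc)
    if np.linalg.matrix_rank(H, tol=1e-12) < 2:
        raise ValueError("degenerate geometry: covariance rank < 2")
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return RigidTransform(R, qc - R @ pc)


# ---------------------------------------------------------------------------
# I/O


def load_calibration(path) -> list[CameraModel]:
    """Read cameras from the calibration JSON format."""
    with open(path) as fh:
        doc = json.load(fh)
    cams = []
    for c in doc["cameras"]:
        R = np.asarray(c["R"], dtype=float).reshape(3, 3)
        t = np.asarray(c["t"], dtype=float)
        cams.append(
            CameraModel(
                id=str(c["id"]),
                fx=float(c["fx"]),
                fy=float(c["fy"]),
                cx=float(c["cx"]),
                cy=float(c["cy"]),
                width=int(c["width"]),
                height=int(c["height"]),
                extrinsic=RigidTransform(R, t),
                depth_scale=float(c.get("depth_scale", 0.001)),
            )
        )
    return cams


def save_calibration(cameras: list[CameraModel], path) -> None:
    doc = {
        "cameras": [
            {
                "id": c.id,
                "fx": c.fx,
                "fy": c.fy,
                "cx": c.cx,
                "cy": c.cy,
                "width": c.width,
                "height": c.height,
                "R": [float(x) for x in c.extrinsic.rotation.ravel()],
                "t": [float(x) for x in c.extrinsic.translation],
                "depth_scale": c.depth_scale,
            }
            for c in cameras
        ]
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def save_point_cloud(cloud: PointCloud, path) -> None:
    """Write a binary little-endian PLY with x,y,z,red,green,blue."""
    colors = cloud.colors
    if colors is None:
        colors = np.full((len(cloud), 3), 200, dtype=np.uint8)
    pc = trimesh.PointCloud(cloud.points, colors=colors.astype(np.uint8))
    pc.export(str(path), file_type="ply")


def load_point_cloud(path) -> PointCloud:
    pc = trimesh.load(str(path), process=False)
    colors = None
    if getattr(pc, "colors", None) is not None and len(pc.colors):
        colors = np.asarray(pc.colors)[:, :3]
    return PointCloud(np.asarray(pc.vertices, dtype=float), colors)
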