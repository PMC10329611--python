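"""Seeded generator of multi-camera RGB-D scenes with exact ground truth.

Emulates a four-camera OR-like acquisition: two *workflow* cameras at
conventional height and angle, two *surgical* cameras mounted high with
steep viewing angles, articulated mannequins standing in for staff, and
static occluder panels standing in for surgical lights that obstruct faces
in the surgical views. Everything — body geometry, rendering, occlusion,
keypoints — is derived from one seed, and the ground truth is exact by
construction: faces are rendered through the same z-buffer used for the
scene itself, so GT visibility and the anonymizer's depth-disparity check
coincide on noise-free data.

Mannequins are rigidly placed (position + yaw) instances of the procedural
body template moving along piecewise-linear waypoint paths at constant
velocity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .body import BodyTemplate, build_template, canonical_joints, fit_body
from .evaluate import GTFace, load_gt, save_gt
from .geometry import (
    CameraModel,
    RGBDFrame,
    RigidTransform,
    load_calibration,
    save_calibration,
)
from .pose import (
    N_JOINTS,
    Keypoints2D,
    PoseTrack,
    Skeleton3D,
    load_keypoints,
    save_keypoints,
)
from .rendering import rasterize_mesh, render_color

__all__ = [
    "PersonSpec",
    "Panel",
    "NoiseParams",
    "SceneConfig",
    "SyntheticScene",
    "generate",
    "corrupt",
    "export_scene",
    "load_scene",
    "preset_config",
]


@dataclass
class PersonSpec:
    """One mannequin: waypoint path (x, y), fixed yaw, body height."""

    waypoints: list[tuple[float, float]]
    yaw: float = np.pi  # 0 faces +y; pi faces -y (toward the workflow cameras)
    height: float = 1.7

    def position(self, t: float) -> np.ndarray:
        """Linear interpolation along the waypoint polyline, t in [0, 1]."""
        wp = np.asarray(self.waypoints, dtype=float)
        if len(wp) == 1:
            return wp[0]
        seg = t * (len(wp) - 1)
        i = min(int(seg), len(wp) - 2)
        frac = seg - i
        return (1 - frac) * wp[i] + frac * wp[i + 1]


@dataclass
class Panel:
    """Static rectangular occluder ("surgical light")."""

    center: tuple[float, float, float]
    e1: tuple[float, float, float]  # half-extent edge vector
    e2: tuple[float, float, float]  # half-extent edge vector

    def mesh(self) -> tuple[np.ndarray, np.ndarray]:
        c = np.asarray(self.center)
        a = np.asarray(self.e1)
        b = np.asarray(self.e2)
        verts = np.array([c - a - b, c + a - b, c + a + b, c - a + b])
        faces = np.array([[0, 1, 2], [0, 2, 3]])
        return verts, faces

    @classmethod
    def blocking(
        cls, camera_pos, target, frac: float = 0.75, half_w: float = 0.28, half_h: float = 0.22
    ) -> "Panel":
        """Panel perpendicular to the camera→target ray at ``frac`` of the way."""
        p = np.asarray(camera_pos, dtype=float)
        q = np.asarray(target, dtype=float)
        d = q - p
        n = d / np.linalg.norm(d)
        up = np.array([0.0, 0.0, 1.0])
        e1 = np.cross(n, up)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(n, e1)
        c = p + frac * d
        return cls(tuple(c), tuple(half_w * e1), tuple(half_h * e2))


@dataclass
class NoiseParams:
    depth_sigma: float = 0.0  # m
    keypoint_sigma: float = 0.0  # px
    dropout: float = 0.0  # probability a joint's confidence is zeroed


@dataclass
class SceneConfig:
    persons: list[PersonSpec]
    occluders: list[Panel] = field(default_factory=list)
    n_frames: int = 20
    width: int = 160
    height: int = 120
    noise: NoiseParams = field(default_factory=NoiseParams)
    seed: int = 0
    visibility_threshold: float = 0.2  # min unoccluded face-pixel fraction
    name: str = "custom"


@dataclass
class SyntheticScene:
    config: SceneConfig
    cameras: list[CameraModel]
    frames: dict[int, list[RGBDFrame]]  # frame_index -> one frame per camera
    detections: list[Keypoints2D]  # noise-free 2D keypoints
    gt_tracks: list[PoseTrack]
    gt_faces: list[GTFace]
    gt_face_meshes: dict[tuple[str, int], tuple[np.ndarray, np.ndarray]]
    templates: list[BodyTemplate]


def default_cameras(width: int = 160, height: int = 120) -> list[CameraModel]:
    """Two workflow + two surgical viewpoints around the table center."""
    f = 0.875 * width  # ~60 degree horizontal field of view
    specs = [
        ("wfc1", (2.6, -3.0, 1.7), (0.0, 0.0, 1.2)),
        ("wfc2", (-2.6, -3.0, 1.7), (0.0, 0.0, 1.2)),
        ("sc1", (0.9, -1.8, 2.9), (0.3, 0.3, 1.0)),
        ("sc2", (-0.9, -1.8, 2.9), (-0.3, 0.3, 1.0)),
    ]
    return [
        _look_at(cid, pos, tgt, f, width, height) for cid, pos, tgt in specs
    ]


def _look_at(cam_id, position, target, focal, width, height) -> CameraModel:
    p = np.asarray(position, dtype=float)
    fwd = np.asarray(target, dtype=float) - p
    fwd /= np.linalg.norm(fwd)
    up = np.array([0.0, 0.0, 1.0])
    right = np.cross(fwd, up)
    right /= np.linalg.norm(right)
    down = np.cross(fwd, right)
    R = np.vstack([right, down, fwd])  # world -> camera
    return CameraModel(
        id=cam_id,
        fx=focal,
        fy=focal,
        cx=(width - 1) / 2.0,
        cy=(height - 1) / 2.0,
        width=width,
        height=height,
        extrinsic=RigidTransform(R, -R @ p),
    )


def preset_config(name: str, seed: int = 0, n_frames: int = 20) -> SceneConfig:
    """Scene templates of graded difficulty.

    ``easy``: three mannequins, no occluders. ``medium``: five mannequins,
    one panel obstructing the first person in surgical camera 1. ``hard``:
    four mannequins around the table with panels obstructing the two central
    persons' faces in both surgical views.
    """
    cams = {c.id: c for c in default_cameras()}
    heights = {"easy": [1.62, 1.75, 1.85], "medium": [1.6, 1.68, 1.74, 1.8, 1.86]}

    def head_of(xy, h):
        return (xy[0], xy[1], 0.9 * h)

    if name == "easy":
        persons = [
            PersonSpec([(0.5, 0.3)], yaw=np.pi, height=1.62),
            PersonSpec([(-0.5, 0.3)], yaw=np.pi, height=1.75),
            PersonSpec([(1.5, -0.6), (1.85, -0.95)], yaw=np.pi, height=1.85),
        ]
        occluders: list[Panel] = []
    elif name == "medium":
        persons = [
            PersonSpec([(0.45, 0.35)], yaw=np.pi, height=1.6),
            PersonSpec([(-0.45, 0.35)], yaw=np.pi, height=1.68),
            PersonSpec([(1.5, -0.6), (1.85, -0.95)], yaw=np.pi, height=1.74),
            PersonSpec([(-1.5, -0.6), (-1.85, -0.95)], yaw=np.pi, height=1.8),
            PersonSpec([(0.0, 1.1)], yaw=np.pi, height=1.86),
        ]
        p0 = persons[0]
        occluders = [
            Panel.blocking(cams["sc1"].center, head_of(p0.waypoints[0], p0.height))
        ]
    elif name == "hard":
        persons = [
            PersonSpec([(0.45, 0.35)], yaw=np.pi, height=1.66),
            PersonSpec([(-0.45, 0.35)], yaw=np.pi, height=1.78),
            PersonSpec([(1.55, -0.6), (1.9, -0.95)], yaw=np.pi, height=1.7),
            PersonSpec([(-1.55, -0.6), (-1.9, -0.95)], yaw=np.pi, height=1.84),
        ]
        p0, p1 = persons[0], persons[1]
        occluders = [
            Panel.blocking(cams["sc1"].center, head_of(p0.waypoints[0], p0.height)),
            Panel.blocking(cams["sc2"].center, head_of(p1.waypoints[0], p1.height)),
        ]
    else:
        raise ValueError(f"unknown preset {name!r}")
    return SceneConfig(
        persons=persons, occluders=occluders, n_frames=n_frames, seed=seed, name=name
    )


def relaxed_joints(height: float, arm_drop_deg: float = 75.0) -> np.ndarray:
    """Canonical joints with the arms lowered from the T-pose.

    OR staff keep their arms near the body; the fully outstretched T-pose
    would sweep long horizontal occluders through the scene. Each arm is
    rotated ``arm_drop_deg`` downward about its shoulder (bone lengths are
    preserved, so a body fit to these joints has zero residual).
    """
    j = canonical_joints(height)
    a = np.deg2rad(arm_drop_deg)
    for sign, sh, el, wr in [(1.0, 5, 7, 9), (-1.0, 6, 8, 10)]:
        c, s = np.cos(a), np.sin(a)
        # rotate about the y-axis through the shoulder, dropping +-x toward -z
        R = np.array([[c, 0.0, sign * s], [0.0, 1.0, 0.0], [-sign * s, 0.0, c]])
        for joint in (el, wr):
            j[joint] = j[sh] + R @ (j[joint] - j[sh])
    return j


def _yaw_transform(yaw: float, xy: np.ndarray) -> RigidTransform:
    c, s = np.cos(yaw), np.sin(yaw)
    R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    return RigidTransform(R, np.array([xy[0], xy[1], 0.0]))


def _floor_mesh(half: float = 5.0):
    verts = np.array(
        [[-half, -half, 0], [half, -half, 0], [half, half, 0], [-half, half, 0]],
        dtype=float,
    )
    faces = np.array([[0, 1, 2], [0, 2, 3]])
    return verts, faces


_BODY_COLORS = np.array(
    [[70, 110, 170], [90, 150, 110], [150, 110, 70], [120, 90, 150], [160, 140, 80]],
    dtype=np.uint8,
)
_FACE_COLOR = np.array([210, 170, 140], dtype=np.uint8)
_PANEL_COLOR = np.array([40, 40, 45], dtype=np.uint8)
_FLOOR_COLOR = np.array([120, 120, 125], dtype=np.uint8)


def generate(config: SceneConfig) -> SyntheticScene:
    """Render the configured scene and derive exact ground truth.

    Per frame and camera the full scene (floor + panels + mannequins) goes
    through the z-buffer once; each face patch is additionally rendered alone
    and compared against the full-scene depth to measure its unoccluded pixel
    fraction. ``partially_visible`` is true when that fraction reaches the
    configured threshold. Deterministic for a fixed config.
    """
    if not config.persons:
        raise ValueError("scene needs at least one person")
    cameras = default_cameras(config.width, config.height)
    templates = [build_template(p.height) for p in config.persons]

    # static geometry
    fl_v, fl_f = _floor_mesh()
    static_v = [fl_v]
    static_f = [fl_f]
    static_c = [np.tile(_FLOOR_COLOR, (len(fl_f), 1))]
    off = len(fl_v)
    for panel in config.occluders:
        pv, pf = panel.mesh()
        static_v.append(pv)
        static_f.append(pf + off)
        static_c.append(np.tile(_PANEL_COLOR, (len(pf), 1)))
        off += len(pv)

    frames: dict[int, list[RGBDFrame]] = {}
    detections: list[Keypoints2D] = []
    gt_faces: list[GTFace] = []
    gt_face_meshes: dict[tuple[str, int], tuple[np.ndarray, np.ndarray]] = {}
    track_skels: dict[str, list[Skeleton3D]] = {p_id(i): [] for i in range(len(config.persons))}

    for fi in range(config.n_frames):
        t = fi / max(config.n_frames - 1, 1)
        scene_v = list(static_v)
        scene_f = list(static_f)
        scene_c = list(static_c)
        offset = off
        posed_people = []
        for pi, (spec, tpl) in enumerate(zip(config.persons, templates)):
            T = _yaw_transform(spec.yaw, spec.position(t))
            pj = T.apply(relaxed_joints(spec.height))
            posed = fit_body(
                tpl,
                Skeleton3D(
                    p_id(pi), fi, pj,
                    np.ones(N_JOINTS, dtype=bool),
                    np.full(N_JOINTS, len(cameras)),
                ),
            )
            pv = posed.posed_vertices
            face_colors = np.tile(_BODY_COLORS[pi % len(_BODY_COLORS)], (len(tpl.faces), 1))
            on_face = np.all(np.isin(tpl.faces, tpl.face_patch), axis=1)
            face_colors[on_face] = _FACE_COLOR
            scene_v.append(pv)
            scene_f.append(tpl.faces + offset)
            scene_c.append(face_colors)
            offset += len(pv)
            posed_people.append((pi, spec, tpl, pv, pj))
            track_skels[p_id(pi)].append(
                Skeleton3D(
                    p_id(pi), fi, pj,
                    np.ones(N_JOINTS, dtype=bool),
                    np.full(N_JOINTS, len(cameras)),
                )
            )

        all_v = np.vstack(scene_v)
        all_f = np.vstack(scene_f)
        all_c = np.vstack(scene_c).astype(np.uint8)

        frames[fi] = []
        for cam in cameras:
            color, depth = render_color(all_v, all_f, all_c, cam)
            depth_u16 = np.round(np.clip(depth, 0, 65.535) * 1000.0).astype(np.uint16)
            frames[fi].append(RGBDFrame(cam.id, fi, color, depth_u16))

            # ground-truth faces: face-only render vs full-scene z-buffer
            for pi, spec, tpl, pv, pj in posed_people:
                fmask_v = pv[tpl.face_patch]
                remap = -np.ones(len(pv), dtype=int)
                remap[tpl.face_patch] = np.arange(len(tpl.face_patch))
                keep = np.all(np.isin(tpl.faces, tpl.face_patch), axis=1)
                ffaces = remap[tpl.faces[keep]]
                ras = rasterize_mesh(fmask_v, ffaces, cam)
                mask = ras.mask
                if not mask.any():
                    continue
                # a face pixel is unoccluded when nothing in the full scene
                # renders strictly in front of it
                full_depth = depth[mask]
                face_depth = ras.depth[mask]
                unoccluded = full_depth >= face_depth - 1e-9
                vis_frac = float(unoccluded.sum()) / mask.sum()
                ys, xs = np.nonzero(mask)
                bbox = (
                    float(xs.min()),
                    float(ys.min()),
                    float(xs.max() - xs.min() + 1),
                    float(ys.max() - ys.min() + 1),
                )
                gt_faces.append(
                    GTFace(
                        person_id=p_id(pi),
                        frame_index=fi,
                        camera_id=cam.id,
                        bbox=bbox,
                        partially_visible=vis_frac >= config.visibility_threshold,
                    )
                )

        for pi, spec, tpl, pv, pj in posed_people:
            fmask_v = pv[tpl.face_patch]
            remap = -np.ones(len(pv), dtype=int)
            remap[tpl.face_patch] = np.arange(len(tpl.face_patch))
            keep = np.all(np.isin(tpl.faces, tpl.face_patch), axis=1)
            gt_face_meshes[(p_id(pi), fi)] = (fmask_v, remap[tpl.faces[keep]])

        # exact keypoint detections
        for cam in cameras:
            for pi, spec, tpl, pv, pj in posed_people:
                joints = np.zeros((N_JOINTS, 3))
                cam_pts = cam.extrinsic.apply(pj)
                z = cam_pts[:, 2]
                ok = z > 1e-6
                u = np.where(ok, cam.fx * cam_pts[:, 0] / np.where(ok, z, 1) + cam.cx, 0)
                v = np.where(ok, cam.fy * cam_pts[:, 1] / np.where(ok, z, 1) + cam.cy, 0)
                inside = ok & (u >= 0) & (u <= cam.width - 1) & (v >= 0) & (v <= cam.height - 1)
                joints[:, 0] = np.where(inside, u, 0)
                joints[:, 1] = np.where(inside, v, 0)
                joints[:, 2] = inside.astype(float)
                if inside.sum() >= 4:
                    detections.append(
                        Keypoints2D(cam.id, fi, joints, person_hint=p_id(pi))
                    )

    gt_tracks = [PoseTrack(pid, skels) for pid, skels in track_skels.items()]
    return SyntheticScene(
        config=config,
        cameras=cameras,
        frames=frames,
        detections=detections,
        gt_tracks=gt_tracks,
        gt_faces=gt_faces,
        gt_face_meshes=gt_face_meshes,
        templates=templates,
    )


def p_id(i: int) -> str:
    return f"gt_{i}"


def corrupt(
    scene: SyntheticScene, noise: NoiseParams, seed: int | None = None
) -> tuple[list[Keypoints2D], dict[int, list[RGBDFrame]]]:
    """Degrade the exact detections and depth maps with seeded noise.

    Gaussian pixel noise on keypoints, Bernoulli dropout to confidence 0,
    Gaussian depth noise (meters, applied to valid pixels only).
    """
    rng = np.random.default_rng(scene.config.seed if seed is None else seed)
    dets = []
    for d in scene.detections:
        joints = d.joints.copy()
        if noise.keypoint_sigma > 0:
            joints[:, :2] += rng.normal(0, noise.keypoint_sigma, size=(N_JOINTS, 2))
        if noise.dropout > 0:
            drop = rng.random(N_JOINTS) < noise.dropout
            joints[drop, 2] = 0.0
        dets.append(Keypoints2D(d.camera_id, d.frame_index, joints, d.person_hint))
    frames: dict[int, list[RGBDFrame]] = {}
    for fi, flist in scene.frames.items():
        frames[fi] = []
        for f in flist:
            depth = f.depth.astype(float)
            if noise.depth_sigma > 0:
                valid = depth > 0
                depth[valid] += rng.normal(0, noise.depth_sigma * 1000.0, size=int(valid.sum()))
                depth = np.clip(depth, 0, 65535)
            frames[fi].append(
                RGBDFrame(f.camera_id, fi, f.color, np.round(depth).astype(np.uint16))
            )
    return dets, frames


# ---------------------------------------------------------------------------
# disk round-trip in the pipeline's own formats


def export_scene(scene: SyntheticScene, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    save_calibration(scene.cameras, d / "calibration.json")
    save_keypoints(scene.detections, d / "keypoints.json")
    save_gt(scene.gt_faces, d / "gt_faces.json")
    meta = {
        "name": scene.config.name,
        "n_frames": scene.config.n_frames,
        "width": scene.config.width,
        "height": scene.config.height,
        "seed": scene.config.seed,
        "visibility_threshold": scene.config.visibility_threshold,
    }
    (d / "scene.json").write_text(json.dumps(meta, indent=2))
    for fi, flist in scene.frames.items():
        for f in flist:
            cam_dir = d / "frames" / f.camera_id
            cam_dir.mkdir(parents=True, exist_ok=True)
            iio.imwrite(cam_dir / f"{fi:04d}_color.png", f.color)
            iio.imwrite(cam_dir / f"{fi:04d}_depth.png", f.depth)


def load_scene_inputs(directory):
    """Read back the exported pipeline inputs (calibration, frames, keypoints, GT)."""
    d = Path(directory)
    cameras = load_calibration(d / "calibration.json")
    detections = load_keypoints(d / "keypoints.json")
    gt = load_gt(d / "gt_faces.json") if (d / "gt_faces.json").exists() else None
    frames: dict[int, list[RGBDFrame]] = {}
    for cam in cameras:
        cam_dir = d / "frames" / cam.id
        for png in sorted(cam_dir.glob("*_color.png")):
            fi = int(png.name.split("_")[0])
            color = np.asarray(iio.imread(png))
            depth = np.asarray(iio.imread(cam_dir / f"{fi:04d}_depth.png"))
            frames.setdefault(fi, []).append(
                RGBDFrame(cam.id, fi, color, depth.astype(np.uint16))
            )
    return cameras, frames, detections, gt


load_scene = load_scene_inputs
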