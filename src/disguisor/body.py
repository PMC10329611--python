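"""Procedural articulated body template and skeleton-driven posing.

A rigid-segment humanoid stands in for a statistical body model: every bone
carries one ellipsoidal segment, the head is a three-axis ellipsoid with a
labeled frontal face patch, and each vertex is bound to exactly one bone.
Downstream stages only need a head segment roughly aligned with the person —
the point-cloud registration stage performs the precise alignment — so rigid
per-bone skinning is adequate. A real statistical mesh (e.g. SMPL) can be
loaded through the same type from OBJ/PLY plus a JSON label file.

Canonical frame: person stands along +z (up), faces +y, T-pose arms along x.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import trimesh

from .geometry import RigidTransform, kabsch
from .pose import (
    N_JOINTS,
    LEFT_HIP,
    LEFT_SHOULDER,
    RIGHT_HIP,
    RIGHT_SHOULDER,
    TORSO_JOINTS,
    Skeleton3D,
)

__all__ = [
    "BodyTemplate",
    "FittedBody",
    "SubMesh",
    "BONES",
    "build_template",
    "fit_body",
    "extract_head",
    "extract_face",
    "load_template",
    "save_template",
]

FACING = np.array([0.0, 1.0, 0.0])  # canonical facing direction
FACE_NORMAL_MIN = 0.25  # cos threshold selecting the frontal face patch

NOSE = 0
L_EYE, R_EYE, L_EAR, R_EAR = 1, 2, 3, 4
L_ELBOW, R_ELBOW, L_WRIST, R_WRIST = 7, 8, 9, 10
L_KNEE, R_KNEE, L_ANKLE, R_ANKLE = 13, 14, 15, 16

# bone: (name, parent bone, parent joint(s), child joint(s)).
# Joint endpoints given as tuples are virtual joints (midpoints).
PELVIS = (LEFT_HIP, RIGHT_HIP)
NECK = (LEFT_SHOULDER, RIGHT_SHOULDER)
BONES: list[tuple[str, str | None, tuple, tuple]] = [
    ("torso", None, PELVIS, NECK),
    ("head", "torso", NECK, (NOSE,)),
    ("left_upper_arm", "torso", (LEFT_SHOULDER,), (L_ELBOW,)),
    ("left_forearm", "left_upper_arm", (L_ELBOW,), (L_WRIST,)),
    ("right_upper_arm", "torso", (RIGHT_SHOULDER,), (R_ELBOW,)),
    ("right_forearm", "right_upper_arm", (R_ELBOW,), (R_WRIST,)),
    ("left_thigh", "torso", (LEFT_HIP,), (L_KNEE,)),
    ("left_shin", "left_thigh", (L_KNEE,), (L_ANKLE,)),
    ("right_thigh", "torso", (RIGHT_HIP,), (R_KNEE,)),
    ("right_shin", "right_thigh", (R_KNEE,), (R_ANKLE,)),
]
BONE_NAMES = [b[0] for b in BONES]


def canonical_joints(height: float) -> np.ndarray:
    """COCO-17 joint positions of the canonical T-pose, scaled to ``height``."""
    h = height
    j = np.zeros((N_JOINTS, 3))
    j[LEFT_HIP] = (0.10 * h, 0, 0.53 * h)
    j[RIGHT_HIP] = (-0.10 * h, 0, 0.53 * h)
    j[L_KNEE] = (0.10 * h, 0, 0.29 * h)
    j[R_KNEE] = (-0.10 * h, 0, 0.29 * h)
    j[L_ANKLE] = (0.10 * h, 0, 0.05 * h)
    j[R_ANKLE] = (-0.10 * h, 0, 0.05 * h)
    j[LEFT_SHOULDER] = (0.13 * h, 0, 0.82 * h)
    j[RIGHT_SHOULDER] = (-0.13 * h, 0, 0.82 * h)
    j[L_ELBOW] = (0.30 * h, 0, 0.82 * h)
    j[R_ELBOW] = (-0.30 * h, 0, 0.82 * h)
    j[L_WRIST] = (0.45 * h, 0, 0.82 * h)
    j[R_WRIST] = (-0.45 * h, 0, 0.82 * h)
    j[NOSE] = (0, 0.066 * h, 0.92 * h)
    j[L_EYE] = (0.022 * h, 0.058 * h, 0.935 * h)
    j[R_EYE] = (-0.022 * h, 0.058 * h, 0.935 * h)
    j[L_EAR] = (0.052 * h, 0.01 * h, 0.925 * h)
    j[R_EAR] = (-0.052 * h, 0.01 * h, 0.925 * h)
    return j


def _joint_pos(joints: np.ndarray, endpoint: tuple) -> np.ndarray:
    return joints[list(endpoint)].mean(axis=0)


@dataclass
class BodyTemplate:
    """Canonical T-pose mesh with rigid skinning and labeled head/face regions."""

    vertices: np.ndarray  # V x 3
    faces: np.ndarray  # F x 3 int
    joint_positions: np.ndarray  # 17 x 3 canonical
    bone_of_vertex: np.ndarray  # V int, index into BONES
    labels: dict[str, np.ndarray]  # segment tag -> vertex indices
    face_patch: np.ndarray  # vertex indices, subset of labels["head"]
    face_uv: np.ndarray  # len(face_patch) x 2, UVs of face-patch vertices
    height: float = 1.7

    def __post_init__(self) -> None:
        head = set(self.labels["head"].tolist())
        if not set(self.face_patch.tolist()) < head:
            raise ValueError("face_patch must be a proper subset of head vertices")
        tri = self.vertices[self.faces]
        areas = 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
        )
        if np.any(areas < 1e-12):
            raise ValueError("template contains degenerate triangles")
        if self.bone_of_vertex.max() >= len(BONES) or self.bone_of_vertex.min() < 0:
            raise ValueError("skinning references an unknown bone")


@dataclass
class FittedBody:
    """A template posed onto one detected skeleton."""

    person_id: str
    frame_index: int
    template: BodyTemplate
    posed_vertices: np.ndarray  # V x 3 world
    bone_transforms: dict[str, RigidTransform]
    scale: float
    residuals: dict[int, float] = field(default_factory=dict)  # joint -> meters

    def __post_init__(self) -> None:
        if not (0.5 <= self.scale <= 2.0):
            raise ValueError(f"implausible body scale {self.scale:.3f}")


@dataclass
class SubMesh:
    """Sub-mesh induced by a vertex subset, with reindexed faces."""

    vertices: np.ndarray
    faces: np.ndarray
    source_indices: np.ndarray  # original vertex index per sub-mesh vertex
    uv: np.ndarray | None = None


def _ellipsoid(center, semi_axes, axis=None, count=(10, 8)) -> trimesh.Trimesh:
    """UV-sphere stretched to semi_axes; optionally aligned so local z → axis."""
    m = trimesh.creation.uv_sphere(radius=1.0, count=count)
    verts = m.vertices * np.asarray(semi_axes)
    if axis is not None:
        z = np.array([0.0, 0.0, 1.0])
        a = np.asarray(axis, dtype=float)
        a = a / np.linalg.norm(a)
        R = _minimal_rotation(z, a)
        verts = verts @ R.T
    return trimesh.Trimesh(verts + np.asarray(center), m.faces, process=False)


def _minimal_rotation(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Smallest rotation taking unit vector src to unit vector dst."""
    v = np.cross(src, dst)
    c = float(np.dot(src, dst))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antipodal: rotate pi about any axis orthogonal to src
        axis = np.cross(src, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-6:
            axis = np.cross(src, [0.0, 1.0, 0.0])
        axis = axis / np.linalg.norm(axis)
        K = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        return np.eye(3) + 2.0 * K @ K
    K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + K + K @ K / (1.0 + c)


def build_template(height: float = 1.7, girth: float = 1.0) -> BodyTemplate:
    """Construct the procedural mannequin. Deterministic for fixed inputs.

    ``girth`` scales segment radii (not lengths); the head is a three-axis
    ellipsoid whose frontal patch (outward normal within 75° of the facing
    direction) is labeled as the face.
    """
    if not (1.2 <= height <= 2.2):
        raise ValueError(f"height {height} outside plausible range [1.2, 2.2]")
    h = height
    joints = canonical_joints(h)

    parts: list[tuple[str, trimesh.Trimesh]] = []

    def limb(name: str, r: float) -> None:
        _, _, pj, cj = BONES[BONE_NAMES.index(name)]
        p0, p1 = _joint_pos(joints, pj), _joint_pos(joints, cj)
        mid, d = 0.5 * (p0 + p1), p1 - p0
        L = np.linalg.norm(d)
        parts.append(
            (name, _ellipsoid(mid, (r * girth, r * girth, 0.5 * L + 0.3 * r), d))
        )

    # torso: flattened ellipsoid spanning pelvis→neck
    p0, p1 = _joint_pos(joints, PELVIS), _joint_pos(joints, NECK)
    mid, d = 0.5 * (p0 + p1), p1 - p0
    L = np.linalg.norm(d)
    parts.append(
        ("torso", _ellipsoid(mid, (0.16 * h * girth, 0.09 * h * girth, 0.62 * L), d))
    )
    # head: three-axis ellipsoid between neck and crown, finer tessellation
    head_center = np.array([0.0, 0.0, 0.92 * h])
    head_axes = (0.055 * h * girth, 0.068 * h * girth, 0.078 * h)
    parts.append(("head", _ellipsoid(head_center, head_axes, count=(14, 12))))
    for name, r in [
        ("left_upper_arm", 0.035 * h),
        ("left_forearm", 0.03 * h),
        ("right_upper_arm", 0.035 * h),
        ("right_forearm", 0.03 * h),
        ("left_thigh", 0.055 * h),
        ("left_shin", 0.04 * h),
        ("right_thigh", 0.055 * h),
        ("right_shin", 0.04 * h),
    ]:
        limb(name, r)

    verts_list, faces_list, bone_idx, labels = [], [], [], {}
    offset = 0
    for name, mesh in parts:
        n = len(mesh.vertices)
        verts_list.append(np.asarray(mesh.vertices))
        faces_list.append(np.asarray(mesh.faces) + offset)
        bone_idx.append(np.full(n, BONE_NAMES.index(name)))
        labels.setdefault(name, []).append(np.arange(offset, offset + n))
        offset += n
    vertices = np.vstack(verts_list)
    faces = np.vstack(faces_list)
    bone_of_vertex = np.concatenate(bone_idx)
    labels = {k: np.concatenate(v) for k, v in labels.items()}

    # frontal face patch: head triangles whose outward normal leans forward
    head_set = set(labels["head"].tolist())
    head_faces = faces[np.all(np.isin(faces, labels["head"]), axis=1)]
    tri = vertices[head_faces]
    n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    n /= np.linalg.norm(n, axis=1, keepdims=True)
    centroids = tri.mean(axis=1)
    outward = np.sign(np.sum(n * (centroids - head_center), axis=1))[:, None]
    n = n * outward
    frontal = head_faces[n @ FACING >= FACE_NORMAL_MIN]
    face_patch = np.unique(frontal)
    assert set(face_patch.tolist()) < head_set

    # planar UVs: x → u, z → v over the patch's bounding box
    fp = vertices[face_patch]
    lo = fp[:, [0, 2]].min(axis=0)
    hi = fp[:, [0, 2]].max(axis=0)
    face_uv = (fp[:, [0, 2]] - lo) / np.maximum(hi - lo, 1e-12)

    return BodyTemplate(
        vertices=vertices,
        faces=faces,
        joint_positions=joints,
        bone_of_vertex=bone_of_vertex,
        labels=labels,
        face_patch=face_patch,
        face_uv=face_uv,
        height=height,
    )


# ---------------------------------------------------------------------------
# fitting


_MIN_VALID_JOINTS = 8


def fit_body(
    template: BodyTemplate, skeleton: Skeleton3D, person_id: str | None = None
) -> FittedBody:
    """Pose the template onto a detected 3D skeleton.

    Three stages: (1) global scale from the median ratio of valid bone
    lengths, (2) root alignment of the torso joints by Kabsch, (3) per-bone
    rotations aligning canonical bone directions to detected ones, propagated
    down the kinematic tree (a bone whose distal joint is missing inherits its
    parent's rotation). Residuals report posed-versus-detected joint
    distances in meters.
    """
    valid = skeleton.valid
    if valid.sum() < _MIN_VALID_JOINTS or not all(valid[j] for j in TORSO_JOINTS):
        raise ValueError(
            f"fit rejected: {int(valid.sum())} valid joints "
            f"(need >= {_MIN_VALID_JOINTS} incl. both shoulders and hips)"
        )
    canon = template.joint_positions
    target = skeleton.joints

    def endpoint_valid(ep: tuple) -> bool:
        return all(valid[j] for j in ep)

    ratios = []
    for _, _, pj, cj in BONES:
        if endpoint_valid(pj) and endpoint_valid(cj):
            c_len = np.linalg.norm(_joint_pos(canon, cj) - _joint_pos(canon, pj))
            t_len = np.linalg.norm(_joint_pos(target, cj) - _joint_pos(target, pj))
            if c_len > 1e-9:
                ratios.append(t_len / c_len)
    s = float(np.median(ratios)) if ratios else 1.0
    s = min(max(s, 0.5), 2.0)

    torso_ids = list(TORSO_JOINTS)
    root = kabsch(s * canon[torso_ids], target[torso_ids])

    bone_R: dict[str, np.ndarray] = {}
    joint_world: dict[tuple, np.ndarray] = {}
    pelvis_can = _joint_pos(canon, PELVIS)
    joint_world[PELVIS] = root.apply(s * pelvis_can)

    for name, parent, pj, cj in BONES:
        R_par = root.rotation if parent is None else bone_R[parent]
        if pj not in joint_world:
            # anchor distal chains at the detected parent joint when available
            if endpoint_valid(pj):
                joint_world[pj] = _joint_pos(target, pj)
            else:
                par_bone = BONES[BONE_NAMES.index(parent)]
                anchor_can, anchor_world = _joint_pos(canon, par_bone[2]), joint_world[par_bone[2]]
                joint_world[pj] = anchor_world + R_par @ (
                    s * (_joint_pos(canon, pj) - anchor_can)
                )
        d0 = _joint_pos(canon, cj) - _joint_pos(canon, pj)
        d0 = d0 / np.linalg.norm(d0)
        if endpoint_valid(cj):
            d1 = _joint_pos(target, cj) - joint_world[pj]
            nrm = np.linalg.norm(d1)
            if nrm > 1e-9:
                d1 = d1 / nrm
                R_b = _minimal_rotation(R_par @ d0, d1) @ R_par
            else:
                R_b = R_par
        else:
            R_b = R_par  # keep parent rotation for unobserved distal bones
        bone_R[name] = R_b
        joint_world[cj] = joint_world[pj] + R_b @ (
            s * (_joint_pos(canon, cj) - _joint_pos(canon, pj))
        )

    transforms = {}
    for name, _, pj, _ in BONES:
        R_b = bone_R[name]
        anchor_can = _joint_pos(canon, pj)
        t_b = joint_world[pj] - R_b @ (s * anchor_can)
        transforms[name] = RigidTransform(R_b, t_b)

    posed = np.empty_like(template.vertices)
    for bi, name in enumerate(BONE_NAMES):
        sel = template.bone_of_vertex == bi
        posed[sel] = transforms[name].apply(s * template.vertices[sel])

    # posed joint positions for residuals: each joint carried by its bone
    residuals = {}
    posed_joints = _pose_joints(canon, s, transforms)
    for j in range(N_JOINTS):
        if valid[j]:
            residuals[j] = float(np.linalg.norm(posed_joints[j] - target[j]))

    return FittedBody(
        person_id=person_id or skeleton.person_id,
        frame_index=skeleton.frame_index,
        template=template,
        posed_vertices=posed,
        bone_transforms=transforms,
        scale=s,
        residuals=residuals,
    )


def _bone_of_joint(j: int) -> str:
    for name, _, pj, cj in BONES:
        if j in cj:
            return name
    for name, _, pj, cj in reversed(BONES):
        if j in pj:
            return name
    return "torso"


def _pose_joints(canon, s, transforms) -> np.ndarray:
    out = np.empty_like(canon)
    for j in range(canon.shape[0]):
        name = _bone_of_joint(j)
        out[j] = transforms[name].apply(s * canon[j])
    return out


def posed_joint_positions(body: FittedBody) -> np.ndarray:
    return _pose_joints(body.template.joint_positions, body.scale, body.bone_transforms)


# ---------------------------------------------------------------------------
# extraction


def _induced_submesh(
    vertices: np.ndarray, faces: np.ndarray, keep: np.ndarray, uv: np.ndarray | None = None
) -> SubMesh:
    keep = np.asarray(keep)
    mask = np.zeros(len(vertices), dtype=bool)
    mask[keep] = True
    fsel = faces[np.all(mask[faces], axis=1)]
    remap = -np.ones(len(vertices), dtype=int)
    remap[keep] = np.arange(len(keep))
    return SubMesh(
        vertices=vertices[keep].copy(),
        faces=remap[fsel],
        source_indices=keep.copy(),
        uv=uv,
    )


def extract_head(body: FittedBody) -> SubMesh:
    """Posed head segment (vertices + induced triangles)."""
    return _induced_submesh(
        body.posed_vertices, body.template.faces, body.template.labels["head"]
    )


def extract_face(body: FittedBody) -> SubMesh:
    """Posed frontal face patch with its UV parameterization."""
    return _induced_submesh(
        body.posed_vertices,
        body.template.faces,
        body.template.face_patch,
        uv=body.template.face_uv,
    )


def canonical_face(template: BodyTemplate) -> SubMesh:
    return _induced_submesh(
        template.vertices, template.faces, template.face_patch, uv=template.face_uv
    )


# ---------------------------------------------------------------------------
# I/O: admit an externally supplied (e.g. statistical) body mesh


def save_template(template: BodyTemplate, mesh_path, labels_path) -> None:
    trimesh.Trimesh(template.vertices, template.faces, process=False).export(
        str(mesh_path)
    )
    doc = {
        "head": [int(i) for i in template.labels["head"]],
        "face": [int(i) for i in template.face_patch],
        "bone_of_vertex": [int(i) for i in template.bone_of_vertex],
        "labels": {k: [int(i) for i in v] for k, v in template.labels.items()},
        "joint_positions": template.joint_positions.tolist(),
        "face_uv": template.face_uv.tolist(),
        "height": template.height,
    }
    with open(labels_path, "w") as fh:
        json.dump(doc, fh)


def load_template(mesh_path, labels_path) -> BodyTemplate:
    mesh = trimesh.load(str(mesh_path), process=False)
    with open(labels_path) as fh:
        doc = json.load(fh)
    labels = {k: np.asarray(v, dtype=int) for k, v in doc.get("labels", {}).items()}
    if "head" not in labels:
        labels["head"] = np.asarray(doc["head"], dtype=int)
    face_patch = np.asarray(doc["face"], dtype=int)
    face_uv = np.asarray(
        doc.get("face_uv", np.zeros((len(face_patch), 2))), dtype=float
    )
    return BodyTemplate(
        vertices=np.asarray(mesh.vertices, dtype=float),
        faces=np.asarray(mesh.faces, dtype=int),
        joint_positions=np.asarray(doc["joint_positions"], dtype=float),
        bone_of_vertex=np.asarray(doc["bone_of_vertex"], dtype=int),
        labels=labels,
        face_patch=face_patch,
        face_uv=face_uv,
        height=float(doc.get("height", 1.7)),
    )
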