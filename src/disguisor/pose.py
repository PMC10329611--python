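"""Multi-view 2D keypoint fusion into 3D skeletons, plus temporal smoothing.

The learned volumetric 2D→3D fusion used in marker-less OR capture systems is
replaced here by a deterministic geometric equivalent: detections are grouped
across views by symmetric epipolar distance and each joint is triangulated by
linear least squares (DLT). Externally computed 3D poses can also be imported
from JSON, bypassing this stage entirely.

Joints follow COCO-17 order: nose, eyes, ears, shoulders, elbows, wrists,
hips, knees, ankles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .geometry import CameraModel, project_many

__all__ = [
    "COCO_JOINTS",
    "Keypoints2D",
    "Skeleton3D",
    "PoseTrack",
    "FusionParams",
    "associate_across_views",
    "triangulate_skeleton",
    "track_identities",
    "smooth_tracks",
    "load_keypoints",
    "save_keypoints",
    "load_skeletons",
    "save_skeletons",
]

COCO_JOINTS = (
    "nose", "left_eye", "right_eye", "left_ear", "right_ear",
    "left_shoulder", "right_shoulder", "left_elbow", "right_elbow",
    "left_wrist", "right_wrist", "left_hip", "right_hip",
    "left_knee", "right_knee", "left_ankle", "right_ankle",
)
N_JOINTS = 17

LEFT_SHOULDER, RIGHT_SHOULDER = 5, 6
LEFT_HIP, RIGHT_HIP = 11, 12
TORSO_JOINTS = (LEFT_SHOULDER, RIGHT_SHOULDER, LEFT_HIP, RIGHT_HIP)


@dataclass
class Keypoints2D:
    """One person detection in one view: 17 joints of (u, v, confidence)."""

    camera_id: str
    frame_index: int
    joints: np.ndarray  # 17 x 3
    person_hint: str | None = None

    def __post_init__(self) -> None:
        self.joints = np.asarray(self.joints, dtype=float).reshape(N_JOINTS, 3)
        conf = self.joints[:, 2]
        if np.any((conf < 0) | (conf > 1)):
            raise ValueError("confidences must lie in [0, 1]")


@dataclass
class Skeleton3D:
    """Fused per-person 3D joints for one frame."""

    person_id: str
    frame_index: int
    joints: np.ndarray  # 17 x 3, world meters; rows for invalid joints are NaN
    valid: np.ndarray  # 17 bool
    support: np.ndarray  # 17 int, number of contributing views

    def __post_init__(self) -> None:
        self.joints = np.asarray(self.joints, dtype=float).reshape(N_JOINTS, 3)
        self.valid = np.asarray(self.valid, dtype=bool).reshape(N_JOINTS)
        self.support = np.asarray(self.support, dtype=int).reshape(N_JOINTS)
        if not np.all(np.isfinite(self.joints[self.valid])):
            raise ValueError("valid joints must be finite")

    @property
    def root(self) -> np.ndarray:
        """Pelvis midpoint (mean of valid hip joints)."""
        hips = [j for j in (LEFT_HIP, RIGHT_HIP) if self.valid[j]]
        if hips:
            return self.joints[hips].mean(axis=0)
        return np.nanmean(np.where(self.valid[:, None], self.joints, np.nan), axis=0)


@dataclass
class PoseTrack:
    """Ordered per-person sequence of skeletons; frame gaps allowed."""

    person_id: str
    skeletons: list[Skeleton3D] = field(default_factory=list)

    def __post_init__(self) -> None:
        idx = [s.frame_index for s in self.skeletons]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("frame indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.skeletons)


@dataclass
class FusionParams:
    """Gates for association, triangulation and tracking.

    Defaults are conservative: exact-pass on noise-free synthetic scenes.
    """

    c_min: float = 0.3  # minimum keypoint confidence to use a view
    tau_epi: float = 15.0  # px, epipolar gate for cross-view association
    r_max: float = 10.0  # px, max mean reprojection error per joint
    d_track: float = 0.5  # m, root-distance gate for frame-to-frame tracking


# ---------------------------------------------------------------------------
# epipolar association


def _fundamental_matrix(cam_a: CameraModel, cam_b: CameraModel) -> np.ndarray:
    """F such that x_b^T F x_a = 0 for corresponding pixels."""
    rel = cam_b.extrinsic.compose(cam_a.extrinsic.inverse())  # a-cam -> b-cam
    R, t = rel.rotation, rel.translation
    tx = np.array([[0, -t[2], t[1]], [t[2], 0, -t[0]], [-t[1], t[0], 0]])
    Ka_inv = np.linalg.inv(cam_a.intrinsic_matrix)
    Kb_inv_T = np.linalg.inv(cam_b.intrinsic_matrix).T
    return Kb_inv_T @ tx @ R @ Ka_inv


def _sym_epipolar_cost(
    det_a: Keypoints2D, det_b: Keypoints2D, F: np.ndarray, c_min: float
) -> float:
    """Mean symmetric point-to-epipolar-line distance over shared confident joints."""
    mask = (det_a.joints[:, 2] >= c_min) & (det_b.joints[:, 2] >= c_min)
    if not mask.any():
        return np.inf
    xa = np.column_stack([det_a.joints[mask, :2], np.ones(mask.sum())])
    xb = np.column_stack([det_b.joints[mask, :2], np.ones(mask.sum())])
    la = xa @ F.T  # epipolar lines in image b
    lb = xb @ F  # epipolar lines in image a
    d_b = np.abs(np.sum(xb * la, axis=1)) / np.hypot(la[:, 0], la[:, 1])
    d_a = np.abs(np.sum(xa * lb, axis=1)) / np.hypot(lb[:, 0], lb[:, 1])
    return float(np.mean(0.5 * (d_a + d_b)))


def associate_across_views(
    detections: list[Keypoints2D],
    cameras: list[CameraModel],
    params: FusionParams | None = None,
) -> list[list[Keypoints2D]]:
    """Group per-view detections into per-person sets.

    Greedy agglomeration on the mean symmetric epipolar distance: candidate
    cross-view pairs are merged in order of increasing cost, subject to the
    gate ``tau_epi`` and the constraint of at most one detection per camera
    per group. Groups spanning fewer than two views are discarded.
    """
    params = params or FusionParams()
    cam_by_id = {c.id: c for c in cameras}
    cam_ids_present = {d.camera_id for d in detections}
    if len(cam_ids_present) >= 2 and len(cam_by_id) < 2:
        raise ValueError("association requires at least two calibrated cameras")

    F_cache: dict[tuple[str, str], np.ndarray] = {}

    def fundamental(a: str, b: str) -> np.ndarray:
        key = (a, b)
        if key not in F_cache:
            F_cache[key] = _fundamental_matrix(cam_by_id[a], cam_by_id[b])
        return F_cache[key]

    pairs = []
    for i, da in enumerate(detections):
        for j in range(i + 1, len(detections)):
            db = detections[j]
            if da.camera_id == db.camera_id:
                continue
            cost = _sym_epipolar_cost(
                da, db, fundamental(da.camera_id, db.camera_id), params.c_min
            )
            if cost <= params.tau_epi:
                pairs.append((cost, i, j))
    pairs.sort(key=lambda p: (p[0], p[1], p[2]))

    parent = list(range(len(detections)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    members: dict[int, list[int]] = {i: [i] for i in range(len(detections))}
    for _, i, j in pairs:
        ri, rj = find(i), find(j)
        if ri == rj:
            continue
        cams_i = {detections[k].camera_id for k in members[ri]}
        cams_j = {detections[k].camera_id for k in members[rj]}
        if cams_i & cams_j:
            continue  # would put two detections of one camera in a group
        parent[rj] = ri
        members[ri].extend(members.pop(rj))

    groups = []
    for root, idxs in members.items():
        if find(root) != root:
            continue
        idxs = sorted(idxs)
        group = [detections[k] for k in idxs]
        if len({d.camera_id for d in group}) >= 2:
            groups.append((idxs[0], group))
    groups.sort(key=lambda g: g[0])  # deterministic: first detection index
    return [g for _, g in groups]


# ---------------------------------------------------------------------------
# triangulation


def _dlt_point(uvs: np.ndarray, mats: list[np.ndarray]) -> np.ndarray:
    """Linear triangulation of one point from >= 2 views."""
    rows = []
    for (u, v), P in zip(uvs, mats):
        rows.append(u * P[2] - P[0])
        rows.append(v * P[2] - P[1])
    A = np.vstack(rows)
    _, _, vt = np.linalg.svd(A)
    X = vt[-1]
    return X[:3] / X[3]


def triangulate_skeleton(
    group: list[Keypoints2D],
    cameras: list[CameraModel],
    params: FusionParams | None = None,
    person_id: str = "p0",
) -> Skeleton3D:
    """Triangulate each joint of a cross-view detection group by DLT.

    Joints observed confidently in fewer than two views are invalid. A joint
    whose mean reprojection error exceeds ``r_max`` is re-solved once after
    dropping the single worst view; if it still fails, it is marked invalid.
    Raises ``ValueError`` if every joint ends up invalid.
    """
    params = params or FusionParams()
    cam_by_id = {c.id: c for c in cameras}
    if len({d.camera_id for d in group}) < 2:
        raise ValueError("triangulation group must span >= 2 views")
    frame_index = group[0].frame_index

    joints = np.full((N_JOINTS, 3), np.nan)
    valid = np.zeros(N_JOINTS, dtype=bool)
    support = np.zeros(N_JOINTS, dtype=int)

    for j in range(N_JOINTS):
        obs = [
            (d.joints[j, :2], cam_by_id[d.camera_id])
            for d in group
            if d.joints[j, 2] >= params.c_min
        ]
        if len(obs) < 2:
            continue

        def solve(observations):
            uvs = np.array([uv for uv, _ in observations])
            mats = [c.projection_matrix for _, c in observations]
            X = _dlt_point(uvs, mats)
            errs = []
            for (uv, cam) in observations:
                puv, _, ok = project_many(cam, X[None])
                errs.append(np.linalg.norm(puv[0] - uv) if ok[0] else np.inf)
            return X, np.array(errs)

        X, errs = solve(obs)
        if errs.mean() > params.r_max:
            if len(obs) > 2:
                worst = int(np.argmax(errs))
                obs2 = [o for k, o in enumerate(obs) if k != worst]
                X2, errs2 = solve(obs2)
                if errs2.mean() <= params.r_max:
                    joints[j], valid[j], support[j] = X2, True, len(obs2)
            continue
        joints[j], valid[j], support[j] = X, True, len(obs)

    if not valid.any():
        raise ValueError("all joints invalid; skeleton rejected")
    return Skeleton3D(person_id, frame_index, joints, valid, support)


# ---------------------------------------------------------------------------
# tracking and smoothing


def track_identities(
    skeletons_per_frame: dict[int, list[Skeleton3D]],
    params: FusionParams | None = None,
) -> list[PoseTrack]:
    """Link skeletons over time by greedy nearest-root matching.

    Matches each frame's skeletons to active tracks when the root distance is
    below ``d_track``; unmatched skeletons start new tracks.
    """
    params = params or FusionParams()
    tracks: list[list[Skeleton3D]] = []
    last_root: list[np.ndarray] = []
    for fi in sorted(skeletons_per_frame):
        skels = skeletons_per_frame[fi]
        cands = []
        for ti, root in enumerate(last_root):
            for si, s in enumerate(skels):
                d = float(np.linalg.norm(s.root - root))
                if d <= params.d_track:
                    cands.append((d, ti, si))
        cands.sort()
        used_t: set[int] = set()
        used_s: set[int] = set()
        for d, ti, si in cands:
            if ti in used_t or si in used_s:
                continue
            tracks[ti].append(skels[si])
            last_root[ti] = skels[si].root
            used_t.add(ti)
            used_s.add(si)
        for si, s in enumerate(skels):
            if si not in used_s:
                tracks.append([s])
                last_root.append(s.root)
    out = []
    for ti, seq in enumerate(tracks):
        pid = f"person_{ti}"
        out.append(
            PoseTrack(
                pid,
                [
                    Skeleton3D(pid, s.frame_index, s.joints, s.valid, s.support)
                    for s in seq
                ],
            )
        )
    return out


def smooth_tracks(
    tracks: list[PoseTrack], gap_max: int = 10, window: int = 5
) -> list[PoseTrack]:
    """Fill short gaps by linear interpolation, then moving-average each joint.

    Gaps of at most ``gap_max`` consecutive missing frames are linearly
    interpolated between the flanking valid frames; longer gaps stay missing.
    The centered moving average (odd ``window``) runs over valid samples only,
    shrinking symmetrically at track ends.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if gap_max < 0:
        raise ValueError("gap_max must be >= 0")
    out = []
    for track in tracks:
        if not track.skeletons:
            out.append(PoseTrack(track.person_id, []))
            continue
        frames = [s.frame_index for s in track.skeletons]
        f0, f1 = frames[0], frames[-1]
        T = f1 - f0 + 1
        pos = np.full((T, N_JOINTS, 3), np.nan)
        present = np.zeros(T, dtype=bool)
        for s in track.skeletons:
            t = s.frame_index - f0
            present[t] = True
            pos[t, s.valid] = s.joints[s.valid]

        filled = pos.copy()
        for j in range(N_JOINTS):
            vt = np.nonzero(np.all(np.isfinite(pos[:, j]), axis=1))[0]
            for a, b in zip(vt, vt[1:]):
                gap = b - a - 1
                if 0 < gap <= gap_max:
                    w = (np.arange(1, gap + 1) / (gap + 1))[:, None]
                    filled[a + 1 : b, j] = (1 - w) * pos[a, j] + w * pos[b, j]

        smoothed = filled.copy()
        half = window // 2
        for j in range(N_JOINTS):
            vt = np.nonzero(np.all(np.isfinite(filled[:, j]), axis=1))[0]
            if len(vt) == 0:
                continue
            vals = filled[vt, j]
            for k, t in enumerate(vt):
                # shrink symmetrically near track ends so the average stays
                # centered (unbiased for constant-velocity motion)
                he = min(half, k, len(vt) - 1 - k)
                smoothed[t, j] = vals[k - he : k + he + 1].mean(axis=0)

        skels = []
        for t in range(T):
            valid = np.all(np.isfinite(smoothed[t]), axis=1)
            if not (present[t] or valid.any()):
                continue
            if not valid.any():
                continue
            support = np.zeros(N_JOINTS, dtype=int)
            orig = next(
                (s for s in track.skeletons if s.frame_index == f0 + t), None
            )
            if orig is not None:
                support = orig.support
            else:
                support[valid] = 2  # interpolated joints rest on two flanking frames
            skels.append(
                Skeleton3D(track.person_id, f0 + t, smoothed[t], valid, support)
            )
        out.append(PoseTrack(track.person_id, skels))
    return out


# ---------------------------------------------------------------------------
# I/O


def save_keypoints(detections: list[Keypoints2D], path) -> None:
    doc = [
        {
            "camera_id": d.camera_id,
            "frame_index": d.frame_index,
            "person_hint": d.person_hint,
            "keypoints": [float(x) for x in d.joints.ravel()],
        }
        for d in detections
    ]
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_keypoints(path) -> list[Keypoints2D]:
    with open(path) as fh:
        doc = json.load(fh)
    return [
        Keypoints2D(
            camera_id=str(d["camera_id"]),
            frame_index=int(d["frame_index"]),
            joints=np.asarray(d["keypoints"], dtype=float).reshape(N_JOINTS, 3),
            person_hint=d.get("person_hint"),
        )
        for d in doc
    ]


def save_skeletons(tracks: list[PoseTrack], path) -> None:
    doc = []
    for tr in tracks:
        for s in tr.skeletons:
            doc.append(
                {
                    "person_id": tr.person_id,
                    "frame_index": s.frame_index,
                    "joints": [
                        [float(x) for x in row] if v else None
                        for row, v in zip(s.joints, s.valid)
                    ],
                    "support": [int(x) for x in s.support],
                }
            )
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_skeletons(path) -> list[PoseTrack]:
    """Import externally computed 3D poses (e.g. a learned multi-view fuser)."""
    with open(path) as fh:
        doc = json.load(fh)
    by_person: dict[str, list[Skeleton3D]] = {}
    for rec in doc:
        joints = np.full((N_JOINTS, 3), np.nan)
        valid = np.zeros(N_JOINTS, dtype=bool)
        for j, row in enumerate(rec["joints"]):
            if row is not None:
                joints[j] = row
                valid[j] = True
        support = np.asarray(rec.get("support", [2] * N_JOINTS), dtype=int)
        by_person.setdefault(str(rec["person_id"]), []).append(
            Skeleton3D(str(rec["person_id"]), int(rec["frame_index"]), joints, valid, support)
        )
    return [
        PoseTrack(pid, sorted(skels, key=lambda s: s.frame_index))
        for pid, skels in sorted(by_person.items())
    ]
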