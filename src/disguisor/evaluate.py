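"""Detection metrics for multi-view face anonymization.

Per-camera recall/precision/F1 at an IoU threshold, plus the scene-level
*holistic recall*: a face instance counts as detected only if it was matched
in every camera view where it is at least partially visible — a miss in any
single view breaches that person's anonymity, so the whole instance counts
as missed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity

__all__ = [
    "GTFace",
    "Prediction",
    "EvalReport",
    "iou",
    "match_frame",
    "holistic_recall",
    "summarize",
    "ssim",
    "load_gt",
    "save_gt",
    "load_predictions",
    "save_predictions",
]

Box = tuple[float, float, float, float]  # x, y, w, h


@dataclass(frozen=True)
class GTFace:
    person_id: str
    frame_index: int
    camera_id: str
    bbox: Box
    partially_visible: bool = True

    def __post_init__(self) -> None:
        if self.bbox[2] <= 0 or self.bbox[3] <= 0:
            raise ValueError("ground-truth box must have positive extent")


@dataclass(frozen=True)
class Prediction:
    person_id: str
    frame_index: int
    camera_id: str
    bbox: Box


@dataclass
class EvalReport:
    """Scene evaluation at IoU threshold ``tau``."""

    tau: float
    per_camera: pd.DataFrame  # index camera_id; recall, precision, f1, counts
    holistic_recall: float | None
    n_gt: int
    n_pred: int
    n_matched: int
    matches: dict = field(default_factory=dict, repr=False)

    def to_csv(self, path) -> None:
        df = self.per_camera.copy()
        df.loc["__scene__"] = {
            "recall": np.nan,
            "precision": np.nan,
            "f1": np.nan,
            "n_gt": self.n_gt,
            "n_pred": self.n_pred,
            "n_matched": self.n_matched,
        }
        df["holistic_recall"] = np.nan
        df.loc["__scene__", "holistic_recall"] = (
            np.nan if self.holistic_recall is None else self.holistic_recall
        )
        df["tau"] = self.tau
        df.to_csv(path)

    def __str__(self) -> str:
        lines = [f"Evaluation @ IoU {self.tau:g}", str(self.per_camera.round(4))]
        hr = "n/a" if self.holistic_recall is None else f"{self.holistic_recall:.4f}"
        lines.append(f"holistic recall: {hr}")
        return "\n".join(lines)


def iou(a: Box, b: Box) -> float:
    """Intersection-over-union of two axis-aligned (x, y, w, h) boxes."""
    ax, ay, aw, ah = a
    bx, by, bw, bh = b
    if aw <= 0 or ah <= 0 or bw <= 0 or bh <= 0:
        raise ValueError("boxes must have positive width and height")
    ix = max(0.0, min(ax + aw, bx + bw) - max(ax, bx))
    iy = max(0.0, min(ay + ah, by + bh) - max(ay, by))
    inter = ix * iy
    union = aw * ah + bw * bh - inter
    # clamp: floating-point roundoff can stray marginally outside [0, 1]
    return min(max(inter / union, 0.0), 1.0)


def match_frame(
    gt: list[Box], pred: list[Box], tau: float = 0.4
) -> list[tuple[int, int]]:
    """Greedy one-to-one matching of boxes from one (frame, camera).

    Pairs are taken in order of descending IoU and kept iff IoU >= tau; ties
    break deterministically toward the lowest GT index, then lowest
    prediction index. Returns (gt_index, pred_index) pairs.
    """
    cands = []
    for i, g in enumerate(gt):
        for j, p in enumerate(pred):
            v = iou(g, p)
            if v >= tau:
                cands.append((-v, i, j))
    cands.sort()
    used_g: set[int] = set()
    used_p: set[int] = set()
    out = []
    for _, i, j in cands:
        if i in used_g or j in used_p:
            continue
        out.append((i, j))
        used_g.add(i)
        used_p.add(j)
    return out


def holistic_recall(
    gt: list[GTFace], matched: set[tuple[str, int, str]]
) -> float | None:
    """Scene-level recall over (person, frame) instances.

    ``matched`` holds (person_id, frame_index, camera_id) triples where the
    instance's GT box was matched. An instance counts as detected only if
    matched in every camera where it is at least partially visible; the
    denominator is all instances visible in >= 1 camera. Returns None when
    the denominator is empty.
    """
    visible_views: dict[tuple[str, int], set[str]] = {}
    for g in gt:
        if g.partially_visible:
            visible_views.setdefault((g.person_id, g.frame_index), set()).add(
                g.camera_id
            )
    if not visible_views:
        return None
    hits = 0
    for (pid, fi), cams in visible_views.items():
        if all((pid, fi, c) in matched for c in cams):
            hits += 1
    return hits / len(visible_views)


def summarize(
    gt: list[GTFace], preds: list[Prediction], tau: float = 0.4
) -> EvalReport:
    """Per-camera recall/precision/F1 plus holistic recall.

    Matching is one-to-one greedy per (frame, camera) against the partially
    visible GT boxes. Precision is reported as NaN when there are no
    predictions for a camera; F1 is 0 in degenerate cases.
    """
    cameras = sorted(
        {g.camera_id for g in gt} | {p.camera_id for p in preds}
    )
    matched: set[tuple[str, int, str]] = set()
    per_cam: dict[str, dict] = {
        c: {"n_gt": 0, "n_pred": 0, "n_matched": 0} for c in cameras
    }

    keys = sorted(
        {(g.frame_index, g.camera_id) for g in gt}
        | {(p.frame_index, p.camera_id) for p in preds}
    )
    for fi, cam in keys:
        g_here = [g for g in gt if g.frame_index == fi and g.camera_id == cam and g.partially_visible]
        p_here = [p for p in preds if p.frame_index == fi and p.camera_id == cam]
        pairs = match_frame([g.bbox for g in g_here], [p.bbox for p in p_here], tau)
        per_cam[cam]["n_gt"] += len(g_here)
        per_cam[cam]["n_pred"] += len(p_here)
        per_cam[cam]["n_matched"] += len(pairs)
        for gi, _ in pairs:
            g = g_here[gi]
            matched.add((g.person_id, g.frame_index, g.camera_id))

    rows = {}
    for cam, c in per_cam.items():
        recall = c["n_matched"] / c["n_gt"] if c["n_gt"] else np.nan
        precision = c["n_matched"] / c["n_pred"] if c["n_pred"] else np.nan
        if np.isnan(recall) or np.isnan(precision) or recall + precision == 0:
            f1 = 0.0
        else:
            f1 = 2 * recall * precision / (recall + precision)
        rows[cam] = {
            "recall": recall,
            "precision": precision,
            "f1": f1,
            **c,
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    hr = holistic_recall(gt, matched)

    report = EvalReport(
        tau=tau,
        per_camera=df,
        holistic_recall=hr,
        n_gt=int(df["n_gt"].sum()) if len(df) else 0,
        n_pred=int(df["n_pred"].sum()) if len(df) else 0,
        n_matched=int(df["n_matched"].sum()) if len(df) else 0,
        matches={"matched": matched},
    )
    _assert_holistic_bound(gt, matched, hr)
    return report


def _assert_holistic_bound(gt, matched, hr) -> None:
    # holistic recall can never exceed the per-camera recall restricted to
    # instances visible in that camera
    if hr is None:
        return
    cams = {g.camera_id for g in gt if g.partially_visible}
    for cam in cams:
        vis = [g for g in gt if g.partially_visible and g.camera_id == cam]
        if not vis:
            continue
        rec = sum(
            (g.person_id, g.frame_index, cam) in matched for g in vis
        ) / len(vis)
        assert hr <= rec + 1e-12, "holistic recall exceeded a per-camera bound"


def ssim(
    a: np.ndarray,
    b: np.ndarray,
    window: int = 11,
    K1: float = 0.01,
    K2: float = 0.03,
    L: float = 255.0,
) -> float:
    """Mean structural similarity with a Gaussian window (sigma = 1.5).

    Standard constants C1 = (K1 L)^2, C2 = (K2 L)^2; inputs of equal shape,
    at least ``window`` pixels in each axis. Color images are converted to
    ITU-R 601 luma first.
    """
    if a.shape != b.shape:
        raise ValueError("images must have identical dimensions")
    if a.ndim == 3:
        a = _luma(a)
        b = _luma(b)
    if min(a.shape) < window:
        raise ValueError("images smaller than the SSIM window")
    return float(
        structural_similarity(
            a.astype(float),
            b.astype(float),
            win_size=window,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            K1=K1,
            K2=K2,
            data_range=L,
        )
    )


def _luma(img: np.ndarray) -> np.ndarray:
    return img[..., 0] * 0.299 + img[..., 1] * 0.587 + img[..., 2] * 0.114


# ---------------------------------------------------------------------------
# I/O (WIDERFACE-style per-view box annotations, serialized as JSON)


def save_gt(gt: list[GTFace], path) -> None:
    doc = [
        {
            "person_id": g.person_id,
            "frame_index": g.frame_index,
            "camera_id": g.camera_id,
            "bbox": [float(v) for v in g.bbox],
            "partially_visible": bool(g.partially_visible),
        }
        for g in gt
    ]
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_gt(path) -> list[GTFace]:
    with open(path) as fh:
        doc = json.load(fh)
    return [
        GTFace(
            person_id=str(d["person_id"]),
            frame_index=int(d["frame_index"]),
            camera_id=str(d["camera_id"]),
            bbox=tuple(d["bbox"]),
            partially_visible=bool(d.get("partially_visible", True)),
        )
        for d in doc
    ]


def save_predictions(preds: list[Prediction], path) -> None:
    doc = [
        {
            "person_id": p.person_id,
            "frame_index": p.frame_index,
            "camera_id": p.camera_id,
            "bbox": [float(v) for v in p.bbox],
        }
        for p in preds
    ]
    with open(path, "w") as fh:
        json.dump(doc, fh, sort_keys=True, indent=1)


def load_predictions(path) -> list[Prediction]:
    with open(path) as fh:
        doc = json.load(fh)
    return [
        Prediction(
            person_id=str(d["person_id"]),
            frame_index=int(d["frame_index"]),
            camera_id=str(d["camera_id"]),
            bbox=tuple(d["bbox"]),
        )
        for d in doc
    ]
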