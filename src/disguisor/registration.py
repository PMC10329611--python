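"""Rigid point-set registration of the head segment against the fused cloud.

Two stages, mirroring a coarse-to-fine strategy: annealed Gaussian
soft-assignment EM (probabilistic correspondences with a uniform outlier
floor and a closed-form weighted rigid update), then point-to-point ICP for
the final fine-tune. The EM treats the moving model points as mixture
centroids and soft-assigns every observed cloud point to them, so cloud
points that belong to other geometry (shoulders, instruments) are absorbed
by the outlier bin instead of dragging the head. Only the head segment of
the fitted body is moved; the rest of the pose is kept.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree

from .body import FittedBody
from .geometry import PointCloud, RigidTransform, kabsch

__all__ = [
    "RegistrationParams",
    "RegistrationResult",
    "crop_head_cloud",
    "register_soft",
    "register_icp",
    "refine_head",
]


@dataclass
class RegistrationParams:
    """Knobs for the head-to-cloud registration, sized for head geometry.

    ``sigma0=None`` starts the Gaussian kernel at 1.5x the median
    cloud-to-model nearest-neighbor distance (clamped below by
    ``sigma_min``), so a nearly aligned initialization is refined gently
    while a coarse one still sees a wide basin.
    """

    crop_radius: float = 0.15  # m, sphere around the estimated head center
    sigma0: float | None = None  # m, initial kernel width; None = adaptive
    anneal: float = 0.9  # multiplicative sigma schedule per EM iteration
    sigma_min: float = 0.002  # m, kernel floor
    outlier_frac: float = 0.1  # prior mass of the uniform outlier bin
    max_iter: int = 50
    tol: float = 1e-7  # max transform-entry change declaring convergence
    icp_max_iter: int = 50
    icp_tol: float = 1e-6
    d_icp: float | None = 0.03  # m, ICP correspondence gate; None disables


@dataclass
class RegistrationResult:
    """Rigid transform estimated for the moving vertices, with diagnostics."""

    transform: RigidTransform
    iterations: int
    final_rms: float
    converged: bool
    n_target_points: int
    rms_history: list[float] | None = None

    def __post_init__(self) -> None:
        if self.final_rms < 0:
            raise ValueError("RMS cannot be negative")


def crop_head_cloud(
    cloud: PointCloud, head_center: np.ndarray, radius: float
) -> PointCloud:
    """Points of ``cloud`` within ``radius`` of the estimated head center."""
    if radius <= 0:
        raise ValueError("crop radius must be positive")
    d = np.linalg.norm(cloud.points - np.asarray(head_center).reshape(3), axis=1)
    keep = d <= radius
    colors = cloud.colors[keep] if cloud.colors is not None else None
    return PointCloud(cloud.points[keep], colors)


def _as_points(target) -> np.ndarray:
    t = target.points if isinstance(target, PointCloud) else np.asarray(target, float)
    t = t.reshape(-1, 3)
    if len(t) == 0:
        raise ValueError("target cloud is empty")
    return t


def _check_moving(moving: np.ndarray) -> np.ndarray:
    m = np.asarray(moving, dtype=float).reshape(-1, 3)
    if len(m) < 3:
        raise ValueError("moving set needs >= 3 points")
    if np.linalg.matrix_rank(m - m.mean(axis=0), tol=1e-12) < 2:
        raise ValueError("moving points are collinear")
    return m


def _rms_nn(points: np.ndarray, target: np.ndarray) -> float:
    d, _ = cKDTree(target).query(points)
    return float(np.sqrt(np.mean(d**2)))


def register_soft(
    moving: np.ndarray,
    target: PointCloud | np.ndarray,
    params: RegistrationParams | None = None,
) -> RegistrationResult:
    """Annealed Gaussian soft-assignment EM registration.

    The transformed moving points act as isotropic Gaussian mixture
    centroids; the E-step computes responsibilities of each centroid for each
    target point (with a uniform outlier component over the target's bounding
    volume), and the M-step applies a closed-form weighted rigid update
    toward each centroid's responsibility-weighted virtual observation. σ
    follows the annealing schedule down to ``sigma_min``.
    """
    params = params or RegistrationParams()
    m0 = _check_moving(moving)
    t = _as_points(target)

    T = RigidTransform.identity()
    if params.sigma0 is not None:
        sigma = params.sigma0
    else:
        d0, _ = cKDTree(m0).query(t)
        sigma = max(1.5 * float(np.median(d0)), params.sigma_min)
    span = np.maximum(t.max(axis=0) - t.min(axis=0), 1e-3)
    volume = float(np.prod(span))
    converged = False
    it = 0
    for it in range(1, params.max_iter + 1):
        m = T.apply(m0)
        d2 = ((t[:, None, :] - m[None, :, :]) ** 2).sum(axis=2)  # obs x centroids
        g = np.exp(-d2 / (2.0 * sigma**2))
        floor = (
            params.outlier_frac
            / max(1.0 - params.outlier_frac, 1e-9)
            * (2.0 * np.pi * sigma**2) ** 1.5
            * len(m0)
            / volume
        )
        denom = g.sum(axis=1) + floor
        P = g / denom[:, None]
        lam = P.sum(axis=0)  # expected observations per centroid
        ok = lam > 1e-12
        if ok.sum() < 3:
            return RegistrationResult(T, it, _rms_nn(T.apply(m0), t), False, len(t))
        virtual = (P.T @ t)[ok] / lam[ok][:, None]
        try:
            step = kabsch(m[ok], virtual, weights=lam[ok])
        except ValueError:
            return RegistrationResult(T, it, _rms_nn(T.apply(m0), t), False, len(t))
        T_new = step.compose(T)
        delta = float(np.abs(T_new.matrix() - T.matrix()).max())
        T = T_new
        sigma = max(sigma * params.anneal, params.sigma_min)
        if delta < params.tol:
            converged = True
            break
    return RegistrationResult(T, it, _rms_nn(T.apply(m0), t), converged, len(t))


def register_icp(
    moving: np.ndarray,
    target: PointCloud | np.ndarray,
    params: RegistrationParams | None = None,
) -> RegistrationResult:
    """Point-to-point ICP with nearest-neighbor correspondences.

    Each target point is matched to its nearest moving sample (so unexplained
    target points beyond ``d_icp`` are dropped); the closed-form rigid update
    is accepted only while the gated RMS does not increase, which makes the
    recorded RMS history non-increasing on every input (asserted).
    """
    params = params or RegistrationParams()
    m0 = _check_moving(moving)
    t = _as_points(target)

    def correspondences(T: RigidTransform):
        m = T.apply(m0)
        d, idx = cKDTree(m).query(t)
        sel = np.ones(len(t), dtype=bool)
        if params.d_icp is not None:
            gated = d <= params.d_icp
            if gated.sum() >= 3:
                sel = gated
        return m, d, idx, sel

    T = RigidTransform.identity()
    m, d, idx, sel = correspondences(T)
    rms = float(np.sqrt(np.mean(d[sel] ** 2)))
    rms_history: list[float] = [rms]
    converged = False
    it = 0
    for it in range(1, params.icp_max_iter + 1):
        try:
            step = kabsch(m[idx[sel]], t[sel])
        except ValueError:
            return RegistrationResult(T, it, rms, False, len(t), rms_history)
        T_new = step.compose(T)
        m2, d2, idx2, sel2 = correspondences(T_new)
        rms_new = float(np.sqrt(np.mean(d2[sel2] ** 2)))
        if rms_new > rms + 1e-12:
            # correspondence churn would raise the error: keep the previous
            # estimate and stop
            converged = True
            break
        delta = float(np.abs(T_new.matrix() - T.matrix()).max())
        T, m, d, idx, sel, rms = T_new, m2, d2, idx2, sel2, rms_new
        rms_history.append(rms)
        if delta < params.icp_tol:
            converged = True
            break
    assert all(
        b <= a + 1e-12 for a, b in zip(rms_history, rms_history[1:])
    ), "ICP RMS increased between iterations"
    return RegistrationResult(T, it, rms, converged, len(t), rms_history)


def head_surface_samples(body: FittedBody) -> np.ndarray:
    """Posed head vertices plus triangle centroids (denser surface sampling
    reduces the lattice bias of point-to-point correspondences)."""
    head_idx = body.template.labels["head"]
    verts = body.posed_vertices[head_idx]
    on_head = np.all(np.isin(body.template.faces, head_idx), axis=1)
    centroids = body.posed_vertices[body.template.faces[on_head]].mean(axis=1)
    return np.vstack([verts, centroids])


def refine_head(
    body: FittedBody,
    cloud: PointCloud,
    params: RegistrationParams | None = None,
    log_path=None,
) -> tuple[FittedBody, dict]:
    """Re-anchor the head segment on the fused point cloud.

    Crops the cloud around the fitted head, runs soft-EM then ICP on a dense
    sampling of the head surface, and applies the resulting transform to the
    head-segment vertices only. An empty crop leaves the body unchanged
    (flagged in the diagnostics) so the face falls back to the
    keypoint-fitted placement.
    """
    params = params or RegistrationParams()
    head_idx = body.template.labels["head"]
    samples = head_surface_samples(body)
    center = body.posed_vertices[head_idx].mean(axis=0)
    cropped = crop_head_cloud(cloud, center, params.crop_radius)
    diag: dict = {
        "person_id": body.person_id,
        "frame_index": body.frame_index,
        "n_cropped": len(cropped),
    }
    if len(cropped) == 0:
        diag["refined"] = False
        _log(log_path, diag)
        return body, diag

    soft = register_soft(samples, cropped, params)
    icp = register_icp(soft.transform.apply(samples), cropped, params)
    total = icp.transform.compose(soft.transform)

    posed = body.posed_vertices.copy()
    posed[head_idx] = total.apply(posed[head_idx])
    transforms = dict(body.bone_transforms)
    transforms["head"] = total.compose(body.bone_transforms["head"])
    refined = replace(body, posed_vertices=posed, bone_transforms=transforms)

    diag.update(
        refined=True,
        soft_iterations=soft.iterations,
        soft_rms=soft.final_rms,
        soft_converged=soft.converged,
        icp_iterations=icp.iterations,
        icp_rms=icp.final_rms,
        icp_converged=icp.converged,
        displacement=float(
            np.linalg.norm(total.apply(samples) - samples, axis=1).max()
        ),
    )
    _log(log_path, diag)
    return refined, diag


def _log(log_path, record: dict) -> None:
    if log_path is None:
        return
    with open(log_path, "a") as fh:
        fh.write(json.dumps(record) + "\n")
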