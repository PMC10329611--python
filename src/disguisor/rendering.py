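"""Software z-buffer triangle rasterization.

Shared by the anonymizer (face masks, depth-disparity visibility) and the
synthetic-scene generator (color + depth rendering, ground-truth visibility),
so that the two occlusion definitions coincide by construction on noise-free
data.

Pixels are sampled at integer centers; depth is interpolated perspective-
correctly (linear in 1/z). Triangles with any vertex closer than the near
plane are discarded rather than clipped — adequate for scenes whose geometry
stays well in front of the cameras.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import CameraModel

__all__ = ["Raster", "rasterize_mesh", "render_color"]

_NEAR = 1e-6


@dataclass
class Raster:
    """Per-pixel rasterization output for one camera."""

    depth: np.ndarray  # H x W, meters; +inf where nothing rendered
    face_index: np.ndarray  # H x W int32; -1 where nothing rendered
    bary: np.ndarray | None = None  # H x W x 3 perspective-correct barycentric

    @property
    def mask(self) -> np.ndarray:
        return self.face_index >= 0


def rasterize_mesh(
    vertices: np.ndarray,
    faces: np.ndarray,
    camera: CameraModel,
    return_bary: bool = False,
) -> Raster:
    """Rasterize a world-frame triangle mesh into ``camera``.

    Deterministic: faces are processed in order and depth ties keep the
    earlier face. Returns per-pixel nearest depth, covering face index and
    (optionally) perspective-correct barycentric coordinates.
    """
    H, W = camera.height, camera.width
    depth_buf = np.full((H, W), np.inf)
    face_buf = np.full((H, W), -1, dtype=np.int32)
    bary_buf = np.zeros((H, W, 3)) if return_bary else None

    verts = np.asarray(vertices, dtype=float).reshape(-1, 3)
    faces = np.asarray(faces, dtype=int).reshape(-1, 3)
    cam_pts = camera.extrinsic.apply(verts)
    z = cam_pts[:, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        u = camera.fx * cam_pts[:, 0] / z + camera.cx
        v = camera.fy * cam_pts[:, 1] / z + camera.cy

    for fi, (a, b, c) in enumerate(faces):
        if z[a] <= _NEAR or z[b] <= _NEAR or z[c] <= _NEAR:
            continue
        ua, va, ub, vb, uc, vc = u[a], v[a], u[b], v[b], u[c], v[c]
        x0 = max(int(np.floor(min(ua, ub, uc))), 0)
        x1 = min(int(np.ceil(max(ua, ub, uc))), W - 1)
        y0 = max(int(np.floor(min(va, vb, vc))), 0)
        y1 = min(int(np.ceil(max(va, vb, vc))), H - 1)
        if x0 > x1 or y0 > y1:
            continue
        area = (ub - ua) * (vc - va) - (uc - ua) * (vb - va)
        if abs(area) < 1e-12:
            continue
        xs = np.arange(x0, x1 + 1)
        ys = np.arange(y0, y1 + 1)
        px, py = np.meshgrid(xs, ys)
        w0 = (ub - ua) * (py - va) - (vb - va) * (px - ua)  # opposite c
        w1 = (uc - ub) * (py - vb) - (vc - vb) * (px - ub)  # opposite a
        w2 = (ua - uc) * (py - vc) - (va - vc) * (px - uc)  # opposite b
        if area < 0:
            w0, w1, w2 = -w0, -w1, -w2
        inside = (w0 >= 0) & (w1 >= 0) & (w2 >= 0)
        if not inside.any():
            continue
        aabs = abs(area)
        b0 = w1 / aabs  # weight of vertex a
        b1 = w2 / aabs  # weight of vertex b
        b2 = w0 / aabs  # weight of vertex c
        inv_z = b0 / z[a] + b1 / z[b] + b2 / z[c]
        pix_z = 1.0 / inv_z
        rows, cols = py[inside], px[inside]
        zi = pix_z[inside]
        nearer = zi < depth_buf[rows, cols]
        if not nearer.any():
            continue
        rows, cols, zi = rows[nearer], cols[nearer], zi[nearer]
        depth_buf[rows, cols] = zi
        face_buf[rows, cols] = fi
        if return_bary:
            # perspective-correct attribute weights
            bb0 = (b0 / z[a])[inside][nearer] * zi
            bb1 = (b1 / z[b])[inside][nearer] * zi
            bb2 = (b2 / z[c])[inside][nearer] * zi
            bary_buf[rows, cols, 0] = bb0
            bary_buf[rows, cols, 1] = bb1
            bary_buf[rows, cols, 2] = bb2

    return Raster(depth_buf, face_buf, bary_buf)


def render_color(
    vertices: np.ndarray,
    faces: np.ndarray,
    face_colors: np.ndarray,
    camera: CameraModel,
    background: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Flat-shaded color + metric depth render of one mesh soup.

    ``face_colors`` is F x 3 uint8; ``background`` an optional H x W x 3 image
    used where nothing is rendered (default mid-gray). Returns (color, depth)
    with depth 0 where empty.
    """
    ras = rasterize_mesh(vertices, faces, camera)
    H, W = camera.height, camera.width
    if background is None:
        color = np.full((H, W, 3), 60, dtype=np.uint8)
    else:
        color = background.copy()
    m = ras.mask
    color[m] = np.asarray(face_colors, dtype=np.uint8)[ras.face_index[m]]
    depth = np.where(np.isfinite(ras.depth), ras.depth, 0.0)
    return color, depth
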