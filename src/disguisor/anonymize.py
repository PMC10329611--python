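"""Face replacement in 2D: rasterize the fitted 3D face into each view,
decide visibility from depth disparity, and blend a replacement texture.

A face localized in 3D is rendered into every camera. It is declared visible
in a view unless the sensor depth map undercuts the rendered mesh depth by
more than a margin ``delta`` over at least a fraction ``theta`` of its pixels
(the depth-disparity check). Visible faces are replaced by a texture warped
through the mesh's UVs and composited with Poisson image editing so the patch
inherits the target image's boundary appearance; occluded faces are left
untouched and excluded from the predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from .body import FittedBody, SubMesh, extract_face
from .geometry import CameraModel, RGBDFrame
from .rendering import rasterize_mesh

__all__ = [
    "AnonymizerParams",
    "RenderedFace",
    "FaceTexture",
    "rasterize_face",
    "visibility_check",
    "poisson_blend",
    "warp_texture",
    "apply_conventional",
    "anonymize_frame",
]


@dataclass
class AnonymizerParams:
    delta: float = 0.05  # m, depth margin before a pixel counts as occluded
    theta: float = 0.5  # occluded-pixel fraction at which the face is hidden
    dilate_px: int = 2  # blend-mask dilation for a clean Poisson seam
    pixelate_block: int = 8  # px, block size of the pixelization baseline
    blur_kernel: int = 61  # px, Gaussian kernel size of the blurring baseline


@dataclass
class RenderedFace:
    """One person's face rasterized into one camera."""

    camera_id: str
    frame_index: int
    person_id: str
    mask: np.ndarray  # H x W bool
    mesh_depth: np.ndarray  # H x W meters, valid under mask
    bbox: tuple[int, int, int, int] | None  # x, y, w, h; None if mask empty
    visible: bool = False
    occluded_fraction: float = 0.0
    bary: np.ndarray | None = None
    face_index: np.ndarray | None = None
    blend_mask: np.ndarray | None = None  # set when the face was blended

    def __post_init__(self) -> None:
        if not self.mask.any():
            if self.bbox is not None or self.visible:
                raise ValueError("empty mask implies no bbox and not visible")


@dataclass
class FaceTexture:
    """Replacement face image plus a stable per-person assignment."""

    image: np.ndarray  # h x w x 3 uint8
    name: str = "default"


def tight_bbox(mask: np.ndarray) -> tuple[int, int, int, int] | None:
    """Smallest axis-aligned rectangle (x, y, w, h) containing the mask."""
    ys, xs = np.nonzero(mask)
    if len(ys) == 0:
        return None
    return (
        int(xs.min()),
        int(ys.min()),
        int(xs.max() - xs.min() + 1),
        int(ys.max() - ys.min() + 1),
    )


def rasterize_face(
    face: SubMesh, camera: CameraModel, frame_index: int = 0, person_id: str = "p0"
) -> RenderedFace:
    """Z-buffer render of the posed face patch into one camera."""
    ras = rasterize_mesh(face.vertices, face.faces, camera, return_bary=True)
    mask = ras.mask
    depth = np.where(mask, ras.depth, 0.0)
    return RenderedFace(
        camera_id=camera.id,
        frame_index=frame_index,
        person_id=person_id,
        mask=mask,
        mesh_depth=depth,
        bbox=tight_bbox(mask),
        bary=ras.bary,
        face_index=ras.face_index,
    )


def visibility_check(
    rendered: RenderedFace,
    sensor_depth_m: np.ndarray,
    delta: float = 0.05,
    theta: float = 0.5,
) -> tuple[bool, float]:
    """Depth-disparity occlusion test.

    Over mask pixels with valid (non-zero) sensor depth, a pixel is occluded
    when the sensor sees something more than ``delta`` meters in front of the
    rendered mesh. The face is visible iff the occluded fraction stays below
    ``theta``. With no valid sensor depth under the mask the face defaults to
    visible — anonymization errs toward privacy.
    """
    if sensor_depth_m.shape != rendered.mask.shape:
        raise ValueError("depth map and mask shapes disagree")
    if not rendered.mask.any():
        raise ValueError("visibility check requires a non-empty mask")
    m = rendered.mask & (sensor_depth_m > 0)
    n_valid = int(m.sum())
    if n_valid == 0:
        return True, 0.0
    occluded = sensor_depth_m[m] < rendered.mesh_depth[m] - delta
    frac = float(occluded.sum()) / n_valid
    return frac < theta, frac


def _laplacian(img: np.ndarray) -> np.ndarray:
    """4-neighbor Laplacian with edge replication."""
    p = np.pad(img.astype(float), 1, mode="edge")
    return 4 * p[1:-1, 1:-1] - p[:-2, 1:-1] - p[2:, 1:-1] - p[1:-1, :-2] - p[1:-1, 2:]


def poisson_blend(target: np.ndarray, source: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Seamless cloning by Poisson image editing.

    Solves, per channel, the discrete Poisson equation over the mask interior
    with the source's gradient field as guidance and Dirichlet boundary values
    taken from the target (4-neighbor Laplacian, sparse direct solve). Pixels
    outside the mask are returned bit-identical to the target.
    """
    if target.shape != source.shape:
        raise ValueError("source must cover the target")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != target.shape[:2]:
        raise ValueError("mask shape mismatch")
    ys, xs = np.nonzero(mask)
    if len(ys) == 0:
        return target.copy()
    H, W = mask.shape
    if ys.min() == 0 or xs.min() == 0 or ys.max() == H - 1 or xs.max() == W - 1:
        raise ValueError("mask touches the image border; pad the image first")

    idx = -np.ones((H, W), dtype=int)
    idx[ys, xs] = np.arange(len(ys))
    n = len(ys)

    single = target.ndim == 2
    tgt = target[..., None] if single else target
    src = source[..., None] if single else source

    rows, cols, vals = [], [], []
    b_boundary = np.zeros((n, tgt.shape[2]))
    for k, (y, x) in enumerate(zip(ys, xs)):
        rows.append(k)
        cols.append(k)
        vals.append(4.0)
        for ny, nx in ((y - 1, x), (y + 1, x), (y, x - 1), (y, x + 1)):
            j = idx[ny, nx]
            if j >= 0:
                rows.append(k)
                cols.append(j)
                vals.append(-1.0)
            else:
                b_boundary[k] += tgt[ny, nx].astype(float)
    A = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))

    out = tgt.astype(float).copy()
    for c in range(tgt.shape[2]):
        guidance = _laplacian(src[..., c])[ys, xs]
        sol = spsolve(A.tocsc(), guidance + b_boundary[:, c])
        out[ys, xs, c] = sol
    out = np.clip(out, 0, 255)
    result = out[..., 0] if single else out
    if np.issubdtype(target.dtype, np.integer):
        result = np.round(result)
    return result.astype(target.dtype)


def warp_texture(texture: FaceTexture, rendered: RenderedFace, face: SubMesh) -> np.ndarray:
    """Map the texture onto the rendered mask via barycentric UV interpolation.

    Returns a full-size image whose mask pixels carry the sampled texture;
    without UVs, falls back to a flat fill with the texture's mean color so
    every mask pixel still receives a value.
    """
    H, W = rendered.mask.shape
    out = np.zeros((H, W, 3), dtype=np.uint8)
    mask = rendered.mask
    tex = texture.image
    if face.uv is None or rendered.bary is None or rendered.face_index is None:
        out[mask] = tex.reshape(-1, 3).mean(axis=0).astype(np.uint8)
        return out
    ys, xs = np.nonzero(mask)
    fidx = rendered.face_index[ys, xs]
    tri_uv = face.uv[face.faces[fidx]]  # n x 3 x 2
    bar = rendered.bary[ys, xs][:, :, None]  # n x 3 x 1
    uv = (tri_uv * bar).sum(axis=1)
    th, tw = tex.shape[:2]
    # bilinear sample
    fu = np.clip(uv[:, 0], 0, 1) * (tw - 1)
    fv = (1.0 - np.clip(uv[:, 1], 0, 1)) * (th - 1)
    x0 = np.floor(fu).astype(int)
    y0 = np.floor(fv).astype(int)
    x1 = np.minimum(x0 + 1, tw - 1)
    y1 = np.minimum(y0 + 1, th - 1)
    wx = (fu - x0)[:, None]
    wy = (fv - y0)[:, None]
    t = tex.astype(float)
    col = (
        t[y0, x0] * (1 - wx) * (1 - wy)
        + t[y0, x1] * wx * (1 - wy)
        + t[y1, x0] * (1 - wx) * wy
        + t[y1, x1] * wx * wy
    )
    out[ys, xs] = np.clip(np.round(col), 0, 255).astype(np.uint8)
    return out


def apply_conventional(
    image: np.ndarray,
    bbox: tuple[int, int, int, int],
    method: str,
    params: AnonymizerParams | None = None,
) -> np.ndarray:
    """Conventional anonymization baselines inside a box.

    ``blacken`` zeroes the box; ``pixelate`` block-averages it into
    ``pixelate_block``-sized cells; ``blur`` applies a normalized Gaussian of
    ``blur_kernel`` size (σ = kernel/6) to the box. Pixels outside the box are
    untouched.
    """
    params = params or AnonymizerParams()
    x, y, w, h = (int(v) for v in bbox)
    H, W = image.shape[:2]
    if not (0 <= x and 0 <= y and x + w <= W and y + h <= H and w > 0 and h > 0):
        raise ValueError(f"bbox {bbox} outside image {W}x{H}")
    out = image.copy()
    region = out[y : y + h, x : x + w]
    if method == "blacken":
        out[y : y + h, x : x + w] = 0
    elif method == "pixelate":
        bs = params.pixelate_block
        for by in range(0, h, bs):
            for bx in range(0, w, bs):
                block = region[by : by + bs, bx : bx + bs]
                block[...] = block.reshape(-1, block.shape[-1]).mean(axis=0).astype(
                    image.dtype
                ) if image.ndim == 3 else block.mean().astype(image.dtype)
    elif method == "blur":
        sigma = params.blur_kernel / 6.0
        truncate = (params.blur_kernel // 2) / sigma
        blurred = region.astype(float)
        for c in range(blurred.shape[2]) if image.ndim == 3 else [None]:
            chan = blurred[..., c] if c is not None else blurred
            sm = ndi.gaussian_filter(chan, sigma=sigma, truncate=truncate, mode="nearest")
            if c is not None:
                blurred[..., c] = sm
            else:
                blurred = sm
        out[y : y + h, x : x + w] = np.clip(np.round(blurred), 0, 255).astype(
            image.dtype
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    return out


def anonymize_frame(
    frames: list[RGBDFrame],
    cameras: list[CameraModel],
    bodies: list[FittedBody],
    textures: dict[str, FaceTexture] | FaceTexture | None,
    params: AnonymizerParams | None = None,
) -> tuple[dict[str, np.ndarray], list[RenderedFace]]:
    """Render, visibility-check and blend every person into every camera.

    Returns the per-camera anonymized color images and the list of rendered
    faces (one per person × camera with a non-empty mask, carrying visibility
    verdicts). Faces judged occluded leave their view untouched.
    """
    params = params or AnonymizerParams()
    cam_by_id = {c.id: c for c in cameras}
    frame_by_cam = {f.camera_id: f for f in frames}
    images = {f.camera_id: f.color.copy() for f in frames}
    rendered_all: list[RenderedFace] = []

    for body in bodies:
        face = extract_face(body)
        for cam_id, frame in frame_by_cam.items():
            cam = cam_by_id[cam_id]
            rf = rasterize_face(face, cam, body.frame_index, body.person_id)
            if not rf.mask.any():
                continue
            sensor = frame.depth.astype(float) * cam.depth_scale
            rf.visible, rf.occluded_fraction = visibility_check(
                rf, sensor, params.delta, params.theta
            )
            rendered_all.append(rf)
            if not rf.visible:
                continue
            tex = textures
            if isinstance(textures, dict):
                tex = textures.get(body.person_id) or next(iter(textures.values()))
            if tex is None:
                tex = FaceTexture(np.full((8, 8, 3), 180, dtype=np.uint8))
            source = warp_texture(tex, rf, face)
            blend_mask = ndi.binary_dilation(rf.mask, iterations=params.dilate_px)
            # keep Poisson boundary inside the image
            blend_mask[0, :] = blend_mask[-1, :] = False
            blend_mask[:, 0] = blend_mask[:, -1] = False
            # fill dilated ring of the source with nearest mask colors
            rf.blend_mask = blend_mask
            ring = blend_mask & ~rf.mask
            if ring.any():
                _, (iy, ix) = ndi.distance_transform_edt(
                    ~rf.mask, return_indices=True
                )
                source = source.copy()
                source[ring] = source[iy[ring], ix[ring]]
            images[cam_id] = poisson_blend(images[cam_id], source, blend_mask)

    return images, rendered_all
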