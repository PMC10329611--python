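import numpy as np
import pytest

from disguisor.anonymize import (
    AnonymizerParams,
    FaceTexture,
    RenderedFace,
    anonymize_frame,
    apply_conventional,
    poisson_blend,
    rasterize_face,
    tight_bbox,
    visibility_check,
    warp_texture,
)
from disguisor.body import SubMesh, build_template, fit_body
from disguisor.geometry import CameraModel, RGBDFrame
from disguisor.pose import N_JOINTS, Skeleton3D
from disguisor.rendering import rasterize_mesh


@pytest.fixture
def camera():
    return CameraModel("c", 100.0, 100.0, 50.0, 50.0, 100, 100)


def tri_mesh(verts):
    return SubMesh(
        vertices=np.asarray(verts, dtype=float),
        faces=np.array([[0, 1, 2]]),
        source_indices=np.arange(3),
        uv=np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]]),
    )


class TestRasterize:
    def test_triangle_over_principal_point(self, camera):
        face = tri_mesh([[-0.1, -0.1, 1.0], [0.3, -0.1, 1.0], [-0.1, 0.3, 1.0]])
        rf = rasterize_face(face, camera)
        assert rf.mask[50, 50]
        assert abs(rf.mesh_depth[50, 50] - 1.0) < 1e-9
        assert rf.bbox is not None

    def test_mesh_behind_camera_empty(self, camera):
        face = tri_mesh([[-0.1, -0.1, -1.0], [0.3, -0.1, -1.0], [-0.1, 0.3, -1.0]])
        rf = rasterize_face(face, camera)
        assert not rf.mask.any()
        assert rf.bbox is None and not rf.visible

    def test_zbuffer_keeps_nearer_surface(self, camera):
        tris = [
            [[-0.1, -0.1, 1.0], [0.3, -0.1, 1.0], [-0.1, 0.3, 1.0]],
            [[-0.2, -0.2, 2.0], [0.6, -0.2, 2.0], [-0.2, 0.6, 2.0]],
        ]
        for order in (tris, tris[::-1]):
            verts = np.vstack(order)
            faces = np.array([[0, 1, 2], [3, 4, 5]])
            ras = rasterize_mesh(verts, faces, camera)
            assert abs(ras.depth[50, 50] - 1.0) < 1e-9

    def test_bbox_is_tight(self, camera):
        face = tri_mesh([[-0.1, -0.1, 1.0], [0.3, -0.1, 1.0], [-0.1, 0.3, 1.0]])
        rf = rasterize_face(face, camera)
        x, y, w, h = rf.bbox
        sub = rf.mask[y : y + h, x : x + w]
        assert sub[0].any() and sub[-1].any() and sub[:, 0].any() and sub[:, -1].any()
        assert tight_bbox(np.zeros((4, 4), bool)) is None


class TestVisibility:
    def _rendered(self, camera, depth=1.0):
        face = tri_mesh([[-0.2, -0.2, depth], [0.4, -0.2, depth], [-0.2, 0.4, depth]])
        return rasterize_face(face, camera)

    def test_matching_depth_visible(self, camera):
        rf = self._rendered(camera)
        sensor = np.where(rf.mask, rf.mesh_depth, 3.0)
        visible, frac = visibility_check(rf, sensor, delta=0.05, theta=0.5)
        assert visible and frac == 0.0

    def test_full_occluder_hides(self, camera):
        rf = self._rendered(camera)
        sensor = np.where(rf.mask, 0.5, 3.0)
        visible, frac = visibility_check(rf, sensor, delta=0.05, theta=0.5)
        assert not visible and frac == 1.0

    def test_half_occluder_threshold(self, camera):
        rf = self._rendered(camera)
        ys, xs = np.nonzero(rf.mask)
        half = len(ys) // 2
        sensor = np.where(rf.mask, rf.mesh_depth, 3.0)
        sensor[ys[:half], xs[:half]] = 0.4
        _, frac = visibility_check(rf, sensor, delta=0.05, theta=0.5)
        assert abs(frac - half / len(ys)) < 1e-12
        vis_lo, _ = visibility_check(rf, sensor, delta=0.05, theta=frac + 0.01)
        vis_hi, _ = visibility_check(rf, sensor, delta=0.05, theta=max(frac - 0.01, 1e-6))
        assert vis_lo and not vis_hi

    def test_invalid_sensor_depth_defaults_visible(self, camera):
        rf = self._rendered(camera)
        visible, frac = visibility_check(rf, np.zeros((100, 100)))
        assert visible and frac == 0.0

    def test_shape_mismatch_rejected(self, camera):
        rf = self._rendered(camera)
        with pytest.raises(ValueError):
            visibility_check(rf, np.ones((50, 50)))


def disk_mask(n, r, cy=None, cx=None):
    cy = cy if cy is not None else n // 2
    cx = cx if cx is not None else n // 2
    yy, xx = np.mgrid[0:n, 0:n]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


class TestPoissonBlend:
    def test_source_equals_target_identity(self):
        rng = np.random.default_rng(2)
        img = rng.integers(0, 255, size=(24, 24, 3)).astype(np.uint8)
        out = poisson_blend(img, img.copy(), disk_mask(24, 8))
        assert np.array_equal(out, img)

    def test_constant_boundary_harmonic_interior(self):
        target = np.full((20, 20), 99.0)
        source = np.full((20, 20), 7.0)  # zero gradients
        out = poisson_blend(target, source, disk_mask(20, 6))
        assert np.abs(out - 99.0).max() < 1e-8

    def test_outside_mask_bit_identical(self):
        rng = np.random.default_rng(3)
        target = rng.integers(0, 255, size=(30, 30, 3)).astype(np.uint8)
        source = rng.integers(0, 255, size=(30, 30, 3)).astype(np.uint8)
        mask = disk_mask(30, 9)
        out = poisson_blend(target, source, mask)
        assert np.array_equal(out[~mask], target[~mask])

    def test_matches_dense_solver_oracle(self):
        """Sparse solve equals an independent dense solve of the same
        Poisson system on a 32x32 instance."""
        rng = np.random.default_rng(4)
        target = rng.uniform(0, 255, size=(32, 32))
        source = rng.uniform(0, 255, size=(32, 32))
        mask = disk_mask(32, 10)
        out = poisson_blend(target, source, mask)

        ys, xs = np.nonzero(mask)
        n = len(ys)
        index = {-1: None}
        idx = -np.ones((32, 32), int)
        idx[ys, xs] = np.arange(n)
        A = np.zeros((n, n))
        b = np.zeros(n)
        pad = np.pad(source, 1, mode="edge")
        lap = (
            4 * pad[1:-1, 1:-1]
            - pad[:-2, 1:-1]
            - pad[2:, 1:-1]
            - pad[1:-1, :-2]
            - pad[1:-1, 2:]
        )
        for k, (y, x) in enumerate(zip(ys, xs)):
            A[k, k] = 4.0
            b[k] = lap[y, x]
            for ny, nx in ((y - 1, x), (y + 1, x), (y, x - 1), (y, x + 1)):
                j = idx[ny, nx]
                if j >= 0:
                    A[k, j] = -1.0
                else:
                    b[k] += target[ny, nx]
        dense = np.linalg.solve(A, b)
        assert np.abs(out[ys, xs] - np.clip(dense, 0, 255)).max() < 1e-6

    def test_border_mask_rejected(self):
        mask = np.zeros((16, 16), bool)
        mask[0, 5] = True
        with pytest.raises(ValueError):
            poisson_blend(np.zeros((16, 16)), np.zeros((16, 16)), mask)


class TestWarpTexture:
    def test_constant_texture_constant_patch(self, camera):
        face = tri_mesh([[-0.2, -0.2, 1.0], [0.4, -0.2, 1.0], [-0.2, 0.4, 1.0]])
        rf = rasterize_face(face, camera)
        tex = FaceTexture(np.full((16, 16, 3), 123, dtype=np.uint8))
        patch = warp_texture(tex, rf, face)
        assert (patch[rf.mask] == 123).all()

    def test_every_mask_pixel_covered(self, camera):
        face = tri_mesh([[-0.2, -0.2, 1.0], [0.4, -0.2, 1.0], [-0.2, 0.4, 1.0]])
        rf = rasterize_face(face, camera)
        rng = np.random.default_rng(0)
        tex = FaceTexture(
            rng.integers(40, 255, size=(16, 16, 3)).astype(np.uint8)
        )
        patch = warp_texture(tex, rf, face)
        assert (patch[rf.mask].sum(axis=1) > 0).all()

    def test_scanline_order_preserved(self, camera):
        """A texture with a left-to-right gradient keeps its ordering along
        an image scanline when U is aligned with screen x."""
        face = tri_mesh([[-0.3, -0.3, 1.0], [0.5, -0.3, 1.0], [-0.3, 0.5, 1.0]])
        grad = np.tile(np.arange(0, 256, 16, dtype=np.uint8), (16, 1))
        tex = FaceTexture(np.stack([grad] * 3, axis=-1))
        rf = rasterize_face(face, camera)
        patch = warp_texture(tex, rf, face)
        row = 40
        cols = np.nonzero(rf.mask[row])[0]
        vals = patch[row, cols, 0].astype(int)
        assert (np.diff(vals) >= 0).all()

    def test_missing_uv_falls_back_to_mean(self, camera):
        face = tri_mesh([[-0.2, -0.2, 1.0], [0.4, -0.2, 1.0], [-0.2, 0.4, 1.0]])
        face.uv = None
        rf = rasterize_face(face, camera)
        tex = FaceTexture(np.full((8, 8, 3), 77, dtype=np.uint8))
        patch = warp_texture(tex, rf, face)
        assert (patch[rf.mask] == 77).all()


class TestConventionalFilters:
    def test_blacken(self):
        img = np.full((40, 40, 3), 200, dtype=np.uint8)
        out = apply_conventional(img, (5, 5, 10, 12), "blacken")
        assert (out[5:17, 5:15] == 0).all()
        assert (out[0:5] == 200).all()

    def test_pixelate_constant_unchanged(self):
        img = np.full((40, 40, 3), 131, dtype=np.uint8)
        out = apply_conventional(img, (4, 4, 24, 24), "pixelate")
        assert np.array_equal(out, img)

    def test_pixelate_blocks_are_8px_means(self):
        rng = np.random.default_rng(1)
        img = rng.integers(0, 255, size=(40, 40, 3)).astype(np.uint8)
        out = apply_conventional(img, (0, 0, 16, 16), "pixelate")
        block = img[0:8, 0:8].reshape(-1, 3).mean(axis=0).astype(np.uint8)
        assert (out[0:8, 0:8] == block).all()

    def test_blur_constant_unchanged(self):
        img = np.full((80, 80, 3), 55, dtype=np.uint8)
        out = apply_conventional(img, (2, 2, 70, 70), "blur")
        assert np.array_equal(out, img)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            apply_conventional(np.zeros((10, 10, 3), np.uint8), (0, 0, 4, 4), "nope")

    def test_bbox_out_of_image_rejected(self):
        with pytest.raises(ValueError):
            apply_conventional(np.zeros((10, 10, 3), np.uint8), (6, 6, 8, 8), "blacken")


class TestAnonymizeFrame:
    def _scene_bits(self, tiny_scene):
        tpl = build_template(1.7)
        bodies = []
        for tr in tiny_scene.gt_tracks:
            s = tr.skeletons[0]
            bodies.append(fit_body(tpl, s))
        return tiny_scene.frames[0], tiny_scene.cameras, bodies

    def test_unobstructed_views_blended_and_predicted(self, tiny_scene):
        frames, cameras, bodies = self._scene_bits(tiny_scene)
        images, rendered = anonymize_frame(frames, cameras, bodies, None)
        visible = [r for r in rendered if r.visible]
        assert len(visible) == len(rendered)  # no occluders in the tiny scene
        assert len(images) == len(cameras)
        per_person = {}
        for r in visible:
            per_person.setdefault(r.person_id, set()).add(r.camera_id)
        for cams in per_person.values():
            assert len(cams) >= 2

    def test_locality_outside_blend_masks(self, tiny_scene):
        frames, cameras, bodies = self._scene_bits(tiny_scene)
        images, rendered = anonymize_frame(frames, cameras, bodies, None)
        originals = {f.camera_id: f.color for f in frames}
        for cam_id, img in images.items():
            union = np.zeros(img.shape[:2], dtype=bool)
            for r in rendered:
                if r.camera_id == cam_id and r.blend_mask is not None:
                    union |= r.blend_mask
            assert np.array_equal(img[~union], originals[cam_id][~union])

    def test_zero_persons_identity(self, tiny_scene):
        frames, cameras, _ = self._scene_bits(tiny_scene)
        images, rendered = anonymize_frame(frames, cameras, [], None)
        assert rendered == []
        for f in frames:
            assert np.array_equal(images[f.camera_id], f.color)
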