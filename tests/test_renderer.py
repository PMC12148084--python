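"""Camera geometry and Beer-Lambert DRR rendering."""

import numpy as np
import pytest

from polypose import se3
from polypose.camera import (
    camera_from_dict,
    camera_to_dict,
    make_camera,
    orbit_camera,
    pixel_to_world,
    project,
    source_position,
)
from polypose.renderer import Projector, RenderConfig, render_drr, render_structure
from polypose.volume import Labelmap, Volume


def random_camera(rng, focal=800.0):
    xi = np.concatenate([rng.uniform(-0.5, 0.5, 3), rng.uniform(-100, 100, 3)])
    return make_camera(focal, (32, 32), (1.5, 1.5), extrinsic=se3.exp_se3(xi))


def cube_volume(n=32, spacing=1.0, mu=0.02):
    """Homogeneous cube centered at the origin."""
    vals = np.full((n, n, n), mu)
    origin = -(n - 1) / 2.0 * spacing
    return Volume.from_spacing(vals, (spacing,) * 3, (origin,) * 3)


class TestCameraGeometry:
    def test_source_identity_camera(self):
        c = make_camera(1000.0)
        np.testing.assert_allclose(source_position(c), [0.0, 0.0, 0.0], atol=1e-12)

    def test_source_translated_camera(self):
        ext = np.eye(4)
        ext[2, 3] = -500.0
        c = make_camera(1000.0, extrinsic=ext)
        np.testing.assert_allclose(source_position(c), [0.0, 0.0, 500.0], atol=1e-12)

    def test_source_satisfies_defining_equation(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            c = random_camera(rng)
            S = source_position(c)
            assert np.linalg.norm(c.rotation @ S + c.translation) < 1e-9

    def test_principal_point_is_on_optical_axis(self):
        rng = np.random.default_rng(1)
        c = random_camera(rng)
        pp = np.array([c.intrinsic[0, 2], c.intrinsic[1, 2]])
        P = pixel_to_world(c, pp)
        S = source_position(c)
        axis = c.rotation[2]  # camera z in world frame
        np.testing.assert_allclose(P - S, c.focal_length * axis, atol=1e-9)

    def test_project_pixel_round_trip(self):
        rng = np.random.default_rng(2)
        c = random_camera(rng)
        pixels = rng.uniform(0, 31, (100, 2))
        back = project(c, pixel_to_world(c, pixels))
        np.testing.assert_allclose(back, pixels, atol=1e-6)

    def test_rigid_camera_translation_translates_detector_points(self):
        rng = np.random.default_rng(3)
        c = random_camera(rng)
        shift = np.array([10.0, -5.0, 3.0])
        ext2 = c.extrinsic.copy()
        ext2[:3, 3] = c.translation - c.rotation @ shift
        c2 = c.with_extrinsic(ext2)
        p = rng.uniform(0, 31, (10, 2))
        np.testing.assert_allclose(pixel_to_world(c2, p), pixel_to_world(c, p) + shift, atol=1e-9)

    def test_json_round_trip(self):
        rng = np.random.default_rng(4)
        c = random_camera(rng)
        c2 = camera_from_dict(camera_to_dict(c))
        np.testing.assert_allclose(c2.intrinsic, c.intrinsic, atol=1e-12)
        np.testing.assert_allclose(c2.extrinsic, c.extrinsic, atol=1e-12)
        assert c2.detector_shape == c.detector_shape


class TestRenderDRR:
    def setup_method(self):
        self.vol = cube_volume(n=32, spacing=1.0, mu=0.02)
        self.cam = orbit_camera(
            isocenter=(0, 0, 0),
            angle_deg=0.0,
            source_to_iso=500.0,
            source_to_detector=1000.0,
            detector_shape=(33, 33),
            pixel_spacing=(2.0, 2.0),
        )

    def test_zero_volume_gives_zero_image(self):
        v = Volume.from_spacing(np.zeros((16, 16, 16)), (1.0,) * 3)
        img = render_drr(v, self.cam)
        np.testing.assert_array_equal(img, 0.0)

    def test_central_ray_matches_analytic_chord(self):
        """Central pixel of an axial view: integral = mu * cube edge within 1%."""
        img = render_drr(self.vol, self.cam, RenderConfig(step_mm=0.5))
        center = img[16, 16]
        expected = 0.02 * 32.0  # chord through a 32 mm cube
        assert abs(center - expected) / expected < 0.01

    def test_quadrature_convergence(self):
        """Halving the step changes the central pixel by < 0.5%."""
        a = render_drr(self.vol, self.cam, RenderConfig(step_mm=0.5))[16, 16]
        b = render_drr(self.vol, self.cam, RenderConfig(step_mm=0.25))[16, 16]
        assert abs(a - b) / abs(b) < 0.005

    def test_linearity_in_volume(self):
        rng = np.random.default_rng(5)
        v = Volume.from_spacing(rng.uniform(0, 0.05, (16, 16, 16)), (2.0,) * 3, (-15.0,) * 3)
        img1 = render_drr(v, self.cam)
        v3 = Volume(3.0 * v.values, v.affine)
        np.testing.assert_allclose(render_drr(v3, self.cam), 3.0 * img1, rtol=1e-12)

    def test_image_nonnegative(self):
        rng = np.random.default_rng(6)
        v = Volume.from_spacing(rng.uniform(0, 0.05, (16, 16, 16)), (2.0,) * 3, (-15.0,) * 3)
        assert render_drr(v, self.cam).min() >= 0.0

    def test_clipping_invariance(self):
        """Clipped rays with M samples ~= unclipped rays with proportionally more."""
        clipped = render_drr(self.vol, self.cam, RenderConfig(n_samples=128, clip_to_volume=True))
        unclipped = render_drr(self.vol, self.cam, RenderConfig(n_samples=4096, clip_to_volume=False))
        ref = np.abs(clipped).max()
        assert np.abs(clipped - unclipped).max() / ref < 0.01

    def test_source_inside_volume_rejected(self):
        cam = make_camera(100.0, (8, 8), (1.0, 1.0))  # source at origin, inside the cube
        with pytest.raises(ValueError, match="inside"):
            render_drr(self.vol, cam)

    def test_pixel_gradient_wrt_translation_matches_finite_differences(self):
        """d(pixel)/d(global translation of the volume) via the adjoint chain
        agrees with central finite differences to 1e-3 relative."""
        from polypose.volume import Volume, sample_trilinear, sample_trilinear_grad

        rng = np.random.default_rng(8)
        from scipy import ndimage

        vals = ndimage.gaussian_filter(rng.uniform(0, 0.05, (16, 16, 16)), 1.0)
        v = Volume.from_spacing(vals, (2.0,) * 3, (-15.0,) * 3)
        proj = Projector(v.grid, self.cam, RenderConfig(n_samples=64))
        centers = v.grid.voxel_centers().reshape(-1, 3)
        pixel = (16, 16)

        def pixel_value(t):
            warped = sample_trilinear(v, centers + t).reshape(v.grid.shape)
            return proj.forward(warped)[pixel]

        # analytic: dI/dt = sum_j A[p, j] * grad V(x_j + t)
        g_img = np.zeros(proj.image_shape)
        g_img[pixel] = 1.0
        b = proj.adjoint(g_img).reshape(-1)
        t0 = np.array([1.3, -0.7, 2.1])
        _, grad_v = sample_trilinear_grad(v, centers + t0)
        analytic = (b[:, None] * grad_v).sum(axis=0)

        h = 1e-4
        for ax in range(3):
            d = np.zeros(3)
            d[ax] = h
            fd = (pixel_value(t0 + d) - pixel_value(t0 - d)) / (2 * h)
            assert abs(analytic[ax] - fd) <= 1e-3 * max(abs(fd), 1e-6)

    def test_adjoint_is_exact_transpose(self):
        """<A v, g> == <v, A^T g> for random v, g (dot-product test)."""
        rng = np.random.default_rng(7)
        proj = Projector(self.vol.grid, self.cam, RenderConfig(n_samples=32))
        v = rng.uniform(0, 1, self.vol.grid.shape)
        g = rng.normal(size=proj.image_shape)
        lhs = float((proj.forward(v) * g).sum())
        rhs = float((v * proj.adjoint(g)).sum())
        assert abs(lhs - rhs) < 1e-8 * max(1.0, abs(lhs))


class TestRenderStructure:
    def setup_method(self):
        self.vol = cube_volume(n=32, spacing=1.0, mu=0.02)
        labels = np.zeros((32, 32, 32), dtype=np.int32)
        labels[12:20, 12:20, 12:20] = 1
        self.lm = Labelmap(labels, self.vol.affine.copy())
        self.cam = orbit_camera((0, 0, 0), 0.0, detector_shape=(33, 33), pixel_spacing=(2.0, 2.0))

    def test_masked_render_equals_render_of_masked_volume(self):
        img = render_structure(self.vol, self.lm, [1], self.cam)
        masked = Volume(np.where(self.lm.labels == 1, self.vol.values, 0.0), self.vol.affine)
        np.testing.assert_allclose(img, render_drr(masked, self.cam), atol=1e-12)

    def test_unknown_id_rejected(self):
        with pytest.raises(ValueError, match="not present"):
            render_structure(self.vol, self.lm, [9], self.cam)

    def test_thickness_map_max_equals_max_chord(self):
        """Binary mask rendered as LAC=1 gives chord lengths through the mask."""
        ones = Volume(np.where(self.lm.labels == 1, 1.0, 0.0), self.vol.affine)
        img = render_drr(ones, self.cam, RenderConfig(step_mm=0.25))
        # cube of 8 voxels at 1 mm spacing: max axial chord = 8 mm
        assert abs(img.max() - 8.0) / 8.0 < 0.05
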