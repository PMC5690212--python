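"""Rigid-transform algebra and DRR rendering contracts."""

import numpy as np
import pytest

from regiq.geometry import (Image2D, Panel, ProjectionGeometry, RigidTransform,
                            apply, compose, invert, render_drr)
from regiq.phantom import Volume

ISO = np.array([30.0, 40.0, 50.0])


def random_transforms(n, seed=0):
    rng = np.random.default_rng(seed)
    return [RigidTransform(t=rng.uniform(-20, 20, 3), r=rng.uniform(-90, 90, 3))
            for _ in range(n)]


class TestRigidTransform:
    def test_compose_matches_sequential_application(self, rng):
        pts = rng.normal(scale=30, size=(10, 3))
        for a, b in zip(random_transforms(5, 1), random_transforms(5, 2)):
            lhs = apply(compose(a, b), pts, ISO)
            rhs = apply(a, apply(b, pts, ISO), ISO)
            assert np.allclose(lhs, rhs, atol=1e-9)

    def test_invert_roundtrip(self, rng):
        pts = rng.normal(scale=30, size=(10, 3))
        for a in random_transforms(5, 3):
            assert np.allclose(apply(invert(a), apply(a, pts, ISO), pts * 0 + ISO),
                               pts, atol=1e-9)

    def test_compose_with_identity_is_identity_on_points(self, rng):
        pts = rng.normal(scale=30, size=(6, 3))
        for a in random_transforms(3, 4):
            c = compose(RigidTransform.identity(), a)
            assert np.allclose(apply(c, pts, ISO), apply(a, pts, ISO), atol=1e-9)

    def test_invert_pure_translation(self):
        inv = invert(RigidTransform(t=[3, 0, 0]))
        assert np.allclose(inv.t, [-3, 0, 0])
        assert np.allclose(inv.r, 0)

    def test_rotation_about_z_through_isocenter(self):
        a = RigidTransform(r=[0, 0, 90])
        p = ISO + np.array([1.0, 0.0, 0.0])
        assert np.allclose(apply(a, p, ISO), ISO + np.array([0.0, 1.0, 0.0]),
                           atol=1e-12)

    def test_rotation_matrices_orthonormal(self):
        for a in random_transforms(10, 5):
            R = a.rotation_matrix()
            assert np.allclose(R.T @ R, np.eye(3), atol=1e-9)

    def test_angles_wrapped_into_half_open_interval(self):
        a = RigidTransform(r=[270.0, -180.0, 180.0])
        assert np.all(a.r > -180.0) and np.all(a.r <= 180.0)
        assert a.r[0] == -90.0


@pytest.fixture(scope="module")
def uniform_cube():
    # 20-voxel cube of intensity 2.0 inside a 40^3 volume at 2 mm spacing
    values = np.zeros((40, 40, 40), dtype=np.float32)
    values[10:30, 10:30, 10:30] = 2.0
    return Volume(values=values, spacing=(2.0, 2.0, 2.0), isocenter=(40.0, 40.0, 40.0))


def lateral_panel(n=40, spacing=2.0):
    return Panel("lateral", view_axis=(1, 0, 0), u_axis=(0, 1, 0),
                 v_axis=(0, 0, 1), pixel_spacing=spacing, size=(n, n))


class TestRenderDrr:
    def test_uniform_cube_line_integral_is_analytic(self, uniform_cube):
        img = render_drr(uniform_cube, RigidTransform.identity(), lateral_panel())
        # interior rays cross 40 mm of intensity 2 -> integral 80
        center = img.values[18:22, 18:22]
        assert np.allclose(center, 80.0, rtol=0.02)
        # rays that miss the cube entirely are zero
        assert np.allclose(img.values[:2, :], 0.0)

    def test_out_of_plane_translation_invariance(self, uniform_cube):
        ref = render_drr(uniform_cube, RigidTransform.identity(), lateral_panel())
        shifted = render_drr(uniform_cube, RigidTransform(t=[7.0, 0, 0]),
                             lateral_panel())
        assert np.allclose(ref.values, shifted.values, atol=1e-6 * ref.values.max())

    def test_in_plane_translation_shifts_image(self, volume):
        panel = Panel("lateral", view_axis=(1, 0, 0), u_axis=(0, 1, 0),
                      v_axis=(0, 0, 1), pixel_spacing=3.0, size=(32, 32))
        ref = render_drr(volume, RigidTransform.identity(), panel)
        # +6 mm along y = 2 pixels along the u (column) axis
        shifted = render_drr(volume, RigidTransform(t=[0, 6.0, 0]), panel)
        inner = slice(4, 28)
        np.testing.assert_allclose(shifted.values[inner, 6:28],
                                   ref.values[inner, 4:26],
                                   atol=0.02 * ref.values.max())

    def test_zero_volume_renders_zero_image(self):
        vol = Volume(values=np.zeros((32, 32, 32)), spacing=(2, 2, 2),
                     isocenter=(32, 32, 32))
        img = render_drr(vol, RigidTransform.identity(), lateral_panel(32, 2.0))
        assert np.all(img.values == 0.0)

    def test_step_refinement_converges(self, volume):
        panel = lateral_panel(32, 3.0)
        pose = RigidTransform(t=[1.0, 2.0, -1.0], r=[2.0, -1.0, 3.0])
        coarse = render_drr(volume, pose, panel, step=3.0).values
        mid = render_drr(volume, pose, panel, step=1.5).values
        fine = render_drr(volume, pose, panel, step=0.75).values
        err_coarse = np.abs(coarse - fine).mean()
        err_mid = np.abs(mid - fine).mean()
        assert err_mid < err_coarse

    def test_perspective_mode_renders_magnified_head(self, volume):
        geom = ProjectionGeometry.default_orthogonal(
            48, 3.0, mode="perspective", source_to_iso=400.0, iso_to_detector=200.0)
        img = render_drr(volume, RigidTransform.identity(), geom.panels[0],
                         mode="perspective")
        assert img.values.max() > 0
        par = render_drr(volume, RigidTransform.identity(), geom.panels[0])
        # divergent beam magnifies: the projected head covers more pixels
        assert (img.values > 0.01 * img.values.max()).sum() > \
            (par.values > 0.01 * par.values.max()).sum()

    def test_degenerate_view_axis_rejected(self):
        with pytest.raises(ValueError):
            Panel("bad", view_axis=(0, 0, 0), u_axis=(0, 1, 0), v_axis=(0, 0, 1),
                  pixel_spacing=1.0, size=(8, 8))

    def test_nonorthogonal_panels_rejected(self):
        a = lateral_panel()
        b = Panel("b", view_axis=(1, 1, 0), u_axis=(0, 0, 1), v_axis=(1, -1, 0),
                  pixel_spacing=2.0, size=(8, 8))
        with pytest.raises(ValueError):
            ProjectionGeometry(panels=(a, b))
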