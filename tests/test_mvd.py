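"""MVD normalization, distance metric and labeling contracts."""

import numpy as np
import pytest

from regiq.geometry import RigidTransform, apply
from regiq.mvd import (SUCCESSFUL, UNSUCCESSFUL, NormalizationFactors, Roi3D,
                       label, mvd_distance, mvd_exact, normalization_factors)

ISO = np.array([50.0, 50.0, 50.0])


@pytest.fixture(scope="module")
def cube_roi():
    return Roi3D(lo=ISO - 30.0, hi=ISO + 30.0)


@pytest.fixture(scope="module")
def factors(cube_roi):
    return normalization_factors(cube_roi, ISO, sample_spacing=2.0)


class TestNormalizationFactors:
    def test_translation_factors_exactly_one(self, factors):
        assert np.array_equal(factors.translation, np.ones(3))

    def test_rotation_factor_matches_mean_perpendicular_distance(self, cube_roi, factors):
        pts = cube_roi.sample_points(2.0) - ISO
        mean_perp_z = np.sqrt(pts[:, 0] ** 2 + pts[:, 1] ** 2).mean()
        assert factors.rotation[2] == pytest.approx(np.deg2rad(1.0) * mean_perp_z)

    def test_factor_agrees_with_brute_force_rotation(self, cube_roi, factors):
        """Rotating every ROI point by 1 degree and averaging displacements
        reproduces the small-angle factor within 1%."""
        one_deg = RigidTransform(r=[0, 0, 1.0])
        brute = mvd_exact(one_deg, RigidTransform.identity(), cube_roi, ISO,
                          sample_spacing=2.0)
        assert factors.rotation[2] == pytest.approx(brute, rel=0.01)

    def test_isotropic_roi_scaling_scales_rotation_factors(self, cube_roi, factors):
        bigger = Roi3D(lo=ISO - 60.0, hi=ISO + 60.0)
        f2 = normalization_factors(bigger, ISO, sample_spacing=4.0)
        assert np.allclose(f2.rotation, 2.0 * factors.rotation, rtol=1e-6)
        assert np.array_equal(f2.translation, factors.translation)

    def test_degenerate_roi_rejected(self):
        with pytest.raises(ValueError):
            Roi3D(lo=ISO, hi=ISO)


class TestMvdDistance:
    def test_identity_distance_zero(self, factors):
        a = RigidTransform(t=[1, 2, 3], r=[4, 5, 6])
        assert mvd_distance(a, a, factors) == 0.0

    def test_pure_translation_is_euclidean(self, factors):
        a = RigidTransform(t=[3, 0, 0])
        assert mvd_distance(a, RigidTransform.identity(), factors) == pytest.approx(3.0)

    def test_one_normalized_rotation_unit_is_one_mm(self, factors):
        a = RigidTransform(r=[0, 0, 1.0 / factors.rotation[2]])
        assert mvd_distance(a, RigidTransform.identity(), factors) == pytest.approx(1.0)

    def test_metric_axioms(self, factors, rng):
        poses = [RigidTransform(t=rng.uniform(-5, 5, 3), r=rng.uniform(-3, 3, 3))
                 for _ in range(6)]
        for a in poses:
            assert mvd_distance(a, a, factors) == 0.0
            for b in poses:
                dab = mvd_distance(a, b, factors)
                assert dab == mvd_distance(b, a, factors)  # symmetry
                assert dab >= 0.0
                if not np.allclose(a.params, b.params):
                    assert dab > 0.0  # identity of indiscernibles
                for c in poses:
                    assert dab <= mvd_distance(a, c, factors) + \
                        mvd_distance(c, b, factors) + 1e-12  # triangle

    def test_small_perturbations_match_exact_mvd(self, cube_roi, factors, rng):
        """First-order Euclidean distance tracks brute-force mean point
        displacement within 5% for perturbations <= 2 mm / <= 1 deg."""
        for _ in range(10):
            a = RigidTransform(t=rng.uniform(-2, 2, 3), r=rng.uniform(-1, 1, 3))
            b = RigidTransform(t=rng.uniform(-2, 2, 3), r=rng.uniform(-1, 1, 3))
            exact = mvd_exact(a, b, cube_roi, ISO, sample_spacing=2.0)
            approx = mvd_distance(a, b, factors)
            assert abs(approx - exact) / exact < 0.05

    def test_exact_mvd_trivial_cases(self, cube_roi):
        ident = RigidTransform.identity()
        assert mvd_exact(ident, ident, cube_roi, ISO) == 0.0
        assert mvd_exact(RigidTransform(t=[3, 0, 0]), ident, cube_roi, ISO) == \
            pytest.approx(3.0)

    def test_rotation_difference_wraps(self, factors):
        a = RigidTransform(r=[0, 0, 179.0])
        b = RigidTransform(r=[0, 0, -179.0])
        d = mvd_distance(a, b, factors)
        assert d == pytest.approx(2.0 * factors.rotation[2], rel=1e-9)


class TestLabel:
    def test_zero_error_successful(self, factors):
        a = RigidTransform.identity()
        assert label(a, a, factors) == SUCCESSFUL

    def test_above_tolerance_unsuccessful(self, factors):
        a = RigidTransform(t=[1.2, 0, 0])
        assert label(a, RigidTransform.identity(), factors, tolerance=1.0) == UNSUCCESSFUL

    def test_boundary_is_successful(self, factors):
        a = RigidTransform(t=[1.0, 0, 0])
        assert label(a, RigidTransform.identity(), factors, tolerance=1.0) == SUCCESSFUL
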