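"""Cost-profile sampling and DO/MS feature contracts."""

import numpy as np
import pytest

from regiq.features import (DegenerateProfileError, FeatureVector, ProfileSet,
                            compute_features, sample_profiles)
from regiq.geometry import RigidTransform
from regiq.similarity import CostFunction


def make_profiles(center, neg, pos, step=5.0):
    neg = np.asarray(neg, dtype=float)
    pos = np.asarray(pos, dtype=float)
    return ProfileSet(center_cost=center, costs_neg=neg, costs_pos=pos,
                      step_size=step, n_per_side=neg.shape[1])


class TestComputeFeatures:
    def test_symmetric_profiles_have_zero_ms(self, rng):
        samples = -1.5 + 0.1 * rng.random((6, 3))
        p = make_profiles(-1.9, samples, samples.copy())
        fv = compute_features(p)
        assert fv.ms_trans == 0.0
        assert fv.ms_rot == 0.0

    def test_flat_profiles_have_zero_do(self):
        flat = np.full((6, 3), -1.7)
        fv = compute_features(make_profiles(-1.7, flat, flat))
        assert fv.do_trans == 0.0
        assert fv.do_rot == 0.0

    def test_hand_computed_single_offset_example(self):
        """Centre -1.90 with side samples -1.80 / -1.84 on every axis:
        DO = ((0.10 + 0.06)/2) = 0.08 and MS = 0.04 / 0.16 = 0.25."""
        neg = np.full((6, 1), -1.84)
        pos = np.full((6, 1), -1.80)
        fv = compute_features(make_profiles(-1.90, neg, pos))
        assert fv.do_trans == pytest.approx(0.08)
        assert fv.do_rot == pytest.approx(0.08)
        assert fv.ms_trans == pytest.approx(0.25)
        assert fv.ms_rot == pytest.approx(0.25)

    def test_invariant_to_constant_cost_shift(self, rng):
        neg = -1.8 + 0.05 * rng.random((6, 3))
        pos = -1.8 + 0.05 * rng.random((6, 3))
        a = compute_features(make_profiles(-1.9, neg, pos))
        b = compute_features(make_profiles(-1.9 + 0.3, neg + 0.3, pos + 0.3))
        for name in ("do_trans", "do_rot", "ms_trans", "ms_rot"):
            assert getattr(a, name) == pytest.approx(getattr(b, name), abs=1e-9)

    def test_do_negative_when_center_above_surroundings(self):
        neg = np.full((6, 2), -1.95)
        pos = np.full((6, 2), -1.95)
        fv = compute_features(make_profiles(-1.90, neg, pos))
        assert fv.do_trans < 0
        assert fv.do_rot < 0

    def test_ms_bounded_to_unit_interval(self, rng):
        for _ in range(10):
            neg = -2.0 + 0.4 * rng.random((6, 3))
            pos = -2.0 + 0.4 * rng.random((6, 3))
            fv = compute_features(make_profiles(-1.9, neg, pos))
            assert 0.0 <= fv.ms_trans <= 1.0
            assert 0.0 <= fv.ms_rot <= 1.0


class TestSampleProfiles:
    def test_evaluation_count(self, volume, noiseless_case, nf):
        cf = CostFunction(volume, noiseless_case)
        p = sample_profiles(volume, noiseless_case, RigidTransform.identity(),
                            nf, step_size=5.0, n_per_side=1, cost_fn=cf)
        assert cf.n_evaluations == 13  # 6 axes * 2 sides + centre
        assert p.n_evaluations == 13

    def test_center_is_minimum_at_true_pose_noiseless(self, volume, noiseless_case, nf):
        p = sample_profiles(volume, noiseless_case, RigidTransform.identity(),
                            nf, step_size=5.0, n_per_side=3)
        assert p.center_cost <= p.costs_neg.min()
        assert p.center_cost <= p.costs_pos.min()

    def test_nesting_of_step_sizes(self, volume, noiseless_case, nf):
        """The k=1 sample at step 2s coincides with the k=2 sample at step s."""
        cf = CostFunction(volume, noiseless_case, memoize=True)
        pose = RigidTransform(t=[1.0, 0.5, -0.5])
        p_s = sample_profiles(volume, noiseless_case, pose, nf, 5.0,
                              n_per_side=2, cost_fn=cf)
        p_2s = sample_profiles(volume, noiseless_case, pose, nf, 10.0,
                               n_per_side=1, cost_fn=cf)
        np.testing.assert_array_equal(p_2s.costs_pos[:, 0], p_s.costs_pos[:, 1])
        np.testing.assert_array_equal(p_2s.costs_neg[:, 0], p_s.costs_neg[:, 1])

    def test_memoized_sweep_shares_center(self, volume, noiseless_case, nf):
        cf = CostFunction(volume, noiseless_case, memoize=True)
        pose = RigidTransform(t=[0.5, 0, 0])
        sample_profiles(volume, noiseless_case, pose, nf, 5.0, n_per_side=1,
                        cost_fn=cf)
        before = cf.n_evaluations
        sample_profiles(volume, noiseless_case, pose, nf, 10.0, n_per_side=1,
                        cost_fn=cf)
        # the centre (and any coinciding offsets) are not re-rendered
        assert cf.n_evaluations - before <= 12

    def test_invalid_arguments(self, volume, noiseless_case, nf):
        with pytest.raises(ValueError):
            sample_profiles(volume, noiseless_case, RigidTransform.identity(),
                            nf, step_size=0.0)
        with pytest.raises(ValueError):
            sample_profiles(volume, noiseless_case, RigidTransform.identity(),
                            nf, step_size=5.0, n_per_side=0)


def test_population_separability(volume, nf):
    """Successful solutions show higher DO and lower MS than unsuccessful
    ones on a labeled mini-campaign (the separability premise of the
    classifier), assessed by a rank-sum test."""
    from scipy.stats import mannwhitneyu

    from regiq.mvd import mvd_distance
    from regiq.phantom import make_case
    from regiq.register import PerturbationRange, RegisterConfig, random_inits, register

    pose_true = RigidTransform(t=[1.0, -1.5, 0.5], r=[0.5, -0.8, 0.3])
    noiseless = make_case(volume, pose_true, 0.0, seed=3)
    sd = 0.04 * max(v.values.max() for v in noiseless.references.values())
    case = make_case(volume, pose_true, sd, seed=3)
    # 32 histogram bins as in the campaign configs: this small ROI holds too
    # few pixels for a well-occupied 64-bin joint histogram
    cf = CostFunction(volume, case, bins=32, memoize=True, degenerate_nmi=1.0)
    cfg = RegisterConfig(bins=32)
    gold = register(volume, case, pose_true, cfg, cost_fn=cf)
    do_rot, ms_rot, labels = [], [], []
    for init in random_inits(RigidTransform.identity(), PerturbationRange(20, 8),
                             30, seed=17):
        sol = register(volume, case, init, cfg, cost_fn=cf)
        fv = compute_features(sample_profiles(volume, case, sol.pose, nf, 5.0,
                                              cost_fn=cf))
        do_rot.append(fv.do_rot)
        ms_rot.append(fv.ms_rot)
        labels.append(mvd_distance(sol.pose, gold.pose, nf) > 1.0)
    labels = np.array(labels)
    do_rot = np.array(do_rot)
    ms_rot = np.array(ms_rot)
    assert labels.any() and (~labels).any(), "need both classes"
    assert do_rot[~labels].mean() > do_rot[labels].mean()
    assert ms_rot[~labels].mean() < ms_rot[labels].mean()
    p_do = mannwhitneyu(do_rot[~labels], do_rot[labels], alternative="greater").pvalue
    p_ms = mannwhitneyu(ms_rot[~labels], ms_rot[labels], alternative="less").pvalue
    assert p_do < 0.01 or p_ms < 0.01
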