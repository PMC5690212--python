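"""Cost-profile sampling and the DO/MS shape features.

Around a candidate solution the cost function is sampled along each of the
six parameter axes of the MVD-normalized space, at offsets ``+-k*s`` for a
step size ``s`` (mm of mean voxel displacement) and ``k = 1..n``.  Two shape
descriptors are computed separately for the translational and rotational
axes:

* distinctiveness of optimum (DO): the mean rise of the cost above the
  centre value over all offsets — a global minimum tends to sit in a deeper
  valley than a local one, so larger DO indicates a more trustworthy
  solution (DO is negative when the centre is not even a local minimum);
* mirror symmetry (MS): the mean normalized asymmetry
  ``|c(+ks) - c(-ks)| / (|c(+ks) - c0| + |c(-ks) - c0| + eps)`` between the
  two sides of the profile, in [0, 1] — global minima tend to have more
  symmetric profiles, so smaller MS indicates a better solution.

Both features depend only on cost differences, so they are invariant to
adding a constant to the cost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from regiq.geometry import RigidTransform
from regiq.mvd import NormalizationFactors
from regiq.similarity import CostFunction, DegenerateImageError

__all__ = [
    "ProfileSet",
    "FeatureVector",
    "DegenerateProfileError",
    "sample_profiles",
    "compute_features",
    "DEFAULT_STEP_GRID",
]

#: step-size grid (mm) swept when selecting the operating step
DEFAULT_STEP_GRID = (1.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0)

_EPS = 1e-12


class DegenerateProfileError(RuntimeError):
    """The cost was degenerate at one of the profile sample points."""


@dataclass
class ProfileSet:
    """Cost samples along the 6 normalized axes around a solution.

    ``costs_neg[a, k-1]`` / ``costs_pos[a, k-1]`` hold the cost at offset
    ``-k*s`` / ``+k*s`` along axis ``a`` (axes 0-2 translations, 3-5
    rotations); ``center_cost`` is the cost at the solution itself.
    """

    center_cost: float
    costs_neg: np.ndarray  # (6, n_per_side)
    costs_pos: np.ndarray  # (6, n_per_side)
    step_size: float  # mm (normalized units)
    n_per_side: int

    def __post_init__(self):
        self.costs_neg = np.asarray(self.costs_neg, dtype=float)
        self.costs_pos = np.asarray(self.costs_pos, dtype=float)
        if self.costs_neg.shape != (6, self.n_per_side) or \
                self.costs_pos.shape != (6, self.n_per_side):
            raise ValueError("profile arrays must have shape (6, n_per_side)")
        if not (np.all(np.isfinite(self.costs_neg))
                and np.all(np.isfinite(self.costs_pos))
                and np.isfinite(self.center_cost)):
            raise ValueError("profile costs must be finite")

    @property
    def n_evaluations(self) -> int:
        return 12 * self.n_per_side + 1


@dataclass(frozen=True)
class FeatureVector:
    """The four classifier inputs."""

    do_trans: float
    do_rot: float
    ms_trans: float
    ms_rot: float

    def as_array(self) -> np.ndarray:
        return np.array([self.do_trans, self.do_rot, self.ms_trans, self.ms_rot])


def sample_profiles(volume, case, pose: RigidTransform,
                    nf: NormalizationFactors, step_size: float,
                    n_per_side: int = 3, bins: int = 64,
                    cost_fn: CostFunction = None) -> ProfileSet:
    """Evaluate the cost at ``pose`` and at ``pose +- k*s`` along each axis.

    Offsets are in normalized (MVD) units: a translational offset of ``d``
    adds ``d`` mm to that translation, a rotational offset adds
    ``d / rotation_factor`` degrees.  ``6 * 2 * n + 1`` cost evaluations;
    pass a memoizing ``cost_fn`` to share evaluations across nested step
    sizes.
    """
    if step_size <= 0:
        raise ValueError("step_size must be > 0")
    if n_per_side < 1:
        raise ValueError("n_per_side must be >= 1")
    if cost_fn is None:
        cost_fn = CostFunction(volume, case, bins=bins)
    scales = nf.scales  # mm per native unit; offset_native = offset_mvd / scale

    def evaluate(params):
        try:
            return cost_fn(params)
        except DegenerateImageError as e:
            raise DegenerateProfileError(str(e)) from e

    p0 = pose.params
    center = evaluate(p0)
    neg = np.empty((6, n_per_side))
    pos = np.empty((6, n_per_side))
    for ax in range(6):
        for k in range(1, n_per_side + 1):
            for sign, out in ((-1.0, neg), (+1.0, pos)):
                p = p0.copy()
                p[ax] += sign * k * step_size / scales[ax]
                out[ax, k - 1] = evaluate(p)
    return ProfileSet(center_cost=center, costs_neg=neg, costs_pos=pos,
                      step_size=step_size, n_per_side=n_per_side)


def compute_features(p: ProfileSet) -> FeatureVector:
    """DO and MS, each computed separately over translations and rotations.

    DO is the mean of ``cost(offset) - cost(center)`` over the three axes of
    the group and all offsets; MS is the mean over the group's axes and k of
    the normalized side asymmetry (see module docstring).
    """
    c0 = p.center_cost

    def do(axes):
        rises = np.concatenate([(p.costs_neg[axes] - c0).ravel(),
                                (p.costs_pos[axes] - c0).ravel()])
        return float(rises.mean())

    def ms(axes):
        cp = p.costs_pos[axes]
        cn = p.costs_neg[axes]
        num = np.abs(cp - cn)
        den = np.abs(cp - c0) + np.abs(cn - c0) + _EPS
        return float((num / den).mean())

    trans = slice(0, 3)
    rot = slice(3, 6)
    return FeatureVector(do_trans=do(trans), do_rot=do(rot),
                         ms_trans=ms(trans), ms_rot=ms(rot))
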