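"""Mean-voxel-displacement (MVD) normalized parameter space.

A 6-DOF pose mixes millimetres and degrees, so raw Euclidean distances in
parameter space are meaningless.  The MVD normalization rescales each
rotational parameter so that one normalized unit of any parameter displaces
the voxels of a user-chosen 3D ROI by 1 mm on average; translations already
have this property.  The distance between two poses in the normalized space
is then itself (to first order) the mean displacement, in mm, of the ROI
voxels — directly comparable to a clinical tolerance.

``mvd_distance`` is the first-order (small-angle) Euclidean distance used
throughout; ``mvd_exact`` averages actual point displacements and serves as
its brute-force oracle.  Solutions farther than the tolerance (default 1 mm)
from the gold standard are labeled unsuccessful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from regiq.geometry import RigidTransform, apply

__all__ = [
    "Roi3D",
    "NormalizationFactors",
    "normalization_factors",
    "mvd_distance",
    "mvd_exact",
    "label",
    "SUCCESSFUL",
    "UNSUCCESSFUL",
]

SUCCESSFUL = "successful"
UNSUCCESSFUL = "unsuccessful"


@dataclass(frozen=True)
class Roi3D:
    """Axis-aligned cuboid in volume physical coordinates (mm corners)."""

    lo: np.ndarray
    hi: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "lo", np.asarray(self.lo, dtype=float).reshape(3))
        object.__setattr__(self, "hi", np.asarray(self.hi, dtype=float).reshape(3))
        if not np.all(self.hi > self.lo):
            raise ValueError("ROI cuboid must have positive extent on every axis")

    def sample_points(self, spacing) -> np.ndarray:
        """Regular grid of sample points at ``spacing`` (mm), cell-centred."""
        spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,))
        axes = []
        for lo, hi, s in zip(self.lo, self.hi, spacing):
            n = max(1, int(np.floor((hi - lo) / s)))
            axes.append(lo + (np.arange(n) + 0.5) * (hi - lo) / n)
        X, Y, Z = np.meshgrid(*axes, indexing="ij")
        return np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])


@dataclass(frozen=True)
class NormalizationFactors:
    """Per-parameter scales to normalized units (1 unit = 1 mm mean displacement).

    ``translation`` factors are exactly 1 (a 1 mm translation displaces every
    voxel by 1 mm); ``rotation`` factors are mm of mean ROI displacement per
    degree about each axis through the isocenter.
    """

    translation: np.ndarray
    rotation: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "translation",
                           np.asarray(self.translation, dtype=float).reshape(3))
        object.__setattr__(self, "rotation",
                           np.asarray(self.rotation, dtype=float).reshape(3))
        if not np.all(self.rotation > 0):
            raise ValueError("rotation factors must be > 0")

    @property
    def scales(self) -> np.ndarray:
        """6-vector applied to (t, r) parameter differences."""
        return np.concatenate([self.translation, self.rotation])


def normalization_factors(roi: Roi3D, isocenter, sample_spacing=2.0) -> NormalizationFactors:
    """MVD normalization factors for a cuboid ROI about ``isocenter``.

    For each rotation axis the factor is the mean, over ROI grid points, of
    the displacement magnitude per degree of rotation about the isocenter —
    in the small-angle limit ``(pi/180) * r_perp`` with ``r_perp`` the
    perpendicular distance from the point to the axis.
    """
    iso = np.asarray(isocenter, dtype=float).reshape(3)
    pts = roi.sample_points(sample_spacing) - iso
    rot = np.empty(3)
    for ax in range(3):
        other = [i for i in range(3) if i != ax]
        r_perp = np.sqrt(pts[:, other[0]] ** 2 + pts[:, other[1]] ** 2)
        rot[ax] = np.deg2rad(1.0) * float(r_perp.mean())
    return NormalizationFactors(translation=np.ones(3), rotation=rot)


def mvd_distance(a: RigidTransform, b: RigidTransform,
                 nf: NormalizationFactors) -> float:
    """Euclidean distance (mm) between poses in the normalized parameter space."""
    d = a.params - b.params
    # wrap rotation differences into (-180, 180]
    d[3:] = -((-d[3:] + 180.0) % 360.0 - 180.0)
    return float(np.linalg.norm(d * nf.scales))


def mvd_exact(a: RigidTransform, b: RigidTransform, roi: Roi3D, isocenter,
              sample_spacing=2.0) -> float:
    """Exact mean displacement (mm) of ROI points between the two poses.

    Brute-force definition: the average of |T_a(p) - T_b(p)| over a regular
    grid of ROI points.  Oracle for :func:`mvd_distance`, which matches it to
    first order in the pose difference.
    """
    pts = roi.sample_points(sample_spacing)
    da = apply(a, pts, isocenter)
    db = apply(b, pts, isocenter)
    return float(np.linalg.norm(da - db, axis=1).mean())


def label(solution, gold, nf: NormalizationFactors, tolerance: float = 1.0) -> str:
    """Classify a solution against the gold standard at an MVD tolerance (mm).

    Unsuccessful iff the normalized distance is strictly greater than the
    tolerance (the boundary itself counts as successful).
    """
    pose = solution.pose if hasattr(solution, "pose") else solution
    gold_pose = gold.pose if hasattr(gold, "pose") else gold
    err = mvd_distance(pose, gold_pose, nf)
    return UNSUCCESSFUL if err > tolerance else SUCCESSFUL
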