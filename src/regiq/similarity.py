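"""Normalized mutual information within a 2D ROI and the registration cost.

The similarity between a rendered DRR and a reference radiograph is the
normalized mutual information NMI = (H(A) + H(B)) / H(A, B) computed from a
joint intensity histogram over the ROI pixels; it lies in (1, 2], reaching 2
only when the images determine each other exactly.  The registration cost is
the negated mean NMI over the two orthogonal panels, so lower is better and
the ideal noiseless match costs -2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from regiq.geometry import Image2D, ProjectionGeometry, RigidTransform, render_drr

__all__ = ["Roi2D", "nmi", "cost", "CostFunction", "DegenerateImageError"]


class DegenerateImageError(ValueError):
    """Raised when an image is constant inside the ROI (zero entropy)."""


@dataclass(frozen=True)
class Roi2D:
    """Half-open pixel rectangle [row_min, row_max) x [col_min, col_max)."""

    row_min: int
    row_max: int
    col_min: int
    col_max: int
    panel_id: str = ""

    def __post_init__(self):
        if self.row_max <= self.row_min or self.col_max <= self.col_min:
            raise ValueError("ROI must be non-empty")
        if self.row_min < 0 or self.col_min < 0:
            raise ValueError("ROI must have non-negative corners")

    def extract(self, img: Image2D) -> np.ndarray:
        v = img.values
        if self.row_max > v.shape[0] or self.col_max > v.shape[1]:
            raise ValueError("ROI exceeds image bounds")
        return v[self.row_min:self.row_max, self.col_min:self.col_max]


def _entropies(a: np.ndarray, b: np.ndarray, bins: int,
               range_a=None, range_b=None):
    if range_a is None:
        range_a = (float(a.min()), float(a.max()))
    if range_b is None:
        range_b = (float(b.min()), float(b.max()))
    if range_a[1] <= range_a[0] or range_b[1] <= range_b[0]:
        raise DegenerateImageError("constant image inside ROI: entropy is zero")
    joint, _, _ = np.histogram2d(a.ravel(), b.ravel(), bins=bins,
                                 range=(range_a, range_b))
    p = joint / joint.sum()
    # marginals via sorted sequential sums: the swapped call sees the
    # transposed joint, and sorting each row/column before a cumulative sum
    # makes the reductions bitwise identical either way round
    pa = np.sort(p, axis=1).cumsum(axis=1)[:, -1]
    pb = np.sort(p, axis=0).cumsum(axis=0)[-1, :]

    def H(q):
        # canonical (sorted) summation order makes nmi(a, b) == nmi(b, a)
        # bitwise exact: the joint histogram of the swapped call is the
        # transpose, so its probabilities are the same multiset
        q = np.sort(q[q > 0])
        return float(-(q * np.log(q)).sum())

    return H(pa), H(pb), H(p.ravel())


def nmi(a: Image2D, b: Image2D, roi: Roi2D, bins: int = 64,
        range_a=None, range_b=None) -> float:
    """Normalized mutual information (H(A)+H(B))/H(A,B) over the ROI.

    Each image is binned min-max inside the ROI unless an explicit intensity
    range is supplied.  Raises :class:`DegenerateImageError` if either image
    is constant inside the ROI.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if a.values.shape != b.values.shape:
        raise ValueError("images must have the same shape")
    ra = roi.extract(a)
    rb = roi.extract(b)
    ha, hb, hab = _entropies(ra, rb, bins, range_a, range_b)
    if hab == 0.0:
        raise DegenerateImageError("joint entropy is zero inside ROI")
    return (ha + hb) / hab


class CostFunction:
    """Negated two-panel NMI as a function of the 6 pose parameters.

    Pre-binds the volume, geometry, reference images and ROIs of one
    registration problem.  The reference intensity range for histogram
    binning is fixed from each reference ROI once, so the cost is comparable
    across iterations; the DRR range is taken min-max per evaluation.

    Calling with a 6-vector ``(tx, ty, tz, rx, ry, rz)`` returns the cost in
    [-2, -1); evaluations are counted and optionally memoized (profile
    sweeps at nested step sizes revisit identical offsets).

    A DRR that is constant inside the ROI (the pose pushed the object out of
    view) has zero entropy; by default this raises
    :class:`DegenerateImageError`.  With ``degenerate_nmi`` set, that panel
    instead contributes the zero-information limit of the NMI —
    ``H(B) = 0`` gives ``(H(A)+0)/H(A,B) = 1`` — so far-field poses get a
    well-defined worst-case cost and profile sweeps beyond the capture range
    stay finite.
    """

    def __init__(self, volume, case, bins: int = 64, step: float = None,
                 memoize: bool = False, degenerate_nmi: float = None):
        self.volume = volume
        self.geometry: ProjectionGeometry = case.geometry
        self.references = case.references
        self.rois = case.rois
        self.bins = bins
        self.step = step
        self.degenerate_nmi = degenerate_nmi
        self.n_evaluations = 0
        self._ref_ranges = {}
        for pid, img in self.references.items():
            r = self.rois[pid].extract(img)
            if r.max() <= r.min():
                raise DegenerateImageError(
                    f"reference image constant inside ROI on panel {pid!r}")
            self._ref_ranges[pid] = (float(r.min()), float(r.max()))
        self._cache = {} if memoize else None

    def pose_cost(self, pose: RigidTransform) -> float:
        return self(pose.params)

    def __call__(self, params) -> float:
        params = np.asarray(params, dtype=float).reshape(6)
        if self._cache is not None:
            key = tuple(np.round(params, 9))
            hit = self._cache.get(key)
            if hit is not None:
                return hit
        pose = RigidTransform.from_params(params)
        vals = []
        for panel in self.geometry.panels:
            pid = panel.panel_id
            drr = render_drr(self.volume, pose, panel, mode=self.geometry.mode,
                             step=self.step)
            try:
                vals.append(nmi(self.references[pid], drr, self.rois[pid],
                                bins=self.bins, range_a=self._ref_ranges[pid]))
            except DegenerateImageError:
                if self.degenerate_nmi is None:
                    raise
                vals.append(self.degenerate_nmi)
        c = -float(np.mean(vals))
        self.n_evaluations += 1
        if self._cache is not None:
            self._cache[key] = c
        return c


def cost(volume, pose: RigidTransform, case, bins: int = 64,
         step: float = None) -> float:
    """Negated mean NMI over the two panels at ``pose``; lower is better."""
    return CostFunction(volume, case, bins=bins, step=step).pose_cost(pose)
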