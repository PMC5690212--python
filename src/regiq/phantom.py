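"""Seeded synthetic head phantoms, reference projection pairs and study campaigns.

The generator stands in for a clinical planning CT plus daily orthogonal
setup radiographs.  A phantom is a bright ellipsoidal shell ("skull") with a
lower-intensity interior, several asymmetrically placed internal blobs (so no
rotation maps the phantom onto itself and the registration optimum is
unique), and zero background.  A *case* is a pair of reference projections
rendered at a known true pose with additive Gaussian noise; a *campaign* is
the full study design of subjects x fractions x repeated registrations, with
per-subject anatomical variation and small per-fraction setup offsets.

The recorded true pose is simulation ground truth; the registration gold
standard is determined separately by multi-start optimization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from regiq.geometry import Image2D, ProjectionGeometry, RigidTransform, render_drr
from regiq.mvd import Roi3D
from regiq.similarity import Roi2D

__all__ = [
    "Volume",
    "StudyDesign",
    "Case",
    "Campaign",
    "make_head_phantom",
    "make_case",
    "make_campaign",
]


@dataclass
class Volume:
    """3D intensity grid with mm spacing and an isocenter (rotation centre).

    The physical origin is the corner of the first voxel; voxel centre ``i``
    is at ``(i + 0.5) * spacing``.  Intensities are HU-like arbitrary units.
    """

    values: np.ndarray
    spacing: np.ndarray
    isocenter: np.ndarray
    volume_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.isocenter = np.asarray(self.isocenter, dtype=float).reshape(3)
        if self.values.ndim != 3:
            raise ValueError("volume values must be 3D")
        if not np.all(self.spacing > 0):
            raise ValueError("all spacing entries must be > 0")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume values must be finite")
        extent = self.extent
        if np.any(self.isocenter < 0) or np.any(self.isocenter > extent):
            raise ValueError("isocenter must lie inside the physical extent")

    @property
    def extent(self) -> np.ndarray:
        """Physical size (mm) per axis."""
        return np.asarray(self.values.shape) * self.spacing


@dataclass(frozen=True)
class StudyDesign:
    """Campaign shape: subjects x fractions/subject x registrations/fraction."""

    n_subjects: int
    n_fractions_per_subject: int
    n_repeats_per_fraction: int
    seed: int = 0

    def __post_init__(self):
        for name in ("n_subjects", "n_fractions_per_subject", "n_repeats_per_fraction"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def n_planned_registrations(self) -> int:
        return (self.n_subjects * self.n_fractions_per_subject
                * self.n_repeats_per_fraction)

    @property
    def n_training_pool(self) -> int:
        """Labeled solutions available per leave-one-subject-out fold."""
        return (self.n_subjects - 1) * self.n_fractions_per_subject * self.n_repeats_per_fraction


@dataclass
class Case:
    """One fraction's reference image pair with geometry, ROIs and ground truth."""

    case_id: str
    subject_id: str
    fraction: int
    references: dict  # panel id -> Image2D
    geometry: ProjectionGeometry
    rois: dict  # panel id -> Roi2D
    true_pose: RigidTransform
    noise_sd: float
    seed: object = None


@dataclass
class Campaign:
    """A full synthetic study: per-subject phantoms and per-fraction cases."""

    design: StudyDesign
    volumes: dict  # subject id -> Volume
    rois3d: dict  # subject id -> Roi3D (MVD normalization ROI)
    cases: list  # of Case
    noise_sd: float

    @property
    def subject_ids(self):
        return sorted(self.volumes)

    def cases_for(self, subject_id: str):
        return [c for c in self.cases if c.subject_id == subject_id]


def make_head_phantom(seed, grid_size=(64, 64, 64), spacing=(2.0, 2.0, 2.0),
                      volume_id: str = "") -> Volume:
    """Generate a head-like phantom volume, deterministic per seed.

    The phantom is a bright ellipsoidal shell (intensity ~1000) around a
    soft-tissue-like interior (~60) containing at least five asymmetric
    Gaussian blobs (200-700); the background is 0.  Shell eccentricity and
    blob count/placement are jittered by the seed, providing subject-level
    anatomical variation.
    """
    if np.ndim(grid_size) == 0:
        grid_size = (int(grid_size),) * 3
    grid_size = tuple(int(g) for g in grid_size)
    if np.ndim(spacing) == 0:
        spacing = (float(spacing),) * 3
    spacing = np.asarray(spacing, dtype=float).reshape(3)
    if min(grid_size) < 32:
        raise ValueError("grid_size must be >= 32 per axis to contain the shell")

    rng = np.random.default_rng(seed)
    extent = np.asarray(grid_size) * spacing
    center = extent / 2.0

    # voxel-centre physical coordinates
    xs = [(np.arange(n) + 0.5) * s for n, s in zip(grid_size, spacing)]
    X, Y, Z = np.meshgrid(*xs, indexing="ij")

    # ellipsoid semi-axes ~38% of extent with per-subject eccentricity jitter
    semi = extent * (0.38 + 0.03 * rng.uniform(-1, 1, size=3))
    rho = np.sqrt(((X - center[0]) / semi[0]) ** 2
                  + ((Y - center[1]) / semi[1]) ** 2
                  + ((Z - center[2]) / semi[2]) ** 2)

    vol = np.zeros(grid_size, dtype=np.float32)
    vol[rho <= 1.0] = 60.0          # interior soft tissue
    vol[(rho > 0.85) & (rho <= 1.0)] = 1000.0  # skull shell

    interior = rho <= 0.85

    def add_blob(pos, sigma, amp):
        d2 = (X - pos[0]) ** 2 + (Y - pos[1]) ** 2 + (Z - pos[2]) ** 2
        blob = amp * np.exp(-0.5 * d2 / sigma**2)
        vol[interior] += blob[interior].astype(np.float32)

    n_blobs = int(rng.integers(5, 9))
    placed = 0
    while placed < n_blobs:
        u = rng.uniform(-0.6, 0.6, size=3)
        if np.sum(u * u) > 0.36:  # keep blob centres well inside the shell
            continue
        add_blob(center + u * semi, rng.uniform(4.0, 10.0), rng.uniform(200.0, 700.0))
        placed += 1

    # two quasi-periodic chains of equal bone-density blobs: repetitive
    # structure (vertebra/skull-base-like) whose self-similarity under a
    # one-period shift creates distant local minima that trap
    # intensity-based registration; projected contrast is comparable to the
    # skull shell's, as for real bony anatomy.  The chains run in two
    # roughly orthogonal directions so aliasing traps exist for more of the
    # initialization space; the random blobs above keep the optimum unique.
    base_axes = (np.array([0.0, 0.0, 1.0]), np.array([1.0, 0.0, 0.0]))
    for base in base_axes:
        n_chain = 3
        period = rng.uniform(20.0, 25.0)  # mm
        axis_dir = base + rng.uniform(-0.25, 0.25, size=3)
        axis_dir /= np.linalg.norm(axis_dir)
        chain_center = center + rng.uniform(-0.25, 0.25, size=3) * semi
        sigma_c = rng.uniform(9.0, 12.0)  # large and smooth: the cost stays
        amp_c = rng.uniform(700.0, 1100.0)  # smooth at mm scale, aliased at ~period
        for k in range(n_chain):
            pos = chain_center + (k - (n_chain - 1) / 2.0) * period * axis_dir
            add_blob(pos, sigma_c, amp_c)

    return Volume(values=vol, spacing=spacing, isocenter=center, volume_id=volume_id)


def brain_roi(volume: Volume, shrink: float = 0.55) -> Roi3D:
    """Axis-aligned cuboid centred on the isocenter enclosing the interior.

    Emulates a whole-brain MVD normalization ROI: the box spans ``shrink`` of
    the volume extent about the isocenter.
    """
    half = volume.extent * shrink / 2.0
    return Roi3D(lo=volume.isocenter - half, hi=volume.isocenter + half)


def _roi_from_projection(img: Image2D, pad: int = 2, frac: float = 0.01) -> Roi2D:
    """Rectangle around pixels above ``frac`` of the image maximum."""
    v = img.values
    mask = v > frac * v.max()
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        raise ValueError("projection is empty; cannot define an ROI")
    return Roi2D(
        row_min=max(0, rows[0] - pad),
        row_max=min(v.shape[0], rows[-1] + 1 + pad),
        col_min=max(0, cols[0] - pad),
        col_max=min(v.shape[1], cols[-1] + 1 + pad),
        panel_id=img.panel_id,
    )


def make_case(volume: Volume, true_pose: RigidTransform, noise_sd: float, seed,
              geometry: ProjectionGeometry = None, case_id: str = "",
              subject_id: str = "", fraction: int = 0) -> Case:
    """Render the two reference panels at ``true_pose`` and add Gaussian noise.

    Returns the reference image pair, rectangular per-panel ROIs covering the
    projected head, and the true pose recorded as simulation ground truth.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if geometry is None:
        n_pix = int(np.ceil(volume.extent.max() / float(volume.spacing.min())))
        geometry = ProjectionGeometry.default_orthogonal(
            n_pixels=n_pix, pixel_spacing=float(volume.spacing.min()))
    rng = np.random.default_rng(seed)
    references, rois = {}, {}
    for panel in geometry.panels:
        img = render_drr(volume, true_pose, panel, mode=geometry.mode)
        rois[panel.panel_id] = _roi_from_projection(img)
        if noise_sd > 0:
            img.values = img.values + rng.normal(0.0, noise_sd, size=img.values.shape)
        references[panel.panel_id] = img
    return Case(case_id=case_id, subject_id=subject_id, fraction=fraction,
                references=references, geometry=geometry, rois=rois,
                true_pose=true_pose, noise_sd=noise_sd, seed=seed)


def make_campaign(design: StudyDesign, grid_size=(64, 64, 64),
                  spacing=(2.0, 2.0, 2.0), noise_frac: float = 0.03,
                  pose_range=(3.0, 1.5), geometry: ProjectionGeometry = None) -> Campaign:
    """Build the synthetic study: one phantom per subject, one true pose and
    reference pair per fraction.

    Per-fraction true poses are drawn uniformly within ``pose_range``
    (+-mm, +-deg) of identity, emulating daily setup variation.  Noise sd is
    ``noise_frac`` of the maximum noiseless projection intensity of the first
    subject, fixed across the campaign so panels are comparable.
    """
    volumes, rois3d, cases = {}, {}, []
    noise_sd = None
    for s in range(design.n_subjects):
        sid = f"S{s + 1:02d}"
        vol = make_head_phantom([design.seed, 101, s], grid_size=grid_size,
                                spacing=spacing, volume_id=sid)
        volumes[sid] = vol
        rois3d[sid] = brain_roi(vol)
        if geometry is None:
            n_pix = int(np.ceil(vol.extent.max() / float(vol.spacing.min())))
            geometry = ProjectionGeometry.default_orthogonal(
                n_pixels=n_pix, pixel_spacing=float(vol.spacing.min()))
        if noise_sd is None:
            ref = render_drr(vol, RigidTransform.identity(), geometry.panels[0],
                             mode=geometry.mode)
            noise_sd = float(noise_frac * ref.values.max())
        for f in range(design.n_fractions_per_subject):
            rng = np.random.default_rng([design.seed, 202, s, f])
            t = rng.uniform(-pose_range[0], pose_range[0], size=3)
            r = rng.uniform(-pose_range[1], pose_range[1], size=3)
            pose = RigidTransform(t=t, r=r)
            case = make_case(vol, pose, noise_sd, seed=[design.seed, 303, s, f],
                             geometry=geometry, case_id=f"{sid}_F{f + 1:02d}",
                             subject_id=sid, fraction=f)
            cases.append(case)
    return Campaign(design=design, volumes=volumes, rois3d=rois3d, cases=cases,
                    noise_sd=noise_sd)
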