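"""Rigid transforms, orthogonal two-panel projection geometry and DRR rendering.

Conventions
-----------
* Physical coordinates are in mm.  A volume occupies ``[0, shape*spacing)``
  with the origin at the corner of the first voxel; voxel centre ``i`` sits at
  ``(i + 0.5) * spacing``.
* A rigid pose has three translations (mm) and three rotations (deg) about
  the x, y and z axes through the volume isocenter.  Rotations are extrinsic
  (fixed-axis), applied x then y then z, followed by the translation:
  ``T(p) = R (p - c) + c + t`` with ``R = Rz Ry Rx`` and ``c`` the isocenter.
* The default two-panel geometry is a lateral view along +x and a
  posterior-anterior (PA) view along +y; the two view axes are orthogonal.
  Parallel-beam projection is the default; a perspective (divergent) mode
  with configurable source/detector distances is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit
from scipy.spatial.transform import Rotation

__all__ = [
    "RigidTransform",
    "Panel",
    "ProjectionGeometry",
    "Image2D",
    "render_drr",
    "compose",
    "invert",
    "apply",
]


def _wrap_angles(r: np.ndarray) -> np.ndarray:
    """Wrap angles (deg) into (-180, 180]."""
    r = np.asarray(r, dtype=float)
    wrapped = -((-r + 180.0) % 360.0 - 180.0)
    return wrapped


@dataclass(frozen=True)
class RigidTransform:
    """6-DOF rigid pose: translations ``t`` (mm) and rotations ``r`` (deg).

    Rotations act about the x, y, z axes through the isocenter, extrinsic,
    in the order x, y, z.  The isocenter itself is a property of the volume,
    not of the transform; two transforms compose consistently as long as they
    share a rotation centre.
    """

    t: np.ndarray = field(default_factory=lambda: np.zeros(3))
    r: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float).reshape(3).copy())
        object.__setattr__(self, "r", _wrap_angles(np.asarray(self.r, dtype=float).reshape(3)))

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_params(cls, params: np.ndarray) -> "RigidTransform":
        """Build from a 6-vector ``(tx, ty, tz, rx, ry, rz)``."""
        p = np.asarray(params, dtype=float).reshape(6)
        return cls(t=p[:3], r=p[3:])

    @property
    def params(self) -> np.ndarray:
        """The 6-vector ``(tx, ty, tz, rx, ry, rz)``."""
        return np.concatenate([self.t, self.r])

    def rotation_matrix(self) -> np.ndarray:
        """3x3 rotation matrix ``Rz @ Ry @ Rx``."""
        return Rotation.from_euler("xyz", self.r, degrees=True).as_matrix()

    def __eq__(self, other) -> bool:
        if not isinstance(other, RigidTransform):
            return NotImplemented
        return bool(np.array_equal(self.t, other.t) and np.array_equal(self.r, other.r))

    def __repr__(self) -> str:
        t = ", ".join(f"{v:.3f}" for v in self.t)
        r = ", ".join(f"{v:.3f}" for v in self.r)
        return f"RigidTransform(t=[{t}] mm, r=[{r}] deg)"


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """The transform applying ``b`` first, then ``a`` (about a shared isocenter)."""
    Ra = a.rotation_matrix()
    Rb = b.rotation_matrix()
    R = Ra @ Rb
    t = a.t + Ra @ b.t
    r = Rotation.from_matrix(R).as_euler("xyz", degrees=True)
    return RigidTransform(t=t, r=r)


def invert(a: RigidTransform) -> RigidTransform:
    """Inverse transform: ``apply(invert(a), apply(a, p)) == p``."""
    Rinv = a.rotation_matrix().T
    r = Rotation.from_matrix(Rinv).as_euler("xyz", degrees=True)
    return RigidTransform(t=-(Rinv @ a.t), r=r)


def apply(a: RigidTransform, points: np.ndarray, isocenter: np.ndarray) -> np.ndarray:
    """Apply the transform to points (mm), rotating about ``isocenter``."""
    c = np.asarray(isocenter, dtype=float)
    p = np.asarray(points, dtype=float)
    R = a.rotation_matrix()
    return (p - c) @ R.T + c + a.t


@dataclass(frozen=True)
class Panel:
    """One detector panel of the orthogonal pair.

    ``view_axis`` is the unit ray direction; ``u_axis``/``v_axis`` span the
    detector plane (image columns/rows).  The detector is centred on the
    isocenter.  ``source_to_iso``/``iso_to_detector`` (mm) are used only in
    perspective mode.
    """

    panel_id: str
    view_axis: np.ndarray
    u_axis: np.ndarray
    v_axis: np.ndarray
    pixel_spacing: float
    size: tuple  # (n_v rows, n_u cols)
    source_to_iso: float = 1000.0
    iso_to_detector: float = 500.0

    def __post_init__(self):
        for name in ("view_axis", "u_axis", "v_axis"):
            v = np.asarray(getattr(self, name), dtype=float).reshape(3)
            n = np.linalg.norm(v)
            if n == 0:
                raise ValueError(f"{name} must be non-zero")
            object.__setattr__(self, name, v / n)
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be > 0")


@dataclass(frozen=True)
class ProjectionGeometry:
    """Two orthogonal panels plus the projection mode."""

    panels: tuple
    mode: str = "parallel"  # "parallel" | "perspective"

    def __post_init__(self):
        if self.mode not in ("parallel", "perspective"):
            raise ValueError(f"unknown projection mode {self.mode!r}")
        if len(self.panels) != 2:
            raise ValueError("exactly two panels are required")
        dot = abs(float(np.dot(self.panels[0].view_axis, self.panels[1].view_axis)))
        if dot > 1e-9:
            raise ValueError("panel view axes must be orthogonal")

    def panel(self, panel_id: str) -> Panel:
        for p in self.panels:
            if p.panel_id == panel_id:
                return p
        raise KeyError(panel_id)

    @classmethod
    def default_orthogonal(cls, n_pixels: int, pixel_spacing: float,
                           mode: str = "parallel",
                           source_to_iso: float = 1000.0,
                           iso_to_detector: float = 500.0) -> "ProjectionGeometry":
        """Lateral panel viewing along +x, PA panel along +y, square detectors."""
        lat = Panel("lateral", view_axis=(1, 0, 0), u_axis=(0, 1, 0), v_axis=(0, 0, 1),
                    pixel_spacing=pixel_spacing, size=(n_pixels, n_pixels),
                    source_to_iso=source_to_iso, iso_to_detector=iso_to_detector)
        pa = Panel("pa", view_axis=(0, 1, 0), u_axis=(1, 0, 0), v_axis=(0, 0, 1),
                   pixel_spacing=pixel_spacing, size=(n_pixels, n_pixels),
                   source_to_iso=source_to_iso, iso_to_detector=iso_to_detector)
        return cls(panels=(lat, pa), mode=mode)


@dataclass
class Image2D:
    """A 2D scalar image with its pixel spacing (mm) and panel id."""

    values: np.ndarray
    pixel_spacing: float
    panel_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("Image2D requires a 2D array")


@njit(cache=True, fastmath=True)
def _drr_parallel(vol, A, b, origins_u, origins_v, origin0, du, dv, ray_dir,
                  n_steps, step, out):  # pragma: no cover - numba
    nx, ny, nz = vol.shape
    H, W = out.shape
    dx, dy, dz = ray_dir[0], ray_dir[1], ray_dir[2]
    for i in range(H):
        for j in range(W):
            ox = origin0[0] + origins_v[i] * dv[0] + origins_u[j] * du[0]
            oy = origin0[1] + origins_v[i] * dv[1] + origins_u[j] * du[1]
            oz = origin0[2] + origins_v[i] * dv[2] + origins_u[j] * du[2]
            acc = 0.0
            for k in range(n_steps):
                t = (k + 0.5) * step
                px = ox + t * dx
                py = oy + t * dy
                pz = oz + t * dz
                x = A[0, 0] * px + A[0, 1] * py + A[0, 2] * pz + b[0]
                y = A[1, 0] * px + A[1, 1] * py + A[1, 2] * pz + b[1]
                z = A[2, 0] * px + A[2, 1] * py + A[2, 2] * pz + b[2]
                if x < 0.0 or y < 0.0 or z < 0.0 or x > nx - 1.0 or y > ny - 1.0 or z > nz - 1.0:
                    continue
                ix = int(x)
                iy = int(y)
                iz = int(z)
                if ix > nx - 2:
                    ix = nx - 2
                if iy > ny - 2:
                    iy = ny - 2
                if iz > nz - 2:
                    iz = nz - 2
                fx = x - ix
                fy = y - iy
                fz = z - iz
                c00 = vol[ix, iy, iz] * (1 - fx) + vol[ix + 1, iy, iz] * fx
                c10 = vol[ix, iy + 1, iz] * (1 - fx) + vol[ix + 1, iy + 1, iz] * fx
                c01 = vol[ix, iy, iz + 1] * (1 - fx) + vol[ix + 1, iy, iz + 1] * fx
                c11 = vol[ix, iy + 1, iz + 1] * (1 - fx) + vol[ix + 1, iy + 1, iz + 1] * fx
                c0 = c00 * (1 - fy) + c10 * fy
                c1 = c01 * (1 - fy) + c11 * fy
                acc += (c0 * (1 - fz) + c1 * fz) * step
            out[i, j] = acc
    return out


@njit(cache=True, fastmath=True)
def _drr_perspective(vol, A, b, origins_u, origins_v, det0, du, dv, source,
                     n_steps, step, out):  # pragma: no cover - numba
    nx, ny, nz = vol.shape
    H, W = out.shape
    for i in range(H):
        for j in range(W):
            px0 = det0[0] + origins_v[i] * dv[0] + origins_u[j] * du[0]
            py0 = det0[1] + origins_v[i] * dv[1] + origins_u[j] * du[1]
            pz0 = det0[2] + origins_v[i] * dv[2] + origins_u[j] * du[2]
            dx = px0 - source[0]
            dy = py0 - source[1]
            dz = pz0 - source[2]
            norm = (dx * dx + dy * dy + dz * dz) ** 0.5
            dx /= norm
            dy /= norm
            dz /= norm
            acc = 0.0
            for k in range(n_steps):
                t = (k + 0.5) * step
                px = source[0] + t * dx
                py = source[1] + t * dy
                pz = source[2] + t * dz
                x = A[0, 0] * px + A[0, 1] * py + A[0, 2] * pz + b[0]
                y = A[1, 0] * px + A[1, 1] * py + A[1, 2] * pz + b[1]
                z = A[2, 0] * px + A[2, 1] * py + A[2, 2] * pz + b[2]
                if x < 0.0 or y < 0.0 or z < 0.0 or x > nx - 1.0 or y > ny - 1.0 or z > nz - 1.0:
                    continue
                ix = int(x)
                iy = int(y)
                iz = int(z)
                if ix > nx - 2:
                    ix = nx - 2
                if iy > ny - 2:
                    iy = ny - 2
                if iz > nz - 2:
                    iz = nz - 2
                fx = x - ix
                fy = y - iy
                fz = z - iz
                c00 = vol[ix, iy, iz] * (1 - fx) + vol[ix + 1, iy, iz] * fx
                c10 = vol[ix, iy + 1, iz] * (1 - fx) + vol[ix + 1, iy + 1, iz] * fx
                c01 = vol[ix, iy, iz + 1] * (1 - fx) + vol[ix + 1, iy, iz + 1] * fx
                c11 = vol[ix, iy + 1, iz + 1] * (1 - fx) + vol[ix + 1, iy + 1, iz + 1] * fx
                c0 = c00 * (1 - fy) + c10 * fy
                c1 = c01 * (1 - fy) + c11 * fy
                acc += (c0 * (1 - fz) + c1 * fz) * step
            out[i, j] = acc
    return out


def _world_to_index_affine(volume, pose: RigidTransform):
    """Affine (A, b) mapping a world point to fractional voxel indices of the
    posed volume: ``idx = A @ p + b`` where the volume has been moved by
    ``pose`` (sampling the posed volume at p = sampling the static volume at
    pose^-1(p))."""
    c = np.asarray(volume.isocenter, dtype=float)
    spacing = np.asarray(volume.spacing, dtype=float)
    Rinv = pose.rotation_matrix().T
    # pose^-1(p) = Rinv (p - c - t) + c ; index = q / spacing - 0.5
    A = Rinv / spacing[:, None]
    b = (c - Rinv @ (c + pose.t)) / spacing - 0.5
    return np.ascontiguousarray(A), np.ascontiguousarray(b)


def render_drr(volume, pose: RigidTransform, panel: Panel,
               mode: str = "parallel", step: float = None) -> Image2D:
    """Render a DRR of ``volume`` posed at ``pose`` onto ``panel``.

    Each pixel is the line integral of trilinearly interpolated volume
    intensity along the pixel's ray (fixed-step midpoint rule); rays missing
    the volume give 0.  ``step`` defaults to half the minimum voxel spacing.

    Parameters
    ----------
    volume : Volume
        Object with ``values`` (3D float array), ``spacing`` (mm) and
        ``isocenter`` (mm) attributes.
    pose : RigidTransform
        Pose of the volume in world coordinates.
    panel : Panel
        Detector description; the detector is centred on the isocenter.
    mode : {"parallel", "perspective"}
    step : float, optional
        Ray sampling step in mm.
    """
    spacing = np.asarray(volume.spacing, dtype=float)
    if step is None:
        step = 0.5 * float(spacing.min())
    if step <= 0:
        raise ValueError("step must be > 0")
    vol = np.ascontiguousarray(volume.values, dtype=np.float32)
    A, b = _world_to_index_affine(volume, pose)
    H, W = int(panel.size[0]), int(panel.size[1])
    iso = np.asarray(volume.isocenter, dtype=float)
    offs_u = (np.arange(W) - (W - 1) / 2.0) * panel.pixel_spacing
    offs_v = (np.arange(H) - (H - 1) / 2.0) * panel.pixel_spacing
    out = np.zeros((H, W), dtype=np.float64)

    # posed bounding-box corners in world coordinates bound the ray interval
    extent = np.asarray(vol.shape) * spacing
    corners = np.array([[x, y, z] for x in (0.0, extent[0])
                        for y in (0.0, extent[1]) for z in (0.0, extent[2])])
    posed = apply(pose, corners, iso)

    d = panel.view_axis
    if mode == "parallel":
        proj = (posed - iso) @ d
        t_lo, t_hi = float(proj.min()) - step, float(proj.max()) + step
        n_steps = max(1, int(np.ceil((t_hi - t_lo) / step)))
        origin0 = iso + t_lo * d
        _drr_parallel(vol, A, b, offs_u, offs_v, origin0, panel.u_axis,
                      panel.v_axis, d, n_steps, step, out)
    elif mode == "perspective":
        source = iso - panel.source_to_iso * d
        det0 = iso + panel.iso_to_detector * d
        # conservative interval from the source; out-of-volume samples are 0
        dist = np.linalg.norm(posed - source, axis=1)
        t_hi = float(dist.max()) + step
        n_steps = max(1, int(np.ceil(t_hi / step)))
        _drr_perspective(vol, A, b, offs_u, offs_v, det0, panel.u_axis,
                         panel.v_axis, source, n_steps, step, out)
    else:
        raise ValueError(f"unknown projection mode {mode!r}")
    return Image2D(values=out, pixel_spacing=panel.pixel_spacing, panel_id=panel.panel_id)


def render_pair(volume, pose: RigidTransform, geometry: ProjectionGeometry,
                step: float = None):
    """Render DRRs on both panels; returns a dict keyed by panel id."""
    return {p.panel_id: render_drr(volume, pose, p, mode=geometry.mode, step=step)
            for p in geometry.panels}
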