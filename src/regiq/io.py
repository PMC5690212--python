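"""File formats: volumes as NIfTI, projections as 16-bit PNG, JSON records.

Volumes are written as ``.nii.gz`` with the voxel spacing in the affine and
a JSON sidecar carrying the isocenter and id (NIfTI has no native slot for a
rotation centre).  Projections are stored as 16-bit PNG with an intensity
scale in a sidecar so the float DRR values round-trip to plotting precision.
Poses, ROIs, geometry and campaign manifests are plain JSON/YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import yaml

from regiq.geometry import Image2D, Panel, ProjectionGeometry, RigidTransform
from regiq.mvd import Roi3D
from regiq.phantom import Volume
from regiq.similarity import Roi2D

__all__ = [
    "save_volume", "load_volume", "save_image", "load_image",
    "save_geometry", "load_geometry", "pose_to_dict", "pose_from_dict",
    "roi2d_to_dict", "roi2d_from_dict", "roi3d_to_dict", "roi3d_from_dict",
]


def save_volume(volume: Volume, path) -> None:
    path = Path(path)
    affine = np.diag(list(volume.spacing) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume.values, dtype=np.float32), affine), path)
    sidecar = {"isocenter_mm": volume.isocenter.tolist(), "volume_id": volume.volume_id}
    path.with_suffix("").with_suffix(".json").write_text(json.dumps(sidecar))


def load_volume(path) -> Volume:
    path = Path(path)
    img = nib.load(path)
    spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
    values = np.asarray(img.dataobj, dtype=np.float32)
    sidecar_path = path.with_suffix("").with_suffix(".json")
    iso = np.asarray(values.shape) * spacing / 2.0
    vid = ""
    if sidecar_path.exists():
        sc = json.loads(sidecar_path.read_text())
        iso = np.asarray(sc.get("isocenter_mm", iso), dtype=float)
        vid = sc.get("volume_id", "")
    return Volume(values=values, spacing=spacing, isocenter=iso, volume_id=vid)


def save_image(img: Image2D, path) -> None:
    """16-bit PNG plus a JSON sidecar with the intensity scale and spacing."""
    path = Path(path)
    v = img.values
    vmax = float(v.max()) if v.size else 1.0
    scale = 65535.0 / vmax if vmax > 0 else 1.0
    iio.imwrite(path, np.clip(v * scale, 0, 65535).astype(np.uint16))
    sidecar = {"intensity_scale": scale, "pixel_spacing_mm": img.pixel_spacing,
               "panel_id": img.panel_id}
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def load_image(path) -> Image2D:
    path = Path(path)
    raw = np.asarray(iio.imread(path), dtype=float)
    sc = json.loads(path.with_suffix(".json").read_text())
    return Image2D(values=raw / sc["intensity_scale"],
                   pixel_spacing=sc["pixel_spacing_mm"], panel_id=sc["panel_id"])


def _panel_to_dict(p: Panel) -> dict:
    return {"panel_id": p.panel_id, "view_axis": p.view_axis.tolist(),
            "u_axis": p.u_axis.tolist(), "v_axis": p.v_axis.tolist(),
            "pixel_spacing": p.pixel_spacing, "size": list(p.size),
            "source_to_iso": p.source_to_iso, "iso_to_detector": p.iso_to_detector}


def save_geometry(geom: ProjectionGeometry, path) -> None:
    d = {"mode": geom.mode, "panels": [_panel_to_dict(p) for p in geom.panels]}
    Path(path).write_text(yaml.safe_dump(d))


def load_geometry(path) -> ProjectionGeometry:
    d = yaml.safe_load(Path(path).read_text())
    panels = tuple(Panel(panel_id=p["panel_id"], view_axis=p["view_axis"],
                         u_axis=p["u_axis"], v_axis=p["v_axis"],
                         pixel_spacing=p["pixel_spacing"], size=tuple(p["size"]),
                         source_to_iso=p.get("source_to_iso", 1000.0),
                         iso_to_detector=p.get("iso_to_detector", 500.0))
                   for p in d["panels"])
    return ProjectionGeometry(panels=panels, mode=d["mode"])


def pose_to_dict(pose: RigidTransform) -> dict:
    return {"t_mm": pose.t.tolist(), "r_deg": pose.r.tolist()}


def pose_from_dict(d: dict) -> RigidTransform:
    return RigidTransform(t=d["t_mm"], r=d["r_deg"])


def roi2d_to_dict(roi: Roi2D) -> dict:
    return {"panel_id": roi.panel_id,
            "rect": [int(roi.row_min), int(roi.row_max),
                     int(roi.col_min), int(roi.col_max)]}


def roi2d_from_dict(d: dict) -> Roi2D:
    r = d["rect"]
    return Roi2D(row_min=r[0], row_max=r[1], col_min=r[2], col_max=r[3],
                 panel_id=d["panel_id"])


def roi3d_to_dict(roi: Roi3D) -> dict:
    return {"lo_mm": roi.lo.tolist(), "hi_mm": roi.hi.tolist()}


def roi3d_from_dict(d: dict) -> Roi3D:
    return Roi3D(lo=d["lo_mm"], hi=d["hi_mm"])
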