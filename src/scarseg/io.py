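"""Reading and writing slices, masks, and cohort manifests.

Images travel as 16-bit PNG with a JSON geometry sidecar, NIfTI (spacing
from the affine), or DICOM (PixelSpacing / SliceThickness tags); masks as
8-bit PNG or NIfTI.  A cohort is a directory of per-slice files plus a
manifest CSV (subject_id, slice_index, paths, burden, split).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from PIL import Image

from .core import SliceRecord, ValidationError, VoxelGeometry

__all__ = [
    "load_slice",
    "save_slice_png",
    "save_slice_nifti",
    "load_mask",
    "save_mask_png",
    "save_cohort",
    "load_cohort",
]


def _geometry_from_sidecar(path: Path) -> VoxelGeometry:
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise ValidationError(
            f"PNG image {path} needs a geometry sidecar {sidecar.name} "
            '({"row_spacing_mm": ..., "col_spacing_mm": ..., "thickness_mm": ...})'
        )
    d = json.loads(sidecar.read_text())
    return VoxelGeometry(d["row_spacing_mm"], d["col_spacing_mm"], d["thickness_mm"])


def load_slice(path) -> SliceRecord:
    """Load one image slice with its geometry (DICOM, NIfTI, or PNG+JSON)."""
    path = Path(path)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith(".dcm"):
        import pydicom

        ds = pydicom.dcmread(path)
        spacing = [float(v) for v in ds.PixelSpacing]
        thickness = float(getattr(ds, "SliceThickness", 0) or 0)
        if thickness <= 0:
            raise ValidationError(f"DICOM {path} lacks a positive SliceThickness")
        return SliceRecord(
            image=ds.pixel_array.astype(float),
            geometry=VoxelGeometry(spacing[0], spacing[1], thickness),
        )
    if suffixes.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        zooms = img.header.get_zooms()
        data = np.asarray(img.dataobj, dtype=float)
        if data.ndim == 3 and data.shape[2] == 1:
            data = data[:, :, 0]
        return SliceRecord(
            image=data,
            geometry=VoxelGeometry(float(zooms[0]), float(zooms[1]), float(zooms[2])),
        )
    if suffixes.endswith(".png"):
        data = np.asarray(Image.open(path), dtype=float)
        return SliceRecord(image=data, geometry=_geometry_from_sidecar(path))
    raise ValidationError(f"unsupported image format: {path}")


def save_slice_png(rec: SliceRecord, path) -> None:
    """Write a slice as 16-bit PNG (min–max scaled) plus a JSON geometry
    sidecar recording spacing and the original intensity range."""
    path = Path(path)
    img = rec.image.astype(float)
    lo, hi = float(img.min()), float(img.max())
    scaled = np.zeros_like(img) if hi == lo else (img - lo) / (hi - lo)
    Image.fromarray((scaled * 65535).astype(np.uint16)).save(path)
    g = rec.geometry
    path.with_suffix(".json").write_text(
        json.dumps(
            {
                "row_spacing_mm": g.row_spacing_mm,
                "col_spacing_mm": g.col_spacing_mm,
                "thickness_mm": g.thickness_mm,
                "intensity_min": lo,
                "intensity_max": hi,
            }
        )
    )


def save_slice_nifti(rec: SliceRecord, path) -> None:
    g = rec.geometry
    affine = np.diag([g.row_spacing_mm, g.col_spacing_mm, g.thickness_mm, 1.0])
    data = rec.image.astype(np.float32)[:, :, None]  # single-slice volume
    nib.save(nib.Nifti1Image(data, affine), str(path))


def load_mask(path) -> np.ndarray:
    path = Path(path)
    if "".join(path.suffixes).lower().endswith((".nii", ".nii.gz")):
        data = np.asarray(nib.load(str(path)).dataobj)
        if data.ndim == 3 and data.shape[2] == 1:
            data = data[:, :, 0]
        return data > 0
    return np.asarray(Image.open(path)) > 0


def save_mask_png(mask: np.ndarray, path) -> None:
    Image.fromarray((np.asarray(mask, dtype=bool) * 255).astype(np.uint8)).save(Path(path))


def save_cohort(cohort: Sequence[SliceRecord], out_dir, splits: Optional[Dict[str, set]] = None) -> Path:
    """Write a cohort as PNG images + masks and a manifest CSV; returns the
    manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    split_of = {}
    if splits:
        for name, ids in splits.items():
            for sid in ids:
                split_of[sid] = name
    for rec in cohort:
        stem = f"{rec.subject_id}_s{rec.slice_index:02d}"
        img_path = out / f"{stem}.png"
        save_slice_png(rec, img_path)
        row = {
            "subject_id": rec.subject_id,
            "slice_index": rec.slice_index,
            "image": img_path.name,
            "burden": rec.meta.get("burden", ""),
            "split": split_of.get(rec.subject_id, ""),
        }
        for name, mask in (("myo", rec.myo_mask), ("scar", rec.scar_mask)):
            if mask is not None:
                mpath = out / f"{stem}_{name}.png"
                save_mask_png(mask, mpath)
                row[f"{name}_mask"] = mpath.name
        rows.append(row)
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_cohort(manifest_path) -> List[SliceRecord]:
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    records = []
    for _, row in pd.read_csv(manifest_path, keep_default_na=False).iterrows():
        rec = load_slice(base / row["image"])
        myo = load_mask(base / row["myo_mask"]) if row.get("myo_mask") else None
        scar = load_mask(base / row["scar_mask"]) if row.get("scar_mask") else None
        records.append(
            rec.with_(
                myo_mask=myo,
                scar_mask=scar,
                subject_id=str(row["subject_id"]),
                slice_index=int(row["slice_index"]),
                meta={"split": row.get("split", ""), "burden": row.get("burden", "")},
            )
        )
    return records
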