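"""File I/O: NIfTI volumes and 4-D series, histology PNG label images with
JSON sidecars, and output manifests with checksums.

Volumes are written as NIfTI-1 (.nii.gz) in RAS orientation with an
isotropic voxel size in the header; label maps as int16; dynamic series as
4-D with the frame axis last.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np

from .phantom.geometry import PhantomLabelMap
from .phantom.histology import HISTO_CLASSES, HistologyField
from .phantom.presets import ROI_LABELS

__all__ = [
    "save_nifti",
    "load_nifti",
    "save_label_map",
    "load_label_map",
    "save_histology_field",
    "load_histology_field",
    "write_manifest",
]


def _affine(voxel_size_mm: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size_mm
    return aff


def save_nifti(array, path, voxel_size_mm: float = 0.5, dtype=None) -> Path:
    """Write a 3-D volume or 4-D series as NIfTI-1 (.nii.gz), RAS."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.asarray(array)
    if dtype is not None:
        data = data.astype(dtype)
    img = nib.Nifti1Image(data, _affine(voxel_size_mm))
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))
    return path


def load_nifti(path):
    """Read a NIfTI file; returns ``(array, voxel_size_mm)``."""
    img = nib.load(str(path))
    voxel = float(img.header.get_zooms()[0])
    return np.asarray(img.dataobj), voxel


def save_label_map(label_map: PhantomLabelMap, path) -> Path:
    return save_nifti(label_map.labels, path, label_map.voxel_size_mm, dtype=np.int16)


def load_label_map(path) -> PhantomLabelMap:
    data, voxel = load_nifti(path)
    return PhantomLabelMap(data.astype(np.int16), dict(ROI_LABELS), voxel)


def save_histology_field(field: HistologyField, path) -> Path:
    """Write a field as a 16-bit PNG label image plus a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, field.classes.astype(np.uint16))
    sidecar = path.with_suffix(".json")
    with open(sidecar, "w") as fh:
        json.dump(
            {
                "pixel_size_um": field.pixel_size_um,
                "magnification": field.magnification,
                "class_names": {str(k): v for k, v in field.class_names.items()},
            },
            fh,
            indent=2,
        )
    return path


def load_histology_field(path) -> HistologyField:
    path = Path(path)
    img = np.asarray(iio.imread(path)).astype(np.uint8)
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
        return HistologyField(img, meta["pixel_size_um"], meta.get("magnification", "x200"),
                              {int(k): v for k, v in meta["class_names"].items()})
    return HistologyField(img, 0.5, "x200", dict(HISTO_CLASSES))


def write_manifest(paths, out_path) -> Path:
    """Write a JSON manifest of every file (path relative to the manifest)
    with its SHA-256 checksum."""
    out_path = Path(out_path)
    root = out_path.parent
    entries = {}
    for p in sorted(Path(p) for p in paths):
        key = str(p.relative_to(root)) if p.is_relative_to(root) else str(p)
        entries[key] = hashlib.sha256(p.read_bytes()).hexdigest()
    with open(out_path, "w") as fh:
        json.dump(entries, fh, indent=2, sort_keys=True)
    return out_path
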