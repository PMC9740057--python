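"""Phantom geometry: a voxel label map with contralateral brain,
intracranial tumor and extracranial tumor ROIs.

The geometry is deliberately schematic (three disjoint ellipsoids on an
empty background) — the pipeline validates parameter recovery, not
anatomy.  The seed jitters ROI centres by up to one voxel so repeated
cohort subjects are not bitwise-identical grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .presets import ROI_LABELS, get_preset

__all__ = ["PhantomLabelMap", "build_phantom", "parameter_volumes"]


@dataclass
class PhantomLabelMap:
    """Integer label volume plus the label dictionary and voxel size (mm)."""

    labels: np.ndarray
    label_names: dict = field(default_factory=lambda: dict(ROI_LABELS))
    voxel_size_mm: float = 0.5

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int16)
        present = set(np.unique(self.labels).tolist())
        if not present <= set(self.label_names):
            raise ValueError("label map contains labels missing from the dictionary")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")

    def roi_mask(self, roi) -> np.ndarray:
        """Boolean mask for a ROI given by integer label or name."""
        if isinstance(roi, str):
            matches = [k for k, v in self.label_names.items() if v == roi]
            if not matches:
                raise KeyError(f"unknown ROI name {roi!r}")
            roi = matches[0]
        return self.labels == roi


def _ellipsoid_mask(shape, center_frac, radii_frac):
    idx = np.indices(shape, dtype=float)
    dims = np.asarray(shape, dtype=float)
    center = np.asarray(center_frac) * (dims - 1)
    radii = np.maximum(np.asarray(radii_frac) * dims, 1.0)
    d2 = sum(((idx[i] - center[i]) / radii[i]) ** 2 for i in range(len(shape)))
    return d2 <= 1.0


# fractional centres / radii of the three ROIs on the grid
_ROI_GEOMETRY = {
    1: ((0.28, 0.50, 0.50), (0.14, 0.16, 0.22)),  # contralateral brain
    2: ((0.62, 0.32, 0.50), (0.10, 0.10, 0.18)),  # intracranial tumor
    3: ((0.70, 0.74, 0.50), (0.12, 0.12, 0.20)),  # extracranial (facial) tumor
}


def build_phantom(grid_shape=(64, 64, 16), preset_name: str = "pre", seed: int | None = 0,
                  voxel_size_mm: float = 0.5):
    """Build the phantom label map and its per-ROI ground truth.

    Returns ``(PhantomLabelMap, dict ROI name -> GroundTruthRecord)``.
    Raises ``KeyError`` for an unknown preset and ``ValueError`` when the
    grid is too small to hold three disjoint, nonempty ROIs.
    """
    records = get_preset(preset_name)  # KeyError on unknown preset
    shape = tuple(int(s) for s in grid_shape)
    if len(shape) != 3:
        raise ValueError("grid_shape must be a 3-D shape")
    if shape[0] < 12 or shape[1] < 12 or shape[2] < 4:
        raise ValueError(
            f"grid {shape} too small to place three disjoint ROIs; need at least 12x12x4")
    rng = np.random.default_rng(seed)
    labels = np.zeros(shape, dtype=np.int16)
    dims = np.asarray(shape, dtype=float)
    for lab, (center, radii) in _ROI_GEOMETRY.items():
        jitter = rng.uniform(-1.0, 1.0, size=3) / np.maximum(dims - 1, 1)
        mask = _ellipsoid_mask(shape, np.asarray(center) + jitter, radii)
        if not mask.any():
            raise ValueError(f"grid {shape} too small to place ROI {ROI_LABELS[lab]!r}")
        if np.any(labels[mask] != 0):
            raise ValueError(f"grid {shape} too small: ROI {ROI_LABELS[lab]!r} overlaps another ROI")
        labels[mask] = lab
    return PhantomLabelMap(labels, dict(ROI_LABELS), voxel_size_mm), records


def parameter_volumes(label_map: PhantomLabelMap, records: dict) -> dict:
    """Paint per-ROI ground-truth values into dense volumes.

    Returns a dict with 3-D arrays ``t1_ms``, ``t2_ms``, ``adc``, ``ce_t1_ms``
    and ``m0`` (background voxels carry M0 = 0 and harmless positive
    relaxation constants so forward models stay defined).
    """
    shape = label_map.labels.shape
    vols = {
        "t1_ms": np.full(shape, 1000.0),
        "t2_ms": np.full(shape, 100.0),
        "adc": np.full(shape, 1e-3),
        "ce_t1_ms": np.full(shape, 1000.0),
        "m0": np.zeros(shape),
    }
    for lab, name in label_map.label_names.items():
        if lab == 0:
            continue
        if name not in records:
            raise KeyError(f"no ground-truth record for ROI {name!r}")
        rec = records[name]
        m = label_map.labels == lab
        vols["t1_ms"][m] = rec.t1_ms
        vols["t2_ms"][m] = rec.t2_ms
        vols["adc"][m] = rec.adc_mm2_per_s
        vols["ce_t1_ms"][m] = rec.ce_t1_ms
        vols["m0"][m] = rec.m0
    return vols
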