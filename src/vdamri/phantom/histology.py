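"""Synthetic histology fields: categorical x200-magnification images with
countable nuclei, an exact-fraction necrosis region, and vessel lumina.

The field is a five-class label image — background (0), viable nucleus (1),
positively stained nucleus (2), necrosis (3), vessel lumen (4) — emulating
a segmented H&E / IHC field rather than raw RGB stains.  Unstained stroma
between nuclei is background, so "tissue" for the necrosis denominator is
the union of necrosis and nucleus pixels.

Placement is by exact count, not by Bernoulli draws: exactly
``round(n_cells * positive_fraction)`` nuclei (round half up) are positive,
and the necrosis pixel count is chosen so that
``necrosis / (necrosis + nucleus pixels)`` hits the requested fraction as
closely as the integer lattice allows (exactly, when the fraction is
lattice-representable).  This makes the downstream quantifiers an exact
recovery surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HistologyField",
    "HISTO_CLASSES",
    "NUCLEUS_RADIUS_PX",
    "NUCLEUS_AREA_PX",
    "simulate_histology_field",
    "simulate_histology_fields",
]

HISTO_CLASSES = {
    0: "background",
    1: "viable_nucleus",
    2: "positive_nucleus",
    3: "necrosis",
    4: "vessel_lumen",
}

NUCLEUS_RADIUS_PX = 3


def _disk_offsets(radius: int) -> np.ndarray:
    dy, dx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    keep = dy * dy + dx * dx <= radius * radius
    return np.stack([dy[keep], dx[keep]], axis=1)

_DISK = _disk_offsets(NUCLEUS_RADIUS_PX)

#: pixel area of one simulated nucleus
NUCLEUS_AREA_PX = _DISK.shape[0]


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass
class HistologyField:
    """2-D categorical histology image with physical pixel size."""

    classes: np.ndarray
    pixel_size_um: float
    magnification: str = "x200"
    class_names: dict = field(default_factory=lambda: dict(HISTO_CLASSES))

    def __post_init__(self):
        self.classes = np.asarray(self.classes, dtype=np.uint8)
        if self.classes.ndim != 2:
            raise ValueError("a histology field is a 2-D image")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        present = set(np.unique(self.classes).tolist())
        if not present <= set(self.class_names):
            raise ValueError("field contains classes missing from the dictionary")


def simulate_histology_field(
    n_cells: int,
    positive_fraction: float,
    necrosis_fraction: float,
    vessel_areas_um2=(),
    pixel_size_um: float = 0.5,
    seed: int | None = 0,
    shape=(520, 520),
) -> HistologyField:
    """Paint one synthetic field.

    Parameters
    ----------
    n_cells : int
        Nuclei placed in the viable region (all identical 4-connected disks).
    positive_fraction : float in [0, 1]
        Fraction of nuclei positively stained; exactly
        ``round_half_up(n_cells * positive_fraction)`` nuclei are positive.
    necrosis_fraction : float in [0, 1]
        Target necrosis share of tissue pixels.  1 paints every tissue pixel
        necrotic and requires ``n_cells == 0``.
    vessel_areas_um2 : sequence of float
        Lumen cross-sectional areas; each lumen is painted with the exact
        pixel count ``round(area / pixel_size^2)``.
    seed : int
        Controls nucleus jitter and which nuclei are positive.
    """
    if not (0 <= positive_fraction <= 1):
        raise ValueError("positive_fraction must lie in [0, 1]")
    if not (0 <= necrosis_fraction <= 1):
        raise ValueError("necrosis_fraction must lie in [0, 1]")
    if n_cells < 0:
        raise ValueError("n_cells must be nonnegative")
    if necrosis_fraction == 1 and n_cells > 0:
        raise ValueError("necrosis_fraction = 1 leaves no viable tissue for nuclei")

    h, w = shape
    margin = 8
    rng = np.random.default_rng(seed)
    img = np.zeros((h, w), dtype=np.uint8)

    # tissue canvas inset from a background border
    r0, r1, c0, c1 = margin, h - margin, margin, w - margin

    # necrosis pixel budget from the a-priori nucleus pixel total
    nuc_px = n_cells * NUCLEUS_AREA_PX
    if necrosis_fraction == 1:
        n_nec = (r1 - r0) * (c1 - c0)
    elif necrosis_fraction == 0:
        n_nec = 0
    else:
        n_nec = _round_half_up(necrosis_fraction / (1 - necrosis_fraction) * nuc_px)

    # paint necrosis as a contiguous block grown column-by-column from the
    # right edge of the tissue canvas
    if n_nec > (r1 - r0) * (c1 - c0):
        raise ValueError("field too small for the requested necrosis area")
    col_h = r1 - r0
    full_cols, rem = divmod(n_nec, col_h)
    if full_cols:
        img[r0:r1, c1 - full_cols:c1] = 3
    if rem:
        img[r0:r0 + rem, c1 - full_cols - 1] = 3

    # viable region: left of the necrosis block, with a separating gap
    viable_c1 = c1 - full_cols - (2 if rem or full_cols else 0) - (1 if rem else 0)

    # vessel lumina: exact-pixel-count near-disks on a horizontal band
    vessel_areas_um2 = list(vessel_areas_um2)
    band_r = r0 + 4
    next_c = c0 + 4
    for area in vessel_areas_um2:
        n_px = max(1, _round_half_up(area / pixel_size_um**2))
        radius = int(np.ceil(np.sqrt(n_px / np.pi))) + 2
        cy, cx = band_r + radius, next_c + radius
        if cx + radius + 2 >= viable_c1 or cy + radius + 2 >= r1:
            raise ValueError("field too small for the requested vessels")
        dy, dx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
        d2 = (dy * dy + dx * dx).ravel()
        order = np.argsort(d2, kind="stable")[:n_px]
        img[cy + dy.ravel()[order], cx + dx.ravel()[order]] = 4
        next_c = cx + radius + 4

    vessel_band_bottom = band_r + (2 * max(
        [int(np.ceil(np.sqrt(max(1, _round_half_up(a / pixel_size_um**2)) / np.pi))) + 2
         for a in vessel_areas_um2], default=0)) + 4

    # nucleus grid in the remaining viable area
    if n_cells > 0:
        # pitch leaves >=2 background pixels between disks after +/-1 jitter,
        # so nuclei never merge under 4- (or even 8-) connectivity
        pitch = 2 * NUCLEUS_RADIUS_PX + 5
        rows = np.arange(vessel_band_bottom + NUCLEUS_RADIUS_PX + 1,
                         r1 - NUCLEUS_RADIUS_PX - 1, pitch)
        cols = np.arange(c0 + NUCLEUS_RADIUS_PX + 1,
                         viable_c1 - NUCLEUS_RADIUS_PX - 1, pitch)
        capacity = rows.size * cols.size
        if capacity < n_cells:
            raise ValueError(
                f"field too small: capacity {capacity} nuclei, requested {n_cells}")
        centers = [(r, c) for r in rows for c in cols][:n_cells]
        n_pos = _round_half_up(n_cells * positive_fraction)
        pos_idx = set(rng.choice(n_cells, size=n_pos, replace=False).tolist())
        for i, (r, c) in enumerate(centers):
            jr, jc = rng.integers(-1, 2, size=2)
            cls = 2 if i in pos_idx else 1
            img[r + jr + _DISK[:, 0], c + jc + _DISK[:, 1]] = cls

    return HistologyField(img, pixel_size_um)


def simulate_histology_fields(
    n_fields: int,
    n_cells_total: int,
    positive_fraction: float,
    necrosis_fraction: float = 0.0,
    vessel_areas_um2=(),
    pixel_size_um: float = 0.5,
    seed: int | None = 0,
) -> list:
    """Simulate several fields whose *pooled* positive count is exact.

    Cells are split near-evenly across fields and the pooled positive count
    ``round_half_up(n_cells_total * positive_fraction)`` is allocated by
    largest remainder, so the pooled rate over the fields recovers the
    requested fraction exactly regardless of per-field rounding.
    """
    if n_fields < 1:
        raise ValueError("n_fields must be >= 1")
    base, extra = divmod(n_cells_total, n_fields)
    cells = [base + (1 if i < extra else 0) for i in range(n_fields)]
    n_pos_total = _round_half_up(n_cells_total * positive_fraction)
    quota = [positive_fraction * c for c in cells]
    pos = [min(int(np.floor(q)), c) for q, c in zip(quota, cells)]
    remainders = sorted(range(n_fields), key=lambda i: quota[i] - pos[i], reverse=True)
    i = 0
    while sum(pos) < n_pos_total:
        j = remainders[i % n_fields]
        if pos[j] < cells[j]:
            pos[j] += 1
        i += 1
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    ss = root.spawn(n_fields)
    fields = []
    for k in range(n_fields):
        frac = pos[k] / cells[k] if cells[k] else 0.0
        fields.append(
            simulate_histology_field(
                cells[k], frac, necrosis_fraction, vessel_areas_um2,
                pixel_size_um, seed=ss[k],
            )
        )
    return fields
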