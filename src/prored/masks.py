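"""Label masks for midsagittal vocal-tract segmentation.

A :class:`LabelMask` is an integer grid where 0 is background and positive
values index anatomical classes.  The speech configuration uses 7 classes:
background plus head, soft palate, jaw, tongue, vocal tract and tooth space.
Masks round-trip through indexed PNG (palette index = class id) and
single-frame NIfTI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SPEECH_CLASS_NAMES", "LabelMask", "boundary_pixels",
    "save_mask_png", "load_mask_png", "save_mask_nifti", "load_mask_nifti",
]

SPEECH_CLASS_NAMES = (
    "background", "head", "soft_palate", "jaw", "tongue", "vocal_tract", "tooth_space",
)

# fixed palette so indexed PNGs are also human-viewable
_PALETTE = [
    (0, 0, 0), (230, 180, 120), (220, 50, 50), (120, 120, 200),
    (230, 100, 180), (60, 60, 60), (240, 240, 120),
]


@dataclass
class LabelMask:
    """H×W integer label grid with class names and optional pixel spacing (mm)."""

    grid: np.ndarray
    class_names: tuple[str, ...] = SPEECH_CLASS_NAMES
    pixel_spacing: tuple[float, float] | None = None  # (row_mm, col_mm)

    def __post_init__(self):
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise ValueError(f"mask grid must be 2-D, got shape {self.grid.shape}")
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise ValueError("mask grid must be an integer array")
        c = len(self.class_names)
        if self.grid.size and (self.grid.min() < 0 or self.grid.max() >= c):
            raise ValueError(f"mask values must lie in [0, {c - 1}]")

    @property
    def num_classes(self) -> int:
        return len(self.class_names)

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def foreground(self) -> np.ndarray:
        return self.grid > 0

    def class_id(self, name: str) -> int:
        return self.class_names.index(name)


_OFFSETS_4 = ((-1, 0), (1, 0), (0, -1), (0, 1))
_OFFSETS_8 = _OFFSETS_4 + ((-1, -1), (-1, 1), (1, -1), (1, 1))


def boundary_pixels(mask: LabelMask, label: int, connectivity: int = 4) -> np.ndarray:
    """Boolean grid marking pixels of ``label`` that touch a different label.

    A pixel is a boundary pixel iff it carries ``label`` and at least one of
    its 4- (or 8-) neighbours carries a different label; positions outside the
    grid count as background, so the grid edge is always a boundary.
    """
    if label == 0:
        raise ValueError("background has no boundary")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    grid = mask.grid
    fg = grid == label
    # pad with -1: out-of-grid differs from every label
    padded = np.pad(grid, 1, constant_values=-1)
    different = np.zeros_like(fg)
    offsets = _OFFSETS_4 if connectivity == 4 else _OFFSETS_8
    h, w = grid.shape
    for dr, dc in offsets:
        neigh = padded[1 + dr:1 + dr + h, 1 + dc:1 + dc + w]
        different |= neigh != label
    return fg & different


# ------------------------------------------------------------------------ I/O

def save_mask_png(mask: LabelMask, path: str | Path) -> None:
    from PIL import Image

    img = Image.fromarray(mask.grid.astype(np.uint8), mode="P")
    palette = list(_PALETTE)
    while len(palette) < mask.num_classes:
        palette.append((17 * len(palette) % 256,) * 3)
    img.putpalette([v for rgb in palette[:256] for v in rgb])
    img.save(path)


def load_mask_png(path: str | Path,
                  class_names: tuple[str, ...] = SPEECH_CLASS_NAMES) -> LabelMask:
    from PIL import Image

    img = Image.open(path)
    if img.mode != "P":
        img = img.convert("P")
    return LabelMask(np.asarray(img, dtype=np.int64), class_names)


def save_mask_nifti(mask: LabelMask, path: str | Path) -> None:
    import nibabel as nib

    affine = np.eye(4)
    if mask.pixel_spacing is not None:
        affine[0, 0], affine[1, 1] = mask.pixel_spacing
    nib.save(nib.Nifti1Image(mask.grid.astype(np.int16), affine), str(path))


def load_mask_nifti(path: str | Path,
                    class_names: tuple[str, ...] = SPEECH_CLASS_NAMES) -> LabelMask:
    import nibabel as nib

    img = nib.load(str(path))
    grid = np.asarray(img.dataobj).astype(np.int64)
    if grid.ndim != 2:
        grid = np.squeeze(grid)
    zooms = img.header.get_zooms()[:2]
    spacing = tuple(float(z) for z in zooms) if any(z != 1 for z in zooms) else None
    return LabelMask(grid, class_names, spacing)
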