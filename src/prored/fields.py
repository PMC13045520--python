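"""Ground-truth directional fields (DF).

For every foreground pixel p the DF stores the unit vector (p − b)/‖p − b‖
pointing *from* the nearest boundary pixel b *toward* p; background pixels and
pixels that are themselves on a boundary carry (0, 0).  Channel order is
(dx, dy) = (column offset, row offset) in 0-based pixel-centre coordinates.

Two nearest-boundary conventions are supported:

``per-class``
    each foreground pixel is referred to the boundary of its own class
    (default);
``union-foreground``
    all class boundaries (including internal class-to-class interfaces) form
    one boundary set shared by every foreground pixel.

Ties between equidistant boundary pixels are broken by row-major order, which
makes the field a pure function of the mask.  ``compute_df`` is the fast
KD-tree path; ``compute_df_bruteforce`` is the exhaustive oracle with the
identical contract.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .masks import LabelMask, boundary_pixels

__all__ = [
    "DirectionalField", "compute_df", "compute_df_bruteforce",
    "save_df", "load_df", "save_df_nifti",
]


@dataclass
class DirectionalField:
    """H×W×2 real array of unit (or zero) vectors, channel order (dx, dy)."""

    vectors: np.ndarray

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 3 or self.vectors.shape[2] != 2:
            raise ValueError(f"DF must be H×W×2, got {self.vectors.shape}")

    @property
    def shape(self):
        return self.vectors.shape[:2]

    def norms(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=2)


def _region_pairs(mask: LabelMask, mode: str):
    """Yield (foreground boolean grid, boundary boolean grid) per region."""
    if mode == "per-class":
        for label in range(1, mask.num_classes):
            fg = mask.grid == label
            if fg.any():
                yield fg, boundary_pixels(mask, label)
    elif mode == "union-foreground":
        fg = mask.grid > 0
        if fg.any():
            bnd = np.zeros_like(fg)
            for label in np.unique(mask.grid[fg]):
                bnd |= boundary_pixels(mask, int(label))
            yield fg, bnd
    else:
        raise ValueError(f"unknown DF mode {mode!r}")


def compute_df(mask: LabelMask, mode: str = "per-class") -> DirectionalField:
    """Nearest-boundary directional field of a label mask (KD-tree fast path).

    Exact-tie resolution: squared pixel distances are integers, so after the
    KD-tree nearest query all boundary pixels at the same integer squared
    distance are enumerated and the row-major smallest one is chosen —
    matching the brute-force oracle bit for bit.
    """
    h, w = mask.shape
    vectors = np.zeros((h, w, 2), dtype=np.float64)
    for fg, bnd in _region_pairs(mask, mode):
        interior = fg & ~bnd
        if not interior.any():
            continue
        bcoords = np.argwhere(bnd)  # row-major sorted
        pcoords = np.argwhere(interior)
        tree = cKDTree(bcoords)
        dist, _ = tree.query(pcoords)
        d2 = np.rint(dist * dist).astype(np.int64)
        radius = np.sqrt(d2.astype(np.float64)) + 1e-7
        candidate_lists = tree.query_ball_point(pcoords, radius)
        for (pr, pc), target_d2, cand in zip(pcoords, d2, candidate_lists):
            cand = np.asarray(cand)
            bc = bcoords[cand]
            exact = ((bc[:, 0] - pr) ** 2 + (bc[:, 1] - pc) ** 2) == target_d2
            best = cand[exact].min()  # KD-tree preserves row-major input order
            br, bcol = bcoords[best]
            v = np.array([pc - bcol, pr - br], dtype=np.float64)
            vectors[pr, pc] = v / np.linalg.norm(v)
    return DirectionalField(vectors)


def compute_df_bruteforce(mask: LabelMask, mode: str = "per-class") -> DirectionalField:
    """Exhaustive-scan oracle for :func:`compute_df` (identical contract)."""
    h, w = mask.shape
    vectors = np.zeros((h, w, 2), dtype=np.float64)
    for fg, bnd in _region_pairs(mask, mode):
        blist = [(r, c) for r in range(h) for c in range(w) if bnd[r, c]]
        for pr in range(h):
            for pc in range(w):
                if not fg[pr, pc] or bnd[pr, pc]:
                    continue
                best_d2, best_b = None, None
                for br, bc in blist:  # row-major: first minimum wins the tie
                    d2 = (pr - br) ** 2 + (pc - bc) ** 2
                    if best_d2 is None or d2 < best_d2:
                        best_d2, best_b = d2, (br, bc)
                dx = pc - best_b[1]
                dy = pr - best_b[0]
                norm = np.sqrt(dx * dx + dy * dy)
                vectors[pr, pc] = (dx / norm, dy / norm)
    return DirectionalField(vectors)


# ------------------------------------------------------------------------ I/O

def save_df(df: DirectionalField, path: str | Path) -> None:
    """Portable container: .npz array + JSON sidecar recording the convention."""
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), vectors=df.vectors)
    sidecar = {"channels": ["dx (column)", "dy (row)"],
               "coordinates": "0-based pixel centres",
               "shape": list(df.vectors.shape)}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_df(path: str | Path) -> DirectionalField:
    path = Path(path)
    with np.load(path.with_suffix(".npz")) as data:
        return DirectionalField(data["vectors"])


def save_df_nifti(df: DirectionalField, path: str | Path) -> None:
    import nibabel as nib

    nib.save(nib.Nifti1Image(df.vectors.astype(np.float32), np.eye(4)), str(path))
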