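"""Synthetic midsagittal vocal-tract phantoms.

The generator renders a stylized midsagittal layout with all seven speech
labels — background, a head region containing the posterior pharyngeal wall,
a mobile soft-palate flap, jaw, tongue, vocal-tract airway and tooth space —
as parametric rectangles/ellipses so contact geometry is exact.  The palate
tip follows a scheduled closure pattern: on closed frames it touches the
posterior wall (8-adjacent); on open frames it retracts, leaving a gap of at
least two pixels.  Frame intensities are per-class base levels plus Gaussian
noise.  The same seed reproduces the series bit for bit.

The phantoms exercise the segmentation and closure machinery; they make no
claim to MR physics (no coil profile, banding or motion artefacts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .closure import ClosureEvent, ClosureSequence, events_to_sequence, save_closure_csv
from .masks import SPEECH_CLASS_NAMES, LabelMask, save_mask_png

__all__ = ["PhantomConfig", "generate_phantom_sequence", "generate_blob_masks",
           "periodic_schedule", "write_series", "RUTHVEN_SERIES_LENGTHS"]

# series lengths of the public midsagittal speech MRI dataset the phantom
# layout emulates (5 subjects, 393 frames of 256×256 pixels in total)
RUTHVEN_SERIES_LENGTHS = (105, 71, 71, 78, 67)

_BASE_INTENSITY = {
    "background": 0.05, "head": 0.85, "soft_palate": 0.70, "jaw": 0.80,
    "tongue": 0.60, "vocal_tract": 0.10, "tooth_space": 0.30,
}


@dataclass
class PhantomConfig:
    frames: int = 40
    size: tuple[int, int] = (64, 64)
    closure_schedule: tuple[ClosureEvent, ...] = ()
    noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self):
        events = sorted(self.closure_schedule, key=lambda e: e.start)
        for ev in events:
            if ev.start < 0 or ev.end >= self.frames:
                raise ValueError(f"scheduled event {ev} falls outside 0..{self.frames - 1}")
        for a, b in zip(events, events[1:]):
            if b.start <= a.end:
                raise ValueError("scheduled closure events must be disjoint")
        self.closure_schedule = tuple(events)


def periodic_schedule(frames: int, period: int = 10, duty: int = 4,
                      offset: int = 3) -> tuple[ClosureEvent, ...]:
    """Closure events of ``duty`` frames every ``period`` frames."""
    events = []
    start = offset
    while start + duty - 1 < frames:
        events.append(ClosureEvent(start, start + duty - 1))
        start += period
    return tuple(events)


def _layout(size: tuple[int, int]) -> dict:
    """Pixel geometry of the phantom, scaled from a 64×64 reference layout."""
    h, w = size

    def r(frac, n):
        return int(round(frac * n))

    return {
        "head_band_rows": (0, r(0.14, h)),                  # cranial arc
        "wall_cols": (r(0.80, w), r(0.88, w)),              # posterior pharyngeal wall
        "wall_rows": (r(0.14, h), r(0.75, h)),
        "palate_rows": (r(0.30, h), r(0.38, h)),
        "palate_col0": r(0.45, w),                          # anterior hinge
        "airway_rows": (r(0.40, h), r(0.52, h)),
        "airway_cols": (r(0.30, w), r(0.78, w)),
        "tongue_center": (r(0.68, h), r(0.35, w)),
        "tongue_radii": (r(0.16, h), r(0.22, w)),
        "jaw_rows": (r(0.88, h), h),
        "jaw_cols": (0, r(0.60, w)),
        "tooth_rows": (r(0.80, h), r(0.86, h)),
        "tooth_cols": (r(0.10, w), r(0.18, w)),
        "open_gap": 3,                                      # ≥ 2-px air gap when open
    }


def _render_mask(size: tuple[int, int], closed: bool) -> LabelMask:
    h, w = size
    lay = _layout(size)
    grid = np.zeros((h, w), dtype=np.int64)
    names = SPEECH_CLASS_NAMES

    def put(label, rows, cols):
        grid[rows[0]:rows[1], cols[0]:cols[1]] = names.index(label)

    put("head", lay["head_band_rows"], (0, w))
    put("head", lay["wall_rows"], lay["wall_cols"])
    put("vocal_tract", lay["airway_rows"], lay["airway_cols"])
    rr, cc = np.ogrid[:h, :w]
    tr, tc = lay["tongue_center"]
    ra, rb = lay["tongue_radii"]
    tongue = ((rr - tr) / ra) ** 2 + ((cc - tc) / rb) ** 2 <= 1.0
    grid[tongue] = names.index("tongue")
    put("jaw", lay["jaw_rows"], lay["jaw_cols"])
    put("tooth_space", lay["tooth_rows"], lay["tooth_cols"])
    wall_left = lay["wall_cols"][0]
    tip = wall_left if closed else wall_left - lay["open_gap"]
    put("soft_palate", lay["palate_rows"], (lay["palate_col0"], tip))
    return LabelMask(grid, names)


def generate_phantom_sequence(config: PhantomConfig
                              ) -> tuple[np.ndarray, list[LabelMask], ClosureSequence]:
    """Render (image series (F,H,W) float32, GT masks, GT closure sequence)."""
    closure = events_to_sequence(list(config.closure_schedule), config.frames)
    rng = np.random.default_rng(config.seed)
    masks = [_render_mask(config.size, bool(c)) for c in closure.labels]
    levels = np.array([_BASE_INTENSITY[n] for n in SPEECH_CLASS_NAMES], dtype=np.float32)
    images = np.stack([levels[m.grid] for m in masks])
    images = images + rng.normal(0.0, config.noise_sigma, images.shape).astype(np.float32)
    # every mask must expose all seven labels — the closure detector and the
    # class-wise metrics rely on it
    for m in masks:
        present = np.unique(m.grid)
        if len(present) != len(SPEECH_CLASS_NAMES):
            raise RuntimeError("phantom rendering lost an anatomical class "
                               f"(size {config.size} too small?)")
    return images.astype(np.float32), masks, closure


def generate_blob_masks(n: int, size: tuple[int, int] = (32, 32), seed: int = 0,
                        num_classes: int = 4) -> list[LabelMask]:
    """Random multi-class blobby masks (thresholded smoothed noise).

    Fixture generator for the directional-field and metric oracles; each mask
    has at least one foreground pixel and values in [0, num_classes-1].
    """
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    names = tuple(f"class_{i}" for i in range(num_classes))
    masks = []
    while len(masks) < n:
        noise = gaussian_filter(rng.normal(size=size), sigma=3.0)
        # quantile thresholds split the smoothed field into contiguous blobs
        qs = np.quantile(noise, np.linspace(0, 1, num_classes + 1)[1:-1])
        grid = np.searchsorted(qs, noise).astype(np.int64)
        if (grid > 0).any():
            masks.append(LabelMask(grid, names))
    return masks


def write_series(out_dir: str | Path, config: PhantomConfig, series_id: str = "series_0"
                 ) -> Path:
    """Write one phantom series in the on-disk layout the pipeline consumes:

    ``<out_dir>/<series_id>/frame_XXX.png`` (8-bit image),
    ``mask_XXX.png`` (indexed PNG) and ``closure.csv``.
    """
    from PIL import Image

    out = Path(out_dir) / series_id
    out.mkdir(parents=True, exist_ok=True)
    images, masks, closure = generate_phantom_sequence(config)
    for i, (img, m) in enumerate(zip(images, masks)):
        arr = np.clip(img, 0, 1)
        Image.fromarray((arr * 255).astype(np.uint8)).save(out / f"frame_{i:03d}.png")
        save_mask_png(m, out / f"mask_{i:03d}.png")
    closure.series_id = series_id
    save_closure_csv(closure, out / "closure.csv")
    return out
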