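"""Evaluation metrics: per-class Dice coefficient and (boundary) Hausdorff
distance, with an exhaustive-scan Hausdorff oracle and a tabular report."""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import directed_hausdorff

from .masks import LabelMask, boundary_pixels

__all__ = ["dice_coefficient", "hausdorff_distance", "hausdorff_bruteforce",
           "EvalReport"]


def dice_coefficient(pred: LabelMask, gt: LabelMask, label: int) -> float:
    """2|A∩B| / (|A|+|B|) on the binary masks of ``label``; 1.0 when both empty."""
    a = pred.grid == label
    b = gt.grid == label
    if a.shape != b.shape:
        raise ValueError("masks must have identical dimensions")
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / total


def _boundary_coords(mask: LabelMask, label: int,
                     spacing: tuple[float, float] | None) -> np.ndarray:
    coords = np.argwhere(boundary_pixels(mask, label)).astype(np.float64)
    if spacing is not None:
        coords *= np.asarray(spacing, dtype=np.float64)
    return coords


def hausdorff_distance(pred: LabelMask, gt: LabelMask, label: int,
                       spacing: tuple[float, float] | None = None) -> float:
    """Symmetric (100th-percentile) Hausdorff distance between the boundary
    pixel sets of ``label``; NaN when either side lacks the label entirely
    (recorded as missing, never as 0 or infinity)."""
    if spacing is None:
        spacing = pred.pixel_spacing or gt.pixel_spacing
    a = _boundary_coords(pred, label, spacing)
    b = _boundary_coords(gt, label, spacing)
    if len(a) == 0 or len(b) == 0:
        return float("nan")
    return max(directed_hausdorff(a, b)[0], directed_hausdorff(b, a)[0])


def hausdorff_bruteforce(pred: LabelMask, gt: LabelMask, label: int,
                         spacing: tuple[float, float] | None = None) -> float:
    """Exhaustive max-min pairwise-distance oracle for :func:`hausdorff_distance`."""
    if spacing is None:
        spacing = pred.pixel_spacing or gt.pixel_spacing
    a = _boundary_coords(pred, label, spacing)
    b = _boundary_coords(gt, label, spacing)
    if len(a) == 0 or len(b) == 0:
        return float("nan")

    def directed(src, dst):
        worst = 0.0
        for p in src:
            best = math.inf
            for q in dst:
                d = math.hypot(p[0] - q[0], p[1] - q[1])
                if d < best:
                    best = d
            worst = max(worst, best)
        return worst

    return max(directed(a, b), directed(b, a))


@dataclass
class EvalReport:
    """Per-class Dice and Hausdorff summary; ``units`` names the HD scale."""

    per_class_dice: dict[str, float]
    per_class_hd: dict[str, float]
    units: str = "px"

    def __post_init__(self):
        for v in self.per_class_dice.values():
            if not (0.0 <= v <= 1.0 + 1e-9):
                raise ValueError("Dice values must lie in [0, 1]")
        for v in self.per_class_hd.values():
            if not (math.isnan(v) or v >= 0):
                raise ValueError("Hausdorff values must be >= 0")

    @property
    def mean_dice(self) -> float:
        return float(np.mean(list(self.per_class_dice.values())))

    @property
    def mean_hd(self) -> float:
        vals = [v for v in self.per_class_hd.values() if not math.isnan(v)]
        return float(np.mean(vals)) if vals else float("nan")

    def to_frame(self) -> pd.DataFrame:
        rows = [{"class": name, "dice": self.per_class_dice[name],
                 "hausdorff": self.per_class_hd.get(name, float("nan")),
                 "units": self.units}
                for name in self.per_class_dice]
        rows.append({"class": "mean", "dice": self.mean_dice,
                     "hausdorff": self.mean_hd, "units": self.units})
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {"per_class_dice": self.per_class_dice,
                   "per_class_hd": {k: (None if math.isnan(v) else v)
                                    for k, v in self.per_class_hd.items()},
                   "mean_dice": self.mean_dice,
                   "mean_hd": None if math.isnan(self.mean_hd) else self.mean_hd,
                   "units": self.units}
        Path(path).write_text(json.dumps(payload, indent=1))

    @staticmethod
    def from_masks(preds: list[LabelMask], gts: list[LabelMask],
                   spacing: tuple[float, float] | None = None) -> "EvalReport":
        """Average per-class Dice/HD over paired frames (foreground classes).

        Frames where the Hausdorff distance is undefined for a class (label
        absent on one side) are skipped for that class's HD mean."""
        if len(preds) != len(gts) or not preds:
            raise ValueError("need equal, non-empty prediction and GT lists")
        names = gts[0].class_names
        dice: dict[str, list[float]] = {n: [] for n in names[1:]}
        hd: dict[str, list[float]] = {n: [] for n in names[1:]}
        for p, g in zip(preds, gts):
            for label in range(1, len(names)):
                dice[names[label]].append(dice_coefficient(p, g, label))
                d = hausdorff_distance(p, g, label, spacing)
                if not math.isnan(d):
                    hd[names[label]].append(d)
        units = "mm" if (spacing or (gts[0].pixel_spacing is not None)) else "px"
        return EvalReport(
            {n: float(np.mean(v)) for n, v in dice.items()},
            {n: (float(np.mean(v)) if v else float("nan")) for n, v in hd.items()},
            units,
        )
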