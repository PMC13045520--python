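"""Training losses: soft Dice over foreground classes and masked MSE for the
directional-field supervision."""

from __future__ import annotations

import numpy as np

from .nn import Tensor

__all__ = ["dice_loss", "df_loss", "one_hot", "downsample_field", "downsample_mask"]

_EPS = 1e-5


def one_hot(labels: np.ndarray, num_classes: int) -> np.ndarray:
    """(B,H,W) integer labels → (B,C,H,W) float32 one-hot."""
    labels = np.asarray(labels)
    if labels.ndim == 2:
        labels = labels[None]
    out = np.zeros((labels.shape[0], num_classes) + labels.shape[1:], dtype=np.float32)
    for c in range(num_classes):
        out[:, c] = labels == c
    return out


def dice_loss(probabilities: Tensor, target: np.ndarray, num_classes: int | None = None,
              eps: float = _EPS) -> Tensor:
    """1 − mean over foreground classes of the soft Dice coefficient.

    ``probabilities`` is a (B,C,H,W) tensor of per-pixel class probabilities
    (softmax output); ``target`` an integer label array, one-hot encoded
    internally.  The background channel is excluded from the mean, matching
    evaluation over the six anatomical classes.
    """
    b, c = probabilities.data.shape[:2]
    num_classes = num_classes or c
    if num_classes != c:
        raise ValueError(f"probability channels ({c}) != num_classes ({num_classes})")
    g = one_hot(target, c)
    if g.shape != probabilities.data.shape:
        raise ValueError(f"target shape {g.shape[0:1] + g.shape[2:]} does not match "
                         f"probabilities {probabilities.data.shape}")
    gt = Tensor(g)
    inter = (probabilities * gt).sum(axis=(0, 2, 3))          # (C,)
    denom = probabilities.sum(axis=(0, 2, 3)) + Tensor(g.sum(axis=(0, 2, 3)))
    dice = (inter * 2.0 + eps) / (denom + eps)
    fg_weight = np.zeros(c, dtype=np.float32)
    fg_weight[1:] = 1.0 / (c - 1)
    return 1.0 - (dice * Tensor(fg_weight)).sum()


def df_loss(predicted_df: Tensor, gt_df: np.ndarray, foreground: np.ndarray) -> Tensor:
    """Mean squared error between predicted and ground-truth DF over foreground.

    Per-pixel squared vector error ‖pred − gt‖², averaged over foreground
    pixels (so an all-zero prediction against unit vectors scores exactly 1).
    ``gt_df`` and ``foreground`` are (B,2,h,w) / (B,h,w) arrays at the
    prediction's resolution.
    """
    gt_df = np.asarray(gt_df, dtype=np.float32)
    fg = np.asarray(foreground, dtype=np.float32)
    if gt_df.shape != predicted_df.data.shape:
        raise ValueError(f"gt DF shape {gt_df.shape} != prediction {predicted_df.data.shape}")
    n_fg = float(fg.sum())
    if n_fg == 0:
        return Tensor(0.0)
    diff = predicted_df - Tensor(gt_df)
    masked = diff * diff * Tensor(fg[:, None])
    return masked.sum() * (1.0 / n_fg)


def downsample_mask(labels: np.ndarray, out_hw: tuple[int, int]) -> np.ndarray:
    """Nearest-index down-sampling of an integer label grid."""
    labels = np.asarray(labels)
    h, w = labels.shape[-2:]
    rows = (np.arange(out_hw[0]) * h // out_hw[0])
    cols = (np.arange(out_hw[1]) * w // out_hw[1])
    return labels[..., rows[:, None], cols[None, :]]


def downsample_field(vectors: np.ndarray, out_hw: tuple[int, int]) -> np.ndarray:
    """Nearest-index down-sampling of a (..., 2, H, W) vector field."""
    return downsample_mask(vectors, out_hw)
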