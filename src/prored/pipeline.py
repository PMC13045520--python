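"""Training, evaluation and cross-validation orchestration.

Subject-wise 5-fold cross-validation rotates the five series through the
test/validation roles (3 train / 1 validation / 1 test per fold).  Training
optimizes soft Dice plus a weighted directional-field supervision term with
Adam; model selection keeps the weights with the best validation mean
foreground Dice.  Checkpoints round-trip weights, configuration, seed and the
metric history in a single ``.npz`` archive.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .closure import (ClosureSequence, detect_closure_frame, extract_events,
                      frame_accuracy, load_closure_csv, match_events)
from .fields import compute_df
from .losses import df_loss, dice_loss, downsample_field, downsample_mask
from .masks import LabelMask, load_mask_png
from .metrics import EvalReport
from .model import ProredConfig, ProredModel
from .nn import Adam, Tensor

__all__ = ["FoldSpec", "TrainConfig", "TrainResult", "make_folds", "train",
           "evaluate", "closure_report", "ablation_sweep",
           "save_checkpoint", "load_checkpoint", "load_series",
           "normalize_frames"]


# ----------------------------------------------------------------- fold logic

@dataclass
class FoldSpec:
    """Per-fold series assignments; every series is the test subject exactly once."""

    folds: list[dict[str, list[str]]]

    def __post_init__(self):
        tests = [f["test"][0] for f in self.folds]
        if len(set(tests)) != len(self.folds):
            raise ValueError("each series must appear exactly once as test")
        for f in self.folds:
            roles = f["train"] + f["val"] + f["test"]
            if len(set(roles)) != len(roles):
                raise ValueError("train/val/test roles must be disjoint within a fold")


def make_folds(series_ids: list[str], k: int | None = None) -> FoldSpec:
    """Rotation folds: fold i tests series i, validates the next, trains the rest.

    The speech protocol uses exactly 5 series; pass ``k`` explicitly to allow
    a generalized rotation over a different count.
    """
    ids = list(series_ids)
    if k is None:
        if len(ids) != 5:
            raise ValueError("the speech protocol expects exactly 5 series "
                             "(pass k to generalize)")
        k = 5
    if len(ids) != k:
        raise ValueError(f"expected {k} series, got {len(ids)}")
    folds = []
    for i in range(k):
        test = ids[i]
        val = ids[(i + 1) % k]
        train = [s for s in ids if s not in (test, val)]
        folds.append({"train": train, "val": [val], "test": [test]})
    return FoldSpec(folds)


# ------------------------------------------------------------------- training

@dataclass
class TrainConfig:
    lr: float = 2e-4
    batch_size: int = 8
    epochs: int = 150
    betas: tuple[float, float] = (0.9, 0.999)
    eps: float = 1e-8
    df_loss_weight: float = 1.0
    seed: int = 0
    max_steps: int | None = None      # cap for smoke runs; None = epochs govern
    df_mode: str = "per-class"
    val_every: int = 1                # epochs between validation passes

    def __post_init__(self):
        if self.lr <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("lr, batch size and epochs must be positive")


@dataclass
class TrainResult:
    model: ProredModel
    history: pd.DataFrame          # per-step training loss
    val_history: pd.DataFrame      # per-validation mean foreground Dice
    best_val_dice: float


def normalize_frames(images: np.ndarray) -> np.ndarray:
    """Per-frame min-max normalization to [0, 1]."""
    images = np.asarray(images, dtype=np.float32)
    flat = images.reshape(len(images), -1)
    lo = flat.min(axis=1).reshape(-1, 1, 1)
    hi = flat.max(axis=1).reshape(-1, 1, 1)
    span = np.where(hi > lo, hi - lo, 1.0)
    return (images - lo) / span


def _gt_df_cache(masks: list[LabelMask], mode: str) -> list[np.ndarray]:
    """(2,H,W) ground-truth DF per frame, channel order (dx, dy)."""
    return [compute_df(m, mode).vectors.transpose(2, 0, 1).astype(np.float32)
            for m in masks]


def _step_loss(model: ProredModel, batch_images: np.ndarray,
               batch_labels: np.ndarray, batch_dfs: np.ndarray,
               cfg: TrainConfig) -> Tensor:
    logits, pred_dfs = model.forward(batch_images)
    probs = logits.softmax(axis=1)
    loss = dice_loss(probs, batch_labels)
    if cfg.df_loss_weight != 0.0:
        for pdf in pred_dfs:
            hw = pdf.data.shape[2:]
            gt_small = downsample_field(batch_dfs, hw)
            fg_small = downsample_mask(batch_labels, hw) > 0
            loss = loss + cfg.df_loss_weight * df_loss(pdf, gt_small, fg_small)
    return loss


def mean_foreground_dice(model: ProredModel, images: np.ndarray,
                         masks: list[LabelMask]) -> float:
    """Validation "accuracy": mean Dice over the foreground classes."""
    from .metrics import dice_coefficient

    model.eval()
    vals = []
    for img, gt in zip(images, masks):
        pred = LabelMask(model.predict_mask(img), gt.class_names)
        for label in range(1, gt.num_classes):
            vals.append(dice_coefficient(pred, gt, label))
    model.train()
    return float(np.mean(vals))


def train(model: ProredModel, config: TrainConfig,
          train_images: np.ndarray, train_masks: list[LabelMask],
          val_images: np.ndarray | None = None,
          val_masks: list[LabelMask] | None = None,
          log_path: str | Path | None = None) -> TrainResult:
    """Optimize Dice + λ·DF loss with Adam; keep the best-validation weights.

    Without a validation set the final weights are kept and the best-val
    metric is reported as NaN.
    """
    if len(train_images) != len(train_masks):
        raise ValueError("training frames and masks are not aligned")
    images = normalize_frames(train_images)
    labels = np.stack([m.grid for m in train_masks])
    gt_dfs = np.stack(_gt_df_cache(train_masks, config.df_mode))
    rng = np.random.default_rng(config.seed)
    optimizer = Adam(model.parameters(), config.lr, config.betas, config.eps)
    n = len(images)
    steps_per_epoch = max(1, math.ceil(n / config.batch_size))
    history, val_history = [], []
    best_val, best_state = float("nan"), None
    step = 0
    model.train()
    done = False
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        for s in range(steps_per_epoch):
            idx = order[s * config.batch_size:(s + 1) * config.batch_size]
            if len(idx) == 0:
                continue
            loss = _step_loss(model, images[idx], labels[idx], gt_dfs[idx], config)
            value = float(loss.data)
            if not np.isfinite(value):
                raise RuntimeError(
                    f"non-finite training loss ({value}) at step {step}; "
                    "check learning rate and input normalization")
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            history.append({"step": step, "epoch": epoch, "loss": value})
            step += 1
            if config.max_steps is not None and step >= config.max_steps:
                done = True
                break
        if val_images is not None and (epoch % config.val_every == 0 or done):
            dice = mean_foreground_dice(model, normalize_frames(val_images), val_masks)
            val_history.append({"epoch": epoch, "step": step, "val_mean_dice": dice})
            if not (best_val >= dice):  # NaN-safe "dice > best"
                best_val = dice
                best_state = model.state_dict()
        if done:
            break
    if best_state is not None:
        model.load_state_dict(best_state)
    hist_df = pd.DataFrame(history)
    val_df = pd.DataFrame(val_history)
    if log_path is not None:
        hist_df.to_csv(Path(log_path), index=False)
    return TrainResult(model, hist_df, val_df, best_val)


# ----------------------------------------------------------------- evaluation

def evaluate(model: ProredModel, images: np.ndarray, masks: list[LabelMask],
             spacing: tuple[float, float] | None = None) -> EvalReport:
    """Segment every frame and report per-class Dice and Hausdorff vs GT."""
    if masks and masks[0].num_classes != model.num_classes:
        raise ValueError(
            f"model predicts {model.num_classes} classes but GT has "
            f"{masks[0].num_classes}")
    model.eval()
    preds = [LabelMask(model.predict_mask(img), masks[0].class_names)
             for img in normalize_frames(images)]
    return EvalReport.from_masks(preds, masks, spacing)


def closure_report(pred_masks: list[LabelMask],
                   gt_closure: ClosureSequence | None = None,
                   roi: tuple[int, int, int, int] | None = None) -> dict:
    """Frame-level and event-level closure analysis of predicted masks.

    Returns a dict with the predicted ClosureSequence, the extracted events,
    and — when GT closure labels are available — the frame accuracy triple and
    the event-match report."""
    pred_seq = ClosureSequence(
        np.array([detect_closure_frame(m, roi) for m in pred_masks]))
    pred_events = extract_events(pred_seq)
    out = {"pred_sequence": pred_seq, "pred_events": pred_events}
    if gt_closure is not None:
        acc, fp, fn = frame_accuracy(gt_closure, pred_seq)
        out["frame"] = {"accuracy": acc, "false_positive": fp, "false_negative": fn}
        out["events"] = match_events(extract_events(gt_closure), pred_events)
    return out


def ablation_sweep(config_factory, train_images: np.ndarray,
                   train_masks: list[LabelMask], train_cfg: TrainConfig,
                   n_refine_values=(0, 1, 2, 3, 4)) -> pd.DataFrame:
    """Train one model per refinement-module count and tabulate mean Dice
    on the training frames (scaffolding for refinement-count ablations)."""
    rows = []
    for n_refine in n_refine_values:
        model = ProredModel(config_factory(n_refine))
        train(model, train_cfg, train_images, train_masks)
        dice = mean_foreground_dice(model, normalize_frames(train_images), train_masks)
        rows.append({"n_refine": n_refine, "mean_dice": dice})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- checkpoints

def save_checkpoint(model: ProredModel, path: str | Path,
                    extra: dict | None = None) -> None:
    """Single-file archive of weights + config + seed (+ optional metadata)."""
    meta = {"config": model.config.to_dict(), "extra": extra or {}}
    state = {f"param:{k}": v for k, v in model.state_dict().items()}
    np.savez(Path(path), meta=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path: str | Path) -> tuple[ProredModel, dict]:
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        state = {k[len("param:"):]: data[k] for k in data.files if k.startswith("param:")}
    model = ProredModel(ProredConfig.from_dict(meta["config"]))
    model.load_state_dict(state)
    return model, meta.get("extra", {})


# ----------------------------------------------------------------- data on disk

def load_series(series_dir: str | Path) -> dict:
    """Load one series directory (frame_XXX.png / mask_XXX.png / closure.csv)."""
    from PIL import Image

    series_dir = Path(series_dir)
    frame_paths = sorted(series_dir.glob("frame_*.png"))
    mask_paths = sorted(series_dir.glob("mask_*.png"))
    if len(frame_paths) != len(mask_paths) or not frame_paths:
        raise ValueError(f"no aligned frame/mask pairs in {series_dir}")
    images = np.stack([
        np.asarray(Image.open(p).convert("L"), dtype=np.float32) / 255.0
        for p in frame_paths])
    masks = [load_mask_png(p) for p in mask_paths]
    closure_path = series_dir / "closure.csv"
    closure = load_closure_csv(closure_path, series_dir.name) if closure_path.exists() else None
    return {"id": series_dir.name, "images": images, "masks": masks, "closure": closure}
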