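"""Progressive refinement decoder (PRORED).

The decoder restores resolution in four stages of bilinear 2× up-sampling
followed by a 3×3 convolution, batch normalization and ReLU; the three
high-resolution stem feature maps enter through skip connections
(concatenated before the convolution).  After a stage, a *refinement module*
may sharpen the features: a 1×1 convolution predicts a 2-channel directional
field (DF), the features are iteratively resampled along that field
(feature rectification, N steps)

    F^k(p) = F^(k-1)(p_x + DF(p)_x, p_y + DF(p)_y),   k = 1..N,

and F^N is concatenated with F^0 and fused by a 1×1 convolution.  Finally all
refined maps are projected to class channels, up-sampled to the decoder
output resolution and summed with the decoder head's own projection
(feature aggregation), giving an H×W×num_classes logits grid.

Refinement modules sit after each of the three skip connections, deepest
first; a fourth (the ablation arm n_refine=4) is placed after the first,
skip-less stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import BatchNorm2d, Conv2d, Module, Tensor, concat
from .nn import functional as F

__all__ = ["DecoderConfig", "UpsampleBlock", "RefinementModule",
           "frf_rectify", "aggregate", "Decoder"]


@dataclass
class DecoderConfig:
    stage_channels: tuple[int, int, int, int] = (256, 128, 64, 16)
    n_refine: int = 3          # refinement-module count, 0..4
    rect_steps: int = 6        # N, rectification steps per module
    num_classes: int = 7

    def __post_init__(self):
        if not 0 <= self.n_refine <= len(self.stage_channels):
            raise ValueError(f"n_refine must lie in [0, {len(self.stage_channels)}]")
        if self.n_refine >= 1 and self.rect_steps < 1:
            raise ValueError("rect_steps must be >= 1 when refinement modules are used")


class UpsampleBlock(Module):
    """Bilinear 2× up-sampling, optional skip concatenation, 3×3 conv + BN + ReLU."""

    def __init__(self, cin: int, cskip: int, cout: int, rng: np.random.Generator):
        super().__init__()
        self.conv = Conv2d(cin + cskip, cout, 3, padding=1, rng=rng)
        self.norm = BatchNorm2d(cout)
        self.cskip = cskip

    def forward(self, x: Tensor, skip: Tensor | None = None) -> Tensor:
        h, w = x.data.shape[2:]
        up = F.bilinear_resize(x, (2 * h, 2 * w))
        if self.cskip:
            if skip is None:
                raise ValueError("this block expects a skip connection")
            if skip.data.shape[2:] != (2 * h, 2 * w):
                raise ValueError(
                    f"skip spatial dims {skip.data.shape[2:]} must be twice the "
                    f"input dims ({h},{w})")
            up = concat([up, skip], axis=1)
        return self.norm(self.conv(up)).relu()


def frf_rectify(features: Tensor, df: Tensor | np.ndarray, steps: int) -> Tensor:
    """Iterated bilinear resampling of ``features`` along ``df`` (pre-fusion map).

    Fractional coordinates are sampled bilinearly; out-of-grid coordinates
    clamp to the border.  The field acts as a constant index map: gradients
    flow through the feature values only.
    """
    df_data = df.data if isinstance(df, Tensor) else np.asarray(df, dtype=np.float32)
    if df_data.shape[2:] != features.data.shape[2:]:
        raise ValueError(
            f"df spatial dims {df_data.shape[2:]} must equal feature dims "
            f"{features.data.shape[2:]}")
    return F.frf_warp(features, df_data, steps)


class RefinementModule(Module):
    """DF module (1×1 conv → 2 channels) + feature rectification fusion."""

    def __init__(self, channels: int, rect_steps: int, rng: np.random.Generator):
        super().__init__()
        self.df_head = Conv2d(channels, 2, 1, rng=rng)
        self.fuse = Conv2d(2 * channels, channels, 1, rng=rng)
        self.rect_steps = rect_steps

    def forward(self, features: Tensor) -> tuple[Tensor, Tensor]:
        """Returns (refined features, predicted DF) so the DF can be supervised."""
        predicted_df = self.df_head(features)
        warped = frf_rectify(features, predicted_df, self.rect_steps)
        refined = self.fuse(concat([warped, features], axis=1))
        return refined, predicted_df


class Decoder(Module):
    """Four up-sampling stages, 0–4 refinement modules, feature aggregation."""

    # stage indices (0-based) in refinement-placement order: the three skip
    # stages deepest-first, then the skip-less first stage for n_refine=4
    _REFINE_ORDER = (1, 2, 3, 0)

    def __init__(self, config: DecoderConfig, in_channels: int,
                 skip_channels: tuple[int, int, int], rng: np.random.Generator):
        super().__init__()
        self.config = config
        ch = config.stage_channels
        # skip_channels is ordered high-res first (stem stage 1..3); the decoder
        # consumes them deepest-first
        deep_skips = (skip_channels[2], skip_channels[1], skip_channels[0])
        self.stages = [
            UpsampleBlock(in_channels, 0, ch[0], rng),
            UpsampleBlock(ch[0], deep_skips[0], ch[1], rng),
            UpsampleBlock(ch[1], deep_skips[1], ch[2], rng),
            UpsampleBlock(ch[2], deep_skips[2], ch[3], rng),
        ]
        refine_at = set(self._REFINE_ORDER[:config.n_refine])
        self.refiners = [RefinementModule(ch[i], config.rect_steps, rng)
                         if i in refine_at else None for i in range(4)]
        self.head = Conv2d(ch[3], config.num_classes, 1, rng=rng)
        # bias-free so a refined map of zeros contributes nothing
        self.aggregate_projs = [Conv2d(ch[i], config.num_classes, 1, rng=rng, bias=False)
                                if i in refine_at else None for i in range(4)]

    def forward(self, features: Tensor, skips: list[Tensor]
                ) -> tuple[Tensor, list[Tensor]]:
        """(encoder grid, stem skips high-res first) → (logits, predicted DFs)."""
        stage_skips = [None, skips[2], skips[1], skips[0]] if skips else [None] * 4
        refined_maps: list[Tensor] = []
        projections: list[Conv2d] = []
        predicted_dfs: list[Tensor] = []
        x = features
        for i, stage in enumerate(self.stages):
            x = stage(x, stage_skips[i])
            if self.refiners[i] is not None:
                x, df = self.refiners[i](x)
                refined_maps.append(x)
                projections.append(self.aggregate_projs[i])
                predicted_dfs.append(df)
        logits = aggregate(refined_maps, self.head(x), projections)
        return logits, predicted_dfs


def aggregate(refined_maps: list[Tensor], decoder_out: Tensor,
              projections: list[Conv2d]) -> Tensor:
    """Project each refined map to class channels, up-sample to the decoder
    output's resolution and sum everything with the decoder output.

    With no refined maps this is the decoder head alone (the n_refine = 0
    ablation arm)."""
    if len(refined_maps) != len(projections):
        raise ValueError("one 1×1 projection is required per refined map")
    out_hw = decoder_out.data.shape[2:]
    logits = decoder_out
    for refined, proj in zip(refined_maps, projections):
        mapped = proj(refined)
        if mapped.data.shape[2:] != tuple(out_hw):
            mapped = F.bilinear_resize(mapped, out_hw)
        logits = logits + mapped
    return logits
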