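"""Hybrid convolution + transformer encoder.

A three-layer convolutional stem (3×3 conv → batch-norm → ReLU, max-pooling
between layers) extracts high-resolution features; the stem output is split
into non-overlapping patches, linearly projected into a D-dimensional token
space, summed with learned position embeddings

    z0 = [x_p^1 E; …; x_p^N E] + E_pos,

and passed through n pre-norm transformer layers

    z'_l = MSA(LN(z_{l-1})) + z_{l-1},   z_l = MLP(LN(z'_l)) + z'_l.

The patch size P is expressed in *input* pixels (P = 16 for the speech
configuration), so the token grid is (H/P)×(W/P) regardless of the stem: the
two max-poolings shrink the image 4×, and patches of P/4 feature pixels are
taken on the stem output.  With the identity stem (``use_stem=False``) the
patches are taken on the raw image directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (BatchNorm2d, Conv2d, LayerNorm, Linear, Module,
                 TransformerBlock, Tensor)
from .nn import functional as F
from .nn.layers import _trunc_normal

__all__ = ["EncoderConfig", "ConvStem", "HybridEncoder",
           "tokenize", "transformer_forward", "reshape_tokens"]


@dataclass
class EncoderConfig:
    image_size: tuple[int, int] = (256, 256)
    in_channels: int = 1
    stem_channels: tuple[int, ...] = (64, 128, 256)
    patch_size: int = 16          # in input pixels
    embed_dim: int = 768
    depth: int = 12
    heads: int = 12
    mlp_dim: int = 3072
    use_stem: bool = True

    @property
    def stem_downsample(self) -> int:
        return 2 ** (len(self.stem_channels) - 1) if self.use_stem else 1

    @property
    def patch_px(self) -> int:
        """Patch edge in stem-output pixels."""
        s = self.stem_downsample
        if self.patch_size % s:
            raise ValueError(
                f"patch size {self.patch_size} must be divisible by the "
                f"stem downsampling factor {s}")
        return self.patch_size // s

    @property
    def token_grid(self) -> tuple[int, int]:
        h, w = self.image_size
        self.validate_size(h, w)
        return h // self.patch_size, w // self.patch_size

    @property
    def num_tokens(self) -> int:
        gh, gw = self.token_grid
        return gh * gw

    def validate_size(self, h: int, w: int) -> None:
        if h % self.patch_size or w % self.patch_size:
            raise ValueError(
                f"input size ({h},{w}) must be divisible by the patch size "
                f"{self.patch_size} (stem downsampling {self.stem_downsample} "
                f"× {self.patch_px}-pixel feature patches)")


def tiny_encoder_config(image_size: tuple[int, int] = (64, 64)) -> EncoderConfig:
    """Desk-scale configuration for tests and smoke training."""
    return EncoderConfig(image_size=image_size, stem_channels=(8, 16, 32),
                         embed_dim=64, depth=2, heads=4, mlp_dim=128)


class ConvStem(Module):
    """Three 3×3 conv(+BN+ReLU) layers with 2×2 max-pooling between them."""

    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        chans = (config.in_channels,) + tuple(config.stem_channels)
        self.convs = [Conv2d(chans[i], chans[i + 1], 3, padding=1, rng=rng)
                      for i in range(len(config.stem_channels))]
        self.norms = [BatchNorm2d(c) for c in config.stem_channels]
        self.downsample = config.stem_downsample

    def forward(self, x: Tensor) -> tuple[Tensor, list[Tensor]]:
        """Returns (final feature grid, per-stage grids for skip connections)."""
        h, w = x.data.shape[2:]
        if h % self.downsample or w % self.downsample:
            raise ValueError(
                f"input size ({h},{w}) must be divisible by the stem "
                f"downsampling factor {self.downsample}")
        skips = []
        for i, (conv, norm) in enumerate(zip(self.convs, self.norms)):
            if i > 0:
                x = F.max_pool2d(x, 2)
            x = norm(conv(x)).relu()
            skips.append(x)
        return x, skips


def tokenize(features: Tensor, patch_px: int, projection: Linear,
             position_embedding: Tensor | None = None) -> Tensor:
    """Flatten non-overlapping patches, project with E and add E_pos."""
    b, c, h, w = features.data.shape
    if h % patch_px or w % patch_px:
        raise ValueError(f"feature grid ({h},{w}) not divisible by patch size {patch_px}")
    gh, gw = h // patch_px, w // patch_px
    patches = features.reshape(b, c, gh, patch_px, gw, patch_px)
    patches = patches.transpose(0, 2, 4, 1, 3, 5)  # (B, gh, gw, C, p, p)
    patches = patches.reshape(b, gh * gw, c * patch_px * patch_px)
    tokens = projection(patches)
    if position_embedding is not None:
        tokens = tokens + position_embedding
    return tokens


def transformer_forward(z: Tensor, blocks: list[TransformerBlock]) -> Tensor:
    for block in blocks:
        z = block(z)
    return z


def reshape_tokens(z: Tensor, grid: tuple[int, int]) -> Tensor:
    """Row-major rearrangement of (B, N, D) tokens into a (B, D, gh, gw) grid."""
    b, n, d = z.data.shape
    gh, gw = grid
    if gh * gw != n:
        raise ValueError(f"{n} tokens do not fill a {gh}×{gw} grid")
    return z.reshape(b, gh, gw, d).transpose(0, 3, 1, 2)


class HybridEncoder(Module):
    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        self.stem = ConvStem(config, rng) if config.use_stem else None
        feat_channels = config.stem_channels[-1] if config.use_stem else config.in_channels
        patch_dim = feat_channels * config.patch_px ** 2
        self.projection = Linear(patch_dim, config.embed_dim, rng)
        self.position_embedding = Tensor(
            _trunc_normal(rng, (config.num_tokens, config.embed_dim)), requires_grad=True)
        self.blocks = [TransformerBlock(config.embed_dim, config.heads, config.mlp_dim, rng)
                       for _ in range(config.depth)]
        self.norm = LayerNorm(config.embed_dim)

    def forward(self, image: Tensor) -> tuple[Tensor, list[Tensor]]:
        """image (B,1,H,W) → (token feature grid (B,D,H/P,W/P), stem skips)."""
        h, w = image.data.shape[2:]
        self.config.validate_size(h, w)
        if (h, w) != tuple(self.config.image_size):
            raise ValueError(
                f"input size ({h},{w}) differs from the configured "
                f"image size {tuple(self.config.image_size)} "
                f"(position embeddings are size-specific)")
        if self.stem is not None:
            feats, skips = self.stem(image)
        else:
            feats, skips = image, []
        z = tokenize(feats, self.config.patch_px, self.projection, self.position_embedding)
        z = self.norm(transformer_forward(z, self.blocks))
        return reshape_tokens(z, self.config.token_grid), skips
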