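"""The full segmentation network: hybrid encoder + progressive refinement decoder.

``ProredModel.forward`` maps a batch of single-channel frames to a
num_classes-channel logits grid at input resolution, and exposes the
2-channel directional-field map predicted by every refinement module so the
trainer can supervise them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .decoder import Decoder, DecoderConfig
from .encoder import EncoderConfig, HybridEncoder, tiny_encoder_config
from .nn import Module, Tensor

__all__ = ["ProredConfig", "ProredModel", "speech_config", "tiny_config"]


@dataclass
class ProredConfig:
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    decoder: DecoderConfig = field(default_factory=DecoderConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ProredConfig":
        enc = dict(d.get("encoder", {}))
        dec = dict(d.get("decoder", {}))
        for key in ("image_size", "stem_channels"):
            if key in enc:
                enc[key] = tuple(enc[key])
        if "stage_channels" in dec:
            dec["stage_channels"] = tuple(dec["stage_channels"])
        return cls(EncoderConfig(**enc), DecoderConfig(**dec), int(d.get("seed", 0)))


def speech_config(n_refine: int = 3, seed: int = 0) -> ProredConfig:
    """Default configuration for 256×256 midsagittal speech frames (7 classes)."""
    return ProredConfig(EncoderConfig(), DecoderConfig(n_refine=n_refine), seed)


def tiny_config(image_size: tuple[int, int] = (64, 64), n_refine: int = 3,
                num_classes: int = 7, seed: int = 0) -> ProredConfig:
    """Desk-scale configuration (D=64, 2 transformer layers) for tests."""
    return ProredConfig(
        tiny_encoder_config(image_size),
        DecoderConfig(stage_channels=(32, 32, 16, 16), n_refine=n_refine,
                      num_classes=num_classes),
        seed,
    )


class ProredModel(Module):
    def __init__(self, config: ProredConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.encoder = HybridEncoder(config.encoder, rng)
        skip_channels = tuple(config.encoder.stem_channels)
        self.decoder = Decoder(config.decoder, config.encoder.embed_dim,
                               skip_channels, rng)

    @property
    def num_classes(self) -> int:
        return self.config.decoder.num_classes

    def forward(self, image: Tensor | np.ndarray) -> tuple[Tensor, list[Tensor]]:
        """(B,1,H,W) frames → ((B,num_classes,H,W) logits, predicted DF maps)."""
        if not isinstance(image, Tensor):
            image = Tensor(np.asarray(image, dtype=np.float32))
        if image.ndim == 2:
            image = Tensor(image.data[None, None])
        elif image.ndim == 3:
            image = Tensor(image.data[:, None])
        features, skips = self.encoder(image)
        return self.decoder(features, skips)

    def predict_mask(self, image: np.ndarray) -> np.ndarray:
        """Argmax class map for a single (H,W) frame or (B,H,W) batch."""
        squeeze = np.asarray(image).ndim == 2
        logits, _ = self.forward(image)
        labels = logits.data.argmax(axis=1).astype(np.int64)
        return labels[0] if squeeze else labels
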