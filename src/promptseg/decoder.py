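"""Attention-guided decoder and the assembled prompt-conditioned model.

The decoder reconstructs a probability mask from the normalized fused
bottleneck and the three encoder skips.  Each of the three stages is a
channel-preserving 2x2 stride-2 transposed convolution, concatenation
with the skip (widths 768/384/192 at full width), and a residual
double-conv block with SE + spatial attention reducing to 256/128/64.  The stage-2 block (128 channels at full
width) optionally carries conditional batch normalization — the decoder
site named in the architecture description.

Three doublings from H/16 reach H/2 (the encoder pools before its first
convolution, so E1 already sits at H/2).  A fourth 2x2 stride-2
transposed convolution (64 -> 64 channels) restores full resolution
before the 1x1 sigmoid head, so the output probability map matches the
input image size exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoder import ConvBlock, Encoder, EncoderConfig
from .fusion import ConditionalBatchNorm, FusionConfig, FusionModule
from .nn import Conv2d, ConvTranspose2x2, Module, Tensor, as_tensor, concat
from .text import EMBED_DIM


@dataclass
class BinaryMask:
    """Thresholded mask with the threshold that produced it."""

    values: np.ndarray
    threshold: float


def binarize(prob: np.ndarray, threshold: float = 0.5) -> BinaryMask:
    """Pixelwise indicator prob >= threshold (ties go to foreground)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0,1), got {threshold}")
    prob = np.asarray(prob)
    return BinaryMask(values=(prob >= threshold).astype(np.uint8),
                      threshold=threshold)


class Decoder(Module):
    """Three up-concat-conv stages, a resolution-restoring upsample, 1x1 head."""

    def __init__(self, base_channels: int = 64, cfg: EncoderConfig | None = None,
                 fusion_cfg: FusionConfig | None = None,
                 rng: np.random.Generator | None = None,
                 embed_dim: int = EMBED_DIM):
        super().__init__()
        cfg = cfg or EncoderConfig()
        fusion_cfg = fusion_cfg or FusionConfig()
        rng = rng if rng is not None else np.random.default_rng(0)
        b = base_channels
        widths = [b * 8, b * 4, b * 2, b]       # bottleneck, then stage outputs
        self.up = []
        self.blocks = []
        for i in range(3):
            skip_c = widths[i + 1]
            # channel-preserving upsample: concat widths 768/384/192 at b=64
            self.up.append(ConvTranspose2x2(widths[i], widths[i], rng))
            self.blocks.append(ConvBlock(widths[i] + skip_c, skip_c, cfg, rng))
        self.cbn = (ConditionalBatchNorm(b * 2, rng, embed_dim)
                    if fusion_cfg.use_cbn and "decoder128" in fusion_cfg.cbn_sites
                    else None)
        self.final_up = ConvTranspose2x2(b, b, rng)
        self.head = Conv2d(b, 1, 1, rng, padding=0)

    def forward(self, e_norm: Tensor, skips: tuple[Tensor, Tensor, Tensor],
                v: Tensor | None = None,
                rng: np.random.Generator | None = None) -> Tensor:
        """e_norm: fused bottleneck; skips: (E1, E2, E3) -> (N, H, W) in [0,1]."""
        e1, e2, e3 = skips
        x = as_tensor(e_norm)
        for stage, (upc, block, skip) in enumerate(
                zip(self.up, self.blocks, (e3, e2, e1)), start=1):
            x = upc(x)
            skip = as_tensor(skip)
            if x.shape[2:] != skip.shape[2:]:
                raise ValueError(
                    f"decoder stage {stage}: upsampled spatial size "
                    f"{x.shape[2:]} does not match skip {skip.shape[2:]}")
            x = block(concat([x, skip], axis=1), rng)
            if stage == 2 and self.cbn is not None:
                if v is None:
                    raise ValueError("decoder CBN is enabled but no prompt "
                                     "embedding was provided")
                x = self.cbn(x, v)
        x = self.final_up(x)
        logits = self.head(x)
        prob = logits.sigmoid()
        n, _, h, w = prob.shape
        return prob.reshape(n, h, w)


class PromptSegModel(Module):
    """Encoder -> cross-modal fusion -> decoder, end to end.

    base_channels=64 is the full-scale architecture (stages 64/128/256/512);
    base_channels=16 is the quarter-width desk-scale variant with identical
    topology.
    """

    def __init__(self, in_channels: int = 1, base_channels: int = 64,
                 encoder_cfg: EncoderConfig | None = None,
                 fusion_cfg: FusionConfig | None = None,
                 embed_dim: int = EMBED_DIM, seed: int = 0):
        super().__init__()
        encoder_cfg = encoder_cfg or EncoderConfig()
        fusion_cfg = fusion_cfg or FusionConfig()
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA11C]))
        self.encoder_cfg = encoder_cfg
        self.fusion_cfg = fusion_cfg
        self.base_channels = base_channels
        self.encoder = Encoder(in_channels, base_channels, encoder_cfg, rng)
        self.fusion = FusionModule(base_channels * 8, fusion_cfg, rng, embed_dim,
                                   se_reduction=encoder_cfg.se_reduction)
        self.decoder = Decoder(base_channels, encoder_cfg, fusion_cfg, rng,
                               embed_dim)

    def forward(self, image: Tensor, v: Tensor,
                rng: np.random.Generator | None = None) -> Tensor:
        """image: (N,C,H,W) in [-1,1]; v: (N,768) -> probabilities (N,H,W)."""
        e1, e2, e3, e4 = self.encoder(image, rng)
        e_norm = self.fusion(e4, v)
        return self.decoder(e_norm, (e1, e2, e3), v, rng)

    def predict(self, image: np.ndarray, v: np.ndarray,
                threshold: float = 0.5) -> tuple[np.ndarray, BinaryMask]:
        """Eval-mode single forward pass -> (probability map, binary mask)."""
        was_training = self.training
        self.eval()
        try:
            image = np.asarray(image, dtype=np.float64)
            if image.ndim == 2:
                image = image[None, None]
            elif image.ndim == 3:
                image = image[None]
            v = np.asarray(v, dtype=np.float64)
            if v.ndim == 1:
                v = v[None]
            prob = self.forward(Tensor(image), Tensor(v)).data[0]
        finally:
            if was_training:
                self.train()
        return prob, binarize(prob, threshold)
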