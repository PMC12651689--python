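"""Hierarchical four-stage image encoder with dual attention.

The backbone is a modified U-Net encoder.  Each stage first halves the
spatial resolution with a 2x2 stride-2 max pool and then applies a
residual double-convolution block augmented with squeeze-and-excitation
(SE) channel attention and a spatial attention map (the spatial branch of
CBAM), followed by dropout.  For an input of size H x W (divisible by 16)
the four stages emit feature maps of

    E1: 64 x H/2 x W/2,   E2: 128 x H/4 x W/4,
    E3: 256 x H/8 x W/8,  E4: 512 x H/16 x W/16

(at the default width; all channel counts scale with ``base_channels``).
E1..E3 are retained as skip connections; E4 is the bottleneck handed to
the cross-modal fusion stage.

Note on CBAM: only the *spatial* branch (channel-pooled 7x7 convolution
-> sigmoid map) is used here, applied after SE.  This deviates from the
original CBAM publication, which also has a channel branch; SE already
plays that role in this architecture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import BatchNorm2d, Conv2d, Dropout, Module, Tensor, as_tensor, concat
from .nn.layers import Parameter, _he_normal


@dataclass
class EncoderConfig:
    """Architecture knobs for the encoder (and reused by the decoder blocks).

    se_reduction: SE bottleneck ratio r; must divide every stage channel count.
    leaky_slope: negative slope of the LeakyReLU activations.
    dropout_rate: dropout after each conv block (active in training only).
    cbam_kernel: odd spatial-attention kernel size.
    use_se / use_cbam: ablation toggles.
    """

    se_reduction: int = 16
    leaky_slope: float = 0.1
    dropout_rate: float = 0.1
    cbam_kernel: int = 7
    use_se: bool = True
    use_cbam: bool = True

    def __post_init__(self):
        if self.se_reduction < 1:
            raise ValueError("se_reduction must be a positive integer")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.cbam_kernel % 2 != 1:
            raise ValueError("cbam_kernel must be odd")


class SEBlock(Module):
    """Squeeze-and-Excitation channel attention.

    Global-average-pools each channel, passes the descriptor through a
    two-layer bottleneck (reduction r) and rescales channels by the
    resulting sigmoid gates.
    """

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        super().__init__()
        if channels % reduction != 0:
            raise ValueError(
                f"SE reduction {reduction} does not divide channel count {channels}")
        hidden = channels // reduction
        self.w1 = Parameter(_he_normal(rng, (channels, hidden), channels))
        self.b1 = Parameter(np.zeros(hidden))
        self.w2 = Parameter(_he_normal(rng, (hidden, channels), hidden))
        self.b2 = Parameter(np.zeros(channels))

    def forward(self, f: Tensor) -> Tensor:
        f = as_tensor(f)
        c = f.shape[1]
        z = f.mean(axis=(2, 3))                       # (N, C) squeeze
        u = ((z @ self.w1 + self.b1).relu() @ self.w2 + self.b2).sigmoid()
        return f * u.reshape(f.shape[0], c, 1, 1)     # excite


class CBAMSpatial(Module):
    """Spatial attention: sigma(conv_kxk([avg_ch(F); max_ch(F)])) applied per pixel."""

    def __init__(self, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.conv = Conv2d(2, 1, kernel, rng)

    def forward(self, f: Tensor) -> Tensor:
        f = as_tensor(f)
        avg = f.mean(axis=1, keepdims=True)
        mx = f.max(axis=1, keepdims=True)
        m_s = self.conv(concat([avg, mx], axis=1)).sigmoid()  # (N,1,H,W)
        return f * m_s

    def attention_map(self, f: Tensor) -> np.ndarray:
        f = as_tensor(f)
        avg = f.mean(axis=1, keepdims=True)
        mx = f.max(axis=1, keepdims=True)
        return self.conv(concat([avg, mx], axis=1)).sigmoid().data


class ConvBlock(Module):
    """Residual double 3x3 conv + BN + LeakyReLU, then SE, CBAM, dropout.

    The shortcut is the identity when in/out channels match, otherwise a
    learned 1x1 projection.
    """

    def __init__(self, in_channels: int, out_channels: int, cfg: EncoderConfig,
                 rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.conv1 = Conv2d(in_channels, out_channels, 3, rng)
        self.bn1 = BatchNorm2d(out_channels)
        self.conv2 = Conv2d(out_channels, out_channels, 3, rng)
        self.bn2 = BatchNorm2d(out_channels)
        self.proj = (Conv2d(in_channels, out_channels, 1, rng)
                     if in_channels != out_channels else None)
        self.se = SEBlock(out_channels, cfg.se_reduction, rng) if cfg.use_se else None
        self.cbam = CBAMSpatial(cfg.cbam_kernel, rng) if cfg.use_cbam else None
        self.dropout = Dropout(cfg.dropout_rate)

    def forward(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        x = as_tensor(x)
        s = self.cfg.leaky_slope
        h = self.bn1(self.conv1(x)).leaky_relu(s)
        h = self.bn2(self.conv2(h)).leaky_relu(s)
        shortcut = self.proj(x) if self.proj is not None else x
        h = h + shortcut
        if self.se is not None:
            h = self.se(h)
        if self.cbam is not None:
            h = self.cbam(h)
        return self.dropout(h, rng)


class Encoder(Module):
    """Four pool-then-convolve stages producing the feature pyramid."""

    STAGE_MULTIPLIERS = (1, 2, 4, 8)

    def __init__(self, in_channels: int = 1, base_channels: int = 64,
                 cfg: EncoderConfig | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        cfg = cfg or EncoderConfig()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.cfg = cfg
        self.base_channels = base_channels
        widths = [base_channels * m for m in self.STAGE_MULTIPLIERS]
        chans = [in_channels] + widths
        self.blocks = [ConvBlock(chans[i], chans[i + 1], cfg, rng)
                       for i in range(4)]
        self.stage_channels = widths

    def forward(self, image: Tensor,
                rng: np.random.Generator | None = None) -> tuple[Tensor, ...]:
        """image: (N, C, H, W) with H, W divisible by 16 -> (E1, E2, E3, E4)."""
        image = as_tensor(image)
        if image.ndim != 4:
            raise ValueError(f"expected (N,C,H,W) input, got shape {image.shape}")
        _, _, h, w = image.shape
        for name, v in (("height", h), ("width", w)):
            if v % 16 != 0:
                raise ValueError(f"input {name} {v} is not divisible by 16")
        feats = []
        x = image
        for block in self.blocks:
            x = block(x.maxpool2x2(), rng)   # downsample THEN convolve
            feats.append(x)
        return tuple(feats)
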