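"""Cross-modal fusion: FiLM, SE recalibration, conditional batch norm,
residual link and channel-wise L2 normalization.

The prompt embedding v_t (768-dim) conditions the visual bottleneck
E4 (512 x h x w at full width) through

    FiLM:      E_fused = (1 + gamma) * E4 + beta,  gamma/beta = affine(v_t)
    SE:        channel recalibration of E_fused under the joint context
    CBN:       batch normalization whose scale/shift are generated from v_t
    residual:  E_final = E4 + E_CBN     (raw bottleneck, pre-FiLM)
    L2 norm:   E_norm = E_final / ||E_final||_2 per spatial location

Each stage is individually toggleable for ablation.  The conditioning
affine maps are zero-initialised so an untrained fusion module is exactly
the identity (up to normalization) regardless of the prompt — training
then grows the modulation from zero, which keeps early optimization
stable.

The running text and the equations place CBN at two different sites (the
decoder's 128-channel block vs. the fused bottleneck); both are
implemented and selected by ``FusionConfig.cbn_sites``; the default
enables both.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .encoder import SEBlock
from .nn import Linear, Module, Tensor, as_tensor
from .text import EMBED_DIM


@dataclass
class FusionConfig:
    use_film: bool = True
    use_cbn: bool = True
    use_se_fused: bool = True
    l2_eps: float = 1e-8
    cbn_sites: frozenset = field(
        default_factory=lambda: frozenset({"bottleneck", "decoder128"}))

    def __post_init__(self):
        if self.l2_eps <= 0:
            raise ValueError("l2_eps must be positive")
        unknown = set(self.cbn_sites) - {"bottleneck", "decoder128"}
        if unknown:
            raise ValueError(f"unknown cbn_sites: {sorted(unknown)}")


class FilmLayer(Module):
    """Generates per-channel (gamma, beta) from v_t and modulates a feature map."""

    def __init__(self, channels: int, rng: np.random.Generator,
                 embed_dim: int = EMBED_DIM):
        super().__init__()
        self.channels = channels
        self.w_gamma = Linear(embed_dim, channels, rng, zero_init=True)
        self.w_beta = Linear(embed_dim, channels, rng, zero_init=True)

    def params_for(self, v: Tensor) -> tuple[Tensor, Tensor]:
        """v: (N, embed_dim) -> gamma, beta each (N, channels)."""
        return self.w_gamma(as_tensor(v)), self.w_beta(as_tensor(v))

    def forward(self, feat: Tensor, v: Tensor) -> Tensor:
        feat = as_tensor(feat)
        n, c = feat.shape[0], feat.shape[1]
        if c != self.channels:
            raise ValueError(
                f"FiLM built for {self.channels} channels, got feature map with {c}")
        gamma, beta = self.params_for(v)
        return modulate(feat, gamma, beta)


def modulate(feat: Tensor, gamma: Tensor, beta: Tensor) -> Tensor:
    """(1 + gamma) * feat + beta with per-channel broadcast over space."""
    feat, gamma, beta = as_tensor(feat), as_tensor(gamma), as_tensor(beta)
    n, c = feat.shape[0], feat.shape[1]
    if gamma.shape[-1] != c or beta.shape[-1] != c:
        raise ValueError(
            f"gamma/beta length {gamma.shape[-1]}/{beta.shape[-1]} != channels {c}")
    g = gamma.reshape(n, c, 1, 1) if gamma.ndim == 2 else gamma.reshape(1, c, 1, 1)
    b = beta.reshape(n, c, 1, 1) if beta.ndim == 2 else beta.reshape(1, c, 1, 1)
    return (1.0 + g) * feat + b


class ConditionalBatchNorm(Module):
    """Batch normalization whose scale/shift come from the prompt embedding.

    gamma_bn = W_g v_t + b_g (b_g init 1), beta_bn = W_b v_t + b_b (init 0);
    the feature map is normalized with batch statistics in training mode and
    with running estimates in eval mode, then scaled/shifted per channel.
    """

    def __init__(self, num_features: int, rng: np.random.Generator,
                 embed_dim: int = EMBED_DIM, eps: float = 1e-5,
                 momentum: float = 0.1):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.w_gamma = Linear(embed_dim, num_features, rng, zero_init=True,
                              bias_init=1.0)
        self.w_beta = Linear(embed_dim, num_features, rng, zero_init=True)
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)

    def params_for(self, v: Tensor) -> tuple[Tensor, Tensor]:
        return self.w_gamma(as_tensor(v)), self.w_beta(as_tensor(v))

    def forward(self, feat: Tensor, v: Tensor) -> Tensor:
        feat = as_tensor(feat)
        n, c = feat.shape[0], feat.shape[1]
        if c != self.num_features:
            raise ValueError(
                f"CBN built for {self.num_features} channels, got {c}")
        if self.training:
            mu = feat.mean(axis=(0, 2, 3), keepdims=True)
            var = ((feat - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            cnt = n * feat.shape[2] * feat.shape[3]
            unbiased = var.data.ravel() * (cnt / max(cnt - 1, 1))
            self.running_var = (1 - m) * self.running_var + m * unbiased
            xhat = (feat - mu) / ((var + self.eps) ** 0.5)
        else:
            mu = self.running_mean.reshape(1, -1, 1, 1)
            sd = np.sqrt(self.running_var + self.eps).reshape(1, -1, 1, 1)
            xhat = (feat - mu) / sd
        gamma, beta = self.params_for(v)
        return xhat * gamma.reshape(n, c, 1, 1) + beta.reshape(n, c, 1, 1)


def l2_normalize_channels(feat: Tensor, eps: float = 1e-8) -> Tensor:
    """Unit-L2 channel vector at every spatial location; eps guards zeros."""
    feat = as_tensor(feat)
    norm_sq = (feat ** 2).sum(axis=1, keepdims=True)
    return feat / ((norm_sq + eps) ** 0.5)


class FusionModule(Module):
    """FiLM -> SE-on-fused -> CBN -> residual -> channel L2 norm pipeline."""

    def __init__(self, channels: int, cfg: FusionConfig | None = None,
                 rng: np.random.Generator | None = None,
                 embed_dim: int = EMBED_DIM, se_reduction: int = 16):
        super().__init__()
        cfg = cfg or FusionConfig()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.cfg = cfg
        self.channels = channels
        self.film = FilmLayer(channels, rng, embed_dim) if cfg.use_film else None
        self.se = (SEBlock(channels, se_reduction, rng)
                   if cfg.use_se_fused else None)
        self.cbn = (ConditionalBatchNorm(channels, rng, embed_dim)
                    if cfg.use_cbn and "bottleneck" in cfg.cbn_sites else None)

    def forward(self, e4: Tensor, v: Tensor) -> Tensor:
        e4 = as_tensor(e4)
        h = e4
        if self.film is not None:
            h = self.film(h, v)
        if self.se is not None:
            h = self.se(h)
        if self.cbn is not None:
            h = self.cbn(h, v)
        e_final = e4 + h          # residual keeps the raw bottleneck
        return l2_normalize_channels(e_final, self.cfg.l2_eps)
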