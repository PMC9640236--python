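"""Full network assembly: dual encoders + mutual-assistance decoder + heads.

``MMANet.forward`` maps (full-resolution, half-resolution) image batches to
the prediction pyramid; M_D[1]'s head is the final segmentation output. With
``num_branches=1`` the network degrades to a single encoder with a plain
attention-skip decoder (the branch-count ablation baseline) and four heads.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .autodiff import Tensor
from .encoders import BranchFeatures, NetConfig, VGGEncoder, build_encoders, \
    encode_branches
from .layers import Module
from .losses import PredictionHeads, PredictionPyramid
from .mma import DecoderFeatures, MMADecoder, SingleBranchDecoder

__all__ = ["MMANet", "build_network", "head_sides"]


def head_sides(cfg: NetConfig) -> list[int]:
    """Spatial sides of the prediction heads in fixed order."""
    s = cfg.input_side
    m_sides = [s, s // 2, s // 4, s // 8]
    if cfg.num_branches == 1:
        return m_sides
    return m_sides + [s // 2, s // 4, s // 8]


class MMANet(Module):
    """The complete segmentation network."""

    def __init__(self, cfg: NetConfig, seed: int = 0):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        self.enc1, self.enc2 = build_encoders(cfg, seed)
        rng_dec = np.random.default_rng(np.random.SeedSequence([seed, 3]))
        rng_heads = np.random.default_rng(np.random.SeedSequence([seed, 4]))
        c = cfg.channels
        if cfg.num_branches == 2:
            self.decoder = MMADecoder(cfg, rng_dec)
            channels = {("M", 1): c[0], ("M", 2): c[1], ("M", 3): c[2],
                        ("M", 4): c[3], ("N", 2): c[1], ("N", 3): c[2],
                        ("N", 4): c[3]}
        else:
            self.decoder = SingleBranchDecoder(cfg, rng_dec)
            channels = {("M", 1): c[0], ("M", 2): c[1], ("M", 3): c[2],
                        ("M", 4): c[3]}
        self.heads = PredictionHeads(channels, cfg.num_classes, rng_heads)

    def encode(self, full: Tensor, half: Optional[Tensor]) -> BranchFeatures:
        return encode_branches(full, half, (self.enc1, self.enc2))

    def decode(self, bf: BranchFeatures) -> DecoderFeatures:
        return self.decoder(bf)

    def forward(self, full, half=None) -> PredictionPyramid:
        full = full if isinstance(full, Tensor) else Tensor(np.asarray(full))
        if full.ndim == 2:
            full = Tensor(full.data[None, None])
        elif full.ndim == 3:
            full = Tensor(full.data[:, None])
        if full.shape[-1] != self.cfg.input_side:
            raise ValueError(
                f"input side {full.shape[-1]} != configured {self.cfg.input_side}")
        if half is not None:
            half = half if isinstance(half, Tensor) else Tensor(np.asarray(half))
            if half.ndim == 2:
                half = Tensor(half.data[None, None])
            elif half.ndim == 3:
                half = Tensor(half.data[:, None])
        return self.heads(self.decode(self.encode(full, half)))

    def attention_maps(self) -> dict[str, np.ndarray]:
        return self.decoder.attention_maps()


def build_network(cfg: NetConfig, seed: int = 0) -> MMANet:
    return MMANet(cfg, seed)
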