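"""Multibranch input module: one VGG19-style encoder per input resolution.

Branch 1 consumes the full-resolution image and emits features M_E[1..5];
branch 2 consumes the half-resolution image and emits N_E[2..6]. Branch-2
stages are numbered 2..6 so that equal stage index implies equal spatial
side: M_E[i] and N_E[i] for i in 2..5 are spatially aligned, and N_E[6] is
one 2x reduction deeper than M_E[5]. The two encoders share no parameters.

The backbone follows the VGG19 convolutional body: five stages with
(2, 2, 4, 4, 4) 3x3 conv layers and nominal widths (64, 128, 256, 512, 512),
BN + ReLU after each conv, 2x max pooling between stages, adapted to a
1-channel (grayscale MR) input. ``width_multiplier`` scales every stage
width for slim desk-scale configurations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .autodiff import Tensor
from .layers import ConvBNReLU, Module, Sequential, pool2x

__all__ = ["NetConfig", "BranchFeatures", "VGGEncoder", "build_encoders",
           "encode_branches", "VGG_STAGE_CONVS"]

VGG_STAGE_CONVS = (2, 2, 4, 4, 4)


@dataclass
class NetConfig:
    """Architecture configuration shared by encoders, decoder, and heads."""

    input_side: int = 224
    num_classes: int = 3
    stage_channels: tuple[int, ...] = (64, 128, 256, 512, 512)
    width_multiplier: float = 1.0
    num_branches: int = 2
    supervision_mode: str = "MLDS"     # "MLDS" or "DS"

    def validate(self) -> None:
        problems = []
        if self.input_side % 32 != 0:
            problems.append(f"input_side {self.input_side} not divisible by 32")
        if self.num_classes < 1:
            problems.append("num_classes must be >= 1")
        if len(self.stage_channels) != 5:
            problems.append("stage_channels must have length 5")
        if self.num_branches not in (1, 2):
            problems.append(f"num_branches must be 1 or 2, got {self.num_branches}")
        if self.supervision_mode not in ("MLDS", "DS"):
            problems.append(f"supervision_mode must be MLDS or DS, got {self.supervision_mode!r}")
        if self.width_multiplier <= 0:
            problems.append("width_multiplier must be positive")
        if problems:
            raise ValueError("invalid NetConfig: " + "; ".join(problems))

    @property
    def channels(self) -> tuple[int, ...]:
        return tuple(max(1, round(c * self.width_multiplier))
                     for c in self.stage_channels)


@dataclass
class BranchFeatures:
    """Encoder outputs: M_E keyed 1..5; N_E keyed 2..6 (None for one branch)."""

    m: dict[int, Tensor]
    n: Optional[dict[int, Tensor]] = None


class VGGEncoder(Module):
    """Five conv stages with 2x max pooling between consecutive stages."""

    def __init__(self, cfg: NetConfig, rng: np.random.Generator):
        super().__init__()
        chans = cfg.channels
        in_ch = 1
        stages = []
        for si, (out_ch, n_convs) in enumerate(zip(chans, VGG_STAGE_CONVS)):
            blocks = []
            for ci in range(n_convs):
                blocks.append(ConvBNReLU(in_ch if ci == 0 else out_ch, out_ch, 3, rng))
                in_ch = out_ch
            stages.append(Sequential(*blocks))
        for i, s in enumerate(stages):
            setattr(self, f"stage{i + 1}", s)
        self._stages = stages

    def forward(self, x: Tensor) -> list[Tensor]:
        feats = []
        for i, stage in enumerate(self._stages):
            if i > 0:
                x = pool2x(x)
            x = stage(x)
            feats.append(x)
        return feats


def build_encoders(config: NetConfig, seed: int = 0):
    """Build the parameter-independent encoders (branch 2 is None if single).

    Each branch draws its weights from its own seeded stream, so the two
    encoders never share parameters.
    """
    config.validate()
    enc1 = VGGEncoder(config, np.random.default_rng(np.random.SeedSequence([seed, 1])))
    enc2 = None
    if config.num_branches == 2:
        enc2 = VGGEncoder(config, np.random.default_rng(np.random.SeedSequence([seed, 2])))
    return enc1, enc2


def encode_branches(full_image: Tensor, half_image: Optional[Tensor],
                    encoders) -> BranchFeatures:
    """Run both branches; returns M_E[1..5] and (if dual) N_E[2..6]."""
    enc1, enc2 = encoders
    full_image = full_image if isinstance(full_image, Tensor) else Tensor(full_image)
    side = full_image.shape[-1]
    if full_image.shape[-2] != side:
        raise ValueError(f"full image must be square, got {full_image.shape}")
    m_feats = enc1(full_image)
    m = {i + 1: f for i, f in enumerate(m_feats)}
    n = None
    if enc2 is not None:
        if half_image is None:
            raise ValueError("dual-branch encoder needs the half-resolution image")
        half_image = half_image if isinstance(half_image, Tensor) else Tensor(half_image)
        if half_image.shape[-1] * 2 != side or half_image.shape[-2] * 2 != side:
            raise ValueError(
                f"half image side {half_image.shape[-2:]} is not half of {side}")
        n_feats = enc2(half_image)
        n = {j + 2: f for j, f in enumerate(n_feats)}
    return BranchFeatures(m=m, n=n)
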