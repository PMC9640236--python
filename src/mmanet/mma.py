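"""Multiresolution mutual-assistance decoder: AG, A, F, and the wiring.

The decoder interleaves the two encoder branches. At the bottleneck, the
deepest global feature N_E[6] gates the deepest local feature M_E[5] through
an additive attention gate (AG), and the two are fused (F) into a shared
bottleneck B. Each subsequent stage fuses the two branches' previous decoder
outputs into one complementary feature C, upsamples it, and lets C gate the
matching encoder skip feature through attention feature selection (A):

    B       = F( Up(N_E[6]), AG(Up(N_E[6]), M_E[5]) )
    M_D[4]  = A( Up(B), M_E[4] );    N_D[4] = A( Up(B), N_E[4] )
    C_i     = Up( F( M_D[i+1], N_D[i+1] ) )         for i = 3, 2
    M_D[i]  = A( C_i, M_E[i] );      N_D[i] = A( C_i, N_E[i] )
    M_D[1]  = A( Up( F( M_D[2], N_D[2] ) ), M_E[1] )

B is computed once and shared by both branch-4 stages, and C_i is shared by
the two branches at each stage. The seven outputs M_D[1..4], N_D[2..4] feed
the prediction heads; M_D[1] is the final segmentation output.

Internal structure choices (the attention blocks are narrow, pluggable
interfaces):

* AG — additive attention in the Attention U-Net lineage: 1x1-project both
  inputs to an intermediate width, add, ReLU, 1x1 to one channel, sigmoid;
  the coefficient map broadcasts over channels of the local feature.
* A — the coefficient map comes from the complementary feature alone
  (1x1 conv + sigmoid); the gated encoder feature is channel-projected if
  needed and then combined with the complementary feature by F.
* F — channel concatenation followed by two 3x3 conv(+BN+ReLU) layers
  projecting back to a single input's channel count.
* Up — factor-2 bilinear interpolation, followed by a 1x1 convolution only
  when the channel count changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .autodiff import Tensor, as_tensor, concat, upsample2x
from .encoders import BranchFeatures, NetConfig
from .layers import Conv2d, ConvBNReLU, Module, Sequential

__all__ = ["DecoderFeatures", "AttentionGate", "AttentionFeatureSelection",
           "FeatureFusion", "Upsample", "MMADecoder", "SingleBranchDecoder"]


@dataclass
class DecoderFeatures:
    """Decoder outputs: M_D keyed 1..4, N_D keyed 2..4 (empty if one branch)."""

    m: dict[int, Tensor]
    n: dict[int, Tensor]

    def ordered(self) -> list[tuple[str, int, Tensor]]:
        """Fixed head order: M_D[1..4] then N_D[2..4]."""
        out = [("M", i, self.m[i]) for i in sorted(self.m)]
        out += [("N", j, self.n[j]) for j in sorted(self.n)]
        return out


def _check_spatial(a: Tensor, b: Tensor, who: str):
    if a.shape[-2:] != b.shape[-2:]:
        raise ValueError(f"{who}: spatial mismatch {a.shape[-2:]} vs {b.shape[-2:]}")


class AttentionGate(Module):
    """Additive attention gate: deep gating feature suppresses background in
    a shallow local feature. Coefficients are in [0, 1] (sigmoid output)."""

    def __init__(self, gate_ch: int, local_ch: int, inter_ch: int,
                 rng: np.random.Generator):
        super().__init__()
        self.wg = Conv2d(gate_ch, inter_ch, 1, rng)
        self.wx = Conv2d(local_ch, inter_ch, 1, rng)
        self.psi = Conv2d(inter_ch, 1, 1, rng)
        self.last_alpha: Optional[np.ndarray] = None

    def forward(self, gating: Tensor, local: Tensor,
                alpha_override=None) -> Tensor:
        _check_spatial(gating, local, "attention_gate")
        if alpha_override is not None:
            alpha = as_tensor(alpha_override)
        else:
            alpha = self.psi((self.wg(gating) + self.wx(local)).relu()).sigmoid()
        self.last_alpha = alpha.data
        return local * alpha


class FeatureFusion(Module):
    """Concat n equal-channel inputs, then two 3x3 convs back to c channels."""

    def __init__(self, channels: int, n_inputs: int, rng: np.random.Generator):
        super().__init__()
        self.channels = channels
        self.n_inputs = n_inputs
        self.block = Sequential(
            ConvBNReLU(channels * n_inputs, channels, 3, rng),
            ConvBNReLU(channels, channels, 3, rng),
        )

    def forward(self, features: list[Tensor]) -> Tensor:
        if len(features) != self.n_inputs:
            raise ValueError(f"feature_fusion expects {self.n_inputs} inputs, "
                             f"got {len(features)}")
        for f in features[1:]:
            _check_spatial(features[0], f, "feature_fusion")
            if f.shape[1] != features[0].shape[1]:
                raise ValueError("feature_fusion inputs must share channel count")
        return self.block(concat(features, axis=1))


class AttentionFeatureSelection(Module):
    """Complementary (decoder-side) feature gates the same-scale encoder skip.

    alpha = sigmoid(1x1 conv(complementary)) in [0, 1]; the gated encoder
    feature is projected to the stage width if its channel count differs and
    the pair is combined by feature fusion. Output carries the stage's
    configured channel count at the inputs' spatial side.
    """

    def __init__(self, comp_ch: int, enc_ch: int, rng: np.random.Generator):
        super().__init__()
        self.att = Conv2d(comp_ch, 1, 1, rng)
        self.proj = Conv2d(enc_ch, comp_ch, 1, rng) if enc_ch != comp_ch else None
        self.fuse = FeatureFusion(comp_ch, 2, rng)
        self.last_alpha: Optional[np.ndarray] = None

    def forward(self, complementary: Tensor, encoder_feature: Tensor,
                alpha_override=None) -> Tensor:
        _check_spatial(complementary, encoder_feature, "attention_feature_selection")
        if alpha_override is not None:
            alpha = as_tensor(alpha_override)
        else:
            alpha = self.att(complementary).sigmoid()
        self.last_alpha = alpha.data
        gated = encoder_feature * alpha
        if self.proj is not None:
            gated = self.proj(gated)
        return self.fuse([complementary, gated])


class Upsample(Module):
    """Bilinear 2x upsampling; a 1x1 conv only when channels change."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        self.proj = Conv2d(in_ch, out_ch, 1, rng) if in_ch != out_ch else None

    def forward(self, x: Tensor) -> Tensor:
        y = upsample2x(x)
        return self.proj(y) if self.proj is not None else y


class MMADecoder(Module):
    """Dual-branch mutual-assistance decoder producing the seven outputs."""

    def __init__(self, cfg: NetConfig, rng: np.random.Generator):
        super().__init__()
        c = cfg.channels
        self.ag = AttentionGate(c[4], c[4], max(1, c[4] // 2), rng)
        self.fuse_bottleneck = FeatureFusion(c[4], 2, rng)
        self.up_bottleneck = Upsample(c[4], c[3], rng)
        # stage 4: complementary Up(B) with c[3] channels; N_E[4] has c[2]
        self.a_m4 = AttentionFeatureSelection(c[3], c[3], rng)
        self.a_n4 = AttentionFeatureSelection(c[3], c[2], rng)
        # stage 3
        self.fuse4 = FeatureFusion(c[3], 2, rng)
        self.up4 = Upsample(c[3], c[2], rng)
        self.a_m3 = AttentionFeatureSelection(c[2], c[2], rng)
        self.a_n3 = AttentionFeatureSelection(c[2], c[1], rng)
        # stage 2
        self.fuse3 = FeatureFusion(c[2], 2, rng)
        self.up3 = Upsample(c[2], c[1], rng)
        self.a_m2 = AttentionFeatureSelection(c[1], c[1], rng)
        self.a_n2 = AttentionFeatureSelection(c[1], c[0], rng)
        # stage 1 (branch 1 only)
        self.fuse2 = FeatureFusion(c[1], 2, rng)
        self.up2 = Upsample(c[1], c[0], rng)
        self.a_m1 = AttentionFeatureSelection(c[0], c[0], rng)

    def forward(self, bf: BranchFeatures) -> DecoderFeatures:
        if bf.n is None:
            raise ValueError("MMADecoder needs dual-branch features (N_E missing)")
        for idx in (1, 2, 3, 4, 5):
            if idx not in bf.m:
                raise ValueError(f"missing encoder feature M_E[{idx}]")
        for idx in (2, 3, 4, 5, 6):
            if idx not in bf.n:
                raise ValueError(f"missing encoder feature N_E[{idx}]")
        u6 = upsample2x(bf.n[6])                         # side s/16, c[4]
        gated = self.ag(u6, bf.m[5])
        bottleneck = self.fuse_bottleneck([u6, gated])   # B, computed once
        cb = self.up_bottleneck(bottleneck)              # Up(B): side s/8, c[3]
        m4 = self.a_m4(cb, bf.m[4])
        n4 = self.a_n4(cb, bf.n[4])
        c3 = self.up4(self.fuse4([m4, n4]))              # side s/4, c[2]
        m3 = self.a_m3(c3, bf.m[3])
        n3 = self.a_n3(c3, bf.n[3])
        c2 = self.up3(self.fuse3([m3, n3]))              # side s/2, c[1]
        m2 = self.a_m2(c2, bf.m[2])
        n2 = self.a_n2(c2, bf.n[2])
        c1 = self.up2(self.fuse2([m2, n2]))              # side s, c[0]
        m1 = self.a_m1(c1, bf.m[1])
        return DecoderFeatures(m={1: m1, 2: m2, 3: m3, 4: m4},
                               n={2: n2, 3: n3, 4: n4})

    def attention_maps(self) -> dict[str, np.ndarray]:
        maps = {}
        for name, mod in self._modules.items():
            if isinstance(mod, (AttentionGate, AttentionFeatureSelection)) \
                    and mod.last_alpha is not None:
                maps[name] = mod.last_alpha
        return maps


class SingleBranchDecoder(Module):
    """Skip-connection decoder for the single-branch ablation (Num = 1):
    each stage applies A(Up(previous), M_E[i]); no AG, no cross-branch F."""

    def __init__(self, cfg: NetConfig, rng: np.random.Generator):
        super().__init__()
        c = cfg.channels
        self.up5 = Upsample(c[4], c[3], rng)
        self.a4 = AttentionFeatureSelection(c[3], c[3], rng)
        self.up4 = Upsample(c[3], c[2], rng)
        self.a3 = AttentionFeatureSelection(c[2], c[2], rng)
        self.up3 = Upsample(c[2], c[1], rng)
        self.a2 = AttentionFeatureSelection(c[1], c[1], rng)
        self.up2 = Upsample(c[1], c[0], rng)
        self.a1 = AttentionFeatureSelection(c[0], c[0], rng)

    def forward(self, bf: BranchFeatures) -> DecoderFeatures:
        for idx in (1, 2, 3, 4, 5):
            if idx not in bf.m:
                raise ValueError(f"missing encoder feature M_E[{idx}]")
        d4 = self.a4(self.up5(bf.m[5]), bf.m[4])
        d3 = self.a3(self.up4(d4), bf.m[3])
        d2 = self.a2(self.up3(d3), bf.m[2])
        d1 = self.a1(self.up2(d2), bf.m[1])
        return DecoderFeatures(m={1: d1, 2: d2, 3: d3, 4: d4}, n={})

    def attention_maps(self) -> dict[str, np.ndarray]:
        return {name: mod.last_alpha
                for name, mod in self._modules.items()
                if isinstance(mod, AttentionFeatureSelection)
                and mod.last_alpha is not None}
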