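"""Multilabel deep supervision: prediction heads, label pyramids, BCE+Dice.

Each of the seven decoder outputs gets its own 1x1-conv head with C sigmoid
channels (one-vs-rest per foreground tissue; C=1 is the pure binary case).
Under multilabel deep supervision (MLDS) every head is compared against the
ground-truth mask downsampled (nearest neighbor, so targets stay binary) to
that head's own resolution. Under classic deep supervision (DS, the ablation
mode) every head is first bilinearly upsampled to full resolution and
compared against the full-resolution label only.

Per head the objective is L = L_BCE + L_Dice with

    L_BCE  = -mean[ G log Q + (1 - G) log(1 - Q) ]          (Q clamped)
    L_Dice = mean_c[ 1 - (2 sum GQ + eps_s) / (sum G + sum Q + eps_s) ]

and the total loss is the unweighted sum over heads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor, upsample2x
from .layers import Conv2d, Module
from .mma import DecoderFeatures

__all__ = ["HeadOutput", "PredictionPyramid", "LabelPyramid", "PredictionHeads",
           "one_hot", "nearest_downsample", "build_label_pyramid",
           "bce_loss", "dice_loss", "total_loss",
           "EPS_PROB", "EPS_SMOOTH"]

EPS_PROB = 1e-7     # probability clamp inside BCE
EPS_SMOOTH = 1.0    # Dice smoothing (empty target and prediction -> loss 0)


@dataclass
class HeadOutput:
    branch: str      # "M" or "N"
    stage: int
    side: int
    q: Tensor        # (N, C, side, side) probabilities in [0, 1]


@dataclass
class PredictionPyramid:
    heads: list[HeadOutput]

    @property
    def sides(self) -> list[int]:
        return [h.side for h in self.heads]

    def final(self) -> HeadOutput:
        """The full-resolution M_D[1] head — the network's segmentation output."""
        return self.heads[0]


@dataclass
class LabelPyramid:
    targets: list[np.ndarray]   # aligned with PredictionPyramid.heads
    sides: list[int]


class PredictionHeads(Module):
    """One 1x1 conv + sigmoid per decoder output; no resizing."""

    def __init__(self, stage_channels: dict[tuple[str, int], int], num_classes: int,
                 rng: np.random.Generator):
        super().__init__()
        self.num_classes = num_classes
        self.order = sorted(stage_channels, key=lambda k: (k[0], k[1]))
        for branch, stage in self.order:
            setattr(self, f"head_{branch}{stage}",
                    Conv2d(stage_channels[(branch, stage)], num_classes, 1, rng))

    def forward(self, decoder: DecoderFeatures) -> PredictionPyramid:
        heads = []
        for branch, stage, feat in decoder.ordered():
            conv = getattr(self, f"head_{branch}{stage}")
            q = conv(feat).sigmoid()
            heads.append(HeadOutput(branch, stage, feat.shape[-1], q))
        return PredictionPyramid(heads)


# ---------------------------------------------------------------------------
# Label pyramid
# ---------------------------------------------------------------------------

def one_hot(mask: np.ndarray, num_classes: int) -> np.ndarray:
    """(..., H, W) int mask -> (..., C, H, W) float one-hot over classes 1..C."""
    mask = np.asarray(mask)
    if mask.max(initial=0) > num_classes:
        raise ValueError(
            f"mask contains class id {int(mask.max())} > num_classes {num_classes}")
    chans = [(mask == c).astype(np.float64) for c in range(1, num_classes + 1)]
    return np.stack(chans, axis=-3)


def nearest_downsample(arr: np.ndarray, side: int) -> np.ndarray:
    """Nearest-neighbor downsample of the last two axes to side x side,
    sampling at row/col indices i * (H // side) (top-left convention)."""
    h, w = arr.shape[-2:]
    if h % side or w % side:
        raise ValueError(f"side {side} does not divide grid {h}x{w}")
    ri = np.arange(side) * (h // side)
    ci = np.arange(side) * (w // side)
    return arr[..., ri[:, None], ci[None, :]]


def build_label_pyramid(mask: np.ndarray, num_classes: int,
                        sides: list[int]) -> LabelPyramid:
    """One-hot the mask, then nearest-neighbor downsample to each head side.

    The full-resolution member equals the one-hot mask exactly; all members
    stay binary.
    """
    oh = one_hot(mask, num_classes)
    full = oh.shape[-1]
    targets = [oh if s == full else nearest_downsample(oh, s) for s in sides]
    return LabelPyramid(targets=targets, sides=list(sides))


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def bce_loss(q, g, eps: float = EPS_PROB) -> Tensor:
    """Binary cross-entropy, mean over all elements; q clamped to
    [eps, 1-eps]."""
    q = as_tensor(q)
    g = np.asarray(g.data if isinstance(g, Tensor) else g)
    if q.shape != g.shape:
        raise ValueError(f"bce_loss: shape mismatch {q.shape} vs {g.shape}")
    qc = q.clamp(eps, 1.0 - eps)
    ll = Tensor(g) * qc.log() + Tensor(1.0 - g) * (1.0 - qc).log()
    return -ll.mean()


def dice_loss(q, g, eps_smooth: float = EPS_SMOOTH) -> Tensor:
    """Soft Dice loss, per channel then averaged.

    For (N, C, H, W) input the sums run over each sample's spatial grid; for
    (C, H, W) over each channel's grid. The smoothing constant makes an
    empty target with an empty prediction a perfect (zero-loss) pair.
    """
    q = as_tensor(q)
    g = np.asarray(g.data if isinstance(g, Tensor) else g)
    if q.shape != g.shape:
        raise ValueError(f"dice_loss: shape mismatch {q.shape} vs {g.shape}")
    axes = (-2, -1)
    inter = (q * Tensor(g)).sum(axis=axes)
    denom = q.sum(axis=axes) + Tensor(g.sum(axis=axes))
    dice = (2.0 * inter + eps_smooth) / (denom + eps_smooth)
    return (1.0 - dice).mean()


def _upsample_to(q: Tensor, target_side: int) -> Tensor:
    while q.shape[-1] < target_side:
        q = upsample2x(q)
    if q.shape[-1] != target_side:
        raise ValueError(f"cannot upsample side {q.shape[-1]} to {target_side}")
    return q


def total_loss(preds: PredictionPyramid, labels: LabelPyramid,
               mode: str = "MLDS", eps: float = EPS_PROB,
               eps_smooth: float = EPS_SMOOTH) -> Tensor:
    """Sum of per-head BCE+Dice.

    MLDS: each head against its own-scale target. DS: each head upsampled to
    full resolution, against the full-resolution target only.
    """
    if mode not in ("MLDS", "DS"):
        raise ValueError(f"unknown supervision mode {mode!r}")
    if len(preds.heads) != len(labels.targets):
        raise ValueError(
            f"pyramid mismatch: {len(preds.heads)} heads vs "
            f"{len(labels.targets)} targets")
    full_side = max(labels.sides)
    full_target = labels.targets[labels.sides.index(full_side)]
    total = None
    for head, target, side in zip(preds.heads, labels.targets, labels.sides):
        if head.side != side:
            raise ValueError(
                f"head {head.branch}{head.stage} side {head.side} does not match "
                f"label side {side}")
        if mode == "MLDS":
            q, g = head.q, target
        else:
            q, g = _upsample_to(head.q, full_side), full_target
        term = bce_loss(q, g, eps) + dice_loss(q, g, eps_smooth)
        total = term if total is None else total + term
    return total
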