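"""Training loop, inference, cross-validation driver, and ablation runner.

Default optimization settings target full-scale training: Adam with
beta1 = 0.9, learning rate 5e-4, weight decay 1e-4, batch size 32, up to
1000 epochs with early stopping after 20 evaluations without improvement of
the monitored metric (validation mean foreground dice). Desk-scale runs
shrink the batch and epoch counts through the same config. Everything is a
deterministic function of the seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .autodiff import Tensor
from .encoders import NetConfig
from .layers import Adam
from .losses import build_label_pyramid, total_loss
from .metrics import MetricsReport, dice_score, evaluate_cases
from .network import MMANet, head_sides
from .preprocess import AugmentConfig, CaseVolume, FoldAssignment, augment, \
    make_half_resolution, prepare_case
from .synthetic import SliceSample

__all__ = ["TrainConfig", "TrainHistory", "train", "predict_samples",
           "predict_volume", "cross_validate", "ablate",
           "save_checkpoint", "load_checkpoint"]


@dataclass
class TrainConfig:
    learning_rate: float = 5e-4
    batch_size: int = 32
    adam_beta1: float = 0.9
    weight_decay: float = 1e-4
    max_epochs: int = 1000
    early_stop_patience: int = 20
    seed: int = 0
    eval_every: int = 1                      # epochs between validation passes
    max_steps: Optional[int] = None          # hard cap on optimizer steps
    target_metric: Optional[float] = None    # stop once val dice reaches this
    augment: Optional[AugmentConfig] = None  # None = no augmentation

    def validate(self):
        if min(self.learning_rate, self.batch_size, self.max_epochs) <= 0:
            raise ValueError("learning_rate, batch_size, max_epochs must be positive")
        if self.early_stop_patience <= 0 or self.early_stop_patience >= self.max_epochs:
            raise ValueError("early_stop_patience must be in (0, max_epochs)")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)      # per epoch
    val_dice: list[float] = field(default_factory=list)        # per evaluation
    val_epochs: list[int] = field(default_factory=list)        # epoch of each eval
    best_epoch: int = -1
    best_metric: float = -np.inf
    stopped_early: bool = False
    steps: int = 0


def _stack_batch(samples: Sequence[SliceSample]):
    imgs = np.stack([s.image for s in samples]).astype(np.float32)[:, None]
    masks = np.stack([s.mask for s in samples])
    return imgs, masks


def _forward(model: MMANet, imgs: np.ndarray):
    half = None
    if model.cfg.num_branches == 2:
        half = make_half_resolution(imgs).astype(np.float32)
    return model(imgs, half)


def _mean_foreground_dice(model: MMANet, samples: Sequence[SliceSample],
                          batch_size: int) -> float:
    preds = predict_samples(model, samples, batch_size=batch_size)
    gts = np.stack([s.mask for s in samples])
    return float(np.mean([
        dice_score((preds == c).astype(int), (gts == c).astype(int))
        for c in range(1, model.cfg.num_classes + 1)
    ]))


def train(net_cfg: NetConfig, train_samples: Sequence[SliceSample],
          val_samples: Sequence[SliceSample], cfg: TrainConfig):
    """Train a network; returns (model-with-best-weights, TrainHistory).

    Validation cases must be disjoint from training cases. The monitored
    metric is validation mean foreground dice; the returned model carries
    the best-epoch parameters.
    """
    cfg.validate()
    net_cfg.validate()
    if not train_samples:
        raise ValueError("empty training set")
    train_cases = {s.case_id for s in train_samples}
    val_cases = {s.case_id for s in val_samples}
    if val_cases and val_cases != train_cases and train_cases & val_cases:
        raise ValueError(
            f"case leakage between train and val: {sorted(train_cases & val_cases)}")

    model = MMANet(net_cfg, seed=cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.learning_rate, beta1=cfg.adam_beta1,
               weight_decay=cfg.weight_decay)
    sides = head_sides(net_cfg)
    history = TrainHistory()
    best_state = model.state_dict()
    patience_left = cfg.early_stop_patience
    n = len(train_samples)
    stop = False

    for epoch in range(1, cfg.max_epochs + 1):
        model.train()
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, epoch]))
        order = rng.permutation(n)
        epoch_losses = []
        for b0 in range(0, n, cfg.batch_size):
            batch = [train_samples[i] for i in order[b0:b0 + cfg.batch_size]]
            if cfg.augment is not None:
                batch = [augment(s, cfg.augment,
                                 seed=int(rng.integers(2 ** 31)))
                         for s in batch]
            imgs, masks = _stack_batch(batch)
            preds = _forward(model, imgs)
            labels = build_label_pyramid(masks, net_cfg.num_classes, sides)
            # keep the loss graph in the network dtype (float32)
            labels.targets = [t.astype(np.float32) for t in labels.targets]
            loss = total_loss(preds, labels, mode=net_cfg.supervision_mode)
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} step {history.steps}: "
                    f"loss={loss.item()}, batch intensity range "
                    f"[{imgs.min():.3g}, {imgs.max():.3g}], "
                    f"mask classes {sorted(np.unique(masks).tolist())}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(loss.item())
            history.steps += 1
            if cfg.max_steps is not None and history.steps >= cfg.max_steps:
                stop = True
                break
        history.train_loss.append(float(np.mean(epoch_losses)))

        if val_samples and (epoch % cfg.eval_every == 0 or stop
                            or epoch == cfg.max_epochs):
            metric = _mean_foreground_dice(model, val_samples, cfg.batch_size)
            history.val_dice.append(metric)
            history.val_epochs.append(epoch)
            if metric > history.best_metric:
                history.best_metric = metric
                history.best_epoch = epoch
                best_state = model.state_dict()
                patience_left = cfg.early_stop_patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    history.stopped_early = True
                    stop = True
            if cfg.target_metric is not None and metric >= cfg.target_metric:
                stop = True
        if stop:
            break

    if history.best_epoch >= 0:
        model.load_state_dict(best_state)
    model.eval()
    return model, history


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

def assemble_mask(probs: np.ndarray, num_classes: int) -> np.ndarray:
    """Turn (N, C, H, W) one-vs-rest probabilities into an integer mask.

    A pixel is background when every foreground probability is below 0.5;
    otherwise it takes the argmax foreground class (1-based).
    """
    fg = probs.max(axis=1)
    cls = probs.argmax(axis=1) + 1
    return np.where(fg >= 0.5, cls, 0).astype(np.int64)


def predict_samples(model: MMANet, samples: Sequence[SliceSample],
                    batch_size: int = 8) -> np.ndarray:
    """Predict integer masks from the final (M_D[1]) head only."""
    model.eval()
    out = []
    for b0 in range(0, len(samples), batch_size):
        imgs = np.stack([s.image for s in samples[b0:b0 + batch_size]]
                        ).astype(np.float32)[:, None]
        pyramid = _forward(model, imgs)
        out.append(assemble_mask(pyramid.final().q.data, model.cfg.num_classes))
    return np.concatenate(out, axis=0)


def predict_volume(model: MMANet, volume: CaseVolume):
    """Preprocess a case and predict each slice.

    Returns (mask stack in the cropped frame, (row_offset, col_offset)) where
    the offsets map the cropped frame back into the original grid (negative
    values indicate padding was added).
    """
    side = model.cfg.input_side
    if side % 32 != 0:
        raise ValueError(f"input side {side} not divisible by 32")
    samples = prepare_case(volume, side)
    masks = predict_samples(model, samples)
    h, w = volume.voxels.shape[-2:]
    offsets = ((max(h, side) - side) // 2 - max(0, (side - h) // 2),
               (max(w, side) - side) // 2 - max(0, (side - w) // 2))
    return masks, offsets


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, model: MMANet, history: TrainHistory | None = None):
    meta = {"net_config": asdict(model.cfg),
            "head_order": [f"{b}{i}" for b, i in model.heads.order]}
    if history is not None:
        meta["best_epoch"] = history.best_epoch
        meta["best_metric"] = history.best_metric
    arrays = {k.replace(".", "/"): v for k, v in model.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> MMANet:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        nc = meta["net_config"]
        nc["stage_channels"] = tuple(nc["stage_channels"])
        cfg = NetConfig(**nc)
        model = MMANet(cfg, seed=0)
        state = {k.replace("/", "."): data[k] for k in data.files
                 if k != "__meta__"}
    model.load_state_dict(state)
    model.eval()
    return model


# ---------------------------------------------------------------------------
# Cross-validation and ablation
# ---------------------------------------------------------------------------

def _group_by_case(samples: Sequence[SliceSample]) -> dict[str, list[SliceSample]]:
    by_case: dict[str, list[SliceSample]] = {}
    for s in samples:
        by_case.setdefault(s.case_id, []).append(s)
    return by_case

# fraction of each fold's training cases carved out (seeded) as the
# early-stopping monitor set, never overlapping the held-out test fold
INNER_VAL_FRACTION = 0.2


def cross_validate(samples: Sequence[SliceSample], folds: FoldAssignment,
                   net_cfg: NetConfig, train_cfg: TrainConfig):
    """Train one model per fold and evaluate on its held-out cases.

    Returns (MetricsReport aggregated over folds, per-fold histories).
    """
    by_case = _group_by_case(samples)
    unknown = set(by_case) ^ set(folds.assignment)
    if unknown:
        raise ValueError(f"fold/case mismatch for: {sorted(unknown)}")
    predictions: dict[str, np.ndarray] = {}
    ground_truths: dict[str, np.ndarray] = {}
    histories = []
    for fold in range(folds.k):
        test_cases = folds.fold_cases(fold)
        pool = folds.train_cases(fold)
        assert not set(test_cases) & set(pool), "case leakage across fold boundary"
        rng = np.random.default_rng(np.random.SeedSequence([train_cfg.seed, fold]))
        n_val = max(1, int(round(INNER_VAL_FRACTION * len(pool))))
        val_cases = set(np.array(sorted(pool))[rng.permutation(len(pool))[:n_val]])
        train_set = [s for c in pool if c not in val_cases for s in by_case[c]]
        val_set = [s for c in sorted(val_cases) for s in by_case[c]]
        model, hist = train(net_cfg, train_set, val_set, train_cfg)
        histories.append(hist)
        for case in test_cases:
            case_samples = sorted(by_case[case], key=lambda s: s.slice_index)
            predictions[case] = predict_samples(model, case_samples,
                                                train_cfg.batch_size)
            ground_truths[case] = np.stack([s.mask for s in case_samples])
    report = evaluate_cases(predictions, ground_truths,
                            class_ids=list(range(1, net_cfg.num_classes + 1)),
                            folds=folds.assignment)
    return report, histories


ABLATION_MODES = {
    "num1_ds": dict(num_branches=1, supervision_mode="DS"),
    "num1_mlds": dict(num_branches=1, supervision_mode="MLDS"),
    "num2_ds": dict(num_branches=2, supervision_mode="DS"),
    "num2_mlds": dict(num_branches=2, supervision_mode="MLDS"),
}


def ablate(samples: Sequence[SliceSample], folds: FoldAssignment,
           modes: Sequence[str], net_cfg: NetConfig, train_cfg: TrainConfig):
    """Run cross_validate per ablation mode with shared folds and seeds.

    Returns a tidy table: one row per mode with class-mean metrics, so the
    only varied factors are branch count and supervision mode.
    """
    import pandas as pd

    rows = []
    for mode in modes:
        if mode not in ABLATION_MODES:
            raise ValueError(f"unknown ablation mode {mode!r}; "
                             f"choose from {sorted(ABLATION_MODES)}")
        overrides = ABLATION_MODES[mode]
        cfg = NetConfig(**{**asdict(net_cfg), **overrides})
        report, _ = cross_validate(samples, folds, cfg, train_cfg)
        means = report.summary.mean()
        rows.append({"mode": mode, **overrides, **means.to_dict()})
    return pd.DataFrame(rows)
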