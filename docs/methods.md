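# Methods

## Problem and model

`mmanet` segments 2D short-axis cardiac MR slices: right ventricle (RV),
myocardium (Myo) and left ventricle (LV) in ACDC-style data, or a single
left-atrium (LA) class in ASC-style data. Cardiac MR is hard to segment
because coil inhomogeneity warps the intensity distribution and partial
voluming blurs tissue boundaries; the network attacks both with a
multiresolution design.

The architecture is a dual-branch encoder–decoder. Branch 1 encodes the
full-resolution image (224×224 nominally; any side divisible by 32) and
branch 2 independently encodes the same image downsampled 2× (112×112), so
branch 1 specializes in local detail and branch 2 in global context without
either competing for the other's receptive field. Each branch is a VGG19
convolutional body — five stages with (2, 2, 4, 4, 4) 3×3 convolutions and
nominal widths (64, 128, 256, 512, 512), BN+ReLU after every convolution,
2× max pooling between stages — adapted to a 1-channel input. Branch-1
stages emit features M_E[1..5]; branch-2 stages are indexed 2..6 so equal
index means equal spatial side.

The decoder makes the branches assist each other:

```
B      = F( Up(N_E[6]), AG(Up(N_E[6]), M_E[5]) )          bottleneck, side s/16
M_D[4] = A( Up(B), M_E[4] )        N_D[4] = A( Up(B), N_E[4] )
C_i    = Up( F( M_D[i+1], N_D[i+1] ) )                    i = 3, 2
M_D[i] = A( C_i, M_E[i] )          N_D[i] = A( C_i, N_E[i] )
M_D[1] = A( Up( F( M_D[2], N_D[2] ) ), M_E[1] )
```

AG is an additive attention gate (Attention-U-Net lineage): both inputs are
1×1-projected to an intermediate width, summed, ReLU'd, reduced to one
channel and squashed by a sigmoid; the resulting coefficient map α ∈ [0,1]
multiplies the local feature. A (attention feature selection) derives α
from the complementary decoder-side feature alone (1×1 conv + sigmoid),
gates the same-scale encoder skip feature with it, and combines the pair by
F. F (feature fusion) concatenates equal-width inputs along channels and
projects back to a single input's width with two 3×3 conv+BN+ReLU layers.
Up is factor-2 bilinear interpolation, followed by a 1×1 convolution only
when the channel count changes. The bottleneck B and each complementary
feature C_i are computed once and shared by the two branches.

Seven heads (1×1 conv + sigmoid, C channels) sit on M_D[1..4] and N_D[2..4].
M_D[1] is the final output. Under multilabel deep supervision (MLDS) each
head is trained against the ground-truth mask one-hot-encoded and
nearest-neighbor-downsampled to that head's own resolution — downsampling
the label instead of upsampling the prediction keeps every target crisp and
binary. The classic deep-supervision (DS) ablation mode instead upsamples
every head to full resolution and compares against the full-resolution
label. Per head the loss is BCE + soft Dice; the total is the unweighted
sum over heads.

## Numerical and design choices

* **Tensor engine.** The package carries its own reverse-mode autodiff
  engine on numpy (`autodiff.py`): broadcasted arithmetic, reductions,
  im2col convolution, 2×2 max pooling, separable bilinear 2× upsampling,
  and batch normalization. Every primitive is validated against central
  finite differences in float64 (`tests/test_autodiff.py`). Networks run in
  float32; the engine preserves the caller's dtype so the loss oracles can
  be checked at float64 precision.
* **Losses.** BCE is the standard negated log-likelihood with mean
  reduction over pixels and channels (batch-size-independent scale) and a
  probability clamp ε_p = 1e-7. Dice is computed per channel and averaged,
  with smoothing ε_s = 1.0 so an empty target with an empty prediction
  scores zero loss. One-vs-rest sigmoid channels handle the multi-class
  case (C=3), matching per-tissue evaluation; C=1 is the pure binary task.
* **Attention internals.** The coefficient maps are single-channel and
  broadcast over feature channels; A projects the gated encoder feature
  with a 1×1 convolution when branch-2 skip widths differ from the stage
  width. Both blocks accept a forced-coefficient override used by the test
  suite to verify the gating contract (α=1 reduces A to
  concatenate-then-project; gated amplitude is monotone in α).
* **Metrics.** dice, specificity, sensitivity and F1 from exact pixel
  confusion counts; dice uses the |A|+|B| denominator, which makes dice ≡
  F1 on hard masks. Degenerate denominators (tissue absent from both
  masks) score 1 with a warning so per-case means stay defined. Evaluation
  pools a case's slices into one volume before computing that case's
  metrics, then averages over cases and folds; per-slice pooling is
  available as an option.
* **Preprocessing.** Fixed order: center crop (undersized axes are
  symmetrically zero-padded first) → max-min normalization over the whole
  case → augmentation (training only; translate ≤10 px, scale 0.9–1.1,
  rotate ±15°, image bilinear, mask nearest-neighbor) → half-resolution
  derivation by 2×2 block averaging from the final full-resolution image.
  A constant-intensity case normalizes to all zeros. Cross-validation
  splits at case level with balanced fold sizes; within each fold a seeded
  20% of training cases is carved out as the early-stopping monitor set,
  never touching the held-out fold.
* **Optimization.** Adam with β1 = 0.9 (playing the role of momentum),
  β2 = 0.999, L2 weight decay 1e-4, batch size 32, learning rate 5e-4, up
  to 1000 epochs, early stopping after 20 evaluations without improvement
  of validation mean foreground dice — these are the library defaults and
  reflect full-scale training. No learning-rate schedule. Training is a
  deterministic function of the seed (pure-numpy compute, seeded batch
  order and augmentation draws).
* **Inference.** Only the M_D[1] head is used. C=1: threshold at 0.5.
  C>1: a pixel is background when every foreground probability is below
  0.5, otherwise it takes the argmax foreground class.

## Synthetic phantoms

The phantom generator emulates what short-axis cardiac MR looks like to a
segmentation network, not cardiac physiology: a bright LV disk, a darker
Myo annulus strictly surrounding it, an RV crescent (annular sector)
abutting the ring — or a single elliptical LA blob in `asc_like` mode.
Masks are rasterized first; the image then renders per-tissue base
intensities and is degraded by a smooth multiplicative bias field (2–3
broad Gaussians normalized to 1 ± bias amplitude, default 0.2), Gaussian
boundary blur (σ = 1 px), additive Gaussian noise (σ = 0.03) and clipping
to [0, 1]. Labels are never blurred. Cases share a geometry draw; slices
within a case jitter the center by ≤1.5 px and radii by ≤10%, so case-level
fold splitting is meaningful. Everything is a pure function of (spec,
seed).

What the phantoms do not model: real anatomical shape variation,
pathology, through-plane geometry changes, Rician noise statistics, k-space
artifacts, or neighboring organs. Passing the phantom experiments shows the
architecture, losses, and pipeline are implemented correctly and can fit
and generalize over this controlled family — it says nothing quantitative
about performance on clinical ACDC/ASC data, which require challenge
registration and GPU-scale training.

## Desk-scale experiment protocol

The self-contained experiments run a slim configuration on 64-px phantoms:
width multiplier 1/8 (stage widths 8, 16, 32, 64, 64), batch size 8, and
learning rate 2e-3. The raised learning rate is the desk-scale counterpart
of the full protocol's 5e-4: with a 1/8-width network, a tiny batch, and a
budget of a few hundred optimizer steps from random initialization, the
full-scale rate underfits simply for lack of steps, and 2e-3 trains
stably across seeds at this scale. Problem sizes: memorization uses 8
slices (2 cases) and at most 200 steps; the generalization experiment
trains on 80 slices from 20 cases and evaluates 20 slices from 5 unseen
cases within 30 epochs; the ablation driver exercises all four
(branches × supervision) modes on 32-px micro phantoms with 2-fold CV. The
micro scale (side 32, width 1/16) exists purely to exercise machinery, not
to measure accuracy.

## Known limitations

* CPU-only and desk-scale: the engine favors clarity and testability over
  throughput; full-resolution (224 px, full-width) training is supported
  but slow.
* Stride-1 'same' convolutions and factor-2 resampling only — sufficient
  for this architecture family, not a general conv library.
* BN uses per-batch statistics with running-average inference; very small
  batches make the running estimates noisy early in training.
* Two conventions in the objective and metrics are sometimes written
  ambiguously in the literature; this package fixes them as: BCE in its
  standard negated (non-negative) form, and dice with the |A|+|B|
  denominator — the convention under which dice ≡ F1 on hard masks.
* NIfTI ingestion assumes the slice axis is last and does not resample to
  a common pixel spacing; DICOM is out of scope.
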