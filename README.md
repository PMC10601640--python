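# renderseg

Point-based rendering segmentation of low-contrast lesions in 2-D medical
image slices — a hybrid transformer/convolution encoder paired with an
uncertainty-driven point-rendering decoder, implemented as a pure
numpy/scipy library with its own reverse-mode autodiff core.

## The problem

Ischemic stroke lesions in brain MRI appear at arbitrary locations, with
extremely irregular shapes, and at intensities barely distinguishable from
healthy tissue.  Decoders that upsample uniformly over the pixel grid blur
exactly the high-frequency information that defines the lesion boundary.
This package implements the alternative: treat mask upsampling as a
*rendering* problem and spend computation only on the pixels the model is
unsure about, which concentrate along the boundary.

It is aimed at researchers who want a fully inspectable, CPU-only,
dependency-light implementation of the approach whose every computation is
testable against closed-form oracles, plus a synthetic data generator that
reproduces the statistical difficulty of the task (low lesion/background
contrast, irregular shapes, multiple embolic foci) without any dataset
download.

## The method

**Encoder.** An image `X ∈ R^{H×W×C}` is split into patches, projected to
`D` dimensions with a learned embedding plus positional term
(`z0 = [x_p1 E; …; x_pN E] + E_pos`), and passed through pre-norm
transformer stages, `t' = MSA(LN(t)) + t`, `t = MLP(LN(t')) + t'`, with
plain multi-head self-attention `softmax(QKᵀ/√d)·V`.  Patch merging between
stages halves resolution and doubles channels, giving global features at
scales 1/4, 1/8, … .  A parallel convolutional branch of residual
Conv3×3–BN–PReLU blocks supplies local features at scales 1, 1/2, 1/4.

**Render decoder.** The deepest features produce a coarse probability map.
Each render level upsamples it 2× bilinearly, forms the uncertainty map
`M_u = |p − p_thd|` (default `p_thd = 0.5`), and selects `N` points: during
training, `k·N` random candidates are drawn and the `β·N` most uncertain
kept, the rest refilled at random (`k = 3`, `β = 0.7` by default); at
inference the `N` globally most uncertain pixels are taken.  For every
selected point the matching-scale transformer features, convolutional
features and coarse probability are bilinearly sampled, concatenated, and
re-predicted by a small two-layer pointwise mixer; the new values replace
the old ones, leaving every other pixel bit-identical.  The per-level maps
are merged by a channel-gated fusion `A(X_r) = σ(FC(GAP(X_r))) + X_r`
followed by a 1×1 projection and sigmoid.

**Objective.**  `L = L_dice(p, g) + λ Σ_levels L_bce` with λ = 0.7: a
smoothed Dice loss on the fused map plus binary cross-entropy computed only
at each level's selected points (deep point supervision).

**Metrics.** DSC `2TP/(2TP+FP+FN)`, symmetric Hausdorff distance in pixels
(optional HD95), F2, precision, recall, and red/blue/green
correct/under/over-segmentation overlays.

## Worked example

Point rendering in isolation (`python examples/02_point_rendering_demo.py`):
a blurred half-resolution mask is upsampled, the 256 most uncertain pixels
(the boundary band) are re-predicted with ground-truth values, and the Dice
score recovers from the interpolation blur:

```
DSC of bilinear upsample : 0.932
DSC after point rendering: 1.000
pixels re-predicted      : 256 selected, 256 changed (all other 3840 pixels untouched)
```

Training the reduced network on synthetic lesions
(`python examples/03_train_reduced_model.py`), 32 training and 8 validation
slices of 64×64 at contrast 0.3 and noise 0.1:

```
epoch     loss     dice  train DSC  val DSC
    0   2.1063   0.7371     0.4747   0.5390
    4   0.7481   0.4619     0.8715   0.8651
    7   0.4837   0.2776     0.9651   0.9705
    9   0.4213   0.2634     0.9603   0.9660
```

`loss` is the combined objective, `dice` its Dice component; the DSC
columns are thresholded scores of deterministic inference.  Other examples
cover the synthetic generator (`01`) and the metric panel plus NIfTI
slicing (`04`).

The same functionality is scriptable from a shell:

```bash
renderseg synth --seed 0 --n 32 --out data/
renderseg train --data data/ --out run/ --seed 0 --k 3 --beta 0.7
renderseg evaluate --checkpoint run/checkpoint.npz --data data/ --out scores/
renderseg render-debug --checkpoint run/checkpoint.npz --data data/ --out debug/
```

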