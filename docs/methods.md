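# Methods

This note documents the model, the synthetic data it is exercised on, the
numerical choices that make results reproducible, and the limits of what the
desk-scale experiments demonstrate.

## Network

The segmenter is an encoder–decoder in which the decoder refines a coarse
prediction *sparsely*, at its most uncertain pixels, instead of convolving
uniformly over the grid.

**Hybrid encoder.** Two branches consume the input slice:

* a hierarchical transformer branch: patch embedding (patch side `P`,
  learned projection and positional embedding added once), then `S` stages
  of pre-norm transformer layers (`t' = MSA(LN(t)) + t`,
  `t = MLP(LN(t')) + t'`, plain softmax attention scaled by `1/√d_k`),
  separated by patch merging (2×2 token concatenation + linear projection:
  resolution ÷2, channels ×2).  It emits "global" features at scales
  `P, 2P, 4P, …`;
* a convolutional branch of channel-preserving residual blocks
  `a = PReLU(BN(conv1(x)))`, `out = PReLU(BN(conv2(a + x))) + a + x`
  (3×3, stride 1), with 1×1 channel lifts and 2×2 mean-pooling between
  levels.  It emits "local" features at scales `1, 2, 4`.

Depths and widths are not architectural constants of the method; the
defaults (patch 4, three stages of two layers, base embedding 48 doubling
per merge, three heads, conv base 16) are Swin-style choices and every one
is a config field.  Weights are seeded truncated-normal; there is no
pretraining path, only an optional checkpoint-loading hook
(`Module.load_state_dict`).

**Render decoder.** The deepest transformer features give a coarse
probability map through a 1×1 projection and sigmoid.  One render level per
2× doubling then recovers full resolution (the level count is therefore
`log2` of the coarse downsampling factor — 4 with the default encoder, 3
with the reduced two-stage one).  Each level:

1. upsamples the running map 2× bilinearly;
2. computes the uncertainty map `M_u = |p − p_thd|`, `p_thd = 0.5`;
3. selects `N` points.  Training: `round(k·N)` candidate pixels drawn
   uniformly without replacement, the `round(β·N)` with smallest `M_u`
   kept, the remaining `(1−β)·N` filled with fresh uniform draws
   (deduplicated; bounded redraws, then lowest-index unused pixels — the
   count invariant `|points| = N` always holds).  Inference: the `N`
   globally smallest `M_u`, seed-free.  All orderings break ties by
   row-major pixel index, which makes selection bit-reproducible.
   `N = (h·w)/16` per level, capped at 8192: a resolution-relative budget
   so the point set scales with the boundary length it must cover;
4. bilinearly samples the nearest-scale global and local skip features and
   the coarse probability at each point's normalised position, concatenates
   them in that fixed order, and re-predicts the point with a two-layer
   pointwise perceptron (PReLU between the affine layers, sigmoid output);
5. scatters the re-predictions back; pixels outside the point set keep
   their interpolated values bit-exactly.

Defaults `k = 3` and `β = 0.7` follow the hyper-parameter comparison that
found them optimal; both are sweepable from the CLI.  The `(1−β)·N`
remainder is read as random *positions* (the plausible alternative —
random feature vectors at chosen positions — is not implemented).

**Fusion.** Per-level maps, upsampled to full resolution and stacked as
channels `X_r`, pass through `A(X_r) = σ(FC(GAP(X_r))) + X_r` — an
*additive* per-channel gate, implemented literally as printed; the
conventional multiplicative gate is available via `fusion_mode="mul"`.  A
1×1 projection and sigmoid collapse the channels to one probability map.
The FC is a single affine layer (no hidden bottleneck).

## Objective

`L = L_dice(p, g) + λ Σ_i L_bce,i` with `λ = 0.7` and

```
L_dice(p, g) = 1 − (2 Σ p_i g_i + δ) / (Σ p_i² + Σ g_i² + δ),   δ = 1.0
```

on the fused map only (the per-level maps are supervised through their
point terms; applying Dice per level is the noted alternative).  Each
render level contributes the mean binary cross-entropy over its selected
points in the standard orientation `−(g log p + (1−g) log(1−p))` with
predictions clipped to `[1e−7, 1−1e−7]`; the orientation with the roles of
`p` and `g` exchanged is undefined for hard 0/1 targets and is not a
trainable objective, so the standard form is used.  Per-level BCE is
*averaged* over points so λ's meaning is independent of the point budget.
Point targets at non-integer positions are bilinear samples of the binary
mask (soft targets).  δ is a smoothing constant, not a tuned quantity; it
also fixes the loss at 0 when both prediction and mask are empty.

## Coordinate and tie conventions

One convention is used everywhere (upsampling, point-feature gathering,
point targets): pixel centres at `(i + 0.5, j + 0.5)` on a half-open
`[0,H)×[0,W)` grid, bilinear sampling without corner alignment, borders
clamped.  The 2× upsampling is computed separably
(`out[2j] = 0.25·in[j−1] + 0.75·in[j]`, `out[2j+1] = 0.75·in[j] +
0.25·in[j+1]`) and is exactly the regular-grid case of the general sampler.
Sorting ties (uncertainty selection) always resolve by row-major pixel
index.

## Numerical and training choices

* **Autodiff.** All gradients come from the package's reverse-mode
  autodiff core over float64 numpy arrays (`renderseg.autograd`), validated
  against central finite differences in the test suite.  Point selection is
  outside the graph (non-differentiable); gradients reach the mixers
  through the scattered values and the encoder through both the dense maps
  and the sampled point features.
* **Fusion initialisation.** The 1×1 collapse starts as a calibrated
  average: weights `4/L`, bias −4, so with the additive gate near 0.5 the
  fused output is `σ(4·mean(X_r) − 2)` — monotone in the mean level
  probability and unsaturated over `[0,1]`.  A steeper start (slope 8)
  saturates early under the Dice loss's initial uniform drift and stalls
  training; slopes ≤2 under-resolve the probability range.  This is the one
  place the implementation needed a choice the formulas do not dictate.
* **Optimiser.**  AdamW with the library-default settings — learning rate
  1e−3, betas (0.9, 0.999), decoupled weight decay 1e−2 — and epoch-based
  early stopping on validation DSC with patience 10.
* **Determinism.**  Every random draw (weights, shuffling, point selection,
  synthetic data) flows through `numpy.random.Generator`s derived from
  explicit seeds; per-step selection seeds are a deterministic function of
  `(seed, epoch, step)`, so a resumed run continues identically to an
  uninterrupted one.  Batch-norm runs on batch statistics in training and
  running statistics at evaluation; unit-test examples pin evaluation mode
  so they are closed-form checkable.
* **Degenerate inputs.**  Empty point sets reduce a render step to pure
  bilinear upsampling; `points_divisor = 0` turns the whole decoder into
  the upsampling-only ablation.  Metric conventions: both masks empty →
  DSC 1, HD 0; exactly one empty → DSC 0, HD = image diagonal.  Boundary
  sets are 4-neighbour erosion differences, making HD bit-reproducible.

## Synthetic data

The generator emulates what makes the clinical task hard, not the physics
of MRI.  Each sample is: constant background (0.4) + smooth random bias
field (amplitude 0.04, from 4×4 low-pass-filtered noise) + `contrast` added
on the lesion support + Gaussian noise, clipped to [0,1].  Lesions are
smoothed random radial polygons — radius `r(θ) = r0 (1 + Σ_k a_k
cos(kθ+φ_k))` with four harmonics — placed rejection-style so components
stay disjoint under 8-connectivity; per-component area is steered into the
requested `[min_area, max_area]` by multiplicative rescaling of `r0`.
Component counting uses 8-connectivity throughout.  Impossible requests
(`count·min_area > H·W/2`, or unplaceable after bounded retries) raise a
capacity error.

The study conditions are 64×64 slices, one lesion of 40–400 px (1–10 % of
the frame), contrast 0.3, noise sd 0.1 — a signal-to-noise ratio of 3 at
the lesion mean, which leaves single-pixel classification genuinely
ambiguous at the boundary.  Lesion size is exposed as a parameter rather
than fixed to a distribution, since no canonical one exists.

What passing on this data does **not** show: robustness to anatomy
(skull, ventricles, partial-volume effects), modality differences
(DWI/ADC/FLAIR appear only as stacked channels in the plumbing), 3-D
context, or domain shift between scanners.  Results on the synthetic study
demonstrate that the machinery trains and that the rendering decoder's
advantage over uniform upsampling materialises under low contrast — the
direction, not the magnitude, of full-scale benchmark differences.

## Desk-scale study

`renderseg.experiments.desk_scale_study` trains the reduced configuration
(two stages of two layers, embedding 16, two heads, conv base 8, 64×64
inputs — small enough for minutes-scale CPU training while keeping every
architectural mechanism active) on 32 training / 8 validation samples, with
and without rendering, for up to 200 epochs with early stopping, and
reports train/validation DSC and validation HD for both variants.
`scripts/acceptance.py` is a thin wrapper that writes these numbers as
JSON.

## Known limitations

* Plain attention is O(N²) in token count; 2-D inputs much beyond ~256×256
  need windowing, which is deliberately out of scope.
* One selection round per level; no iterative subdivision or test-time
  point-budget scheduling.
* The training loop is single-process, full-precision CPU code built for
  reproducibility and inspectability, not throughput.
* No pretraining of the transformer branch; all results here are from
  random initialisation.
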