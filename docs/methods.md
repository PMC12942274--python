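# Methods

This note documents the model, the training protocol, the synthetic
benchmark, the numerical choices, and the known limits of what the tests
show. It is the package's own account of its science; every number quoted
here is computed by the test suite or by `scripts/acceptance.py`.

## 1. Model

**Promptable segmenter.** A frozen convolutional image encoder produces a
stride-16, D = 64-channel embedding `Z_img` (64×64 input → 4×4×64). A
two-way-attention mask decoder turns the (conditioned) embedding into mask
logits at input resolution: L = 2 rounds of token self-attention,
token→image cross-attention and image→token cross-attention (2 heads),
followed by four stride-2 transposed convolutions (realized as 1×1
convolution + pixel shuffle, channels halving 64→32→16→8→4) and a per-pixel
dot product with the projected output token plus a scalar bias. Sinusoidal
positional encodings enter attention through the query/key projections
only; the value/residual stream stays content-only.

**Feature prompts.** A small detector backbone–neck (channels 8/16/32 at
strides 8/16/32) supplies P3/P4/P5. Fusion upsamples P4/P5 bilinearly to
P3's grid, concatenates, and mixes with a 1×1 then 3×3 (reflect-padded)
convolution into a stride-8, C = 64 map. The dense prompt is a stride-2
convolutional head of that map, injected as `Z_cond = Z_img + α·P_dense`
with the scalar gate α initialized to exactly 0; the sparse prompt is
GAP → two-layer MLP → K = 4 tokens of dimension D. The box-prompt baseline
encodes each box's two corners as sinusoidal position encodings plus a
learned corner-type embedding.

**Detection head and localization distillation.** Each pyramid cell is an
anchor point at its center; the head predicts 2-way class logits and 4×B
edge logits (B = 8 bins, bin width = anchor stride). Boxes decode by the
softmax expectation of bin index × bin width per edge. Distillation softens
teacher (channel width 4×, parameter count ≈ 16× the student's) and student
edge distributions at τ = 10 and matches them with KL divergence summed
over the four edges, restricted to the main region (best-DIoU ≥ α_pos =
0.7) and the valuable localization region (γ·α_pos ≤ X < α_pos, γ = 0.5),
with region weights λ_main = λ_vlr = 1 on top of the detection loss. KL
(zero exactly at teacher–student equality) is used rather than
cross-entropy; the two differ only by the teacher-entropy constant. Losses
are rescaled by τ² by default (flag `tau_square_rescale`), the standard
correction that keeps gradient scale roughly temperature-independent.

**Detection loss.** Named but not decomposed by the reference protocol, so
its composition is a design choice here: 2-way class cross-entropy on
objectness (positives = main region; VLR anchors are excluded from this
term — they receive distillation only), mean (1 − DIoU) between decoded and
matched ground-truth boxes over the main region, and soft two-bin
(distribution-focal) cross-entropy on the edge distributions. The
threshold-on-DIoU assigner cannot bootstrap from random initialization
(decoded boxes start near-uniform, so no anchor reaches α_pos); the trainer
therefore forces the best-DIoU anchor per ground-truth box into the
positive set — the standard best-anchor guarantee of YOLO-family assigners.
`select_regions` itself keeps the pure thresholding semantics.

## 2. Training protocol

**Phase 0 — foundation pretraining.** The reference protocol assumes a
*pretrained* frozen encoder and decoder. The miniature stand-in earns that
status by self-supervised reconstruction: encoder + decoder (run without
prompts) are trained to reproduce the input image under MSE for 120 epochs
(lr 3e-3, cosine). Only images are consumed — no masks or boxes — so
annotation budgets are unaffected; the pretrained weights are shared by
every arm of a study at a given seed. After pretraining, thresholding the
reconstruction at 0.5 already yields a mean Dice around 0.6 on held-out
scenes, i.e. the foundation is useful but far from saturated.

**Phase 1 — localization distillation.** The teacher is fitted to the box
annotations (12 epochs, AdamW, lr 3e-3 cosine, batch 16) and frozen; its
per-image class/edge logits are cached. The student (10 epochs, same
optimizer) minimizes the composite objective under the configured
distillation mode (`none`, `kd` = tempered KL on the 2-way class logits
over the main region, `ld_main`, `ld_main_vlr`). The student is then frozen
entirely.

**Phase 2 — segmentation fine-tuning.** Trainable set: prompt encoder
(including α), encoder adapters (1×1 bottleneck, width 8, zero-initialized
up-projection), and mask decoder. Objective: soft-Dice + mean BCE on
logits; optimizer AdamW under a cosine schedule; 40 epochs, batch 16.
Predictions binarize at logit 0 (probability 0.5). The `RunConfig` default
initial learning rate is 1e-4, matching the reference protocol's 200-epoch
schedule; the miniature study preset uses 2e-3, chosen from step-count
arithmetic (≈ 360 steps instead of tens of thousands) and verified stable
across seeds — at 3e-3 and above, occasional runs collapse to the empty
mask (see section 4).

**Box-prompt baseline.** Trained on mask-derived tight boxes (no detector
needed), evaluated with the distilled student's predicted boxes (greedy NMS
on objectness-scored decoded boxes, at least one box kept). This is the
automatic-pipeline reading of the prompt-mode comparison: the baseline's
score depends on the detector, and box localization noise reaches the
decoder — exactly the failure mode feature prompting is meant to remove.
With no student supplied, evaluation falls back to ground-truth boxes
(interactive-style prompting).

## 3. Synthetic benchmark

Each 64×64 scene holds 1–3 smooth, deformable blobs (radial polygons with
low-order Fourier radius perturbation, smoothed), intensity means 0.62
foreground / 0.38 background, Gaussian boundary blur of 2 px applied
*before* adding pixel noise of σ = 0.18 — so edge pixels genuinely carry
intermediate values and the contrast-to-noise ratio is ≈ 1.3. Instances may
touch but not substantially overlap; boxes always derive from masks via the
tight-box rule. Splits follow the deterministic protocol: ids sorted
lexicographically, one shuffle with seed 2025, ⌈fraction·n⌉ test and
validation sizes, remainder to train. Annotation budgets are nested prefix
subsets of a seeded shuffle, so 10% ⊂ 20% ⊂ 50% ⊂ 100% and the same subset
feeds phase-1 boxes and phase-2 masks.

These scenes emulate low contrast, ambiguous boundaries and crowded small
structures. They do **not** emulate modality-specific texture, anatomy
priors, intensity calibration, 3-D context, or annotation noise; a passing
test here shows the mechanism behaves as designed under the stated
statistical structure, not that it reaches any particular accuracy on real
images.

The generator defaults were calibrated once against their stated purpose —
an unprompted miniature model must be imperfect with headroom for
prompting. At higher contrast/lower noise the reconstruction-pretrained
segmenter alone is near-ceiling and every prompting arm degenerates to a
tie; the chosen setting leaves the unprompted model clearly imperfect while
keeping the task learnable in CPU minutes.

## 4. Numerical choices

* Everything runs in float64 on a small reverse-mode autodiff engine
  (`ldprompt.nn`); all randomness flows through explicitly passed
  `numpy.random.Generator`s, so training is bit-deterministic under a fixed
  seed and single-threaded BLAS.
* Three zero-initialized gates stabilize miniature-scale training, in the
  same spirit as the α = 0 dense gate and the zero-initialized adapter
  up-projections: the image-stream attention output projection, the
  readout-token refinement (`token_gate`), and the scalar mask bias. At
  initialization the decoder is therefore exactly its unconditioned,
  attention-free readout; conditioning is strictly additive. Without these
  gates the tempered training budget either diverges (the O(1) attention
  updates drown the ≈ 0.2-scale content stream) or collapses to the empty
  mask (global logit calibration otherwise has to go through the spatial
  readout weights).
* The α gate carries a 10× per-parameter step scale: a zero-initialized
  scalar gate is a saddle (gradients into the dense head are proportional
  to α), and within a few hundred steps the plain step size never breaks
  it.
* No LayerNorm on the decoder's image stream: at width 64 the embedding
  content is nearly rank-one, and per-position normalization provably
  erases its scale — the very signal the mask readout needs. Token-side
  LayerNorms are kept.
* Upsampling in the fusion block is bilinear with the half-pixel-center
  (align_corners = false) convention; interpolation dialects change values,
  so the convention is fixed and tested.
* Degenerate cases are pinned by tests: empty masks (Dice = IoU = 1 when
  both empty, 0 against a nonempty mask, image-diagonal sentinel + flag for
  boundary distances), zero-area boxes (IoU contribution 0), the empty
  γ = 1 VLR band, and the −1 score sentinel when no ground truth exists.

## 5. Study design and problem sizes

The directional study trains the full two-phase pipeline on 200 scenes
(140 train / 20 validation / 40 test) for every cell of
{box baseline, dense+sparse} × {no distillation, LD main+VLR} ×
{10, 42, 123 seeds} plus the budget sweep {10, 20, 50, 100%} for the
dense+sparse arm, sharing teachers and students across cells where the
configuration coincides. These sizes keep a full study around ten minutes
on one CPU core while leaving each arm enough signal for the orderings of
interest; they are the package's study conditions, not tuned per outcome.
The assertions are *directional*: feature prompts ≥ detector-box baseline,
LD-distilled prompts ≥ undistilled prompts (both on seed-mean test Dice),
and budget monotonicity within a 0.02 sampling tolerance. Absolute Dice
values at this scale are not comparable to any full-scale system.

## 6. Known limitations

* The 4×4 embedding bottleneck caps boundary fidelity; Hausdorff distances
  of a few pixels are expected even for good masks.
* The α gate often stays small within the miniature phase-2 budget; part of
  the dense+sparse arm's advantage is carried by the sparse tokens and the
  fused-feature pathway rather than a large dense injection.
* The unprompted (`none`) arm is competitive at this scale — with a
  reconstruction-pretrained foundation on single-class blobs, prompts add
  localization robustness rather than raw accuracy. The study's claims are
  therefore about orderings among *prompted* configurations.
* `kd` and the single-prompt arms (`dense`, `sparse`) are implemented and
  tested for contract correctness but are not part of the headline
  directional assertions.
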