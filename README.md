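# ldprompt

Localization-distilled **feature prompting** for promptable segmentation,
built and tested end-to-end at desk scale on synthetic low-contrast shape
scenes.

## The problem

Promptable segmenters of the segment-anything family condition a mask
decoder on geometric prompts — boxes or points. A box encodes only a coarse
region of interest: it carries no shape or appearance information, and any
localization noise in the box propagates straight into the mask. For
structures with low contrast and blurred, deformable boundaries (the typical
medical-imaging regime) this is the dominant failure mode.

`ldprompt` implements the alternative studied here: replace the geometric
prompt with **latent feature prompts** generated by a small detector whose
localization ability was sharpened by **localization distillation (LD)**
from a larger teacher. Two complementary prompts condition the decoder:

* **Dense feature prompt** `P_dense`: the detector's multi-scale pyramid
  (P3/P4/P5) is fused to a stride-8 map, projected to the image-embedding
  scale, and injected residually,

      Z_cond = Z_img + α · P_dense,        α learned, initialized to 0.

* **Sparse feature prompts** `T_sparse`: global average pooling of the fused
  map followed by an MLP yields K (= 4) tokens that join the decoder's
  self/cross attention.

The detector itself is trained with LD: each box edge e ∈ {t, b, l, r} is a
categorical distribution over B spatial bins; teacher and student
distributions are softened with a generalized softmax
`p_i = exp(z_i/τ) / Σ_j exp(z_j/τ)` (τ = 10) and matched with a KL
divergence summed over the four edges. Distillation is restricted to the
**main region** (anchors whose best DIoU against ground truth reaches
α_pos) and the **valuable localization region** (VLR), the band
`γ·α_pos ≤ X_k < α_pos` of semi-positive anchors, giving the objective

    L_total = L_det + λ_main Σ_{k∈Ω_main} L_LD^k + λ_vlr Σ_{k∈Ω_vlr} L_LD^k

with λ_main = λ_vlr = 1. Training is two-phase: (1) teacher fixed, student
distilled, student backbone–neck frozen; (2) prompt encoder + encoder
adapters + mask decoder fine-tuned on masks with Dice + BCE under a cosine
schedule. Everything — the autodiff engine included — runs on numpy; no GPU
or deep-learning framework is required.

## Worked example

```python
import numpy as np
from ldprompt.synthetic import SceneConfig, generate_dataset, split_dataset
from ldprompt.models import ModelSpec, Detector
from ldprompt.distill import DistillConfig
from ldprompt.training import (RunConfig, pretrain_foundation, train_teacher,
                               phase1_distill, Segmenter, phase2_segment,
                               evaluate)

samples = generate_dataset(SceneConfig(seed=2025), 200)
train, val, test = split_dataset(samples, 0.2, 0.1)     # 140 / 20 / 40

spec, dcfg = ModelSpec(), DistillConfig()
cfg = RunConfig(phase2_lr=2e-3)
pre = pretrain_foundation(spec, train, cfg, np.random.default_rng([10, 11]))
teacher = train_teacher(spec, train, cfg, dcfg, np.random.default_rng([10, 17]))
student = Detector(spec.student_width, spec, np.random.default_rng([10, 23]))
phase1_distill(student, teacher, train, cfg, dcfg, np.random.default_rng([10, 29]))

seg = Segmenter(spec, "dense+sparse", np.random.default_rng([10, 31]),
                student=student, pretrained=pre)
phase2_segment(seg, train, cfg, np.random.default_rng([10, 37]))
report = evaluate(seg, test, seed=10)
print({k: round(v, 3) for k, v in report.means.items()})
```

On this seed the evaluation prints

```
{'dice': 0.783, 'iou': 0.65, 'acc': 0.968, 'hd': 6.307, 'assd': 1.113}
```

i.e. the feature-prompted segmenter reaches a mean test Dice of 0.783 with a
mean Hausdorff boundary error of about 6 px on held-out 64×64 scenes; the
per-case scores and a 95% bootstrap CI on the Dice mean live in
`report.per_case` and `report.ci_dice`.

## Command line

`ldprompt synth | distill | train | eval | ablate` drive the same pipeline
from YAML configs (see `configs/miniature.yaml`); datasets are written as
PNG images/masks + JSON boxes + a CSV manifest, models as single-file `.npz`
checkpoints with a JSON manifest, and ablation grids as resumable per-cell
JSON records plus a summary CSV.

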