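# lcmamba

Selective state-space (SS2D) segmentation of liver tumors in 2-D CT/MRI
slices, as a tested, CPU-runnable library and CLI.

Hepatocellular carcinoma is hard to delineate automatically: lesions are
heterogeneous, their margins infiltrative, and the surrounding cirrhotic
parenchyma is itself distorted. 3-D volumetric networks capture context but
are too heavy for routine clinical deployment; plain 2-D CNNs are light but
myopic. This package implements a 2-D middle path: a hierarchical encoder
whose blocks are **selective state-space models** — linear-time recurrences
that carry global context across a whole slice — combined with a
**reverse-attention decoder** specialised for lesion boundaries, and a
**boundary-aware composite loss**. Everything is exercisable without
external datasets or GPUs via a deterministic liver-phantom generator, and
a full metric/statistics suite (Dice, mIoU, recall, precision, F2, HD95,
lesion-size stratification, Wilcoxon + Holm–Bonferroni) evaluates results
the way the clinical-imaging literature reports them.

## The model

**SS2D core.** A diagonal state-space layer maps a serialised feature
sequence x_t to y_t through

    h_t = Ā h_{t−1} + B̄ x_t,      y_t = C h_t,

with zero-order-hold discretisation of a continuous system A = diag(Λ):

    Ā = exp(Δ·Λ),    B̄ = ((exp(Δ·Λ) − 1)/Λ)·B     (→ Δ·B as Λ → 0).

Δ, B and C are read off the input at each position ("selective"). A 2-D
feature map is serialised along four directions (→ row-major, ← its
reversal, ↓ column-major, ↑ its reversal), scanned independently, mapped
back to the grid, concatenated and projected: Y = Proj(Concat[Y→,Y←,Y↓,Y↑]).
Cost is linear in pixel count — O(HW)·O(C²)·O(N) — unlike quadratic
self-attention.

**Encoder.** A stride-4 convolutional stem, then four stages of pre-norm
residual SS2D blocks with 2×2 stride-2 transitions: feature maps f1..f4 at
1/4 … 1/32 resolution. Two deployable variants: `T` (tiny; depths 2,2,4,2)
and `S` (small; depths 2,2,8,2 plus one extra SSM block), plus a `nano`
preset for CPU tests.

**LCAM decoder.** From a coarse prediction P, each level builds the
reverse-attention map Θ(P) = 1 − P + γ·|∇P|: confident regions are
suppressed, uncertain regions and boundaries (large |∇P|) emphasised. The
attention modulates a transformed encoder feature, R_i = Θ(P_{i+1}) ⊙ δ(f_i),
a 1×1 head reads a residual logit, and P_i = σ(p_i + logit(P_{i+1}↑)).
Supervision is applied at every pyramid level.

**Loss.** L = α·L_BCE + β·L_Dice + λ·L_Boundary, where the boundary term is
an Є-smoothed Dice complement restricted to a ~3-px band B around the
ground-truth contour:

    L_Boundary = 1 − (2Σ_{i∈B} y_i ŷ_i + Є) / (Σ_{i∈B} y_i + Σ_{i∈B} ŷ_i + Є).

The network and its training loop run on a compact numpy reverse-mode
autodiff engine (`lcmamba.nn`) written for this package — no deep-learning
framework required.

## Worked example

```python
import numpy as np
from lcmamba import (PhantomConfig, generate_arrays, overlap_metrics, hd95,
                     stratify_lesions, profile)

data = generate_arrays(3, PhantomConfig(seed=7))
img, mask, spacing = data[0]
for rec in stratify_lesions(mask, spacing):
    print(f"lesion: {rec.area_px} px, d = {rec.equiv_diameter_mm:.1f} mm -> {rec.size_class}")

pred = np.roll(mask, 2, axis=1)          # a deliberately shifted prediction
m = overlap_metrics(pred, mask)
print(f"dice = {m['dice']:.3f}  precision = {m['precision']:.3f}  "
      f"recall = {m['recall']:.3f}  hd95 = {hd95(pred, mask, spacing):.2f} mm")

for v in ("T", "S"):
    rep = profile(v, (256, 256))
    print(f"LCMamba-{v}: {rep.params_millions:.2f} M params, "
          f"{rep.flops_giga:.2f} G FLOPs at 256x256")
```

prints

```
lesion: 225 px, d = 16.9 mm -> Small
dice = 0.867  precision = 0.867  recall = 0.867  hd95 = 2.00 mm
LCMamba-T: 15.27 M params, 4.05 G FLOPs at 256x256
LCMamba-S: 23.41 M params, 5.48 G FLOPs at 256x256
```

The phantom's single lesion lands in the "Small" (< 2 cm) stratum; shifting
the mask by two pixels costs ~13 points of Dice and produces a 2 mm HD95,
matching the 2-px offset. The `T`/`S` budgets are the quantities the
efficiency benchmark tracks.

Training end-to-end on phantoms (≈ 90 s on one CPU):

```sh
lcmamba --out ds generate --n-slices 200 --image-size 64
lcmamba --out run train --manifest ds/manifest.json --variant nano --epochs 20
lcmamba --out run profile --variant T
```

The `train` command reports best validation Dice (≈ 0.9 on the default
phantom benchmark) and writes a checkpoint plus a per-epoch CSV log.

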