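# Methods

## Model

The network is a 2-D encoder–decoder. The encoder embeds a 3-channel slice
(grayscale inputs are replicated) with two stacked 3×3 stride-2
convolutions — a stride-4 patch embedding — and processes it through four
stages of selective state-space (SS2D) blocks separated by 2×2 stride-2
transitions, yielding features at strides 4/8/16/32 with strictly
increasing widths. Input height and width must be multiples of 32; the CLI
resizes to 256×256 before inference.

Each SS2D block is pre-norm residual with a sigmoid gate: LayerNorm over
channels, a linear projection to value and gate, the four-direction
selective scan on the value, gate multiplication, and a residual add. Per
direction the block holds a learned log-parameterised decay Λ < 0
(initialised to −1…−N per channel), linear maps reading Δ (softplus, bias
initialised so Δ ∈ [1e−3, 1e−1]), B_t and C_t from the input at each
position, a direct skip term D·x, and a channel-concat merge projection
back to the block width. States are real-valued; the zero-order-hold
discretisation uses the diagonal closed form Ā = exp(ΔΛ),
B̄ = ((exp(ΔΛ)−1)/Λ)·B with the series limit B̄ → Δ·B when |ΔΛ| < 1e−6
(the factor (ΔA)⁻¹ is undefined at zero). The output map C is applied
directly to the state without discretisation. Serialisation orders are
fixed as: → row-major, ← reversed row-major, ↓ column-major, ↑ reversed
column-major; any consistent choice is equivalent up to a parameter
permutation.

The decoder reads a coarse probability map from the deepest feature via a
1×1 head and refines level by level (4 → 1). The reverse-attention map
Θ(P) = 1 − P + γ·|∇P| uses the gradient magnitude by central differences
with edge replication — the only reading under which Θ stays
single-channel. The coarse prior at the deepest level lives on f4's own
grid, so no upsampling happens there; every finer level upsamples the prior
×2 bilinearly first. The transform δ is a 3×3 convolution + batch norm +
ReLU; the refined feature is R_i = Θ ⊙ δ(f_i). Because the level head
produces a logit while the prior is a probability, the combination is done
in logit space, P_i = σ(p_i + logit(clamp(P↑, ε, 1−ε))) with ε = 1e−4: the
prior passes through unchanged when the head is silent. Deep supervision
applies the loss at all five pyramid levels (each upsampled to full
resolution) with equal weights.

## Loss

L = α·BCE + β·(1 − soft Dice) + λ·L_Boundary with defaults α = β = 1,
λ = 0.5, Є = 1e−6. The boundary band B is computed from the ground-truth
mask only, per sample: mask XOR its one-pixel morphological erosion
(8-connected structuring element), dilated by one pixel — a band roughly
three pixels wide straddling the contour. Probabilities are clamped to
[1e−7, 1−1e−7] inside the BCE. The area-level Dice term plus the
contour-level boundary term absorb the foreground/background imbalance; no
extra pixel weighting is used.

## Numerical substrate

All tensors are float32 on a compact tape-based reverse-mode autodiff
engine written for this package (`lcmamba.nn`): broadcast-aware
elementwise ops, matmul, im2col convolution, dense-matrix separable
bilinear resize, a linear-recurrence scan primitive whose backward replays
the recurrence in reverse, and a numerically guarded (exp(z)−1)/z
primitive for the discretisation. Adam and a reduce-on-plateau schedule
(factor 0.5, patience 5, monitoring validation Dice in max mode) complete
the training stack. Runs are single-threaded numpy and therefore
deterministic per platform; cross-platform bit-exactness of float
reductions is not claimed.

## Variants and profiling

| variant | channels            | depths      | extra SSM blocks | state dim |
|---------|---------------------|-------------|------------------|-----------|
| T       | 96, 192, 384, 768   | 2, 2, 4, 2  | 0                | 16        |
| S       | 96, 192, 384, 768   | 2, 2, 8, 2  | 1 (stage 4)      | 16        |
| nano    | 8, 16, 32, 64       | 1, 1, 2, 1  | 0                | 4         |

The SS2D expansion factor is 1 (inner width = block width) and the decoder
works at width 64 (16 for nano); these choices keep the instantiated
T/S variants inside the target ≤ 18.6 M / 24.2 M parameter and
≤ 38.5 G / 49.8 G FLOP budgets at 256×256 (measured: 15.27 M / 4.05 G and
23.41 M / 5.48 G). The extra S block is appended to stage 4, the deepest
and cheapest placement. FLOPs are counted by shape propagation over the
layer graph — each layer reports its multiply-accumulate count for a given
input shape, with 1 MAC = 1 FLOP; scan steps count 5·E·N MACs per position
per direction plus the selective parameter reads. The dominant-term
complexity estimate H·W·C²·N is exposed separately and the profiled count
is exactly linear in pixel count.

## Evaluation conventions

- Both masks empty → Dice = mIoU = 1, HD95 = 0; exactly one empty →
  Dice = 0, HD95 = image diagonal × spacing (a finite penalty).
- mIoU is the mean of foreground and background IoU; foreground-only IoU is
  also exported.
- HD95 boundary pixels are mask XOR its one-pixel erosion; distances come
  from the exact Euclidean distance transform; both directions are pooled
  before the 95th percentile. Per-case means per-slice; volume-level
  grouping is possible when cases carry a volume id.
- Lesions are 8-connected components; the equivalent circular diameter is
  2·√(area/π)·spacing; strata are Small < 20 mm, Medium 20–50 mm
  (inclusive), Large > 50 mm.
- Aggregates are mean ± sample SD (n−1) with Student-t 95% CIs (bootstrap
  percentile CIs available); paired comparisons use the two-sided Wilcoxon
  signed-rank test (exact where sample size permits, zero differences
  dropped) with Holm step-down adjustment, p < 0.05.

## Phantom generator

The generator emulates the phenomenology the method targets, not CT/MR
physics: an elliptical organ (≈ 80–90% of the frame) with band-limited
Gaussian texture (correlation length 3 px, amplitude 0.06) over a dark
background (0.15 vs parenchyma 0.50); elliptical lesions with axis ratio
0.8–1.25, sigmoid margins, intensity offset `lesion_contrast` (default
0.35), optional hypointense cores, and additive Gaussian noise (default SD
0.05). Lesions sit fully inside the organ with ≥ 2 px clearance so the
boundary band is well defined; the mask is the union of supports at
half-maximum, which makes measured equivalent diameters track requested
ones. Item i of a dataset is seeded `seed ^ i`, so regeneration is
order-independent; dataset splits shuffle with a fixed split seed
(default 42).

What it does **not** emulate: enhancement-phase variability, mimicking
benign lesions, cirrhotic architectural distortion, partial-volume
effects, scanner noise spectra. Passing the synthetic benchmark therefore
demonstrates that the pipeline learns and evaluates correctly — not
clinical-grade accuracy on real CT/MRI.

## Training protocol and test-bed sizes

Full-scale defaults follow the reference protocol: Adam at 1e−4, batch 16,
256×256 inputs, seed 3407, rotation ±15° plus horizontal/vertical flips
(images bilinear, masks nearest-neighbour, so they stay binary), epoch
budget 100 with early stopping (patience 15). Augmentation presets nest
monotonically: none ⊂ basic (flips) ⊂ full (flips + rotation).

The CPU test bed trains the nano variant on 200 phantoms at 64×64 for 20
epochs. At this scale Adam 1e−4 cannot converge the tiny model within the
epoch budget; the preset uses lr 3e−3 and batch 8, which converges by
roughly epoch 12 (validation Dice ≈ 0.9). The augmentation comparison runs
a lighter setting (120 slices, 10 epochs, three seeds per preset) and is
read directionally, with a tolerance covering seed-to-seed noise: with
scarce, easy synthetic data the presets often tie.

## Known limitations

- Slice-wise only: no inter-slice (Z-axis) consistency.
- Real-valued diagonal states; no complex modes, no fused scan kernels.
- The numpy engine is CPU-bound; the full T/S variants train impractically
  slowly at scale (they instantiate and profile in under a second, and
  forward passes are fine; large-scale training was never the goal here).
- No pretrained encoder weights are shipped; a best-effort load hook maps
  matching parameter names from a checkpoint and logs the rest.
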