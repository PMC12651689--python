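# Methods

## The model

`promptseg` implements a prompt-conditioned binary segmentation network:
a single encoder–decoder convnet whose output target is selected at
inference time by a natural-language instruction ("Segment the liver
region", "Isolate the meningioma"). The network never sees class ids;
the only task signal is a frozen 768-dimensional text embedding `v_t`
fused into the visual bottleneck.

### Image encoder

Four stages; each stage max-pools 2×2/stride 2 **first** and then applies
a residual double 3×3-conv block (BatchNorm, LeakyReLU slope 0.1),
squeeze-and-excitation channel attention (reduction r=16), a spatial
attention map (σ of a 7×7 convolution over the channel-wise avg/max
pooling, applied multiplicatively), and dropout δ=0.1. Pool-then-conv is
the ordering consistent with the stage shapes 64×H/2×W/2 … 512×H/16×W/16:
the input is pooled immediately, so E1 already lives at half resolution.
The "CBAM" here is deliberately only the spatial branch of the original
CBAM publication — SE already provides the channel branch in this
architecture.

The residual shortcut inside a conv block is the identity when channel
counts match and a learned 1×1 projection otherwise. Batch-norm eps is
1e-5; batch size 1 is permitted in training but batch variance is then
poorly estimated (documented instability); eval mode uses running
statistics. Dropout is inactive at inference (standard practice; the
alternative was never specified).

### Text side

Prompts are built from class-synonym tables (e.g. glioma → "Glioma",
"Brain tumor", "Tumor", "Neoplasm", …) substituted into templates such
as "Segment the {} region". Tokenization is uncased, punctuation-split,
wrapped in [CLS]/[SEP] markers and capped at 16 positions; the embedding
is the mean of the per-token 768-vectors over non-padding positions
(markers included — "all token embeddings"; padding excluded, since
including it would make the pooled vector depend on prompt length in an
arbitrary way).

The token embedder is a pluggable callable. The bundled default derives
each token's vector from a salted SHA-256 hash (seeded standard normal,
scaled 1/√768): deterministic, offline, and frozen by construction. A
pretrained contextual encoder can be dropped in behind the same
interface; nothing downstream changes because only the fixed pooled
vector crosses the boundary. The trade-off is explicit: hash embeddings
carry no semantics across synonyms — "Tumor" and "Neoplasm" are
unrelated vectors — so generalization across unseen phrasings is not a
property this package's experiments can (or claim to) test.

### Cross-modal fusion

At the bottleneck E4 (512 channels at full width):

1. **FiLM** — `E_fused = (1+γ)⊙E4 + β`, with γ, β affine functions of
   `v_t` (768→512). The generating maps are zero-initialised, so an
   untrained fusion stage is the identity and modulation grows from
   zero during training.
2. **SE on the fused map** — channel recalibration under the joint
   visual-textual context (r=16).
3. **Conditional batch normalization** — batch normalization whose
   per-channel scale/shift are generated from `v_t` (scale bias
   initialised to 1, shift to 0).
4. **Residual** — `E_final = E4 + E_CBN`, where E4 is the raw bottleneck
   (read literally; the alternative, residual on the post-FiLM map, was
   a genuinely open choice).
5. **Channel-wise L2 normalization** — every spatial location's channel
   vector is scaled to unit norm, eps-guarded (1e-8).

The architecture description places CBN both at the bottleneck equations
and "in the last convolution layer of the decoder, while the feature map
has 128 channels". The two statements conflict; both sites are
implemented and selected by `FusionConfig.cbn_sites`, defaulting to
both, which satisfies every stated sentence at negligible cost.

### Decoder

Three stages of (2×2 stride-2 transposed convolution → concatenation
with the matching skip → residual conv block with SE + spatial
attention). The transposed convolutions preserve channel count, so the
concatenations have widths 768/384/192 (512+256, 256+128, 128+64); the
conv blocks reduce to 256/128/64. The stage-2 block (128 channels)
carries the decoder-side CBN. Because the encoder pools before its
first convolution, three doublings from H/16 only reach H/2; a fourth
2×2 stride-2 transposed convolution (64→64) restores full resolution
before the 1×1 convolution + sigmoid head. Output: one probability map,
thresholded at τ=0.5 by default (the threshold was never specified;
0.5 is the symmetric choice). Multi-organ segmentation is one forward
pass per organ prompt — a single-channel, prompt-selected head is the
design's point. Decoder conv blocks keep the encoder's dropout δ=0.1
(assumption; unstated).

## Losses

Six objectives, standalone or weighted-sum combined (`combined_loss`):
Dice (squared-denominator soft Dice), Focal (γ=2, no class-balance α
term), Jaccard (soft IoU), Tversky (α=0.7 on false
positives, β=0.3 on false negatives), DiceBCE (unit weights), and a
Hausdorff term. All ratio losses carry a smoothing eps (default 1e-6,
settable to 0 for the oracle tests) because the pure formulas divide by
zero on empty masks. With eps only in the denominator (the squared-sum
Dice form used here), an empty-prediction/empty-target pair yields Dice
loss 1, not 0 — the eps prevents NaN, it does not redefine the
empty-mask limit.

The true Hausdorff distance — max over both directions of the largest
nearest-boundary distance, boundaries being foreground pixels with a
4-connected background neighbour or on the image border — is
non-differentiable in the predicted probabilities, so it is an
evaluation metric here. Empty-mask convention: one empty mask → the
image diagonal (sentinel); both empty → 0. For *training* under the
`hausdorff` name the package uses a differentiable surrogate of its own
design: squared prediction error weighted by the squared distance
transforms of the target and of the binarized prediction, so errors far
from the correct region dominate. It is zero on a perfect match and
smooth everywhere, but it is **not** the max-min formula.

## Metrics

Ten per-image metrics from the pixel contingency table: IoU, Dice,
F1 (≡ Dice for binary masks), mAP, HD, Cohen's κ, specificity, recall,
precision, pixel accuracy. mAP is defined as pixelwise average
precision (step-interpolated area under the PR curve over all score
thresholds), averaged over classes in multi-organ settings — for dense
probability maps, pixelwise AP is the natural reading of "mAP".
Zero-denominator convention, uniform across metrics: a count ratio with
denominator 0 is 1.0 when the corresponding error count is also 0,
else 0.0. κ is computed from the 2×2 table and cannot exceed 1; the
suite asserts this property explicitly (published tables in this area
have carried κ values above 1, which are arithmetic anomalies a correct
implementation cannot reproduce). Metrics are computed per image and
averaged over the evaluation set (macro); micro-averaging over pooled
counts is available via `confusion_counts`.

## Numerical substrate

No deep-learning framework is used: the package carries a small
reverse-mode autodiff engine over numpy (`promptseg.nn`) with exactly
the primitives the architecture needs (conv2d via im2col + BLAS matmul,
non-overlapping 2×2 stride-2 transposed conv, 2×2 max pool, batch norm,
elementwise ops, reductions). Every hand-written backward rule is
verified against central finite differences in the test suite. The
working dtype defaults to float32 (single-precision matmuls are about
twice as fast on one CPU core); the gradient checks and the
machine-precision identity tests switch to float64. Max-pool gradient
ties route to the first maximum — deterministic, and measure-zero for
continuous activations. Optimization is AdamW (decoupled weight decay)
with cosine annealing of the learning rate to 0.

## Synthetic scenes

The generators emulate the two benchmark regimes without any external
data:

* **single-lesion**: one lesion per image — irregular infiltrative
  blob (glioma-like; low-order Fourier perturbation of a circle,
  roughness 0.35), smooth near-circular disc (meningioma-like), or
  small compact ellipse (pituitary-like) — uniform class draw, optional
  no-lesion fraction (default 0).
* **multi-organ**: four disjoint regions per scene — a large lobed
  region ("liver", brightest), a mid-size disc ("spleen"), and two
  small ellipses ("kidneys") — placed by rejection sampling with a
  1-pixel separation moat.

Background 0.12, additive Gaussian noise σ=0.05 on the [0,1] scale
(images are mapped to [-1,1] by the preprocessing), intensities per
class drawn from disjoint ranges. The kidneys are **lateralized**
(placement bands: left kidney in the left ~45 % of columns, right in
the right ~45 %), mirroring anatomy: with identical shape families, a
positional cue plus disjoint intensity bands is what makes each class
identifiable at all, and class identifiability is a precondition for
the prompt-conditioning experiments to be meaningful. Every multi-organ
scene contains all four classes, so the target mask is unrecoverable
from the image alone — the prompt carries the missing information.

What the generator does **not** emulate: imaging physics (bias fields,
partial-volume effects, acquisition artifacts), anatomical texture,
inter-subject shape statistics, 3D context. Passing tests therefore
demonstrate that the conditioning pathway works and the implementation
is correct — not that the architecture reaches any particular accuracy
on clinical data.

## Training protocol and desk scale

Full-scale defaults: resize to 128×128,
intensities to [-1,1], 80/20 stratified split, AdamW lr 1e-4 / weight
decay 1e-4, cosine annealing, 500 epochs, dropout 0.1, frozen text
encoder, metrics as mean ± std over k independent runs with 95 %
Student-t confidence intervals and a Shapiro–Wilk normality check
(constant samples are rejected as degenerate). Batch size is a free
config knob rather than a fixed constant.

The test suite and bundled experiments run a **desk-scale**
configuration chosen once: 64×64 scenes, quarter-width model (base 16
channels; identical topology), 200 scenes (160 train / 40 val), batch
8, 60 epochs, lr 1e-3. The larger learning rate is deliberate: 1e-4 is
tied to batch-512 full-scale training and is far too slow for ~1500
batch-8 steps. The prompt-recovery experiment trains with matched
prompts and evaluates twice — matched, and with every prompt swapped to
a different organ while keeping the original target mask. High matched
Dice with near-zero swapped Dice is the signature that the FiLM/CBN
pathway, not the image prior, selects the output.

Multi-run experiments reseed everything per run (data, split,
initialization, shuffling); the harness equally supports fixed-data
reseeding. Seeds for k runs default to 0..k-1. Runs are bit-reproducible
under a fixed seed: all randomness flows from `numpy` SeedSequences
derived from the config seed.

## Known limitations

* The hash embedder makes prompt *identity* available to the model but
  not prompt *semantics*; cross-synonym generalization requires
  plugging in a pretrained text encoder.
* 2D only; single-channel output head; no deep supervision or
  test-time augmentation.
* The Hausdorff training surrogate is a proxy; optimizing it does not
  certify small true Hausdorff distances.
* Batch-norm at batch size 1 trains but is unstable; prefer ≥ 4.
* The engine is CPU/numpy: full-scale 500-epoch training is possible
  but slow; the desk-scale configuration is the intended operating
  point for experimentation.
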