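# promptseg

Prompt-driven image segmentation for biomedical-style 2D scenes: a
single encoder–decoder network that segments **whichever structure a
natural-language instruction names**. Instead of training one model per
organ or lesion, the instruction ("Segment the liver region", "Isolate
the meningioma") is embedded to a fixed vector `v_t ∈ R^768` and fused
into the visual features, so one set of weights serves many targets and
the target is chosen at inference time.

The package is aimed at researchers studying language-conditioned
segmentation mechanisms and loss-function selection: everything runs
offline on synthetic, seeded, prompt-conditioned scenes, on one CPU,
with no pretrained weights.

## The model

A modified U-Net with dual attention, conditioned through feature-wise
linear modulation (FiLM) and conditional batch normalization (CBN):

* **Encoder** — four stages of 2×2 max-pool followed by a residual
  double 3×3-conv block with squeeze-and-excitation (SE, r=16) and a
  spatial attention map (σ(conv7×7[avg; max])), dropout 0.1; feature
  pyramid 64×H/2×W/2 → 512×H/16×W/16.
* **Fusion** at the bottleneck E4:
  `E_fused = (1+γ)⊙E4 + β` with `γ = W_γ v_t + b_γ`,
  `β = W_β v_t + b_β`; then SE, then CBN
  (`γ_bn ⊙ (E − μ)/√(σ²+ε) + β_bn`, scale/shift generated from `v_t`),
  residual `E_final = E4 + E_CBN`, and per-location channel-wise L2
  normalization.
* **Decoder** — three transposed-conv up-samplings concatenated with
  the skips (widths 768/384/192), attention conv blocks (256/128/64,
  CBN at the 128-channel block), a final up-sampling to full
  resolution, and a 1×1 sigmoid head producing a probability mask
  `M̂ ∈ [0,1]^{H×W}`.

Six training losses (Dice, Focal γ=2, Jaccard, Tversky α=0.7/β=0.3,
DiceBCE, and a differentiable Hausdorff surrogate), ten evaluation
metrics (IoU, Dice, F1, pixelwise mAP, Hausdorff distance, Cohen's κ,
specificity, recall, precision, pixel accuracy), and a multi-seed
harness (mean ± std, 95 % t-intervals, Shapiro–Wilk) round out the
toolkit. There is no deep-learning framework underneath: the network
runs on a small, fully tested reverse-mode autodiff engine over numpy
(`promptseg.nn`).

## Worked example

Train a quarter-width model on synthetic multi-organ scenes (every
scene contains a liver, a spleen and two kidneys, so the image alone
cannot tell the model what to segment — only the prompt can):

```python
from promptseg.training import prompt_recovery_experiment

out = prompt_recovery_experiment(seed=0)   # 200 scenes, 60 epochs, ~4 min
print("matched dice", round(out["matched"].dice, 4))
print("swapped dice", round(out["swapped"].dice, 4))
```

```
matched dice 0.8731
swapped dice 0.0009
```

Matched prompts recover the named organ (validation Dice ≈ 0.87);
swapping every prompt to a *different* organ at test time collapses the
score to ≈ 0 against the original target — the conditioning pathway,
not the image prior, selects the output.

The same workflow is available from a shell:

```bash
promptseg synth --task multi_organ --n 200 --seed 0 --image-size 64 --out data/
promptseg train --data data/ --out run/ --loss dice --epochs 60 --seed 0
promptseg infer --image data/images/00000.png --checkpoint run/checkpoint.npz \
                --prompt "Segment the Spleen region" --out masks/
promptseg compare-losses --task multi_organ --runs 3 --out cmp/
```

Ablation flags (`--no-film --no-cbn --no-se --no-cbam`) switch off the
fusion and attention components individually.

## Layout

```
src/promptseg/
  nn/          autodiff engine, layers, AdamW + cosine schedule
  encoder.py   SE, spatial attention, residual conv blocks, 4-stage pyramid
  text.py      synonym tables, prompts, tokenizer, hash embedder, pooling
  fusion.py    FiLM, CBN, SE-on-fused, residual, channel L2 norm
  decoder.py   attention decoder, sigmoid head, model assembly, binarize
  losses.py    six objectives + Hausdorff distance
  metrics.py   ten metrics, aggregation, report tables
  synthetic.py seeded single-lesion / multi-organ scene generators
  training.py  train/evaluate, splits, multi-run statistics, experiments
  io.py, cli.py  dataset + checkpoint IO, `promptseg` command
```

See `docs/methods.md` for modelling assumptions, numerical choices and
known limitations.
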