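# waveseg

Binary semantic segmentation of 2-D biomedical images — polyps in
endoscopy, skin lesions in dermoscopy, thyroid nodules in ultrasound,
teeth in radiographs — with a U-shaped encoder–decoder that adds three
refinement blocks to the classic U-Net:

* **Wavelet convolution (`WtConv`)** — a single-level orthonormal 2-D Haar
  transform splits a feature map X into sub-bands (X_LL, X_LH, X_HL, X_HH);
  each is filtered by an independent depthwise convolution, the quadruple
  is reconstructed by the inverse transform, and a final depthwise
  convolution integrates the result.  Low-frequency contours and
  directional high-frequency detail get separate learned filters, and the
  half-resolution sub-bands double the effective receptive field.
* **Large receptive field attention (`LRFA`)** —
  `Y = X + Conv1×1(MHA(Σᵢ DWConvᵢ(Conv3×3(GELU(Conv1×1(LN(X)))))))`:
  multi-scale depthwise aggregation (kernels 3/5/7) followed by exact
  multi-head self-attention over spatial positions, as a residual block at
  the low-resolution bottleneck.
* **Weighted contextual fusion (`WCF`)** — at each skip junction,
  `Y = DWConv(softmax_c(Linear(X₁)) ⊙ Linear(DWConv(X₂)))`: the encoder
  skip stream X₁ generates a per-position channel attention distribution
  that modulates the upsampled decoder stream X₂.

Training uses the hybrid loss `L = λ₁·L_CE + λ₂·L_Dice` (λ₁ = 0.4,
λ₂ = 0.6), AdamW with cosine-annealed learning rate, five-fold
cross-validation, and joint image/mask augmentation.  Evaluation reports
DSC, IoU, Precision and Sensitivity from exact pixel confusion counts.

Everything runs on plain NumPy: the package ships a small reverse-mode
autodiff engine whose operators are verified against finite differences,
so every mathematical component is testable on one CPU without a GPU
framework or dataset downloads.  A deterministic synthetic-data generator
emulates the four modalities' difficulty regimes (indistinct boundaries,
speckle noise, densely packed fine structures).

## Worked example

Generate a synthetic lesion dataset, train a reduced model, and evaluate:

```python
import numpy as np
from waveseg import (ModelConfig, TrainConfig, RegimeSpec, generate_sample,
                     run_training, evaluate_masks)

samples = [generate_sample(RegimeSpec.preset("lesion", image_size=64),
                           seed=7, index=i) for i in range(32)]
model_cfg = ModelConfig(num_stages=4, base_width=8, image_size=64, seed=0,
                        wtconv_stages={3, 4}, lrfa_stages={4})
train_cfg = TrainConfig(lr=1e-3, lr_min=1e-5, epochs=150, batch_size=8,
                        image_size=64, augment=False, seed=0)
result = run_training(model_cfg, train_cfg, samples,
                      max_steps=600, eval_every=5, stop_at_dice=0.90)

masks = [s.mask for s in samples]
all_fg, _ = evaluate_masks([np.ones_like(m) for m in masks], masks)
print(f"steps:        {len(result.loss_history)}")
print(f"train dice:   {result.best_metrics.dsc:.4f}")
print(f"all-fg dice:  {all_fg.dsc:.4f}")
```

Output (about a minute on one CPU core):

```
steps:        84
train dice:   0.9209
all-fg dice:  0.2398
```

The reduced network reaches Dice 0.92 on 32 boundary-blurred lesion
samples in 84 optimizer steps; the all-foreground baseline — predicting
every pixel as lesion — scores 0.24, so the model is learning geometry,
not a trivial prior.  `run_training` returns the loss history, the best
metrics report (DSC/IoU/Precision/Sensitivity) and a checkpoint path when
an output directory is given.

The same workflow is available from the shell:

```bash
waveseg gen-data --regime lesion --n 32 --seed 7 --image-size 64 --out data/
waveseg train --config config.yaml --data data/ --out run/
waveseg cv     --config config.yaml --data data/ --out run/      # k-fold CV
waveseg ablate --config config.yaml --data data/ --out run/      # 8 variants
waveseg eval    --checkpoint run/train_fold0.npz --data data/ --out run/
waveseg predict --checkpoint run/train_fold0.npz --image img.png \
                --out mask.png --overlay overlay.png
```

`ablate` trains the eight standard variants (baseline U-Net; baseline plus
one block; full model minus one block; full model) under an identical data
split and seed and writes a comparison table.

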