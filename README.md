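# frcnet

Lightweight context-guided encoder–decoder for binary polyp segmentation in
colonoscopy images, for researchers and engineers who need a small
(≤ 0.78 M parameter), fully reproducible segmentation model plus the
standard evaluation suite — without a GPU framework: all network math runs
on a self-contained numpy autodiff backend inside the package.

## What is inside

- **Three context modules** implemented as pure, shape-contracted tensor
  transforms:
  - *ECC* (enhanced context-calibrated convolution): split–fuse–select with a
    sigmoid calibration gate `X_att = σ(X₂ ⊕ Up(F̂₃ₓ₃(Down(X₂))))`;
  - *PCF* (progressive context-aware fusion): local 3×3 + dilation-5
    "surrounding" branches with softmax global attention pooling
    `y = x + x′ + γ(Σⱼ βⱼ x′ⱼ)`, `γ = S₃ ReLU LN S₂`;
  - *MPA* (multi-scale pyramid aggregation): five decoder levels upsampled,
    concatenated, projected, and re-weighted by squeeze-and-excitation
    `Y = G ⊗ δ(M(g(G), ω))`.
- **The assembled network** with ablation variants (`baseline`, `ecc`,
  `pcf`, `mpa`, `full`) and a parameter audit against the 0.78 M budget.
- **The compound loss** `L = 0.6·L_BCE + 0.4·L_Dice` (Dice smoothed with
  ξ = 1e-8).
- **Seven evaluation statistics**: mDice, mIoU, weighted F-measure `F^w_β`,
  S-measure `S_α`, mean/max E-measure `E_ξ`, MAE.
- **A seeded synthetic scene generator** emulating the three clinical
  challenge regimes (low contrast, small polyps, large polyps) with exact
  masks, so everything here runs without downloads.
- **Training / inference / evaluation orchestration** as a scikit-learn
  style estimator (`FRCNetSegmenter`), a thin pipeline module, and a
  `frcnet` command line.

## Worked example

```python
import numpy as np
from frcnet import FRCNetSegmenter, SynthConfig, generate_sample, evaluate

def scenes(seed, n):
    cfg = SynthConfig(n_images=n, size=96, seed=seed)
    pairs = [generate_sample(cfg, i) for i in range(n)]
    return (np.stack([p.image for p in pairs]),   # (n, 3, 96, 96) in [0, 1]
            np.stack([p.mask for p in pairs]))    # (n, 1, 96, 96) in {0, 1}

X, y = scenes(seed=1, n=200)
est = FRCNetSegmenter(variant="full", epochs=10, seed=1)
est.fit(X, y)                 # seeded 10% internal validation split
print("parameters:", est.n_params_)
print("best val mDice:", round(est.val_mdice_, 3))

Xt, yt = scenes(seed=2, n=60)  # unseen scenes
report = evaluate(est.predict_proba(Xt)[:, 0], yt[:, 0])
print("test mDice:", round(report.mdice, 3), " mIoU:", round(report.miou, 3))
```

Output from this exact computation (one CPU core, ~10 minutes):

```
parameters: 374402
best val mDice: 0.918
test mDice: 0.939  mIoU: 0.899
```

374 402 learnable weights is the full model under the 0.78 M budget;
mDice/mIoU ≈ 0.94/0.90 say the trained model closely overlaps the exact
synthetic masks after ten epochs — the synthetic task is easier than real
colonoscopy, which is precisely what makes it a fast end-to-end check.

The same run from the shell:

```bash
frcnet synth --n 200 --size 96 --seed 0 --out data/
frcnet train --data data/ --out run/ --config config.yaml   # model/train YAML
frcnet predict --ckpt run/checkpoint.npz --images data/images --out preds/
frcnet eval --pred preds/ --gt data/masks --report report.json
frcnet audit
```

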