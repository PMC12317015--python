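# dualgland

GAN-based augmentation for multi-channel fluorescent cell images, built
around two biologically motivated loss functions and a fully synthetic
benchmark so that every component runs end-to-end on a laptop CPU.

## The problem

Protein subcellular-localization datasets such as the Human Protein Atlas
(4-channel confocal images: protein of interest, nucleus, microtubules,
endoplasmic reticulum; 19 multi-label localization classes) suffer from
severe class imbalance (up to 21:1), missing-pixel artifacts from
photobleaching, and limited morphological diversity in rare classes.
Augmenting minority classes with GAN-generated images helps only if the
synthetic cells remain *biologically plausible*: organelle volume fractions,
organelle network topology and cell shape must stay in physiological ranges,
and reconstructed regions must respect protein-gradient continuity.

`dualgland` implements a dual-generator / shared-discriminator GAN in which
each generator is specialized by its loss:

* **SG-Loss** (salivary-gland, modelling graded acinar secretion): a
  multi-scale reconstruction loss with Laplacian gradient regularization,

  `L_SG = Σ_s w_s · [ MSE(F_s(x), F_s(G_SG(z))) + λ_grad · mean(∇²F_s(G_SG(z)))² ]`,

  with scale weights `w = [0.6, 0.3, 0.1]` and `λ_grad = 0.1`; `F_s` is a
  Gaussian pyramid by default (a learned embedder is pluggable). An optional
  neighbour-difference continuity term (`λ_cont`) provides the distance-based
  variant.

* **PG-Loss** (pituitary-gland, modelling homeostatic structural stability):
  compartment-aware adaptive smoothness plus an organelle-intensity penalty,

  `L_PG = mean_{i, j∈N(i)} α_ij · (G_PG(z)_j − G_PG(z)_i)² + λ_hom · Σ_k |mean(O_k) − μ_k|²`,

  with `α_ij = exp(−β‖f_i − f_j‖²) · C_compartment(i,j) · exp(−t/τ)`,
  `β = 2`, `τ = 5`, and compartment factors 1.0 / 0.5 / 0.1 for same /
  adjacent / distant compartments.

Generator outputs are blended by a temperature-scaled, confidence-weighted
softmax (`γ_SG + γ_PG = 1`) driven by image-derived secretion and structure
measures; biological plausibility is enforced by explicit volume /
MST-connectivity / aspect-ratio penalties; and the loss weights `λ_SG ∈
[0.3, 1.2]`, `λ_PG ∈ [0.2, 0.9]` are adapted during training by a PI
controller fed by convergence-rate EWMAs, with per-epoch changes capped at
0.15.

The evaluation stack (FID, Inception Score, SSIM/PSNR, MS-SSIM diversity,
k-NN manifold precision/recall, and the quality/diversity/combined scoring
with weights [0.4, 0.35, 0.25] / [0.6, 0.4] and a geometric-mean combination)
plus multi-label classification metrics round out the package.

A built-in simulator generates HPA-like cell scenes (elliptical nuclei,
mitochondrial blob clusters, reticular ER, per-class protein painting,
controlled volume fractions, missing-pixel corruption), so tests and demos
need no external data. Real 4-channel data can be supplied through the same
TIFF + JSON-sidecar scene format.

## Worked example

```python
import numpy as np
from dualgland.scenes import generate_dataset
from dualgland.model import DualGlandGAN, NetSpec, TrainConfig
from dualgland.genmetrics import evaluate_generators

scenes = generate_dataset(96, seed=0, height=32, width=32)
model = DualGlandGAN(scenes,
                     net_spec=NetSpec(image_size=32, base_channels=64),
                     train_config=TrainConfig(seed=0))
results = model.fit(epochs=5)
print(results.summary())
```

```
Dual-gland GAN training results
==================================
epochs run          5
best epoch (val)    4
final D loss        0.1253
final SG loss       0.2067
final PG loss       0.0518
final val loss      0.1807
lambda_SG           0.7507
lambda_PG           0.5005
gamma_SG (mean)     0.9750
```

The discriminator loss (0.13) shows it currently separates real from fake
easily — expected after five epochs. The SG reconstruction loss (0.21) and
PG structural loss (0.05) are the quantities the controller watches: both
loss weights have barely moved from their initial values (0.75, 0.5) because
the convergence-rate difference has not crossed the 0.3 divergence trigger.
The mean fusion weight γ_SG ≈ 0.98 says fused samples are currently
dominated by the SG generator (its outputs carry stronger protein-channel
gradients).

Evaluating fused samples against the real set:

```python
real = np.stack([s.image for s in scenes[:48]])
report = evaluate_generators(real, {
    "fused":   results.sample(48, seed=1, use_fusion=True),
    "sg_only": results.sample(48, seed=1, generator="SG"),
})
print(report.table().round(3))
```

```
architecture    fid  msssim  precision  recall  quality  diversity  combined
       fused 53.463   0.783        0.0     0.0    0.525        0.2     0.324
     sg_only 53.465   0.776        0.0     0.0    0.475        0.8     0.616
```

FID here uses the package's analytic embedder, so absolute values are not
comparable to Inception-based numbers; manifold precision/recall of 0 is the
honest verdict on a 5-epoch toy run — the generated distribution has not yet
reached the real manifold. Quality/diversity/combined are cohort-relative
(min–max normalized across the architectures in one report).

The same pipeline is scriptable from the shell:

```bash
dualgland simulate --n 64 --height 32 --width 32 --seed 0 --out scenes/
dualgland train --out run1/ --n-scenes 64 --epochs 5
dualgland preset weight_grid --out grid.csv
```

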