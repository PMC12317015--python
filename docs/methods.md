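# Methods

This note documents the models and procedures implemented in `dualgland`,
the defaults they use, and the design choices made where the underlying
formulation left details open.

## Synthetic cell scenes

The simulator emulates the structure of 4-channel confocal
protein-localization data. A scene is a tilted ellipse (cell footprint,
target aspect ratio 1.8, within the observed 1.2–2.5 range) containing:

* a **nucleus** rendered as an ellipse, grown to an exact pixel count by
  ranking an elliptical distance field — the achieved area fraction equals
  its target (default 0.175 of cell area, inside the physiological 15–20 %);
* **mitochondria** as blob clusters (top-ranked pixels of a σ=2-smoothed
  Gaussian noise field; default fraction 0.125, inside 10–15 %);
* **ER** as a reticular network (near-zero level set of a σ=3-smoothed
  field; default fraction 0.10, inside 8–12 %);
* a small "other organelle" blob (3 % of cell area) supporting punctate
  protein painters.

The exact-count construction means volume-fraction tests are exact rather
than statistical. The protein channel is painted by the localization class's
*family* (nuclear, cytosolic, membrane, ER-/mitochondria-colocated,
punctate, negative) — seven painters are sufficient to exercise every loss
term; 19 bespoke painters would add nothing the losses can distinguish.
Class sampling uses the published 19-class percentages; because the dataset
is multi-label the printed column sums to 110 %, and the frequency table
normalizes it to probabilities. Scenes carry one consistent label per image;
image-level weak supervision (labels true for the image but not every cell)
is *not* modelled, and the simulator makes no attempt to emulate real
point-spread functions, uneven illumination, or inter-cell-type morphology
differences. Passing tests therefore demonstrate correctness of the losses,
controller and metrics — not performance on real microscopy.

Noise is additive Gaussian (default sd 0.02), clipped to [0, 1]. Missing
pixels are zeros across all channels (photobleaching-style), never NaN, and
exactly `round(rate·H·W)` positions are corrupted.

Preprocessing follows the standard protocol: CLAHE on single channels (clip
limit 2.0 in the OpenCV convention, converted to scikit-image's normalized
convention as `clip/nbins`), 256×256 patches at stride 128 with reflect
padding (mirror without edge repetition), and augmentation by rotations
(±20°), flips, and zoom (0.8–1.2) with shape-preserving crop/pad.
Coordinates are 0-based (row, col) with half-open patch windows.

## SG loss

Canonical form: `Σ_s w_s [D_s(F_s(real), F_s(gen)) + λ_grad·mean(∇²F_s(gen))²]
+ λ_cont·L_cont`. Defaults `w = [0.6, 0.3, 0.1]`, `λ_grad = 0.1`,
`λ_cont = 0`, `D = MSE`. Decisions:

* `F_s` is a Gaussian pyramid (σ=1, 5×5 support, reflect padding,
  ×2 floor-halving downsampling). A learned dense embedder can be passed via
  the `features` argument; the analytic default keeps the loss deterministic
  and testable without pretrained weights.
* The Laplacian gradient term is a map, not a scalar; it is reduced to the
  mean squared Laplacian of the *generated* features — nonnegative,
  differentiable, and resolution-independent. MSE is per-pixel mean (not
  sum), which only rescales λ.
* The continuity variant preserves 4-neighbour differences:
  `mean((Δgen − Δreal)²)`, zero exactly when gen = real + constant.
* Two conflicting published defaults exist for the scale weights
  ([0.6, 0.3, 0.1] vs [0.2, 0.3, 0.5]); the ablation evidence identifies
  [0.6, 0.3, 0.1] as optimal and it is the default. Both are reachable via
  config, and the scale-grid preset sweeps the published six triples.

The training loop uses the analytic gradient of this loss with respect to
the generated image (adjoint of the linear pyramid), verified against finite
differences to ~1e-11.

## PG loss

`mean_{i,j∈N(i)} α_ij (gen_j − gen_i)² + λ_hom · Σ_k (mean(O_k) − μ_k)²`
over ordered 8-neighbour pairs (Moore neighbourhood, configurable to 4),
averaged over channels; all sums are means so magnitudes are
resolution-independent. Decisions:

* **Per-pixel features** `f_i`: channel values ⊕ 3×3 local mean and std per
  channel, min–max scaled (12 components for 4-channel images). A global
  patch embedder cannot supply the per-pixel vectors the weighting formula
  requires, so a local analytic descriptor is the default; a dense extractor
  is pluggable.
* **Compartment factor**: 1.0 same nonzero label, 0.5 different labels
  related by adjacency (masks touch after 1-pixel dilation), 0.1 otherwise
  including background pairs.
* **Temporal decay** `exp(−t/τ)`, τ=5: with `t` = raw epoch the smoothness
  term would be extinct by epoch ~25, so `t` counts epochs since the last
  constraint-monitor trigger (reset on trigger). Raw-epoch behaviour is
  available by driving `t` directly.
* **Reference intensities** μ_k are never published; package defaults are
  nucleus 0.60, mitochondria 0.45, ER 0.30, all user-overridable.
  `λ_hom` defaults to 1.0 (also unpublished).
* The organelle-weighted structural variant is implemented as
  `Σ_o λ_o·[mean |∇|² over interior(M_o) + hinge(0.1 − mean boundary |∇|)²]
  + λ_reg·R`, i.e. smooth interiors with sharp boundaries, with R supplied
  by the biological-constraint loss.
* In training, α is treated as stop-gradient (standard for adaptive-weight
  smoothness losses); the gradient is exact for fixed features.

## Fusion

`γ_SG = exp(C_SG/T)·S_sec / (exp(C_SG/T)·S_sec + exp(C_PG/T)·S_str)`,
`T = 2.0` (adaptive range 1.5–3.0). The published weight equations carry no
temperature while the hyperparameter table defines one; placing `C/T` inside
the exponent recovers the published equations at `T = 1`. Confidences are
the discriminator's mean realness score for each generator's recent batches
(tracked as an EWMA); the state measures are the mean Sobel gradient
magnitude of the protein channel (secretion) and the variance of Sobel
magnitudes at organelle boundary pixels (structure). When both state
measures are zero the weights fall back to a plain softmax of the
confidences. γ is a scalar pair per sample (no spatial variation).

## Biological constraints

Squared-hinge penalties on interval constraints (smooth, exactly zero on the
feasible set): volume fractions (nucleus [0.15, 0.20], mitochondria
[0.10, 0.15], ER [0.08, 0.12]) and aspect ratio ([1.2, 2.5], computed from
the eigenvalues of the mask's coordinate covariance). Connectivity compares
minimum spanning trees of organelle component graphs (8-connected
components, centroid-distance-weighted): nodes are greedily matched by
globally smallest centroid distance, and the penalty is the normalized
symmetric difference of MST edge sets with unmatched nodes counted as
violations — 0 for identical topology, bounded in [0, 1], symmetric.
Component weights λ default to 1.0 each (unpublished).

The plausibility metrics for the controller are: boundary definition
(mean boundary Sobel magnitude through `x/(1+x)`), coherence (Moran's I of
the protein channel with rook weights, mapped to [0, 1]; constant images
defined as 0.5), and plausibility (1 − clamped sum of volume and morphology
penalties).

During GAN training the constraint loss is evaluated on *thresholded*
organelle structure inferred from generated images (nucleus and ER from
their channels, cell footprint from smoothed total intensity). Because the
penalties act on discrete masks they are non-differentiable; they enter the
logged generator objective and the controller's monitor but contribute no
gradient. `λ_bio` defaults to 0.1 (unpublished).

## Adaptive controller

Convergence rates: `rate ← 0.9·rate + 0.1·|L_t − L_{t−1}|/L_{t−1}` per
epoch. The PI update `λ ← λ·[1 + 0.05·error + 0.01·Σerror]` with
`error = 0.02 − rate` applies when `|rate_SG − rate_PG| > 0.3` (the
published trigger text is garbled; the absolute-difference reading is the
only recoverable closed form) or when the constraint monitor (every 10
epochs; thresholds 0.85 / 0.80 / 0.75, strict `<`) forces it. Order of
operations: multiplicative proposal → step clip (±0.15) → bound clamp
(λ_SG ∈ [0.3, 1.2], λ_PG ∈ [0.2, 0.9]). The integral error accumulates only
on applied steps and is never reset when the trigger deactivates. Because
the rate measures |change|, slow convergence yields a positive error and a
weight increase. A proportional-only multiplicative rule is available as
`mode="p_only"`. The ±20 % sensitivity probe evaluates a supplied scoring
callable at {0.8λ, λ, 1.2λ} without mutating state.

## GAN

Dense generators (latent 64 → 128 → 256 → C·H·W, sigmoid) and a shared
dense discriminator (logit head; LeakyReLU, dropout 0.3) on a numpy core
with manual backprop — at desk scale (32–64 px) dense networks train in
seconds per epoch on one CPU, and the network architecture is not a fidelity
target. Discriminator loss follows the dual value function exactly;
generators use the non-saturating surrogate. Xavier-uniform initialization
for output heads, Kaiming-normal for hidden layers, Adam (β₁ 0.5, β₂ 0.999),
gradient-norm clipping at 1.0, L2 1e-5, cosine annealing with warm restarts
(period 40), early stopping (patience 10, min delta 1e-4) on a validation
loss computed from fixed latent draws, best-validation checkpointing. The
two generators draw independent latent vectors each step. Training is
deterministic given the seed (single-threaded numpy).

## Evaluation stack

FID uses the analytic embedder by default (8×8 downsampled channels ⊕
16-bin histograms per channel, all components in [0, 1], unstandardized);
the covariance square root is computed via the symmetric form
`Tr((Σr^½ Σg Σr^½)^½)` with 1e-6 jitter, which stays stable for
rank-deficient sample covariances, and the result is clamped at 0. Absolute
FID/IS values under this embedder are not comparable to Inception-based
numbers; relative comparisons within a report are. IS and KL use natural
logs; PSNR uses log10. The published SSIM formula is printed with numerator
and denominator exchanged relative to the standard index; the standard form
is implemented (it alone satisfies SSIM(x,x)=1). MS-SSIM diversity is the
mean pairwise 3-scale SSIM geometric mean over up to 100 samples (seeded
subsample beyond). Generative precision/recall use the k-NN manifold
estimate (k=3) since no procedure is published. Quality/diversity/combined
scores are cohort-relative (min–max normalization across the architectures
in one report, FID and MS-SSIM inverted); combined is the geometric mean.
Relative improvements between published table rows are computed from values
at printed (3 d.p.) precision, matching how the published columns were
derived.

## Classification metrics and the toy experiment

Confusion-based metrics with macro averaging as primary and micro also
reported; undefined denominators return 0 with an explicit flag. Per-class
thresholds default to 0.35 and are optimized by 0.01-grid search over
[0.25, 0.45], ties to the lowest threshold. The minority "improvement ratio"
is after/before minority-class F1 and the robustness score is cross-dataset
after/before — both reverse-engineered from the published rows (a few
printed digits are truncated rather than rounded; tests use a one-ulp
tolerance). The toy experiment trains a tiny multi-label MLP (numpy core;
features = 8×8 downsampled channels) twice — original scenes vs original +
generated minority samples — under identical seeds and a 70/15/15 stratified
split. At desk scale (~100–300 scenes, 19 classes) test-set macro F1 is
dominated by classes with one or two test samples; micro F1 and balanced
accuracy are the stable summaries.

## Problem sizes

The test suite trains on 300 synthetic 32×32 scenes for 5 epochs (the
end-to-end smoke standard); the acceptance script uses 128 scenes / 4 epochs
plus 64-sample evaluation sets, and property suites use 10⁴ random states or
traces. These sizes were chosen so the full pipeline, including training,
exercises every component in well under a minute while leaving the loss,
controller and metric arithmetic exact.
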