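"""Published benchmark values for GAN-augmentation architectures on
HPA-scale protein-localization data.

These tables are *inputs*: the scoring utilities in :mod:`dualgland.genmetrics`
and :mod:`dualgland.clf` recompute the derived columns (F1, combined scores,
relative improvements, improvement ratios, robustness scores) from the raw
columns at run time.  Values reflect full-scale training on the Human Protein
Atlas dataset and are not reproducible at desk scale; only the aggregation
arithmetic is.
"""

ARCHITECTURES = [
    "Dual-Gland GAN", "Traditional GAN", "DCGAN", "WGAN", "Pix2Pix GAN",
    "Conditional GAN", "CycleGAN", "GSIP-GAN", "ECP-IGANN", "MCI-GAN",
]

#: raw generative metrics per architecture: FID (lower better), IS (higher),
#: MS-SSIM diversity (lower), manifold precision / recall.
GENERATIVE_METRICS = {
    "Dual-Gland GAN":  {"fid": 8.47,  "is_mean": 9.83, "msssim": 0.187, "precision": 0.872, "recall": 0.835},
    "Traditional GAN": {"fid": 22.35, "is_mean": 5.21, "msssim": 0.493, "precision": 0.631, "recall": 0.458},
    "DCGAN":           {"fid": 17.82, "is_mean": 6.72, "msssim": 0.412, "precision": 0.712, "recall": 0.582},
    "WGAN":            {"fid": 14.61, "is_mean": 7.63, "msssim": 0.351, "precision": 0.765, "recall": 0.673},
    "Pix2Pix GAN":     {"fid": 12.87, "is_mean": 8.12, "msssim": 0.322, "precision": 0.823, "recall": 0.764},
    "Conditional GAN": {"fid": 15.23, "is_mean": 7.85, "msssim": 0.338, "precision": 0.791, "recall": 0.712},
    "CycleGAN":        {"fid": 13.27, "is_mean": 8.23, "msssim": 0.315, "precision": 0.812, "recall": 0.752},
    "GSIP-GAN":        {"fid": 10.82, "is_mean": 8.92, "msssim": 0.256, "precision": 0.841, "recall": 0.798},
    "ECP-IGANN":       {"fid": 9.91,  "is_mean": 9.16, "msssim": 0.231, "precision": 0.857, "recall": 0.813},
    "MCI-GAN":         {"fid": 11.35, "is_mean": 8.75, "msssim": 0.274, "precision": 0.831, "recall": 0.784},
}

#: published F1 column of the precision/recall comparison (derived from the
#: precision/recall columns above; kept for cross-checking).
GENERATIVE_F1 = {
    "Dual-Gland GAN": 0.853, "Traditional GAN": 0.531, "DCGAN": 0.641,
    "WGAN": 0.716, "Pix2Pix GAN": 0.792, "Conditional GAN": 0.749,
    "CycleGAN": 0.781, "GSIP-GAN": 0.819, "ECP-IGANN": 0.834, "MCI-GAN": 0.807,
}

#: published quality / diversity scores of the trade-off analysis; the
#: combined and relative-improvement columns are recomputed from these.
QUALITY_DIVERSITY = {
    "Dual-Gland GAN":  {"quality": 0.912, "diversity": 0.894, "combined": 0.903},
    "Traditional GAN": {"quality": 0.482, "diversity": 0.427, "combined": 0.454},
    "DCGAN":           {"quality": 0.605, "diversity": 0.563, "combined": 0.584},
    "WGAN":            {"quality": 0.683, "diversity": 0.647, "combined": 0.665},
    "Pix2Pix GAN":     {"quality": 0.758, "diversity": 0.712, "combined": 0.735},
    "Conditional GAN": {"quality": 0.726, "diversity": 0.681, "combined": 0.703},
    "CycleGAN":        {"quality": 0.751, "diversity": 0.705, "combined": 0.728},
    "GSIP-GAN":        {"quality": 0.835, "diversity": 0.804, "combined": 0.819},
    "ECP-IGANN":       {"quality": 0.862, "diversity": 0.827, "combined": 0.844},
    "MCI-GAN":         {"quality": 0.821, "diversity": 0.793, "combined": 0.807},
}

#: published relative-improvement column (% over each architecture, from the
#: combined scores); kept for cross-checking the recomputation.
RELATIVE_IMPROVEMENT = {
    "Traditional GAN": 98.9, "DCGAN": 54.6, "WGAN": 35.8, "Pix2Pix GAN": 22.9,
    "Conditional GAN": 28.4, "CycleGAN": 24.0, "GSIP-GAN": 10.3,
    "ECP-IGANN": 7.0, "MCI-GAN": 11.9,
}

CLASSIFIERS = [
    "ResNet-50", "DenseNet-121", "EfficientNet-B3", "Vision Transformer",
    "MobileNetV3", "Inception-v4", "Swin Transformer", "ConvNeXt",
    "RegNet-Y", "NFNet",
]

#: classifier performance before/after augmentation:
#: (acc_before %, acc_after %, f1_before, f1_after, auc_before, auc_after)
CLASSIFIER_PERFORMANCE = {
    "ResNet-50":          (84.3, 91.7, 0.837, 0.913, 0.864, 0.932),
    "DenseNet-121":       (85.8, 92.4, 0.852, 0.920, 0.875, 0.938),
    "EfficientNet-B3":    (86.2, 93.5, 0.859, 0.931, 0.882, 0.947),
    "Vision Transformer": (85.1, 93.9, 0.848, 0.935, 0.873, 0.951),
    "MobileNetV3":        (82.7, 89.3, 0.821, 0.889, 0.848, 0.914),
    "Inception-v4":       (84.9, 92.1, 0.843, 0.917, 0.867, 0.935),
    "Swin Transformer":   (86.4, 94.2, 0.861, 0.939, 0.885, 0.953),
    "ConvNeXt":           (85.7, 93.1, 0.853, 0.927, 0.876, 0.942),
    "RegNet-Y":           (83.9, 90.8, 0.835, 0.904, 0.859, 0.925),
    "NFNet":              (86.8, 94.7, 0.864, 0.944, 0.889, 0.957),
}

#: minority-class F1 and balanced accuracy before/after augmentation:
#: (min_f1_before, min_f1_after, bal_acc_before, bal_acc_after)
MINORITY_PERFORMANCE = {
    "ResNet-50":          (0.762, 0.881, 0.812, 0.904),
    "DenseNet-121":       (0.781, 0.892, 0.828, 0.915),
    "EfficientNet-B3":    (0.790, 0.907, 0.837, 0.928),
    "Vision Transformer": (0.778, 0.913, 0.825, 0.932),
    "MobileNetV3":        (0.741, 0.858, 0.794, 0.885),
    "Inception-v4":       (0.773, 0.889, 0.821, 0.912),
    "Swin Transformer":   (0.796, 0.918, 0.841, 0.936),
    "ConvNeXt":           (0.784, 0.903, 0.831, 0.924),
    "RegNet-Y":           (0.757, 0.874, 0.806, 0.897),
    "NFNet":              (0.803, 0.925, 0.846, 0.941),
}

#: minority-class F1 before/after by augmenting GAN (before identical across
#: rows: the same baseline classifier).
MINORITY_BY_GAN = {
    "Dual-Gland GAN":  (0.777, 0.896),
    "ECP-IGANN":       (0.777, 0.876),
    "GSIP-GAN":        (0.777, 0.864),
    "MCI-GAN":         (0.777, 0.851),
    "WGAN":            (0.777, 0.842),
    "CycleGAN":        (0.777, 0.836),
    "Conditional GAN": (0.777, 0.834),
    "DCGAN":           (0.777, 0.827),
    "Traditional GAN": (0.777, 0.812),
}

#: robustness columns: (val-test gap before %, after %, cross-dataset
#: performance before %, after %)
ROBUSTNESS = {
    "ResNet-50":          (6.8, 3.2, 73.5, 85.3),
    "DenseNet-121":       (6.1, 2.9, 75.2, 86.7),
    "EfficientNet-B3":    (5.7, 2.4, 76.3, 88.1),
    "Vision Transformer": (5.9, 2.1, 74.8, 88.5),
    "MobileNetV3":        (7.3, 3.7, 71.4, 82.6),
    "Inception-v4":       (6.4, 2.8, 74.1, 85.9),
    "Swin Transformer":   (5.4, 2.0, 76.9, 89.3),
    "ConvNeXt":           (5.8, 2.5, 75.6, 87.4),
    "RegNet-Y":           (6.9, 3.3, 72.8, 84.1),
    "NFNet":              (5.2, 1.8, 77.4, 89.8),
}

#: loss-weight ablation grid: (lambda_SG, lambda_PG) pairs evaluated in the
#: weighting study, in published order.
WEIGHT_GRID = [(1.0, 0.0), (0.8, 0.2), (0.75, 0.5), (0.6, 0.7), (0.5, 0.8), (0.0, 1.0)]

#: scale-weight ablation grid of the multi-scale study.
SCALE_GRID = [
    [0.8, 0.2, 0.0], [0.7, 0.3, 0.0], [0.6, 0.3, 0.1],
    [0.5, 0.3, 0.2], [0.4, 0.4, 0.2], [0.33, 0.33, 0.33],
]
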