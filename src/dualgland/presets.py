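"""Experiment presets: ablation configurations at toy scale.

Each preset toggles exactly the named component(s) of the full pipeline and
produces one comparison row; ``weight_grid`` and ``scale_grid`` sweep the
published (lambda_SG, lambda_PG) pairs and scale-weight triples.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import benchmarks
from .constraints import ConstraintConfig
from .control import ControllerConfig
from .genmetrics import FeatureEmbedder, fid, msssim_diversity
from .model import DualGlandGAN, NetSpec, TrainConfig
from .scenes import generate_dataset
from .sg import SGConfig, ScaleWeights

PRESETS = ("full", "sg_only", "pg_only", "no_fusion", "no_multiscale",
           "no_bio", "single_generator", "weight_grid", "scale_grid")


def _preset_variants(name: str):
    """Yield (label, kwargs) config variants for one preset."""
    if name == "weight_grid":
        for lam_sg, lam_pg in benchmarks.WEIGHT_GRID:
            yield f"lambda_sg={lam_sg}_pg={lam_pg}", {"lambda_SG": lam_sg,
                                                      "lambda_PG": lam_pg}
        return
    if name == "scale_grid":
        for ws in benchmarks.SCALE_GRID:
            w = np.asarray(ws, dtype=float)
            yield "w=" + "-".join(f"{x:g}" for x in ws), {
                "sg_config": SGConfig(weights=ScaleWeights(w / w.sum()))}
        return
    kwargs = {}
    if name == "sg_only":
        kwargs["lambda_PG"] = 0.0
    elif name == "pg_only":
        kwargs["lambda_SG"] = 0.0
    elif name == "no_fusion":
        kwargs["use_fusion"] = False
    elif name == "no_multiscale":
        kwargs["sg_config"] = SGConfig(S=1, weights=ScaleWeights([1.0]))
    elif name == "no_bio":
        kwargs["constraint_config"] = ConstraintConfig(
            lambda_volume=0.0, lambda_connectivity=0.0, lambda_morphology=0.0)
        kwargs["lambda_bio"] = 0.0
    elif name == "single_generator":
        kwargs["single_generator"] = True
    elif name != "full":
        raise ValueError(f"unknown preset '{name}' (choose from {PRESETS})")
    yield name, kwargs


def run_preset(name: str, n_scenes: int = 48, image_size: int = 32,
               epochs: int = 2, seed: int = 0) -> pd.DataFrame:
    """Run one ablation preset at toy scale; returns one summary row per
    configuration variant (FID and MS-SSIM diversity under the analytic
    embedder, final losses, epochs run)."""
    scenes = generate_dataset(n_scenes, seed=seed, height=image_size,
                              width=image_size)
    embed = FeatureEmbedder()
    real = np.stack([s.image for s in scenes[: min(48, len(scenes))]])
    feats_real = embed(real)

    rows = []
    for label, kw in _preset_variants(name):
        use_fusion = kw.pop("use_fusion", True)
        single = kw.pop("single_generator", False)
        lam_sg = kw.pop("lambda_SG", None)
        lam_pg = kw.pop("lambda_PG", None)
        lambda_bio = kw.pop("lambda_bio", 0.1)
        init = None
        if lam_sg is not None or lam_pg is not None:
            init = (0.75 if lam_sg is None else lam_sg,
                    0.5 if lam_pg is None else lam_pg)
        model = DualGlandGAN(
            scenes,
            net_spec=NetSpec(image_size=image_size, base_channels=64),
            train_config=TrainConfig(max_epochs=epochs, seed=seed,
                                     lambda_bio=lambda_bio),
            controller_config=ControllerConfig(),
            initial_lambdas=init,
            adapt_weights=init is None,
            **kw,
        )
        res = model.fit(epochs=epochs)
        gen = res.sample(min(32, n_scenes), seed=seed + 1,
                         use_fusion=use_fusion and not single,
                         generator="SG" if single else None)
        feats_gen = embed(gen)
        rows.append({
            "preset": name,
            "configuration": label,
            "fid": fid(feats_real, feats_gen),
            "msssim_diversity": msssim_diversity(gen, max_samples=32, seed=seed),
            "d_loss": res.log[-1]["d_loss"],
            "sg_loss": res.log[-1]["sg_loss"],
            "pg_loss": res.log[-1]["pg_loss"],
            "epochs": res.n_epochs,
        })
    return pd.DataFrame(rows)
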