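"""Run configuration: schema-validated YAML tree over all module configs.

Defaults are the published training-protocol values (initial lambda_SG 0.75,
lambda_PG 0.5, batch size 16, scale weights [0.6, 0.3, 0.1], beta 2.0,
fusion temperature 2.0, classification threshold 0.35, ...).  Unknown keys
are rejected by name.
"""

from __future__ import annotations

import copy
import json

import yaml

DEFAULTS = {
    "seed": 42,
    "out_dir": "runs",
    "log_level": "info",
    "simulator": {
        "height": 32, "width": 32,
        "nucleus_fraction": 0.175, "mitochondria_fraction": 0.125, "er_fraction": 0.10,
        "aspect_ratio": 1.8, "missing_rate": 0.0, "noise_sd": 0.02,
    },
    "preprocess": {
        "clahe_clip_limit": 2.0, "patch_size": 256, "patch_stride": 128,
        "rotation_deg": 20.0, "zoom_min": 0.8, "zoom_max": 1.2,
    },
    "sg": {"scales": 3, "scale_weights": [0.6, 0.3, 0.1],
           "lambda_gradient": 0.1, "lambda_cont": 0.0, "distance": "mse"},
    "pg": {"beta": 2.0, "tau": 5.0, "lambda_homeostasis": 1.0, "neighborhood": 8,
           "mu_nucleus": 0.60, "mu_mitochondria": 0.45, "mu_er": 0.30},
    "fusion": {"temperature": 2.0},
    "constraints": {"lambda_volume": 1.0, "lambda_connectivity": 1.0,
                    "lambda_morphology": 1.0},
    "controller": {"alpha_p": 0.05, "alpha_i": 0.01, "target_rate": 0.02,
                   "divergence_trigger": 0.3, "max_step": 0.15,
                   "monitor_interval": 10, "validation_interval": 5,
                   "lambda_sg_init": 0.75, "lambda_pg_init": 0.5,
                   "mode": "pi"},
    "train": {"max_epochs": 200, "batch_size": 16, "lr_g": 0.0002, "lr_d": 0.0001,
              "adam_beta1": 0.5, "adam_beta2": 0.999, "cosine_restart_period": 40,
              "early_stop_patience": 10, "early_stop_min_delta": 1e-4,
              "grad_clip_norm": 1.0, "dropout": 0.3, "l2_reg": 1e-5,
              "lambda_bio": 0.1},
    "net": {"latent_dim": 64, "base_channels": 128, "image_size": 32},
    "classification": {"threshold": 0.35, "threshold_range": [0.25, 0.45]},
}


class ConfigError(ValueError):
    pass


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in (override or {}).items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise ConfigError(f"unknown configuration key: '{here}'")
        if isinstance(base[key], dict):
            if not isinstance(val, dict):
                raise ConfigError(f"'{here}' must be a mapping")
            out[key] = _merge(base[key], val, here)
        else:
            out[key] = val
    return out


def load_config(path=None) -> dict:
    """Load a YAML config; an empty/missing file yields pure defaults."""
    override = {}
    if path is not None:
        with open(path) as fh:
            override = yaml.safe_load(fh) or {}
    return _merge(DEFAULTS, override)


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def build_objects(cfg: dict):
    """Materialize the dataclass configs from a resolved config tree."""
    from .control import ControllerConfig, ControllerState
    from .constraints import ConstraintConfig
    from .model import NetSpec, TrainConfig
    from .pg import PGConfig, OrganelleReference
    from .sg import SGConfig, ScaleWeights

    sg = SGConfig(S=cfg["sg"]["scales"],
                  weights=ScaleWeights(cfg["sg"]["scale_weights"]),
                  lambda_gradient=cfg["sg"]["lambda_gradient"],
                  lambda_cont=cfg["sg"]["lambda_cont"],
                  distance=cfg["sg"]["distance"])
    pg = PGConfig(beta=cfg["pg"]["beta"], tau=cfg["pg"]["tau"],
                  lambda_homeostasis=cfg["pg"]["lambda_homeostasis"],
                  neighborhood=cfg["pg"]["neighborhood"])
    refs = OrganelleReference(mu={1: cfg["pg"]["mu_nucleus"],
                                  2: cfg["pg"]["mu_mitochondria"],
                                  3: cfg["pg"]["mu_er"]})
    cons = ConstraintConfig(lambda_volume=cfg["constraints"]["lambda_volume"],
                            lambda_connectivity=cfg["constraints"]["lambda_connectivity"],
                            lambda_morphology=cfg["constraints"]["lambda_morphology"])
    ctrl = ControllerConfig(alpha_p=cfg["controller"]["alpha_p"],
                            alpha_i=cfg["controller"]["alpha_i"],
                            target_rate=cfg["controller"]["target_rate"],
                            divergence_trigger=cfg["controller"]["divergence_trigger"],
                            max_step=cfg["controller"]["max_step"],
                            monitor_interval=cfg["controller"]["monitor_interval"],
                            validation_interval=cfg["controller"]["validation_interval"],
                            mode=cfg["controller"]["mode"])
    t = cfg["train"]
    train = TrainConfig(max_epochs=t["max_epochs"], batch_size=t["batch_size"],
                        lr_G=t["lr_g"], lr_D=t["lr_d"], adam_beta1=t["adam_beta1"],
                        adam_beta2=t["adam_beta2"],
                        cosine_restart_period=t["cosine_restart_period"],
                        early_stop_patience=t["early_stop_patience"],
                        early_stop_min_delta=t["early_stop_min_delta"],
                        grad_clip_norm=t["grad_clip_norm"], dropout=t["dropout"],
                        l2_reg=t["l2_reg"], lambda_bio=t["lambda_bio"],
                        seed=cfg["seed"])
    net = NetSpec(latent_dim=cfg["net"]["latent_dim"],
                  base_channels=cfg["net"]["base_channels"],
                  image_size=cfg["net"]["image_size"])
    return {"sg": sg, "pg": pg, "refs": refs, "constraints": cons,
            "controller": ctrl, "train": train, "net": net}


def error_record(message: str, **context) -> str:
    """Machine-readable error record for CLI failures."""
    return json.dumps({"error": message, **context})
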