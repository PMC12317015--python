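"""Dual-generator / shared-discriminator GAN with gland-inspired losses.

The model follows the statsmodels convention: :class:`DualGlandGAN` is built
from data (a list of :class:`~dualgland.scenes.CellScene`) plus configuration,
``fit()`` runs the adversarial training loop and returns a
:class:`TrainingResults` carrying the per-epoch log, the fitted weights, a
``sample()`` method and a ``summary()`` table.

Objectives
----------
Discriminator (value function of the dual adversarial game):

    L_D = -E[log D(x)] - E[log(1 - D(G_SG(z)))] - E[log(1 - D(G_PG(z)))]

Generators use the standard non-saturating surrogate -E[log D(G(z))] for
their adversarial term.  On top of that, the SG generator carries the
multi-scale reconstruction loss (weighted by the controller's lambda_SG) and
the PG generator the compartment-aware structural loss (lambda_PG); both add
a biological-constraint term (lambda_bio) evaluated on thresholded organelle
structure of the generated images (monitored, not back-propagated, since the
constraint penalties act on discrete masks).

The loss weights evolve under the PI controller; the temporal factor of the
PG loss counts epochs since the last constraint-monitor trigger.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._nn import MLP, Dense, LeakyReLU, Sigmoid, Dropout, Adam
from . import sg as sgmod
from . import pg as pgmod
from .constraints import ConstraintConfig, biological_loss, plausibility_metrics
from .control import (ControllerConfig, ControllerState, observe_losses,
                      pi_step, constraint_trigger)
from .fusion import fusion_weights, fuse, secretion_measure, structure_measure

_EPS = 1e-7


@dataclass
class NetSpec:
    latent_dim: int = 64
    base_channels: int = 128
    image_size: int = 64
    n_channels: int = 4

    def __post_init__(self):
        s = self.image_size
        if s < 16 or (s & (s - 1)) != 0:
            raise ValueError("image_size must be a power of 2, >= 16")


@dataclass
class TrainConfig:
    max_epochs: int = 200
    batch_size: int = 16
    lr_G: float = 2e-4
    lr_D: float = 1e-4
    adam_beta1: float = 0.5
    adam_beta2: float = 0.999
    cosine_restart_period: int = 40
    early_stop_patience: int = 10
    early_stop_min_delta: float = 1e-4
    grad_clip_norm: float = 1.0
    dropout: float = 0.3
    l2_reg: float = 1e-5
    lambda_bio: float = 0.1
    val_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2")


def _clamp(p):
    return np.clip(p, _EPS, 1.0 - _EPS)


def adversarial_losses(d_real, d_fake_sg, d_fake_pg) -> dict:
    """Adversarial losses from discriminator probabilities.

    ``L_D`` follows the dual value function exactly; the generator terms are
    the non-saturating surrogates.  Probabilities at exactly 0/1 are clamped.
    """
    d_real = _clamp(np.asarray(d_real, dtype=float))
    d_fake_sg = _clamp(np.asarray(d_fake_sg, dtype=float))
    d_fake_pg = _clamp(np.asarray(d_fake_pg, dtype=float))
    L_D = float(-np.mean(np.log(d_real)) - np.mean(np.log1p(-d_fake_sg))
                - np.mean(np.log1p(-d_fake_pg)))
    return {
        "L_D": L_D,
        "L_adv_SG": float(-np.mean(np.log(d_fake_sg))),
        "L_adv_PG": float(-np.mean(np.log(d_fake_pg))),
    }


def infer_scene_structure(image: np.ndarray):
    """Threshold a generated 4-channel image into (organelle labels, cell mask).

    Nucleus and ER are recovered from their dedicated channels; the cell
    footprint from smoothed total intensity.  Used to evaluate biological
    constraints on generator outputs, which carry no ground-truth masks.
    """
    img = np.asarray(image, dtype=float)
    total = ndimage.gaussian_filter(img.mean(axis=0), 1.0)
    cell = total > max(0.08, 0.25 * total.max())
    cell = ndimage.binary_fill_holes(cell)
    if cell.sum() < 16:
        cell = np.ones(total.shape, dtype=bool)
    labels = np.zeros(total.shape, dtype=np.int32)
    nuc = (img[1] > max(0.3, 0.5 * img[1].max())) & cell
    er = (img[3] > max(0.3, 0.5 * img[3].max())) & cell & ~nuc
    labels[nuc] = 1
    labels[er] = 3
    return labels, cell


class DualGlandGAN:
    """Dual-generator GAN model over a dataset of cell scenes.

    Parameters
    ----------
    scenes : list of CellScene
        Training data; must contain at least ``train_config.batch_size``.
    net_spec, train_config, controller_config, sg_config, pg_config,
    constraint_config, organelle_refs : configuration objects (defaults
        follow the published training protocol at desk scale).
    """

    def __init__(self, scenes, net_spec: NetSpec | None = None,
                 train_config: TrainConfig | None = None,
                 controller_config: ControllerConfig | None = None,
                 sg_config: sgmod.SGConfig | None = None,
                 pg_config: pgmod.PGConfig | None = None,
                 constraint_config: ConstraintConfig | None = None,
                 organelle_refs: pgmod.OrganelleReference | None = None,
                 initial_lambdas: tuple | None = None,
                 adapt_weights: bool = True):
        if not scenes:
            raise ValueError("empty dataset")
        h, w = scenes[0].image.shape[1:]
        self.spec = net_spec or NetSpec(image_size=h)
        self.cfg = train_config or TrainConfig()
        if len(scenes) < self.cfg.batch_size:
            raise ValueError("dataset smaller than one batch")
        self.ctrl_cfg = controller_config or ControllerConfig()
        self.sg_cfg = sg_config or sgmod.SGConfig()
        self.pg_cfg = pg_config or pgmod.PGConfig()
        self.constraint_cfg = constraint_config or ConstraintConfig()
        self.refs = organelle_refs or pgmod.OrganelleReference()
        self.scenes = scenes
        self._h, self._w = h, w
        self._dim = 4 * h * w
        self._built = False
        self._cmap_cache = {}
        self.initial_lambdas = initial_lambdas
        self.adapt_weights = adapt_weights

    @classmethod
    def from_simulator(cls, n_scenes: int, image_size: int = 32, seed: int = 0,
                       **kwargs):
        from .scenes import generate_dataset
        scenes = generate_dataset(n_scenes, seed=seed, height=image_size,
                                  width=image_size)
        return cls(scenes, **kwargs)

    # -- network construction ------------------------------------------------
    def _build(self, rng):
        bc = self.spec.base_channels
        zd = self.spec.latent_dim

        def gen():
            return MLP([
                Dense(rng, zd, bc, init="kaiming"), LeakyReLU(),
                Dense(rng, bc, 2 * bc, init="kaiming"), LeakyReLU(),
                Dense(rng, 2 * bc, self._dim, init="xavier"), Sigmoid(),
            ])

        self.G_SG = gen()
        self.G_PG = gen()
        self.D = MLP([
            Dense(rng, self._dim, 2 * bc, init="kaiming"), LeakyReLU(),
            Dropout(rng, self.cfg.dropout),
            Dense(rng, 2 * bc, bc, init="kaiming"), LeakyReLU(),
            Dense(rng, bc, 1, init="xavier"),  # logit head
        ])
        mk = lambda net, lr: Adam(net, lr=lr, beta1=self.cfg.adam_beta1,
                                  beta2=self.cfg.adam_beta2, l2=self.cfg.l2_reg,
                                  clip_norm=self.cfg.grad_clip_norm)
        self.opt_sg = mk(self.G_SG, self.cfg.lr_G)
        self.opt_pg = mk(self.G_PG, self.cfg.lr_G)
        self.opt_d = mk(self.D, self.cfg.lr_D)
        self._built = True

    def _lr(self, base, epoch):
        # cosine annealing with warm restarts
        T = max(self.cfg.cosine_restart_period, 1)
        frac = (epoch % T) / T
        return 0.1 * base + 0.45 * base * (1 + np.cos(np.pi * frac))

    def _d_prob(self, flat, train=False):
        logit = self.D.forward(flat, train=train)
        return _clamp(1.0 / (1.0 + np.exp(-np.clip(logit, -60, 60))))

    # -- objectives ----------------------------------------------------------
    def generator_objective(self, gen_kind: str, gen_images, real_scenes,
                            state: ControllerState, t_pg: float = 0.0) -> dict:
        """Componentwise objective of one generator on a batch.

        Returns ``{"adversarial", "reconstruction", "bio", "total"}`` with
        total equal to the exact sum of the components (adversarial +
        lambda * reconstruction + lambda_bio * bio).
        """
        gen_images = np.asarray(gen_images, dtype=float)
        flat = gen_images.reshape(len(gen_images), -1)
        p = self._d_prob(flat)
        adv = float(-np.mean(np.log(p)))
        real = np.stack([s.image for s in real_scenes])
        if gen_kind == "SG":
            lam = state.lambda_SG
            recon = sgmod.sg_loss(real, gen_images, self.sg_cfg).total
        elif gen_kind == "PG":
            lam = state.lambda_PG
            vals = []
            for img, scene in zip(gen_images, real_scenes):
                cmap = self._cmap(scene)
                vals.append(pgmod.pg_loss(img, None, cmap, scene.organelle_labels,
                                          self.refs, t_pg, self.pg_cfg).total)
            recon = float(np.mean(vals))
        else:
            raise ValueError("gen_kind must be 'SG' or 'PG'")
        bio = self._bio_value(gen_images[0], real_scenes[0])
        total = adv + lam * recon + self.cfg.lambda_bio * bio
        return {"adversarial": adv, "reconstruction": recon, "bio": bio,
                "total": float(total), "lambda": lam}

    def _bio_value(self, gen_image, ref_scene) -> float:
        labels, cell = infer_scene_structure(gen_image)
        return biological_loss(labels, cell, ref_scene.organelle_labels,
                               self.constraint_cfg).total

    def _cmap(self, scene):
        key = id(scene)
        if key not in self._cmap_cache:
            self._cmap_cache[key] = pgmod.CompartmentMap.from_labels(scene.organelle_labels)
        return self._cmap_cache[key]

    # -- training ------------------------------------------------------------
    def fit(self, epochs: int | None = None, verbose: bool = False) -> "TrainingResults":
        cfg = self.cfg
        epochs = epochs if epochs is not None else cfg.max_epochs
        rng = np.random.default_rng(cfg.seed)
        self._build(rng)
        self._cmap_cache = {}

        n_val = max(int(round(cfg.val_fraction * len(self.scenes))), 0)
        order = rng.permutation(len(self.scenes))
        val_scenes = [self.scenes[i] for i in order[:n_val]]
        train_scenes = [self.scenes[i] for i in order[n_val:]]
        if len(train_scenes) < cfg.batch_size:
            train_scenes = list(self.scenes)
        z_val = rng.standard_normal((min(len(val_scenes), 8) or 4, self.spec.latent_dim))

        state = ControllerState()
        if self.initial_lambdas is not None:
            state.lambda_SG, state.lambda_PG = self.initial_lambdas
        log, best = [], {"val": np.inf, "epoch": -1, "weights": None}
        since_improve = 0
        t_pg = 0.0  # epochs since last constraint trigger
        c_sg_track, c_pg_track = 0.5, 0.5

        for epoch in range(epochs):
            tic = time.perf_counter()
            idx = rng.permutation(len(train_scenes))
            ep = {k: [] for k in ("d", "adv_sg", "adv_pg", "sg", "pg")}
            gamma_means = []
            for b0 in range(0, len(idx) - cfg.batch_size + 1, cfg.batch_size):
                batch = [train_scenes[i] for i in idx[b0:b0 + cfg.batch_size]]
                real = np.stack([s.image for s in batch])
                flat_real = real.reshape(len(batch), -1)
                n = len(batch)

                # --- discriminator update (value-function form) ---
                z1 = rng.standard_normal((n, self.spec.latent_dim))
                z2 = rng.standard_normal((n, self.spec.latent_dim))
                fake_sg = self.G_SG.forward(z1, train=False)
                fake_pg = self.G_PG.forward(z2, train=False)
                self.D.zero_grad()
                stack = np.concatenate([flat_real, fake_sg, fake_pg])
                p = self._d_prob(stack, train=True)
                losses = adversarial_losses(p[:n], p[n:2 * n], p[2 * n:])
                targets = np.concatenate([np.ones(n), np.zeros(2 * n)])
                self.D.backward(((p.ravel() - targets) / n)[:, None])
                self.opt_d.step(lr=self._lr(cfg.lr_D, epoch))
                ep["d"].append(losses["L_D"])

                # --- SG generator update ---
                z = rng.standard_normal((n, self.spec.latent_dim))
                gen_flat = self.G_SG.forward(z, train=True)
                gen_img = gen_flat.reshape(n, 4, self._h, self._w)
                self.D.zero_grad()
                p_fake = self._d_prob(gen_flat, train=True)
                c_sg_track = 0.8 * c_sg_track + 0.2 * float(p_fake.mean())
                g_in = self.D.backward(((p_fake.ravel() - 1.0) / n)[:, None])
                sg_val = sgmod.sg_loss(real, gen_img, self.sg_cfg).total
                g_rec = sgmod.sg_loss_grad(real, gen_img, self.sg_cfg)
                total_g = g_in + state.lambda_SG * g_rec.reshape(n, -1)
                self.G_SG.zero_grad()
                self.G_SG.backward(total_g)
                self.opt_sg.step(lr=self._lr(cfg.lr_G, epoch))
                ep["adv_sg"].append(float(-np.mean(np.log(p_fake))))
                ep["sg"].append(sg_val)

                # --- PG generator update ---
                z = rng.standard_normal((n, self.spec.latent_dim))
                gen_flat = self.G_PG.forward(z, train=True)
                gen_img = gen_flat.reshape(n, 4, self._h, self._w)
                self.D.zero_grad()
                p_fake = self._d_prob(gen_flat, train=True)
                c_pg_track = 0.8 * c_pg_track + 0.2 * float(p_fake.mean())
                g_in = self.D.backward(((p_fake.ravel() - 1.0) / n)[:, None])
                pg_vals = []
                g_rec = np.zeros_like(gen_img)
                for i, scene in enumerate(batch):
                    cmap = self._cmap(scene)
                    pg_vals.append(pgmod.pg_loss(gen_img[i], None, cmap,
                                                 scene.organelle_labels, self.refs,
                                                 t_pg, self.pg_cfg).total)
                    g_rec[i] = (pgmod.pg_smoothness_grad(gen_img[i], None, cmap,
                                                         t_pg, self.pg_cfg)
                                + self.pg_cfg.lambda_homeostasis
                                * pgmod.homeostatic_grad(gen_img[i],
                                                         scene.organelle_labels,
                                                         self.refs))
                g_rec /= n
                total_g = g_in + state.lambda_PG * g_rec.reshape(n, -1)
                self.G_PG.zero_grad()
                self.G_PG.backward(total_g)
                self.opt_pg.step(lr=self._lr(cfg.lr_G, epoch))
                ep["adv_pg"].append(float(-np.mean(np.log(p_fake))))
                ep["pg"].append(float(np.mean(pg_vals)))

                gsg, _ = fusion_weights(c_sg_track, c_pg_track,
                                        secretion_measure(gen_img[0]),
                                        max(structure_measure(
                                            gen_img[0],
                                            infer_scene_structure(gen_img[0])[0]), 0.0))
                gamma_means.append(gsg)

            mean_sg = float(np.mean(ep["sg"]))
            mean_pg = float(np.mean(ep["pg"]))
            observe_losses(state, mean_sg, mean_pg, self.ctrl_cfg)

            # biological monitor on a fused sample
            metrics, triggered = None, False
            if self.ctrl_cfg.monitor_interval > 0 and epoch % self.ctrl_cfg.monitor_interval == 0:
                probe = self.sample(2, seed=cfg.seed + 9000 + epoch, use_fusion=True)
                labels, cell = infer_scene_structure(probe[0])
                metrics = plausibility_metrics(probe[0], labels,
                                               self.constraint_cfg, cell_mask=cell)
                triggered, _ = constraint_trigger(metrics, self.ctrl_cfg, epoch=epoch)
                if triggered:
                    t_pg = 0.0
            if self.adapt_weights and (epoch % self.ctrl_cfg.validation_interval == 0
                                       or triggered):
                pi_step(state, self.ctrl_cfg, force=triggered)
            else:
                state.epoch += 1
            t_pg += 1.0

            # bio-constraint bookkeeping on one sample per generator
            bio_sg = self._bio_value(
                self.G_SG.forward(rng.standard_normal((1, self.spec.latent_dim)),
                                  train=False).reshape(4, self._h, self._w),
                train_scenes[0])
            bio_pg = self._bio_value(
                self.G_PG.forward(rng.standard_normal((1, self.spec.latent_dim)),
                                  train=False).reshape(4, self._h, self._w),
                train_scenes[0])

            val = self._validation_loss(val_scenes or train_scenes[:4], z_val, state, t_pg)
            rec = {
                "epoch": epoch,
                "d_loss": float(np.mean(ep["d"])),
                "adv_sg": float(np.mean(ep["adv_sg"])),
                "adv_pg": float(np.mean(ep["adv_pg"])),
                "sg_loss": mean_sg,
                "pg_loss": mean_pg,
                "bio_sg": bio_sg,
                "bio_pg": bio_pg,
                "obj_sg": float(np.mean(ep["adv_sg"])) + state.lambda_SG * mean_sg
                          + cfg.lambda_bio * bio_sg,
                "obj_pg": float(np.mean(ep["adv_pg"])) + state.lambda_PG * mean_pg
                          + cfg.lambda_bio * bio_pg,
                "lambda_SG": state.lambda_SG,
                "lambda_PG": state.lambda_PG,
                "conv_rate_SG": state.conv_rate_SG,
                "conv_rate_PG": state.conv_rate_PG,
                "gamma_SG_mean": float(np.mean(gamma_means)) if gamma_means else 0.5,
                "val_loss": val,
                "plausibility": metrics,
                "wall_time": time.perf_counter() - tic,
            }
            log.append(rec)
            if verbose:
                print(f"epoch {epoch}: D={rec['d_loss']:.3f} SG={mean_sg:.4f} "
                      f"PG={mean_pg:.4f} val={val:.4f} "
                      f"lam=({state.lambda_SG:.3f},{state.lambda_PG:.3f})")

            if val < best["val"] - cfg.early_stop_min_delta:
                best = {"val": val, "epoch": epoch, "weights": self._weights()}
                since_improve = 0
            else:
                since_improve += 1
                if since_improve >= cfg.early_stop_patience:
                    break

        if best["weights"] is not None:
            self._set_weights(best["weights"])
        self._confidences = (c_sg_track, c_pg_track)
        return TrainingResults(self, log, state, best_epoch=best["epoch"])

    def _validation_loss(self, scenes, z_val, state, t_pg) -> float:
        real = np.stack([s.image for s in scenes[:len(z_val)]])
        z = z_val[:len(real)]
        g_sg = self.G_SG.forward(z, train=False).reshape(-1, 4, self._h, self._w)
        g_pg = self.G_PG.forward(z, train=False).reshape(-1, 4, self._h, self._w)
        sg_val = sgmod.sg_loss(real, g_sg, self.sg_cfg).total
        pg_vals = [pgmod.pg_loss(g_pg[i], None, self._cmap(s), s.organelle_labels,
                                 self.refs, t_pg, self.pg_cfg).total
                   for i, s in enumerate(scenes[:len(real)])]
        return float(state.lambda_SG * sg_val + state.lambda_PG * np.mean(pg_vals))

    # -- weights / sampling --------------------------------------------------
    def _weights(self):
        return {"G_SG": self.G_SG.get_weights(), "G_PG": self.G_PG.get_weights(),
                "D": self.D.get_weights()}

    def _set_weights(self, w):
        self.G_SG.set_weights(w["G_SG"])
        self.G_PG.set_weights(w["G_PG"])
        self.D.set_weights(w["D"])

    def sample(self, n: int, seed: int = 0, use_fusion: bool = True,
               generator: str | None = None) -> np.ndarray:
        """Draw ``n`` images in [0,1]; fused by default, or per-generator."""
        if not self._built:
            raise RuntimeError("model has not been fitted/built")
        if n == 0:
            return np.zeros((0, 4, self._h, self._w))
        rng = np.random.default_rng(seed)
        z = rng.standard_normal((n, self.spec.latent_dim))
        g_sg = self.G_SG.forward(z, train=False).reshape(n, 4, self._h, self._w)
        g_pg = self.G_PG.forward(z, train=False).reshape(n, 4, self._h, self._w)
        if generator == "SG":
            return np.clip(g_sg, 0, 1)
        if generator == "PG":
            return np.clip(g_pg, 0, 1)
        if not use_fusion:
            return np.clip(np.concatenate([g_sg, g_pg])[:n], 0, 1)
        c_sg, c_pg = getattr(self, "_confidences", (0.5, 0.5))
        out = np.empty_like(g_sg)
        for i in range(n):
            s_sec = secretion_measure(g_sg[i])
            labels, _ = infer_scene_structure(g_pg[i])
            s_str = structure_measure(g_pg[i], labels)
            w = fusion_weights(c_sg, c_pg, s_sec, s_str)
            out[i] = fuse(g_sg[i], g_pg[i], w)
        return np.clip(out, 0, 1)


class TrainingResults:
    """Results of a fitted :class:`DualGlandGAN`.

    Attributes: ``log`` (one record per completed epoch), ``controller_state``,
    ``best_epoch``.  ``sample()`` delegates to the fitted model (best
    validation weights restored).
    """

    def __init__(self, model: DualGlandGAN, log: list, controller_state,
                 best_epoch: int):
        self.model = model
        self.log = log
        self.controller_state = controller_state
        self.best_epoch = best_epoch

    @property
    def n_epochs(self) -> int:
        return len(self.log)

    def sample(self, n: int, seed: int = 0, use_fusion: bool = True,
               generator: str | None = None) -> np.ndarray:
        return self.model.sample(n, seed=seed, use_fusion=use_fusion,
                                 generator=generator)

    def trace(self, key: str):
        return np.array([r[key] for r in self.log])

    def save(self, path) -> None:
        """Serialize weights + log (npz + JSON sidecar)."""
        import json
        import pathlib

        base = pathlib.Path(path)
        base.parent.mkdir(parents=True, exist_ok=True)
        w = self.model._weights()
        arrays = {}
        for net, ws in w.items():
            for i, arr in enumerate(ws):
                arrays[f"{net}__{i}"] = arr
        np.savez(base.with_suffix(".npz"), **arrays)
        clean = [{k: v for k, v in r.items() if k != "plausibility"} for r in self.log]
        with open(base.with_suffix(".json"), "w") as fh:
            json.dump({"log": clean, "best_epoch": self.best_epoch,
                       "controller": self.controller_state.to_dict()}, fh)

    def summary(self) -> str:
        last = self.log[-1] if self.log else {}
        lines = [
            "Dual-gland GAN training results",
            "=" * 34,
            f"epochs run          {self.n_epochs}",
            f"best epoch (val)    {self.best_epoch}",
            f"final D loss        {last.get('d_loss', float('nan')):.4f}",
            f"final SG loss       {last.get('sg_loss', float('nan')):.4f}",
            f"final PG loss       {last.get('pg_loss', float('nan')):.4f}",
            f"final val loss      {last.get('val_loss', float('nan')):.4f}",
            f"lambda_SG           {self.controller_state.lambda_SG:.4f}",
            f"lambda_PG           {self.controller_state.lambda_PG:.4f}",
            f"gamma_SG (mean)     {last.get('gamma_SG_mean', float('nan')):.4f}",
        ]
        return "\n".join(lines)
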