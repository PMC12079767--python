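"""Joint training of both network stages under the six-component loss.

The optimizer is AdamW (decoupled weight decay) with defaults lr=1e-4,
betas=(0.9, 0.999), weight decay=1e-2. Per training sample the forward pass
is: Stage-1 velocity -> conditional template; Stage-2 velocity -> predicted
scan; tracker EMA update with the (detached) Stage-2 velocity; mean-adjusted
template from the combined velocity. One optimizer step is taken on the
weighted total loss.

Reproducibility: a master seed fans out, via ``numpy.random.SeedSequence``
spawning keyed on the epoch index, to weight init, latent sampling and batch
shuffling, so a run can be resumed from a checkpoint bit-exactly.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import Tensor, concat
from .grids import ImageGrid
from .losses import DEFAULT_WEIGHTS, LossBundle
from .meantrack import BinTracker
from .networks import Stage1Config, Stage1Net, Stage2Config, Stage2Net
from .nnet import AdamW
from .spatial import (
    bending_energy_t,
    displacement_magnitude_t,
    integrate_velocity,
    mse,
    warp_image,
)

__all__ = ["TrainConfig", "TemplateModel", "train_step", "run_training", "load_checkpoint"]


@dataclass
class TrainConfig:
    lr: float = 1e-4
    betas: tuple[float, float] = (0.9, 0.999)
    weight_decay: float = 1e-2
    epochs: int = 40
    batch_size: int = 4
    seed: int = 0
    gammas: tuple[float, ...] = DEFAULT_WEIGHTS
    lam: float = 0.1
    bin_centres: tuple[float, ...] = tuple(float(a) for a in range(50, 95, 5))
    sas_steps: int = 7
    mean_loss_kind: str = "mse"  # "mse" or "l1"
    sample_latent: bool = True
    stage1: Stage1Config = field(default_factory=Stage1Config)
    stage2: Stage2Config = field(default_factory=Stage2Config)

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if len(self.gammas) != 6:
            raise ValueError("expected six loss weights")
        if any(g < 0 for g in self.gammas):
            raise ValueError("loss weights must be non-negative")

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        """Build a config from a plain (e.g. YAML/JSON) dictionary."""
        d = dict(d)
        if "stage1" in d and not isinstance(d["stage1"], Stage1Config):
            s1 = dict(d["stage1"])
            for key in ("grid_shape", "decoder_widths", "cov_bounds"):
                if key in s1:
                    s1[key] = tuple(s1[key])
            d["stage1"] = Stage1Config(**s1)
        if "stage2" in d and not isinstance(d["stage2"], Stage2Config):
            s2 = dict(d["stage2"])
            for key in ("grid_shape", "widths"):
                if key in s2:
                    s2[key] = tuple(s2[key])
            d["stage2"] = Stage2Config(**s2)
        for key in ("gammas", "betas", "bin_centres"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def with_ablation(self, index: int) -> "TrainConfig":
        """Copy of the config with gamma_index (2..6, one-based) set to zero."""
        if index not in (2, 3, 4, 5, 6):
            raise ValueError("ablation index must be one of 2..6")
        g = list(self.gammas)
        g[index - 1] = 0.0
        cfg = asdict_config(self)
        cfg["gammas"] = tuple(g)
        return TrainConfig(**cfg)


def asdict_config(cfg: TrainConfig) -> dict:
    d = asdict(cfg)
    d["stage1"] = Stage1Config(**d["stage1"])
    d["stage2"] = Stage2Config(**d["stage2"])
    return d


class TemplateModel:
    """Bundle of the two network stages, the mean tracker and the template."""

    def __init__(self, cfg: TrainConfig, template: ImageGrid, init_rng: np.random.Generator):
        self.cfg = cfg
        self.template = template
        self.stage1 = Stage1Net(cfg.stage1, init_rng)
        self.stage2 = Stage2Net(cfg.stage2, init_rng)
        self.tracker = BinTracker(cfg.bin_centres, (2, *self.stage1.vel_shape), cfg.lam)
        self._t_const = np.asarray(template.data, dtype=np.float32)[None, None]

    def parameters(self):
        return self.stage1.parameters() + self.stage2.parameters()

    def template_batch(self, b: int) -> Tensor:
        return Tensor(np.broadcast_to(self._t_const, (b, 1, *self.template.shape)).copy())


def train_step(
    model: TemplateModel,
    optimizer: AdamW,
    images: np.ndarray,
    alphas: np.ndarray,
    rng: np.random.Generator,
    extra_cov: np.ndarray | None = None,
) -> LossBundle:
    """One optimizer step on a batch; returns the realized loss components.

    ``images``: (B, H, W) float array in [0, 1]; ``alphas``: (B,) ages.
    Components whose weight is zero are skipped (recorded as 0), which is
    what realises the gamma-ablation protocol.
    """
    cfg = model.cfg
    g1, g2, g3, g4, g5, g6 = cfg.gammas
    b = images.shape[0]
    x = Tensor(np.asarray(images, dtype=np.float32)[:, None])
    cov = np.asarray(alphas, dtype=np.float32)[:, None]
    if extra_cov is not None:
        cov = np.concatenate([cov, np.atleast_2d(extra_cov)], axis=1)

    vf = cfg.stage1.vel_factor
    v_a = model.stage1(cov, sample=cfg.sample_latent, rng=rng)
    u_a = integrate_velocity(v_a, cfg.sas_steps, upsample=vf)
    t_b = model.template_batch(b)
    t_alpha = warp_image(t_b, u_a)

    v_p = model.stage2(concat([t_alpha, x], axis=1))
    u_p = integrate_velocity(v_p, cfg.sas_steps, upsample=cfg.stage2.vel_factor)
    x_hat = warp_image(t_alpha, u_p)

    # EMA update of the tracked means, once per sample, outside the gradient
    # graph. Update first, then combine (within the same forward pass).
    for i in range(b):
        model.tracker.update(v_p.data[i], float(alphas[i]))

    terms = []
    bundle = {}
    recon = mse(x_hat, x)
    bundle["recon"] = float(recon.data)
    terms.append(recon * g1)
    if g2 > 0:
        bend1 = bending_energy_t(u_a)
        bundle["bend1"] = float(bend1.data)
        terms.append(bend1 * g2)
    if g3 > 0:
        bend2 = bending_energy_t(u_p)
        bundle["bend2"] = float(bend2.data)
        terms.append(bend2 * g3)
    if g4 > 0:
        disp1 = displacement_magnitude_t(u_a)
        bundle["disp1"] = float(disp1.data)
        terms.append(disp1 * g4)
    if g5 > 0:
        disp2 = displacement_magnitude_t(u_p)
        bundle["disp2"] = float(disp2.data)
        terms.append(disp2 * g5)
    if g6 > 0:
        # The mean-adjusted template is the *target*: it is built outside the
        # gradient graph (tracked means and v_alpha both constant) and the
        # penalty pulls T_alpha toward it. A symmetric formulation would be
        # translation-invariant to first order and exert no centring force.
        adj = np.stack([model.tracker.mean_adjustment(float(a)) for a in alphas], axis=0)
        v_hat = Tensor(v_a.data + adj.astype(np.float32))
        u_hat = integrate_velocity(v_hat, cfg.sas_steps, upsample=vf)
        t_hat = warp_image(Tensor(t_b.data), u_hat)
        if cfg.mean_loss_kind == "l1":
            mean_l = (t_alpha - t_hat.detach()).abs().mean()
        else:
            mean_l = mse(t_alpha, t_hat.detach())
        bundle["mean"] = float(mean_l.data)
        terms.append(mean_l * g6)

    total = terms[0]
    for t in terms[1:]:
        total = total + t
    if not np.isfinite(total.data):
        bad = [k for k, val in bundle.items() if not np.isfinite(val)]
        raise FloatingPointError(f"non-finite loss component(s): {bad or ['total']}")

    optimizer.zero_grad()
    if any(g > 0 for g in cfg.gammas):
        total.backward()
    optimizer.step()
    return LossBundle(
        recon=bundle.get("recon", 0.0),
        bend1=bundle.get("bend1", 0.0),
        bend2=bundle.get("bend2", 0.0),
        disp1=bundle.get("disp1", 0.0),
        disp2=bundle.get("disp2", 0.0),
        mean=bundle.get("mean", 0.0),
        weights=cfg.gammas,
    )


def _epoch_rngs(seed: int, epoch: int) -> tuple[np.random.Generator, np.random.Generator]:
    shuffle_rng = np.random.default_rng([seed, epoch, 0])
    latent_rng = np.random.default_rng([seed, epoch, 1])
    return shuffle_rng, latent_rng


def run_training(
    images: np.ndarray,
    alphas: np.ndarray,
    template: ImageGrid,
    cfg: TrainConfig,
    out_dir: str | Path | None = None,
    extra_cov: np.ndarray | None = None,
    start_epoch: int = 0,
    model: TemplateModel | None = None,
    optimizer: AdamW | None = None,
    log_every_step: bool = False,
) -> tuple[TemplateModel, "list[dict]"]:
    """Train for ``cfg.epochs`` epochs of shuffled batches.

    Returns the trained model and the per-epoch loss records. If ``out_dir``
    is given, writes ``losses.csv`` and ``checkpoint.npz`` there.
    """
    n = len(images)
    if n == 0:
        raise ValueError("empty training set")
    if model is None:
        model = TemplateModel(cfg, template, np.random.default_rng([cfg.seed, 12345]))
    if optimizer is None:
        optimizer = AdamW(
            model.parameters(),
            lr=cfg.lr,
            betas=cfg.betas,
            weight_decay=cfg.weight_decay,
        )
    history: list[dict] = []
    for epoch in range(start_epoch, cfg.epochs):
        shuffle_rng, latent_rng = _epoch_rngs(cfg.seed, epoch)
        order = shuffle_rng.permutation(n)
        totals = np.zeros(7)
        n_batches = 0
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo : lo + cfg.batch_size]
            extra = extra_cov[idx] if extra_cov is not None else None
            bundle = train_step(model, optimizer, images[idx], alphas[idx], latent_rng, extra)
            totals += np.array([*bundle.components, bundle.total])
            n_batches += 1
            if log_every_step:
                history.append(
                    {"epoch": epoch, "step": n_batches - 1, "total": bundle.total, **dict(zip(
                        ("recon", "bend1", "bend2", "disp1", "disp2", "mean"), bundle.components))}
                )
        avg = totals / n_batches
        if not log_every_step:
            history.append(
                {
                    "epoch": epoch,
                    "recon": avg[0],
                    "bend1": avg[1],
                    "bend2": avg[2],
                    "disp1": avg[3],
                    "disp2": avg[4],
                    "mean": avg[5],
                    "total": avg[6],
                }
            )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "losses.csv", "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(history[0].keys()))
            writer.writeheader()
            writer.writerows(history)
        save_checkpoint(out_dir / "checkpoint.npz", model, optimizer, cfg.epochs)
    return model, history


def save_checkpoint(path: str | Path, model: TemplateModel, optimizer: AdamW | None, epoch: int) -> None:
    cfg = model.cfg
    payload: dict[str, np.ndarray] = {}
    for k, v in model.stage1.state_dict().items():
        payload[f"stage1/{k}"] = v
    for k, v in model.stage2.state_dict().items():
        payload[f"stage2/{k}"] = v
    payload["tracker/means"] = model.tracker.means
    payload["tracker/centres"] = model.tracker.centres
    payload["template"] = np.asarray(model.template.data, dtype=np.float32)
    payload["template_spacing"] = model.template.spacing
    payload["template_affine"] = model.template.affine
    payload["epoch"] = np.asarray(epoch)
    if optimizer is not None:
        payload["opt/t"] = np.asarray(optimizer.t)
        for i, (m, v) in enumerate(zip(optimizer.m, optimizer.v)):
            payload[f"opt/m{i}"] = m
            payload[f"opt/v{i}"] = v
    d = asdict(cfg)
    payload["config_json"] = np.frombuffer(json.dumps(d).encode(), dtype=np.uint8)
    np.savez_compressed(path, **payload)


def load_checkpoint(path: str | Path) -> tuple[TemplateModel, AdamW, int]:
    """Rebuild model, optimizer and epoch counter from a checkpoint file."""
    with np.load(path) as data:
        cfg = TrainConfig.from_dict(json.loads(bytes(data["config_json"]).decode()))
        template = ImageGrid(
            data["template"].astype(float), data["template_spacing"], data["template_affine"]
        )
        model = TemplateModel(cfg, template, np.random.default_rng([cfg.seed, 12345]))
        model.stage1.load_state_dict(
            {k.split("/", 1)[1]: data[k] for k in data.files if k.startswith("stage1/")}
        )
        model.stage2.load_state_dict(
            {k.split("/", 1)[1]: data[k] for k in data.files if k.startswith("stage2/")}
        )
        model.tracker.means = data["tracker/means"].copy()
        optimizer = AdamW(
            model.parameters(), lr=cfg.lr, betas=cfg.betas, weight_decay=cfg.weight_decay
        )
        if "opt/t" in data.files:
            optimizer.t = int(data["opt/t"])
            optimizer.m = [data[f"opt/m{i}"].copy() for i in range(len(optimizer.params))]
            optimizer.v = [data[f"opt/v{i}"].copy() for i in range(len(optimizer.params))]
        epoch = int(data["epoch"])
    return model, optimizer, epoch
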