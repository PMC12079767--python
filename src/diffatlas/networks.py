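"""Stage-1 conditional velocity generator and Stage-2 registration U-Net.

Stage 1 maps a (normalized) conditioning vector through fully connected
layers to the mean and log-variance of a latent code, samples it (or takes
the mean in deterministic mode), and decodes it with transposed-convolution
blocks into a stationary velocity field. Warping the group template with the
integrated field yields the conditional template.

Stage 2 is a U-Net over the 2-channel stack (conditional template,
participant scan) predicting the stationary velocity field that registers the
template onto the scan.

Both networks emit velocities at half the image resolution; integration
runs on that native grid and the resulting displacement is upsampled and
rescaled to the full grid. Final layers are zero-initialised so training
starts from identity deformations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, avg_pool2d, bilinear_upsample2d, concat
from .grids import ImageGrid, VectorField
from .meantrack import BinTracker
from .nnet import Conv2d, Linear, Module, UpConv2d
from .spatial import integrate_velocity, warp_image

__all__ = ["Stage1Config", "Stage2Config", "Stage1Net", "Stage2Net", "build_templates"]


@dataclass
class Stage1Config:
    grid_shape: tuple[int, int] = (64, 64)
    latent_dim: int = 16
    decoder_widths: tuple[int, ...] = (32, 32, 16)
    cov_dim: int = 1
    cov_bounds: tuple[float, float] = (50.0, 90.0)  # age range mapped to [-1, 1]
    hidden: int = 32
    vel_factor: int = 2  # velocity predicted at 1/vel_factor resolution

    def __post_init__(self) -> None:
        lo, hi = self.cov_bounds
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError("covariate bounds must be finite with min < max")


@dataclass
class Stage2Config:
    grid_shape: tuple[int, int] = (64, 64)
    widths: tuple[int, ...] = (16, 32, 32, 32)  # encoder widths, top to bottleneck
    in_channels: int = 2
    vel_factor: int = 2


class Stage1Net(Module):
    """Covariate -> latent -> transposed-conv decoder -> velocity field."""

    def __init__(self, cfg: Stage1Config, rng: np.random.Generator):
        self.cfg = cfg
        h, w = cfg.grid_shape
        vf = cfg.vel_factor
        if h % vf or w % vf:
            raise ValueError("grid shape must divide by vel_factor")
        self.vel_shape = (h // vf, w // vf)
        n_up = len(cfg.decoder_widths)
        if self.vel_shape[0] % (2**n_up) or self.vel_shape[1] % (2**n_up):
            raise ValueError("velocity grid must divide by 2**len(decoder_widths)")
        self.seed_shape = (self.vel_shape[0] // 2**n_up, self.vel_shape[1] // 2**n_up)

        self.fc_in = Linear(cfg.cov_dim, cfg.hidden, rng)
        self.fc_mu = Linear(cfg.hidden, cfg.latent_dim, rng)
        self.fc_logvar = Linear(cfg.hidden, cfg.latent_dim, rng, zero_init=True)
        c0 = cfg.decoder_widths[0]
        self.fc_seed = Linear(cfg.latent_dim, c0 * self.seed_shape[0] * self.seed_shape[1], rng)
        ups = []
        widths = list(cfg.decoder_widths)
        for c_in, c_out in zip(widths, widths[1:] + [widths[-1]]):
            ups.append(UpConv2d(c_in, c_out, 3, rng))
        self.ups = ups
        self.head = Conv2d(widths[-1], 2, 3, rng, zero_init=True)

    def normalize(self, cov: np.ndarray) -> np.ndarray:
        """Map ages (first column) linearly to [-1, 1]; extra columns pass through."""
        cov = np.atleast_2d(np.asarray(cov, dtype=np.float32))
        if cov.shape[1] != self.cfg.cov_dim:
            raise ValueError(f"expected covariate dim {self.cfg.cov_dim}, got {cov.shape[1]}")
        if not np.all(np.isfinite(cov)):
            raise ValueError("covariates must be finite")
        lo, hi = self.cfg.cov_bounds
        out = cov.copy()
        out[:, 0] = 2.0 * (np.clip(cov[:, 0], lo, hi) - lo) / (hi - lo) - 1.0
        return out

    def latent(self, cov: np.ndarray) -> tuple[Tensor, Tensor]:
        x = Tensor(self.normalize(cov))
        hmid = self.fc_in(x).leaky_relu()
        return self.fc_mu(hmid), self.fc_logvar(hmid)

    def __call__(
        self,
        cov: np.ndarray,
        sample: bool = False,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        """Predict velocity fields on the native velocity grid (B, 2, h, w)."""
        mu, logvar = self.latent(cov)
        if sample:
            if rng is None:
                raise ValueError("sampling requires an rng")
            eps = rng.standard_normal(mu.shape).astype(np.float32)
            z = mu + (logvar * 0.5).exp() * Tensor(eps)
        else:
            z = mu
        b = z.shape[0]
        c0 = self.cfg.decoder_widths[0]
        x = self.fc_seed(z).leaky_relu().reshape(b, c0, *self.seed_shape)
        for up in self.ups:
            x = up(x).leaky_relu()
        return self.head(x)


class Stage2Net(Module):
    """U-Net (template, scan) -> stationary velocity field."""

    def __init__(self, cfg: Stage2Config, rng: np.random.Generator):
        self.cfg = cfg
        self.vel_shape = tuple(n // cfg.vel_factor for n in cfg.grid_shape)
        widths = list(cfg.widths)
        self.enc = []
        c_prev = cfg.in_channels
        for c in widths:
            self.enc.append(Conv2d(c_prev, c, 3, rng))
            c_prev = c
        # decoder runs from the bottleneck back up to the velocity resolution
        self.dec = []
        n_levels = len(widths)
        vf = cfg.vel_factor
        self.n_up = n_levels - 1 - int(np.log2(vf)) if vf > 1 else n_levels - 1
        c_prev = widths[-1]
        for i in range(self.n_up):
            skip_c = widths[n_levels - 2 - i]
            self.dec.append(Conv2d(c_prev + skip_c, skip_c, 3, rng))
            c_prev = skip_c
        self.head = Conv2d(c_prev, 2, 3, rng, zero_init=True)

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(f"expected {self.cfg.in_channels} input channels, got {x.shape[1]}")
        if tuple(x.shape[2:]) != tuple(self.cfg.grid_shape):
            raise ValueError(f"grid mismatch: {x.shape[2:]} vs {self.cfg.grid_shape}")
        skips = []
        for i, enc in enumerate(self.enc):
            if i > 0:
                x = avg_pool2d(x, 2)
            x = enc(x).leaky_relu()
            skips.append(x)
        for i, dec in enumerate(self.dec):
            x = bilinear_upsample2d(x, 2)
            x = concat([x, skips[-2 - i]], axis=1)
            x = dec(x).leaky_relu()
        return self.head(x)


def build_templates(
    stage1: Stage1Net,
    tracker: BinTracker | None,
    alphas,
    template: ImageGrid,
    steps: int = 7,
    extra_cov: np.ndarray | None = None,
):
    """Deterministically export conditional templates for a list of ages.

    Returns a list of dicts with keys ``age``, ``template`` (T_alpha),
    ``template_adj`` (mean-adjusted T_alpha-hat), ``phi`` and ``phi_adj``.
    Ages outside the configured covariate bounds are clamped (with the
    network's normalization handling the clamp).
    """
    import warnings

    results = []
    t_data = np.asarray(template.data, dtype=np.float32)[None, None]
    lo, hi = stage1.cfg.cov_bounds
    for i, alpha in enumerate(np.atleast_1d(np.asarray(alphas, dtype=float))):
        if not lo <= alpha <= hi:
            warnings.warn(
                f"age {alpha} outside the training range [{lo}, {hi}]; clamping",
                stacklevel=2,
            )
        cov = np.array([[alpha]], dtype=np.float32)
        if extra_cov is not None:
            cov = np.concatenate([cov, np.atleast_2d(extra_cov)[i : i + 1]], axis=1)
        v = stage1(cov, sample=False)
        vf = stage1.cfg.vel_factor
        u = integrate_velocity(v, steps, upsample=vf)
        t_alpha = warp_image(Tensor(t_data), u)
        entry = {
            "age": float(alpha),
            "template": ImageGrid(t_alpha.data[0, 0].astype(float), template.spacing, template.affine),
            "phi": VectorField(u.data[0].astype(float), "deformation", template.spacing, template.affine),
        }
        if tracker is not None:
            v_hat = Tensor(tracker.combine(v.data[0], float(alpha))[None])
            u_hat = integrate_velocity(v_hat, steps, upsample=vf)
            t_hat = warp_image(Tensor(t_data), u_hat)
            entry["template_adj"] = ImageGrid(
                t_hat.data[0, 0].astype(float), template.spacing, template.affine
            )
            entry["phi_adj"] = VectorField(
                u_hat.data[0].astype(float), "deformation", template.spacing, template.affine
            )
        results.append(entry)
    return results
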