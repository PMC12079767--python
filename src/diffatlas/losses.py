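"""The six training-loss components and their weighted total.

The total objective is

    L_total = g1*L_recon + g2*L_bend1 + g3*L_bend2
            + g4*L_disp1 + g5*L_disp2 + g6*L_mean

with defaults g = (1.0, 0.01, 0.01, 0.01, 0.01, 1.0). ``L_bend*`` is the
bending energy (mean squared Laplacian) of the Stage-1 / Stage-2 output
deformations, ``L_disp*`` the mean squared displacement magnitude, and
``L_mean`` the discrepancy between the conditional template and its
mean-adjusted counterpart.

These numpy implementations are the reference used in evaluation and tests;
the trainer computes the same quantities through the autodiff graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import ImageGrid, VectorField

__all__ = [
    "DEFAULT_WEIGHTS",
    "LossBundle",
    "bending_energy",
    "displacement_magnitude",
    "recon_mse",
    "mean_consistency_loss",
    "total_loss",
]

#: Default loss weights (gamma_1 ... gamma_6).
DEFAULT_WEIGHTS: tuple[float, ...] = (1.0, 0.01, 0.01, 0.01, 0.01, 1.0)


def bending_energy(phi: VectorField) -> float:
    """Mean over interior voxels of the squared Laplacian of the displacement.

    Computed on the displacement ``u`` rather than the full map ``phi = id + u``;
    the two are identical because the Laplacian of the identity map vanishes.
    Affine fields (translation, rotation, scaling) score zero. Borders are
    excluded: one-sided second differences are noisy.
    """
    if any(n < 3 for n in phi.spatial_shape):
        raise ValueError("grid too small for second differences (need >= 3 per axis)")
    u = phi.data.astype(float)
    d = phi.ndim
    lap = np.zeros_like(u)
    for axis in range(1, d + 1):
        lap += np.diff(u, n=2, axis=axis, prepend=np.take(u, [0], axis=axis), append=np.take(u, [-1], axis=axis))
    interior = (slice(None),) + (slice(1, -1),) * d
    lap_int = lap[interior]
    return float(np.mean(np.sum(lap_int**2, axis=0)))


def displacement_magnitude(phi: VectorField) -> float:
    """Mean over all voxels of the squared displacement magnitude ``|u(x)|^2``."""
    u = phi.data.astype(float)
    return float(np.mean(np.sum(u**2, axis=0)))


def _check_same_grid(a: ImageGrid, b: ImageGrid) -> None:
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")


def recon_mse(pred: ImageGrid, target: ImageGrid) -> float:
    """Mean squared intensity difference between predicted and true scans."""
    _check_same_grid(pred, target)
    return float(np.mean((pred.data.astype(float) - target.data.astype(float)) ** 2))


def mean_consistency_loss(t_alpha: ImageGrid, t_alpha_hat: ImageGrid, kind: str = "mse") -> float:
    """Discrepancy between a conditional template and its mean-adjusted version.

    ``kind="mse"`` (default) is the squared form used in the total loss;
    ``kind="l1"`` is exposed as an alternative absolute-difference reading.
    """
    _check_same_grid(t_alpha, t_alpha_hat)
    diff = t_alpha.data.astype(float) - t_alpha_hat.data.astype(float)
    if kind == "mse":
        return float(np.mean(diff**2))
    if kind == "l1":
        return float(np.mean(np.abs(diff)))
    raise ValueError(f"kind must be 'mse' or 'l1', got {kind!r}")


@dataclass
class LossBundle:
    """The six loss components, their weights, and the weighted total."""

    recon: float = 0.0
    bend1: float = 0.0
    bend2: float = 0.0
    disp1: float = 0.0
    disp2: float = 0.0
    mean: float = 0.0
    weights: tuple[float, ...] = field(default_factory=lambda: DEFAULT_WEIGHTS)

    def __post_init__(self) -> None:
        if len(self.weights) != 6:
            raise ValueError("expected six loss weights")

    @property
    def components(self) -> tuple[float, ...]:
        return (self.recon, self.bend1, self.bend2, self.disp1, self.disp2, self.mean)

    @property
    def total(self) -> float:
        return total_loss(self)


def total_loss(bundle: LossBundle) -> float:
    """Weighted sum of the six components."""
    comps = np.asarray(bundle.components, dtype=float)
    w = np.asarray(bundle.weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("loss weights must be non-negative")
    if not (np.all(np.isfinite(comps)) and np.all(np.isfinite(w))):
        raise ValueError("loss components and weights must be finite")
    return float(comps @ w)
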