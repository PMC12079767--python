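"""Differentiable spatial-transformer operations on batched tensors.

These mirror the numpy geometry in :mod:`diffatlas.diffeo` (same displacement
convention, scaling-and-squaring scheme and border clamping) but run inside
the autodiff graph so the networks can be trained through them. Tests assert
agreement between the two routes.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, bilinear_upsample2d, grid_sample2d

__all__ = [
    "base_coords",
    "integrate_velocity",
    "warp_image",
    "upsample_velocity",
    "mse",
    "bending_energy_t",
    "displacement_magnitude_t",
]


def base_coords(batch: int, shape: tuple[int, int], dtype=np.float32) -> Tensor:
    """Constant identity coordinate grid of shape (B, 2, H, W)."""
    h, w = shape
    yy, xx = np.meshgrid(np.arange(h, dtype=dtype), np.arange(w, dtype=dtype), indexing="ij")
    grid = np.stack([yy, xx], axis=0)
    return Tensor(np.broadcast_to(grid, (batch, 2, h, w)).copy())


def integrate_velocity(v: Tensor, steps: int = 7, upsample: int = 1) -> Tensor:
    """Scaling-and-squaring flow of a batched stationary velocity field.

    ``v``: (B, 2, H, W) in voxel units; returns the displacement of the
    unit-time deformation. With ``upsample > 1`` the integration runs on the
    native (e.g. half-resolution) velocity grid and the resulting
    displacement is bilinearly upsampled and rescaled to the full grid —
    the usual cost saving for downsampled velocity fields.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    b, d, h, w = v.shape
    if d != 2:
        raise ValueError("integrate_velocity expects 2-D fields (B, 2, H, W)")
    base = base_coords(b, (h, w), dtype=v.data.dtype)
    u = v * float(2.0 ** (-steps))
    for _ in range(steps):
        u = u + grid_sample2d(u, base + u)
    if upsample > 1:
        u = upsample_velocity(u, upsample)
    return u


def warp_image(img: Tensor, u: Tensor) -> Tensor:
    """Warp (B, C, H, W) images by displacement ``u``: out(x) = img(x + u(x))."""
    b = img.shape[0]
    base = base_coords(b, img.shape[2:], dtype=img.data.dtype)
    return grid_sample2d(img, base + u)


def upsample_velocity(v_half: Tensor, factor: int = 2) -> Tensor:
    """Upsample a half-resolution velocity field, rescaling voxel units."""
    return bilinear_upsample2d(v_half, factor) * float(factor)


def mse(a: Tensor, b: Tensor) -> Tensor:
    return (a - b).square().mean()


def bending_energy_t(u: Tensor) -> Tensor:
    """Batched differentiable analogue of :func:`diffatlas.losses.bending_energy`."""
    b, d, h, w = u.shape
    c = (slice(None), slice(None))
    inner = u.crop(c + (slice(1, -1), slice(1, -1)))
    lap = (
        u.crop(c + (slice(2, None), slice(1, -1)))
        + u.crop(c + (slice(None, -2), slice(1, -1)))
        + u.crop(c + (slice(1, -1), slice(2, None)))
        + u.crop(c + (slice(1, -1), slice(None, -2)))
        - 4.0 * inner
    )
    # mean over voxels of the squared Laplacian summed over components
    return lap.square().mean() * float(d)


def displacement_magnitude_t(u: Tensor) -> Tensor:
    """Batched differentiable analogue of mean squared displacement magnitude."""
    d = u.shape[1]
    return u.square().mean() * float(d)
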