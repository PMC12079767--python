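"""Stationary-velocity-field geometry: integration, warping, composition,
and Jacobian-determinant analysis.

A deformation ``phi`` is represented by its displacement ``u`` (voxel units),
``phi(x) = x + u(x)``. The unit-time flow of a stationary velocity field ``v``
is obtained by scaling and squaring: an Euler step ``u_0 = v / 2**steps``
followed by ``steps`` self-compositions. Out-of-bounds samples clamp to the
border voxel by default (switchable to zero padding), which avoids zero-halo
artefacts when warping templates.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import map_coordinates

from .grids import ImageGrid, VectorField, identity_grid

__all__ = [
    "integrate_svf",
    "warp",
    "compose",
    "jacobian_determinant",
]

_BOUNDARY_MODES = {"border": "nearest", "zero": "constant"}


def _check_boundary(boundary: str) -> str:
    if boundary not in _BOUNDARY_MODES:
        raise ValueError(f"boundary must be one of {sorted(_BOUNDARY_MODES)}, got {boundary!r}")
    return _BOUNDARY_MODES[boundary]


def _sample_channels(data: np.ndarray, coords: np.ndarray, order: int, boundary: str) -> np.ndarray:
    """Sample each leading channel of ``data`` at ``coords`` (shape (d, *grid))."""
    mode = _check_boundary(boundary)
    return np.stack(
        [map_coordinates(c, coords, order=order, mode=mode, cval=0.0) for c in data],
        axis=0,
    )


def integrate_svf(v: VectorField, steps: int = 7, boundary: str = "border") -> VectorField:
    """Integrate a stationary velocity field to its unit-time deformation.

    Parameters
    ----------
    v:
        Velocity field in voxel units.
    steps:
        Number of scaling-and-squaring operations (>= 1).

    Returns
    -------
    VectorField
        Deformation (displacement from identity) ``phi(x, 1)``.
    """
    if v.role != "velocity":
        raise ValueError("integrate_svf expects a velocity-role field")
    if steps < 1:
        raise ValueError(f"steps must be >= 1, got {steps}")
    if not np.all(np.isfinite(v.data)):
        raise ValueError("velocity field contains non-finite values")

    if not np.any(v.data):
        # Zero field: exact identity, bypass interpolation entirely.
        return VectorField(np.zeros_like(v.data, dtype=float), "deformation", v.spacing, v.affine)

    u = v.data.astype(float) / (2.0**steps)
    base = identity_grid(v.spatial_shape)
    for _ in range(steps):
        coords = base + u
        u = u + _sample_channels(u, coords, order=1, boundary=boundary)
    return VectorField(u, "deformation", v.spacing, v.affine)


def warp(
    img: ImageGrid,
    phi: VectorField,
    mode: str = "linear",
    boundary: str = "border",
) -> ImageGrid:
    """Resample ``img`` through deformation ``phi``: ``out(x) = img(phi(x))``.

    ``mode="linear"`` uses (bi/tri)linear interpolation; ``mode="nearest"`` is
    for label maps.
    """
    if phi.role != "deformation":
        raise ValueError("warp expects a deformation-role field")
    if not phi.same_grid(img):
        raise ValueError(f"grid mismatch: image {img.shape} vs field {phi.spatial_shape}")
    orders = {"linear": 1, "nearest": 0}
    if mode not in orders:
        raise ValueError(f"mode must be 'linear' or 'nearest', got {mode!r}")
    coords = identity_grid(img.shape) + phi.data
    out = map_coordinates(
        img.data.astype(float, copy=False),
        coords,
        order=orders[mode],
        mode=_check_boundary(boundary),
        cval=0.0,
    )
    return ImageGrid(out, img.spacing, img.affine)


def compose(phi_outer: VectorField, phi_inner: VectorField, boundary: str = "border") -> VectorField:
    """Compose two deformations: ``result(x) = phi_outer(phi_inner(x))``.

    In displacement form ``u(x) = u_inner(x) + u_outer(x + u_inner(x))``, with
    the outer displacement resampled by linear interpolation.
    """
    if phi_outer.role != "deformation" or phi_inner.role != "deformation":
        raise ValueError("compose expects deformation-role fields")
    if not phi_outer.same_grid(phi_inner):
        raise ValueError("grid mismatch between composed deformations")
    coords = identity_grid(phi_inner.spatial_shape) + phi_inner.data
    u = phi_inner.data + _sample_channels(phi_outer.data.astype(float), coords, order=1, boundary=boundary)
    return VectorField(u, "deformation", phi_outer.spacing, phi_outer.affine)


def jacobian_determinant(phi: VectorField) -> ImageGrid:
    """Per-voxel determinant of the Jacobian of ``phi = id + u``.

    The gradient of the full map is ``I + grad(u)``; ``grad(u)`` uses central
    differences at interior voxels and one-sided differences at the borders.
    Identity deformations therefore yield exactly 1 everywhere.
    """
    if phi.role != "deformation":
        raise ValueError("jacobian_determinant expects a deformation-role field")
    d = phi.ndim
    if any(n < 3 for n in phi.spatial_shape):
        raise ValueError(f"grid {phi.spatial_shape} too small for Jacobian (need >= 3 per axis)")
    # J[i, j] = d phi_i / d x_j = delta_ij + d u_i / d x_j
    jac = np.empty((d, d) + phi.spatial_shape)
    for i in range(d):
        grads = np.gradient(phi.data[i].astype(float), edge_order=1)
        for j in range(d):
            jac[i, j] = grads[j] + (1.0 if i == j else 0.0)
    # det over the leading (d, d) axes
    det = np.linalg.det(np.moveaxis(jac, (0, 1), (-2, -1)))
    return ImageGrid(det, phi.spacing, phi.affine)
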