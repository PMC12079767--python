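"""Image and vector-field containers.

Everything downstream operates in voxel space on 0-based indices: images are
assumed to be affinely pre-aligned, so the world affine is carried only as
metadata. Deformations are stored as *displacement from identity* in voxel
units, i.e. ``phi(x) = x + u(x)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageGrid", "VectorField", "identity_grid"]


def _default_affine() -> np.ndarray:
    return np.eye(4)


@dataclass
class ImageGrid:
    """A scalar intensity volume on a regular 2-D or 3-D grid.

    Parameters
    ----------
    data:
        Scalar intensities, shape ``(H, W)`` or ``(D, H, W)``.
    spacing:
        Per-axis voxel size in mm (defaults to isotropic 1 mm).
    affine:
        Voxel-to-world transform, metadata only.
    """

    data: np.ndarray
    spacing: np.ndarray | None = None
    affine: np.ndarray = field(default_factory=_default_affine)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (2, 3):
            raise ValueError(f"ImageGrid expects 2-D or 3-D data, got {self.data.ndim}-D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("ImageGrid intensities must be finite")
        if self.spacing is None:
            self.spacing = np.ones(self.data.ndim)
        self.spacing = np.asarray(self.spacing, dtype=float)
        if self.spacing.shape != (self.data.ndim,):
            raise ValueError("spacing must have one entry per spatial axis")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be strictly positive")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def same_grid(self, other: "ImageGrid | VectorField") -> bool:
        return self.shape == tuple(other.spatial_shape if isinstance(other, VectorField) else other.shape)

    def copy(self) -> "ImageGrid":
        return ImageGrid(self.data.copy(), self.spacing.copy(), self.affine.copy())


@dataclass
class VectorField:
    """A per-voxel vector field on the same grid as an :class:`ImageGrid`.

    ``data`` has shape ``(d, *spatial)`` with ``d`` equal to the spatial
    dimensionality. ``role`` is either ``"velocity"`` (a stationary velocity
    field) or ``"deformation"`` (displacement ``u`` with ``phi = id + u``).
    Components are in voxel units.
    """

    data: np.ndarray
    role: str = "velocity"
    spacing: np.ndarray | None = None
    affine: np.ndarray = field(default_factory=_default_affine)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4):
            raise ValueError("VectorField expects (d, H, W) or (d, D, H, W) data")
        d = self.data.shape[0]
        if d != self.data.ndim - 1:
            raise ValueError(
                f"vector dimensionality {d} must equal spatial dimensionality {self.data.ndim - 1}"
            )
        if self.role not in ("velocity", "deformation"):
            raise ValueError(f"unknown role {self.role!r}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("VectorField components must be finite")
        if self.spacing is None:
            self.spacing = np.ones(d)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def ndim(self) -> int:
        """Spatial dimensionality."""
        return self.data.ndim - 1

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.data.shape[1:]

    def same_grid(self, other: "VectorField | ImageGrid") -> bool:
        shape = other.spatial_shape if isinstance(other, VectorField) else other.shape
        return self.spatial_shape == tuple(shape)

    def copy(self) -> "VectorField":
        return VectorField(self.data.copy(), self.role, self.spacing.copy(), self.affine.copy())


def identity_grid(shape: tuple[int, ...]) -> np.ndarray:
    """Coordinate grid of shape ``(d, *shape)`` with ``grid[i] = x_i``."""
    axes = [np.arange(n, dtype=float) for n in shape]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=0)
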