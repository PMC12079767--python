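"""Small-deformation SVF registration by direct velocity optimization.

Used for the pre- vs post-registration structural-similarity comparison
between adjacent conditional templates: a stationary velocity field is
optimized by gradient descent (Adam, zero weight decay) on mean squared
intensity difference plus a bending-energy penalty, then integrated by
scaling and squaring. This is an internal small-deformation registration,
not an external registration toolkit.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor
from .grids import ImageGrid, VectorField
from .nnet import AdamW
from .spatial import bending_energy_t, integrate_velocity, mse, warp_image

__all__ = ["register_svf"]


def register_svf(
    moving: ImageGrid,
    fixed: ImageGrid,
    iterations: int = 150,
    lr: float = 0.2,
    bending_weight: float = 0.05,
    steps: int = 7,
) -> tuple[ImageGrid, VectorField]:
    """Register ``moving`` onto ``fixed``; returns (warped moving, deformation).

    Deterministic: the velocity field is initialized to zero and optimized
    with a fixed schedule.
    """
    if moving.shape != fixed.shape:
        raise ValueError(f"grid mismatch: {moving.shape} vs {fixed.shape}")
    mov = Tensor(np.asarray(moving.data, dtype=np.float32)[None, None])
    fix = Tensor(np.asarray(fixed.data, dtype=np.float32)[None, None])
    v = Tensor(np.zeros((1, 2, *moving.shape), dtype=np.float32), requires_grad=True)
    opt = AdamW([v], lr=lr, weight_decay=0.0)
    for _ in range(iterations):
        u = integrate_velocity(v, steps)
        loss = mse(warp_image(mov, u), fix) + bending_energy_t(u) * bending_weight
        opt.zero_grad()
        loss.backward()
        opt.step()
    u = integrate_velocity(v, steps)
    warped = warp_image(mov, u)
    return (
        ImageGrid(warped.data[0, 0].astype(float), moving.spacing, moving.affine),
        VectorField(u.data[0].astype(float), "deformation", moving.spacing, moving.affine),
    )
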