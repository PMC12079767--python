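"""Condition-local mean-deformation tracking with soft binning.

The conditioning axis (age) is divided into bins with centres ``c_1 < ... < c_K``.
Each bin stores a running mean ``vbar_k`` of Stage-2 velocity fields, updated
with an exponential moving average whose rate is modulated by a triangular
soft-binning weight: a sample of age ``alpha`` contributes to the two nearest
bins with weights that sum to one,

    vbar_k <- (1 - q_k) * vbar_k + q_k * v,   q_k = lam * zeta_k(alpha).

The tracked means are pure state: no gradients flow through them. They are
added back onto Stage-1 velocities (``combine``) to build the mean-adjusted
conditional template whose agreement with the plain conditional template is
penalised during training, keeping conditional templates centred in the
distribution of Stage-2 deformations.
"""

from __future__ import annotations

import numpy as np

__all__ = ["BinTracker"]


class BinTracker:
    """Per-bin tracked mean velocity fields over a scalar conditioning axis.

    Parameters
    ----------
    centres:
        Strictly increasing bin centres (e.g. ages ``[50, 55, ..., 90]``).
    field_shape:
        Shape ``(d, *spatial)`` of the tracked velocity fields.
    lam:
        Global EMA update rate, ``0 < lam < 1`` (default 0.1).
    """

    def __init__(self, centres, field_shape, lam: float = 0.1, dtype=np.float32):
        centres = np.asarray(centres, dtype=float)
        if centres.ndim != 1 or len(centres) < 2:
            raise ValueError("need at least two bin centres")
        if np.any(np.diff(centres) <= 0):
            raise ValueError("bin centres must be strictly increasing")
        if not 0.0 < lam < 1.0:
            raise ValueError(f"lam must lie in (0, 1), got {lam}")
        self.centres = centres
        self.lam = float(lam)
        self.field_shape = tuple(field_shape)
        self.means = np.zeros((len(centres),) + self.field_shape, dtype=dtype)

    @property
    def n_bins(self) -> int:
        return len(self.centres)

    # -- soft binning -------------------------------------------------------

    def bin_weight(self, k: int, alpha: float) -> float:
        """Triangular weight of bin ``k`` for conditioning value ``alpha``.

        1 at the bin centre, linear to 0 at the neighbouring centres, 0
        beyond. Values of ``alpha`` outside the covered range clamp to the
        nearest edge bin (weight 1 there).
        """
        if not 0 <= k < self.n_bins:
            raise IndexError(f"bin index {k} out of range [0, {self.n_bins})")
        if not np.isfinite(alpha):
            raise ValueError("alpha must be finite")
        c = self.centres
        alpha = float(np.clip(alpha, c[0], c[-1]))
        ck = c[k]
        if alpha == ck:
            return 1.0
        if alpha < ck:
            lo = c[k - 1] if k > 0 else None
            if lo is None or alpha <= lo:
                return 0.0
            return float((alpha - lo) / (ck - lo))
        hi = c[k + 1] if k < self.n_bins - 1 else None
        if hi is None or alpha >= hi:
            return 0.0
        return float((hi - alpha) / (hi - ck))

    def neighbours(self, alpha: float) -> tuple[int, int]:
        """Indices ``(k, k+1)`` of the bins bracketing ``alpha`` (clamped)."""
        c = self.centres
        alpha = float(np.clip(alpha, c[0], c[-1]))
        k = int(np.searchsorted(c, alpha, side="right") - 1)
        k = min(max(k, 0), self.n_bins - 2)
        return k, k + 1

    # -- state update and use ----------------------------------------------

    def update(self, v: np.ndarray, alpha: float) -> None:
        """EMA-update the two bins nearest to ``alpha`` with velocity ``v``."""
        v = np.asarray(v)
        if v.shape != self.field_shape:
            raise ValueError(f"velocity shape {v.shape} != tracker grid {self.field_shape}")
        k, k1 = self.neighbours(alpha)
        for idx in (k, k1):
            q = self.lam * self.bin_weight(idx, alpha)
            if q > 0.0:
                self.means[idx] *= 1.0 - q
                self.means[idx] += q * v.astype(self.means.dtype, copy=False)

    def combine(self, v_alpha: np.ndarray, alpha: float) -> np.ndarray:
        """Mean-adjusted velocity: ``v_alpha + zeta_k*vbar_k + zeta_{k+1}*vbar_{k+1}``."""
        v_alpha = np.asarray(v_alpha)
        if v_alpha.shape != self.field_shape:
            raise ValueError(f"velocity shape {v_alpha.shape} != tracker grid {self.field_shape}")
        return v_alpha + self.mean_adjustment(alpha).astype(v_alpha.dtype, copy=False)

    def mean_adjustment(self, alpha: float) -> np.ndarray:
        """The tracked-mean contribution ``zeta_k*vbar_k + zeta_{k+1}*vbar_{k+1}``."""
        k, k1 = self.neighbours(alpha)
        return self.bin_weight(k, alpha) * self.means[k] + self.bin_weight(k1, alpha) * self.means[k1]

    # -- (de)serialization --------------------------------------------------

    def state_dict(self) -> dict:
        return {
            "centres": self.centres.copy(),
            "lam": self.lam,
            "means": self.means.copy(),
        }

    @classmethod
    def from_state(cls, state: dict) -> "BinTracker":
        means = np.asarray(state["means"])
        tracker = cls(state["centres"], means.shape[1:], float(state["lam"]), dtype=means.dtype)
        tracker.means = means.copy()
        return tracker
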