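"""Trainable layers and the AdamW optimizer built on the autodiff core."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, avg_pool2d, bilinear_upsample2d, concat, conv2d, zero_upsample2d

__all__ = ["Module", "Linear", "Conv2d", "UpConv2d", "AdamW"]


class Module:
    """Minimal parameter container with named-parameter traversal."""

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out: list[tuple[str, Tensor]] = []
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Tensor) and val.requires_grad:
                out.append((key, val))
            elif isinstance(val, Module):
                out.extend(val.named_parameters(f"{key}."))
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(f"{key}.{i}."))
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out.append((f"{key}.{i}", item))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"parameter name mismatch: {sorted(missing)}")
        for k, p in params.items():
            arr = np.asarray(state[k], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()


def _he_init(rng: np.random.Generator, shape: tuple, fan_in: int, dtype=np.float32) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, zero_init: bool = False):
        if zero_init:
            w = np.zeros((n_in, n_out), dtype=np.float32)
        else:
            w = _he_init(rng, (n_in, n_out), n_in)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(n_out, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    """Stride-1 'same' convolution with odd kernel size."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator, zero_init: bool = False):
        if zero_init:
            w = np.zeros((c_out, c_in, k, k), dtype=np.float32)
        else:
            w = _he_init(rng, (c_out, c_in, k, k), c_in * k * k)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias)


class UpConv2d(Module):
    """Factor-2 transposed convolution realised as zero-insertion + conv."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        self.conv = Conv2d(c_in, c_out, k, rng)

    def __call__(self, x: Tensor) -> Tensor:
        # Scale by 4 so the expected response matches a dense input
        # (three quarters of the zero-stuffed samples are zero).
        return self.conv(zero_upsample2d(x, 2) * 4.0)


class AdamW(Module):
    """Adam with decoupled weight decay.

    Defaults follow common practice for this family of registration networks:
    ``betas=(0.9, 0.999)`` and ``weight_decay=1e-2``.
    """

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 1e-2,
    ):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = float(eps)
        self.weight_decay = float(weight_decay)
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                g = np.zeros_like(p.data)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * (
                mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p.data
            )

    def state_dict(self) -> dict:
        return {
            "t": self.t,
            "m": [m.copy() for m in self.m],
            "v": [v.copy() for v in self.v],
        }

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        self.m = [np.asarray(m) for m in state["m"]]
        self.v = [np.asarray(v) for v in state["v"]]


# re-export the functional pieces networks use alongside layers
__all__ += ["avg_pool2d", "bilinear_upsample2d", "concat"]
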