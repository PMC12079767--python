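"""A compact reverse-mode automatic-differentiation core on numpy arrays.

Implements exactly the operator set the two-stage template network needs:
elementwise arithmetic, matrix multiplication, reductions, ReLU-family
activations, reshape/concat/crop, stride-1 2-D convolution (im2col),
zero-insertion upsampling (the transposed-convolution building block),
average pooling, and bilinear grid sampling with gradients with respect to
both the source image and the sampling coordinates (the spatial transformer).

Tensors hold float arrays; ``backward()`` runs reverse topological order.
Float32 is used for training; gradcheck-style tests run the same ops in
float64.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "conv2d",
    "avg_pool2d",
    "zero_upsample2d",
    "grid_sample2d",
    "bilinear_upsample2d",
]


class Tensor:
    """A node in the computation graph wrapping a numpy array."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        if self.data.dtype.kind != "f":
            self.data = self.data.astype(np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing -----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Reverse-mode sweep seeding ``self`` with ``grad`` (default: ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- elementwise arithmetic --------------------------------------------

    def __add__(self, other):
        return _binary(self, other, lambda a, b: a + b, lambda g, a, b: g, lambda g, a, b: g)

    __radd__ = __add__

    def __sub__(self, other):
        return _binary(self, other, lambda a, b: a - b, lambda g, a, b: g, lambda g, a, b: -g)

    def __rsub__(self, other):
        return _wrap(other) - self

    def __mul__(self, other):
        return _binary(self, other, lambda a, b: a * b, lambda g, a, b: g * b, lambda g, a, b: g * a)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            raise NotImplementedError("divide by a Tensor is not needed; multiply by .reciprocal")
        return self * (1.0 / other)

    def square(self) -> "Tensor":
        return self * self

    def abs(self) -> "Tensor":
        out = _node(np.abs(self.data), (self,))
        if out.requires_grad:
            sign = np.sign(self.data)

            def bw(g, t=self):
                t._accumulate(g * sign)

            out._backward = bw
        return out

    def exp(self) -> "Tensor":
        val = np.exp(self.data)
        out = _node(val, (self,))
        if out.requires_grad:

            def bw(g, t=self):
                t._accumulate(g * val)

            out._backward = bw
        return out

    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = _node(np.where(mask, self.data, 0.0), (self,))
        if out.requires_grad:

            def bw(g, t=self):
                t._accumulate(g * mask)

            out._backward = bw
        return out

    def leaky_relu(self, slope: float = 0.2) -> "Tensor":
        mask = self.data > 0
        out = _node(np.where(mask, self.data, slope * self.data), (self,))
        if out.requires_grad:

            def bw(g, t=self):
                t._accumulate(g * np.where(mask, 1.0, slope))

            out._backward = bw
        return out

    # -- reductions ---------------------------------------------------------

    def sum(self) -> "Tensor":
        out = _node(np.asarray(self.data.sum()), (self,))
        if out.requires_grad:

            def bw(g, t=self):
                t._accumulate(np.broadcast_to(g, t.data.shape).astype(t.data.dtype))

            out._backward = bw
        return out

    def mean(self) -> "Tensor":
        return self.sum() * np.asarray(1.0 / self.data.size, dtype=self.data.dtype)

    # -- shape surgery ------------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        orig = self.data.shape
        out = _node(self.data.reshape(*shape), (self,))
        if out.requires_grad:

            def bw(g, t=self):
                t._accumulate(g.reshape(orig))

            out._backward = bw
        return out

    def crop(self, slices: tuple) -> "Tensor":
        """Slice; the backward pass zero-pads back to the original shape."""
        out = _node(self.data[slices], (self,))
        if out.requires_grad:

            def bw(g, t=self):
                full = np.zeros_like(t.data)
                full[slices] = g
                t._accumulate(full)

            out._backward = bw
        return out

    # -- linear algebra ------------------------------------------------------

    def matmul(self, other: "Tensor") -> "Tensor":
        a, b = self, other
        out = _node(a.data @ b.data, (a, b))
        if out.requires_grad:

            def bw(g):
                if a.requires_grad or a._parents:
                    a._accumulate(g @ b.data.T)
                if b.requires_grad or b._parents:
                    b._accumulate(a.data.T @ g)

            out._backward = bw
        return out

    def __matmul__(self, other):
        return self.matmul(other)


def _wrap(x) -> Tensor:
    if isinstance(x, Tensor):
        return x
    is_array = isinstance(x, np.ndarray)
    arr = np.asarray(x)
    if arr.ndim == 0 and not is_array:
        # Python scalars as float32 so they never upcast a float32 graph;
        # numpy promotion keeps float64 graphs in float64. Explicit 0-d
        # numpy arrays keep their dtype.
        arr = arr.astype(np.float32)
    return Tensor(arr)


def _needs_grad(*tensors: Tensor) -> bool:
    return any(t.requires_grad or t._parents for t in tensors)


def _node(data: np.ndarray, parents: tuple[Tensor, ...]) -> Tensor:
    out = Tensor(data)
    if _needs_grad(*parents):
        out.requires_grad = True
        out._parents = parents
    return out


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a gradient back to ``shape`` after numpy broadcasting."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def _binary(a, b, fwd, bwd_a, bwd_b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out = _node(fwd(a.data, b.data), (a, b))
    if out.requires_grad:

        def bw(g):
            if a.requires_grad or a._parents:
                a._accumulate(_unbroadcast(bwd_a(g, a.data, b.data), a.data.shape))
            if b.requires_grad or b._parents:
                b._accumulate(_unbroadcast(bwd_b(g, a.data, b.data), b.data.shape))

        out._backward = bw
    return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    out = _node(np.concatenate(datas, axis=axis), tuple(tensors))
    if out.requires_grad:
        sizes = [d.shape[axis] for d in datas]
        splits = np.cumsum(sizes)[:-1]

        def bw(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad or t._parents:
                    t._accumulate(piece)

        out._backward = bw
    return out


# -- convolution (stride 1, symmetric zero padding) ---------------------------


def _windows(x: np.ndarray, kh: int, kw: int, pad: int) -> np.ndarray:
    """Zero-padded sliding windows, shape (B, C, H, W, kh, kw) (a view)."""
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    return np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))


def _correlate(x: np.ndarray, w: np.ndarray, pad: int) -> np.ndarray:
    """'same' cross-correlation of (B, C, H, W) with (O, C, kh, kw)."""
    win = _windows(x, w.shape[2], w.shape[3], pad)
    # (B, C, H, W, kh, kw) x (O, C, kh, kw) -> (B, H, W, O)
    y = np.tensordot(win, w, axes=([1, 4, 5], [1, 2, 3]))
    return y.transpose(0, 3, 1, 2)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Stride-1 'same' 2-D convolution (cross-correlation) over (B, C, H, W).

    ``weight`` has shape (out_ch, in_ch, kh, kw) with odd kernel sizes.
    The input gradient uses the convolution identity (correlation of the
    output gradient with the spatially flipped, channel-transposed kernel)
    rather than an explicit patch-scatter.
    """
    b, c, h, w = x.data.shape
    oc, ic, kh, kw = weight.data.shape
    if ic != c:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight expects {ic}")
    if kh % 2 == 0 or kw % 2 == 0:
        raise ValueError("conv2d requires odd kernel sizes")
    pad = kh // 2
    y = _correlate(x.data, weight.data, pad)
    if bias is not None:
        y = y + bias.data[None, :, None, None]
    y = np.ascontiguousarray(y)
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = _node(y, parents)
    if out.requires_grad:

        def bw(g):
            if weight.requires_grad or weight._parents:
                win = _windows(x.data, kh, kw, pad)
                # (B, O, H, W) x (B, C, H, W, kh, kw) -> (O, C, kh, kw)
                gw = np.tensordot(g, win, axes=([0, 2, 3], [0, 2, 3]))
                weight._accumulate(np.ascontiguousarray(gw))
            if bias is not None and (bias.requires_grad or bias._parents):
                bias._accumulate(g.sum(axis=(0, 2, 3)))
            if x.requires_grad or x._parents:
                w_flip = weight.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
                x._accumulate(_correlate(g, np.ascontiguousarray(w_flip), pad).astype(x.data.dtype))

        out._backward = bw
    return out


def avg_pool2d(x: Tensor, k: int = 2) -> Tensor:
    """Non-overlapping k*k average pooling; spatial sizes must divide by k."""
    b, c, h, w = x.data.shape
    if h % k or w % k:
        raise ValueError(f"avg_pool2d: spatial size ({h},{w}) not divisible by {k}")
    y = x.data.reshape(b, c, h // k, k, w // k, k).mean(axis=(3, 5))
    out = _node(y, (x,))
    if out.requires_grad:

        def bw(g):
            gx = np.repeat(np.repeat(g, k, axis=2), k, axis=3) / (k * k)
            x._accumulate(gx.astype(x.data.dtype))

        out._backward = bw
    return out


def zero_upsample2d(x: Tensor, k: int = 2) -> Tensor:
    """Insert ``k-1`` zeros between samples along both spatial axes.

    Followed by a convolution this realises a stride-``k`` transposed
    convolution; the backward pass is a strided slice.
    """
    b, c, h, w = x.data.shape
    y = np.zeros((b, c, h * k, w * k), dtype=x.data.dtype)
    y[:, :, ::k, ::k] = x.data
    out = _node(y, (x,))
    if out.requires_grad:

        def bw(g):
            x._accumulate(g[:, :, ::k, ::k])

        out._backward = bw
    return out


# -- bilinear sampling (spatial transformer) ----------------------------------


def grid_sample2d(src: Tensor, coords: Tensor) -> Tensor:
    """Bilinearly sample ``src`` (B, C, H, W) at ``coords`` (B, 2, H', W').

    ``coords[:, 0]`` are row positions and ``coords[:, 1]`` column positions in
    voxel units of ``src``. Out-of-range positions clamp to the border
    (replicate padding); their positional gradient is zero. Gradients flow to
    both the source image and the coordinates.
    """
    b, c, h, w = src.data.shape
    if coords.data.shape[0] != b or coords.data.shape[1] != 2:
        raise ValueError(f"coords must be (B, 2, H', W'), got {coords.data.shape}")
    _, _, ho, wo = coords.data.shape
    dt = src.data.dtype

    y = coords.data[:, 0]
    x = coords.data[:, 1]
    in_y = (y >= 0) & (y <= h - 1)
    in_x = (x >= 0) & (x <= w - 1)
    yc = np.clip(y, 0, h - 1)
    xc = np.clip(x, 0, w - 1)
    y0 = np.minimum(np.floor(yc), h - 2).astype(np.intp)
    x0 = np.minimum(np.floor(xc), w - 2).astype(np.intp)
    wy = (yc - y0).astype(dt)
    wx = (xc - x0).astype(dt)

    bidx = np.arange(b, dtype=np.intp)[:, None, None]
    flat = src.data.reshape(b, c, h * w)
    i00 = (y0 * w + x0)
    i01 = i00 + 1
    i10 = i00 + w
    i11 = i10 + 1

    # gather all four corners with one advanced-indexing call
    n = ho * wo
    idx4 = np.concatenate(
        [i00.reshape(b, n), i01.reshape(b, n), i10.reshape(b, n), i11.reshape(b, n)], axis=1
    )
    corners = flat[np.arange(b, dtype=np.intp)[:, None], :, idx4]  # (B, 4n, C)
    corners = corners.transpose(0, 2, 1).reshape(b, c, 4, ho, wo)
    c00, c01, c10, c11 = corners[:, :, 0], corners[:, :, 1], corners[:, :, 2], corners[:, :, 3]
    wy_ = wy[:, None]
    wx_ = wx[:, None]
    top = c00 * (1 - wx_) + c01 * wx_
    bot = c10 * (1 - wx_) + c11 * wx_
    val = top * (1 - wy_) + bot * wy_

    out = _node(val, (src, coords))
    if out.requires_grad:

        def bw(g):
            if src.requires_grad or src._parents:
                # One bincount over (batch, channel, voxel)-flattened indices:
                # far faster than repeated fancy-index scatter-adds.
                n = ho * wo
                chan = np.arange(c, dtype=np.intp)[None, :, None]
                base = (bidx * c + chan) * (h * w)  # (B, C, 1)
                gv = g.reshape(b, c, n)
                w00 = ((1 - wy) * (1 - wx)).reshape(b, 1, n)
                w01 = ((1 - wy) * wx).reshape(b, 1, n)
                w10 = (wy * (1 - wx)).reshape(b, 1, n)
                w11 = (wy * wx).reshape(b, 1, n)
                idx_all = np.concatenate(
                    [np.broadcast_to(base + i.reshape(b, 1, n), (b, c, n)).ravel() for i in (i00, i01, i10, i11)]
                )
                val_all = np.concatenate([(gv * wgt).ravel() for wgt in (w00, w01, w10, w11)])
                gflat = np.bincount(idx_all, weights=val_all, minlength=b * c * h * w)
                src._accumulate(gflat.reshape(src.data.shape).astype(dt))
            if coords.requires_grad or coords._parents:
                dvdy = (bot - top)  # (B, C, H', W')
                dvdx = (c01 - c00) * (1 - wy_) + (c11 - c10) * wy_
                gy = (g * dvdy).sum(axis=1) * in_y
                gx = (g * dvdx).sum(axis=1) * in_x
                coords._accumulate(np.stack([gy, gx], axis=1).astype(coords.data.dtype))

        out._backward = bw
    return out


def _up2_axis(x: np.ndarray, axis: int) -> np.ndarray:
    """Factor-2 linear upsampling along one axis (pixel-centre alignment).

    Output sample 2m sits a quarter-voxel below input m (weights 0.25/0.75
    on inputs m-1/m, edge-clamped); sample 2m+1 a quarter above (0.75/0.25
    on m/m+1).
    """
    x = np.moveaxis(x, axis, -1)
    n = x.shape[-1]
    lo = np.concatenate([x[..., :1], x[..., :-1]], axis=-1)  # x[m-1], clamped
    hi = np.concatenate([x[..., 1:], x[..., -1:]], axis=-1)  # x[m+1], clamped
    out = np.empty(x.shape[:-1] + (2 * n,), dtype=x.dtype)
    out[..., 0::2] = 0.25 * lo + 0.75 * x
    out[..., 1::2] = 0.75 * x + 0.25 * hi
    return np.moveaxis(out, -1, axis)


def _up2_axis_adjoint(g: np.ndarray, axis: int) -> np.ndarray:
    """Exact adjoint of :func:`_up2_axis`."""
    g = np.moveaxis(g, axis, -1)
    ge = g[..., 0::2]
    go = g[..., 1::2]
    out = 0.75 * ge + 0.75 * go
    out[..., :-1] += 0.25 * ge[..., 1:]  # x[m] feeds out[2(m+1)] with 0.25
    out[..., 1:] += 0.25 * go[..., :-1]  # x[m] feeds out[2(m-1)+1] with 0.25
    out[..., 0] += 0.25 * ge[..., 0]  # edge clamps
    out[..., -1] += 0.25 * go[..., -1]
    return np.moveaxis(out, -1, axis)


def bilinear_upsample2d(x: Tensor, k: int = 2) -> Tensor:
    """Bilinear upsampling by an integer factor (pixel-centre alignment).

    Factor 2 uses a fused separable kernel with an exact adjoint; other
    factors fall back to fixed-coordinate grid sampling.
    """
    b, c, h, w = x.data.shape
    if k == 2:
        y = _up2_axis(_up2_axis(x.data, 2), 3)
        out = _node(y, (x,))
        if out.requires_grad:

            def bw(g):
                x._accumulate(_up2_axis_adjoint(_up2_axis_adjoint(g, 3), 2).astype(x.data.dtype))

            out._backward = bw
        return out
    ho, wo = h * k, w * k
    # output pixel centres mapped into input voxel coordinates
    ys = (np.arange(ho, dtype=x.data.dtype) + 0.5) / k - 0.5
    xs = (np.arange(wo, dtype=x.data.dtype) + 0.5) / k - 0.5
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    coords = Tensor(np.broadcast_to(np.stack([yy, xx], axis=0), (b, 2, ho, wo)).copy())
    return grid_sample2d(x, coords)
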