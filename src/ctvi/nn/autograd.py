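"""Minimal reverse-mode automatic differentiation over numpy arrays.

A compact tape-based engine carrying exactly the operations the ventilation
synthesis networks need: 3D convolution, batch normalisation, ReLU/sigmoid,
2x max pooling, trilinear upsampling, the voxel-wise fusion arithmetic
(sum / product / maximum), channel concatenation and a masked mean-absolute
-error loss. Tensors are ``(channels, x, y, z)`` float32; batch size is
always one, matching the training regime of the synthesis task.

Everything is pure numpy, so results are bit-reproducible given fixed
parameter seeds.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "conv3d",
    "batch_norm",
    "relu",
    "sigmoid",
    "maxpool2",
    "upsample_trilinear",
    "add",
    "mul",
    "maximum",
    "concat",
    "mae_loss",
]


class Tensor:
    """A node in the computation graph: value, gradient, backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Reverse-accumulate gradients from this (scalar) tensor."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss tensor")
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def _track(*tensors: Tensor) -> bool:
    return any(t.requires_grad or t._parents for t in tensors)


def _make(data, parents, backward, track: bool) -> Tensor:
    if track:
        return Tensor(data, parents=parents, backward=backward)
    return Tensor(data)


# --------------------------------------------------------------------------
# convolution

def conv3d(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Same-padding 3D convolution; weight is (C_out, C_in, k, k, k).

    Implemented as k^3 shifted GEMMs, which keeps every matrix product
    contiguous and avoids materialising an im2col patch matrix.
    """
    c_out, c_in, k = weight.shape[0], weight.shape[1], weight.shape[2]
    if x.shape[0] != c_in:
        raise ValueError(f"conv3d: input has {x.shape[0]} channels, weight expects {c_in}")
    pad = k // 2
    d, h, w = x.shape[1:]
    xp = np.pad(x.data, ((0, 0),) + ((pad, pad),) * 3)
    wm = weight.data.reshape(c_out, c_in, k**3)
    shifts = []  # cache the contiguous shifted slabs for the weight gradient
    y = np.zeros((c_out, d * h * w), dtype=np.float32)
    o = 0
    for a in range(k):
        for b in range(k):
            for e in range(k):
                xs = np.ascontiguousarray(xp[:, a : a + d, b : b + h, e : e + w]).reshape(c_in, -1)
                shifts.append(xs)
                y += wm[:, :, o] @ xs
                o += 1
    if bias is not None:
        y += bias.data[:, None]
    y = y.reshape(c_out, d, h, w)
    track = _track(x, weight) or (bias is not None and _track(bias))

    def backward(gy: np.ndarray) -> None:
        g2 = gy.reshape(c_out, -1)
        if bias is not None and (bias.requires_grad or bias._parents):
            bias._accumulate(g2.sum(axis=1))
        need_w = weight.requires_grad or weight._parents
        need_x = x.requires_grad or x._parents
        if need_w:
            gw = np.empty_like(wm)
        if need_x:
            gxp = np.zeros_like(xp)
        o = 0
        for a in range(k):
            for b in range(k):
                for e in range(k):
                    if need_w:
                        gw[:, :, o] = g2 @ shifts[o].T
                    if need_x:
                        gxp[:, a : a + d, b : b + h, e : e + w] += (
                            wm[:, :, o].T @ g2
                        ).reshape(c_in, d, h, w)
                    o += 1
        if need_w:
            weight._accumulate(gw.reshape(weight.shape))
        if need_x:
            if pad:
                x._accumulate(gxp[:, pad:-pad, pad:-pad, pad:-pad])
            else:
                x._accumulate(gxp)

    parents = (x, weight) + ((bias,) if bias is not None else ())
    return _make(y, parents, backward, track)


# --------------------------------------------------------------------------
# normalisation / activations

def batch_norm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running: dict,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel normalisation over the spatial axes (batch size one).

    ``running`` holds 'mean' and 'var' arrays updated in training mode and
    used verbatim in eval mode.
    """
    c = x.shape[0]
    flat = x.data.reshape(c, -1)
    if training:
        mean = flat.mean(axis=1)
        var = flat.var(axis=1)
        running["mean"] = (1 - momentum) * running["mean"] + momentum * mean
        running["var"] = (1 - momentum) * running["var"] + momentum * var
    else:
        mean = running["mean"]
        var = running["var"]
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (flat - mean[:, None]) * inv[:, None]
    y = (gamma.data[:, None] * xhat + beta.data[:, None]).reshape(x.shape)
    track = _track(x, gamma, beta)

    def backward(gy: np.ndarray) -> None:
        g = gy.reshape(c, -1)
        if gamma.requires_grad or gamma._parents:
            gamma._accumulate((g * xhat).sum(axis=1))
        if beta.requires_grad or beta._parents:
            beta._accumulate(g.sum(axis=1))
        if x.requires_grad or x._parents:
            gxhat = g * gamma.data[:, None]
            if training:
                n = xhat.shape[1]
                dx = (
                    gxhat
                    - gxhat.mean(axis=1, keepdims=True)
                    - xhat * (gxhat * xhat).mean(axis=1, keepdims=True)
                ) * inv[:, None]
            else:
                dx = gxhat * inv[:, None]
            x._accumulate(dx.reshape(x.shape).astype(np.float32))

    return _make(y.astype(np.float32), (x, gamma, beta), backward, track)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    track = _track(x)

    def backward(gy: np.ndarray) -> None:
        if x.requires_grad or x._parents:
            x._accumulate(gy * mask)

    return _make(x.data * mask, (x,), backward, track)


def sigmoid(x: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-x.data))
    track = _track(x)

    def backward(gy: np.ndarray) -> None:
        if x.requires_grad or x._parents:
            x._accumulate(gy * y * (1.0 - y))

    return _make(y, (x,), backward, track)


# --------------------------------------------------------------------------
# resolution changes

def maxpool2(x: Tensor) -> Tensor:
    """2x2x2 max pooling with floor semantics (odd trailing planes dropped)."""
    c, d, h, w = x.shape
    d2, h2, w2 = d // 2, h // 2, w // 2
    if min(d2, h2, w2) < 1:
        raise ValueError(f"maxpool2: spatial shape {x.shape[1:]} too small")
    xc = x.data[:, : 2 * d2, : 2 * h2, : 2 * w2]
    blocks = xc.reshape(c, d2, 2, h2, 2, w2, 2).transpose(0, 1, 3, 5, 2, 4, 6)
    blocks = blocks.reshape(c, d2, h2, w2, 8)
    arg = blocks.argmax(axis=-1)
    y = np.take_along_axis(blocks, arg[..., None], axis=-1)[..., 0]
    track = _track(x)

    def backward(gy: np.ndarray) -> None:
        if not (x.requires_grad or x._parents):
            return
        gb = np.zeros((c, d2, h2, w2, 8), dtype=np.float32)
        np.put_along_axis(gb, arg[..., None], gy[..., None], axis=-1)
        gx = np.zeros_like(x.data)
        gx[:, : 2 * d2, : 2 * h2, : 2 * w2] = (
            gb.reshape(c, d2, h2, w2, 2, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3, 6)
            .reshape(c, 2 * d2, 2 * h2, 2 * w2)
        )
        x._accumulate(gx)

    return _make(y, (x,), backward, track)


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Dense 1D linear-interpolation operator, cell-centred convention."""
    m = np.zeros((n_out, n_in), dtype=np.float32)
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    t = (src - lo).astype(np.float32)
    m[np.arange(n_out), lo] += 1.0 - t
    m[np.arange(n_out), hi] += t
    return m


def upsample_trilinear(x: Tensor, target_shape) -> Tensor:
    """Trilinear resize to an arbitrary spatial shape (separable linear maps)."""
    mats = [
        _interp_matrix(int(t), int(s)) for t, s in zip(target_shape, x.shape[1:])
    ]
    y = np.einsum("ai,cijk->cajk", mats[0], x.data)
    y = np.einsum("bj,cajk->cabk", mats[1], y)
    y = np.einsum("ek,cabk->cabe", mats[2], y)
    track = _track(x)

    def backward(gy: np.ndarray) -> None:
        if not (x.requires_grad or x._parents):
            return
        g = np.einsum("ek,cabe->cabk", mats[2], gy)
        g = np.einsum("bj,cabk->cajk", mats[1], g)
        g = np.einsum("ai,cajk->cijk", mats[0], g)
        x._accumulate(g.astype(np.float32))

    return _make(y.astype(np.float32), (x,), backward, track)


# --------------------------------------------------------------------------
# elementwise fusion arithmetic

def _binary(x: Tensor, y: Tensor, fwd, bwd_x, bwd_y) -> Tensor:
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    out = fwd(x.data, y.data)
    track = _track(x, y)

    def backward(g: np.ndarray) -> None:
        if x.requires_grad or x._parents:
            x._accumulate(bwd_x(g, x.data, y.data))
        if y.requires_grad or y._parents:
            y._accumulate(bwd_y(g, x.data, y.data))

    return _make(out, (x, y), backward, track)


def add(x: Tensor, y: Tensor) -> Tensor:
    return _binary(x, y, lambda a, b: a + b, lambda g, a, b: g, lambda g, a, b: g)


def mul(x: Tensor, y: Tensor) -> Tensor:
    return _binary(x, y, lambda a, b: a * b, lambda g, a, b: g * b, lambda g, a, b: g * a)


def maximum(x: Tensor, y: Tensor) -> Tensor:
    # ties route the gradient to the first argument
    return _binary(
        x,
        y,
        np.maximum,
        lambda g, a, b: g * (a >= b),
        lambda g, a, b: g * (b > a),
    )


def concat(tensors: list[Tensor]) -> Tensor:
    """Concatenate along the channel axis."""
    out = np.concatenate([t.data for t in tensors], axis=0)
    sizes = [t.shape[0] for t in tensors]
    track = any(_track(t) for t in tensors)

    def backward(g: np.ndarray) -> None:
        off = 0
        for t, s in zip(tensors, sizes):
            if t.requires_grad or t._parents:
                t._accumulate(g[off : off + s])
            off += s

    return _make(out, tuple(tensors), backward, track)


def mae_loss(pred: Tensor, target: np.ndarray, mask: np.ndarray | None = None) -> Tensor:
    """Mean absolute error, optionally restricted to a binary mask.

    With a mask, both prediction and target are zeroed outside it and the
    mean runs over mask voxels only.
    """
    t = np.asarray(target, dtype=np.float32)
    if mask is not None:
        m = (np.asarray(mask) > 0).astype(np.float32)
        if m.sum() == 0:
            raise ValueError("mae_loss: empty mask")
        diff = (pred.data - t) * m
        denom = float(m.sum()) * (pred.shape[0] if m.ndim < len(pred.shape) else 1)
    else:
        m = None
        diff = pred.data - t
        denom = float(diff.size)
    loss = np.abs(diff).sum() / denom
    track = _track(pred)

    def backward(g: np.ndarray) -> None:
        if pred.requires_grad or pred._parents:
            s = np.sign(diff) / denom
            pred._accumulate(g * s)

    return _make(np.float32(loss), (pred,), backward, track)
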