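"""A small reverse-mode automatic-differentiation engine on numpy arrays.

Only the operations the segmentation networks need are implemented:
reflect padding, depthwise / pointwise / dense 3x3 convolution, batch
normalization, h-swish and ReLU, 2x2 max pooling, 2x nearest and
bilinear upsampling, channel concatenation, elementwise addition, and the
fused sigmoid / binary-cross-entropy and softmax / cross-entropy losses.
Feature maps are ``N x C x H x W`` float32 throughout.

Each forward op records its parents and a closure that maps the upstream
gradient to per-parent gradients; ``Tensor.backward`` runs the closures
in reverse topological order. This is deliberately minimal — no
broadcasting rules, no graphs across batches — which keeps every
backward rule explicit and testable by finite differences.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor"]


class Tensor:
    """An array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (a scalar unless ``grad`` given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad needs a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: deep U-Nets overflow recursion limits
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
        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, g in zip(node._parents, node._backward(node.grad)):
                if g is None or not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = g.astype(np.float32, copy=True)
                else:
                    parent.grad += g


def _result(data, parents: tuple[Tensor, ...], backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = parents
        out._backward = backward
    return out


# ---------------------------------------------------------------------------
# elementwise

def add(a: Tensor, b: Tensor) -> Tensor:
    if a.shape != b.shape:
        raise ValueError(f"add shapes differ: {a.shape} vs {b.shape}")
    return _result(a.data + b.data, (a, b), lambda g: (g, g))


def h_swish(x: Tensor) -> Tensor:
    z = x.data
    out = z * np.clip(z + 3.0, 0.0, 6.0) / 6.0

    def backward(g):
        d = np.where(z >= 3.0, 1.0,
                     np.where(z <= -3.0, 0.0, (2.0 * z + 3.0) / 6.0))
        return (g * d.astype(np.float32),)

    return _result(out, (x,), backward)


def relu(x: Tensor) -> Tensor:
    out = np.maximum(x.data, 0.0)
    return _result(out, (x,), lambda g: (g * (x.data > 0),))


# ---------------------------------------------------------------------------
# padding and convolutions

def reflect_pad1(x: Tensor) -> Tensor:
    """Reflect-pad the two spatial axes by one pixel."""
    out = np.pad(x.data, ((0, 0), (0, 0), (1, 1), (1, 1)), mode="reflect")

    def backward(g):
        gx = g[:, :, 1:-1, 1:-1].copy()
        gx[:, :, 1, :] += g[:, :, 0, 1:-1]
        gx[:, :, -2, :] += g[:, :, -1, 1:-1]
        gx[:, :, :, 1] += g[:, :, 1:-1, 0]
        gx[:, :, :, -2] += g[:, :, 1:-1, -1]
        gx[:, :, 1, 1] += g[:, :, 0, 0]
        gx[:, :, 1, -2] += g[:, :, 0, -1]
        gx[:, :, -2, 1] += g[:, :, -1, 0]
        gx[:, :, -2, -2] += g[:, :, -1, -1]
        return (gx,)

    return _result(out, (x,), backward)


def depthwise_conv3x3(x_padded: Tensor, weight: Tensor) -> Tensor:
    """Per-channel 3x3 correlation on an already padded input.

    ``weight`` is ``C x 3 x 3``; output is ``N x C x H x W`` where
    ``H = H_pad - 2``.
    """
    xp = x_padded.data
    n, c, hp, wp = xp.shape
    h, w = hp - 2, wp - 2
    wk = weight.data
    out = np.zeros((n, c, h, w), dtype=np.float32)
    for di in range(3):
        for dj in range(3):
            out += wk[:, di, dj][None, :, None, None] * \
                xp[:, :, di:di + h, dj:dj + w]

    def backward(g):
        gx = np.zeros_like(xp)
        gw = np.zeros_like(wk)
        for di in range(3):
            for dj in range(3):
                view = xp[:, :, di:di + h, dj:dj + w]
                gw[:, di, dj] = np.einsum("nchw,nchw->c", g, view)
                gx[:, :, di:di + h, dj:dj + w] += \
                    wk[:, di, dj][None, :, None, None] * g
        return gx, gw

    return _result(out, (x_padded, weight), backward)


def pointwise_conv(x: Tensor, weight: Tensor,
                   bias: Tensor | None = None) -> Tensor:
    """1x1 convolution; ``weight`` is ``C_out x C_in``."""
    out = np.tensordot(weight.data, x.data,
                       axes=([1], [1])).swapaxes(0, 1)
    if bias is not None:
        out = out + bias.data[None, :, None, None]

    def backward(g):
        gx = np.tensordot(weight.data.T, g, axes=([1], [1])).swapaxes(0, 1)
        gw = np.einsum("nohw,nchw->oc", g, x.data)
        grads = [gx, gw]
        if bias is not None:
            grads.append(g.sum(axis=(0, 2, 3)))
        return tuple(grads)

    parents = (x, weight) if bias is None else (x, weight, bias)
    return _result(np.ascontiguousarray(out), parents, backward)


def conv3x3(x_padded: Tensor, weight: Tensor) -> Tensor:
    """Dense 3x3 correlation (the plain-U-Net baseline block).

    ``weight`` is ``C_out x C_in x 3 x 3``; input must already be padded.
    """
    xp = x_padded.data
    n, cin, hp, wp = xp.shape
    h, w = hp - 2, wp - 2
    wk = weight.data
    out = np.zeros((n, wk.shape[0], h, w), dtype=np.float32)
    for di in range(3):
        for dj in range(3):
            out += np.tensordot(
                wk[:, :, di, dj], xp[:, :, di:di + h, dj:dj + w],
                axes=([1], [1])).swapaxes(0, 1)

    def backward(g):
        gx = np.zeros_like(xp)
        gw = np.zeros_like(wk)
        for di in range(3):
            for dj in range(3):
                view = xp[:, :, di:di + h, dj:dj + w]
                gw[:, :, di, dj] = np.einsum("nohw,nchw->oc", g, view)
                gx[:, :, di:di + h, dj:dj + w] += np.tensordot(
                    wk[:, :, di, dj].T, g, axes=([1], [1])).swapaxes(0, 1)
        return gx, gw

    return _result(out, (x_padded, weight), backward)


# ---------------------------------------------------------------------------
# batch normalization

def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               running_mean: np.ndarray, running_var: np.ndarray,
               training: bool, momentum: float = 0.1,
               eps: float = 1e-5) -> Tensor:
    """Channelwise batch normalization.

    In training mode the batch statistics are used and the running
    estimates updated in place; in eval mode the running estimates are
    used, making inference deterministic for any batch size.
    """
    xd = x.data
    if training:
        mean = xd.mean(axis=(0, 2, 3))
        var = xd.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mean[None, :, None, None]) * inv_std[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + \
        beta.data[None, :, None, None]

    def backward(g):
        gbeta = g.sum(axis=(0, 2, 3))
        ggamma = (g * xhat).sum(axis=(0, 2, 3))
        gs = gamma.data[None, :, None, None] * inv_std[None, :, None, None]
        if training:
            m = xd.shape[0] * xd.shape[2] * xd.shape[3]
            gx = gs * (g - gbeta[None, :, None, None] / m
                       - xhat * ggamma[None, :, None, None] / m)
        else:
            gx = gs * g
        return gx, ggamma, gbeta

    return _result(out.astype(np.float32), (x, gamma, beta), backward)


# ---------------------------------------------------------------------------
# resampling

def max_pool2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2."""
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"max_pool2 needs even spatial dims, got {h}x{w}")
    xr = x.data.reshape(n, c, h // 2, 2, w // 2, 2) \
        .transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gr = np.zeros_like(xr)
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
        gx = gr.reshape(n, c, h // 2, w // 2, 2, 2) \
            .transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
        return (gx,)

    return _result(out, (x,), backward)


def _up2_axis(a: np.ndarray, axis: int) -> np.ndarray:
    """2x bilinear upsampling along one axis (align_corners=False)."""
    a = np.moveaxis(a, axis, -1)
    am = np.concatenate([a[..., :1], a[..., :-1]], axis=-1)
    ap = np.concatenate([a[..., 1:], a[..., -1:]], axis=-1)
    even = 0.25 * am + 0.75 * a
    odd = 0.75 * a + 0.25 * ap
    out = np.empty(a.shape[:-1] + (2 * a.shape[-1],), dtype=a.dtype)
    out[..., 0::2] = even
    out[..., 1::2] = odd
    return np.moveaxis(out, -1, axis)


def _down2_axis(g: np.ndarray, axis: int) -> np.ndarray:
    """Adjoint of :func:`_up2_axis`."""
    g = np.moveaxis(g, axis, -1)
    ge, go = g[..., 0::2], g[..., 1::2]
    gx = 0.75 * ge + 0.75 * go
    gx[..., :-1] += 0.25 * ge[..., 1:]
    gx[..., 0] += 0.25 * ge[..., 0]
    gx[..., 1:] += 0.25 * go[..., :-1]
    gx[..., -1] += 0.25 * go[..., -1]
    return np.moveaxis(gx, -1, axis)


def upsample2(x: Tensor, mode: str = "bilinear") -> Tensor:
    """Double both spatial dimensions."""
    if mode == "nearest":
        out = x.data.repeat(2, axis=2).repeat(2, axis=3)

        def backward(g):
            n, c, h2, w2 = g.shape
            return (g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(
                axis=(3, 5)),)

    elif mode == "bilinear":
        out = _up2_axis(_up2_axis(x.data, 2), 3)

        def backward(g):
            return (_down2_axis(_down2_axis(g, 3), 2).astype(np.float32),)

    else:
        raise ValueError(f"unknown upsample mode {mode!r}")
    return _result(out, (x,), backward)


def concat_channels(tensors: list[Tensor]) -> Tensor:
    sizes = [t.shape[1] for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=1)

    def backward(g):
        grads = []
        start = 0
        for s in sizes:
            grads.append(g[:, start:start + s])
            start += s
        return tuple(grads)

    return _result(out, tuple(tensors), backward)


# ---------------------------------------------------------------------------
# losses

def bce_with_logits(logits: Tensor, targets: np.ndarray,
                    mask: np.ndarray) -> Tensor:
    """Mean binary cross-entropy over masked elements, fused with sigmoid.

    Uses the numerically stable form ``max(z,0) - z*y + log1p(exp(-|z|))``
    so extreme logits cannot overflow. ``targets`` and ``mask`` are plain
    arrays broadcastable to the logits' shape; the mean runs over elements
    where ``mask`` is nonzero.
    """
    z = logits.data.astype(np.float64)
    y = np.asarray(targets, dtype=np.float64)
    m = np.broadcast_to(np.asarray(mask, dtype=np.float64), z.shape)
    total = m.sum()
    if total == 0:
        raise ValueError("empty mask: no valid elements to average over")
    elem = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    loss = (elem * m).sum() / total

    def backward(g):
        sig = 1.0 / (1.0 + np.exp(-z))
        return ((g * (sig - y) * m / total).astype(np.float32),)

    return _result(np.float32(loss), (logits,), backward)


def softmax_cross_entropy(logits: Tensor, targets: np.ndarray,
                          mask: np.ndarray) -> Tensor:
    """Mean per-pixel softmax cross-entropy over masked pixels.

    ``targets`` is one-hot over the channel axis; ``mask`` is ``N x H x W``.
    """
    z = logits.data.astype(np.float64)
    y = np.asarray(targets, dtype=np.float64)
    m = np.asarray(mask, dtype=np.float64)
    total = m.sum()
    if total == 0:
        raise ValueError("empty mask: no valid pixels to average over")
    zmax = z.max(axis=1, keepdims=True)
    logp = z - zmax - np.log(np.exp(z - zmax).sum(axis=1, keepdims=True))
    loss = -((y * logp).sum(axis=1) * m).sum() / total

    def backward(g):
        p = np.exp(logp)
        return ((g * (p - y) * m[:, None] / total).astype(np.float32),)

    return _result(np.float32(loss), (logits,), backward)


def sigmoid(z: np.ndarray) -> np.ndarray:
    """Numerically stable elementwise sigmoid (plain numpy, no autograd)."""
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out
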