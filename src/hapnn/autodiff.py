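"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The imputation networks in this package are small (tens of thousands to a
few hundred thousand parameters) and are trained on a single CPU, so a
compact define-by-run tape over NumPy is the right size of tool: every
operation below records its inputs and a closure computing input gradients,
and :meth:`Tensor.backward` walks the tape in reverse topological order.

Only the operations the RCDA and RNN models need are provided: elementwise
arithmetic and activations, (batched) matrix products, concatenation /
slicing / gathering for recurrent nets, same-padding 1-D convolution via
im2col, max-pooling and nearest-neighbour upsampling with stride 2, batch
normalisation, and a fused softmax cross-entropy.  Shapes follow the
``(batch, channels, length)`` convention for convolutional tensors and
``(batch, features)`` for recurrent steps.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "tensor",
    "add",
    "sub",
    "mul",
    "ones_minus",
    "matmul",
    "sigmoid",
    "tanh",
    "relu",
    "concat",
    "narrow",
    "stack_steps",
    "gather_steps",
    "transpose",
    "conv1d",
    "max_pool1d_2",
    "upsample1d_2",
    "batch_norm",
    "softmax",
    "softmax_cross_entropy",
    "gru_sequence",
    "Adam",
]


class Tensor:
    """A NumPy array plus the bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "_parents", "_bwd")

    def __init__(self, data, _parents=(), _bwd=None):
        self.data = np.asarray(data)
        self.grad = None
        self._parents = tuple(_parents)
        self._bwd = _bwd

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, dtype={self.data.dtype})"

    def backward(self):
        """Backpropagate from a scalar tensor through the recorded tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss tensor")
        # Iterative post-order DFS: recursion would overflow on the long
        # tapes produced by backprop-through-time.
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                if id(parent) not in seen:
                    stack.append((parent, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._bwd is None or node.grad is None:
                continue
            grads = node._bwd(node.grad)
            for parent, g in zip(node._parents, grads):
                if g is None:
                    continue
                parent.grad = g if parent.grad is None else parent.grad + g


def tensor(data, dtype=np.float32) -> Tensor:
    """Wrap ``data`` as a leaf tensor (no gradient history)."""
    return Tensor(np.asarray(data, dtype=dtype))


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` undoing NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, (g_dim, s_dim) in enumerate(zip(grad.shape, shape)):
        if s_dim == 1 and g_dim != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, (a, b))
    out._bwd = lambda g: (_unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape))
    return out


def sub(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data - b.data, (a, b))
    out._bwd = lambda g: (_unbroadcast(g, a.data.shape), _unbroadcast(-g, b.data.shape))
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, (a, b))
    out._bwd = lambda g: (
        _unbroadcast(g * b.data, a.data.shape),
        _unbroadcast(g * a.data, b.data.shape),
    )
    return out


def ones_minus(a: Tensor) -> Tensor:
    """``1 - a``, used for the GRU update-gate complement."""
    out = Tensor(1.0 - a.data, (a,))
    out._bwd = lambda g: (-g,)
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Matrix product; supports stacked (batched) operands of equal rank."""
    out = Tensor(a.data @ b.data, (a, b))

    def _bwd(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        return _unbroadcast(ga, a.data.shape), _unbroadcast(gb, b.data.shape)

    out._bwd = _bwd
    return out


def sigmoid(a: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-a.data))
    out = Tensor(s, (a,))
    out._bwd = lambda g: (g * s * (1.0 - s),)
    return out


def tanh(a: Tensor) -> Tensor:
    t = np.tanh(a.data)
    out = Tensor(t, (a,))
    out._bwd = lambda g: (g * (1.0 - t * t),)
    return out


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    out = Tensor(np.where(mask, a.data, 0.0), (a,))
    out._bwd = lambda g: (g * mask,)
    return out


def concat(tensors: Sequence[Tensor], axis: int) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    out._bwd = lambda g: tuple(np.split(g, splits, axis=axis))
    return out


def narrow(a: Tensor, axis: int, start: int, size: int) -> Tensor:
    """Contiguous slice ``[start, start+size)`` along ``axis``."""
    index = [slice(None)] * a.data.ndim
    index[axis] = slice(start, start + size)
    index = tuple(index)
    out = Tensor(a.data[index], (a,))

    def _bwd(g):
        full = np.zeros_like(a.data)
        full[index] = g
        return (full,)

    out._bwd = _bwd
    return out


def stack_steps(steps: Sequence[Tensor]) -> Tensor:
    """Stack per-timestep ``(batch, features)`` tensors into
    ``(batch, length, features)``."""
    out = Tensor(np.stack([s.data for s in steps], axis=1), steps)
    out._bwd = lambda g: tuple(g[:, i, :] for i in range(len(steps)))
    return out


def gather_steps(a: Tensor, idx: np.ndarray) -> Tensor:
    """Gather timesteps ``idx`` from ``(batch, length, features)``."""
    idx = np.asarray(idx)
    out = Tensor(a.data[:, idx, :], (a,))

    def _bwd(g):
        full = np.zeros_like(a.data)
        np.add.at(full, (slice(None), idx), g)
        return (full,)

    out._bwd = _bwd
    return out


def transpose(a: Tensor, axes: tuple[int, ...]) -> Tensor:
    inverse = np.argsort(axes)
    out = Tensor(np.ascontiguousarray(a.data.transpose(axes)), (a,))
    out._bwd = lambda g: (g.transpose(tuple(inverse)),)
    return out


def conv1d(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Same-padding 1-D convolution.

    ``x``: (batch, in_channels, length); ``weight``: (out_channels,
    in_channels, k) with odd ``k``; ``bias``: (out_channels,).
    Implemented as im2col + matmul so NumPy's BLAS does the work.
    """
    batch, c_in, length = x.data.shape
    c_out, c_in_w, k = weight.data.shape
    if c_in_w != c_in:
        raise ValueError(f"conv1d channel mismatch: input {c_in}, weight {c_in_w}")
    if k % 2 != 1:
        raise ValueError("conv1d requires an odd kernel size")
    pad = k // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad)))
    # (batch, c_in, length, k) -> (batch, length, c_in * k)
    col = sliding_window_view(xp, k, axis=2).transpose(0, 2, 1, 3).reshape(
        batch, length, c_in * k
    )
    w2 = weight.data.reshape(c_out, c_in * k).T
    out_blc = col @ w2 + bias.data
    out = Tensor(np.ascontiguousarray(out_blc.transpose(0, 2, 1)), (x, weight, bias))

    def _bwd(g):
        g2 = g.transpose(0, 2, 1)  # (batch, length, c_out)
        gw2 = col.reshape(-1, c_in * k).T @ g2.reshape(-1, c_out)
        g_weight = gw2.T.reshape(c_out, c_in, k)
        g_bias = g2.sum(axis=(0, 1))
        gcol = (g2 @ w2.T).reshape(batch, length, c_in, k).transpose(0, 2, 1, 3)
        gxp = np.zeros_like(xp)
        for tap in range(k):
            gxp[:, :, tap : tap + length] += gcol[:, :, :, tap]
        return gxp[:, :, pad : pad + length], g_weight, g_bias

    out._bwd = _bwd
    return out


def max_pool1d_2(x: Tensor) -> Tensor:
    """Max-pool with pool size 2 over the length axis (length must be even)."""
    batch, channels, length = x.data.shape
    if length % 2 != 0:
        raise ValueError(f"max_pool1d_2 needs an even length, got {length}")
    xr = x.data.reshape(batch, channels, length // 2, 2)
    argmax = xr.argmax(axis=-1)
    out = Tensor(np.take_along_axis(xr, argmax[..., None], axis=-1)[..., 0], (x,))

    def _bwd(g):
        gz = np.zeros_like(xr)
        np.put_along_axis(gz, argmax[..., None], g[..., None], axis=-1)
        return (gz.reshape(batch, channels, length),)

    out._bwd = _bwd
    return out


def upsample1d_2(x: Tensor) -> Tensor:
    """Nearest-neighbour upsampling by 2 over the length axis."""
    batch, channels, length = x.data.shape
    out = Tensor(np.repeat(x.data, 2, axis=2), (x,))
    out._bwd = lambda g: (g.reshape(batch, channels, length, 2).sum(axis=-1),)
    return out


def batch_norm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Batch normalisation over (batch, length) per channel.

    ``running_mean`` / ``running_var`` are plain arrays owned by the calling
    layer and are updated in place when ``training`` is true.
    """
    if training:
        mean = x.data.mean(axis=(0, 2))
        var = x.data.var(axis=(0, 2))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    x_hat = (x.data - mean[None, :, None]) * inv_std[None, :, None]
    out = Tensor(
        gamma.data[None, :, None] * x_hat + beta.data[None, :, None],
        (x, gamma, beta),
    )
    n = x.data.shape[0] * x.data.shape[2]

    def _bwd(g):
        g_gamma = (g * x_hat).sum(axis=(0, 2))
        g_beta = g.sum(axis=(0, 2))
        scale = gamma.data[None, :, None] * inv_std[None, :, None]
        if training:
            g_mean = g.mean(axis=(0, 2))[None, :, None]
            gx_hat_mean = (g * x_hat).sum(axis=(0, 2))[None, :, None] / n
            g_x = scale * (g - g_mean - x_hat * gx_hat_mean)
        else:
            g_x = scale * g
        return g_x, g_gamma, g_beta

    out._bwd = _bwd
    return out


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    """Plain-NumPy softmax for inference-time probability output."""
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy with integer labels over the last axis of
    ``logits``; fused with softmax for numerical stability."""
    labels = np.asarray(labels)
    if labels.shape != logits.data.shape[:-1]:
        raise ValueError(
            f"label shape {labels.shape} does not match logits "
            f"{logits.data.shape[:-1]}"
        )
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    log_probs = z - np.log(np.exp(z).sum(axis=-1, keepdims=True))
    picked = np.take_along_axis(log_probs, labels[..., None], axis=-1)[..., 0]
    n = labels.size
    out = Tensor(np.asarray(-picked.sum() / n, dtype=logits.data.dtype), (logits,))

    def _bwd(g):
        probs = np.exp(log_probs)
        np.subtract.at(probs.reshape(-1, probs.shape[-1]),
                       (np.arange(n), labels.reshape(-1)), 1.0)
        return (g * probs / n,)

    out._bwd = _bwd
    return out


def gru_sequence(gx: Tensor, u: Tensor, b_h: Tensor, reverse: bool = False) -> Tensor:
    """Run a GRU over a sequence whose input projections are precomputed.

    ``gx``: (batch, length, 3H) = x_t W + b_x per step, gate order (r, z, n);
    ``u``: (H, 3H) recurrent weights; ``b_h``: (3H,) recurrent bias.  The
    cell update is

        r_t = sigmoid(gx_r + h U_r + b_r)
        z_t = sigmoid(gx_z + h U_z + b_z)
        n_t = tanh(gx_n + r_t * (h U_n + b_n))
        h_t = (1 - z_t) n_t + z_t h_{t-1}

    The whole sequence loop is a single tape node with a hand-derived
    backward pass (backprop through time), which keeps the per-step cost
    at raw-NumPy level.  Returns hidden states (batch, length, H) indexed
    in the original sequence order regardless of direction.
    """
    batch, length, h3 = gx.data.shape
    h_size = h3 // 3
    u_d, b_d = u.data, b_h.data
    dtype = gx.data.dtype
    order = range(length - 1, -1, -1) if reverse else range(length)
    h = np.zeros((batch, h_size), dtype=dtype)
    hs = np.empty((batch, length, h_size), dtype=dtype)
    saved_r = np.empty_like(hs)
    saved_z = np.empty_like(hs)
    saved_n = np.empty_like(hs)
    saved_ghn = np.empty_like(hs)
    saved_hprev = np.empty_like(hs)
    for t in order:
        gh = h @ u_d + b_d
        gxt = gx.data[:, t, :]
        r = 1.0 / (1.0 + np.exp(-(gxt[:, :h_size] + gh[:, :h_size])))
        z = 1.0 / (1.0 + np.exp(-(gxt[:, h_size : 2 * h_size] + gh[:, h_size : 2 * h_size])))
        ghn = gh[:, 2 * h_size :]
        n = np.tanh(gxt[:, 2 * h_size :] + r * ghn)
        saved_hprev[:, t, :] = h
        saved_r[:, t, :] = r
        saved_z[:, t, :] = z
        saved_n[:, t, :] = n
        saved_ghn[:, t, :] = ghn
        h = (1.0 - z) * n + z * h
        hs[:, t, :] = h
    out = Tensor(hs, (gx, u, b_h))

    def _bwd(g):
        d_gx = np.empty_like(gx.data)
        d_u = np.zeros_like(u_d, dtype=np.float64)
        d_bh = np.zeros_like(b_d, dtype=np.float64)
        dh = np.zeros((batch, h_size), dtype=dtype)
        for t in reversed(order):
            dh = dh + g[:, t, :]
            r = saved_r[:, t, :]
            z = saved_z[:, t, :]
            n = saved_n[:, t, :]
            ghn = saved_ghn[:, t, :]
            h_prev = saved_hprev[:, t, :]
            dz = dh * (h_prev - n)
            dn = dh * (1.0 - z)
            dh_prev = dh * z
            da_n = dn * (1.0 - n * n)
            da_r = (da_n * ghn) * r * (1.0 - r)
            da_z = dz * z * (1.0 - z)
            d_gx[:, t, :h_size] = da_r
            d_gx[:, t, h_size : 2 * h_size] = da_z
            d_gx[:, t, 2 * h_size :] = da_n
            dgh = np.concatenate([da_r, da_z, da_n * r], axis=1)
            d_u += h_prev.T @ dgh
            d_bh += dgh.sum(axis=0)
            dh = dh_prev + dgh @ u_d.T
        return d_gx, d_u.astype(u_d.dtype), d_bh.astype(b_d.dtype)

    out._bwd = _bwd
    return out


class Adam:
    """Adam optimiser with bias correction (Kingma & Ba defaults)."""

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            m_hat = m / (1.0 - b1**self.t)
            v_hat = v / (1.0 - b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
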