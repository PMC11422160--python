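"""Neural-network layers used by the imputation models.

Thin parameter-owning wrappers around the autodiff primitives: 1-D
convolution, batch normalisation, the residual convolution block, and a
bidirectional GRU stack.  Layers expose ``params()`` (trainable tensors in a
stable order, so checkpoints are plain lists of arrays) and a functional
``forward``.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "Conv1d",
    "BatchNorm1d",
    "ResidualBlock1d",
    "GRULayer",
    "BiGRUStack",
    "glorot",
]


def glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> Tensor:
    limit = float(np.sqrt(6.0 / (fan_in + fan_out)))
    return ad.tensor(rng.uniform(-limit, limit, size=shape))


class Conv1d:
    """Same-padding 1-D convolution with odd kernel size."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, zero_init: bool = False):
        if kernel_size % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        fan_in = in_channels * kernel_size
        fan_out = out_channels * kernel_size
        if zero_init:
            self.weight = ad.tensor(np.zeros((out_channels, in_channels, kernel_size)))
        else:
            self.weight = glorot(rng, (out_channels, in_channels, kernel_size), fan_in, fan_out)
        self.bias = ad.tensor(np.zeros(out_channels))

    def params(self) -> list[Tensor]:
        return [self.weight, self.bias]

    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        return ad.conv1d(x, self.weight, self.bias)


class BatchNorm1d:
    """Per-channel batch normalisation over (batch, length)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = ad.tensor(np.ones(channels))
        self.beta = ad.tensor(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def params(self) -> list[Tensor]:
        return [self.gamma, self.beta]

    def state(self) -> list[np.ndarray]:
        return [self.running_mean, self.running_var]

    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        return ad.batch_norm(
            x, self.gamma, self.beta, self.running_mean, self.running_var,
            training, self.momentum, self.eps,
        )


class ResidualBlock1d:
    """Residual 1-D convolution block.

    Main path: conv → batch-norm → ReLU → conv → batch-norm.  Skip path:
    identity when channel counts match, otherwise a 1×1 convolution.  The
    block output is the elementwise sum of the two paths; any outer
    activation is left to the caller, so a zero-initialised block with an
    identity skip is exactly the identity map (which keeps gradients
    flowing early in training).
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, zero_init: bool = False):
        self.conv1 = Conv1d(in_channels, out_channels, kernel_size, rng, zero_init)
        self.bn1 = BatchNorm1d(out_channels)
        self.conv2 = Conv1d(out_channels, out_channels, kernel_size, rng, zero_init)
        self.bn2 = BatchNorm1d(out_channels)
        if in_channels == out_channels:
            self.skip = None
        else:
            self.skip = Conv1d(in_channels, out_channels, 1, rng, zero_init)
        self.out_channels = out_channels

    def params(self) -> list[Tensor]:
        out = self.conv1.params() + self.bn1.params() + self.conv2.params() + self.bn2.params()
        if self.skip is not None:
            out += self.skip.params()
        return out

    def state(self) -> list[np.ndarray]:
        return self.bn1.state() + self.bn2.state()

    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        h = self.conv1.forward(x, training)
        h = self.bn1.forward(h, training)
        h = ad.relu(h)
        h = self.conv2.forward(h, training)
        h = self.bn2.forward(h, training)
        shortcut = x if self.skip is None else self.skip.forward(x, training)
        return ad.add(h, shortcut)


class GRULayer:
    """Single-direction gated recurrent layer over (batch, length, din).

    The input projection ``x W + b_x`` for all timesteps is one batched
    matmul; the sequential part runs inside the fused
    :func:`~hapnn.autodiff.gru_sequence` op (gate order r, z, n with the
    reset gate applied to the recurrent contribution of the candidate).
    """

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        self.input_size = input_size
        self.hidden_size = hidden_size
        h = hidden_size
        self.w = glorot(rng, (input_size, 3 * h), input_size, h)
        self.u = glorot(rng, (h, 3 * h), h, h)
        self.b_x = ad.tensor(np.zeros(3 * h))
        self.b_h = ad.tensor(np.zeros(3 * h))

    def params(self) -> list[Tensor]:
        return [self.w, self.u, self.b_x, self.b_h]

    def forward(self, x: Tensor, reverse: bool = False) -> Tensor:
        """Hidden states (batch, length, hidden), sequence order preserved."""
        gx = ad.add(ad.matmul(x, self.w), self.b_x)
        return ad.gru_sequence(gx, self.u, self.b_h, reverse=reverse)


class BiGRUStack:
    """Stack of bidirectional GRU layers over a marker sequence.

    Layer ``l`` consumes the concatenated forward/backward states of layer
    ``l-1`` (the raw inputs for ``l = 0``), so every layer above the first
    has input size ``2 * hidden_size``.
    """

    def __init__(self, input_size: int, hidden_size: int, n_layers: int,
                 rng: np.random.Generator):
        self.hidden_size = hidden_size
        self.n_layers = n_layers
        self.layers: list[tuple[GRULayer, GRULayer]] = []
        din = input_size
        for _ in range(n_layers):
            fwd = GRULayer(din, hidden_size, rng)
            bwd = GRULayer(din, hidden_size, rng)
            self.layers.append((fwd, bwd))
            din = 2 * hidden_size

    def params(self) -> list[Tensor]:
        out: list[Tensor] = []
        for fwd, bwd in self.layers:
            out += fwd.params() + bwd.params()
        return out

    def forward(self, x: Tensor) -> Tensor:
        """Top-layer states as (batch, length, 2*hidden)."""
        current = x
        for fwd, bwd in self.layers:
            current = ad.concat(
                [fwd.forward(current, reverse=False),
                 bwd.forward(current, reverse=True)],
                axis=2,
            )
        return current
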