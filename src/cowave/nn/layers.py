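"""Layers: seeded Glorot-initialized convolution, dense and (Bi)LSTM blocks."""

from __future__ import annotations

from typing import List, Tuple

import numpy as np

from cowave.nn.autograd import Tensor
from cowave.nn import ops


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def _glorot(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    def parameters(self) -> List[Parameter]:
        raise NotImplementedError


class Conv1d(Layer):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int, rng):
        fan_in = in_channels * kernel_size
        fan_out = out_channels * kernel_size
        self.w = Parameter(_glorot(rng, (out_channels, in_channels, kernel_size), fan_in, fan_out))
        self.b = Parameter(np.zeros(out_channels))

    def __call__(self, x: Tensor) -> Tensor:
        return ops.conv1d(x, self.w, self.b)

    def parameters(self):
        return [self.w, self.b]


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng):
        self.w = Parameter(_glorot(rng, (in_features, out_features), in_features, out_features))
        self.b = Parameter(np.zeros(out_features))

    def __call__(self, x: Tensor) -> Tensor:
        return ops.add(ops.matmul(x, self.w), self.b)

    def parameters(self):
        return [self.w, self.b]


class LSTM(Layer):
    """Single-direction LSTM; input (N, T, I) -> (sequence (N, T, H), last (N, H)).

    Gate order i, f, g, o; forget-gate bias initialized to 1. The input
    projection for all timesteps is computed as one matrix product before the
    recurrence.
    """

    def __init__(self, input_size: int, hidden_size: int, rng):
        H = hidden_size
        self.hidden_size = H
        self.w = Parameter(_glorot(rng, (input_size, 4 * H), input_size, H))
        self.u = Parameter(_glorot(rng, (H, 4 * H), H, H))
        b = np.zeros(4 * H)
        b[H : 2 * H] = 1.0
        self.b = Parameter(b)

    def __call__(self, x: Tensor, reverse: bool = False) -> Tuple[Tensor, Tensor]:
        T = x.shape[1]
        seq = ops.lstm(x, self.w, self.u, self.b, reverse=reverse)
        # final processed state: t = T-1 forward, t = 0 when reversed
        last = ops.getitem(seq, (slice(None), 0 if reverse else T - 1))
        return seq, last

    def parameters(self):
        return [self.w, self.u, self.b]


class BiLSTM(Layer):
    """Bidirectional LSTM: concatenated forward/backward sequences and states."""

    def __init__(self, input_size: int, hidden_size: int, rng):
        self.fw = LSTM(input_size, hidden_size, rng)
        self.bw = LSTM(input_size, hidden_size, rng)

    def __call__(self, x: Tensor) -> Tuple[Tensor, Tensor]:
        seq_f, last_f = self.fw(x, reverse=False)
        seq_b, last_b = self.bw(x, reverse=True)
        return ops.concat([seq_f, seq_b], axis=2), ops.concat([last_f, last_b], axis=1)

    def parameters(self):
        return self.fw.parameters() + self.bw.parameters()
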