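"""Differentiable operations on :class:`~cowave.nn.autograd.Tensor`.

Shapes follow the channels-first convention for convolutional ops
(batch, channels, length) and batch-first for recurrent ones
(batch, time, features).
"""

from __future__ import annotations

from typing import Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from cowave.nn.autograd import Tensor, accumulate, from_op, unbroadcast


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def backward(g):
        accumulate(a, unbroadcast(g, a.shape))
        accumulate(b, unbroadcast(g, b.shape))

    return from_op(a.data + b.data, (a, b), backward)


def sub(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def backward(g):
        accumulate(a, unbroadcast(g, a.shape))
        accumulate(b, unbroadcast(-g, b.shape))

    return from_op(a.data - b.data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def backward(g):
        accumulate(a, unbroadcast(g * b.data, a.shape))
        accumulate(b, unbroadcast(g * a.data, b.shape))

    return from_op(a.data * b.data, (a, b), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        accumulate(a, g @ b.data.T)
        accumulate(b, a.data.T @ g)

    return from_op(a.data @ b.data, (a, b), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g):
        accumulate(x, g * mask)

    return from_op(x.data * mask, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        accumulate(x, g * y * (1.0 - y))

    return from_op(y, (x,), backward)


def tanh(x: Tensor) -> Tensor:
    y = np.tanh(x.data)

    def backward(g):
        accumulate(x, g * (1.0 - y * y))

    return from_op(y, (x,), backward)


def reshape(x: Tensor, shape: Tuple[int, ...]) -> Tensor:
    old = x.shape

    def backward(g):
        accumulate(x, g.reshape(old))

    return from_op(x.data.reshape(shape), (x,), backward)


def transpose(x: Tensor, axes: Tuple[int, ...]) -> Tensor:
    inv = np.argsort(axes)

    def backward(g):
        accumulate(x, g.transpose(inv))

    return from_op(x.data.transpose(axes), (x,), backward)


def _is_basic_key(key) -> bool:
    parts = key if isinstance(key, tuple) else (key,)
    return all(isinstance(p, (int, np.integer, slice)) for p in parts)


def getitem(x: Tensor, key) -> Tensor:
    basic = _is_basic_key(key)  # basic indexing selects unique elements

    def backward(g):
        if x.requires_grad:
            gz = np.zeros_like(x.data)
            if basic:
                gz[key] += g
            else:
                np.add.at(gz, key, g)
            accumulate(x, gz)

    return from_op(x.data[key], (x,), backward)


def concat(tensors: Sequence[Tensor], axis: int) -> Tensor:
    tensors = tuple(tensors)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            accumulate(t, piece)

    return from_op(np.concatenate([t.data for t in tensors], axis=axis), tensors, backward)


def mean(x: Tensor) -> Tensor:
    n = x.data.size

    def backward(g):
        accumulate(x, np.full_like(x.data, float(g) / n))

    return from_op(np.mean(x.data), (x,), backward)


def conv1d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-padding 1-D convolution (cross-correlation).

    x: (N, C_in, L); w: (C_out, C_in, K) with K odd; b: (C_out,).
    """
    K = w.shape[2]
    if K % 2 != 1:
        raise ValueError("conv1d requires an odd kernel size for same padding")
    p = (K - 1) // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p)))
    windows = sliding_window_view(xp, K, axis=2)  # (N, C_in, L, K)
    y = np.einsum("nclk,ock->nol", windows, w.data, optimize=True) + b.data[None, :, None]

    def backward(g):
        accumulate(w, np.einsum("nol,nclk->ock", g, windows, optimize=True))
        accumulate(b, g.sum(axis=(0, 2)))
        if x.requires_grad:
            gp = np.pad(g, ((0, 0), (0, 0), (p, p)))
            gwin = sliding_window_view(gp, K, axis=2)
            accumulate(
                x, np.einsum("nolk,ock->ncl", gwin, w.data[:, :, ::-1], optimize=True)
            )

    return from_op(y, (x, w, b), backward)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def lstm(x: Tensor, w: Tensor, u: Tensor, b: Tensor, reverse: bool = False) -> Tensor:
    """Fused LSTM recurrence: input (N, T, I) -> hidden sequence (N, T, H).

    The whole recurrence is one graph node with hand-written
    backpropagation-through-time, which keeps the per-timestep cost to a few
    numpy calls instead of a dozen graph nodes. Gate order i, f, g, o;
    zero initial state; with ``reverse`` the sequence is processed from t =
    T-1 down to 0 (outputs stay time-aligned with the input).
    """
    N, T, I = x.shape
    H = u.shape[0]
    xw = (x.data.reshape(N * T, I) @ w.data + b.data).reshape(N, T, 4 * H)
    order = range(T - 1, -1, -1) if reverse else range(T)
    h = np.zeros((N, H))
    c = np.zeros((N, H))
    seq = np.empty((N, T, H))
    gi = np.empty((N, T, H))
    gf = np.empty((N, T, H))
    gg = np.empty((N, T, H))
    go = np.empty((N, T, H))
    c_prev = np.empty((N, T, H))
    tan_c = np.empty((N, T, H))
    for t in order:
        z = xw[:, t] + h @ u.data
        i_t = _sigmoid(z[:, :H])
        f_t = _sigmoid(z[:, H : 2 * H])
        g_t = np.tanh(z[:, 2 * H : 3 * H])
        o_t = _sigmoid(z[:, 3 * H :])
        c_prev[:, t] = c
        c = f_t * c + i_t * g_t
        tc = np.tanh(c)
        h = o_t * tc
        seq[:, t] = h
        gi[:, t], gf[:, t], gg[:, t], go[:, t], tan_c[:, t] = i_t, f_t, g_t, o_t, tc

    def backward(g_out):
        dxw = np.empty((N, T, 4 * H))
        du = np.zeros_like(u.data)
        dh_next = np.zeros((N, H))
        dc_next = np.zeros((N, H))
        steps = list(order)
        for t in reversed(steps):
            dh = g_out[:, t] + dh_next
            do = dh * tan_c[:, t]
            dc = dc_next + dh * go[:, t] * (1.0 - tan_c[:, t] ** 2)
            di = dc * gg[:, t]
            dg = dc * gi[:, t]
            df = dc * c_prev[:, t]
            dz = dxw[:, t]
            dz[:, :H] = di * gi[:, t] * (1.0 - gi[:, t])
            dz[:, H : 2 * H] = df * gf[:, t] * (1.0 - gf[:, t])
            dz[:, 2 * H : 3 * H] = dg * (1.0 - gg[:, t] ** 2)
            dz[:, 3 * H :] = do * go[:, t] * (1.0 - go[:, t])
            # the hidden state feeding step t is seq at the previously
            # processed index; before the first processed step it is zero
            prev_t = t + 1 if reverse else t - 1
            if 0 <= prev_t < T:
                du += seq[:, prev_t].T @ dz
            dh_next = dz @ u.data.T
            dc_next = dc * gf[:, t]
        accumulate(u, du)
        accumulate(b, dxw.sum(axis=(0, 1)))
        flat = dxw.reshape(N * T, 4 * H)
        accumulate(w, x.data.reshape(N * T, I).T @ flat)
        if x.requires_grad:
            accumulate(x, (flat @ w.data.T).reshape(N, T, I))

    return from_op(seq, (x, w, u, b), backward)


def maxpool1d(x: Tensor, k: int = 2) -> Tensor:
    N, C, L = x.shape
    if L % k:
        raise ValueError(f"length {L} not divisible by pool factor {k}")
    xr = x.data.reshape(N, C, L // k, k)
    idx = xr.argmax(axis=-1)
    y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gz = np.zeros_like(xr)
        np.put_along_axis(gz, idx[..., None], g[..., None], axis=-1)
        accumulate(x, gz.reshape(N, C, L))

    return from_op(y, (x,), backward)


def upsample1d(x: Tensor, k: int = 2) -> Tensor:
    """Nearest-neighbour upsampling along the temporal axis."""
    N, C, L = x.shape

    def backward(g):
        accumulate(x, g.reshape(N, C, L, k).sum(axis=-1))

    return from_op(np.repeat(x.data, k, axis=2), (x,), backward)
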