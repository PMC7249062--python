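"""NumPy implementations of the primitive layers used by the layer modules.

Shapes follow the channel-major convention ``(N, C, L)``.  Convolutions are
"same"-padded (zero padding of (k-1)/2 per side for odd k) so that the
pre-pooling length equals the input length; average pooling right-pads with
zeros to the next multiple of the stride so output length is ceil(L/s).
"""

from __future__ import annotations

import numpy as np

from .core import Module, Parameter

__all__ = [
    "Conv1d",
    "ReLU",
    "ChannelDropout",
    "AvgPool1d",
    "BatchNorm1d",
    "BiLSTM",
]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically stable logistic
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Conv1d(Module):
    """1-D convolution with same-length output (odd kernels).

    Weight shape ``(w_out, w_in, k)``.  Bias is optional; layer modules omit it
    when a batch-norm follows (the shift is redundant then).
    """

    def __init__(self, w_in: int, w_out: int, k: int, bias: bool, rng: np.random.Generator):
        if k < 1 or k % 2 == 0:
            raise ValueError(f"kernel length must be a positive odd integer, got {k}")
        scale = np.sqrt(2.0 / (w_in * k))  # He init for the ReLU that follows
        self.weight = Parameter(rng.normal(0.0, scale, size=(w_out, w_in, k)), "conv.weight")
        self.bias = Parameter(np.zeros(w_out), "conv.bias") if bias else None
        self.k = k
        self._cols = None
        self._xshape = None

    def parameters(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x, train=False, rng=None):
        k = self.k
        pad = (k - 1) // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad))) if pad else x
        # (N, C, L, k) sliding view; einsum contracts channel and tap axes
        cols = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)
        self._cols = cols
        self._xshape = x.shape
        y = np.einsum("oct,nclt->nol", self.weight.value, cols, optimize=True)
        if self.bias is not None:
            y += self.bias.value[None, :, None]
        return y

    def backward(self, grad):
        k = self.k
        pad = (k - 1) // 2
        n, c, length = self._xshape
        self.weight.grad += np.einsum("nol,nclt->oct", grad, self._cols, optimize=True)
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=(0, 2))
        dcols = np.einsum("oct,nol->nclt", self.weight.value, grad, optimize=True)
        dxp = np.zeros((n, c, length + k - 1))
        for t in range(k):
            dxp[:, :, t : t + length] += dcols[:, :, :, t]
        return dxp[:, :, pad : pad + length]


class ReLU(Module):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad):
        return np.where(self._mask, grad, 0.0)


class ChannelDropout(Module):
    """Drops entire input channels (per sample in the batch) during training.

    Surviving channels are rescaled by 1/(1-p) so the expected activation is
    unchanged; eval mode is the identity.
    """

    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p
        self._mask = None

    def forward(self, x, train=False, rng=None):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("channel dropout in train mode needs an rng")
        keep = 1.0 - self.p
        mask = (rng.random((x.shape[0], x.shape[1], 1)) < keep).astype(np.float64) / keep
        self._mask = mask
        return x * mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class AvgPool1d(Module):
    """Average pooling with kernel = stride = s; right zero-pad to a multiple of s."""

    def __init__(self, s: int):
        if s < 1:
            raise ValueError(f"stride must be >= 1, got {s}")
        self.s = s
        self._length = None

    def forward(self, x, train=False, rng=None):
        s = self.s
        if s == 1:
            self._length = None
            return x
        n, c, length = x.shape
        padded = -(-length // s) * s
        self._length = length
        if padded != length:
            x = np.pad(x, ((0, 0), (0, 0), (0, padded - length)))
        return x.reshape(n, c, padded // s, s).mean(axis=3)

    def backward(self, grad):
        if self._length is None:
            return grad
        s = self.s
        g = np.repeat(grad / s, s, axis=2)
        return g[:, :, : self._length]


class BatchNorm1d(Module):
    """Per-channel batch normalization over (batch x time).

    Train mode normalizes with batch statistics and updates running statistics
    (momentum 0.1, unbiased variance); eval mode uses the running statistics,
    making inference deterministic.
    """

    def __init__(self, w: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Parameter(np.ones(w), "bn.gamma")
        self.beta = Parameter(np.zeros(w), "bn.beta")
        self.running_mean = np.zeros(w)
        self.running_var = np.ones(w)
        self.eps = eps
        self.momentum = momentum

    def parameters(self):
        return [self.gamma, self.beta]

    def buffers(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def set_buffers(self, bufs):
        self.running_mean = np.asarray(bufs["running_mean"], dtype=np.float64).copy()
        self.running_var = np.asarray(bufs["running_var"], dtype=np.float64).copy()

    def forward(self, x, train=False, rng=None):
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            n = x.shape[0] * x.shape[2]
            unbiased = var * n / (n - 1) if n > 1 else var
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (unbiased - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) / std[None, :, None]
        self._xhat = xhat
        self._std = std
        self._train = train
        return self.gamma.value[None, :, None] * xhat + self.beta.value[None, :, None]

    def backward(self, grad):
        g = self.gamma.value[None, :, None]
        self.gamma.grad += (grad * self._xhat).sum(axis=(0, 2))
        self.beta.grad += grad.sum(axis=(0, 2))
        if not self._train:
            return grad * g / self._std[None, :, None]
        dxhat = grad * g
        mean_d = dxhat.mean(axis=(0, 2), keepdims=True)
        mean_dx = (dxhat * self._xhat).mean(axis=(0, 2), keepdims=True)
        return (dxhat - mean_d - self._xhat * mean_dx) / self._std[None, :, None]


class BiLSTM(Module):
    """Bidirectional LSTM; hidden size H per direction, output 2H channels.

    Gate layout follows the common (input, forget, cell, output) convention
    with separate input and recurrent biases.  The backward pass is full BPTT
    over the cached gate activations.
    """

    def __init__(self, w_in: int, hidden: int, rng: np.random.Generator):
        self.w_in = w_in
        self.hidden = hidden
        bound = 1.0 / np.sqrt(hidden)
        self._p = {}
        for d in (0, 1):
            self._p[f"W_ih{d}"] = Parameter(rng.uniform(-bound, bound, (4 * hidden, w_in)), f"lstm.W_ih{d}")
            self._p[f"W_hh{d}"] = Parameter(rng.uniform(-bound, bound, (4 * hidden, hidden)), f"lstm.W_hh{d}")
            self._p[f"b_ih{d}"] = Parameter(rng.uniform(-bound, bound, 4 * hidden), f"lstm.b_ih{d}")
            self._p[f"b_hh{d}"] = Parameter(rng.uniform(-bound, bound, 4 * hidden), f"lstm.b_hh{d}")

    def parameters(self):
        return list(self._p.values())

    def _run_direction(self, xs, d):
        """xs: (L, N, C) already in processing order. Returns hs and the cache."""
        h_dim = self.hidden
        w_ih = self._p[f"W_ih{d}"].value
        w_hh = self._p[f"W_hh{d}"].value
        bias = self._p[f"b_ih{d}"].value + self._p[f"b_hh{d}"].value
        length, n, _ = xs.shape
        zx = xs @ w_ih.T + bias  # (L, N, 4H)
        h = np.zeros((n, h_dim))
        c = np.zeros((n, h_dim))
        hs = np.empty((length, n, h_dim))
        cache = []
        for t in range(length):
            z = zx[t] + h @ w_hh.T
            i = _sigmoid(z[:, :h_dim])
            f = _sigmoid(z[:, h_dim : 2 * h_dim])
            g = np.tanh(z[:, 2 * h_dim : 3 * h_dim])
            o = _sigmoid(z[:, 3 * h_dim :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            cache.append((i, f, g, o, c, tc, h))
            h = o * tc
            c = c_new
            hs[t] = h
        return hs, cache

    def forward(self, x, train=False, rng=None):
        xs = np.ascontiguousarray(np.transpose(x, (2, 0, 1)))  # (L, N, C)
        hs_f, cache_f = self._run_direction(xs, 0)
        hs_b, cache_b = self._run_direction(xs[::-1], 1)
        self._xs = xs
        self._cache = (cache_f, cache_b)
        # concat forward and (re-reversed) backward hidden sequences
        out = np.concatenate([hs_f, hs_b[::-1]], axis=2)  # (L, N, 2H)
        return np.transpose(out, (1, 2, 0))

    def _back_direction(self, dhs, d, cache):
        h_dim = self.hidden
        w_ih = self._p[f"W_ih{d}"]
        w_hh = self._p[f"W_hh{d}"]
        b_ih = self._p[f"b_ih{d}"]
        b_hh = self._p[f"b_hh{d}"]
        length, n, _ = dhs.shape
        xs = self._xs if d == 0 else self._xs[::-1]
        dh_next = np.zeros((n, h_dim))
        dc_next = np.zeros((n, h_dim))
        dz_all = np.empty((length, n, 4 * h_dim))
        for t in range(length - 1, -1, -1):
            i, f, g, o, c_prev, tc, _h_prev = cache[t]
            dh = dhs[t] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)],
                axis=1,
            )
            dz_all[t] = dz
            dh_next = dz @ w_hh.value
            dc_next = dc * f
        # weight gradients batched over time
        flat_dz = dz_all.reshape(-1, 4 * h_dim)
        w_ih.grad += flat_dz.T @ xs.reshape(-1, self.w_in)
        hs_prev = np.stack([cache[t][6] for t in range(length)])  # h_{t-1}
        w_hh.grad += flat_dz.T @ hs_prev.reshape(-1, h_dim)
        db = flat_dz.sum(axis=0)
        b_ih.grad += db
        b_hh.grad += db
        dxs = dz_all @ w_ih.value  # (L, N, C)
        return dxs

    def backward(self, grad):
        h_dim = self.hidden
        dout = np.transpose(grad, (2, 0, 1))  # (L, N, 2H)
        cache_f, cache_b = self._cache
        dx_f = self._back_direction(np.ascontiguousarray(dout[:, :, :h_dim]), 0, cache_f)
        dx_b = self._back_direction(np.ascontiguousarray(dout[::-1, :, h_dim:]), 1, cache_b)
        dxs = dx_f + dx_b[::-1]
        return np.transpose(dxs, (1, 2, 0))
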