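"""A small, deterministic numpy neural-network engine.

Implements exactly the layers the sleep stager needs — 1-D convolution with
"same" padding, ReLU, per-channel batch normalization, non-overlapping max
pooling, dense layers, softmax, and a (bi-directional) LSTM — with manual
reverse-mode gradients and an Adam optimizer.  Parameters default to float32
(float64 available for verification work) and all randomness flows through
explicit ``numpy.random.Generator`` streams, so training is bit-reproducible
given a seed.

Gradient correctness is enforced by finite-difference tests in the suite; the
layer API is intentionally minimal: ``forward(x, train)``, ``backward(dout)``,
with parameters and gradients exposed as parallel lists.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer", "Conv1d", "ReLU", "BatchNorm1d", "MaxPool1d", "Flatten",
    "Dense", "Softmax", "Sequential", "LSTM", "BiLSTM", "Adam",
    "glorot_uniform", "softmax",
]


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - np.max(z, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=axis, keepdims=True)


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                   fan_in: int, fan_out: int,
                   dtype=np.float32) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Layer:
    """Base layer; stateless layers keep empty parameter lists."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params()))


class Conv1d(Layer):
    """1-D convolution, stride 1, "same" padding.

    Input (N, C_in, L) -> output (N, C_out, L).  The correlation, its input
    gradient (a full convolution) and its kernel gradient (another
    correlation) are all evaluated in the Fourier domain, which keeps memory
    traffic low and is exact to rounding.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, dtype=np.float32):
        self.k = kernel_size
        self.c_in = in_channels
        self.c_out = out_channels
        fan_in = in_channels * kernel_size
        self.W = glorot_uniform(rng, (out_channels, in_channels, kernel_size),
                                fan_in, out_channels, dtype)
        self.b = np.zeros(out_channels, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._pad_l = (kernel_size - 1) // 2
        self._pad_r = kernel_size // 2

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train=False):
        from scipy.fft import next_fast_len, rfft, irfft

        N, _, L = x.shape
        Lp = L + self.k - 1
        m = next_fast_len(Lp, real=True)
        xpad = np.pad(x, ((0, 0), (0, 0), (self._pad_l, self._pad_r)))
        self._Xf = rfft(xpad, n=m, axis=2)          # (N, C_in, F)
        self._Wf = rfft(self.W, n=m, axis=2)        # (C_out, C_in, F)
        self._L, self._m = L, m
        # out[n,o,l] = sum_{c,k} W[o,c,k] xpad[n,c,l+k]  (cross-correlation)
        Of = np.einsum("ocf,ncf->nof", np.conj(self._Wf), self._Xf)
        out = irfft(Of, n=m, axis=2)[:, :, :L]
        return out + self.b[None, :, None]

    def backward(self, dout):
        from scipy.fft import rfft, irfft

        L, m = self._L, self._m
        Df = rfft(dout, n=m, axis=2)                # (N, C_out, F)
        # dW[o,c,k] = sum_{n,l} dout[n,o,l] xpad[n,c,l+k]
        Gf = np.einsum("nof,ncf->ocf", np.conj(Df), self._Xf)
        self.dW[...] = irfft(Gf, n=m, axis=2)[:, :, :self.k]
        self.db[...] = dout.sum(axis=(0, 2))
        # dxpad[n,c,j] = sum_{o,l} dout[n,o,l] W[o,c,j-l]  (full convolution)
        dXf = np.einsum("ocf,nof->ncf", self._Wf, Df)
        dxpad = irfft(dXf, n=m, axis=2)
        return dxpad[:, :, self._pad_l:self._pad_l + L]


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (N, C, L).

    Trainable scale/offset; running statistics (momentum 0.1, eps 1e-5) used
    at inference.  Running statistics are not counted as trainable parameters.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 dtype=np.float32):
        self.gamma = np.ones(channels, dtype=dtype)
        self.beta = np.zeros(channels, dtype=dtype)
        self.dgamma = np.zeros(channels, dtype=dtype)
        self.dbeta = np.zeros(channels, dtype=dtype)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.eps = eps
        self.momentum = momentum

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None]) / self._std[None, :, None]
        self._train = train
        return self.gamma[None, :, None] * self._xhat + self.beta[None, :, None]

    def backward(self, dout):
        self.dgamma[...] = (dout * self._xhat).sum(axis=(0, 2))
        self.dbeta[...] = dout.sum(axis=(0, 2))
        g = self.gamma[None, :, None]
        if not self._train:
            return dout * g / self._std[None, :, None]
        N, C, L = dout.shape
        m = N * L
        dxhat = dout * g
        return (dxhat - dxhat.mean(axis=(0, 2), keepdims=True)
                - self._xhat * (dxhat * self._xhat).mean(axis=(0, 2), keepdims=True)
                ) / self._std[None, :, None]


class MaxPool1d(Layer):
    """Non-overlapping max pooling (stride = pool size, floor semantics)."""

    def __init__(self, size: int):
        self.size = size

    def forward(self, x, train=False):
        N, C, L = x.shape
        L_out = L // self.size
        xt = x[:, :, :L_out * self.size].reshape(N, C, L_out, self.size)
        self._argmax = xt.argmax(axis=3)
        self._in_shape = x.shape
        return xt.max(axis=3)

    def backward(self, dout):
        N, C, L = self._in_shape
        L_out = dout.shape[2]
        rows = N * C * L_out
        dx = np.zeros((rows, self.size), dtype=dout.dtype)
        dx[np.arange(rows), self._argmax.ravel()] = dout.ravel()
        out = np.zeros(self._in_shape, dtype=dout.dtype)
        out[:, :, :L_out * self.size] = dx.reshape(N, C, L_out * self.size)
        return out


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, dtype=np.float32):
        self.W = glorot_uniform(rng, (in_features, out_features),
                                in_features, out_features, dtype)
        self.b = np.zeros(out_features, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        return dout @ self.W.T


class Softmax(Layer):
    """Row softmax with a full Jacobian backward (for end-to-end coupling)."""

    def forward(self, x, train=False):
        self._p = softmax(x, axis=-1)
        return self._p

    def backward(self, dout):
        p = self._p
        return p * (dout - np.sum(dout * p, axis=-1, keepdims=True))


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for lay in self.layers for p in lay.params()]

    def grads(self):
        return [g for lay in self.layers for g in lay.grads()]

    def forward(self, x, train=False):
        for lay in self.layers:
            x = lay.forward(x, train=train)
        return x

    def backward(self, dout):
        for lay in reversed(self.layers):
            dout = lay.backward(dout)
        return dout


# ---------------------------------------------------------------------------
# LSTM / BiLSTM
# ---------------------------------------------------------------------------

class LSTM(Layer):
    """Unidirectional LSTM over (N, T, D) -> (N, T, H); gate order i,f,g,o."""

    def __init__(self, input_size: int, hidden_size: int,
                 rng: np.random.Generator, dtype=np.float32):
        D, H = input_size, hidden_size
        self.H = H
        self.dtype = dtype
        self.Wx = glorot_uniform(rng, (D, 4 * H), D, H, dtype)
        self.Wh = glorot_uniform(rng, (H, 4 * H), H, H, dtype)
        self.b = np.zeros(4 * H, dtype=dtype)
        self.b[H:2 * H] = 1.0  # forget-gate bias
        self.dWx = np.zeros_like(self.Wx)
        self.dWh = np.zeros_like(self.Wh)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.Wx, self.Wh, self.b]

    def grads(self):
        return [self.dWx, self.dWh, self.db]

    def forward(self, x, train=False):
        N, T, D = x.shape
        H = self.H
        h = np.zeros((N, H), dtype=self.dtype)
        c = np.zeros((N, H), dtype=self.dtype)
        self._x = x
        self._cache = []
        out = np.empty((N, T, H), dtype=self.dtype)
        # input projection for all timesteps in one matmul
        xw = (x.reshape(N * T, D) @ self.Wx).reshape(N, T, 4 * H) + self.b
        for t in range(T):
            z = xw[:, t] + h @ self.Wh
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            self._cache.append((h, c, i, f, g, o, tc))
            h, c = h_new, c_new
            out[:, t] = h
        return out

    def backward(self, dout):
        x = self._x
        N, T, D = x.shape
        H = self.H
        dZ = np.empty((T, N, 4 * H), dtype=self.dtype)
        dh_next = np.zeros((N, H), dtype=self.dtype)
        dc_next = np.zeros((N, H), dtype=self.dtype)
        WhT = np.ascontiguousarray(self.Wh.T)
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc = self._cache[t]
            dh = dout[:, t] + dh_next
            do = dh * tc
            dc = dc_next + dh * o * (1 - tc ** 2)
            dz = dZ[t]
            dz[:, :H] = dc * g * i * (1 - i)
            dz[:, H:2 * H] = dc * c_prev * f * (1 - f)
            dz[:, 2 * H:3 * H] = dc * i * (1 - g ** 2)
            dz[:, 3 * H:] = do * o * (1 - o)
            dh_next = dz @ WhT
            dc_next = dc * f
        # weight gradients batched over time
        dZ_flat = dZ.transpose(1, 0, 2).reshape(N * T, 4 * H)
        self.dWx[...] = x.reshape(N * T, D).T @ dZ_flat
        hprev = np.stack([self._cache[t][0] for t in range(T)], axis=1)
        self.dWh[...] = hprev.reshape(N * T, H).T @ dZ_flat
        self.db[...] = dZ_flat.sum(axis=0)
        return (dZ_flat @ self.Wx.T).reshape(N, T, D)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class BiLSTM(Layer):
    """Bidirectional LSTM with per-sequence length-aware reversal.

    The reverse direction reverses only each sequence's valid prefix (given
    ``lengths``), so padded tail positions never contaminate valid steps.
    Output is the concatenation (N, T, 2H).
    """

    def __init__(self, input_size: int, hidden_size: int,
                 rng: np.random.Generator, dtype=np.float32):
        self.fwd = LSTM(input_size, hidden_size, rng, dtype)
        self.bwd = LSTM(input_size, hidden_size, rng, dtype)
        self.H = hidden_size

    def params(self):
        return self.fwd.params() + self.bwd.params()

    def grads(self):
        return self.fwd.grads() + self.bwd.grads()

    @staticmethod
    def _reverse(x: np.ndarray, lengths: np.ndarray) -> np.ndarray:
        out = x.copy()
        for n, ln in enumerate(lengths):
            out[n, :ln] = x[n, :ln][::-1]
        return out

    def forward(self, x, train=False, lengths: np.ndarray | None = None):
        N, T, _ = x.shape
        self._lengths = (np.full(N, T, dtype=int)
                         if lengths is None else np.asarray(lengths, dtype=int))
        hf = self.fwd.forward(x, train=train)
        hb = self.bwd.forward(self._reverse(x, self._lengths), train=train)
        hb = self._reverse(hb, self._lengths)
        return np.concatenate([hf, hb], axis=2)

    def backward(self, dout):
        H = self.H
        dxf = self.fwd.backward(dout[:, :, :H])
        dxb = self.bwd.backward(self._reverse(dout[:, :, H:], self._lengths))
        return dxf + self._reverse(dxb, self._lengths)


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam with the standard bias correction (beta1 .9, beta2 .999)."""

    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray],
                 lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = params
        self.grad_refs = grads
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, self.grad_refs, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
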