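"""Minimal neural-network layers with explicit backpropagation.

Implements exactly what the two trajectory classifiers need: 1D
convolution, max-pooling, dense layers, batch normalization, dropout, a
bidirectional (Elman) recurrent layer, ReLU, softmax cross-entropy and
Adam. Tensors are ``(N, C, T)`` for sequence layers and ``(N, D)`` for
dense layers. All randomness flows through an explicit generator, so
training is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    params: list
    grads: list

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x, train=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError


class Conv1D(Layer):
    """Valid (unpadded) 1D convolution: (N, Cin, T) -> (N, Cout, T-k+1)."""

    def __init__(self, c_in, c_out, kernel, rng):
        super().__init__()
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.W = rng.standard_normal((c_out, c_in, kernel)) * scale
        self.b = np.zeros(c_out)
        self.kernel = kernel
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=False):
        self._x = x
        xw = sliding_window_view(x, self.kernel, axis=2)  # (N, Cin, To, k)
        self._xw = xw
        y = np.einsum("nctk,ock->not", xw, self.W, optimize=True)
        return y + self.b[None, :, None]

    def backward(self, grad):
        self.grads[0][...] = np.einsum("nctk,not->ock", self._xw, grad,
                                       optimize=True)
        self.grads[1][...] = grad.sum(axis=(0, 2))
        N, C, T = self._x.shape
        dx = np.zeros_like(self._x)
        for k in range(self.kernel):
            dx[:, :, k:k + grad.shape[2]] += np.einsum(
                "not,oc->nct", grad, self.W[:, :, k], optimize=True)
        return dx


class MaxPool1D(Layer):
    def __init__(self, pool=2):
        super().__init__()
        self.pool = pool

    def forward(self, x, train=False):
        N, C, T = x.shape
        T2 = (T // self.pool) * self.pool
        xr = x[:, :, :T2].reshape(N, C, T2 // self.pool, self.pool)
        self._arg = xr.argmax(axis=3)
        self._shape = x.shape
        return xr.max(axis=3)

    def backward(self, grad):
        N, C, To = grad.shape
        dx = np.zeros(self._shape)
        dxr = dx[:, :, :To * self.pool].reshape(N, C, To, self.pool)
        n, c, t = np.ogrid[:N, :C, :To]
        dxr[n, c, t, self._arg] = grad
        return dx


class ReLU(Layer):
    def forward(self, x, train=False):
        self._m = x > 0
        return x * self._m

    def backward(self, grad):
        return grad * self._m


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(len(x), -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, d_in, d_out, rng):
        super().__init__()
        self.W = rng.standard_normal((d_in, d_out)) * np.sqrt(2.0 / d_in)
        self.b = np.zeros(d_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.W.T


class Dropout(Layer):
    def __init__(self, p, rng):
        super().__init__()
        if not 0 <= p < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.p == 0:
            self._m = None
            return x
        self._m = (self.rng.random(x.shape) >= self.p) / (1 - self.p)
        return x * self._m

    def backward(self, grad):
        return grad if self._m is None else grad * self._m


class BatchNorm(Layer):
    """Per-channel batch normalization over (N, T) for (N, C, T) inputs
    (or over N for (N, D) inputs)."""

    def __init__(self, channels, momentum=0.9, eps=1e-5):
        super().__init__()
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.momentum, self.eps = momentum, eps
        self.run_mean = np.zeros(channels)
        self.run_var = np.ones(channels)

    def _axes(self, x):
        return (0, 2) if x.ndim == 3 else (0,)

    def _expand(self, v, ndim):
        return v[None, :, None] if ndim == 3 else v[None, :]

    def forward(self, x, train=False):
        ax = self._axes(x)
        if train:
            mean = x.mean(axis=ax)
            var = x.var(axis=ax)
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        xm = x - self._expand(mean, x.ndim)
        std = np.sqrt(var + self.eps)
        xhat = xm / self._expand(std, x.ndim)
        self._cache = (xhat, std, x.ndim, ax)
        return self._expand(self.gamma, x.ndim) * xhat + self._expand(self.beta, x.ndim)

    def backward(self, grad):
        xhat, std, ndim, ax = self._cache
        n = np.prod([grad.shape[a] for a in ax])
        self.grads[0][...] = (grad * xhat).sum(axis=ax)
        self.grads[1][...] = grad.sum(axis=ax)
        g = grad * self._expand(self.gamma, ndim)
        dx = (g - g.mean(axis=ax, keepdims=True)
              - xhat * (g * xhat).mean(axis=ax, keepdims=True))
        return dx / self._expand(std, ndim)


class BiRNN(Layer):
    """Bidirectional Elman (tanh) recurrent layer.

    Input (N, C, T) -> output (N, 2H, T'), where T' = ceil(T / stride):
    forward and backward hidden sequences are concatenated on the channel
    axis and optionally subsampled in time, so stacked layers reduce the
    sequence dimension progressively.
    """

    def __init__(self, c_in, hidden, rng, stride=1):
        super().__init__()
        s_in = np.sqrt(1.0 / c_in)
        s_h = np.sqrt(1.0 / hidden)
        self.Wx = rng.standard_normal((2, c_in, hidden)) * s_in
        self.Wh = rng.standard_normal((2, hidden, hidden)) * s_h
        self.b = np.zeros((2, hidden))
        self.hidden = hidden
        self.stride = stride
        self.params = [self.Wx, self.Wh, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]

    def _run(self, x, direction):
        N, C, T = x.shape
        Wx, Wh, b = self.Wx[direction], self.Wh[direction], self.b[direction]
        hs = np.zeros((T, N, self.hidden))
        h = np.zeros((N, self.hidden))
        order = range(T) if direction == 0 else range(T - 1, -1, -1)
        for t in order:
            h = np.tanh(x[:, :, t] @ Wx + h @ Wh + b)
            hs[t] = h
        return hs

    def forward(self, x, train=False):
        self._x = x
        self._hs = [self._run(x, 0), self._run(x, 1)]
        T = x.shape[2]
        self._keep = np.arange(0, T, self.stride)
        out = np.concatenate([
            self._hs[0].transpose(1, 2, 0),
            self._hs[1].transpose(1, 2, 0)], axis=1)
        return out[:, :, self._keep]

    def _back_dir(self, gh_seq, direction):
        """gh_seq: (T, N, H) gradient wrt the hidden state sequence."""
        x = self._x
        hs = self._hs[direction]
        N, C, T = x.shape
        Wx, Wh = self.Wx[direction], self.Wh[direction]
        dWx = np.zeros_like(Wx); dWh = np.zeros_like(Wh)
        db = np.zeros(self.hidden)
        dx = np.zeros_like(x)
        carry = np.zeros((N, self.hidden))
        order = range(T - 1, -1, -1) if direction == 0 else range(T)
        for t in order:
            g = gh_seq[t] + carry
            pre = g * (1 - hs[t] ** 2)
            hprev_idx = t - 1 if direction == 0 else t + 1
            if 0 <= hprev_idx < T and ((direction == 0 and t > 0)
                                       or (direction == 1 and t < T - 1)):
                hprev = hs[hprev_idx]
                carry = pre @ Wh.T
            else:
                hprev = np.zeros((N, self.hidden))
                carry = np.zeros((N, self.hidden))
            dWx += x[:, :, t].T @ pre
            dWh += hprev.T @ pre
            db += pre.sum(axis=0)
            dx[:, :, t] += pre @ Wx.T
        return dWx, dWh, db, dx

    def backward(self, grad):
        N, _, Tk = grad.shape
        T = self._x.shape[2]
        H = self.hidden
        gh = np.zeros((2, T, N, H))
        for d in range(2):
            sub = grad[:, d * H:(d + 1) * H, :]        # (N, H, Tk)
            gh[d][self._keep] = sub.transpose(2, 0, 1)
        dx = np.zeros_like(self._x)
        for d in range(2):
            dWx, dWh, db, dxd = self._back_dir(gh[d], d)
            self.grads[0][d] = dWx
            self.grads[1][d] = dWh
            self.grads[2][d] = db
            dx += dxd
        return dx


class LastTimestep(Layer):
    """(N, C, T) -> (N, C): forward-direction last step + backward first."""

    def forward(self, x, train=False):
        self._shape = x.shape
        C = x.shape[1] // 2
        self._C = C
        return np.concatenate([x[:, :C, -1], x[:, C:, 0]], axis=1)

    def backward(self, grad):
        dx = np.zeros(self._shape)
        C = self._C
        dx[:, :C, -1] = grad[:, :C]
        dx[:, C:, 0] = grad[:, C:]
        return dx


class Sequential(Layer):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self):
        for layer in self.layers:
            yield from zip(layer.params, layer.grads)


def softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits, y):
    """Mean softmax cross-entropy and its gradient wrt the logits."""
    p = softmax(logits)
    n = len(y)
    loss = -np.log(np.maximum(p[np.arange(n), y], 1e-300)).mean()
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n


class Adam:
    def __init__(self, param_grad_pairs, lr=1e-3, beta1=0.9, beta2=0.999,
                 eps=1e-8):
        self.pairs = list(param_grad_pairs)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.pairs]
        self.v = [np.zeros_like(p) for p, _ in self.pairs]
        self.t = 0

    def step(self):
        self.t += 1
        for k, (p, g) in enumerate(self.pairs):
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
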