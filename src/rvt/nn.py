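"""Low-level numpy building blocks: convolution, pooling, batch-norm, Adam.

Shapes follow the channels-last convention: images are (N, H, W, C) and
convolution kernels are (K, K, C_in, C_out).  Convolutions are stride 1 with
zero-filled "same" padding; max pooling is 2x2 with stride 2 (odd inputs are
padded with -inf so output size is ceil(n/2)).

Every forward returns the cache its backward needs; there is no autograd.
"""

from __future__ import annotations

import numpy as np


# ---------------------------------------------------------------- convolution

def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N,H,W,C) -> (N*H*W, k*k*C) patch matrix for stride-1 same conv."""
    n, h, w, c = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    # windows over spatial axes: (N, H, W, k, k, C)
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
    # sliding_window_view yields (N, H, W, C, k, k); put C innermost-last
    win = win.transpose(0, 1, 2, 4, 5, 3)
    return np.ascontiguousarray(win).reshape(n * h * w, k * k * c)


def conv2d_forward(x: np.ndarray, weights: np.ndarray):
    """Stride-1 same convolution. Returns (out, cache)."""
    k, _, c_in, c_out = weights.shape
    n, h, w, c = x.shape
    if c != c_in:
        raise ValueError(f"input has {c} channels, kernel expects {c_in}")
    cols = _im2col(x, k)
    out = cols @ weights.reshape(k * k * c_in, c_out)
    return out.reshape(n, h, w, c_out), (cols, x.shape, k)


def conv2d_backward(dout: np.ndarray, weights: np.ndarray, cache):
    """Gradients wrt input and weights for conv2d_forward."""
    cols, x_shape, k = cache
    n, h, w, c_in = x_shape
    c_out = weights.shape[-1]
    dmat = dout.reshape(n * h * w, c_out)
    dw = (cols.T @ dmat).reshape(weights.shape)
    dcols = dmat @ weights.reshape(k * k * c_in, c_out).T
    # fold columns back: scatter-add each kernel offset into the padded image
    p = k // 2
    dxp = np.zeros((n, h + 2 * p, w + 2 * p, c_in), dtype=dout.dtype)
    dcols = dcols.reshape(n, h, w, k, k, c_in)
    for i in range(k):
        for j in range(k):
            dxp[:, i:i + h, j:j + w, :] += dcols[:, :, :, i, j, :]
    dx = dxp[:, p:p + h, p:p + w, :]
    return dx, dw


# -------------------------------------------------------------------- pooling

def maxpool_forward(x: np.ndarray):
    """2x2 stride-2 max pooling with ceil sizing. Returns (out, cache).

    Ties within a window route the gradient to the first maximal position.
    """
    n, h, w, c = x.shape
    hp, wp = -(-h // 2) * 2, -(-w // 2) * 2
    if (hp, wp) != (h, w):
        x = np.pad(x, ((0, 0), (0, hp - h), (0, wp - w), (0, 0)),
                   constant_values=-np.inf)
    # gather each 2x2 window's 4 entries on one axis
    xr = (x.reshape(n, hp // 2, 2, wp // 2, 2, c)
           .transpose(0, 1, 3, 2, 4, 5)
           .reshape(n, hp // 2, wp // 2, 4, c))
    idx = xr.argmax(axis=3)
    out = np.take_along_axis(xr, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]
    return out, (idx, (n, h, w, c), (hp, wp))


def maxpool_backward(dout: np.ndarray, cache):
    idx, (n, h, w, c), (hp, wp) = cache
    dxr = np.zeros((n, hp // 2, wp // 2, 4, c), dtype=dout.dtype)
    np.put_along_axis(dxr, idx[:, :, :, None, :], dout[:, :, :, None, :], axis=3)
    dx = (dxr.reshape(n, hp // 2, wp // 2, 2, 2, c)
             .transpose(0, 1, 3, 2, 4, 5)
             .reshape(n, hp, wp, c))
    return dx[:, :h, :w, :]


# ----------------------------------------------------------------- batch-norm

class BatchNormState:
    """Gain/shift plus running statistics for one normalisation site."""

    __slots__ = ("gamma", "beta", "running_mean", "running_var")

    def __init__(self, n_features: int, dtype=np.float64):
        self.gamma = np.ones(n_features, dtype=dtype)
        self.beta = np.zeros(n_features, dtype=dtype)
        self.running_mean = np.zeros(n_features, dtype=dtype)
        self.running_var = np.ones(n_features, dtype=dtype)

    def copy(self) -> "BatchNormState":
        other = BatchNormState(self.gamma.shape[0], dtype=self.gamma.dtype)
        other.gamma = self.gamma.copy()
        other.beta = self.beta.copy()
        other.running_mean = self.running_mean.copy()
        other.running_var = self.running_var.copy()
        return other


def batchnorm_forward(x: np.ndarray, bn: BatchNormState, *, training: bool,
                      momentum: float = 0.9, eps: float = 1e-5):
    """Per-feature-map normalisation over (N, H, W). Returns (out, cache)."""
    if training:
        axes = tuple(range(x.ndim - 1))
        mean = x.mean(axis=axes)
        var = x.var(axis=axes)
        bn.running_mean = momentum * bn.running_mean + (1 - momentum) * mean
        bn.running_var = momentum * bn.running_var + (1 - momentum) * var
    else:
        mean, var = bn.running_mean, bn.running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x - mean) * inv_std
    out = bn.gamma * xhat + bn.beta
    return out, (xhat, inv_std, bn.gamma, training)


def batchnorm_backward(dout: np.ndarray, cache):
    xhat, inv_std, gamma, training = cache
    axes = tuple(range(dout.ndim - 1))
    dgamma = (dout * xhat).sum(axis=axes)
    dbeta = dout.sum(axis=axes)
    if not training:
        dx = dout * gamma * inv_std
        return dx, dgamma, dbeta
    m = dout.size // dout.shape[-1]
    dxhat = dout * gamma
    dx = (inv_std / m) * (m * dxhat - dxhat.sum(axis=axes)
                          - xhat * (dxhat * xhat).sum(axis=axes))
    return dx, dgamma, dbeta


# ------------------------------------------------------------------- readouts

def relu_forward(x):
    mask = x > 0
    return x * mask, mask


def global_avg_pool(x: np.ndarray) -> np.ndarray:
    return x.mean(axis=(1, 2))


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def sigmoid(z):
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


# ----------------------------------------------------------------------- Adam

class Adam:
    """Adam optimiser over a flat dict of numpy arrays."""

    def __init__(self, lr: float = 0.005, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 0.1):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m: dict = {}
        self.v: dict = {}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for key, g in grads.items():
            if key not in self.m:
                self.m[key] = np.zeros_like(g)
                self.v[key] = np.zeros_like(g)
            self.m[key] = b1 * self.m[key] + (1 - b1) * g
            self.v[key] = b2 * self.v[key] + (1 - b2) * g * g
            mhat = self.m[key] / bc1
            vhat = self.v[key] / bc2
            params[key] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
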