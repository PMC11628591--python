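"""Layer implementations with explicit forward/backward passes.

Convolutions use im2col + BLAS matmul; the input-gradient is itself a
convolution with the spatially flipped, channel-transposed kernel, so the
same machinery serves both directions.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N,C,H,W) -> (N, H*W, C*k*k) patch matrix for stride-1 convolution."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    # win: (N, C, H, W, k, k) -> (N, H, W, C, k, k)
    win = win.transpose(0, 2, 3, 1, 4, 5)
    return np.ascontiguousarray(win).reshape(n, h * w, c * k * k)


class Layer:
    params: list
    grads: list

    def __init__(self):
        self.params = []
        self.grads = []

    def forward(self, x, training=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2d(Layer):
    """Stride-1 'same' 2-D convolution (odd kernel), He-initialized."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        super().__init__()
        assert k % 2 == 1
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.pad = k // 2
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.W = (rng.standard_normal((c_out, c_in, k, k)) * scale).astype(F32)
        self.b = np.zeros(c_out, dtype=F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.params = [self.W, self.b]
        self.grads = [self.dW, self.db]
        self._x_col = None
        self._x_shape = None

    def forward(self, x, training=False):
        n, c, h, w = x.shape
        x_col = _im2col(x, self.k, self.pad)            # (N, HW, C*k*k)
        w_mat = self.W.reshape(self.c_out, -1)          # (Cout, C*k*k)
        out = x_col @ w_mat.T + self.b                  # (N, HW, Cout)
        if training:
            self._x_col = x_col
            self._x_shape = x.shape
        return out.transpose(0, 2, 1).reshape(n, self.c_out, h, w)

    def backward(self, grad):
        n, _, h, w = grad.shape
        g = grad.transpose(0, 2, 3, 1).reshape(n, h * w, self.c_out)
        # weight/bias gradients from cached patches
        dW = np.einsum("npo,npk->ok", g, self._x_col, optimize=True)
        self.dW[...] = dW.reshape(self.W.shape)
        self.db[...] = g.sum(axis=(0, 1))
        # input gradient: full correlation with flipped, transposed kernel
        w_flip = self.W[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (Cin,Cout,k,k)
        g_img = grad  # (N, Cout, H, W)
        g_col = _im2col(g_img, self.k, self.pad)
        dx = g_col @ w_flip.reshape(self.c_in, -1).T
        self._x_col = None
        return dx.transpose(0, 2, 1).reshape(self._x_shape)


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = np.ones(c, dtype=F32)
        self.beta = np.zeros(c, dtype=F32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.params = [self.gamma, self.beta]
        self.grads = [self.dgamma, self.dbeta]
        self.running_mean = np.zeros(c, dtype=F32)
        self.running_var = np.ones(c, dtype=F32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, training=False):
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if training:
            self._xhat = xhat.astype(F32)
            self._inv = inv.astype(F32)
        return (self.gamma[None, :, None, None] * xhat
                + self.beta[None, :, None, None]).astype(F32)

    def backward(self, grad):
        xhat, inv = self._xhat, self._inv
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        self.dgamma[...] = (grad * xhat).sum(axis=(0, 2, 3))
        self.dbeta[...] = grad.sum(axis=(0, 2, 3))
        g = grad * self.gamma[None, :, None, None]
        gsum = g.sum(axis=(0, 2, 3), keepdims=True)
        gxsum = (g * xhat).sum(axis=(0, 2, 3), keepdims=True)
        dx = inv[None, :, None, None] * (g - gsum / m - xhat * gxsum / m)
        self._xhat = None
        return dx.astype(F32)


class ReLU(Layer):
    def forward(self, x, training=False):
        out = np.maximum(x, 0)
        if training:
            self._mask = x > 0
        return out

    def backward(self, grad):
        out = grad * self._mask
        self._mask = None
        return out


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2; ties route gradient to the first maximum."""

    def forward(self, x, training=False):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = np.ascontiguousarray(xr).reshape(n, c, h // 2, w // 2, 4)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        if training:
            self._idx = idx
            self._shape = x.shape
        return out

    def backward(self, grad):
        n, c, h, w = self._shape
        flat = np.zeros((n, c, h // 2, w // 2, 4), dtype=grad.dtype)
        np.put_along_axis(flat, self._idx[..., None], grad[..., None], axis=-1)
        out = flat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self._idx = None
        return np.ascontiguousarray(out).reshape(n, c, h, w)


class UpsampleNearest2d(Layer):
    """2x nearest-neighbor upsampling; backward sums each 2x2 block."""

    def forward(self, x, training=False):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, grad):
        n, c, h, w = grad.shape
        return grad.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Dropout2d(Layer):
    """Spatial dropout: whole feature maps are zeroed during training."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0 <= p < 1:
            raise ValueError("dropout fraction must lie in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.p == 0:
            return x
        keep = (self.rng.random((x.shape[0], x.shape[1], 1, 1)) >= self.p)
        self._mask = keep.astype(F32) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad):
        if not hasattr(self, "_mask") or self._mask is None:
            return grad
        out = grad * self._mask
        self._mask = None
        return out


class Sequential(Layer):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)
        for lyr in self.layers:
            self.params.extend(lyr.params)
            self.grads.extend(lyr.grads)

    def forward(self, x, training=False):
        for lyr in self.layers:
            x = lyr.forward(x, training=training)
        return x

    def backward(self, grad):
        for lyr in reversed(self.layers):
            grad = lyr.backward(grad)
        return grad
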