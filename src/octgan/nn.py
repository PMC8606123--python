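"""Minimal convolutional network engine with explicit backpropagation.

Self-contained numpy implementation of the handful of primitives the cGAN
needs: strided convolution, strided transposed convolution, batch
normalization, the LeakyReLU / ReLU / tanh / sigmoid activations, a linear
head and an Adam optimizer. Layers are functional: ``forward`` returns
``(output, cache)`` and ``backward(grad, cache)`` returns the input gradient
while accumulating parameter gradients, so several passes (e.g. the
discriminator's real and fake branches) can be in flight at once.

Array layout is (N, C, H, W) float32 throughout. Convolutions use im2col /
col2im so the inner loop is a BLAS matmul.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param", "Conv2d", "ConvTranspose2d", "BatchNorm2d", "Linear",
    "LeakyReLU", "ReLU", "Tanh", "Sigmoid", "Adam",
    "im2col", "col2im",
]


class Param:
    """A learnable array with its gradient accumulator."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)


def _out_size(size: int, k: int, stride: int, pad: int) -> int:
    return (size + 2 * pad - k) // stride + 1


def im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (N, C*k*k, Ho*Wo) patch matrix."""
    n, c, h, w = x.shape
    ho, wo = _out_size(h, k, stride, pad), _out_size(w, k, stride, pad)
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((n, c, k, k, ho, wo), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i:i + stride * ho:stride,
                                  j:j + stride * wo:stride]
    return cols.reshape(n, c * k * k, ho * wo)


def col2im(cols: np.ndarray, xshape: tuple, k: int, stride: int,
           pad: int) -> np.ndarray:
    """Adjoint of :func:`im2col`: scatter-add patches back to (N, C, H, W)."""
    n, c, h, w = xshape
    ho, wo = _out_size(h, k, stride, pad), _out_size(w, k, stride, pad)
    cols = cols.reshape(n, c, k, k, ho, wo)
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            xp[:, :, i:i + stride * ho:stride,
               j:j + stride * wo:stride] += cols[:, :, i, j]
    return xp[:, :, pad:pad + h, pad:pad + w]


def _init_weight(rng: np.random.Generator, shape: tuple,
                 std: float = 0.02) -> np.ndarray:
    """Truncated normal (std 0.02, clipped at 2 std), the Pix2Pix convention."""
    w = rng.normal(0.0, std, size=shape)
    return np.clip(w, -2.0 * std, 2.0 * std)


class Conv2d:
    def __init__(self, cin: int, cout: int, k: int = 4, stride: int = 2,
                 pad: int = 1, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.k, self.stride, self.pad = k, stride, pad
        self.cin, self.cout = cin, cout
        self.weight = Param(_init_weight(rng, (cout, cin * k * k)))
        self.bias = Param(np.zeros(cout))

    def params(self):
        return [("weight", self.weight), ("bias", self.bias)]

    def forward(self, x: np.ndarray):
        n, c, h, w = x.shape
        cols = im2col(x, self.k, self.stride, self.pad)
        y = self.weight.data @ cols + self.bias.data[None, :, None]
        ho = _out_size(h, self.k, self.stride, self.pad)
        wo = _out_size(w, self.k, self.stride, self.pad)
        return y.reshape(n, self.cout, ho, wo), (x.shape, cols)

    def backward(self, dy: np.ndarray, cache):
        xshape, cols = cache
        n = dy.shape[0]
        dyf = dy.reshape(n, self.cout, -1)
        self.weight.grad += np.einsum("ncl,nkl->ck", dyf, cols,
                                      optimize=True)
        self.bias.grad += dy.sum(axis=(0, 2, 3))
        dcols = self.weight.data.T @ dyf
        return col2im(dcols, xshape, self.k, self.stride, self.pad)


class ConvTranspose2d:
    """Stride-2 upsampling convolution (adjoint geometry of Conv2d)."""

    def __init__(self, cin: int, cout: int, k: int = 4, stride: int = 2,
                 pad: int = 1, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.k, self.stride, self.pad = k, stride, pad
        self.cin, self.cout = cin, cout
        self.weight = Param(_init_weight(rng, (cin, cout * k * k)))
        self.bias = Param(np.zeros(cout))

    def params(self):
        return [("weight", self.weight), ("bias", self.bias)]

    def out_shape(self, h: int, w: int):
        ho = (h - 1) * self.stride - 2 * self.pad + self.k
        wo = (w - 1) * self.stride - 2 * self.pad + self.k
        return ho, wo

    def forward(self, x: np.ndarray):
        n, c, h, w = x.shape
        xf = x.reshape(n, c, h * w)
        cols = np.swapaxes(self.weight.data.T @ xf, 0, 0)
        ho, wo = self.out_shape(h, w)
        y = col2im(cols, (n, self.cout, ho, wo), self.k, self.stride, self.pad)
        y += self.bias.data[None, :, None, None]
        return y, (x.shape, xf)

    def backward(self, dy: np.ndarray, cache):
        xshape, xf = cache
        n, c, h, w = xshape
        dcols = im2col(dy, self.k, self.stride, self.pad)
        self.weight.grad += np.einsum("nil,njl->ij", xf, dcols,
                                      optimize=True)
        self.bias.grad += dy.sum(axis=(0, 2, 3))
        dx = self.weight.data @ dcols
        return dx.reshape(xshape)


class BatchNorm2d:
    """Per-channel normalization over the (N, H, W) axes.

    With the batch size of 1 used throughout training this reduces to
    instance normalization; batch statistics are used in inference too, so
    a stored checkpoint needs no running moments.
    """

    def __init__(self, c: int, eps: float = 1e-5):
        self.eps = eps
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))

    def params(self):
        return [("gamma", self.gamma), ("beta", self.beta)]

    def forward(self, x: np.ndarray):
        m = x.shape[0] * x.shape[2] * x.shape[3]
        if m == 1:
            # normalizing a single element would zero the signal entirely;
            # fall through to a per-channel affine map instead
            y = self.gamma.data[None, :, None, None] * x \
                + self.beta.data[None, :, None, None]
            return y, (x, None)
        mu = x.mean(axis=(0, 2, 3), keepdims=True)
        var = x.var(axis=(0, 2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        y = self.gamma.data[None, :, None, None] * xhat \
            + self.beta.data[None, :, None, None]
        return y, (xhat, inv)

    def backward(self, dy: np.ndarray, cache):
        xhat, inv = cache
        if inv is None:  # degenerate single-element path
            self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
            self.beta.grad += dy.sum(axis=(0, 2, 3))
            return dy * self.gamma.data[None, :, None, None]
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma.data[None, :, None, None]
        mean_d = dxhat.mean(axis=(0, 2, 3), keepdims=True)
        mean_dx = (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        return inv * (dxhat - mean_d - xhat * mean_dx)


class Linear:
    def __init__(self, cin: int, cout: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.weight = Param(_init_weight(rng, (cout, cin)))
        self.bias = Param(np.zeros(cout))

    def params(self):
        return [("weight", self.weight), ("bias", self.bias)]

    def forward(self, x: np.ndarray):
        return x @ self.weight.data.T + self.bias.data, x

    def backward(self, dy: np.ndarray, cache):
        x = cache
        self.weight.grad += dy.T @ x
        self.bias.grad += dy.sum(axis=0)
        return dy @ self.weight.data


class LeakyReLU:
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def params(self):
        return []

    def forward(self, x):
        mask = x > 0
        return np.where(mask, x, self.slope * x), mask

    def backward(self, dy, mask):
        return np.where(mask, dy, self.slope * dy)


class ReLU:
    def params(self):
        return []

    def forward(self, x):
        mask = x > 0
        return x * mask, mask

    def backward(self, dy, mask):
        return dy * mask


class Tanh:
    def params(self):
        return []

    def forward(self, x):
        y = np.tanh(x)
        return y, y

    def backward(self, dy, y):
        return dy * (1.0 - y * y)


class Sigmoid:
    def params(self):
        return []

    def forward(self, x):
        y = 1.0 / (1.0 + np.exp(-x))
        return y, y

    def backward(self, dy, y):
        return dy * y * (1.0 - y)


class Adam:
    """Adam over a flat list of :class:`Param`."""

    def __init__(self, params: list, lr: float = 2e-4,
                 betas: tuple = (0.5, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1.0 - b1) * p.grad
            v *= b2
            v += (1.0 - b2) * p.grad * p.grad
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
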