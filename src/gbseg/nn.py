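"""Minimal NumPy neural-network layers with explicit backpropagation.

Only what the encoder–decoder segmentation network needs: same-padded
convolution (im2col), batch normalization, ReLU, 2x2 max pooling that
returns argmax indices, index-driven max unpooling, adaptive average
pooling, bilinear upsampling (as an exact linear map, so its transpose is
the backward pass), softmax cross-entropy, and Adam.

All layers work on float32 arrays shaped (N, C, H, W).  Each layer caches
what its backward pass needs during forward; ``backward`` consumes the
output gradient and returns the input gradient while accumulating parameter
gradients in ``Parameter.grad``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F32 = np.float32


class Parameter:
    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=F32)
        self.grad = np.zeros_like(self.data)

    def zero_grad(self) -> None:
        self.grad[...] = 0


class Layer:
    """Base layer: parameters, buffers (non-learned state), train/eval mode."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Parameter]:
        return []

    def buffers(self) -> list[np.ndarray]:
        return []

    def set_training(self, mode: bool) -> None:
        self.training = mode


def _conv2d_same(x: np.ndarray, weight: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Stride-1 same-padded correlation; returns (output, im2col matrix)."""
    n, c, h, w = x.shape
    cout, cin, k, _ = weight.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (N,C,H,W,k,k)
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n, h * w, c * k * k)
    out = cols @ weight.reshape(cout, cin * k * k).T  # (N, HW, Cout)
    return out.transpose(0, 2, 1).reshape(n, cout, h, w), cols


class Conv2d(Layer):
    """k x k convolution, stride 1, same padding, He-initialized."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator):
        super().__init__()
        if kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd for same padding")
        fan_in = in_channels * kernel_size * kernel_size
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0, std, (out_channels, in_channels,
                                                    kernel_size, kernel_size)))
        self.bias = Parameter(np.zeros(out_channels))
        self._cols: np.ndarray | None = None

    def parameters(self):
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        out, self._cols = _conv2d_same(x, self.weight.data)
        return out + self.bias.data[None, :, None, None]

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        n, cout, h, w = grad_out.shape
        gflat = grad_out.reshape(n, cout, h * w)
        self.bias.grad += gflat.sum(axis=(0, 2))
        # dW: accumulate over batch and positions
        self.weight.grad += np.tensordot(gflat, self._cols, axes=([0, 2], [0, 1])
                                         ).reshape(self.weight.data.shape)
        # dX = correlation of grad with spatially flipped, in/out-swapped kernels
        w_t = np.ascontiguousarray(
            self.weight.data.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1])
        grad_in, _ = _conv2d_same(grad_out, w_t)
        self._cols = None
        return grad_in


class BatchNorm2d(Layer):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(channels, dtype=F32)
        self.running_var = np.ones(channels, dtype=F32)
        self._cache = None

    def parameters(self):
        return [self.gamma, self.beta]

    def buffers(self):
        return [self.running_mean, self.running_var]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std)
        return self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        self._cache = None
        n, c, h, w = grad_out.shape
        m = n * h * w
        dbeta = grad_out.sum(axis=(0, 2, 3))
        dgamma = (grad_out * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dbeta
        self.gamma.grad += dgamma
        if not self.training:
            return grad_out * (self.gamma.data * inv_std)[None, :, None, None]
        coeff = (self.gamma.data * inv_std / m)[None, :, None, None]
        return coeff * (m * grad_out - dbeta[None, :, None, None]
                        - xhat * dgamma[None, :, None, None])


class ReLU(Layer):
    def __init__(self):
        super().__init__()
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        mask, self._mask = self._mask, None
        return np.where(mask, grad_out, 0)


def max_pool2d(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """2x2 stride-2 max pooling.

    Returns the pooled map and, per pooled cell, the flat (row*W + col)
    position of the retained maximum in the input map.  Both are (N,C,Ho,Wo).
    """
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"spatial dims must be even for 2x2 pooling, got {h}x{w}")
    ho, wo = h // 2, w // 2
    cells = x.reshape(n, c, ho, 2, wo, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho, wo, 4)
    local = cells.argmax(axis=-1)
    pooled = np.take_along_axis(cells, local[..., None], axis=-1)[..., 0]
    rows = 2 * np.arange(ho)[None, None, :, None] + local // 2
    cols = 2 * np.arange(wo)[None, None, None, :] + local % 2
    return pooled, (rows * w + cols).astype(np.int64)


def max_unpool2d(pooled: np.ndarray, indices: np.ndarray,
                 out_hw: tuple[int, int]) -> np.ndarray:
    """Scatter pooled values to their stored argmax positions, zeros elsewhere."""
    n, c, ho, wo = pooled.shape
    h, w = out_hw
    if indices.shape != pooled.shape:
        raise ValueError("indices shape must match pooled map shape")
    if indices.min() < 0 or indices.max() >= h * w:
        raise ValueError("pooling indices out of range for the requested output size")
    out = np.zeros((n, c, h * w), dtype=pooled.dtype)
    np.put_along_axis(out, indices.reshape(n, c, -1), pooled.reshape(n, c, -1), axis=2)
    return out.reshape(n, c, h, w)


def _unpool_gather(grad_out: np.ndarray, indices: np.ndarray) -> np.ndarray:
    n, c, ho, wo = indices.shape
    flat = grad_out.reshape(n, c, -1)
    return np.take_along_axis(flat, indices.reshape(n, c, -1), axis=2).reshape(n, c, ho, wo)


class MaxPool2d(Layer):
    """Stateful wrapper around max_pool2d keeping indices for backward."""

    def __init__(self):
        super().__init__()
        self.indices: np.ndarray | None = None
        self.in_hw: tuple[int, int] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.in_hw = x.shape[2:]
        pooled, self.indices = max_pool2d(x)
        return pooled

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return max_unpool2d(grad_out, self.indices, self.in_hw)


class MaxUnpool2d(Layer):
    """Unpooling driven by externally supplied indices (the paired pool's)."""

    def __init__(self):
        super().__init__()
        self._indices = None

    def forward(self, x: np.ndarray, indices: np.ndarray,
                out_hw: tuple[int, int]) -> np.ndarray:
        self._indices = indices
        return max_unpool2d(x, indices, out_hw)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return _unpool_gather(grad_out, self._indices)


def _pool_edges(n_in: int, n_out: int) -> list[tuple[int, int]]:
    return [(int(np.floor(i * n_in / n_out)), int(np.ceil((i + 1) * n_in / n_out)))
            for i in range(n_out)]


def adaptive_avg_pool2d(x: np.ndarray, bins: int) -> np.ndarray:
    """Average-pool to a bins x bins grid with near-equal integer cells."""
    n, c, h, w = x.shape
    if bins > min(h, w):
        raise ValueError(f"bin count {bins} exceeds feature-map size {h}x{w}")
    out = np.empty((n, c, bins, bins), dtype=x.dtype)
    for i, (r0, r1) in enumerate(_pool_edges(h, bins)):
        for j, (c0, c1) in enumerate(_pool_edges(w, bins)):
            out[:, :, i, j] = x[:, :, r0:r1, c0:c1].mean(axis=(2, 3))
    return out


class AdaptiveAvgPool2d(Layer):
    def __init__(self, bins: int):
        super().__init__()
        self.bins = bins
        self._in_shape = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return adaptive_avg_pool2d(x, self.bins)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        grad_in = np.zeros(self._in_shape, dtype=grad_out.dtype)
        for i, (r0, r1) in enumerate(_pool_edges(h, self.bins)):
            for j, (c0, c1) in enumerate(_pool_edges(w, self.bins)):
                area = (r1 - r0) * (c1 - c0)
                grad_in[:, :, r0:r1, c0:c1] += grad_out[:, :, i:i + 1, j:j + 1] / area
        return grad_in


def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """1-D bilinear interpolation as an (n_out, n_in) matrix (half-pixel centers)."""
    m = np.zeros((n_out, n_in), dtype=F32)
    if n_in == 1:
        m[:, 0] = 1
        return m
    src = np.clip((np.arange(n_out) + 0.5) * n_in / n_out - 0.5, 0, n_in - 1)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = (src - lo).astype(F32)
    np.add.at(m, (np.arange(n_out), lo), 1 - frac)
    np.add.at(m, (np.arange(n_out), hi), frac)
    return m


class BilinearUpsample(Layer):
    """Bilinear resize to a fixed target size; exactly linear, so backward
    is multiplication by the transposed interpolation matrices."""

    def __init__(self, out_hw: tuple[int, int]):
        super().__init__()
        self.out_hw = out_hw
        self._mats: tuple[np.ndarray, np.ndarray] | None = None

    def _matrices(self, in_hw):
        if self._mats is None or self._mats[0].shape[1] != in_hw[0] \
                or self._mats[1].shape[1] != in_hw[1]:
            self._mats = (_interp_matrix(in_hw[0], self.out_hw[0]),
                          _interp_matrix(in_hw[1], self.out_hw[1]))
        return self._mats

    def forward(self, x: np.ndarray) -> np.ndarray:
        mr, mc = self._matrices(x.shape[2:])
        y = np.einsum("oi,ncij->ncoj", mr, x, optimize=True)
        return np.einsum("pj,ncoj->ncop", mc, y, optimize=True)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        mr, mc = self._mats
        y = np.einsum("oi,ncoj->ncij", mr, grad_out, optimize=True)
        return np.einsum("pj,ncip->ncij", mc, y, optimize=True)


def softmax_cross_entropy(logits: np.ndarray, targets: np.ndarray
                          ) -> tuple[float, np.ndarray]:
    """Mean per-pixel cross-entropy over (N, C, H, W) logits and integer
    (N, H, W) targets; returns (loss, gradient w.r.t. logits)."""
    n, c, h, w = logits.shape
    shifted = logits - logits.max(axis=1, keepdims=True)
    exp = np.exp(shifted)
    softmax = exp / exp.sum(axis=1, keepdims=True)
    idx = (np.arange(n)[:, None, None], targets,
           np.arange(h)[None, :, None], np.arange(w)[None, None, :])
    picked = shifted[np.arange(n)[:, None, None], targets,
                     np.arange(h)[None, :, None], np.arange(w)[None, None, :]]
    logz = np.log(exp.sum(axis=1))
    loss = float((logz - picked).mean())
    grad = softmax / (n * h * w)
    np.subtract.at(grad, idx, 1.0 / (n * h * w))
    return loss, grad.astype(F32)


class Adam:
    def __init__(self, parameters: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.parameters = parameters
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in parameters]
        self.v = [np.zeros_like(p.data) for p in parameters]

    def zero_grad(self) -> None:
        for p in self.parameters:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for p, m, v in zip(self.parameters, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
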