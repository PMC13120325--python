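"""Layer primitives with explicit forward/backward passes.

All activations are ``float32`` arrays in *channel-major* layout
``(C, N, H, W)``: with channels leading, a stride-1 "same" convolution over
the whole batch collapses to a single wide GEMM

    Y(O, N*H*W) = W(O, C*k*k) @ cols(C*k*k, N*H*W)

whose column matrix is assembled by k*k contiguous tap-slice copies — no
transposition anywhere on the hot path, which is what makes CPU training
feasible.  The input gradient is itself a convolution of the upstream
gradient with the spatially flipped, channel-transposed kernel, so it rides
the same fast path; the weight gradient is one GEMM against the (cached or
rebuilt) column matrix.

Each layer stores what its backward pass needs on ``self``; ``backward``
consumes the upstream gradient, returns the input gradient, and accumulates
parameter gradients in ``self.grads``.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base class: parameterless layers inherit empty param/grad dicts."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


#: reusable scratch buffers for the large, short-lived conv intermediates
#: (column matrices and padded inputs).  Allocating these fresh on every
#: call dominates runtime through page-fault overhead; reusing one arena
#: per role keeps the pages warm.  Not thread-safe, like the rest of the
#: engine.
_SCRATCH: dict[str, np.ndarray] = {}


def _scratch(tag: str, shape: tuple[int, ...], dtype=np.float32) -> np.ndarray:
    nbytes = int(np.prod(shape)) * np.dtype(dtype).itemsize
    buf = _SCRATCH.get(tag)
    if buf is None or buf.nbytes < nbytes:
        _SCRATCH[tag] = buf = np.empty(nbytes, dtype=np.uint8)
    return buf[:nbytes].view(dtype).reshape(shape)


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(C,N,H,W) -> (C*k*k, N*H*W) column matrix for stride-1 convolution.

    Returns a view into shared scratch: valid only until the next
    ``_im2col`` call, which is all the GEMM consumers need.
    """
    c, n, h, w = x.shape
    xp = _scratch("im2col_pad", (c, n, h + 2 * pad, w + 2 * pad), x.dtype)
    if pad:
        xp[:, :, :pad] = 0
        xp[:, :, -pad:] = 0
        xp[:, :, :, :pad] = 0
        xp[:, :, :, -pad:] = 0
    xp[:, :, pad:pad + h, pad:pad + w] = x
    cols = _scratch("im2col_cols", (c, k * k, n, h, w), x.dtype)
    t = 0
    for i in range(k):
        for j in range(k):
            cols[:, t] = xp[:, :, i:i + h, j:j + w]
            t += 1
    return cols.reshape(c * k * k, n * h * w)


class Conv2d(Layer):
    """k x k stride-1 same-convolution, He-uniform initialized."""

    def __init__(self, in_ch: int, out_ch: int, kernel_size: int = 3,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, kernel_size
        self.pad = kernel_size // 2
        rng = rng or np.random.default_rng()
        fan_in = in_ch * kernel_size * kernel_size
        bound = np.sqrt(6.0 / fan_in)
        self.params["W"] = rng.uniform(
            -bound, bound, (out_ch, in_ch, kernel_size, kernel_size)
        ).astype(np.float32)
        self.params["b"] = np.zeros(out_ch, dtype=np.float32)

    #: forward column matrices up to this element count are kept for the
    #: weight gradient; larger ones are rebuilt in backward to bound memory
    CACHE_MAX = 40_000_000

    def forward(self, x, train):
        c, n, h, w = x.shape
        cols = _im2col(x, self.k, self.pad)
        y = self.params["W"].reshape(self.out_ch, -1) @ cols
        y += self.params["b"][:, None]
        if train:
            self._shape = (c, n, h, w)
            if cols.size <= self.CACHE_MAX:
                # copy out of shared scratch into a per-layer buffer
                if getattr(self, "_cols_buf", None) is None \
                        or self._cols_buf.shape != cols.shape:
                    self._cols_buf = cols.copy()
                else:
                    np.copyto(self._cols_buf, cols)
                self._cols, self._x = self._cols_buf, None
            else:
                self._cols, self._x = None, x
        return y.reshape(self.out_ch, n, h, w)

    def backward(self, dy, need_dx: bool = True):
        c, n, h, w = self._shape
        k, pad = self.k, self.pad
        dout = dy.reshape(self.out_ch, n * h * w)

        self.grads["b"] = dout.sum(axis=1)

        cols = self._cols if self._cols is not None \
            else _im2col(self._x, k, pad)
        self.grads["W"] = (dout @ cols.T).reshape(self.params["W"].shape)
        self._cols = self._x = None
        if not need_dx:
            return None

        # input gradient = convolution of dy with the flipped kernel,
        # channels transposed — reuses the same single-GEMM fast path
        w_flip = np.ascontiguousarray(
            self.params["W"][:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        ).reshape(self.in_ch, -1)
        dy_cols = _im2col(dy, k, pad)
        return (w_flip @ dy_cols).reshape(c, n, h, w)


class BatchNorm2d(Layer):
    """Per-channel batch normalization over (N, H, W).

    Training mode normalizes by batch statistics and updates running
    estimates; evaluation mode uses the running estimates only, which makes
    inference deterministic and batch-size independent.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params["gamma"] = np.ones(channels, dtype=np.float32)
        self.params["beta"] = np.zeros(channels, dtype=np.float32)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x, train):
        g = self.params["gamma"][:, None, None, None]
        b = self.params["beta"][:, None, None, None]
        if train:
            mean = x.mean(axis=(1, 2, 3))
            var = x.var(axis=(1, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean[:, None, None, None]) * inv[:, None, None, None]
            self._xhat, self._inv = xhat, inv
            return g * xhat + b
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        xhat = (x - self.running_mean[:, None, None, None]) \
            * inv[:, None, None, None]
        return g * xhat + b

    def backward(self, dy):
        xhat, inv = self._xhat, self._inv
        m = dy.shape[1] * dy.shape[2] * dy.shape[3]
        self.grads["gamma"] = (dy * xhat).sum(axis=(1, 2, 3))
        self.grads["beta"] = dy.sum(axis=(1, 2, 3))
        g = self.params["gamma"][:, None, None, None]
        dxhat = dy * g
        s1 = dxhat.sum(axis=(1, 2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(1, 2, 3), keepdims=True)
        dx = (inv[:, None, None, None] / m) * (m * dxhat - s1 - xhat * s2)
        self._xhat = None
        return dx.astype(dy.dtype)


class ReLU(Layer):
    """Rectifier; clips its input in place (the producing layer's caches
    never reference the raw pre-activation)."""

    def forward(self, x, train):
        self._mask = x > 0
        return np.maximum(x, 0, out=x)

    def backward(self, dy):
        dy *= self._mask
        self._mask = None
        return dy


class MaxPool2(Layer):
    """2x2 max-pooling, stride 2; input H and W must be even."""

    def forward(self, x, train):
        c, n, h, w = x.shape
        xr = x.reshape(c, n, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = np.ascontiguousarray(xr).reshape(c, n, h // 2, w // 2, 4)
        self._arg = flat.argmax(axis=-1)
        self._shape = x.shape
        return flat.max(axis=-1)

    def backward(self, dy):
        c, n, h, w = self._shape
        dflat = np.zeros((c, n, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(dflat, self._arg[..., None], dy[..., None], axis=-1)
        dx = dflat.reshape(c, n, h // 2, w // 2, 2, 2).transpose(
            0, 1, 2, 4, 3, 5).reshape(c, n, h, w)
        self._arg = None
        return np.ascontiguousarray(dx)


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Row-interpolation matrix for 2x bilinear upsampling (half-pixel
    centers, edge-clamped), shape (n_out, n_in)."""
    a = np.zeros((n_out, n_in), dtype=np.float32)
    src = (np.arange(n_out) + 0.5) / (n_out / n_in) - 0.5
    lo = np.clip(np.floor(src).astype(int), 0, n_in - 1)
    hi = np.clip(lo + 1, 0, n_in - 1)
    frac = np.clip(src - np.floor(src), 0.0, 1.0)
    frac[src < 0] = 0.0
    a[np.arange(n_out), lo] += 1.0 - frac
    a[np.arange(n_out), hi] += frac
    return a


class BilinearUp2(Layer):
    """2x bilinear upsampling as separable linear maps (exact transpose
    in backward)."""

    def __init__(self):
        super().__init__()
        self._mats: dict[int, np.ndarray] = {}

    def _mat(self, n_in: int) -> np.ndarray:
        if n_in not in self._mats:
            self._mats[n_in] = _interp_matrix(2 * n_in, n_in)
        return self._mats[n_in]

    def forward(self, x, train):
        c, n, h, w = x.shape
        self._hw = (h, w)
        ah, aw = self._mat(h), self._mat(w)
        y = np.tensordot(x, aw, axes=([3], [1]))          # C,N,H,2W
        y = np.tensordot(y, ah, axes=([2], [1]))          # C,N,2W,2H
        return np.ascontiguousarray(y.transpose(0, 1, 3, 2))

    def backward(self, dy):
        h, w = self._hw
        ah, aw = self._mat(h), self._mat(w)
        dx = np.tensordot(dy, ah, axes=([2], [0]))        # C,N,2W,H
        dx = np.tensordot(dx, aw, axes=([2], [0]))        # C,N,H,W
        return np.ascontiguousarray(dx)


class NearestUp2(Layer):
    """2x nearest-neighbour upsampling (alternative upsample_mode)."""

    def forward(self, x, train):
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dy):
        c, n, h2, w2 = dy.shape
        return dy.reshape(c, n, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))


class Sigmoid(Layer):
    def forward(self, x, train):
        np.negative(x, out=x)
        np.exp(x, out=x)
        x += 1.0
        np.reciprocal(x, out=x)
        self._y = x
        return x

    def backward(self, dy):
        dx = dy * self._y * (1.0 - self._y)
        self._y = None
        return dx
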