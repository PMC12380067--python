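"""Minimal CPU neural-network engine (numpy, manual backprop).

Supports exactly what the dual-branch SSVEP decoder needs: stride-1 2-D
convolutions (optionally dilated, computed via FFT products so broad
kernels stay cheap), batch normalization, ReLU, max pooling, dropout,
linear layers, residual blocks, softmax cross-entropy, and plain SGD with
a cosine-annealing warm-restart schedule.  All layers carry explicit
``forward``/``backward`` passes; parameters live in :class:`Param` pairs
of value and gradient.
"""

from __future__ import annotations

import math

import numpy as np
import scipy.fft as sfft

__all__ = [
    "Param", "Layer", "Conv2d", "BatchNorm2d", "ReLU", "MaxPool2d",
    "Dropout", "Flatten", "Linear", "Sequential", "Residual",
    "softmax", "cross_entropy", "SGD", "cosine_warm_restarts",
]


class Param:
    """A trainable array and its gradient accumulator."""

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []


class Conv2d(Layer):
    """Stride-1 2-D convolution (cross-correlation) via FFT products.

    ``padding='valid'`` shrinks the map by the effective kernel size;
    ``'same'`` keeps it.  Dilation enlarges the effective kernel by
    inserting zeros between taps.  FFTs are taken once per call at fast
    lengths; the frequency-domain contraction is a small batched product,
    which beats explicit window gathering for the broad dilated kernels
    used in the decoder's time-frequency branch.
    """

    def __init__(self, c_in: int, c_out: int, kernel: tuple[int, int],
                 dilation: tuple[int, int] = (1, 1),
                 padding: str = "valid", rng: np.random.Generator | None = None):
        kh, kw = kernel
        self.dilation = dilation
        self.padding = padding
        self.eff = ((kh - 1) * dilation[0] + 1, (kw - 1) * dilation[1] + 1)
        rng = rng or np.random.default_rng(0)
        scale = math.sqrt(2.0 / (c_in * kh * kw))  # He init
        self.w = Param((scale * rng.standard_normal((c_out, c_in, kh, kw))
                        ).astype(np.float32))
        self.b = Param(np.zeros(c_out, dtype=np.float32))

    def params(self):
        return [self.w, self.b]

    def _dilated_kernel(self) -> np.ndarray:
        kh, kw = self.w.value.shape[2:]
        if self.dilation == (1, 1):
            return self.w.value
        eh, ew = self.eff
        wd = np.zeros(self.w.value.shape[:2] + (eh, ew),
                      dtype=self.w.value.dtype)
        wd[:, :, ::self.dilation[0], ::self.dilation[1]] = self.w.value
        return wd

    def _offsets_eff(self, H: int, W: int, eh: int, ew: int):
        if self.padding == "valid":
            if eh > H or ew > W:
                raise ValueError(
                    f"effective kernel ({eh}, {ew}) larger than map "
                    f"({H}, {W}) with valid padding")
            return (eh - 1, ew - 1), (H - eh + 1, W - ew + 1)
        if self.padding == "same":
            return ((eh - 1) // 2, (ew - 1) // 2), (H, W)
        raise ValueError(f"unknown padding {self.padding!r}")

    def forward(self, x, train=True):
        B, C, H, W = x.shape
        eh, ew = self.eff
        # a full-height valid kernel collapses exactly to a 1-D
        # convolution over width with channels = C * H
        self._collapse = (self.padding == "valid" and eh == H and eh > 1
                          and self.dilation[0] == 1)
        if self._collapse:
            x = x.reshape(B, C * H, 1, W)
            H, C = 1, C * H
            eh = 1
        self._xshape = (B, C, H, W)
        (oh, ow), (Ho, Wo) = self._offsets_eff(H, W, eh, ew)
        wd = self._work_kernel()[:, :, ::-1, ::-1]
        if eh == 1 and ew == 1:  # pointwise: plain channel mixing
            self._mode = "point"
            self._x = x
            y = np.einsum("bchw,oc->bohw", x, wd[:, :, 0, 0],
                          optimize=True)
        elif eh == 1:  # 1-D convolution along width only
            self._mode = "1d"
            FW = sfft.next_fast_len(W + ew - 1)
            self._fsize = FW
            self._xf = sfft.rfft(x, n=FW, axis=-1)
            self._wf = sfft.rfft(wd[:, :, 0, :], n=FW, axis=-1)
            yf = np.einsum("bchx,ocx->bohx", self._xf, self._wf)
            y = sfft.irfft(yf, n=FW, axis=-1)[:, :, :, ow:ow + Wo]
        else:
            self._mode = "2d"
            FH = sfft.next_fast_len(H + eh - 1)
            FW = sfft.next_fast_len(W + ew - 1)
            self._fsize = (FH, FW)
            self._xf = sfft.rfft2(x, s=(FH, FW))
            self._wf = sfft.rfft2(wd, s=(FH, FW))
            yf = np.einsum("bcxy,ocxy->boxy", self._xf, self._wf)
            y = sfft.irfft2(yf, s=(FH, FW))[:, :, oh:oh + Ho, ow:ow + Wo]
        return np.ascontiguousarray(y) + self.b.value[None, :, None, None]

    def _work_kernel(self) -> np.ndarray:
        """Dilated kernel, collapsed to (O, C*kh, 1, ew) when applicable."""
        wd = self._dilated_kernel()
        if self._collapse:
            O, C, kh, ew = wd.shape
            return wd.reshape(O, C * kh, 1, ew)
        return wd

    def backward(self, dy):
        B, C, H, W = self._xshape
        eh, ew = self.eff
        if self._collapse:
            eh = 1
        (oh, ow), (Ho, Wo) = self._offsets_eff(H, W, eh, ew)
        self.b.grad += dy.sum(axis=(0, 2, 3))
        if self._mode == "point":
            wp = self._work_kernel()[:, :, 0, 0]
            dx = np.einsum("bohw,oc->bchw", dy, wp, optimize=True)
            dwp = np.einsum("bohw,bchw->oc", dy, self._x, optimize=True)
            dwd = dwp[:, :, None, None]
            self._x = None
        elif self._mode == "1d":
            FW = self._fsize
            dy_full = np.zeros((dy.shape[0], dy.shape[1], H, FW),
                               dtype=dy.dtype)
            dy_full[:, :, :, ow:ow + Wo] = dy
            dyf = sfft.rfft(dy_full, n=FW, axis=-1)
            dxf = np.einsum("bohx,ocx->bchx", dyf, np.conj(self._wf))
            dx = sfft.irfft(dxf, n=FW, axis=-1)[:, :, :, :W]
            dwf = np.einsum("bohx,bchx->ocx", dyf, np.conj(self._xf))
            dwd = sfft.irfft(dwf, n=FW, axis=-1)[:, :, None, :ew]
            self._xf = self._wf = None
        else:
            FH, FW = self._fsize
            dy_full = np.zeros((dy.shape[0], dy.shape[1], FH, FW),
                               dtype=dy.dtype)
            dy_full[:, :, oh:oh + Ho, ow:ow + Wo] = dy
            dyf = sfft.rfft2(dy_full, s=(FH, FW))
            dxf = np.einsum("boxy,ocxy->bcxy", dyf, np.conj(self._wf))
            dx = sfft.irfft2(dxf, s=(FH, FW))[:, :, :H, :W]
            dwf = np.einsum("boxy,bcxy->ocxy", dyf, np.conj(self._xf))
            dwd = sfft.irfft2(dwf, s=(FH, FW))[:, :, :eh, :ew]
            self._xf = self._wf = None
        # undo flip, collapse and dilation to recover tap gradients
        dwd = dwd[:, :, ::-1, ::-1]
        if self._collapse:
            O = dwd.shape[0]
            kh = self.w.value.shape[2]
            dwd = dwd.reshape(O, -1, kh, dwd.shape[-1])
            dx = dx.reshape(B, -1, kh, W)
        dwd = dwd[:, :, ::self.dilation[0], ::self.dilation[1]]
        self.w.grad += dwd.astype(self.w.grad.dtype)
        return np.ascontiguousarray(dx)


class BatchNorm2d(Layer):
    """Per-channel batch normalization over (batch, H, W)."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c, dtype=np.float32))
        self.beta = Param(np.zeros(c, dtype=np.float32))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def params(self):
        return [self.gamma, self.beta]

    def _stats_axes(self, x):
        return (0, 2, 3) if x.ndim == 4 else (0,)

    def _bcast(self, v, ndim):
        return v[None, :, None, None] if ndim == 4 else v[None, :]

    def forward(self, x, train=True):
        ax = self._stats_axes(x)
        if train:
            mean = x.mean(axis=ax)
            var = x.var(axis=ax)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - self._bcast(mean, x.ndim)) * self._bcast(inv, x.ndim)
        if train:
            self._xhat, self._inv, self._ax = xhat, inv, ax
        return self._bcast(self.gamma.value, x.ndim) * xhat \
            + self._bcast(self.beta.value, x.ndim)

    def backward(self, dy):
        ax = self._ax
        n = dy.size // dy.shape[1]
        xhat, inv = self._xhat, self._inv
        self.gamma.grad += (dy * xhat).sum(axis=ax)
        self.beta.grad += dy.sum(axis=ax)
        g = self._bcast(self.gamma.value * inv, dy.ndim)
        s1 = self._bcast(dy.sum(axis=ax), dy.ndim)
        s2 = self._bcast((dy * xhat).sum(axis=ax), dy.ndim)
        dx = g * (dy - s1 / n - xhat * s2 / n)
        self._xhat = None
        return dx


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool2d(Layer):
    """Non-overlapping max pooling; trailing remainder columns are cropped."""

    def __init__(self, pool: tuple[int, int]):
        self.ph, self.pw = pool

    def forward(self, x, train=True):
        B, C, H, W = x.shape
        Ho, Wo = H // self.ph, W // self.pw
        self._xshape = x.shape
        v = np.ascontiguousarray(
            x[:, :, :Ho * self.ph, :Wo * self.pw]
            .reshape(B, C, Ho, self.ph, Wo, self.pw)
            .transpose(0, 1, 2, 4, 3, 5)
        ).reshape(B, C, Ho, Wo, self.ph * self.pw)
        self._arg = v.argmax(axis=-1)
        return np.take_along_axis(v, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        B, C, H, W = self._xshape
        Ho, Wo = H // self.ph, W // self.pw
        grad = np.zeros((B, C, Ho, Wo, self.ph * self.pw), dtype=dy.dtype)
        np.put_along_axis(grad, self._arg[..., None], dy[..., None],
                          axis=-1)
        grad = grad.reshape(B, C, Ho, Wo, self.ph, self.pw) \
                   .transpose(0, 1, 2, 4, 3, 5)
        dx = np.zeros(self._xshape, dtype=dy.dtype)
        dx[:, :, :Ho * self.ph, :Wo * self.pw] = grad.reshape(
            B, C, Ho * self.ph, Wo * self.pw)
        self._arg = None
        return dx


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, p: float, rng: np.random.Generator | None = None):
        if not 0 <= p < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x, train=True):
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1 - self.p)
        return x * self._mask.astype(x.dtype)

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask.astype(dy.dtype)


class Flatten(Layer):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.reshape(len(x), -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = math.sqrt(2.0 / n_in)
        self.w = Param((scale * rng.standard_normal((n_out, n_in))
                        ).astype(np.float32))
        self.b = Param(np.zeros(n_out, dtype=np.float32))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=True):
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, dy):
        self.w.grad += dy.T @ self._x
        self.b.grad += dy.sum(axis=0)
        dx = dy @ self.w.value
        self._x = None
        return dx


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def params(self):
        return [p for layer in self.layers for p in layer.params()]


class Residual(Layer):
    """y = relu(x + inner(x)); inner must preserve the map shape."""

    def __init__(self, inner: Layer):
        self.inner = inner

    def forward(self, x, train=True):
        y = x + self.inner.forward(x, train)
        self._mask = y > 0
        return y * self._mask

    def backward(self, dy):
        dy = dy * self._mask
        return dy + self.inner.backward(dy)

    def params(self):
        return self.inner.params()


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean softmax cross-entropy; returns (loss, dlogits)."""
    p = softmax(logits.astype(np.float64))
    n = len(labels)
    loss = -np.log(p[np.arange(n), labels] + 1e-12).mean()
    dlogits = p
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), (dlogits / n).astype(logits.dtype)


class SGD:
    """Plain stochastic gradient descent with an external schedule."""

    def __init__(self, params: list[Param], lr: float):
        self.params = params
        self.lr = lr

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0

    def step(self):
        for p in self.params:
            p.value -= self.lr * p.grad


def cosine_warm_restarts(epoch: int, lr0: float, t0: int = 50,
                         t_mult: int = 2, lr_min: float = 0.0) -> float:
    """Learning rate at ``epoch`` under cosine annealing with warm restarts.

    Cycle lengths are ``t0, t0*t_mult, t0*t_mult^2, ...``; the rate decays
    from ``lr0`` to ``lr_min`` within each cycle and restarts at ``lr0``.
    ``epoch`` 0 maps to exactly ``lr0``.
    """
    t_i, t_cur = t0, epoch
    while t_cur >= t_i:
        t_cur -= t_i
        t_i *= t_mult
    return lr_min + 0.5 * (lr0 - lr_min) * (1 + math.cos(math.pi * t_cur / t_i))
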