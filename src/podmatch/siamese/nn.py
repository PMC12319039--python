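"""Minimal trainable convnet layers in numpy.

Implements exactly what the SE-Siamese similarity network needs — im2col
convolution, batch normalization, max pooling, squeeze-and-excitation
gating, bottleneck residual blocks, linear/dropout heads — each with a
hand-written backward pass, plus SGD-momentum and Adam optimizers.  Layers
cache activations on ``forward`` and consume them in ``backward``; parameter
gradients accumulate into ``Param.grad`` until ``zero_grad``.

Shapes follow the NCHW convention.  dtype follows the parameters (float32
by default; float64 is used by the finite-difference gradient checks).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = ""):
        self.data = np.asarray(data)
        self.grad = np.zeros_like(self.data)
        self.name = name


class Layer:
    """Base class: forward/backward plus recursive parameter discovery."""

    def forward(self, x, train: bool = False):
        raise NotImplementedError

    def backward(self, dout):
        raise NotImplementedError

    def __call__(self, x, train: bool = False):
        return self.forward(x, train=train)

    def named_params(self, prefix: str = ""):
        out = []
        for attr, val in vars(self).items():
            name = f"{prefix}{attr}"
            if isinstance(val, Param):
                out.append((name, val))
            elif isinstance(val, Layer):
                out.extend(val.named_params(prefix=name + "."))
            elif isinstance(val, (list, tuple)):
                for k, item in enumerate(val):
                    if isinstance(item, Layer):
                        out.extend(item.named_params(prefix=f"{name}.{k}."))
        return out

    def params(self):
        return [p for _, p in self.named_params()]

    def modules(self):
        yield self
        for val in vars(self).values():
            if isinstance(val, Layer):
                yield from val.modules()
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Layer):
                        yield from item.modules()

    def zero_grad(self):
        for p in self.params():
            p.grad[...] = 0


def _he_init(rng, shape, fan_in, dtype):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Conv2d(Layer):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 pad: int = 0, bias: bool = True, rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.in_ch, self.out_ch = in_ch, out_ch
        self.k, self.stride, self.pad = kernel, stride, pad
        fan_in = in_ch * kernel * kernel
        self.weight = Param(_he_init(rng, (out_ch, in_ch, kernel, kernel), fan_in, dtype))
        self.bias = Param(np.zeros(out_ch, dtype=dtype)) if bias else None
        self._cache = None

    def _weight_mat(self) -> np.ndarray:
        """(O, C, kh, kw) -> (O, kh*kw*C), column order matching the im2col rows."""
        return np.ascontiguousarray(
            self.weight.data.transpose(0, 2, 3, 1).reshape(self.out_ch, -1))

    def forward(self, x, train: bool = False):
        """im2col convolution as one GEMM per layer.

        The column matrix is laid out (kh*kw*C, N*OH*OW) and built from
        contiguous per-offset strided slices, so both the gather and the
        single BLAS call stay cache-friendly.
        """
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        n, c, hp, wp = xp.shape
        oh = (hp - k) // s + 1
        ow = (wp - k) // s + 1
        m = oh * ow
        cols = np.empty((k * k * c, n * m), dtype=x.dtype)
        for i in range(k):
            for j in range(k):
                blk = (i * k + j) * c
                sl = xp[:, :, i:i + s * oh:s, j:j + s * ow:s]
                cols[blk:blk + c] = sl.transpose(1, 0, 2, 3).reshape(c, n * m)
        out = self._weight_mat() @ cols
        if self.bias is not None:
            out += self.bias.data[:, None]
        self._cache = (cols, xp.shape, x.shape, (oh, ow))
        return np.ascontiguousarray(
            out.reshape(self.out_ch, n, oh, ow).transpose(1, 0, 2, 3))

    def backward(self, dout):
        cols, padded_shape, x_shape, (oh, ow) = self._cache
        n = x_shape[0]
        c = self.in_ch
        k, s, p = self.k, self.stride, self.pad
        m = oh * ow
        dmat = np.ascontiguousarray(dout.transpose(1, 0, 2, 3)).reshape(
            self.out_ch, n * m)
        if self.bias is not None:
            self.bias.grad += dmat.sum(axis=1)
        dw_mat = dmat @ cols.T
        self.weight.grad += dw_mat.reshape(self.out_ch, k, k, c).transpose(0, 3, 1, 2)
        dcols = self._weight_mat().T @ dmat
        dxp = np.zeros(padded_shape, dtype=dout.dtype)
        for i in range(k):
            for j in range(k):
                blk = (i * k + j) * c
                dxp[:, :, i:i + s * oh:s, j:j + s * ow:s] += dcols[
                    blk:blk + c].reshape(c, n, oh, ow).transpose(1, 0, 2, 3)
        self._cache = None
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class BatchNorm2d(Layer):
    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32):
        self.gamma = Param(np.ones(ch, dtype=dtype))
        self.beta = Param(np.zeros(ch, dtype=dtype))
        self.running_mean = np.zeros(ch, dtype=dtype)
        self.running_var = np.ones(ch, dtype=dtype)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def forward(self, x, train: bool = False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(
                self.running_mean.dtype)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(
                self.running_var.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None]) * inv_std[:, None, None]
        self._cache = (xhat, inv_std, train, x.shape)
        return self.gamma.data[:, None, None] * xhat + self.beta.data[:, None, None]

    def backward(self, dout):
        xhat, inv_std, train, x_shape = self._cache
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        g = self.gamma.data[:, None, None]
        if not train:
            return dout * g * inv_std[:, None, None]
        n = x_shape[0] * x_shape[2] * x_shape[3]
        dxhat = dout * g
        return (inv_std[:, None, None] / n) * (
            n * dxhat
            - dxhat.sum(axis=(0, 2, 3))[:, None, None]
            - xhat * (dxhat * xhat).sum(axis=(0, 2, 3))[:, None, None])


class ReLU(Layer):
    def forward(self, x, train: bool = False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2d(Layer):
    def __init__(self, kernel: int, stride: int | None = None, pad: int = 0):
        self.k, self.stride, self.pad = kernel, stride or kernel, pad

    def forward(self, x, train: bool = False):
        k, s, p = self.k, self.stride, self.pad
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)),
                       constant_values=-np.inf)
        win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        n, c, oh, ow = win.shape[:4]
        flat = win.reshape(n, c, oh, ow, k * k)
        self._arg = flat.argmax(axis=-1)
        self._shapes = (x.shape, (n, c, oh, ow))
        out = np.take_along_axis(flat, self._arg[..., None], axis=-1)[..., 0]
        return np.ascontiguousarray(out)

    def backward(self, dout):
        padded_shape, (n, c, oh, ow) = self._shapes
        k, s, p = self.k, self.stride, self.pad
        dxp = np.zeros(padded_shape, dtype=dout.dtype)
        for i in range(k):
            for j in range(k):
                sel = self._arg == (i * k + j)
                dxp[:, :, i:i + s * oh:s, j:j + s * ow:s] += dout * sel
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C) channel means."""

    def forward(self, x, train: bool = False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None] / (h * w),
                               self._shape).astype(dout.dtype).copy()


class Linear(Layer):
    def __init__(self, in_f: int, out_f: int, rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.weight = Param(_he_init(rng, (out_f, in_f), in_f, dtype))
        self.bias = Param(np.zeros(out_f, dtype=dtype))

    def forward(self, x, train: bool = False):
        self._x = x
        return x @ self.weight.data.T + self.bias.data

    def backward(self, dout):
        self.weight.grad += dout.T @ self._x
        self.bias.grad += dout.sum(axis=0)
        return dout @ self.weight.data


class Dropout(Layer):
    def __init__(self, rate: float, seed: int = 0):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = np.random.default_rng(seed)

    def reseed(self, seed: int) -> None:
        self.rng = np.random.default_rng(seed)

    def forward(self, x, train: bool = False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask.astype(x.dtype)

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask.astype(dout.dtype)


class SEBlock(Layer):
    """Squeeze-and-excitation channel gate.

    Squeeze: global average per channel.  Excite: bottleneck MLP
    C -> C/r -> C with ReLU then logistic, giving per-channel gates in (0,1)
    that rescale the input.  With ``pinned`` set, the gates are forced to 1
    and the block is the identity — the reduction used to compare against the
    plain residual network.
    """

    def __init__(self, ch: int, reduction: int = 16, rng=None, dtype=np.float32):
        if ch % reduction != 0:
            raise ValueError(f"channels ({ch}) must be divisible by reduction ({reduction})")
        rng = rng or np.random.default_rng(0)
        hidden = ch // reduction
        self.fc1 = Linear(ch, hidden, rng=rng, dtype=dtype)
        self.fc2 = Linear(hidden, ch, rng=rng, dtype=dtype)
        self.pinned = False
        self._cache = None

    def forward(self, x, train: bool = False):
        if self.pinned:
            self._cache = None
            return x
        s = x.mean(axis=(2, 3))
        z1 = self.fc1.forward(s)
        z1 = z1 * (z1 > 0)          # relu (mask re-derived in backward)
        z = self.fc2.forward(z1)
        gate = 1.0 / (1.0 + np.exp(-z))
        self._cache = (x, s, z1, z, gate)
        return x * gate[:, :, None, None]

    def backward(self, dout):
        if self._cache is None:
            return dout
        x, s, z1, z, gate = self._cache
        n, c, h, w = x.shape
        dx = dout * gate[:, :, None, None]
        dgate = (dout * x).sum(axis=(2, 3))
        dz = dgate * gate * (1.0 - gate)
        dz1 = self.fc2.backward(dz)
        dz1 = dz1 * (z1 > 0)
        ds = self.fc1.backward(dz1)
        dx += (ds / (h * w))[:, :, None, None]
        return dx


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x, train: bool = False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


class Bottleneck(Layer):
    """Residual bottleneck (1x1 reduce, 3x3, 1x1 expand) with optional SE gate
    applied to the residual branch output before the skip addition."""

    def __init__(self, in_ch: int, width: int, out_ch: int, stride: int = 1,
                 se_reduction: int | None = None, rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.conv1 = Conv2d(in_ch, width, 1, bias=False, rng=rng, dtype=dtype)
        self.bn1 = BatchNorm2d(width, dtype=dtype)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(width, width, 3, stride=stride, pad=1, bias=False,
                            rng=rng, dtype=dtype)
        self.bn2 = BatchNorm2d(width, dtype=dtype)
        self.relu2 = ReLU()
        self.conv3 = Conv2d(width, out_ch, 1, bias=False, rng=rng, dtype=dtype)
        self.bn3 = BatchNorm2d(out_ch, dtype=dtype)
        self.se = SEBlock(out_ch, se_reduction, rng=rng, dtype=dtype) \
            if se_reduction else None
        if stride != 1 or in_ch != out_ch:
            self.proj_conv = Conv2d(in_ch, out_ch, 1, stride=stride, bias=False,
                                    rng=rng, dtype=dtype)
            self.proj_bn = BatchNorm2d(out_ch, dtype=dtype)
        else:
            self.proj_conv = self.proj_bn = None
        self.relu_out = ReLU()

    def forward(self, x, train: bool = False):
        out = self.relu1(self.bn1(self.conv1(x, train), train))
        out = self.relu2(self.bn2(self.conv2(out, train), train))
        out = self.bn3(self.conv3(out, train), train)
        if self.se is not None:
            out = self.se.forward(out, train=train)
        if self.proj_conv is not None:
            skip = self.proj_bn(self.proj_conv(x, train), train)
        else:
            skip = x
        self._identity_skip = self.proj_conv is None
        return self.relu_out(out + skip)

    def backward(self, dout):
        dsum = self.relu_out.backward(dout)
        dres = dsum
        if self.se is not None:
            dres = self.se.backward(dres)
        dres = self.conv1.backward(self.bn1.backward(self.relu1.backward(
            self.conv2.backward(self.bn2.backward(self.relu2.backward(
                self.conv3.backward(self.bn3.backward(dres))))))))
        if self.proj_conv is not None:
            dskip = self.proj_conv.backward(self.proj_bn.backward(dsum))
        else:
            dskip = dsum
        return dres + dskip


class SGD:
    def __init__(self, params, lr: float = 1e-2, momentum: float = 0.9):
        self.params = list(params)
        self.lr, self.momentum = lr, momentum
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self.velocity):
            v *= self.momentum
            v -= self.lr * p.grad
            p.data += v.astype(p.data.dtype)


class Adam:
    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.data.dtype)


def make_optimizer(name: str, params, lr: float):
    if name == "adam":
        return Adam(params, lr=lr)
    if name == "sgd":
        return SGD(params, lr=lr, momentum=0.9)
    raise ValueError(f"unknown optimizer {name!r}")
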