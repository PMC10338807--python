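"""Minimal NumPy neural-network layers with manual backpropagation.

All layers follow the same protocol: ``forward(x, train=False)`` caches
whatever the backward pass needs (only when ``train=True``), and
``backward(gy)`` returns the gradient with respect to the layer input while
accumulating parameter gradients in-place.  Arrays are float32 throughout;
volumetric tensors are laid out ``(N, C, D, H, W)``.

The engine is deliberately small: grouped 3D convolution, batch
normalisation, fully connected layers, ReLU, inverted dropout and softmax
are the only primitives the network needs.
"""

from __future__ import annotations

import itertools

import numpy as np

DTYPE = np.float32


class Parameter:
    """A learnable array with an accumulated gradient."""

    __slots__ = ("value", "grad", "trainable")

    def __init__(self, value: np.ndarray, trainable: bool = True):
        self.value = np.ascontiguousarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.trainable = trainable

    @property
    def shape(self):
        return self.value.shape

    @property
    def size(self):
        return self.value.size


class Module:
    """Base class: parameter traversal and gradient reset."""

    def parameters(self):
        """Yield ``(name, Parameter)`` pairs, depth first."""
        for attr, obj in vars(self).items():
            if isinstance(obj, Parameter):
                yield attr, obj
            elif isinstance(obj, Module):
                for sub, p in obj.parameters():
                    yield f"{attr}.{sub}", p
            elif isinstance(obj, (list, tuple)):
                for i, item in enumerate(obj):
                    if isinstance(item, Module):
                        for sub, p in item.parameters():
                            yield f"{attr}.{i}.{sub}", p

    def zero_grad(self):
        for _, p in self.parameters():
            p.grad[...] = 0.0

    def num_parameters(self) -> int:
        return sum(p.size for _, p in self.parameters())

    def forward(self, x, train: bool = False):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, gy):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x, train: bool = False):
        return self.forward(x, train=train)

    # --- running-state traversal (used by checkpointing) ---
    def state_arrays(self):
        """Yield ``(name, ndarray)`` for non-learnable running state."""
        for attr, obj in vars(self).items():
            if isinstance(obj, Module):
                for sub, a in obj.state_arrays():
                    yield f"{attr}.{sub}", a
            elif isinstance(obj, (list, tuple)):
                for i, item in enumerate(obj):
                    if isinstance(item, Module):
                        for sub, a in item.state_arrays():
                            yield f"{attr}.{i}.{sub}", a


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x, train: bool = False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, gy):
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy


def _fans_conv(cin_g: int, cout_g: int, k: int) -> tuple[int, int]:
    return cin_g * k**3, cout_g * k**3


def xavier_uniform(shape, fan_in, fan_out, rng: np.random.Generator):
    bound = float(np.sqrt(6.0 / (fan_in + fan_out)))
    return rng.uniform(-bound, bound, size=shape).astype(DTYPE)


class Conv3d(Module):
    """Grouped 3D convolution with cubic kernel and same/strided geometry.

    Weight layout ``(C_out, C_in/groups, k, k, k)``.  Padding defaults to
    ``k // 2`` (same padding at stride 1).  The im2col buffers needed by the
    backward pass are only retained when ``train=True``.
    """

    def __init__(self, cin, cout, k, stride=1, groups=1, bias=False,
                 rng: np.random.Generator | None = None, pad=None):
        if cin % groups or cout % groups:
            raise ValueError(
                f"channels ({cin}->{cout}) not divisible by groups={groups}")
        self.cin, self.cout, self.k = cin, cout, k
        self.stride, self.groups = stride, groups
        self.pad = k // 2 if pad is None else pad
        rng = rng or np.random.default_rng(0)
        fan_in, fan_out = _fans_conv(cin // groups, cout // groups, k)
        self.weight = Parameter(
            xavier_uniform((cout, cin // groups, k, k, k), fan_in, fan_out, rng))
        self.bias = Parameter(np.zeros(cout, dtype=DTYPE)) if bias else None
        self._cache = None

    def out_shape(self, spatial):
        k, s, p = self.k, self.stride, self.pad
        return tuple((d + 2 * p - k) // s + 1 for d in spatial)

    def _im2col(self, x):
        """(N,C,D,H,W) -> columns (N, C, k^3, P) via cheap slice copies."""
        N = x.shape[0]
        k, s, p = self.k, self.stride, self.pad
        Do, Ho, Wo = self.out_shape(x.shape[2:])
        P = Do * Ho * Wo
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        col = np.empty((N, self.cin, k**3, P), dtype=DTYPE)
        col5 = col.reshape(N, self.cin, k**3, Do, Ho, Wo)
        idx = 0
        for i, j, l in itertools.product(range(k), repeat=3):
            col5[:, :, idx] = xp[:, :, i:i + s * Do:s, j:j + s * Ho:s,
                                 l:l + s * Wo:s]
            idx += 1
        return col, (Do, Ho, Wo)

    def forward(self, x, train: bool = False):
        if x.ndim != 5 or x.shape[1] != self.cin:
            raise ValueError(
                f"expected (N,{self.cin},D,H,W) input, got {x.shape}")
        x = np.ascontiguousarray(x, dtype=DTYPE)
        if self.k == 1:
            return self._forward_1x1(x, train)
        N = x.shape[0]
        k, G = self.k, self.groups
        col, (Do, Ho, Wo) = self._im2col(x)
        cg, og = self.cin // G, self.cout // G
        P = Do * Ho * Wo
        out = np.empty((N, self.cout, Do, Ho, Wo), dtype=DTYPE)
        for g in range(G):
            cols = col[:, g * cg:(g + 1) * cg].reshape(N, cg * k**3, P)
            Wg = self.weight.value[g * og:(g + 1) * og].reshape(og, cg * k**3)
            out[:, g * og:(g + 1) * og] = (Wg @ cols).reshape(
                N, og, Do, Ho, Wo)
        if self.bias is not None:
            out += self.bias.value[None, :, None, None, None]
        if train:
            self._cache = (x.shape, col, (Do, Ho, Wo))
        return out

    def _forward_1x1(self, x, train):
        s = self.stride
        xs = np.ascontiguousarray(x[:, :, ::s, ::s, ::s]) if s > 1 else x
        N, _, Do, Ho, Wo = xs.shape
        G = self.groups
        cg, og = self.cin // G, self.cout // G
        P = Do * Ho * Wo
        xv = xs.reshape(N, self.cin, P)
        out = np.empty((N, self.cout, Do, Ho, Wo), dtype=DTYPE)
        for g in range(G):
            W1 = self.weight.value[g * og:(g + 1) * og, :, 0, 0, 0]  # (og,cg)
            out[:, g * og:(g + 1) * og] = (
                W1 @ xv[:, g * cg:(g + 1) * cg]).reshape(N, og, Do, Ho, Wo)
        if self.bias is not None:
            out += self.bias.value[None, :, None, None, None]
        if train:
            self._cache = (x.shape, xv, (Do, Ho, Wo))
        return out

    def backward(self, gy):
        if self._cache is None:
            raise RuntimeError("backward called without a train-mode forward")
        if self.k == 1:
            return self._backward_1x1(gy)
        x_shape, col, (Do, Ho, Wo) = self._cache
        N = x_shape[0]
        k, s, p, G = self.k, self.stride, self.pad, self.groups
        cg, og = self.cin // G, self.cout // G
        P = Do * Ho * Wo
        pd, ph, pw = (x_shape[2] + 2 * p, x_shape[3] + 2 * p,
                      x_shape[4] + 2 * p)
        gxp = np.zeros((N, self.cin, pd, ph, pw), dtype=DTYPE)
        gy = np.ascontiguousarray(gy, dtype=DTYPE)
        for g in range(G):
            gy_g = gy[:, g * og:(g + 1) * og].reshape(N, og, P)
            cols = col[:, g * cg:(g + 1) * cg].reshape(N, cg * k**3, P)
            gW = np.matmul(gy_g, cols.transpose(0, 2, 1)).sum(axis=0)
            self.weight.grad[g * og:(g + 1) * og] += gW.reshape(
                og, cg, k, k, k)
            Wg = self.weight.value[g * og:(g + 1) * og].reshape(og, cg * k**3)
            gcols = np.matmul(Wg.T, gy_g).reshape(N, cg, k**3, P)
            sl = gxp[:, g * cg:(g + 1) * cg]
            idx = 0
            for i, j, l in itertools.product(range(k), repeat=3):
                sl[:, :, i:i + s * Do:s, j:j + s * Ho:s, l:l + s * Wo:s] += \
                    gcols[:, :, idx].reshape(N, cg, Do, Ho, Wo)
                idx += 1
        if self.bias is not None:
            self.bias.grad += gy.sum(axis=(0, 2, 3, 4))
        self._cache = None
        if p:
            return gxp[:, :, p:-p, p:-p, p:-p]
        return gxp

    def _backward_1x1(self, gy):
        x_shape, xv, (Do, Ho, Wo) = self._cache
        s, G = self.stride, self.groups
        cg, og = self.cin // G, self.cout // G
        N = x_shape[0]
        P = Do * Ho * Wo
        gy = np.ascontiguousarray(gy, dtype=DTYPE)
        gyv = gy.reshape(N, self.cout, P)
        gx = np.zeros(x_shape, dtype=DTYPE)
        gxs = gx[:, :, ::s, ::s, ::s] if s > 1 else gx
        for g in range(G):
            gy_g = gyv[:, g * og:(g + 1) * og]
            x_g = xv[:, g * cg:(g + 1) * cg]
            self.weight.grad[g * og:(g + 1) * og, :, 0, 0, 0] += np.matmul(
                gy_g, x_g.transpose(0, 2, 1)).sum(axis=0)
            W1 = self.weight.value[g * og:(g + 1) * og, :, 0, 0, 0]
            gxs[:, g * cg:(g + 1) * cg] = np.matmul(
                W1.T, gy_g).reshape(N, cg, Do, Ho, Wo)
        if self.bias is not None:
            self.bias.grad += gy.sum(axis=(0, 2, 3, 4))
        self._cache = None
        return gx


class _BatchNormBase(Module):
    """Batch normalisation over the batch (and any spatial) axes."""

    def __init__(self, num_features, momentum=0.1, eps=1e-5):
        self.nf = num_features
        self.momentum = momentum
        self.eps = eps
        self.gamma = Parameter(np.ones(num_features, dtype=DTYPE))
        self.beta = Parameter(np.zeros(num_features, dtype=DTYPE))
        self.running_mean = np.zeros(num_features, dtype=DTYPE)
        self.running_var = np.ones(num_features, dtype=DTYPE)
        self._cache = None
        self._axes: tuple[int, ...] = (0,)

    def _bshape(self, ndim):
        shape = [1] * ndim
        shape[1 if ndim > 2 else -1] = self.nf
        return tuple(shape)

    def forward(self, x, train: bool = False):
        x = np.ascontiguousarray(x, dtype=DTYPE)
        axes = (0,) if x.ndim == 2 else (0, 2, 3, 4)
        bs = self._bshape(x.ndim)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = float(np.prod([x.shape[a] for a in axes]))
            self.running_mean += self.momentum * (mean - self.running_mean)
            unbiased = var * (m / max(m - 1.0, 1.0))
            self.running_var += self.momentum * (unbiased - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(bs)) * inv.reshape(bs)
        out = self.gamma.value.reshape(bs) * xhat + self.beta.value.reshape(bs)
        if train:
            self._cache = (xhat, inv, axes, bs)
        return out.astype(DTYPE)

    def backward(self, gy):
        xhat, inv, axes, bs = self._cache
        self._cache = None
        m = float(np.prod([gy.shape[a] for a in axes]))
        self.gamma.grad += (gy * xhat).sum(axis=axes)
        self.beta.grad += gy.sum(axis=axes)
        g = gy * self.gamma.value.reshape(bs)
        gsum = g.sum(axis=axes, keepdims=True)
        gxsum = (g * xhat).sum(axis=axes, keepdims=True)
        gx = (inv.reshape(bs) / m) * (m * g - gsum - xhat * gxsum)
        return gx.astype(DTYPE)

    def state_arrays(self):
        yield "running_mean", self.running_mean
        yield "running_var", self.running_var


class BatchNorm3d(_BatchNormBase):
    pass


class BatchNorm1d(_BatchNormBase):
    pass


class ReLU(Module):
    def __init__(self):
        self._mask = None

    def forward(self, x, train: bool = False):
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, gy):
        gx = gy * self._mask
        self._mask = None
        return gx


class Dropout(Module):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, p=0.5, rng: np.random.Generator | None = None):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng or np.random.default_rng(0)
        self._mask = None

    def forward(self, x, train: bool = False):
        if not train or self.p == 0.0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.shape) < keep).astype(DTYPE) / keep
        self._mask = mask
        return x * mask

    def backward(self, gy):
        if self._mask is None:
            return gy
        gx = gy * self._mask
        self._mask = None
        return gx


class Linear(Module):
    def __init__(self, cin, cout, bias=True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout = cin, cout
        self.weight = Parameter(xavier_uniform((cout, cin), cin, cout, rng))
        self.bias = Parameter(np.zeros(cout, dtype=DTYPE)) if bias else None
        self._x = None

    def forward(self, x, train: bool = False):
        if x.shape[-1] != self.cin:
            raise ValueError(f"expected last dim {self.cin}, got {x.shape}")
        x = np.ascontiguousarray(x, dtype=DTYPE)
        out = x @ self.weight.value.T
        if self.bias is not None:
            out += self.bias.value
        if train:
            self._x = x
        return out

    def backward(self, gy):
        self.weight.grad += gy.T @ self._x
        if self.bias is not None:
            self.bias.grad += gy.sum(axis=0)
        gx = gy @ self.weight.value
        self._x = None
        return gx


class Softmax(Module):
    """Row-wise softmax over the last axis (numerically stabilised)."""

    def __init__(self):
        self._p = None

    def forward(self, x, train: bool = False):
        z = x - x.max(axis=-1, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=-1, keepdims=True)
        p = p.astype(DTYPE)
        if train:
            self._p = p
        return p

    def backward(self, gy):
        p = self._p
        self._p = None
        dot = (gy * p).sum(axis=-1, keepdims=True)
        return (p * (gy - dot)).astype(DTYPE)


class GlobalAvgPool3d(Module):
    """(N, C, D, H, W) -> (N, C)."""

    def __init__(self):
        self._shape = None

    def forward(self, x, train: bool = False):
        if train:
            self._shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, gy):
        shape = self._shape
        self._shape = None
        scale = 1.0 / (shape[2] * shape[3] * shape[4])
        return np.broadcast_to(
            (gy * scale)[:, :, None, None, None], shape).astype(DTYPE).copy()
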