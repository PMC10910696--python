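"""Neural-network building blocks on top of the autodiff tensor.

Layers follow the familiar ``Module`` container pattern: parameters are
registered automatically by attribute assignment, ``named_parameters`` walks
the tree, and ``state_dict``/``load_state_dict`` exchange plain float32
arrays so checkpoints are simple ``.npz`` archives.

Convolutions are evaluated by im2col + matmul; their backward pass is written
by hand (col2im scatter) because it dominates the training profile.
Normalization layers likewise use fused backward formulas.
"""

from __future__ import annotations

import math

import numpy as np

from .tensor import Tensor, astensor

__all__ = [
    "Module",
    "Linear",
    "Conv2d",
    "GroupNorm",
    "LayerNorm",
    "interpolate_bilinear",
    "avg_pool2d",
]


class Module:
    """Base class with parameter/submodule registration by attribute."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_buffers", {})

    def register_buffer(self, name: str, value: np.ndarray):
        """Non-trainable state saved with the module (e.g. running statistics)."""
        self._buffers[name] = np.asarray(value, dtype=np.float32)
        object.__setattr__(self, name, self._buffers[name])

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        elif isinstance(value, (list, tuple)) and value and all(
                isinstance(v, Module) for v in value):
            for i, v in enumerate(value):
                self._modules[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, mod in self._modules.items():
            yield from mod.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def named_buffers(self, prefix: str = ""):
        for name, b in self._buffers.items():
            yield prefix + name, b
        for name, mod in self._modules.items():
            yield from mod.named_buffers(prefix + name + ".")

    def _set_buffer(self, name: str, value: np.ndarray):
        self._buffers[name] = np.asarray(value, dtype=np.float32)
        object.__setattr__(self, name, self._buffers[name])

    def state_dict(self) -> dict:
        out = {name: p.data.copy() for name, p in self.named_parameters()}
        out.update({name: b.copy() for name, b in self.named_buffers()})
        return out

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        missing = (set(own) | set(buffers)) - set(state)
        unexpected = set(state) - set(own) - set(buffers)
        if missing or unexpected:
            raise ValueError(
                f"state dict mismatch: missing={sorted(missing)}, unexpected={sorted(unexpected)}"
            )
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()
        for name, b in buffers.items():
            arr = np.asarray(state[name], dtype=np.float32)
            if arr.shape != b.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {b.shape}")
            # walk to the owning module so the attribute alias stays in sync
            mod = self
            parts = name.split(".")
            i = 0
            while i < len(parts) - 1:
                for j in range(len(parts) - 1, i, -1):
                    key = ".".join(parts[i:j])
                    if key in mod._modules:
                        mod = mod._modules[key]
                        i = j
                        break
                else:
                    raise ValueError(f"cannot locate module owning buffer {name}")
            mod._set_buffer(parts[-1], arr)

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _param(rng: np.random.Generator, shape, fan_in: int, zero: bool = False) -> Tensor:
    if zero:
        data = np.zeros(shape, dtype=np.float32)
    else:
        bound = math.sqrt(2.0 / fan_in)  # He initialization for ReLU nets
        data = rng.normal(0.0, bound, size=shape).astype(np.float32)
    return Tensor(data, requires_grad=True)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 zero_init: bool = False):
        super().__init__()
        self.weight = _param(rng, (in_features, out_features), in_features, zero=zero_init)
        self.bias = Tensor(np.zeros(out_features, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    b, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (x.shape[2] - kh) // stride + 1
    ow = (x.shape[3] - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]          # (B, C, oh, ow, kh, kw)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(b, oh * ow, c * kh * kw)
    return np.ascontiguousarray(cols), oh, ow


def _col2im(gcols: np.ndarray, x_shape, kh: int, kw: int, stride: int, pad: int,
            oh: int, ow: int) -> np.ndarray:
    b, c, h, w = x_shape
    gx = np.zeros((b, c, h + 2 * pad, w + 2 * pad), dtype=np.float32)
    g = gcols.reshape(b, oh, ow, c, kh, kw).transpose(0, 3, 4, 5, 1, 2)  # B,C,kh,kw,oh,ow
    for i in range(kh):
        for j in range(kw):
            gx[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += g[:, :, i, j]
    if pad:
        gx = gx[:, :, pad:-pad, pad:-pad]
    return gx


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int | None = None, zero_init: bool = False):
        super().__init__()
        if padding is None:
            padding = kernel // 2
        self.stride, self.padding, self.kernel = stride, padding, kernel
        fan_in = in_ch * kernel * kernel
        self.weight = _param(rng, (out_ch, in_ch, kernel, kernel), fan_in, zero=zero_init)
        self.bias = Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        x = astensor(x)
        w, bias = self.weight, self.bias
        kh = kw = self.kernel
        stride, pad = self.stride, self.padding
        cols, oh, ow = _im2col(x.data, kh, kw, stride, pad)      # (B, L, C*kh*kw)
        wmat = w.data.reshape(w.data.shape[0], -1)               # (O, C*kh*kw)
        out = cols @ wmat.T + bias.data                          # (B, L, O)
        b = x.data.shape[0]
        out_data = out.transpose(0, 2, 1).reshape(b, -1, oh, ow)

        def backward(g):
            go = g.reshape(b, -1, oh * ow).transpose(0, 2, 1)    # (B, L, O)
            if bias.requires_grad:
                bias._accum(go.sum(axis=(0, 1)))
            if w.requires_grad:
                gw = np.einsum("blo,blk->ok", go, cols)
                w._accum(gw.reshape(w.data.shape))
            if x.requires_grad:
                gcols = go @ wmat                                # (B, L, C*kh*kw)
                x._accum(_col2im(gcols, x.data.shape, kh, kw, stride, pad, oh, ow))

        return Tensor._result(out_data, (x, w, bias), backward)


def _norm_forward_backward(x: Tensor, gamma: Tensor, beta: Tensor,
                           reduce_shape, restore_shape, affine_shape, eps: float):
    """Shared machinery: normalize over the last axis of ``reduce_shape``."""
    xr = x.data.reshape(reduce_shape)
    mu = xr.mean(axis=-1, keepdims=True)
    xc = xr - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out_data = (xhat.reshape(restore_shape) * gamma.data.reshape(affine_shape)
                + beta.data.reshape(affine_shape))
    n = reduce_shape[-1]

    def backward(g):
        if beta.requires_grad:
            axes = tuple(i for i in range(g.ndim)
                         if np.asarray(affine_shape)[i] == 1)
            beta._accum(g.sum(axis=axes).reshape(beta.data.shape))
        if gamma.requires_grad:
            axes = tuple(i for i in range(g.ndim)
                         if np.asarray(affine_shape)[i] == 1)
            gamma._accum((g * xhat.reshape(restore_shape)).sum(axis=axes).reshape(gamma.data.shape))
        if x.requires_grad:
            gy = (g * gamma.data.reshape(affine_shape)).reshape(reduce_shape)
            m1 = gy.mean(axis=-1, keepdims=True)
            m2 = (gy * xhat).mean(axis=-1, keepdims=True)
            gx = inv * (gy - m1 - xhat * m2)
            x._accum(gx.reshape(x.data.shape).astype(np.float32))

    return Tensor._result(out_data.astype(np.float32), (x, gamma, beta), backward)


class GroupNorm(Module):
    """Group normalization over (C/groups, H, W) slices — batch-size independent."""

    def __init__(self, groups: int, channels: int, eps: float = 1e-5):
        super().__init__()
        if channels % groups:
            raise ValueError("channels must be divisible by groups")
        self.groups, self.channels, self.eps = groups, channels, eps
        self.gamma = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        b, c, h, w = x.data.shape
        g = self.groups
        return _norm_forward_backward(
            x, self.gamma, self.beta,
            reduce_shape=(b, g, (c // g) * h * w),
            restore_shape=(b, c, h, w),
            affine_shape=(1, c, 1, 1),
            eps=self.eps,
        )


class LayerNorm(Module):
    """LayerNorm over the channel axis of (B, C, P) token tensors."""

    def __init__(self, channels: int, eps: float = 1e-5):
        super().__init__()
        self.channels, self.eps = channels, eps
        self.gamma = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        b, c, p = x.data.shape
        # normalize each token's channel vector: move C last
        xt = x.transpose(0, 2, 1)                                # (B, P, C)
        out = _norm_forward_backward(
            xt, self.gamma, self.beta,
            reduce_shape=(b, p, c),
            restore_shape=(b, p, c),
            affine_shape=(1, 1, c),
            eps=self.eps,
        )
        return out.transpose(0, 2, 1)


def _bilinear_weights(in_size: int, out_size: int):
    """Half-pixel-center source coordinates, edge-clamped."""
    coords = (np.arange(out_size, dtype=np.float64) + 0.5) * in_size / out_size - 0.5
    lo = np.floor(coords).astype(np.int64)
    frac = (coords - lo).astype(np.float32)
    lo0 = np.clip(lo, 0, in_size - 1)
    lo1 = np.clip(lo + 1, 0, in_size - 1)
    return lo0, lo1, frac


def interpolate_bilinear(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Bilinear resize of (B, C, H, W) with half-pixel sample centers."""
    x = astensor(x)
    b, c, h, w = x.data.shape
    y0, y1, fy = _bilinear_weights(h, out_h)
    x0, x1, fx = _bilinear_weights(w, out_w)
    fy = fy[:, None]
    fx = fx[None, :]
    w00 = (1 - fy) * (1 - fx)
    w01 = (1 - fy) * fx
    w10 = fy * (1 - fx)
    w11 = fy * fx
    d = x.data
    out_data = (d[:, :, y0[:, None], x0[None, :]] * w00
                + d[:, :, y0[:, None], x1[None, :]] * w01
                + d[:, :, y1[:, None], x0[None, :]] * w10
                + d[:, :, y1[:, None], x1[None, :]] * w11)

    def backward(g):
        gx = np.zeros_like(x.data)
        for ys, xs, wt in ((y0, x0, w00), (y0, x1, w01), (y1, x0, w10), (y1, x1, w11)):
            np.add.at(gx, (slice(None), slice(None), ys[:, None], xs[None, :]), g * wt)
        x._accum(gx)

    return Tensor._result(out_data.astype(np.float32), (x,), backward)


def avg_pool2d(x: Tensor, k: int) -> Tensor:
    """Non-overlapping k×k average pooling (spatial sizes must divide by k)."""
    x = astensor(x)
    b, c, h, w = x.data.shape
    if h % k or w % k:
        raise ValueError("avg_pool2d requires spatial sizes divisible by k")
    r = x.reshape(b, c, h // k, k, w // k, k)
    return r.mean(axis=5).mean(axis=3)
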