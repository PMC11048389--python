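"""Compact reverse-mode autodiff and conv-net layers on numpy arrays.

Supports exactly what the toy-scale adversarial training needs: NCHW
convolutions (stride/groups), leaky ReLU, nearest-neighbour upsampling,
depth-to-space (pixel shuffle), average pooling, channel concat, elementwise
arithmetic, reductions, and a frequency-domain loss with an analytic
adjoint-FFT backward.  Everything is float64 and fully deterministic.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided

__all__ = [
    "Tensor", "Parameter", "Module", "Conv2d", "Sequential", "LeakyReLU",
    "AvgPool2", "NearestUp", "DepthToSpace", "Adam",
    "conv2d", "leaky_relu", "nearest_up", "depth_to_space", "avg_pool2",
    "concat_channels", "charbonnier_loss", "fd_loss", "per_sample_mean",
]


class Tensor:
    """Node in the autodiff graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "_backward", "_parents")

    def __init__(self, data, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # ---- graph mechanics ------------------------------------------------

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, g) -> None:
        self.grad = g if self.grad is None else self.grad + g

    # ---- elementwise ops -------------------------------------------------

    def __add__(self, other):
        other = _wrap(other)

        def bw(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        return Tensor(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)

        return Tensor(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-_wrap(other))

    def __rsub__(self, other):
        return _wrap(other) + (-self)

    def __mul__(self, other):
        other = _wrap(other)

        def bw(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def square(self):
        def bw(g):
            self._accum(g * 2.0 * self.data)

        return Tensor(self.data ** 2, (self,), bw)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bw(g):
            self._accum(g * 0.5 / np.maximum(out_data, 1e-30))

        return Tensor(out_data, (self,), bw)

    def abs(self):
        def bw(g):
            self._accum(g * np.sign(self.data))

        return Tensor(np.abs(self.data), (self,), bw)

    def mean(self):
        n = self.data.size

        def bw(g):
            self._accum(np.full(self.data.shape, float(g) / n))

        return Tensor(self.data.mean(), (self,), bw)

    def sum(self):
        def bw(g):
            self._accum(np.full(self.data.shape, float(g)))

        return Tensor(self.data.sum(), (self,), bw)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


class Parameter(Tensor):
    pass


# --------------------------------------------------------------------------
# structured ops
# --------------------------------------------------------------------------

def leaky_relu(x: Tensor, alpha: float = 0.2) -> Tensor:
    mask = np.where(x.data > 0, 1.0, alpha)

    def bw(g):
        x._accum(g * mask)

    return Tensor(x.data * mask, (x,), bw)


def _im2col(xp: np.ndarray, k: int, stride: int):
    b, c, h, w = xp.shape
    ho = (h - k) // stride + 1
    wo = (w - k) // stride + 1
    sb, sc, sh, sw = xp.strides
    win = as_strided(xp, shape=(b, c, ho, wo, k, k),
                     strides=(sb, sc, sh * stride, sw * stride, sh, sw))
    return win, ho, wo


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           pad: int | None = None, groups: int = 1) -> Tensor:
    """NCHW convolution (cross-correlation); 'same' zero padding by default
    at stride 1, ``pad`` otherwise."""
    cout, cin_g, k, _ = w.data.shape
    if pad is None:
        pad = (k - 1) // 2 if stride == 1 else 0
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    bsz, cin, hp, wp = xp.shape
    if cin != cin_g * groups:
        raise ValueError(f"channel mismatch: x has {cin}, w expects {cin_g}*{groups}")
    win, ho, wo = _im2col(xp, k, stride)
    wing = win.reshape(bsz, groups, cin_g, ho, wo, k, k)
    wg = w.data.reshape(groups, cout // groups, cin_g, k, k)
    out = np.einsum("bgchwij,gocij->bgohw", wing, wg, optimize=True)
    out = out.reshape(bsz, cout, ho, wo)
    if b is not None:
        out = out + b.data.reshape(1, cout, 1, 1)

    def bw(g):
        gg = g.reshape(bsz, groups, cout // groups, ho, wo)
        gw = np.einsum("bgohw,bgchwij->gocij", gg, wing, optimize=True)
        w._accum(gw.reshape(cout, cin_g, k, k))
        if b is not None:
            b._accum(g.sum(axis=(0, 2, 3)))
        gxp = np.zeros_like(xp).reshape(bsz, groups, cin_g, hp, wp)
        for i in range(k):
            for j in range(k):
                tmp = np.einsum("bgohw,goc->bgchw", gg, wg[:, :, :, i, j],
                                optimize=True)
                gxp[:, :, :, i:i + stride * ho:stride,
                    j:j + stride * wo:stride] += tmp
        gxp = gxp.reshape(bsz, cin, hp, wp)
        if pad:
            gxp = gxp[:, :, pad:hp - pad, pad:wp - pad]
        x._accum(gxp)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out, parents, bw)


def nearest_up(x: Tensor, scale: int) -> Tensor:
    out = x.data.repeat(scale, axis=-2).repeat(scale, axis=-1)

    def bw(g):
        b, c, h, w = x.data.shape
        gr = g.reshape(b, c, h, scale, w, scale).sum(axis=(3, 5))
        x._accum(gr)

    return Tensor(out, (x,), bw)


def depth_to_space(x: Tensor, scale: int) -> Tensor:
    """Pixel shuffle: (B, C*s^2, H, W) -> (B, C, H*s, W*s)."""
    b, c2, h, w = x.data.shape
    c = c2 // (scale * scale)
    out = (x.data.reshape(b, c, scale, scale, h, w)
           .transpose(0, 1, 4, 2, 5, 3).reshape(b, c, h * scale, w * scale))

    def bw(g):
        gr = (g.reshape(b, c, h, scale, w, scale)
              .transpose(0, 1, 3, 5, 2, 4).reshape(b, c2, h, w))
        x._accum(gr)

    return Tensor(out, (x,), bw)


def avg_pool2(x: Tensor, k: int = 2) -> Tensor:
    b, c, h, w = x.data.shape
    ho, wo = h // k, w // k
    out = x.data[:, :, :ho * k, :wo * k].reshape(b, c, ho, k, wo, k).mean(axis=(3, 5))

    def bw(g):
        gx = np.zeros_like(x.data)
        gx[:, :, :ho * k, :wo * k] = (
            g[:, :, :, None, :, None] / (k * k)
        ).repeat(k, axis=3).repeat(k, axis=5).reshape(b, c, ho * k, wo * k)
        x._accum(gx)

    return Tensor(out, (x,), bw)


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    ca = a.data.shape[1]

    def bw(g):
        a._accum(g[:, :ca])
        b._accum(g[:, ca:])

    return Tensor(np.concatenate([a.data, b.data], axis=1), (a, b), bw)


def per_sample_mean(x: Tensor) -> Tensor:
    """(B, C, H, W) -> (B,) mean over channels and space."""
    n = int(np.prod(x.data.shape[1:]))

    def bw(g):
        x._accum((g / n).reshape(-1, 1, 1, 1) * np.ones_like(x.data))

    return Tensor(x.data.reshape(x.data.shape[0], -1).mean(axis=1), (x,), bw)


def charbonnier_loss(pred: Tensor, target: np.ndarray, eps: float = 1e-3) -> Tensor:
    diff = pred - Tensor(target)
    return (diff.square() + eps ** 2).sqrt().mean()


def fd_loss(pred: Tensor, target: np.ndarray, rel_damp: float = 1e-2) -> Tensor:
    """Frequency-domain L1 loss (amplitude + phase, mean over bins and batch)
    with an analytic backward through the FFT adjoint.

    Matches :func:`srpomb.losses.frequency_domain_loss` on the same arrays.
    The phase derivative carries a 1/amplitude^2 factor that explodes on
    near-empty bins; the backward damps it with a Tikhonov denominator
    ``A^2 + (rel_damp * A_max)^2`` (forward value unaffected).  Set
    ``rel_damp=0`` for the raw derivative.
    """
    p = pred.data
    t = np.asarray(target, dtype=np.float64)
    bsz = p.shape[0]
    p2 = p.reshape(bsz, p.shape[-2], p.shape[-1])
    t2 = t.reshape(bsz, t.shape[-2], t.shape[-1])
    nbins = p2.shape[-1] * p2.shape[-2]

    fp = np.fft.fft2(p2)
    ft = np.fft.fft2(t2)
    ap, at = np.abs(fp), np.abs(ft)
    php, pht = np.angle(fp), np.angle(ft)
    value = float(np.mean(
        np.mean(np.abs(ap - at), axis=(1, 2))
        + np.mean(np.abs(php - pht), axis=(1, 2))))

    def bw(g):
        g = float(g)
        ga = np.sign(ap - at) / (nbins * bsz)          # dL/dA
        gp = np.sign(php - pht) / (nbins * bsz)        # dL/dP
        safe = np.maximum(ap, 1e-30)
        delta2 = (rel_damp * ap.max(axis=(1, 2), keepdims=True)) ** 2
        re, im = fp.real, fp.imag
        # dA/dF = (Re + i Im)/A ; dP/dF = (-Im + i Re)/A^2
        gf = (ga * (re + 1j * im) / safe
              + gp * (-im + 1j * re) / (safe ** 2 + delta2))
        # adjoint of the unnormalized DFT: W^H = N * ifft
        gx = np.real(np.fft.ifft2(gf)) * nbins
        pred._accum(g * gx.reshape(pred.data.shape))

    return Tensor(value, (pred,), bw)


# --------------------------------------------------------------------------
# modules
# --------------------------------------------------------------------------

class Module:
    def parameters(self) -> list[Parameter]:
        out = []
        for v in vars(self).values():
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        out.append(item)
        return out

    def param_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state array count mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=np.float64).copy()

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)


class Conv2d(Module):
    def __init__(self, cin, cout, k, rng, stride=1, groups=1, zero_init=False):
        fan_in = cin // groups * k * k
        scale = 0.0 if zero_init else np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0.0, 1.0, (cout, cin // groups, k, k))
                                * scale)
        self.bias = Parameter(np.zeros(cout))
        self.stride = stride
        self.groups = groups

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, stride=self.stride,
                      groups=self.groups)


class LeakyReLU(Module):
    def __init__(self, alpha=0.2):
        self.alpha = alpha

    def forward(self, x):
        return leaky_relu(x, self.alpha)


class AvgPool2(Module):
    def __init__(self, k=2):
        self.k = k

    def forward(self, x):
        return avg_pool2(x, self.k)


class NearestUp(Module):
    def __init__(self, scale=2):
        self.scale = scale

    def forward(self, x):
        return nearest_up(x, self.scale)


class DepthToSpace(Module):
    def __init__(self, scale=2):
        self.scale = scale

    def forward(self, x):
        return depth_to_space(x, self.scale)


class Sequential(Module):
    def __init__(self, *mods):
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


class Adam:
    """Adam with L2 weight decay added to the gradient."""

    def __init__(self, params, lr=1e-4, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.wd = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad + self.wd * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
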