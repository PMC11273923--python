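"""Minimal reverse-mode autodiff and neural-network layers on NumPy.

The toolkit trains small convolutional networks (search cells, one-shot
supernets, age-estimation heads) on CPU at desk scale, so the runtime is a
compact tape-based autodiff over ``numpy.ndarray`` with exactly the layer
vocabulary the search spaces need: standard / depthwise / grouped
convolutions with "same" padding, batch normalization, ReLU6, pooling,
fully connected layers and a squeeze-excitation gate.

Conventions
-----------
* Feature maps are ``(N, C, H, W)`` float64 arrays.
* "same" padding: a stride-``s`` layer maps spatial size ``n`` to
  ``ceil(n / s)`` (TensorFlow-style asymmetric padding when the total pad
  is odd).
* Convolutions are bias-free; normalization layers carry the affine terms.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "Module",
    "Parameter",
    "Conv2d",
    "BatchNorm2d",
    "Linear",
    "ReLU6",
    "Identity",
    "Zero",
    "AvgPool2d",
    "MaxPool2d",
    "GlobalAvgPool",
    "Sequential",
    "SqueezeExcite",
    "SGD",
    "Adam",
    "softmax",
    "log_softmax",
    "cross_entropy",
    "same_pad",
]


# ---------------------------------------------------------------------------
# autodiff core
# ---------------------------------------------------------------------------

class Tensor:
    """An ndarray with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- graph plumbing ------------------------------------------------------
    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- broadcasting helper -------------------------------------------------
    @staticmethod
    def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
        if g.shape == shape:
            return g
        nd = g.ndim - len(shape)
        if nd > 0:
            g = g.sum(axis=tuple(range(nd)))
        axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
        if axes:
            g = g.sum(axis=axes, keepdims=True)
        return g.reshape(shape)

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accum(self._unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(self._unbroadcast(g, other.data.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accum(self._unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(self._unbroadcast(g * self.data, other.data.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** -1.0

    def __pow__(self, p: float):
        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1.0))

        return self._make(self.data ** p, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        return self ** 0.5

    # -- reductions / reshapes -----------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))

        return self._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, axes):
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx):
        def backward(g):
            if self.requires_grad:
                gg = np.zeros_like(self.data)
                np.add.at(gg, idx, g)
                self._accum(gg)

        return self._make(self.data[idx], (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), backward)

    # -- nonlinearities --------------------------------------------------------
    def relu6(self):
        mask = (self.data > 0) & (self.data < 6)

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return self._make(np.clip(self.data, 0.0, 6.0), (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    out = Tensor(data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._prev = tuple(tensors)
        out._backward = backward
    return out


def stack_sum(tensors: Sequence[Tensor], weights: Sequence[Tensor | float]) -> Tensor:
    """Weighted sum of same-shape tensors (the mixed-edge primitive)."""
    out = None
    for t, w in zip(tensors, weights):
        term = t * w
        out = term if out is None else out + term
    return out


# ---------------------------------------------------------------------------
# padding / convolution primitives
# ---------------------------------------------------------------------------

def same_pad(n: int, k: int, s: int) -> tuple[int, int]:
    """(before, after) zero padding so output size is ceil(n / s)."""
    out = math.ceil(n / s)
    total = max((out - 1) * s + k - n, 0)
    return total // 2, total - total // 2


def _im2col(xp: np.ndarray, kh: int, kw: int, sh: int, sw: int) -> np.ndarray:
    # xp: padded (N, C, Hp, Wp) -> windows (N, C, Ho, Wo, kh, kw)
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    return win[:, :, ::sh, ::sw]


def conv2d(x: Tensor, w: Tensor, stride: int | tuple[int, int] = 1,
           groups: int = 1) -> Tensor:
    """Grouped 2-D convolution with "same" padding, no bias.

    ``w`` has shape ``(cout, cin // groups, kh, kw)``.
    """
    sh, sw = (stride, stride) if isinstance(stride, int) else stride
    n, cin, h, wdt = x.data.shape
    cout, cin_g, kh, kw = w.data.shape
    if cin % groups or cout % groups or cin // groups != cin_g:
        raise ValueError(
            f"channels ({cin}->{cout}) not divisible into {groups} groups")
    pt, pb = same_pad(h, kh, sh)
    pl, pr = same_pad(wdt, kw, sw)
    xp = np.pad(x.data, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
    cols = _im2col(xp, kh, kw, sh, sw)           # N,C,Ho,Wo,kh,kw
    ho, wo = cols.shape[2], cols.shape[3]
    g = groups
    cols_g = cols.reshape(n, g, cin_g, ho, wo, kh, kw)
    w_g = w.data.reshape(g, cout // g, cin_g, kh, kw)
    out_data = np.einsum("ngchwij,gocij->ngohw", cols_g, w_g, optimize=True)
    out_data = out_data.reshape(n, cout, ho, wo)

    def backward(grad):
        gout = grad.reshape(n, g, cout // g, ho, wo)
        if w.requires_grad:
            gw = np.einsum("ngchwij,ngohw->gocij", cols_g, gout, optimize=True)
            w._accum(gw.reshape(cout, cin_g, kh, kw))
        if x.requires_grad:
            dcols = np.einsum("gocij,ngohw->ngchwij", w_g, gout, optimize=True)
            dcols = dcols.reshape(n, cin, ho, wo, kh, kw)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + sh * ho:sh, j:j + sw * wo:sw] += dcols[:, :, :, :, i, j]
            x._accum(dxp[:, :, pt:pt + h, pl:pl + wdt])

    out = Tensor(out_data)
    if x.requires_grad or w.requires_grad:
        out.requires_grad = True
        out._prev = (x, w)
        out._backward = backward
    return out


def _pool2d(x: Tensor, k: int, stride: int, mode: str) -> Tensor:
    n, c, h, wdt = x.data.shape
    pt, pb = same_pad(h, k, stride)
    pl, pr = same_pad(wdt, k, stride)
    if mode == "max":
        fill = -np.inf
    else:
        fill = 0.0
    xp = np.pad(x.data, ((0, 0), (0, 0), (pt, pb), (pl, pr)),
                constant_values=fill)
    cols = _im2col(xp, k, k, stride, stride)     # N,C,Ho,Wo,k,k
    ho, wo = cols.shape[2], cols.shape[3]
    if mode == "max":
        out_data = cols.max(axis=(4, 5))
        amax = cols.reshape(n, c, ho, wo, k * k).argmax(axis=4)
    else:
        # count_include_pad=False: divide by the number of real cells
        ones = np.pad(np.ones((1, 1, h, wdt)), ((0, 0), (0, 0), (pt, pb), (pl, pr)))
        counts = _im2col(ones, k, k, stride, stride).sum(axis=(4, 5))
        out_data = cols.sum(axis=(4, 5)) / counts

    def backward(grad):
        if not x.requires_grad:
            return
        dxp = np.zeros_like(xp)
        if mode == "max":
            ii, jj = np.divmod(amax, k)
            nn, cc, hh, ww = np.indices((n, c, ho, wo))
            np.add.at(dxp, (nn, cc, hh * stride + ii, ww * stride + jj), grad)
        else:
            gshare = grad / counts
            for i in range(k):
                for j in range(k):
                    dxp[:, :, i:i + stride * ho:stride,
                        j:j + stride * wo:stride] += gshare
        x._accum(dxp[:, :, pt:pt + h, pl:pl + wdt])

    out = Tensor(out_data)
    if x.requires_grad:
        out.requires_grad = True
        out._prev = (x,)
        out._backward = backward
    return out


def max_pool2d(x: Tensor, k: int = 3, stride: int = 1) -> Tensor:
    return _pool2d(x, k, stride, "max")


def avg_pool2d(x: Tensor, k: int = 3, stride: int = 1) -> Tensor:
    return _pool2d(x, k, stride, "avg")


# ---------------------------------------------------------------------------
# softmax / losses
# ---------------------------------------------------------------------------

def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = np.max(x.data, axis=axis, keepdims=True)
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = np.max(x.data, axis=axis, keepdims=True)
    z = x - shift
    return z - z.exp().sum(axis=axis, keepdims=True).log()


def cross_entropy(logits: Tensor, target_probs: np.ndarray) -> Tensor:
    """Mean cross-entropy between a target distribution and the logits."""
    logp = log_softmax(logits, axis=-1)
    n = logits.data.shape[0]
    return -(logp * Tensor(target_probs)).sum() * (1.0 / n)


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Tiny module system: parameter discovery by attribute walk."""

    training: bool = True

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        self._collect(params, seen)
        return params

    def _collect(self, params: list, seen: set) -> None:
        for v in self.__dict__.values():
            self._collect_value(v, params, seen)

    @staticmethod
    def _collect_value(v, params, seen):
        if isinstance(v, Parameter):
            if id(v) not in seen:
                seen.add(id(v))
                params.append(v)
        elif isinstance(v, Module):
            v._collect(params, seen)
        elif isinstance(v, (list, tuple)):
            for item in v:
                Module._collect_value(item, params, seen)
        elif isinstance(v, dict):
            for item in v.values():
                Module._collect_value(item, params, seen)

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for v in self.__dict__.values():
            self._set_mode(v, mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    @staticmethod
    def _set_mode(v, mode):
        if isinstance(v, Module):
            v.train(mode)
        elif isinstance(v, (list, tuple)):
            for item in v:
                Module._set_mode(item, mode)
        elif isinstance(v, dict):
            for item in v.values():
                Module._set_mode(item, mode)

    def num_params(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: Iterable[np.ndarray]) -> None:
        params = self.parameters()
        state = list(state)
        if len(state) != len(params):
            raise ValueError("state size mismatch")
        for p, s in zip(params, state):
            if p.data.shape != s.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {s.shape}")
            p.data = s.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _kaiming(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, math.sqrt(2.0 / max(fan_in, 1)), size=shape)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, kernel: int | tuple[int, int],
                 stride: int = 1, groups: int = 1,
                 rng: np.random.Generator | None = None):
        kh, kw = (kernel, kernel) if isinstance(kernel, int) else kernel
        if cin % groups or cout % groups:
            raise ValueError(
                f"channels ({cin}->{cout}) not divisible by groups={groups}")
        rng = rng or np.random.default_rng(0)
        fan_in = (cin // groups) * kh * kw
        self.weight = Parameter(_kaiming(rng, (cout, cin // groups, kh, kw), fan_in))
        self.stride = stride
        self.groups = groups

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, stride=self.stride, groups=self.groups)


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Parameter(np.ones((1, channels, 1, 1)))
        self.beta = Parameter(np.zeros((1, channels, 1, 1)))
        self.running_mean = np.zeros((1, channels, 1, 1))
        self.running_var = np.ones((1, channels, 1, 1))
        self.eps = eps
        self.momentum = momentum

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data)
        else:
            mu, var = Tensor(self.running_mean), Tensor(self.running_var)
        xhat = (x - mu) * ((var + self.eps) ** -0.5)
        return xhat * self.gamma + self.beta


class Linear(Module):
    def __init__(self, cin: int, cout: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(_kaiming(rng, (cin, cout), cin))
        self.bias = Parameter(np.zeros(cout)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class ReLU6(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu6()


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class Zero(Module):
    """The no-connection operator: an all-zero map at the strided shape."""

    def __init__(self, stride: int = 1):
        self.stride = stride

    def forward(self, x: Tensor) -> Tensor:
        if self.stride == 1:
            return x * 0.0
        return x[:, :, ::self.stride, ::self.stride] * 0.0


class AvgPool2d(Module):
    def __init__(self, kernel: int = 3, stride: int = 1):
        self.kernel, self.stride = kernel, stride

    def forward(self, x: Tensor) -> Tensor:
        return avg_pool2d(x, self.kernel, self.stride)


class MaxPool2d(Module):
    def __init__(self, kernel: int = 3, stride: int = 1):
        self.kernel, self.stride = kernel, stride

    def forward(self, x: Tensor) -> Tensor:
        return max_pool2d(x, self.kernel, self.stride)


class GlobalAvgPool(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.mean(axis=(2, 3))


class Sequential(Module):
    def __init__(self, *mods: Module):
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x


class SqueezeExcite(Module):
    """Channel gate: GAP -> FC(c -> c/r) -> ReLU6 -> FC -> sigmoid -> scale.

    The two fully connected layers carry biases.
    """

    def __init__(self, channels: int, reduction: int = 4,
                 rng: np.random.Generator | None = None):
        hidden = max(channels // reduction, 1)
        self.fc1 = Linear(channels, hidden, bias=True, rng=rng)
        self.fc2 = Linear(hidden, channels, bias=True, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        n, c = x.data.shape[0], x.data.shape[1]
        s = x.mean(axis=(2, 3))
        s = self.fc2(self.fc1(s).relu6()).sigmoid()
        return x * s.reshape(n, c, 1, 1)


# ---------------------------------------------------------------------------
# optimizers
# ---------------------------------------------------------------------------

class SGD:
    def __init__(self, params: Sequence[Parameter], lr: float,
                 momentum: float = 0.0, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class Adam:
    def __init__(self, params: Sequence[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
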