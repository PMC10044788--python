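"""Minimal reverse-mode automatic differentiation and neural-network layers.

The detection and similarity models in this package are small convolutional
networks trained on a CPU.  This module provides the numerical substrate:
a :class:`Tensor` wrapping a numpy array with a recorded operation graph,
the differentiable operations the models need (dense/convolution layers,
batch normalisation, pooling, nearest-neighbour upsampling, the usual
elementwise functions and numerically stable binary cross-entropy), and a
plain SGD-with-momentum optimiser with a one-cycle cosine schedule.

Arrays keep whatever float dtype they are given; gradient-checking tests run
in float64 while training runs in float32.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "concat",
    "conv2d",
    "maxpool2d_same",
    "upsample2x",
    "global_avg_pool",
    "leaky_relu",
    "sigmoid",
    "exp",
    "log",
    "sqrt",
    "maximum",
    "minimum",
    "bce_with_logits",
    "take",
    "Module",
    "Conv2d",
    "BatchNorm2d",
    "Linear",
    "ConvBlock",
    "Sequential",
    "SGD",
    "one_cycle_lr",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the backward functions that produced it."""

    __slots__ = ("data", "grad", "_parents", "_grad_fns")

    def __init__(self, data, parents=(), grad_fns=(), requires_grad=False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        # leaves created with requires_grad=True carry an empty parent list
        # but still participate in backward; mark them with a sentinel.
        self._parents = tuple(parents)
        self._grad_fns = tuple(grad_fns)
        if requires_grad and not self._parents:
            self._grad_fns = (None,)  # sentinel: leaf that accumulates grad

    # -- graph -----------------------------------------------------------
    @property
    def requires_grad(self) -> bool:
        return bool(self._grad_fns)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            stack = [(t, iter(t._parents))]
            if id(t) in seen:
                return
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen and p.requires_grad:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node.grad is None:
                continue
            for parent, fn in zip(node._parents, node._grad_fns):
                if fn is None or not parent.requires_grad:
                    continue
                g = fn(node.grad)
                if parent.grad is None:
                    parent.grad = g.astype(parent.data.dtype, copy=True)
                else:
                    parent.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    def __add__(self, other):
        o = self._lift(other)
        return Tensor(
            self.data + o.data,
            parents=(self, o),
            grad_fns=(
                lambda g: _unbroadcast(g, self.data.shape),
                lambda g: _unbroadcast(g, o.data.shape),
            ),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, parents=(self,), grad_fns=(lambda g: -g,))

    def __sub__(self, other):
        o = self._lift(other)
        return Tensor(
            self.data - o.data,
            parents=(self, o),
            grad_fns=(
                lambda g: _unbroadcast(g, self.data.shape),
                lambda g: _unbroadcast(-g, o.data.shape),
            ),
        )

    def __rsub__(self, other):
        return self._lift(other) - self

    def __mul__(self, other):
        o = self._lift(other)
        return Tensor(
            self.data * o.data,
            parents=(self, o),
            grad_fns=(
                lambda g: _unbroadcast(g * o.data, self.data.shape),
                lambda g: _unbroadcast(g * self.data, o.data.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = self._lift(other)
        return Tensor(
            self.data / o.data,
            parents=(self, o),
            grad_fns=(
                lambda g: _unbroadcast(g / o.data, self.data.shape),
                lambda g: _unbroadcast(-g * self.data / o.data**2, o.data.shape),
            ),
        )

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, k):
        if not np.isscalar(k):
            raise TypeError("only scalar exponents are supported")
        return Tensor(
            self.data**k,
            parents=(self,),
            grad_fns=(lambda g: g * k * self.data ** (k - 1),),
        )

    def __matmul__(self, other):
        o = self._lift(other)
        return Tensor(
            self.data @ o.data,
            parents=(self, o),
            grad_fns=(
                lambda g: g @ o.data.swapaxes(-1, -2),
                lambda g: self.data.swapaxes(-1, -2) @ g,
            ),
        )

    # -- shape -----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        return Tensor(
            self.data.reshape(shape),
            parents=(self,),
            grad_fns=(lambda g: g.reshape(old),),
        )

    def transpose(self, *axes):
        inv = np.argsort(axes)
        return Tensor(
            self.data.transpose(axes),
            parents=(self,),
            grad_fns=(lambda g: g.transpose(inv),),
        )

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.data.shape

        def grad_fn(g):
            if axis is None:
                return np.broadcast_to(g, shape).copy()
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            return np.broadcast_to(gg, shape).copy()

        return Tensor(out, parents=(self,), grad_fns=(grad_fn,))

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


# ---------------------------------------------------------------------------
# elementwise functions
# ---------------------------------------------------------------------------

def leaky_relu(x: Tensor, negative_slope: float = 0.1) -> Tensor:
    mask = x.data > 0
    scale = np.where(mask, 1.0, negative_slope)
    return Tensor(x.data * scale, parents=(x,), grad_fns=(lambda g: g * scale,))


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))
    return Tensor(s, parents=(x,), grad_fns=(lambda g: g * s * (1.0 - s),))


def exp(x: Tensor) -> Tensor:
    e = np.exp(np.clip(x.data, -60, 60))
    return Tensor(e, parents=(x,), grad_fns=(lambda g: g * e,))


def log(x: Tensor) -> Tensor:
    return Tensor(np.log(x.data), parents=(x,), grad_fns=(lambda g: g / x.data,))


def sqrt(x: Tensor) -> Tensor:
    r = np.sqrt(x.data)
    return Tensor(r, parents=(x,), grad_fns=(lambda g: g * 0.5 / np.maximum(r, 1e-12),))


def maximum(a: Tensor, b) -> Tensor:
    b = Tensor._lift(b)
    mask = a.data >= b.data
    return Tensor(
        np.maximum(a.data, b.data),
        parents=(a, b),
        grad_fns=(
            lambda g: _unbroadcast(g * mask, a.data.shape),
            lambda g: _unbroadcast(g * ~mask, b.data.shape),
        ),
    )


def minimum(a: Tensor, b) -> Tensor:
    b = Tensor._lift(b)
    mask = a.data <= b.data
    return Tensor(
        np.minimum(a.data, b.data),
        parents=(a, b),
        grad_fns=(
            lambda g: _unbroadcast(g * mask, a.data.shape),
            lambda g: _unbroadcast(g * ~mask, b.data.shape),
        ),
    )


def bce_with_logits(logits: Tensor, targets, weight=None) -> Tensor:
    """Numerically stable binary cross-entropy.

    Returns the weighted mean ``sum(w * bce) / sum(w)``; `weight` defaults to
    uniform (plain mean over all elements).
    """
    z = logits.data
    t = np.broadcast_to(np.asarray(targets, dtype=z.dtype), z.shape)
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    if weight is None:
        w = np.ones_like(z)
    else:
        w = np.broadcast_to(np.asarray(weight, dtype=z.dtype), z.shape)
    denom = max(float(w.sum()), 1e-12)

    def grad_fn(g):
        s = 1.0 / (1.0 + np.exp(-z))
        return g * w * (s - t) / denom

    return Tensor(np.array((w * loss).sum() / denom), parents=(logits,),
                  grad_fns=(grad_fn,))


def take(x: Tensor, index) -> Tensor:
    """Differentiable fancy indexing (gather); `index` is any numpy index."""
    out = x.data[index]
    shape = x.data.shape

    def grad_fn(g):
        gx = np.zeros(shape, dtype=g.dtype)
        np.add.at(gx, index, g)
        return gx

    return Tensor(out, parents=(x,), grad_fns=(grad_fn,))


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def make_fn(i):
        sl = [slice(None)] * data.ndim
        sl[axis] = slice(int(offsets[i]), int(offsets[i + 1]))
        sl = tuple(sl)
        return lambda g: g[sl]

    return Tensor(
        data,
        parents=tuple(tensors),
        grad_fns=tuple(make_fn(i) for i in range(len(tensors))),
    )


# ---------------------------------------------------------------------------
# spatial operations (NCHW layout)
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, stride: int = 1,
           padding: int = 0) -> Tensor:
    """2-D cross-correlation via im2col.  x: (N,C,H,W); weight: (O,C,k,k)."""
    n, c, h, w = x.data.shape
    o, c2, k, _ = weight.data.shape
    if c != c2:
        raise ValueError(f"channel mismatch: input {c}, weight {c2}")
    s, p = stride, padding
    ho = (h + 2 * p - k) // s + 1
    wo = (w + 2 * p - k) // s + 1
    if ho < 1 or wo < 1:
        raise ValueError("kernel larger than (padded) input")
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    win = win[:, :, ::s, ::s]                       # N,C,Ho,Wo,k,k
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
    wmat = weight.data.reshape(o, c * k * k)
    out = cols @ wmat.T                             # (N*Ho*Wo, O)
    if bias is not None:
        out = out + bias.data
    out = out.reshape(n, ho, wo, o).transpose(0, 3, 1, 2)

    def grad_x(g):
        if s == 1:
            # dX is a full correlation of g with the flipped, transposed
            # kernel; one im2col matmul beats a k*k scatter loop
            q = k - 1 - p
            gp = np.pad(g, ((0, 0), (0, 0), (q, q), (q, q))) if q else g
            gwin = np.lib.stride_tricks.sliding_window_view(gp, (k, k), axis=(2, 3))
            gcols = gwin.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, o * k * k)
            wflip = weight.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
            return (gcols @ wflip.reshape(c, o * k * k).T).reshape(n, h, w, c) \
                .transpose(0, 3, 1, 2)
        gc = g.transpose(0, 2, 3, 1).reshape(n * ho * wo, o)
        dcols = gc @ wmat                           # (N*Ho*Wo, C*k*k)
        dcols = dcols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=g.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += dcols[:, :, :, :, i, j]
        return dxp[:, :, p:p + h, p:p + w] if p else dxp

    def grad_w(g):
        gc = g.transpose(0, 2, 3, 1).reshape(n * ho * wo, o)
        return (gc.T @ cols).reshape(o, c, k, k)

    parents = [x, weight]
    fns = [grad_x, grad_w]
    if bias is not None:
        parents.append(bias)
        fns.append(lambda g: g.sum(axis=(0, 2, 3)))
    return Tensor(out, parents=tuple(parents), grad_fns=tuple(fns))


def maxpool2d_same(x: Tensor, kernel: int) -> Tensor:
    """Stride-1 max pooling with 'same' output size (odd kernel)."""
    if kernel % 2 != 1:
        raise ValueError("kernel must be odd")
    n, c, h, w = x.data.shape
    p = kernel // 2
    neg = np.finfo(x.data.dtype).min if x.data.dtype.kind == "f" else np.iinfo(x.data.dtype).min
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=neg)
    win = np.lib.stride_tricks.sliding_window_view(xp, (kernel, kernel), axis=(2, 3))
    flat = win.reshape(n, c, h, w, kernel * kernel)
    arg = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
    ii, jj = np.unravel_index(arg, (kernel, kernel))
    gi = (np.arange(h)[None, None, :, None] + ii)  # row in padded coords
    gj = (np.arange(w)[None, None, None, :] + jj)

    def grad_fn(g):
        gxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=g.dtype)
        nn_, cc = np.meshgrid(np.arange(n), np.arange(c), indexing="ij")
        nn_ = nn_[:, :, None, None]
        cc = cc[:, :, None, None]
        np.add.at(gxp, (nn_, cc, gi, gj), g)
        return gxp[:, :, p:p + h, p:p + w]

    return Tensor(out, parents=(x,), grad_fns=(grad_fn,))


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling."""
    n, c, h, w = x.data.shape
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def grad_fn(g):
        return g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5))

    return Tensor(out, parents=(x,), grad_fns=(grad_fn,))


def global_avg_pool(x: Tensor) -> Tensor:
    """(N,C,H,W) -> (N,C) mean over space."""
    n, c, h, w = x.data.shape
    out = x.data.mean(axis=(2, 3))

    def grad_fn(g):
        return np.broadcast_to(g[:, :, None, None] / (h * w), (n, c, h, w)).copy()

    return Tensor(out, parents=(x,), grad_fns=(grad_fn,))


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Module:
    """Base class; submodules and Parameters are discovered by attribute scan."""

    training = True

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()

        def collect(obj):
            for v in vars(obj).values():
                if isinstance(v, Parameter) and id(v) not in seen:
                    seen.add(id(v))
                    params.append(v)
                elif isinstance(v, Module):
                    collect(v)
                elif isinstance(v, (list, tuple)):
                    for item in v:
                        if isinstance(item, Module):
                            collect(item)

        collect(self)
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]

        def collect(obj):
            for v in vars(obj).values():
                if isinstance(v, Module):
                    mods.append(v)
                    collect(v)
                elif isinstance(v, (list, tuple)):
                    for item in v:
                        if isinstance(item, Module):
                            mods.append(item)
                            collect(item)

        collect(self)
        return mods

    def train(self) -> None:
        for m in self.modules():
            m.training = True

    def eval(self) -> None:
        for m in self.modules():
            m.training = False

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name->array mapping of parameters and buffers (for saving)."""
        out: dict[str, np.ndarray] = {}

        def collect(obj, prefix):
            for k, v in vars(obj).items():
                name = f"{prefix}{k}"
                if isinstance(v, Parameter):
                    out[name] = v.data
                elif isinstance(v, np.ndarray):
                    out[name] = v
                elif isinstance(v, Module):
                    collect(v, name + ".")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            collect(item, f"{name}.{i}.")

        collect(self, "")
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        def assign(obj, prefix):
            for k, v in vars(obj).items():
                name = f"{prefix}{k}"
                if isinstance(v, Parameter):
                    v.data = np.asarray(state[name]).astype(v.data.dtype)
                elif isinstance(v, np.ndarray):
                    setattr(obj, k, np.asarray(state[name]).astype(v.dtype))
                elif isinstance(v, Module):
                    assign(v, name + ".")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            assign(item, f"{name}.{i}.")

        assign(self, "")


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * math.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d(Module):
    def __init__(self, c_in, c_out, kernel=3, stride=1, padding=None, bias=True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        if padding is None:
            padding = kernel // 2
        self.stride = stride
        self.padding = padding
        self.weight = Parameter(_kaiming(rng, (c_out, c_in, kernel, kernel),
                                         c_in * kernel * kernel))
        self.bias = Parameter(np.zeros(c_out, dtype=np.float32)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class BatchNorm2d(Module):
    def __init__(self, channels, eps=1e-5, momentum=0.1):
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.ravel()).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.ravel()).astype(np.float32)
        else:
            mu = Tensor(self.running_mean.reshape(1, -1, 1, 1).astype(x.data.dtype))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1).astype(x.data.dtype))
        xhat = (x - mu) / sqrt(var + 1e-12 + self.eps)
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return xhat * g + b


class Linear(Module):
    def __init__(self, n_in, n_out, bias=True, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.weight = Parameter(_kaiming(rng, (n_in, n_out), n_in))
        self.bias = Parameter(np.zeros(n_out, dtype=np.float32)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class ConvBlock(Module):
    """Conv + BatchNorm + LeakyReLU — the CBL unit of the detector."""

    def __init__(self, c_in, c_out, kernel=3, stride=1, rng=None):
        self.conv = Conv2d(c_in, c_out, kernel, stride, bias=False, rng=rng)
        self.bn = BatchNorm2d(c_out)

    def __call__(self, x: Tensor) -> Tensor:
        return leaky_relu(self.bn(self.conv(x)))


class Sequential(Module):
    def __init__(self, *layers):
        self.layers = list(layers)

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


# ---------------------------------------------------------------------------
# optimisation
# ---------------------------------------------------------------------------

class SGD:
    """SGD with classical momentum."""

    def __init__(self, params: list[Parameter], lr: float, momentum: float = 0.937):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            v *= self.momentum
            v += p.grad
            p.data = p.data - self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def one_cycle_lr(step: int, total_steps: int, lr0: float, final_factor: float = 0.2) -> float:
    """Cosine decay from lr0 to lr0*final_factor over the run."""
    if total_steps <= 1:
        return lr0
    t = min(max(step, 0), total_steps - 1) / (total_steps - 1)
    return lr0 * (final_factor + (1 - final_factor) * 0.5 * (1 + math.cos(math.pi * t)))
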