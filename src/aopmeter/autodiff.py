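"""A compact reverse-mode automatic-differentiation engine on NumPy arrays.

Provides exactly the operator set the multitask network needs: broadcasted
elementwise arithmetic, matrix product, 2-D convolution (stride 1, via
im2col + GEMM), 2x2 max pooling, x2 bilinear upsampling (cached sparse
operators), reductions, activations, concatenation/slicing and pixel
gathering.  Layers (`Conv2d`, `BatchNorm2d`, ...), Kaiming initialization,
the Adam optimizer and a step learning-rate schedule live here too.

Everything is float32 end to end; gradients are accumulated into ``.grad``
by :meth:`Tensor.backward` over a topologically sorted tape.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Tensor", "Parameter", "Module",
    "Conv2d", "BatchNorm2d", "Linear", "ChannelConv1d",
    "concat", "kaiming_normal", "Adam", "StepLR",
]


def _as_f32(x):
    return np.asarray(x, dtype=np.float32)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev=()):
        self.data = _as_f32(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _prev)
        self._backward = None
        self._prev = tuple(_prev)

    # -- bookkeeping --------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            g = np.ascontiguousarray(g, dtype=np.float32)
            self.grad = g.reshape(self.data.shape)  # 0-d safety: keep exact shape
        else:
            self.grad += g.reshape(self.data.shape)

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.requires_grad:
                t._backward()
        # break the closure<->node reference cycles so the tape is freed
        # by reference counting instead of waiting for the gc
        for t in topo:
            t._backward = None
            t._prev = ()

    def release(self) -> None:
        """Drop the graph below this node (for forward-only evaluations)."""
        stack, seen = [self], set()
        while stack:
            t = stack.pop()
            if id(t) in seen:
                continue
            seen.add(id(t))
            stack.extend(t._prev)
            t._backward = None
            t._prev = ()

    # -- arithmetic ---------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def _bw():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.data.shape))
        out._backward = _bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def _bw():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.data.shape))
        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * Tensor(np.float32(-1.0))

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def pow(self, p: float):
        out = Tensor(self.data ** p, _prev=(self,))

        def _bw():
            if self.requires_grad:
                self._accum(out.grad * p * self.data ** (p - 1))
        out._backward = _bw
        return out

    def exp(self):
        out = Tensor(np.exp(self.data), _prev=(self,))

        def _bw():
            if self.requires_grad:
                self._accum(out.grad * out.data)
        out._backward = _bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))

        def _bw():
            if self.requires_grad:
                self._accum(out.grad / self.data)
        out._backward = _bw
        return out

    def clamp(self, lo: float, hi: float):
        out = Tensor(np.clip(self.data, lo, hi), _prev=(self,))
        mask = (self.data > lo) & (self.data < hi)

        def _bw():
            if self.requires_grad:
                self._accum(out.grad * mask)
        out._backward = _bw
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0), _prev=(self,))

        def _bw():
            if self.requires_grad:
                self._accum(out.grad * (self.data > 0))
        out._backward = _bw
        return out

    def sigmoid(self):
        out = Tensor(1.0 / (1.0 + np.exp(-self.data)), _prev=(self,))

        def _bw():
            if self.requires_grad:
                self._accum(out.grad * out.data * (1.0 - out.data))
        out._backward = _bw
        return out

    # -- reductions / reshaping --------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def _bw():
            if not self.requires_grad:
                return
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())
        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * Tensor(np.float32(1.0 / n))

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _prev=(self,))

        def _bw():
            if self.requires_grad:
                self._accum(out.grad.reshape(self.data.shape))
        out._backward = _bw
        return out

    def narrow(self, axis: int, start: int, length: int):
        """Slice ``[start:start+length]`` along ``axis``."""
        idx = [slice(None)] * self.data.ndim
        idx[axis] = slice(start, start + length)
        idx = tuple(idx)
        out = Tensor(self.data[idx], _prev=(self,))

        def _bw():
            if self.requires_grad:
                g = np.zeros_like(self.data)
                g[idx] = out.grad
                self._accum(g)
        out._backward = _bw
        return out

    def matmul(self, other: "Tensor"):
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def _bw():
            if self.requires_grad:
                self._accum(out.grad @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ out.grad)
        out._backward = _bw
        return out

    def gather_pixels(self, n_idx, c_idx, y_idx, x_idx):
        """Advanced-indexing read ``self[n, c, y, x]`` -> 1-D tensor."""
        idx = (np.asarray(n_idx), np.asarray(c_idx), np.asarray(y_idx), np.asarray(x_idx))
        out = Tensor(self.data[idx], _prev=(self,))

        def _bw():
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.add.at(g, idx, out.grad)
                self._accum(g)
        out._backward = _bw
        return out

    # -- spatial ops --------------------------------------------------------
    def maxpool2x2(self):
        n, c, h, w = self.data.shape
        x = self.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x = np.ascontiguousarray(x).reshape(n, c, h // 2, w // 2, 4)
        arg = x.argmax(axis=-1)
        out = Tensor(np.take_along_axis(x, arg[..., None], axis=-1)[..., 0],
                     _prev=(self,))

        def _bw():
            if not self.requires_grad:
                return
            g = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
            np.put_along_axis(g, arg[..., None], out.grad[..., None], axis=-1)
            g = g.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            self._accum(np.ascontiguousarray(g).reshape(n, c, h, w))
        out._backward = _bw
        return out

    def upsample2x(self):
        n, c, h, w = self.data.shape
        M, MT = _bilinear_ops(h, w)
        y = (M @ self.data.reshape(n * c, h * w).T).T.reshape(n, c, 2 * h, 2 * w)
        out = Tensor(y, _prev=(self,))

        def _bw():
            if self.requires_grad:
                g = (MT @ out.grad.reshape(n * c, 4 * h * w).T).T
                self._accum(g.reshape(n, c, h, w).astype(np.float32))
        out._backward = _bw
        return out

    def softmax_channels(self):
        """Softmax over axis 1 (numerically stabilized)."""
        m = Tensor(self.data.max(axis=1, keepdims=True))
        z = (self - m).exp()
        return z * z.sum(axis=1, keepdims=True).pow(-1.0)

    def global_avg_pool(self):
        """(N, C, H, W) -> (N, C) spatial mean."""
        return self.mean(axis=(2, 3))


def concat(tensors, axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), _prev=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def _bw():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * out.grad.ndim
                idx[axis] = slice(lo, hi)
                t._accum(out.grad[tuple(idx)])
    out._backward = _bw
    return out


# ---------------------------------------------------------------------------
# cached sparse bilinear x2 upsampling operators
# ---------------------------------------------------------------------------

_BILINEAR_CACHE: dict = {}


def _bilinear_axis_matrix(size: int) -> sp.csr_matrix:
    dst = np.arange(2 * size)
    src = np.clip((dst + 0.5) / 2.0 - 0.5, 0.0, size - 1.0)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, size - 1)
    w1 = src - i0
    rows = np.repeat(dst, 2)
    cols = np.stack([i0, i1], axis=1).ravel()
    vals = np.stack([1.0 - w1, w1], axis=1).ravel()
    return sp.csr_matrix((vals, (rows, cols)), shape=(2 * size, size))


def _bilinear_ops(h: int, w: int):
    key = (h, w)
    if key not in _BILINEAR_CACHE:
        M = sp.kron(_bilinear_axis_matrix(h), _bilinear_axis_matrix(w)).tocsr()
        M = M.astype(np.float32)
        _BILINEAR_CACHE[key] = (M, M.T.tocsr())
    return _BILINEAR_CACHE[key]


# ---------------------------------------------------------------------------
# conv2d (stride 1) via im2col
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, weight: Tensor, bias: Tensor, padding: int) -> Tensor:
    """2-D convolution, stride 1.  weight: (Cout, Cin, kh, kw).

    Channels-first im2col: the patch matrix is laid out (Cin*kh*kw, N*H*W)
    so both the forward product and the two backward products are single
    GEMMs with contiguous operands.
    """
    n, cin, h, w = x.data.shape
    cout, _, kh, kw = weight.data.shape
    if padding:
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    else:
        xp = x.data
    ho, wo = h + 2 * padding - kh + 1, w + 2 * padding - kw + 1
    if kh == kw == 1:
        cols = np.ascontiguousarray(xp.transpose(1, 0, 2, 3)).reshape(cin, n * ho * wo)
    else:
        win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
        # (n, cin, ho, wo, kh, kw) -> (cin, kh, kw, n, ho, wo)
        cols = np.ascontiguousarray(win.transpose(1, 4, 5, 0, 2, 3)).reshape(
            cin * kh * kw, n * ho * wo)
    wf = weight.data.reshape(cout, cin * kh * kw)
    y = (wf @ cols).reshape(cout, n, ho, wo).transpose(1, 0, 2, 3)
    out = Tensor(y + bias.data.reshape(1, cout, 1, 1), _prev=(x, weight, bias))

    def _bw():
        gyf = np.ascontiguousarray(out.grad.transpose(1, 0, 2, 3)).reshape(
            cout, n * ho * wo)
        if bias.requires_grad:
            bias._accum(gyf.sum(axis=1))
        if weight.requires_grad:
            weight._accum((gyf @ cols.T).reshape(cout, cin, kh, kw))
        if x.requires_grad:
            gcols = (wf.T @ gyf).reshape(cin, kh, kw, n, ho, wo)
            gxp = np.zeros((cin, n, h + 2 * padding, w + 2 * padding),
                           dtype=np.float32)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i:i + ho, j:j + wo] += gcols[:, i, j]
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            x._accum(gxp.transpose(1, 0, 2, 3))
    out._backward = _bw
    return out


def batchnorm2d_train(x: Tensor, gamma: Tensor, beta: Tensor, eps: float):
    """Fused training-mode batch normalization over (N, H, W) per channel.

    Returns (out, batch_mean, batch_var) with the biased batch variance;
    backward uses the closed-form batchnorm gradient.
    """
    mu = x.data.mean(axis=(0, 2, 3), keepdims=True)
    var = x.data.var(axis=(0, 2, 3), keepdims=True)
    ivar = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * ivar
    out = Tensor(gamma.data * xhat + beta.data, _prev=(x, gamma, beta))

    def _bw():
        g = out.grad
        if beta.requires_grad:
            beta._accum(g.sum(axis=(0, 2, 3), keepdims=True))
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=(0, 2, 3), keepdims=True))
        if x.requires_grad:
            gh = g * gamma.data
            m1 = gh.mean(axis=(0, 2, 3), keepdims=True)
            m2 = (gh * xhat).mean(axis=(0, 2, 3), keepdims=True)
            x._accum(ivar * (gh - m1 - xhat * m2))
    out._backward = _bw
    return out, mu, var


def channel_conv1d(v: Tensor, weight: Tensor) -> Tensor:
    """Single-kernel 1-D convolution over the channel axis of (N, C),
    zero-padded to keep the length (the attention op over pooled channels)."""
    n, c = v.data.shape
    k = weight.data.shape[0]
    pad = k // 2
    vp = np.pad(v.data, ((0, 0), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(vp, k, axis=1)  # (n, c, k)
    out = Tensor(win @ weight.data, _prev=(v, weight))

    def _bw():
        if weight.requires_grad:
            weight._accum(np.einsum("ncK,nc->K", win, out.grad))
        if v.requires_grad:
            gvp = np.zeros_like(vp)
            for j in range(k):
                gvp[:, j:j + c] += weight.data[j] * out.grad
            v._accum(gvp[:, pad:pad + c] if pad else gvp)
    out._backward = _bw
    return out


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def kaiming_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    """He-normal initialization for ReLU networks: std = sqrt(2 / fan_in)."""
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Module:
    """Minimal parameter container with recursive discovery."""

    training: bool = True

    def modules(self):
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for m in v:
                    if isinstance(m, Module):
                        yield m
                        yield from m.modules()

    def named_parameters(self, prefix: str = ""):
        for k, v in self.__dict__.items():
            name = f"{prefix}{k}"
            if isinstance(v, Parameter):
                yield name, v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{name}.")
            elif isinstance(v, (list, tuple)):
                for i, m in enumerate(v):
                    if isinstance(m, Module):
                        yield from m.named_parameters(f"{name}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for k, v in self.__dict__.items():
            name = f"{prefix}{k}"
            if isinstance(v, np.ndarray):
                yield name, v
            elif isinstance(v, Module):
                yield from v.named_buffers(f"{name}.")
            elif isinstance(v, (list, tuple)):
                for i, m in enumerate(v):
                    if isinstance(m, Module):
                        yield from m.named_buffers(f"{name}.{i}.")

    def train(self, flag: bool = True):
        self.training = flag
        for m in self.modules():
            m.training = flag
        return self

    def eval(self):
        return self.train(False)


class Conv2d(Module):
    """3x3/1x1 convolution; ``bias=False`` for layers feeding a batch norm,
    where a bias is exactly redundant."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 padding: int | None = None, bias: bool = True):
        self.padding = k // 2 if padding is None else padding
        self.weight = Parameter(kaiming_normal(rng, (cout, cin, k, k), cin * k * k))
        self.bias = (Parameter(np.zeros(cout, dtype=np.float32)) if bias
                     else Tensor(np.zeros(cout, dtype=np.float32)))

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.padding)


class BatchNorm2d(Module):
    """Batch normalization over (N, H, W), identity-initialized."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones((1, c, 1, 1), dtype=np.float32))
        self.beta = Parameter(np.zeros((1, c, 1, 1), dtype=np.float32))
        self.running_mean = np.zeros((1, c, 1, 1), dtype=np.float32)
        self.running_var = np.ones((1, c, 1, 1), dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            out, mu, var = batchnorm2d_train(x, self.gamma, self.beta, self.eps)
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
            return out
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        scale = Tensor(inv) * self.gamma
        return scale * (x - Tensor(self.running_mean)) + self.beta


class Linear(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.weight = Parameter(kaiming_normal(rng, (cin, cout), cin))
        self.bias = Parameter(np.zeros(cout, dtype=np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        return x.matmul(self.weight) + self.bias


class ChannelConv1d(Module):
    """The learned kernel of the channel-attention 1-D convolution."""

    def __init__(self, k: int, rng: np.random.Generator):
        self.weight = Parameter(kaiming_normal(rng, (k,), k))

    def __call__(self, v: Tensor) -> Tensor:
        return channel_conv1d(v, self.weight)


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------

class Adam:
    """Adaptive-moment optimizer (beta1=0.9, beta2=0.999)."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class StepLR:
    """lr(epoch) = lr0 * gamma^floor(epoch / step_size)."""

    def __init__(self, optimizer: Adam, step_size: int = 20, gamma: float = 0.1):
        self.opt = optimizer
        self.lr0 = optimizer.lr
        self.step_size = step_size
        self.gamma = gamma

    def lr_at(self, epoch: int) -> float:
        return self.lr0 * self.gamma ** (epoch // self.step_size)

    def set_epoch(self, epoch: int) -> None:
        self.opt.lr = self.lr_at(epoch)
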