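"""Minimal NumPy reverse-mode autodiff for small convolutional networks.

Supports exactly the operations the heatmap-regression model needs:
strided 3×3/1×1 convolution (im2col + GEMM), batch normalization, ReLU,
elementwise sum, nearest-neighbor upsampling and mean-squared-error loss,
plus an Adam optimizer.  Tensors are NCHW float32.  Everything is seeded
through explicit ``numpy.random.Generator`` instances, so builds and
training runs are bit-reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "Conv2d", "BatchNorm2d", "Module",
           "relu", "add", "upsample_nearest", "mse_loss", "Adam"]


class Tensor:
    """Array node in the backward graph."""

    __slots__ = ("data", "grad", "_backward", "_parents")

    def __init__(self, data, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def backward(self):
        """Reverse-mode sweep from this (scalar) node."""
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


def _accum(t: Tensor, g: np.ndarray) -> None:
    if t.grad is None:
        t.grad = g.astype(np.float32, copy=True)
    else:
        t.grad += g


class Parameter(Tensor):
    """Trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data)


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """(N,C,H,W) -> (N*OH*OW, C*kh*kw) patch matrix."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    N, C, H, W = x.shape
    oh = (H - kh) // stride + 1
    ow = (W - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]          # N,C,oh,ow,kh,kw
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(N * oh * ow, C * kh * kw)
    return np.ascontiguousarray(cols), oh, ow


def _col2im(cols: np.ndarray, x_shape, kh, kw, stride, pad):
    """Adjoint of _im2col: scatter patch gradients back to the input."""
    N, C, H, W = x_shape
    Hp, Wp = H + 2 * pad, W + 2 * pad
    oh = (Hp - kh) // stride + 1
    ow = (Wp - kw) // stride + 1
    out = np.zeros((N, C, Hp, Wp), dtype=np.float32)
    cols6 = cols.reshape(N, oh, ow, C, kh, kw).transpose(0, 3, 1, 2, 4, 5)
    for i in range(kh):
        ys = slice(i, i + stride * oh, stride)
        for j in range(kw):
            xs = slice(j, j + stride * ow, stride)
            out[:, :, ys, xs] += cols6[:, :, :, :, i, j]
    if pad:
        out = out[:, :, pad:-pad, pad:-pad]
    return out


def conv2d(x: Tensor, w: Parameter, b: Parameter,
           stride: int = 1, pad: int = 1) -> Tensor:
    """2-D convolution; w is (Cout, Cin, kh, kw), b is (Cout,)."""
    cout, cin, kh, kw = w.shape
    cols, oh, ow = _im2col(x.data, kh, kw, stride, pad)
    wmat = w.data.reshape(cout, -1)
    out = cols @ wmat.T + b.data
    N = x.data.shape[0]
    out = out.reshape(N, oh, ow, cout).transpose(0, 3, 1, 2)

    def backward(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(-1, cout)
        _accum(w, (gmat.T @ cols).reshape(w.shape))
        _accum(b, gmat.sum(axis=0))
        gcols = gmat @ wmat
        _accum(x, _col2im(gcols, x.data.shape, kh, kw, stride, pad))

    return Tensor(out, (x, w, b), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = x.data * mask

    def backward(g):
        _accum(x, g * mask)

    return Tensor(out, (x,), backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    out = a.data + b.data

    def backward(g):
        _accum(a, g)
        _accum(b, g)

    return Tensor(out, (a, b), backward)


def upsample_nearest(x: Tensor, factor: int) -> Tensor:
    out = x.data.repeat(factor, axis=2).repeat(factor, axis=3)

    def backward(g):
        N, C, H, W = x.data.shape
        gr = g.reshape(N, C, H, factor, W, factor).sum(axis=(3, 5))
        _accum(x, gr)

    return Tensor(out, (x,), backward)


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    """Mean of squared differences over every element."""
    t = np.asarray(target, dtype=np.float32)
    diff = pred.data - t
    out = np.float32(np.mean(diff ** 2))

    def backward(g):
        _accum(pred, g * 2.0 * diff / diff.size)

    return Tensor(out, (pred,), backward)


class Module:
    """Base class: parameter registry plus train/eval mode."""

    def __init__(self):
        self._params: dict[str, Parameter] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._children: dict[str, "Module"] = {}
        self.training = True

    def register(self, name: str, p: Parameter) -> Parameter:
        self._params[name] = p
        return p

    def add_child(self, name: str, m: "Module") -> "Module":
        self._children[name] = m
        return m

    def parameters(self, prefix: str = "") -> dict[str, Parameter]:
        out = {prefix + k: v for k, v in self._params.items()}
        for name, child in self._children.items():
            out.update(child.parameters(f"{prefix}{name}."))
        return out

    def buffers(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {prefix + k: v for k, v in self._buffers.items()}
        for name, child in self._children.items():
            out.update(child.buffers(f"{prefix}{name}."))
        return out

    def set_training(self, mode: bool) -> None:
        self.training = mode
        for child in self._children.values():
            child.set_training(mode)


class Conv2d(Module):
    """Convolution layer with He-normal initialization."""

    def __init__(self, cin, cout, k, stride=1, rng: np.random.Generator = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / (cin * k * k))
        self.w = self.register("w", Parameter(
            rng.normal(0.0, std, (cout, cin, k, k))))
        self.b = self.register("b", Parameter(np.zeros(cout)))
        self.stride = stride
        self.pad = k // 2

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, self.stride, self.pad)


class BatchNorm2d(Module):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, c, momentum=0.1, eps=1e-5):
        super().__init__()
        self.gamma = self.register("gamma", Parameter(np.ones(c)))
        self.beta = self.register("beta", Parameter(np.zeros(c)))
        self._buffers["running_mean"] = np.zeros(c, dtype=np.float32)
        self._buffers["running_var"] = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        g, b = self.gamma, self.beta
        if self.training:
            mean = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            rm, rv = self._buffers["running_mean"], self._buffers["running_var"]
            rm += self.momentum * (mean - rm)
            rv += self.momentum * (var - rv)
        else:
            mean = self._buffers["running_mean"]
            var = self._buffers["running_var"]
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mean[:, None, None]) * inv[:, None, None]
        out = xhat * g.data[:, None, None] + b.data[:, None, None]
        m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
        training = self.training

        def backward(grad):
            _accum(g, (grad * xhat).sum(axis=(0, 2, 3)))
            _accum(b, grad.sum(axis=(0, 2, 3)))
            gi = grad * g.data[:, None, None]
            if training:
                # full batch-norm backward (mean/var depend on x)
                sum_gi = gi.sum(axis=(0, 2, 3))
                sum_gi_xhat = (gi * xhat).sum(axis=(0, 2, 3))
                gx = (gi - sum_gi[:, None, None] / m
                      - xhat * sum_gi_xhat[:, None, None] / m) \
                    * inv[:, None, None]
            else:
                gx = gi * inv[:, None, None]
            _accum(x, gx.astype(np.float32))

        return Tensor(out, (x, g, b), backward)


class Adam:
    """Adam optimizer over a named parameter dict."""

    def __init__(self, params: dict[str, Parameter], lr=1e-3,
                 betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None
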