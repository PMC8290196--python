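"""Small reverse-mode autodiff engine for convolutional segmentation nets.

Implements exactly the operations the root-segmentation architectures
need — stride-1 "same" convolution, stride-2 transposed convolution
(zero-stuffing + convolution), 2x2 average pooling, ELU, batch
normalization, summation/concatenation merges and a softmax
cross-entropy loss — on float32 numpy arrays in NCHW layout, plus an
Adam optimizer with L2 weight decay.

Gradients flow through a tape: every op records a backward closure on
the output tensor; ``backward()`` runs them in reverse topological
order.  Correctness of every op's gradient is pinned by finite
difference checks in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor", "Parameter", "Module", "Conv2d", "ConvTranspose2d",
    "BatchNorm2d", "Adam", "elu", "avg_pool2", "add", "concat",
    "softmax", "softmax_op", "softmax_cross_entropy", "conv2d",
    "zero_upsample2", "add_bias", "batch_norm",
]


class Tensor:
    """Array node on the autodiff tape."""

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self._parents = parents
        self._backward = backward
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


# ---------------------------------------------------------------- ops

def _tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def conv2d(x: Tensor, w: Tensor, pad: int) -> Tensor:
    """Stride-1 2D convolution (cross-correlation), NCHW x (O,C,k,k)."""
    k = w.data.shape[2]
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # N,C,Ho,Wo,k,k
    n, c, ho, wo = win.shape[:4]
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)
                                ).reshape(n * ho * wo, c * k * k)
    o = w.data.shape[0]
    y = cols @ w.data.reshape(o, -1).T
    out = Tensor(y.reshape(n, ho, wo, o).transpose(0, 3, 1, 2), (x, w))

    def bwd(gy):
        gmat = gy.transpose(0, 2, 3, 1).reshape(n * ho * wo, o)
        if w.requires_grad:
            w._accumulate((gmat.T @ cols).reshape(w.data.shape))
        if x.requires_grad:
            # full correlation of gy with channel-transposed, flipped kernel
            wf = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
            gp = np.pad(gy, ((0, 0), (0, 0), (k - 1 - pad, k - 1 - pad),
                             (k - 1 - pad, k - 1 - pad)))
            gwin = sliding_window_view(gp, (k, k), axis=(2, 3))
            gn, go, gh, gw_ = gwin.shape[:4]
            gcols = np.ascontiguousarray(
                gwin.transpose(0, 2, 3, 1, 4, 5)).reshape(
                    gn * gh * gw_, go * k * k)
            gx = gcols @ wf.reshape(c, -1).T
            x._accumulate(gx.reshape(gn, gh, gw_, c).transpose(0, 3, 1, 2))

    out._backward = bwd
    return out


def add_bias(x: Tensor, b: Tensor) -> Tensor:
    out = Tensor(x.data + b.data[None, :, None, None], (x, b))

    def bwd(gy):
        if x.requires_grad:
            x._accumulate(gy)
        if b.requires_grad:
            b._accumulate(gy.sum(axis=(0, 2, 3)))

    out._backward = bwd
    return out


def zero_upsample2(x: Tensor) -> Tensor:
    """Insert zeros between samples: (N,C,H,W) -> (N,C,2H,2W)."""
    n, c, h, w = x.data.shape
    y = np.zeros((n, c, 2 * h, 2 * w), dtype=np.float32)
    y[:, :, ::2, ::2] = x.data
    out = Tensor(y, (x,))

    def bwd(gy):
        if x.requires_grad:
            x._accumulate(gy[:, :, ::2, ::2])

    out._backward = bwd
    return out


def avg_pool2(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError("avg_pool2 requires even spatial dimensions")
    y = x.data.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))
    out = Tensor(y, (x,))

    def bwd(gy):
        if x.requires_grad:
            g = np.repeat(np.repeat(gy, 2, axis=2), 2, axis=3) * 0.25
            x._accumulate(g)

    out._backward = bwd
    return out


def elu(x: Tensor, alpha: float = 1.0) -> Tensor:
    pos = x.data > 0
    y = x.data.copy()
    y[~pos] = alpha * np.expm1(y[~pos])
    out = Tensor(y, (x,))

    def bwd(gy):
        if x.requires_grad:
            x._accumulate(gy * np.where(pos, 1.0, y + alpha))

    out._backward = bwd
    return out


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, (a, b))

    def bwd(gy):
        if a.requires_grad:
            a._accumulate(gy)
        if b.requires_grad:
            b._accumulate(gy)

    out._backward = bwd
    return out


def concat(tensors, axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]

    def bwd(gy):
        pieces = np.split(gy, np.cumsum(sizes)[:-1], axis=axis)
        for t, g in zip(tensors, pieces):
            if t.requires_grad:
                t._accumulate(g)

    out._backward = bwd
    return out


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               running: dict, training: bool,
               momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running["mean"] = (1 - momentum) * running["mean"] + momentum * mu
        running["var"] = (1 - momentum) * running["var"] + momentum * var
    else:
        mu, var = running["mean"], running["var"]
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) * inv_std[None, :, None, None]
    y = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
    out = Tensor(y, (x, gamma, beta))

    def bwd(gy):
        if gamma.requires_grad:
            gamma._accumulate((gy * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accumulate(gy.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gs = gamma.data[None, :, None, None] * inv_std[None, :, None, None]
            if training:
                m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
                mean_gy = gy.mean(axis=(0, 2, 3), keepdims=True)
                mean_gyx = (gy * xhat).mean(axis=(0, 2, 3), keepdims=True)
                x._accumulate(gs * (gy - mean_gy - xhat * mean_gyx))
            else:
                x._accumulate(gs * gy)

    out._backward = bwd
    return out


def softmax_op(x: Tensor, axis: int = 1) -> Tensor:
    """Differentiable softmax along ``axis``."""
    y = softmax(x.data, axis=axis)
    out = Tensor(y, (x,))

    def bwd(gy):
        if x.requires_grad:
            x._accumulate(y * (gy - (gy * y).sum(axis=axis, keepdims=True)))

    out._backward = bwd
    return out


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: Tensor, target: np.ndarray) -> Tensor:
    """Mean pixelwise cross-entropy; ``target`` is a binary {0,1} mask
    over the root class (channel 1 of the 2-channel logits)."""
    p = softmax(logits.data, axis=1)
    t = np.stack([1.0 - target, target], axis=1).astype(np.float32)
    eps = 1e-12
    loss = -(t * np.log(p + eps)).sum(axis=1).mean()
    out = Tensor(np.float32(loss), (logits,))
    npix = target.size

    def bwd(gy):
        if logits.requires_grad:
            logits._accumulate(gy * (p - t) / npix)

    out._backward = bwd
    return out


# ------------------------------------------------------------ modules

class Module:
    """Base class: parameter collection and train/eval mode."""

    def __init__(self):
        self.training = False

    def modules(self):
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Module):
                out.append(v)
                out.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.append(item)
                        out.extend(item.modules())
        return out

    def named_parameters(self):
        out = []
        for name, v in self.__dict__.items():
            if isinstance(v, Parameter):
                out.append((name, v))
            elif isinstance(v, Module):
                out.extend((f"{name}.{n}", p) for n, p in v.named_parameters())
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.extend((f"{name}.{i}.{n}", p)
                                   for n, p in item.named_parameters())
        return out

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def train(self, mode: bool = True):
        self.training = mode
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- checkpointing (plain .npz) --
    def state_dict(self):
        state = {n: p.data for n, p in self.named_parameters()}
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                state[f"__bn{i}.mean"] = m.running["mean"]
                state[f"__bn{i}.var"] = m.running["var"]
        return state

    def load_state_dict(self, state):
        for n, p in self.named_parameters():
            p.data = np.asarray(state[n], dtype=np.float32)
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                m.running["mean"] = np.asarray(state[f"__bn{i}.mean"],
                                               dtype=np.float32)
                m.running["var"] = np.asarray(state[f"__bn{i}.var"],
                                              dtype=np.float32)

    def save(self, path):
        np.savez(path, **self.state_dict())

    def load(self, path):
        with np.load(path) as f:
            self.load_state_dict(dict(f.items()))


def _he_init(rng, shape, fan_in):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)
            ).astype(np.float32)


class Conv2d(Module):
    """3x3/1x1 stride-1 same convolution; bias optional (the
    segmentation nets use bias-free convs followed by batch norm)."""

    def __init__(self, cin, cout, k=3, bias=True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.k, self.pad = k, k // 2
        self.weight = Parameter(_he_init(rng, (cout, cin, k, k),
                                         cin * k * k))
        self.bias = Parameter(np.zeros(cout, dtype=np.float32)) if bias else None

    def __call__(self, x):
        y = conv2d(_tensor(x), self.weight, self.pad)
        if self.bias is not None:
            y = add_bias(y, self.bias)
        return y


class ConvTranspose2d(Module):
    """Stride-2 transposed convolution (x2 upsampling), kernel 3,
    implemented as zero-stuffing followed by a same convolution."""

    def __init__(self, cin, cout, k=3, bias=True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.k = k
        self.weight = Parameter(_he_init(rng, (cout, cin, k, k),
                                         cin * k * k / 4))
        self.bias = Parameter(np.zeros(cout, dtype=np.float32)) if bias else None

    def __call__(self, x):
        y = conv2d(zero_upsample2(_tensor(x)), self.weight, self.k // 2)
        if self.bias is not None:
            y = add_bias(y, self.bias)
        return y


class BatchNorm2d(Module):
    def __init__(self, c, momentum=0.1, eps=1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(c, dtype=np.float32))
        self.beta = Parameter(np.zeros(c, dtype=np.float32))
        self.running = {"mean": np.zeros(c, dtype=np.float32),
                        "var": np.ones(c, dtype=np.float32)}
        self.momentum, self.eps = momentum, eps

    def __call__(self, x):
        return batch_norm(_tensor(x), self.gamma, self.beta, self.running,
                          self.training, self.momentum, self.eps)


class Adam:
    """Adam with decoupled L2 weight decay added to the raw gradient."""

    def __init__(self, params, lr=1e-4, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.0):
        self.params = list(params)
        self.lr, self.b1, self.b2 = lr, betas[0], betas[1]
        self.eps, self.wd = eps, weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad + self.wd * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
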