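"""Reverse-mode automatic differentiation over numpy arrays, plus the
neural-network layers and the Adam optimizer used by the CATM model.

The engine is deliberately small: a :class:`Tensor` wraps an ndarray and
records a backward closure per operation; :func:`Tensor.backward` runs the
tape in reverse topological order.  Convolutions are same-padding/stride-1
(all the model needs, since every block preserves the 8 x 9 electrode
grid) and are evaluated with stride-trick window views and einsum.
Everything is float64 and fully deterministic given the numpy Generators
passed in; there is no hidden global state.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "softmax_cross_entropy",
    "Module",
    "Linear",
    "Conv2d",
    "BatchNorm2d",
    "MaxPool2dSame",
    "Dropout",
    "BiLSTM",
    "Adam",
]


#: Engine dtype.  float32 keeps training fast; switch to float64 (e.g. in
#: numerical gradient checks) with :func:`set_default_dtype`.
DEFAULT_DTYPE = np.float32


def set_default_dtype(dtype) -> None:
    global DEFAULT_DTYPE
    DEFAULT_DTYPE = np.dtype(dtype).type


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=DEFAULT_DTYPE)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._backward = None
        self._prev = _prev

    @property
    def shape(self):
        return self.data.shape

    # -- graph mechanics ---------------------------------------------------

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: tapes can be deep (LSTM over time)
            node, expanded = stack.pop()
            if expanded:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        for node in order:
            node.grad = np.zeros_like(node.data) if node.requires_grad else None
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.requires_grad:
                node._backward()

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def _bw():
            if self.requires_grad:
                self.grad += _unbroadcast(out.grad, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(out.grad, other.data.shape)

        out._backward = _bw
        return out

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def _bw():
            if self.requires_grad:
                self.grad += _unbroadcast(out.grad * other.data, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(out.grad * self.data, other.data.shape)

        out._backward = _bw
        return out

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._lift(other))

    __radd__ = __add__
    __rmul__ = __mul__

    def pow(self, exponent: float) -> "Tensor":
        out = Tensor(self.data**exponent, _prev=(self,))

        def _bw():
            if self.requires_grad:
                self.grad += out.grad * exponent * self.data ** (exponent - 1.0)

        out._backward = _bw
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def _bw():
            if self.requires_grad:
                self.grad += out.grad @ other.data.T
            if other.requires_grad:
                other.grad += self.data.T @ out.grad

        out._backward = _bw
        return out

    # -- nonlinearities ----------------------------------------------------

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), _prev=(self,))

        def _bw():
            if self.requires_grad:
                self.grad += out.grad * (self.data > 0.0)

        out._backward = _bw
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60.0, 60.0)))
        out = Tensor(s, _prev=(self,))

        def _bw():
            if self.requires_grad:
                self.grad += out.grad * s * (1.0 - s)

        out._backward = _bw
        return out

    def tanh(self) -> "Tensor":
        t = np.tanh(self.data)
        out = Tensor(t, _prev=(self,))

        def _bw():
            if self.requires_grad:
                self.grad += out.grad * (1.0 - t * t)

        out._backward = _bw
        return out

    # -- shape / reductions ------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), _prev=(self,))

        def _bw():
            if self.requires_grad:
                self.grad += out.grad.reshape(self.data.shape)

        out._backward = _bw
        return out

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx], _prev=(self,))

        def _bw():
            if self.requires_grad:
                np.add.at(self.grad, idx, out.grad)

        out._backward = _bw
        return out

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def _bw():
            if self.requires_grad:
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self.grad += np.broadcast_to(g, self.data.shape)

        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False) -> "Tensor":
        data = self.data.max(axis=axis, keepdims=True)
        mask = self.data == data  # ties share gradient equally
        mask = mask / mask.sum(axis=axis, keepdims=True)
        out_data = data if keepdims else np.squeeze(data, axis=axis)
        out = Tensor(out_data, _prev=(self,))

        def _bw():
            if self.requires_grad:
                g = out.grad if keepdims else np.expand_dims(out.grad, axis)
                self.grad += g * mask

        out._backward = _bw
        return out


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _bw():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * out.grad.ndim
                idx[axis] = slice(lo, hi)
                t.grad += out.grad[tuple(idx)]

    out._backward = _bw
    return out


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of (B, K) logits against integer labels."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    b = logits.data.shape[0]
    nll = -np.log(p[np.arange(b), labels] + 1e-300).mean()
    out = Tensor(nll, _prev=(logits,))

    def _bw():
        if logits.requires_grad:
            g = p.copy()
            g[np.arange(b), labels] -= 1.0
            logits.grad += out.grad * g / b

    out._backward = _bw
    return out


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


class Module:
    """Minimal layer container: parameter discovery by attribute scan."""

    training: bool = True

    def parameters(self) -> list[Tensor]:
        params, seen = [], set()
        for m in self.modules():
            for v in vars(m).values():
                if isinstance(v, Tensor) and v.requires_grad and id(v) not in seen:
                    seen.add(id(v))
                    params.append(v)
        return params

    def modules(self) -> list["Module"]:
        found = [self]
        for v in vars(self).values():
            items = v if isinstance(v, (list, tuple)) else [v]
            for item in items:
                if isinstance(item, Module):
                    found.extend(item.modules())
        return found

    def train(self, flag: bool = True) -> "Module":
        for m in self.modules():
            m.training = flag
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def n_params(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, bias: bool = True):
        bound = 1.0 / np.sqrt(n_in)
        self.weight = Tensor(rng.uniform(-bound, bound, (n_in, n_out)), requires_grad=True)
        self.bias = Tensor(rng.uniform(-bound, bound, n_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x.matmul(self.weight)
        return out + self.bias if self.bias is not None else out


def _window_view(xpad: np.ndarray, k: int) -> np.ndarray:
    """(B, C, H + k - 1, W + k - 1) -> (B, C, H, W, k, k) stride view."""
    return np.lib.stride_tricks.sliding_window_view(xpad, (k, k), axis=(2, 3))


class Conv2d(Module):
    """Same-padding, stride-1 2D convolution (cross-correlation)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd for same padding")
        self.kernel = kernel
        self.pad = kernel // 2
        bound = 1.0 / np.sqrt(c_in * kernel * kernel)
        self.weight = Tensor(rng.uniform(-bound, bound, (c_out, c_in, kernel, kernel)), requires_grad=True)
        self.bias = Tensor(rng.uniform(-bound, bound, c_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        w, b, k, p = self.weight, self.bias, self.kernel, self.pad
        bs, c, h, wd = x.data.shape
        o = w.data.shape[0]
        if k == 1:
            # pointwise: a single matmul over flattened pixels
            xm = x.data.transpose(0, 2, 3, 1).reshape(-1, c)
            wm = w.data.reshape(o, c).T
            out_data = (xm @ wm + b.data).reshape(bs, h, wd, o).transpose(0, 3, 1, 2)
            out = Tensor(out_data, _prev=(x, w, b))

            def _bw():
                g = out.grad.transpose(0, 2, 3, 1).reshape(-1, o)
                if b.requires_grad:
                    b.grad += g.sum(axis=0)
                if w.requires_grad:
                    w.grad += (xm.T @ g).T.reshape(o, c, 1, 1)
                if x.requires_grad:
                    x.grad += (g @ wm.T).reshape(bs, h, wd, c).transpose(0, 3, 1, 2)

            out._backward = _bw
            return out
        # k > 1: im2col + BLAS matmul
        xpad = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)))
        cols = _window_view(xpad, k)  # (B, C, H, W, k, k) view
        colm = np.ascontiguousarray(cols.transpose(0, 2, 3, 1, 4, 5)).reshape(bs * h * wd, c * k * k)
        wm = w.data.reshape(o, -1).T  # (C*k*k, O)
        out_data = (colm @ wm + b.data).reshape(bs, h, wd, o).transpose(0, 3, 1, 2)
        out = Tensor(out_data, _prev=(x, w, b))

        def _bw():
            g = out.grad.transpose(0, 2, 3, 1).reshape(-1, o)
            if b.requires_grad:
                b.grad += g.sum(axis=0)
            if w.requires_grad:
                w.grad += (colm.T @ g).T.reshape(w.data.shape)
            if x.requires_grad:
                gcols = (g @ wm.T).reshape(bs, h, wd, c, k, k)
                gpad = np.zeros_like(xpad)
                for u in range(k):
                    for v in range(k):
                        gpad[:, :, u : u + h, v : v + wd] += gcols[:, :, :, :, u, v].transpose(0, 3, 1, 2)
                x.grad += gpad[:, :, p : p + h, p : p + wd]

        out._backward = _bw
        return out


class MaxPool2dSame(Module):
    """k x k max pooling, stride 1, same padding (grid size preserved)."""

    def __init__(self, kernel: int = 3):
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd for same padding")
        self.kernel = kernel

    def __call__(self, x: Tensor) -> Tensor:
        k, p = self.kernel, self.kernel // 2
        b_, c_, h_, w_ = x.data.shape
        xpad = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
        out_data = np.full((b_, c_, h_, w_), -np.inf, dtype=x.data.dtype)
        for u in range(k):
            for v in range(k):
                np.maximum(out_data, xpad[:, :, u : u + h_, v : v + w_], out=out_data)
        out = Tensor(out_data, _prev=(x,))

        def _bw():
            if not x.requires_grad:
                return
            gpad = np.zeros_like(xpad)
            claimed = np.zeros((b_, c_, h_, w_), dtype=bool)
            for u in range(k):
                for v in range(k):
                    sl = xpad[:, :, u : u + h_, v : v + w_]
                    hit = (sl == out_data) & ~claimed  # first match wins on ties
                    claimed |= hit
                    gpad[:, :, u : u + h_, v : v + w_] += np.where(hit, out.grad, 0.0)
            x.grad += gpad[:, :, p : p + h_, p : p + w_]

        out._backward = _bw
        return out


class BatchNorm2d(Module):
    """Batch statistics while training, running averages at evaluation."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.weight = Tensor(np.ones(channels), requires_grad=True)
        self.bias = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=DEFAULT_DTYPE)
        self.running_var = np.ones(channels, dtype=DEFAULT_DTYPE)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        w, b = self.weight, self.bias
        shape = (1, -1, 1, 1)
        axes = (0, 2, 3)
        if self.training:
            mu = x.data.mean(axis=axes, keepdims=True)
            var = x.data.var(axis=axes, keepdims=True)
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            self.running_mean += self.momentum * (mu.ravel() - self.running_mean)
            self.running_var += self.momentum * (var.ravel() * (n / max(n - 1, 1)) - self.running_var)
        else:
            mu = self.running_mean.reshape(shape)
            var = self.running_var.reshape(shape)
        inv_sd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu) * inv_sd
        out = Tensor(xhat * w.data.reshape(shape) + b.data.reshape(shape), _prev=(x, w, b))
        use_batch_stats = self.training

        def _bw():
            g = out.grad
            if b.requires_grad:
                b.grad += g.sum(axis=axes)
            if w.requires_grad:
                w.grad += (g * xhat).sum(axis=axes)
            if x.requires_grad:
                gx = g * w.data.reshape(shape)
                if use_batch_stats:
                    x.grad += inv_sd * (
                        gx
                        - gx.mean(axis=axes, keepdims=True)
                        - xhat * (gx * xhat).mean(axis=axes, keepdims=True)
                    )
                else:
                    x.grad += gx * inv_sd

        out._backward = _bw
        return out


class Dropout(Module):
    def __init__(self, p: float = 0.5):
        self.p = p
        self.rng: np.random.Generator | None = None  # set by the trainer

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0.0:
            return x
        rng = self.rng if self.rng is not None else np.random.default_rng(0)
        mask = (rng.random(x.data.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class _LSTMDirection(Module):
    """One direction of the Bi-LSTM: input, forget, cell and output gates
    with both input-to-hidden and hidden-to-hidden biases."""

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        self.hidden = hidden
        bound = 1.0 / np.sqrt(hidden)
        u = lambda *s: Tensor(rng.uniform(-bound, bound, s), requires_grad=True)
        self.w_ih = u(n_in, 4 * hidden)
        self.w_hh = u(hidden, 4 * hidden)
        self.b_ih = u(4 * hidden)
        self.b_hh = u(4 * hidden)

    def __call__(self, xs: list[Tensor]) -> Tensor:
        """``xs`` is a time-ordered list of (B, n_in); returns final h."""
        bsz = xs[0].data.shape[0]
        h = Tensor(np.zeros((bsz, self.hidden)))
        c = Tensor(np.zeros((bsz, self.hidden)))
        hd = self.hidden
        for x in xs:
            z = x.matmul(self.w_ih) + h.matmul(self.w_hh) + self.b_ih + self.b_hh
            i = z[:, 0 * hd : 1 * hd].sigmoid()
            f = z[:, 1 * hd : 2 * hd].sigmoid()
            g = z[:, 2 * hd : 3 * hd].tanh()
            o = z[:, 3 * hd : 4 * hd].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
        return h


class BiLSTM(Module):
    """Forward and backward recurrences; final hidden states concatenated."""

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        self.fwd = _LSTMDirection(n_in, hidden, rng)
        self.bwd = _LSTMDirection(n_in, hidden, rng)

    def __call__(self, xs: list[Tensor]) -> Tensor:
        if not xs:
            raise ValueError("empty sequence")
        return concat([self.fwd(xs), self.bwd(xs[::-1])], axis=1)


class Adam:
    """Adam with decoupled-from-nothing classic L2 via the loss (the
    trainer adds the penalty to the loss; this class is plain Adam)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if g is None:
                continue
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
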