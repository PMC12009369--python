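"""Minimal reverse-mode automatic differentiation and neural-net layers.

Everything is float64 numpy and fully deterministic given a seed: gradients
come from a tape built during the forward pass, parameters are updated with
Adam, and there is no threading or atomics anywhere — two runs with the same
seed produce bit-identical weights.

Only the ops the ODE-RNN and its recurrent baselines need are implemented:
elementwise arithmetic, matmul, tanh/sigmoid, concatenation and a fused
softmax cross-entropy.
"""

from __future__ import annotations

import math

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "_parents", "_backward")

    # make `ndarray <op> Tensor` dispatch to the reflected Tensor op
    __array_ufunc__ = None
    __array_priority__ = 1000

    def __init__(self, data, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # -- arithmetic (constants stay raw ndarrays: no graph node) ----------

    def __add__(self, other):
        o_data, parents = _split(self, other)

        def bwd(g, a=self, b=other):
            _accum(a, _unbroadcast(g, a.data.shape))
            if isinstance(b, Tensor):
                _accum(b, _unbroadcast(g, b.data.shape))

        return Tensor(self.data + o_data, parents, bwd)

    __radd__ = __add__

    def __sub__(self, other):
        o_data, parents = _split(self, other)

        def bwd(g, a=self, b=other):
            _accum(a, _unbroadcast(g, a.data.shape))
            if isinstance(b, Tensor):
                _accum(b, _unbroadcast(-g, b.data.shape))

        return Tensor(self.data - o_data, parents, bwd)

    def __rsub__(self, other):  # constant - tensor
        def bwd(g, a=self):
            _accum(a, _unbroadcast(-g, a.data.shape))

        return Tensor(np.asarray(other, dtype=np.float64) - self.data, (self,), bwd)

    def __mul__(self, other):
        o_data, parents = _split(self, other)

        def bwd(g, a=self, b=other, bd=o_data):
            _accum(a, _unbroadcast(g * bd, a.data.shape))
            if isinstance(b, Tensor):
                _accum(b, _unbroadcast(g * a.data, b.data.shape))

        return Tensor(self.data * o_data, parents, bwd)

    __rmul__ = __mul__

    def __neg__(self):
        def bwd(g, a=self):
            _accum(a, -g)

        return Tensor(-self.data, (self,), bwd)

    def matmul(self, other: "Tensor") -> "Tensor":
        def bwd(g, a=self, b=other):
            _accum(a, g @ b.data.T)
            _accum(b, a.data.T @ g)

        return Tensor(self.data @ other.data, (self, other), bwd)

    __matmul__ = matmul

    # -- nonlinearities ---------------------------------------------------

    def tanh(self) -> "Tensor":
        out = np.tanh(self.data)

        def bwd(g, a=self, o=out):
            _accum(a, g * (1.0 - o * o))

        return Tensor(out, (self,), bwd)

    def sigmoid(self) -> "Tensor":
        x = self.data
        out = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                       np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))

        def bwd(g, a=self, o=out):
            _accum(a, g * o * (1.0 - o))

        return Tensor(out, (self,), bwd)

    def sum(self) -> "Tensor":
        def bwd(g, a=self):
            _accum(a, np.broadcast_to(g, a.data.shape).copy())

        return Tensor(self.data.sum(), (self,), bwd)

    # -- backward driver --------------------------------------------------

    def backward(self) -> None:
        """Backpropagate from this (scalar) node through the tape."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def _split(a: Tensor, b):
    if isinstance(b, Tensor):
        return b.data, (a, b)
    return np.asarray(b, dtype=np.float64), (a,)


def _accum(t: Tensor, g: np.ndarray) -> None:
    if t.grad is None:
        t.grad = np.array(g, dtype=np.float64)
    else:
        t.grad = t.grad + g


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bwd(g, ts=tensors, offs=offsets, ax=axis):
        for t, lo, hi in zip(ts, offs[:-1], offs[1:]):
            sl = [slice(None)] * g.ndim
            sl[ax] = slice(lo, hi)
            _accum(t, g[tuple(sl)])

    return Tensor(np.concatenate(datas, axis=axis), tuple(tensors), bwd)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray,
                          sample_weight: np.ndarray | None = None) -> tuple[Tensor, np.ndarray]:
    """Mean cross-entropy of softmax(logits) against integer labels.

    Returns (scalar loss node, softmax probabilities as a plain array).
    """
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = len(labels)
    w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, dtype=float)
    w_norm = w / w.sum()
    nll = -np.log(np.clip(probs[np.arange(n), labels], 1e-300, None))
    loss_val = float((w_norm * nll).sum())

    def bwd(g, a=logits, p=probs, y=labels, wn=w_norm):
        grad = p.copy()
        grad[np.arange(len(y)), y] -= 1.0
        _accum(a, g * grad * wn[:, None])

    return Tensor(loss_val, (logits,), bwd), probs


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# Layers


def glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    lim = math.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-lim, lim, size=(n_in, n_out))


class Module:
    """Base class exposing a flat, ordered parameter list."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor):
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for v in value:
                    if isinstance(v, Tensor):
                        params.append(v)
                    elif isinstance(v, Module):
                        params.extend(v.parameters())
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def get_weights(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(weights):
            raise ValueError("weight list length mismatch")
        for p, w in zip(params, weights):
            if p.data.shape != w.shape:
                raise ValueError("weight shape mismatch")
            p.data = np.asarray(w, dtype=np.float64)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = Tensor(glorot(rng, n_in, n_out))
        self.b = Tensor(np.zeros((1, n_out)))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class MLP(Module):
    """Tanh multilayer perceptron with a linear output layer.

    Tanh keeps the learned vector field smooth, which matters for the
    high-order accuracy of the RK4 solver on the hidden-state ODE.
    """

    def __init__(self, n_in: int, hidden: list[int], n_out: int,
                 rng: np.random.Generator, final_scale: float = 1.0):
        dims = [n_in] + list(hidden) + [n_out]
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        if final_scale != 1.0:
            self.layers[-1].W.data *= final_scale

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers[:-1]:
            x = layer(x).tanh()
        return self.layers[-1](x)


class GRUCell(Module):
    """Standard GRU: h' = z*h + (1-z)*c with reset/update gates."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.Wr = Tensor(glorot(rng, n_in, n_hidden))
        self.Ur = Tensor(glorot(rng, n_hidden, n_hidden))
        self.br = Tensor(np.zeros((1, n_hidden)))
        self.Wz = Tensor(glorot(rng, n_in, n_hidden))
        self.Uz = Tensor(glorot(rng, n_hidden, n_hidden))
        self.bz = Tensor(np.zeros((1, n_hidden)))
        self.Wc = Tensor(glorot(rng, n_in, n_hidden))
        self.Uc = Tensor(glorot(rng, n_hidden, n_hidden))
        self.bc = Tensor(np.zeros((1, n_hidden)))

    def __call__(self, u: Tensor, h: Tensor) -> Tensor:
        r = (u @ self.Wr + h @ self.Ur + self.br).sigmoid()
        z = (u @ self.Wz + h @ self.Uz + self.bz).sigmoid()
        c = (u @ self.Wc + (r * h) @ self.Uc + self.bc).tanh()
        return z * h + (1.0 - z) * c


class LSTMCell(Module):
    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.Wi = Tensor(glorot(rng, n_in + n_hidden, n_hidden))
        self.bi = Tensor(np.zeros((1, n_hidden)))
        self.Wf = Tensor(glorot(rng, n_in + n_hidden, n_hidden))
        self.bf = Tensor(np.ones((1, n_hidden)))  # forget-gate bias 1
        self.Wo = Tensor(glorot(rng, n_in + n_hidden, n_hidden))
        self.bo = Tensor(np.zeros((1, n_hidden)))
        self.Wg = Tensor(glorot(rng, n_in + n_hidden, n_hidden))
        self.bg = Tensor(np.zeros((1, n_hidden)))

    def __call__(self, u: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        uh = concat([u, h], axis=1)
        i = (uh @ self.Wi + self.bi).sigmoid()
        f = (uh @ self.Wf + self.bf).sigmoid()
        o = (uh @ self.Wo + self.bo).sigmoid()
        g = (uh @ self.Wg + self.bg).tanh()
        c_new = f * c + i * g
        return o * c_new.tanh(), c_new


class RNNCell(Module):
    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.W = Tensor(glorot(rng, n_in, n_hidden))
        self.U = Tensor(glorot(rng, n_hidden, n_hidden))
        self.b = Tensor(np.zeros((1, n_hidden)))

    def __call__(self, u: Tensor, h: Tensor) -> Tensor:
        return (u @ self.W + h @ self.U + self.b).tanh()


class Adam:
    """Adam with bias correction; state kept per parameter index."""

    def __init__(self, params: list[Tensor], lr: float = 3e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self, clip_norm: float | None = 5.0) -> None:
        self.t += 1
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data)
                 for p in self.params]
        if clip_norm is not None:
            total = math.sqrt(sum(float((g * g).sum()) for g in grads))
            if total > clip_norm:
                scale = clip_norm / total
                grads = [g * scale for g in grads]
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for i, (p, g) in enumerate(zip(self.params, grads)):
            self.m[i] = self.beta1 * self.m[i] + (1.0 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1.0 - self.beta2) * g * g
            m_hat = self.m[i] / b1t
            v_hat = self.v[i] / b2t
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
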