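"""A small reverse-mode automatic-differentiation engine over numpy arrays.

This is the numerical substrate for :mod:`thermodesign.mpnn_core`: dense
tensors, a handful of differentiable operations (broadcast arithmetic,
matmul, gather, concat, reductions, relu/exp/log), and an Adam optimizer.
Gradients flow through a dynamically recorded tape; ``Tensor.backward()``
topologically sorts the tape and accumulates ``grad`` on every tensor with
``requires_grad``. Shapes follow numpy broadcasting; the backward pass
un-broadcasts gradients by summing over broadcast axes.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (the inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph ------------------------------------------------------------

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- arithmetic -------------------------------------------------------

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def backward(grad):
            if self.requires_grad:
                self._accumulate(_unbroadcast(grad, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(grad, other.shape))
        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))

        def backward(grad):
            if self.requires_grad:
                self._accumulate(-grad)
        out._backward = backward
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def backward(grad):
            if self.requires_grad:
                self._accumulate(_unbroadcast(grad * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(grad * self.data, other.shape))
        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other ** -1.0

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, parents=(self,))

        def backward(grad):
            if self.requires_grad:
                self._accumulate(grad * exponent * self.data ** (exponent - 1.0))
        out._backward = backward
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def backward(grad):
            if self.requires_grad:
                g = grad @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                g = np.swapaxes(self.data, -1, -2) @ grad
                other._accumulate(_unbroadcast(g, other.shape))
        out._backward = backward
        return out

    # -- shape ops --------------------------------------------------------

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))

        def backward(grad):
            if self.requires_grad:
                self._accumulate(grad.reshape(self.shape))
        out._backward = backward
        return out

    def take(self, indices) -> "Tensor":
        """Gather rows along axis 0: ``out = x[indices]`` for an integer
        index array of any shape."""
        indices = np.asarray(indices)
        out = Tensor(self.data[indices], parents=(self,))

        def backward(grad):
            if self.requires_grad:
                acc = np.zeros_like(self.data)
                np.add.at(acc, indices.reshape(-1),
                          grad.reshape(-1, *self.shape[1:]))
                self._accumulate(acc)
        out._backward = backward
        return out

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def backward(grad):
            if self.requires_grad:
                g = grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.shape).copy())
        out._backward = backward
        return out

    def mean(self, axis=None, keepdims=False):
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    # -- nonlinearities ---------------------------------------------------

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))

        def backward(grad):
            if self.requires_grad:
                self._accumulate(grad * (self.data > 0.0))
        out._backward = backward
        return out

    def exp(self):
        out = Tensor(np.exp(self.data), parents=(self,))

        def backward(grad):
            if self.requires_grad:
                self._accumulate(grad * out.data)
        out._backward = backward
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))

        def backward(grad):
            if self.requires_grad:
                self._accumulate(grad / self.data)
        out._backward = backward
        return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(grad):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                index = [slice(None)] * grad.ndim
                index[axis] = slice(lo, hi)
                t._accumulate(grad[tuple(index)])
    out._backward = backward
    return out


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(x.data.max(axis=axis, keepdims=True))  # detached, grad-safe
    s = x - shift
    return s - s.exp().sum(axis=axis, keepdims=True).log()


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    return centered * (var + eps) ** -0.5 * gain + bias


def dropout(x: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; identity when rate == 0."""
    if rate <= 0.0:
        return x
    mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * Tensor(mask)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Linear:
    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int):
        self.weight = Parameter(glorot(rng, n_in, n_out))
        self.bias = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]


class LayerNorm:
    def __init__(self, dim: int):
        self.gain = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gain, self.bias)

    def parameters(self) -> list[Parameter]:
        return [self.gain, self.bias]


class MLP:
    """Position-wise multilayer perceptron with ReLU between layers."""

    def __init__(self, rng: np.random.Generator, dims: list[int]):
        self.layers = [Linear(rng, a, b) for a, b in zip(dims[:-1], dims[1:])]

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.relu()
        return x

    def parameters(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.parameters()]


class Adam:
    """Adam with an optional inverse-square-root warmup schedule (the
    transformer-style preset used by the reference training loop)."""

    def __init__(self, parameters: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.98), eps: float = 1e-9,
                 schedule: str = "constant", warmup: int = 200,
                 model_dim: int = 128, max_grad_norm: float | None = 1.0,
                 total_steps: int | None = None):
        self.parameters = parameters
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.max_grad_norm = max_grad_norm
        self.schedule = schedule
        self.warmup = warmup
        self.model_dim = model_dim
        self.total_steps = total_steps
        self.step_count = 0
        self.m = [np.zeros_like(p.data) for p in parameters]
        self.v = [np.zeros_like(p.data) for p in parameters]

    def _rate(self) -> float:
        if self.schedule == "constant":
            return self.lr
        if self.schedule == "cosine":
            if not self.total_steps:
                raise ValueError("cosine schedule needs total_steps")
            t = min(self.step_count / self.total_steps, 1.0)
            return self.lr * 0.5 * (1.0 + np.cos(np.pi * t))
        if self.schedule == "reference":
            step = max(self.step_count, 1)
            return (self.model_dim ** -0.5
                    * min(step ** -0.5, step * self.warmup ** -1.5))
        raise ValueError(f"unknown schedule {self.schedule!r}")

    def step(self) -> None:
        if self.max_grad_norm is not None:
            total = np.sqrt(sum(
                float((p.grad ** 2).sum())
                for p in self.parameters if p.grad is not None))
            if total > self.max_grad_norm:
                scale = self.max_grad_norm / total
                for p in self.parameters:
                    if p.grad is not None:
                        p.grad = p.grad * scale
        self.step_count += 1
        rate = self._rate()
        b1, b2 = self.betas
        for i, p in enumerate(self.parameters):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad ** 2
            m_hat = self.m[i] / (1 - b1 ** self.step_count)
            v_hat = self.v[i] / (1 - b2 ** self.step_count)
            p.data -= rate * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.parameters:
            p.grad = None
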