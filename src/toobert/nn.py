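"""Minimal reverse-mode automatic differentiation and neural-network layers.

A purpose-built, NumPy-backed tensor engine sized for the small sequence
models in this package (tens of thousands to a few hundred thousand
parameters).  It provides exactly the primitives the trajectory encoder
needs -- broadcasting arithmetic, batched matmul, fused (log-)softmax,
embedding gather, layer norm, dropout, a GRU -- plus an Adam optimizer.

Gradients are accumulated by topological traversal of the operation graph;
correctness is established by finite-difference checks in the test suite.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "Linear",
    "Embedding",
    "LayerNorm",
    "Dropout",
    "MultiHeadSelfAttention",
    "TransformerEncoderLayer",
    "BiGRU",
    "Adam",
    "sinusoidal_table",
    "concat",
    "stack",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An n-d array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        # list of (parent, fn) where fn maps upstream grad -> grad wrt parent
        self._parents: list[tuple["Tensor", Callable[[np.ndarray], np.ndarray]]] = []

    # -- graph plumbing ------------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents) -> "Tensor":
        out = Tensor(data)
        live = [(p, fn) for p, fn in parents if p.requires_grad]
        if live:
            out.requires_grad = True
            out._parents = live
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        # iterative post-order topological sort
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
            for p, _ in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))

        grads: dict[int, np.ndarray] = {id(self): grad}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and not node._parents:  # leaf
                node.grad = g if node.grad is None else node.grad + g
            for parent, fn in node._parents:
                pg = fn(g)
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg

    # -- arithmetic ----------------------------------------------------
    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._coerce(other)
        return Tensor._make(
            self.data + other.data,
            [
                (self, lambda g: _unbroadcast(g, self.shape)),
                (other, lambda g: _unbroadcast(g, other.shape)),
            ],
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, [(self, lambda g: -g)])

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        return Tensor._make(
            self.data * other.data,
            [
                (self, lambda g: _unbroadcast(g * other.data, self.shape)),
                (other, lambda g: _unbroadcast(g * self.data, other.shape)),
            ],
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        return Tensor._make(
            self.data / other.data,
            [
                (self, lambda g: _unbroadcast(g / other.data, self.shape)),
                (
                    other,
                    lambda g: _unbroadcast(
                        -g * self.data / (other.data**2), other.shape
                    ),
                ),
            ],
        )

    def __pow__(self, p: float):
        return Tensor._make(
            self.data**p,
            [(self, lambda g: g * p * self.data ** (p - 1))],
        )

    def __matmul__(self, other):
        other = self._coerce(other)
        out = self.data @ other.data

        def d_a(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            return _unbroadcast(ga, self.shape)

        def d_b(g):
            gb = np.swapaxes(self.data, -1, -2) @ g
            return _unbroadcast(gb, other.shape)

        return Tensor._make(out, [(self, d_a), (other, d_b)])

    # -- elementwise nonlinearities -------------------------------------
    def exp(self):
        out = np.exp(self.data)
        return Tensor._make(out, [(self, lambda g: g * out)])

    def log(self):
        return Tensor._make(np.log(self.data), [(self, lambda g: g / self.data)])

    def tanh(self):
        out = np.tanh(self.data)
        return Tensor._make(out, [(self, lambda g: g * (1.0 - out**2))])

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._make(out, [(self, lambda g: g * out * (1.0 - out))])

    def relu(self):
        mask = self.data > 0
        return Tensor._make(self.data * mask, [(self, lambda g: g * mask)])

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def back(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return np.broadcast_to(g, self.shape).copy()

        return Tensor._make(out, [(self, back)])

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops -------------------------------------------------------
    def reshape(self, *shape):
        orig = self.shape
        return Tensor._make(
            self.data.reshape(*shape), [(self, lambda g: g.reshape(orig))]
        )

    def transpose(self, *axes):
        inv = np.argsort(axes)
        return Tensor._make(
            self.data.transpose(*axes), [(self, lambda g: g.transpose(*inv))]
        )

    def swapaxes(self, a: int, b: int):
        return Tensor._make(
            np.swapaxes(self.data, a, b), [(self, lambda g: np.swapaxes(g, a, b))]
        )

    def __getitem__(self, idx):
        out = self.data[idx]

        def back(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return full

        return Tensor._make(out, [(self, back)])

    # -- fused ops -------------------------------------------------------
    def log_softmax(self, axis: int = -1):
        m = self.data.max(axis=axis, keepdims=True)
        z = self.data - m
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        out = z - lse
        sm = np.exp(out)

        def back(g):
            return g - sm * g.sum(axis=axis, keepdims=True)

        return Tensor._make(out, [(self, back)])

    def softmax(self, axis: int = -1):
        m = self.data.max(axis=axis, keepdims=True)
        e = np.exp(self.data - m)
        out = e / e.sum(axis=axis, keepdims=True)

        def back(g):
            return out * (g - (g * out).sum(axis=axis, keepdims=True))

        return Tensor._make(out, [(self, back)])

    def masked_fill(self, mask: np.ndarray, value: float):
        """Replace entries where `mask` is True with `value` (constant)."""
        out = np.where(mask, value, self.data)
        return Tensor._make(out, [(self, lambda g: np.where(mask, 0.0, g))])


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    parents = []
    for i, t in enumerate(tensors):
        lo, hi = offsets[i], offsets[i + 1]

        def back(g, lo=lo, hi=hi):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            return g[tuple(sl)]

        parents.append((t, back))
    return Tensor._make(out, parents)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    out = np.stack([t.data for t in tensors], axis=axis)
    parents = []
    for i, t in enumerate(tensors):
        parents.append((t, lambda g, i=i: np.take(g, i, axis=axis)))
    return Tensor._make(out, parents)


def embedding_lookup(table: Tensor, idx: np.ndarray) -> Tensor:
    idx = np.asarray(idx)
    out = table.data[idx]

    def back(g):
        full = np.zeros_like(table.data)
        np.add.at(full, idx, g)
        return full

    return Tensor._make(out, [(table, back)])


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


# ---------------------------------------------------------------------------
# modules


class Module:
    """Base class: parameter discovery and train/eval mode propagation."""

    training: bool = True

    def modules(self):
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item
                        yield from item.modules()

    def named_parameters(self, prefix: str = ""):
        for name, v in self.__dict__.items():
            full = f"{prefix}{name}"
            if isinstance(v, Parameter):
                yield full, v
            elif isinstance(v, Module):
                yield from v.named_parameters(full + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{full}.{i}", item

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

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray], strict: bool = True):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if strict and missing:
            raise KeyError(f"missing parameters: {sorted(missing)}")
        for name, arr in state.items():
            if name in own:
                if own[name].data.shape != arr.shape:
                    raise ValueError(
                        f"shape mismatch for {name}: "
                        f"{own[name].data.shape} vs {arr.shape}"
                    )
                own[name].data = np.asarray(arr, dtype=np.float64).copy()
        return self


def _trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Truncated normal at +/- 2 std, the BERT-family initialization."""
    x = rng.normal(0.0, std, size=shape)
    bad = np.abs(x) > 2 * std
    while bad.any():
        x[bad] = rng.normal(0.0, std, size=int(bad.sum()))
        bad = np.abs(x) > 2 * std
    return x


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.weight = Parameter(_trunc_normal(rng, (d_in, d_out)))
        self.bias = Parameter(np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Embedding(Module):
    def __init__(self, n: int, d: int, rng: np.random.Generator):
        self.weight = Parameter(_trunc_normal(rng, (n, d)))

    def __call__(self, idx: np.ndarray) -> Tensor:
        return embedding_lookup(self.weight, idx)


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(d))
        self.beta = Parameter(np.zeros(d))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xn = xc * ((var + self.eps) ** -0.5)
        return xn * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        assert 0.0 <= p < 1.0
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(keep)


class MultiHeadSelfAttention(Module):
    """Self-attention where every head uses the full key/value width d_head.

    With h heads the concatenated head outputs (h * d_head) are projected
    back to d_model.  Retains the last forward pass's attention maps in
    `last_attention` with shape (batch, heads, L, L).
    """

    def __init__(
        self,
        d_model: int,
        n_heads: int,
        d_head: int,
        dropout: float,
        rng: np.random.Generator,
    ):
        self.n_heads = n_heads
        self.d_head = d_head
        self.wq = Linear(d_model, n_heads * d_head, rng)
        self.wk = Linear(d_model, n_heads * d_head, rng)
        self.wv = Linear(d_model, n_heads * d_head, rng)
        self.wo = Linear(n_heads * d_head, d_model, rng)
        self.drop = Dropout(dropout, rng)
        self.last_attention: np.ndarray | None = None

    def __call__(self, x: Tensor, pad_mask: np.ndarray | None = None) -> Tensor:
        B, L, _ = x.shape
        h, dh = self.n_heads, self.d_head

        def split(t: Tensor) -> Tensor:  # (B,L,h*dh) -> (B,h,L,dh)
            return t.reshape(B, L, h, dh).transpose(0, 2, 1, 3)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / math.sqrt(dh))
        if pad_mask is not None:
            # pad_mask: (B, L) True at padding -> mask out as attention keys
            scores = scores.masked_fill(pad_mask[:, None, None, :], -1e9)
        attn = scores.softmax(axis=-1)
        self.last_attention = attn.data
        ctx = self.drop(attn) @ v  # (B,h,L,dh)
        ctx = ctx.transpose(0, 2, 1, 3).reshape(B, L, h * dh)
        return self.wo(ctx)


class TransformerEncoderLayer(Module):
    """Post-norm encoder block: attention + position-wise feed-forward."""

    def __init__(
        self,
        d_model: int,
        n_heads: int,
        d_head: int,
        d_ff: int,
        dropout: float,
        rng: np.random.Generator,
    ):
        self.attn = MultiHeadSelfAttention(d_model, n_heads, d_head, dropout, rng)
        self.ln1 = LayerNorm(d_model)
        self.fc1 = Linear(d_model, d_ff, rng)
        self.fc2 = Linear(d_ff, d_model, rng)
        self.ln2 = LayerNorm(d_model)
        self.drop = Dropout(dropout, rng)

    def __call__(self, x: Tensor, pad_mask: np.ndarray | None = None) -> Tensor:
        x = self.ln1(x + self.drop(self.attn(x, pad_mask)))
        ff = self.fc2(self.drop(self.fc1(x).relu()))
        return self.ln2(x + self.drop(ff))


class _GRUDirection(Module):
    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator):
        s = 1.0 / math.sqrt(d_hidden)
        self.wx = Parameter(rng.uniform(-s, s, (d_in, 3 * d_hidden)))
        self.wh = Parameter(rng.uniform(-s, s, (d_hidden, 3 * d_hidden)))
        self.b = Parameter(np.zeros(3 * d_hidden))
        self.d_hidden = d_hidden

    def run(self, x: Tensor, mask: np.ndarray, reverse: bool) -> Tensor:
        """x: (B, L, D); mask: (B, L) 1.0 at real tokens. Returns final h."""
        B, L, _ = x.shape
        d = self.d_hidden
        h = Tensor(np.zeros((B, d)))
        steps = range(L - 1, -1, -1) if reverse else range(L)
        xw = x @ self.wx + self.b  # precompute input projections (B,L,3d)
        for t in steps:
            xt = xw[:, t, :]
            hw = h @ self.wh
            r = (xt[:, :d] + hw[:, :d]).sigmoid()
            z = (xt[:, d : 2 * d] + hw[:, d : 2 * d]).sigmoid()
            n = (xt[:, 2 * d :] + r * hw[:, 2 * d :]).tanh()
            h_new = (1.0 - z) * n + z * h
            m = Tensor(mask[:, t : t + 1])
            h = m * h_new + (1.0 - m) * h
        return h


class BiGRU(Module):
    """Bidirectional GRU returning the concatenated final states."""

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator):
        self.fwd = _GRUDirection(d_in, d_hidden, rng)
        self.bwd = _GRUDirection(d_in, d_hidden, rng)

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        hf = self.fwd.run(x, mask, reverse=False)
        hb = self.bwd.run(x, mask, reverse=True)
        return concat([hf, hb], axis=-1)


def sinusoidal_table(max_pos: int, d: int) -> np.ndarray:
    """Fixed sin/cos positional table: PE[p, 2i] = sin(p / 10000^(2i/d))."""
    pe = np.zeros((max_pos, d))
    pos = np.arange(max_pos)[:, None]
    div = np.exp(np.arange(0, d, 2) * (-math.log(10000.0) / d))
    pe[:, 0::2] = np.sin(pos * div)
    pe[:, 1::2] = np.cos(pos * div[: pe[:, 1::2].shape[1]])
    return pe


class Adam:
    """Adam with (coupled) L2 weight decay, per-parameter-group learning rates.

    groups: list of dicts {"params": [(name, Parameter), ...], "lr": float}.
    """

    def __init__(
        self,
        groups,
        lr: float = 7e-5,
        weight_decay: float = 0.015,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        if groups and isinstance(groups[0], tuple):
            groups = [{"params": groups, "lr": lr}]
        self.groups = groups
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.state: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for group in self.groups:
            lr = group["lr"]
            for name, p in group["params"]:
                if p.grad is None:
                    continue
                g = p.grad + self.weight_decay * p.data
                m, v = self.state.get(
                    name, (np.zeros_like(p.data), np.zeros_like(p.data))
                )
                m = b1 * m + (1 - b1) * g
                v = b2 * v + (1 - b2) * g * g
                self.state[name] = (m, v)
                mhat = m / (1 - b1**self.t)
                vhat = v / (1 - b2**self.t)
                p.data = p.data - lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for group in self.groups:
            for _, p in group["params"]:
                p.grad = None
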