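"""A small reverse-mode automatic-differentiation engine on numpy arrays.

Supports exactly the operations the network needs: broadcasting
arithmetic, matmul, elementwise transcendentals, reductions, reshaping,
slicing, concatenation, a valid 2D cross-correlation primitive and a
numerically stable binary cross-entropy-with-logits primitive.  Gradients
are accumulated by topological traversal from the output scalar; the
engine is exercised end-to-end by finite-difference checks in the test
suite.
"""

from __future__ import annotations

from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

from phoskan.errors import ContractError


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # make numpy defer to the reflected operators below
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False,
                 parents: Tuple["Tensor", ...] = (),
                 backward: Optional[Callable[[np.ndarray], None]] = None):
        self.data = np.asarray(data)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in parents
        )
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # ------------------------------------------------------------------
    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor."""
        if self.data.size != 1:
            raise ContractError("backward() requires a scalar output")
        topo: List[Tensor] = []
        seen = set()

        def visit(t: Tensor) -> None:
            stack = [(t, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    topo.append(node)
                    continue
                if id(node) in seen or not node.requires_grad:
                    continue
                seen.add(id(node))
                stack.append((node, True))
                for p in node._parents:
                    stack.append((p, False))

        visit(self)
        self._accumulate(np.ones_like(self.data))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------------
    # arithmetic
    def __add__(self, other):
        other = _as_tensor(other)

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor(self.data + other.data, parents=(self, other), backward=bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accumulate(-g)

        return Tensor(-self.data, parents=(self,), backward=bw)

    def __sub__(self, other):
        other = _as_tensor(other)

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(-g, other.shape))

        return Tensor(self.data - other.data, parents=(self, other), backward=bw)

    def __rsub__(self, other):
        return _as_tensor(other) - self

    def __mul__(self, other):
        other = _as_tensor(other)

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor(self.data * other.data, parents=(self, other), backward=bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data ** 2, other.shape)
                )

        return Tensor(self.data / other.data, parents=(self, other), backward=bw)

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise ContractError("only scalar exponents are supported")

        def bw(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1))

        return Tensor(self.data ** exponent, parents=(self,), backward=bw)

    def __matmul__(self, other):
        other = _as_tensor(other)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g @ np.swapaxes(other.data, -1, -2))
            if other.requires_grad:
                gw = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gw, other.shape))

        return Tensor(self.data @ other.data, parents=(self, other), backward=bw)

    # ------------------------------------------------------------------
    # elementwise transcendentals
    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            self._accumulate(g * out_data)

        return Tensor(out_data, parents=(self,), backward=bw)

    def log(self):
        def bw(g):
            self._accumulate(g / self.data)

        return Tensor(np.log(self.data), parents=(self,), backward=bw)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bw(g):
            self._accumulate(g * (1.0 - out_data ** 2))

        return Tensor(out_data, parents=(self,), backward=bw)

    def sigmoid(self):
        out_data = _sigmoid(self.data)

        def bw(g):
            self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor(out_data, parents=(self,), backward=bw)

    def relu(self):
        mask = self.data > 0

        def bw(g):
            self._accumulate(g * mask)

        return Tensor(self.data * mask, parents=(self,), backward=bw)

    def sin(self):
        def bw(g):
            self._accumulate(g * np.cos(self.data))

        return Tensor(np.sin(self.data), parents=(self,), backward=bw)

    def cos(self):
        def bw(g):
            self._accumulate(-g * np.sin(self.data))

        return Tensor(np.cos(self.data), parents=(self,), backward=bw)

    def abs(self):
        sign = np.sign(self.data)

        def bw(g):
            self._accumulate(g * sign)

        return Tensor(np.abs(self.data), parents=(self,), backward=bw)

    def sinc(self):
        """Normalized sinc: sin(pi x) / (pi x), with sinc(0) = 1."""
        x = self.data
        out_data = np.sinc(x)
        px = np.pi * x
        small = np.abs(px) < 1e-6
        with np.errstate(divide="ignore", invalid="ignore"):
            deriv = np.where(
                small,
                -np.pi ** 2 * x / 3.0,
                (np.cos(px) - out_data) / np.where(small, 1.0, x),
            )

        def bw(g):
            self._accumulate(g * deriv)

        return Tensor(out_data, parents=(self,), backward=bw)

    # ------------------------------------------------------------------
    # reductions & shape ops
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        return Tensor(out_data, parents=(self,), backward=bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            count = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def bw(g):
            self._accumulate(g.reshape(old))

        return Tensor(self.data.reshape(shape), parents=(self,), backward=bw)

    def transpose(self, axes: Sequence[int]):
        axes = tuple(axes)
        inverse = tuple(np.argsort(axes))

        def bw(g):
            self._accumulate(np.transpose(g, inverse).copy())

        return Tensor(np.transpose(self.data, axes).copy(), parents=(self,),
                      backward=bw)

    def __getitem__(self, key):
        def bw(g):
            full = np.zeros_like(self.data)
            full[key] = g
            self._accumulate(full)

        return Tensor(self.data[key], parents=(self,), backward=bw)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out.astype(x.dtype, copy=False)


def concatenate(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    """Concatenate tensors along an axis (differentiable)."""
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                  parents=tuple(tensors), backward=bw)


def conv2d_valid(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Valid 2D cross-correlation of a single-channel batch.

    ``x``: (B, H, W); ``weight``: (K, kh, kw); ``bias``: (K,).
    Output: (B, K, H - kh + 1, W - kw + 1).  Implemented by im2col +
    matmul; cross-correlation (no kernel flip), the deep-learning
    convention.
    """
    x = _as_tensor(x)
    weight = _as_tensor(weight)
    bias = _as_tensor(bias)
    B, H, W = x.shape
    K, kh, kw = weight.shape
    if H < kh or W < kw:
        raise ContractError(
            f"input {H}x{W} smaller than kernel {kh}x{kw}"
        )
    oh, ow = H - kh + 1, W - kw + 1
    patches = np.lib.stride_tricks.sliding_window_view(x.data, (kh, kw),
                                                       axis=(1, 2))
    col = patches.reshape(B * oh * ow, kh * kw)  # copy
    wmat = weight.data.reshape(K, kh * kw).T
    out_data = (col @ wmat).reshape(B, oh, ow, K).transpose(0, 3, 1, 2)
    out_data = out_data + bias.data.reshape(1, K, 1, 1)

    def bw(g):
        g_flat = g.transpose(0, 2, 3, 1).reshape(B * oh * ow, K)
        if bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if weight.requires_grad:
            gw = (col.T @ g_flat).T.reshape(K, kh, kw)
            weight._accumulate(gw)
        if x.requires_grad:
            dcol = (g_flat @ wmat.T).reshape(B, oh, ow, kh, kw)
            dx = np.zeros((B, H, W), dtype=x.data.dtype)
            for di in range(kh):
                for dj in range(kw):
                    dx[:, di : di + oh, dj : dj + ow] += dcol[:, :, :, di, dj]
            x._accumulate(dx)

    return Tensor(out_data, parents=(x, weight, bias), backward=bw)


def bce_with_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on raw logits, in stable log-sum-exp form.

    loss_i = max(z, 0) - z*y + log(1 + exp(-|z|)); gradient sigma(z) - y.
    """
    logits = _as_tensor(logits)
    y = np.asarray(labels, dtype=np.float64).reshape(logits.shape)
    if y.size == 0:
        raise ContractError("empty input to BCE loss")
    z = logits.data.astype(np.float64)
    loss = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    mean = loss.mean()

    def bw(g):
        grad = (g * (_sigmoid(z) - y) / y.size).astype(
            logits.data.dtype, copy=False
        )
        logits._accumulate(grad.reshape(logits.shape))

    return Tensor(mean, parents=(logits,), backward=bw)
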