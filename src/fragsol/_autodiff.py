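"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Just enough machinery for the attention/GRU network: elementwise arithmetic
with broadcasting, matrix products, the activations the architecture uses,
row gathering and segment reductions (the vectorized form of per-target
neighborhood aggregation).  Gradients are accumulated by a topological-order
sweep; correctness is checked against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False):
        arr = np.asarray(data)
        if arr.dtype not in (np.float32, np.float64):
            arr = arr.astype(np.float64)
        self.data = arr
        self.grad = None
        self.requires_grad = requires_grad
        self._parents = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    # -- graph construction helpers -------------------------------------

    @staticmethod
    def _lift(x, dtype=None):
        if isinstance(x, Tensor):
            return x
        arr = np.asarray(x)
        # scalars adopt the partner tensor's dtype to avoid silent promotion
        if dtype is not None and arr.ndim == 0:
            arr = arr.astype(dtype)
        return Tensor(arr)

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, g):
        if self.grad is None:
            # copy: g may be a view into (or alias of) another node's buffer
            self.grad = np.array(g, dtype=self.data.dtype)
        else:
            self.grad += g

    @staticmethod
    def _unbroadcast(g, shape):
        """Reduce gradient ``g`` back to ``shape`` after NumPy broadcasting."""
        if g.shape == shape:
            return g
        while g.ndim > len(shape):
            g = g.sum(axis=0)
        for ax, dim in enumerate(shape):
            if dim == 1 and g.shape[ax] != 1:
                g = g.sum(axis=ax, keepdims=True)
        return g.reshape(shape)

    # -- arithmetic ------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other, self.data.dtype)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(self._unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(self._unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other, self.data.dtype))

    def __rsub__(self, other):
        return self._lift(other, self.data.dtype) + (-self)

    def __mul__(self, other):
        other = self._lift(other, self.data.dtype)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(self._unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(self._unbroadcast(g * self.data, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other, self.data.dtype)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(self._unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    self._unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return self._make(out_data, (self, other), backward)

    def matmul(self, other):
        other = self._lift(other)
        out_data = self.data @ other.data
        a_vec, b_vec = self.data.ndim == 1, other.data.ndim == 1

        def backward(g):
            a = self.data[None, :] if a_vec else self.data
            b = other.data[:, None] if b_vec else other.data
            gm = g
            if a_vec:
                gm = gm[None, ...]
            if b_vec:
                gm = gm[..., None]
            if self.requires_grad:
                ga = gm @ b.swapaxes(-1, -2)
                self._accumulate(ga[0] if a_vec else ga)
            if other.requires_grad:
                gb = a.swapaxes(-1, -2) @ gm
                other._accumulate(gb[..., 0] if b_vec else gb)

        return self._make(out_data, (self, other), backward)

    __matmul__ = matmul

    # -- reductions -------------------------------------------------------

    def sum(self, axis=None):
        out_data = self.data.sum(axis=axis)

        def backward(g):
            if self.requires_grad:
                if axis is None:
                    self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                else:
                    self._accumulate(
                        np.broadcast_to(np.expand_dims(g, axis), self.data.shape).copy()
                    )

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis) / float(n)

    # -- activations ------------------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out_data)

        return self._make(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - out_data**2))

        return self._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def elu(self, alpha=1.0):
        neg = alpha * (np.exp(np.minimum(self.data, 0.0)) - 1.0)
        out_data = np.where(self.data > 0, self.data, neg)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * np.where(self.data > 0, 1.0, neg + alpha))

        return self._make(out_data, (self,), backward)

    def leaky_relu(self, slope=0.01):
        out_data = np.where(self.data > 0, self.data, slope * self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * np.where(self.data > 0, 1.0, slope))

        return self._make(out_data, (self,), backward)

    def abs(self):
        out_data = np.abs(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * np.sign(self.data))

        return self._make(out_data, (self,), backward)

    # -- indexing / shaping ------------------------------------------------

    def take(self, idx):
        """Gather rows; gradient scatters (with accumulation) back."""
        idx = np.asarray(idx, dtype=np.intp)
        out_data = self.data[idx]

        def backward(g):
            if self.requires_grad:
                acc = np.zeros_like(self.data)
                np.add.at(acc, idx, g)
                self._accumulate(acc)

        return self._make(out_data, (self,), backward)

    def reshape(self, *shape):
        old = self.data.shape
        out_data = self.data.reshape(*shape)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(old))

        return self._make(out_data, (self,), backward)

    # -- autodiff driver ---------------------------------------------------

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)


# ---------------------------------------------------------------------------
# free functions


def concat(tensors, axis=0):
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor._make(out_data, tensors, backward)


def segment_sum(t: Tensor, segment_ids, num_segments: int) -> Tensor:
    """Sum rows of ``t`` into ``num_segments`` buckets; empty buckets give 0."""
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    out_shape = (num_segments,) + t.data.shape[1:]
    out_data = np.zeros(out_shape, dtype=t.data.dtype)
    np.add.at(out_data, segment_ids, t.data)

    def backward(g):
        if t.requires_grad:
            t._accumulate(g[segment_ids])

    return Tensor._make(out_data, (t,), backward)


def segment_mean(t: Tensor, segment_ids, num_segments: int) -> Tensor:
    counts = np.bincount(np.asarray(segment_ids), minlength=num_segments).astype(t.data.dtype)
    counts = np.maximum(counts, 1.0).reshape((num_segments,) + (1,) * (t.data.ndim - 1))
    return segment_sum(t, segment_ids, num_segments) / Tensor(counts)


def segment_softmax(scores: Tensor, segment_ids, num_segments: int) -> Tensor:
    """Softmax of ``scores`` within each segment (per-target attention weights).

    The per-segment max is subtracted as a constant for numerical stability;
    softmax is shift-invariant so gradients are unaffected.
    """
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    maxes = np.full(num_segments, -np.inf, dtype=scores.data.dtype)
    np.maximum.at(maxes, segment_ids, scores.data)
    maxes[~np.isfinite(maxes)] = 0.0
    shifted = scores - Tensor(maxes[segment_ids])
    e = shifted.exp()
    denom = segment_sum(e, segment_ids, num_segments)
    return e / denom.take(segment_ids)
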