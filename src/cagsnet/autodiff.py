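"""Minimal reverse-mode automatic differentiation on numpy arrays.

Provides exactly the operator set the segmentation network needs: broadcasted
arithmetic, matmul, 3D convolution (arbitrary stride/padding), leaky ReLU,
sigmoid, exp/log/pow, reductions, reshape/concat, and separable linear
interpolation along spatial axes (used for trilinear upsampling). Gradients
are accumulated by topological-order traversal of the recorded tape.

All data is float32 by default; the engine is single-threaded numpy and fully
deterministic.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat", "no_grad"]

_grad_enabled = True


class no_grad:
    """Context manager disabling tape recording (inference mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")
    __array_priority__ = 100  # numpy defers binary ops to Tensor

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad) and _grad_enabled
        self._backward = None
        self._parents = ()

    # ---- construction helpers -------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # ---- tape machinery --------------------------------------------------
    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None):
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=np.float32)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t._backward is not None:
                for parent, pg in t._backward(g):
                    if not parent.requires_grad:
                        continue
                    if id(parent) in grads:
                        grads[id(parent)] = grads[id(parent)] + pg
                    else:
                        grads[id(parent)] = pg
            else:  # leaf
                t.grad = g if t.grad is None else t.grad + g
        # non-leaf tensors that still hold grads (e.g. self when it is a leaf)
        if self._backward is None and self.requires_grad and self.grad is None:
            self.grad = np.asarray(grad, dtype=np.float32)

    # ---- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = self._make(
            self.data + other.data,
            (self, other),
            lambda g: [
                (self, _unbroadcast(g, self.shape)),
                (other, _unbroadcast(g, other.shape)),
            ],
        )
        return out

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: [(self, -g)])

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = self._make(
            self.data * other.data,
            (self, other),
            lambda g: [
                (self, _unbroadcast(g * other.data, self.shape)),
                (other, _unbroadcast(g * self.data, other.shape)),
            ],
        )
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * as_tensor(other).pow(-1.0)

    def __rtruediv__(self, other):
        return as_tensor(other) * self.pow(-1.0)

    def pow(self, exponent: float) -> "Tensor":
        data = self.data ** exponent
        return self._make(
            data,
            (self,),
            lambda g: [(self, g * exponent * self.data ** (exponent - 1.0))],
        )

    def matmul(self, other: "Tensor") -> "Tensor":
        other = as_tensor(other)
        out = self._make(
            self.data @ other.data,
            (self, other),
            lambda g: [(self, g @ other.data.T), (other, self.data.T @ g)],
        )
        return out

    __matmul__ = matmul

    # ---- elementwise nonlinearities -------------------------------------
    def exp(self) -> "Tensor":
        data = np.exp(self.data)
        return self._make(data, (self,), lambda g: [(self, g * data)])

    def log(self) -> "Tensor":
        return self._make(np.log(self.data), (self,), lambda g: [(self, g / self.data)])

    def sigmoid(self) -> "Tensor":
        # clamp the pre-activation to avoid overflow in exp
        z = np.clip(self.data, -50.0, 50.0)
        data = 1.0 / (1.0 + np.exp(-z))
        return self._make(data, (self,), lambda g: [(self, g * data * (1.0 - data))])

    def leaky_relu(self, mu: float = 0.01) -> "Tensor":
        pos = self.data > 0
        data = np.where(pos, self.data, mu * self.data)
        return self._make(
            data, (self,), lambda g: [(self, np.where(pos, g, np.float32(mu) * g))]
        )

    def clip(self, lo: float, hi: float) -> "Tensor":
        inside = (self.data >= lo) & (self.data <= hi)
        return self._make(
            np.clip(self.data, lo, hi),
            (self,),
            lambda g: [(self, np.where(inside, g, 0.0))],
        )

    # ---- reductions and shaping -----------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return [(self, np.broadcast_to(g, self.shape).astype(np.float32))]

        return self._make(data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        return self._make(
            self.data.reshape(shape), (self,), lambda g: [(self, g.reshape(old))]
        )

    def transpose(self, *axes) -> "Tensor":
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)
        return self._make(
            self.data.transpose(axes), (self,), lambda g: [(self, g.transpose(inv))]
        )

    # ---- 3D convolution --------------------------------------------------
    def conv3d(self, weight: "Tensor", bias: "Tensor" = None,
               stride: int = 1, padding: int = 0) -> "Tensor":
        """3D cross-correlation of a (C_in, D, H, W) map with a
        (C_out, C_in, k, k, k) kernel; single-sample (no batch axis)."""
        x, w = self, as_tensor(weight)
        k = w.shape[2]
        s, p = int(stride), int(padding)
        xp = np.pad(x.data, ((0, 0), (p, p), (p, p), (p, p))) if p else x.data
        dims_out = tuple((xd + 2 * p - k) // s + 1 for xd in x.shape[1:])
        co, ci = w.shape[0], w.shape[1]
        out = np.zeros((co,) + dims_out, dtype=np.float32)
        od, oh, ow = dims_out
        # accumulate one kernel offset at a time: a (C_out x C_in) mix of a
        # strided view of the padded input; avoids materialising im2col
        for a in range(k):
            for b in range(k):
                for c in range(k):
                    patch = xp[:, a:a + s * od:s, b:b + s * oh:s, c:c + s * ow:s]
                    out += np.tensordot(w.data[:, :, a, b, c], patch, axes=1)
        if bias is not None:
            out += as_tensor(bias).data[:, None, None, None]

        parents = (x, w) if bias is None else (x, w, as_tensor(bias))

        def backward(g):
            grads = []
            if x.requires_grad:
                dxp = np.zeros_like(xp)
                for a in range(k):
                    for b in range(k):
                        for c in range(k):
                            dxp[:, a:a + s * od:s, b:b + s * oh:s, c:c + s * ow:s] += \
                                np.tensordot(w.data[:, :, a, b, c].T, g, axes=1)
                dx = dxp[:, p:p + x.shape[1], p:p + x.shape[2], p:p + x.shape[3]] \
                    if p else dxp
                grads.append((x, dx))
            else:
                grads.append((x, None))
            dw = np.zeros_like(w.data)
            for a in range(k):
                for b in range(k):
                    for c in range(k):
                        patch = xp[:, a:a + s * od:s, b:b + s * oh:s, c:c + s * ow:s]
                        dw[:, :, a, b, c] = np.tensordot(
                            g, patch, axes=([1, 2, 3], [1, 2, 3]))
            grads.append((w, dw))
            if bias is not None:
                grads.append((parents[2], g.sum(axis=(1, 2, 3))))
            return [(t, gr) for t, gr in grads if gr is not None]

        return self._make(out, parents, backward)

    def maxpool2(self) -> "Tensor":
        """2x2x2 max pooling of a (C, D, H, W) map with even spatial dims;
        gradient routes to the first argmax of each window."""
        c, d, h, w = self.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError(f"maxpool2 needs even spatial dims, got {(d, h, w)}")
        win = self.data.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
        win = win.transpose(0, 1, 3, 5, 2, 4, 6).reshape(c, d // 2, h // 2, w // 2, 8)
        idx = win.argmax(axis=-1)
        out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

        def backward(g):
            dwin = np.zeros((c, d // 2, h // 2, w // 2, 8), dtype=np.float32)
            np.put_along_axis(dwin, idx[..., None], g[..., None], axis=-1)
            dx = dwin.reshape(c, d // 2, h // 2, w // 2, 2, 2, 2)
            dx = dx.transpose(0, 1, 4, 2, 5, 3, 6).reshape(c, d, h, w)
            return [(self, dx)]

        return self._make(out, (self,), backward)

    # ---- separable linear interpolation (trilinear upsampling) ----------
    def interp_axes(self, matrices) -> "Tensor":
        """Apply a fixed interpolation matrix along each of the three spatial
        axes of a (C, D, H, W) map; matrices[i] has shape (out_i, in_i)."""
        mats = [np.asarray(m, dtype=np.float32) for m in matrices]
        data = self.data
        for ax, m in enumerate(mats, start=1):
            data = np.moveaxis(np.tensordot(m, data, axes=([1], [ax])), 0, ax)

        def backward(g):
            for ax, m in enumerate(mats, start=1):
                g = np.moveaxis(np.tensordot(m.T, g, axes=([1], [ax])), 0, ax)
            return [(self, g)]

        return self._make(data, (self,), backward)


def as_tensor(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)


def concat(tensors, axis: int = 0) -> Tensor:
    """Concatenate tensors along `axis`, differentiable through every input."""
    tensors = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        pieces = np.split(g, splits, axis=axis)
        return list(zip(tensors, pieces))

    out = Tensor(data)
    if _grad_enabled and any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = backward
    return out
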