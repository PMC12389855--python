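"""A compact reverse-mode automatic-differentiation engine on numpy arrays.

Only the operations needed by the networks in this package are provided:
broadcast-aware arithmetic, matmul, reductions, shape ops, 2-D (dilated)
convolution, 2x2 stride-2 transposed convolution and average pooling.
All data is float64; gradients are accumulated into ``Tensor.grad`` by
``Tensor.backward()`` over a topologically sorted tape.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

Array = np.ndarray


def _as_array(x) -> Array:
    return np.asarray(x, dtype=np.float64)


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data: Array = _as_array(data)
        self.grad: Array | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[], None] | None = None
        self._prev: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data: Array, prev: Sequence["Tensor"], backward) -> "Tensor":
        req = any(p.requires_grad for p in prev)
        out = Tensor(data, requires_grad=req)
        if req:
            out._prev = tuple(prev)
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def _accum(self, g: Array) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data + other.data

        def backward():
            self._accum(_unbroadcast(out.grad, self.shape))
            other._accum(_unbroadcast(out.grad, other.shape))

        out = Tensor._make(out_data, (self, other), backward)
        return out

    __radd__ = __add__

    def __neg__(self):
        def backward():
            self._accum(-out.grad)

        out = Tensor._make(-self.data, (self,), backward)
        return out

    def __sub__(self, other):
        return self + (-(other if isinstance(other, Tensor) else Tensor(other)))

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data * other.data

        def backward():
            self._accum(_unbroadcast(out.grad * other.data, self.shape))
            other._accum(_unbroadcast(out.grad * self.data, other.shape))

        out = Tensor._make(out_data, (self, other), backward)
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data / other.data

        def backward():
            self._accum(_unbroadcast(out.grad / other.data, self.shape))
            other._accum(
                _unbroadcast(-out.grad * self.data / other.data**2, other.shape)
            )

        out = Tensor._make(out_data, (self, other), backward)
        return out

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __pow__(self, p: float):
        out_data = self.data**p

        def backward():
            self._accum(out.grad * p * self.data ** (p - 1))

        out = Tensor._make(out_data, (self,), backward)
        return out

    def exp(self):
        out_data = np.exp(self.data)

        def backward():
            self._accum(out.grad * out_data)

        out = Tensor._make(out_data, (self,), backward)
        return out

    def log(self):
        def backward():
            self._accum(out.grad / self.data)

        out = Tensor._make(np.log(self.data), (self,), backward)
        return out

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward():
            self._accum(out.grad * 0.5 / out_data)

        out = Tensor._make(out_data, (self,), backward)
        return out

    def relu(self):
        mask = self.data > 0
        out_data = self.data * mask

        def backward():
            self._accum(out.grad * mask)

        out = Tensor._make(out_data, (self,), backward)
        return out

    # -- linear algebra -------------------------------------------------------
    def matmul(self, other: "Tensor") -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = np.matmul(self.data, other.data)

        def backward():
            ga = np.matmul(out.grad, np.swapaxes(other.data, -1, -2))
            gb = np.matmul(np.swapaxes(self.data, -1, -2), out.grad)
            self._accum(_unbroadcast(ga, self.shape))
            other._accum(_unbroadcast(gb, other.shape))

        out = Tensor._make(out_data, (self, other), backward)
        return out

    __matmul__ = matmul

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward():
            g = out.grad
            if not keepdims and axis is not None:
                axes = axis if isinstance(axis, tuple) else (axis,)
                axes = tuple(a % self.ndim for a in axes)
                shape = [
                    1 if i in axes else s for i, s in enumerate(self.shape)
                ]
                g = g.reshape(shape)
            self._accum(np.broadcast_to(g, self.shape).copy())

        out = Tensor._make(out_data, (self,), backward)
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a % self.ndim] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def backward():
            self._accum(out.grad.reshape(old))

        out = Tensor._make(self.data.reshape(shape), (self,), backward)
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward():
            self._accum(out.grad.transpose(inv))

        out = Tensor._make(self.data.transpose(axes), (self,), backward)
        return out

    def __getitem__(self, idx):
        def backward():
            g = np.zeros_like(self.data)
            g[idx] = out.grad
            self._accum(g)

        out = Tensor._make(self.data[idx], (self,), backward)
        return out

    # -- autodiff driver ------------------------------------------------------
    def backward(self, grad: Array | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(node: "Tensor"):
            stack = [(node, False)]
            while stack:
                n, done = stack.pop()
                if done:
                    topo.append(n)
                    continue
                if id(n) in seen or not n.requires_grad:
                    continue
                seen.add(id(n))
                stack.append((n, True))
                for p in n._prev:
                    stack.append((p, False))

        visit(self)
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()


# -- free functions ------------------------------------------------------------
def concatenate(tensors: Sequence[Tensor], axis: int) -> Tensor:
    sizes = [t.shape[axis] for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)

    def backward():
        splits = np.cumsum(sizes)[:-1]
        grads = np.split(out.grad, splits, axis=axis)
        for t, g in zip(tensors, grads):
            t._accum(g)

    out = Tensor._make(out_data, tuple(tensors), backward)
    return out


def pad2d(x: Tensor, pads: tuple[int, int, int, int]) -> Tensor:
    """Zero-pad the last two axes of an [..., H, W] tensor.

    ``pads`` is (top, bottom, left, right).
    """
    t, b, l, r = pads
    width = [(0, 0)] * (x.ndim - 2) + [(t, b), (l, r)]
    out_data = np.pad(x.data, width)
    H, W = x.shape[-2:]
    sl = (Ellipsis, slice(t, t + H), slice(l, l + W))

    def backward():
        x._accum(out.grad[sl])

    out = Tensor._make(out_data, (x,), backward)
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(np.max(x.data, axis=axis, keepdims=True))  # constant
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, dilation: int = 1) -> Tensor:
    """'Same'-padded 2-D convolution (cross-correlation).

    x: [N, C, H, W]; w: [O, C, kh, kw] with odd kh, kw; output [N, O, H, W].
    """
    N, C, H, W = x.shape
    O, C2, kh, kw = w.shape
    if C != C2:
        raise ValueError(f"channel mismatch: input {C}, kernel {C2}")
    d = dilation
    ph, pw = d * (kh - 1) // 2, d * (kw - 1) // 2
    eh, ew = d * (kh - 1) + 1, d * (kw - 1) + 1  # dilated extents
    if H + 2 * ph < eh or W + 2 * pw < ew:
        raise ValueError(
            f"input {H}x{W} smaller than dilated receptive field {eh}x{ew}; "
            f"need at least {eh - 2 * ph}x{ew - 2 * pw}"
        )
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (eh, ew), axis=(2, 3))
    win = win[:, :, :, :, ::d, ::d]  # [N, C, H, W, kh, kw]
    out_data = np.einsum("nchwij,ocij->nohw", win, w.data, optimize=True)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]

    def backward():
        g = out.grad
        if w.requires_grad:
            gw = np.einsum("nchwij,nohw->ocij", win, g, optimize=True)
            w._accum(gw)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i * d : i * d + H, j * d : j * d + W] += np.einsum(
                        "nohw,oc->nchw", g, w.data[:, :, i, j], optimize=True
                    )
            x._accum(gxp[:, :, ph : ph + H, pw : pw + W])

    prev = (x, w) if b is None else (x, w, b)
    out = Tensor._make(out_data, prev, backward)
    return out


def conv_transpose2x2(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Stride-2 transposed convolution with a 2x2 kernel (exact 2x upsampling).

    x: [N, C, H, W]; w: [C, O, 2, 2]; output [N, O, 2H, 2W].
    """
    N, C, H, W = x.shape
    C2, O, kh, kw = w.shape
    if C != C2 or (kh, kw) != (2, 2):
        raise ValueError("expected kernel [C, O, 2, 2] matching input channels")
    out6 = np.einsum("nchw,coab->nohawb", x.data, w.data, optimize=True)
    out_data = out6.reshape(N, O, 2 * H, 2 * W)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]

    def backward():
        g6 = out.grad.reshape(N, O, H, 2, W, 2)
        if x.requires_grad:
            x._accum(np.einsum("nohawb,coab->nchw", g6, w.data, optimize=True))
        if w.requires_grad:
            w._accum(np.einsum("nchw,nohawb->coab", x.data, g6, optimize=True))
        if b is not None and b.requires_grad:
            b._accum(out.grad.sum(axis=(0, 2, 3)))

    prev = (x, w) if b is None else (x, w, b)
    out = Tensor._make(out_data, prev, backward)
    return out


def avg_pool2d(x: Tensor, k: int) -> Tensor:
    """Non-overlapping k x k average pooling; H and W must divide by k."""
    N, C, H, W = x.shape
    if H % k or W % k:
        raise ValueError(f"spatial dims {H}x{W} not divisible by pool size {k}")
    out_data = x.data.reshape(N, C, H // k, k, W // k, k).mean(axis=(3, 5))

    def backward():
        g = np.repeat(np.repeat(out.grad, k, axis=2), k, axis=3) / (k * k)
        x._accum(g)

    out = Tensor._make(out_data, (x,), backward)
    return out


def stack_params(params: Iterable[Tensor]) -> list[Tensor]:
    return [p for p in params if p.requires_grad]
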