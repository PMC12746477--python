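"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The registration and classification networks in this package need exact
gradients of a composite objective (Parzen-window mutual information of a
warped image, plus field regularizers) with respect to convolution kernels.
This module provides the small tensor engine they are built on: a
:class:`Tensor` wrapper recording a computation graph, generic elementwise /
reduction / matmul ops with broadcasting-aware backward rules, and three
domain ops written with bespoke backward passes for speed — strided 3D
convolution, nearest-neighbour upsampling, and trilinear warping of a volume
by a displacement field.

The engine is validated end-to-end by a numerical-vs-analytic gradient check
on small volumes (see the test suite); it is deliberately eager, single
threaded and deterministic.
"""

from __future__ import annotations

from typing import Callable, Iterable, List, Optional, Sequence, Tuple

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A NumPy array plus gradient bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad: Optional[np.ndarray] = None
        self._backward: Optional[Callable[[np.ndarray], None]] = None
        self._parents: Tuple["Tensor", ...] = ()

    # -- graph construction -------------------------------------------------
    @staticmethod
    def _result(data: np.ndarray, parents: Sequence["Tensor"],
                backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        g = _unbroadcast(np.asarray(g), self.data.shape).astype(self.data.dtype, copy=False)
        self.grad = g if self.grad is None else self.grad + g

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        """Reverse-mode sweep seeding ``d(self)/d(self)`` with ``grad``."""
        topo: List[Tensor] = []
        seen = set()

        def visit(t: "Tensor") -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- arithmetic ---------------------------------------------------------
    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    def __add__(self, other):
        o = Tensor._coerce(other)
        out_data = self.data + o.data

        def bwd(g):
            if self.requires_grad:
                self._accum(g)
            if o.requires_grad:
                o._accum(g)

        return Tensor._result(out_data, (self, o), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accum(-g)

        return Tensor._result(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        o = Tensor._coerce(other)
        out_data = self.data * o.data

        def bwd(g):
            if self.requires_grad:
                self._accum(g * o.data)
            if o.requires_grad:
                o._accum(g * self.data)

        return Tensor._result(out_data, (self, o), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = Tensor._coerce(other)
        out_data = self.data / o.data

        def bwd(g):
            if self.requires_grad:
                self._accum(g / o.data)
            if o.requires_grad:
                o._accum(-g * self.data / (o.data**2))

        return Tensor._result(out_data, (self, o), bwd)

    def __matmul__(self, other):
        o = Tensor._coerce(other)
        out_data = self.data @ o.data

        def bwd(g):
            if self.requires_grad:
                self._accum(g @ o.data.T)
            if o.requires_grad:
                o._accum(self.data.T @ g)

        return Tensor._result(out_data, (self, o), bwd)

    # -- shape ops ----------------------------------------------------------
    def reshape(self, *shape):
        shape = shape[0] if len(shape) == 1 and isinstance(shape[0], (tuple, list)) else shape
        old = self.data.shape

        def bwd(g):
            self._accum(g.reshape(old))

        return Tensor._result(self.data.reshape(shape), (self,), bwd)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g) if isinstance(idx, np.ndarray) else full.__setitem__(idx, g)
            self._accum(full)

        return Tensor._result(out_data, (self,), bwd)

    # -- reductions / elementwise -------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        return Tensor._result(out_data, (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            self._accum(g * out_data)

        return Tensor._result(out_data, (self,), bwd)

    def log(self):
        def bwd(g):
            self._accum(g / self.data)

        return Tensor._result(np.log(self.data), (self,), bwd)


def leaky_relu(x: Tensor, alpha: float = 0.2) -> Tensor:
    pos = x.data > 0
    out_data = np.where(pos, x.data, alpha * x.data)

    def bwd(g):
        x._accum(g * np.where(pos, 1.0, alpha))

    return Tensor._result(out_data, (x,), bwd)


def sigmoid(x: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-x.data))

    def bwd(g):
        x._accum(g * out_data * (1.0 - out_data))

    return Tensor._result(out_data, (x,), bwd)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    return Tensor._result(out_data, tuple(tensors), bwd)


# ---------------------------------------------------------------------------
# domain ops: strided 3D convolution, upsampling, trilinear warp
# ---------------------------------------------------------------------------


def conv3d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1) -> Tensor:
    """'Same'-padded 3D convolution over a ``(C_in, D, H, W)`` tensor.

    ``w`` has shape ``(C_out, C_in, k, k, k)`` (odd ``k``); with ``stride=2``
    and even spatial dims the output halves each spatial dimension. The
    kernel loop runs over the k^3 taps with one GEMM per tap, which keeps
    memory flat and is fast for the narrow channel counts used here.
    """
    ci, d, h, wd = x.data.shape
    co, ci2, k, _, _ = w.data.shape
    if ci2 != ci:
        raise ValueError(f"channel mismatch: input {ci}, kernel expects {ci2}")
    p = k // 2
    s = stride
    do, ho, wo = ((d + 2 * p - k) // s + 1, (h + 2 * p - k) // s + 1, (wd + 2 * p - k) // s + 1)
    xp = np.pad(x.data, ((0, 0), (p, p), (p, p), (p, p)))
    n = do * ho * wo
    out = np.zeros((co, n), dtype=x.data.dtype)
    views = []
    for a in range(k):
        for bb in range(k):
            for c in range(k):
                xs = xp[:, a : a + s * do : s, bb : bb + s * ho : s, c : c + s * wo : s]
                views.append(xs)
                out += w.data[:, :, a, bb, c] @ xs.reshape(ci, n)
    out = out.reshape(co, do, ho, wo) + b.data.reshape(co, 1, 1, 1)

    def bwd(g):
        gmat = g.reshape(co, n)
        if b.requires_grad:
            b._accum(gmat.sum(axis=1))
        gw = np.zeros_like(w.data) if w.requires_grad else None
        gxp = np.zeros_like(xp) if x.requires_grad else None
        i = 0
        for a in range(k):
            for bb in range(k):
                for c in range(k):
                    xs = views[i]
                    i += 1
                    if gw is not None:
                        gw[:, :, a, bb, c] = gmat @ xs.reshape(ci, n).T
                    if gxp is not None:
                        gxs = (w.data[:, :, a, bb, c].T @ gmat).reshape(ci, do, ho, wo)
                        gxp[:, a : a + s * do : s, bb : bb + s * ho : s, c : c + s * wo : s] += gxs
        if gw is not None:
            w._accum(gw)
        if gxp is not None:
            x._accum(gxp[:, p : p + d, p : p + h, p : p + wd])

    return Tensor._result(out, (x, w, b), bwd)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour doubling of each spatial dimension of (C, D, H, W)."""
    out_data = x.data.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)
    c, d, h, w = x.data.shape

    def bwd(g):
        x._accum(g.reshape(c, d, 2, h, 2, w, 2).sum(axis=(2, 4, 6)))

    return Tensor._result(out_data, (x,), bwd)


def warp_trilinear(moving: np.ndarray, u: Tensor) -> Tensor:
    """Sample ``moving`` at ``x + u(x)`` with trilinear interpolation.

    ``moving`` is a constant ``(D, H, W)`` array; ``u`` is a ``(3, D, H, W)``
    displacement tensor in voxel units. Sampling coordinates are clamped to
    the border of the moving grid; gradients with respect to ``u`` vanish in
    the strictly-clamped region, matching the clamped forward map.
    """
    d, h, w = moving.shape
    if u.data.shape != (3, d, h, w):
        raise ValueError(f"field shape {u.data.shape} does not match volume {(d, h, w)}")
    base = np.stack(
        np.meshgrid(np.arange(d), np.arange(h), np.arange(w), indexing="ij")
    ).astype(u.data.dtype)
    raw = base + u.data
    lims = np.array([d - 1, h - 1, w - 1], dtype=u.data.dtype).reshape(3, 1, 1, 1)
    inside = (raw > 0) & (raw < lims)  # strict: clamped coords get zero gradient
    co = np.clip(raw, 0.0, lims)
    i0 = np.minimum(co.astype(np.int64), (lims - 1).astype(np.int64))
    t = co - i0
    ix, iy, iz = i0[0], i0[1], i0[2]
    tx, ty, tz = t[0], t[1], t[2]

    c = {}
    for a in (0, 1):
        for bb in (0, 1):
            for cc in (0, 1):
                c[a, bb, cc] = moving[ix + a, iy + bb, iz + cc]

    wx0, wx1 = 1.0 - tx, tx
    wy0, wy1 = 1.0 - ty, ty
    wz0, wz1 = 1.0 - tz, tz
    val = (
        wx0 * (wy0 * (wz0 * c[0, 0, 0] + wz1 * c[0, 0, 1]) + wy1 * (wz0 * c[0, 1, 0] + wz1 * c[0, 1, 1]))
        + wx1 * (wy0 * (wz0 * c[1, 0, 0] + wz1 * c[1, 0, 1]) + wy1 * (wz0 * c[1, 1, 0] + wz1 * c[1, 1, 1]))
    )

    def bwd(g):
        dx = (
            wy0 * (wz0 * (c[1, 0, 0] - c[0, 0, 0]) + wz1 * (c[1, 0, 1] - c[0, 0, 1]))
            + wy1 * (wz0 * (c[1, 1, 0] - c[0, 1, 0]) + wz1 * (c[1, 1, 1] - c[0, 1, 1]))
        )
        dy = (
            wx0 * (wz0 * (c[0, 1, 0] - c[0, 0, 0]) + wz1 * (c[0, 1, 1] - c[0, 0, 1]))
            + wx1 * (wz0 * (c[1, 1, 0] - c[1, 0, 0]) + wz1 * (c[1, 1, 1] - c[1, 0, 1]))
        )
        dz = (
            wx0 * (wy0 * (c[0, 0, 1] - c[0, 0, 0]) + wy1 * (c[0, 1, 1] - c[0, 1, 0]))
            + wx1 * (wy0 * (c[1, 0, 1] - c[1, 0, 0]) + wy1 * (c[1, 1, 1] - c[1, 1, 0]))
        )
        u._accum(np.stack([g * dx, g * dy, g * dz]) * inside)

    return Tensor._result(val, (u,), bwd)


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-4,
                 betas: Tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = [p for p in params if p.requires_grad]
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
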