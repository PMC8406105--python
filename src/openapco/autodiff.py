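"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied
to it; :meth:`Tensor.backward` walks the tape in reverse topological order
and accumulates gradients. The op set is exactly what the stroke-volume
network needs: broadcast arithmetic, batched matmul, ReLU, exp/log/sqrt,
axis reductions, reshaping/transposition/concatenation, 1-D convolution
and average pooling (im2col-based, with stride and dilation), and a
numerically shifted softmax. Gradient correctness is pinned down by
central-difference checks in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "conv1d", "avg_pool1d", "softmax", "concat",
           "default_dtype", "set_default_dtype"]

_DTYPE = np.float32  # float32 keeps CPU training fast; switchable for
                     # high-precision work such as numerical gradient checks


def default_dtype():
    return _DTYPE


def set_default_dtype(dt) -> None:
    global _DTYPE
    _DTYPE = np.dtype(dt).type


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _make(data, prev, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in prev):
            out.requires_grad = True
            out._prev = tuple(p for p in prev if p.requires_grad)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return self._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, p: float):
        out_data = self.data**p

        def backward(g):
            self._accum(g * p * self.data ** (p - 1))

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        return self._make(out_data, (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accum(g * mask)

        return self._make(self.data * mask, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            self._accum(g * 0.5 / out_data)

        return self._make(out_data, (self,), backward)

    # -- reductions / reshaping ----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            gg = np.asarray(g)
            if not keepdims and axis is not None:
                axes = (axis,) if isinstance(axis, int) else tuple(axis)
                for ax in sorted(a % self.data.ndim for a in axes):
                    gg = np.expand_dims(gg, ax)
            self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def backward(g):
            self._accum(g.reshape(old))

        return self._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            self._accum(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, key):
        out_data = self.data[key]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            self._accum(full)

        return self._make(out_data, (self,), backward)

    # -- autodiff engine -------------------------------------------------------
    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype)
        else:
            self.grad += g

    def backward(self, grad=None) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = (
            np.ones_like(self.data)
            if grad is None
            else np.asarray(grad, dtype=self.data.dtype)
        )
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None


# ---------------------------------------------------------------------------
# composite / structural ops


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), backward)


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax (shift by a detached max)."""
    shift = np.max(t.data, axis=axis, keepdims=True)
    e = (t - Tensor(shift)).exp()
    return e / e.sum(axis=axis, keepdims=True)


def _window_view(
    xp: np.ndarray, K: int, stride: int, dilation: int
) -> tuple[np.ndarray, int]:
    """Strided (copy-free) window view [N, C, L_out, K] of a padded signal."""
    keff = (K - 1) * dilation + 1
    Lp = xp.shape[-1]
    L_out = (Lp - keff) // stride + 1
    if L_out <= 0:
        raise ValueError(f"window (k={K}, d={dilation}) longer than input {Lp}")
    win = np.lib.stride_tricks.sliding_window_view(xp, keff, axis=-1)
    return win[:, :, :: stride if stride > 1 else 1, :: dilation if dilation > 1 else 1][
        :, :, :L_out, :K
    ], L_out


def _scatter_windows(
    shape: tuple[int, ...], g_win: np.ndarray, K: int, stride: int, dilation: int
) -> np.ndarray:
    """Adjoint of `_window_view`: scatter-add window grads [N,C,L_out,K]."""
    out = np.zeros(shape, dtype=g_win.dtype)
    L_out = g_win.shape[2]
    for kk in range(K):  # taps at a fixed offset never overlap across windows
        start = kk * dilation
        out[:, :, start : start + stride * L_out : stride] += g_win[:, :, :, kk]
    return out


def _padding_1d(padding: str | int, keff: int) -> tuple[int, int]:
    if padding == "same":
        pl = (keff - 1) // 2
        return pl, keff - 1 - pl
    return int(padding), int(padding)


def conv1d(
    x: Tensor,
    w: Tensor,
    b: Tensor | None = None,
    stride: int = 1,
    dilation: int = 1,
    padding: str | int = "same",
) -> Tensor:
    """1-D convolution (cross-correlation): x [N,C,L], w [F,C,K] -> [N,F,L'].

    ``padding='same'`` keeps the temporal length at stride 1; integer
    padding pads both ends. With stride > 1, L' = floor((L+2p-K_eff)/s)+1.
    """
    N, C, L = x.data.shape
    F, C2, K = w.data.shape
    if C != C2:
        raise ValueError(f"channel mismatch: input {C}, kernel {C2}")
    keff = (K - 1) * dilation + 1
    pad = _padding_1d(padding, keff)
    if pad[0] or pad[1]:
        xp = np.zeros((N, C, L + pad[0] + pad[1]), dtype=x.data.dtype)
        xp[:, :, pad[0] : pad[0] + L] = x.data
    else:
        xp = x.data
    cols, L_out = _window_view(xp, K, stride, dilation)  # [N, C, L_out, K] view
    if K == 1:
        out_data = np.einsum("fc,ncl->nfl", w.data[:, :, 0], cols[..., 0])
    else:
        out_data = np.einsum("fck,nclk->nfl", w.data, cols, optimize=True)
    if b is not None:
        out_data += b.data[None, :, None]

    def backward(g):
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2)))
        if w.requires_grad:
            w._accum(np.einsum("nfl,nclk->fck", g, cols, optimize=True))
        if x.requires_grad:
            dcols = np.einsum("fck,nfl->nclk", w.data, g, optimize=True)
            dxp = _scatter_windows(xp.shape, dcols, K, stride, dilation)
            x._accum(
                dxp[:, :, pad[0] : pad[0] + L] if (pad[0] or pad[1]) else dxp
            )

    prev = (x, w) if b is None else (x, w, b)
    return Tensor._make(out_data, prev, backward)


def avg_pool1d(
    x: Tensor, k: int, stride: int | None = None, padding: str | int = 0
) -> Tensor:
    """Average pooling over the last axis; zero padding counts in the mean."""
    stride = stride or k
    N, C, L = x.data.shape
    pad = _padding_1d(padding, k)
    if pad[0] or pad[1]:
        xp = np.zeros((N, C, L + pad[0] + pad[1]), dtype=x.data.dtype)
        xp[:, :, pad[0] : pad[0] + L] = x.data
    else:
        xp = x.data
    win, L_out = _window_view(xp, k, stride, 1)
    out_data = win.mean(axis=-1)

    def backward(g):
        g_win = np.broadcast_to(g[..., None] / k, g.shape + (k,))
        dxp = _scatter_windows(xp.shape, g_win, k, stride, 1)
        x._accum(dxp[:, :, pad[0] : pad[0] + L] if (pad[0] or pad[1]) else dxp)

    return Tensor._make(out_data, (x,), backward)
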