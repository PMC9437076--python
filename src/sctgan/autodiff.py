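"""Compact reverse-mode automatic differentiation on NumPy arrays.

Provides exactly the operator set the translation networks and their
training losses need: broadcast arithmetic, reductions, strided 2-D
convolution, instance normalisation, the usual activations, nearest
2x upsampling, a uniform ("box") valid-window filter for windowed SSIM,
and bilinear warping of an image through a fixed displacement field.

Gradients follow the standard adjoint rules; every backward pass is a
topological sweep over the recorded graph.  Arrays keep whatever float
dtype they come in with (the network trains in float32; loss unit tests
run in float64).
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "as_tensor", "conv2d", "instance_norm", "leaky_relu",
           "relu", "tanh", "sigmoid", "upsample2x", "box_filter_valid",
           "warp_bilinear", "numeric_grad"]


class Tensor:
    """A NumPy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False,
                 parents: Sequence["Tensor"] = (),
                 backward: Callable[[np.ndarray], None] | None = None):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    # -- bookkeeping ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __float__(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def accumulate(self, g: np.ndarray) -> None:
        g = np.asarray(g, dtype=self.data.dtype)
        if self.grad is None:
            self.grad = g.copy() if g.base is not None or g is self.data else g
        else:
            self.grad = self.grad + g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Reverse sweep from this node; seeds with ones for scalars."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a seed requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs are deep (9 residual blocks)
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.accumulate(np.asarray(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other, like=self)
        out_data = self.data + other.data

        def bwd(g):
            _acc(self, g)
            _acc(other, g)
        return Tensor(out_data, parents=(self, other), backward=bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            _acc(self, -g)
        return Tensor(-self.data, parents=(self,), backward=bwd)

    def __sub__(self, other):
        return self + (-as_tensor(other, like=self))

    def __rsub__(self, other):
        return as_tensor(other, like=self) + (-self)

    def __mul__(self, other):
        other = as_tensor(other, like=self)
        out_data = self.data * other.data

        def bwd(g):
            _acc(self, g * other.data)
            _acc(other, g * self.data)
        return Tensor(out_data, parents=(self, other), backward=bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other, like=self)
        out_data = self.data / other.data

        def bwd(g):
            _acc(self, g / other.data)
            _acc(other, -g * self.data / (other.data * other.data))
        return Tensor(out_data, parents=(self, other), backward=bwd)

    def __rtruediv__(self, other):
        return as_tensor(other, like=self) / self

    def __pow__(self, exponent: float):
        out_data = self.data ** exponent

        def bwd(g):
            _acc(self, g * exponent * self.data ** (exponent - 1))
        return Tensor(out_data, parents=(self,), backward=bwd)

    def abs(self):
        def bwd(g):
            _acc(self, g * np.sign(self.data))
        return Tensor(np.abs(self.data), parents=(self,), backward=bwd)

    # -- reductions ----------------------------------------------------
    def sum(self):
        def bwd(g):
            _acc(self, np.broadcast_to(g, self.data.shape))
        return Tensor(self.data.sum(), parents=(self,), backward=bwd)

    def mean(self):
        n = self.data.size

        def bwd(g):
            _acc(self, np.broadcast_to(g / n, self.data.shape))
        return Tensor(self.data.mean(), parents=(self,), backward=bwd)

    def reshape(self, *shape):
        old = self.data.shape

        def bwd(g):
            _acc(self, g.reshape(old))
        return Tensor(self.data.reshape(*shape), parents=(self,), backward=bwd)

    def __getitem__(self, idx):
        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            _acc(self, full)
        return Tensor(self.data[idx], parents=(self,), backward=bwd)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `g` down to `shape` (adjoint of NumPy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def _acc(t: Tensor, g: np.ndarray) -> None:
    if t.requires_grad or t._parents:
        t.accumulate(_unbroadcast(np.asarray(g), t.data.shape))


def as_tensor(x, like: Tensor | None = None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    dtype = like.data.dtype if like is not None and np.isscalar(x) else None
    return Tensor(np.asarray(x, dtype=dtype))


# ---------------------------------------------------------------------
# neural-network operators
# ---------------------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """Strided 2-D convolution (cross-correlation) with zero padding.

    x: (B, C, H, W); w: (O, C, kh, kw); b: (O,).

    Lowered to one channel-mixing matmul over a tap-concatenated column
    matrix (strided window slices stacked along the channel axis); the
    adjoint scatters the column gradients back through the same taps.
    """
    x = as_tensor(x)
    w = as_tensor(w)
    B, C, H, W = x.shape
    O, Cw, kh, kw = w.shape
    if C != Cw:
        raise ValueError(f"channel mismatch: input {C} vs kernel {Cw}")
    s, p = stride, padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    Ho = (H + 2 * p - kh) // s + 1
    Wo = (W + 2 * p - kw) // s + 1
    parents = (x, w) if b is None else (x, w, b)

    taps = [(i, j) for i in range(kh) for j in range(kw)]
    M = Ho * Wo
    cols = np.empty((B, len(taps) * C, M), dtype=xp.dtype)
    for t, (i, j) in enumerate(taps):
        cols[:, t * C:(t + 1) * C] = \
            xp[:, :, i:i + s * Ho:s, j:j + s * Wo:s].reshape(B, C, M)
    # tap-major weight matrix matching the column layout
    wm = np.ascontiguousarray(w.data.transpose(0, 2, 3, 1)
                              ).reshape(O, len(taps) * C)
    out_flat = wm @ cols                            # (B, O, M)
    if b is not None:
        out_flat += b.data[:, None]
    out = out_flat.reshape(B, O, Ho, Wo)

    def bwd(g):
        gf = np.ascontiguousarray(g).reshape(B, O, M)
        gw_flat = (gf @ cols.transpose(0, 2, 1)).sum(axis=0)
        _acc(w, gw_flat.reshape(O, kh, kw, C).transpose(0, 3, 1, 2))
        if b is not None:
            _acc(b, gf.sum(axis=(0, 2)))
        gcols = wm.T @ gf                           # (B, taps*C, M)
        gxp = np.zeros((B, C, H + 2 * p, W + 2 * p), dtype=g.dtype)
        for t, (i, j) in enumerate(taps):
            gxp[:, :, i:i + s * Ho:s, j:j + s * Wo:s] += \
                gcols[:, t * C:(t + 1) * C].reshape(B, C, Ho, Wo)
        _acc(x, gxp[:, :, p:p + H, p:p + W] if p else gxp)

    return Tensor(out, parents=parents, backward=bwd)


def instance_norm(x: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-sample, per-channel normalisation over the spatial axes."""
    x = as_tensor(x)
    mu = x.data.mean(axis=(2, 3), keepdims=True)
    var = x.data.var(axis=(2, 3), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    y = (x.data - mu) * inv

    def bwd(g):
        gm = g.mean(axis=(2, 3), keepdims=True)
        gym = (g * y).mean(axis=(2, 3), keepdims=True)
        _acc(x, inv * (g - gm - y * gym))

    return Tensor(y, parents=(x,), backward=bwd)


def leaky_relu(x: Tensor, negative_slope: float = 0.2) -> Tensor:
    x = as_tensor(x)
    mask = x.data >= 0
    out = np.where(mask, x.data, negative_slope * x.data)

    def bwd(g):
        _acc(x, np.where(mask, g, negative_slope * g))
    return Tensor(out, parents=(x,), backward=bwd)


def relu(x: Tensor) -> Tensor:
    return leaky_relu(x, 0.0)


def tanh(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = np.tanh(x.data)

    def bwd(g):
        _acc(x, g * (1.0 - out * out))
    return Tensor(out, parents=(x,), backward=bwd)


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = 1.0 / (1.0 + np.exp(-x.data))

    def bwd(g):
        _acc(x, g * out * (1.0 - out))
    return Tensor(out, parents=(x,), backward=bwd)


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour spatial upsampling by a factor of two."""
    x = as_tensor(x)
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)
    B, C, H, W = x.shape

    def bwd(g):
        _acc(x, g.reshape(B, C, H, 2, W, 2).sum(axis=(3, 5)))
    return Tensor(out, parents=(x,), backward=bwd)


def box_filter_valid(x: Tensor, k: int) -> Tensor:
    """Uniform k x k windowed mean of a 2-D image, 'valid' positions only.

    Adjoint: each output window spreads its gradient uniformly back over
    the k x k inputs it covered.
    """
    x = as_tensor(x)
    if x.ndim != 2:
        raise ValueError("box_filter_valid expects a 2-D image")
    H, W = x.shape
    if H < k or W < k:
        raise ValueError(f"image {x.shape} smaller than window {k}")
    win = np.lib.stride_tricks.sliding_window_view(x.data, (k, k))
    out = win.mean(axis=(2, 3))

    def bwd(g):
        gx = np.zeros((H, W), dtype=g.dtype)
        gk = g / (k * k)
        for i in range(k):
            for j in range(k):
                gx[i:i + g.shape[0], j:j + g.shape[1]] += gk
        _acc(x, gx)

    return Tensor(out, parents=(x,), backward=bwd)


def warp_bilinear(img: Tensor, flow: np.ndarray) -> Tensor:
    """Backward-sampling warp: out(p) = img(p + flow(p)), bilinear.

    `flow` is a fixed (H, W, 2) displacement field in (row, col) pixel
    units; it is data, not a differentiable input.  Out-of-bounds sample
    coordinates are clamped (border replication), so warping never
    invents values outside [img.min(), img.max()].  A zero flow is the
    bit-exact identity.
    """
    img = as_tensor(img)
    flow = np.asarray(flow)
    if img.ndim != 2:
        raise ValueError("warp_bilinear expects a 2-D image")
    if flow.shape != img.shape + (2,):
        raise ValueError(f"flow shape {flow.shape} does not match image "
                         f"{img.shape}")
    if not np.all(np.isfinite(flow)):
        raise ValueError("flow contains non-finite displacements")
    H, W = img.shape
    rr, cc = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    r = np.clip(rr + flow[..., 0], 0, H - 1)
    c = np.clip(cc + flow[..., 1], 0, W - 1)
    r0 = np.floor(r).astype(np.intp)
    c0 = np.floor(c).astype(np.intp)
    r1 = np.minimum(r0 + 1, H - 1)
    c1 = np.minimum(c0 + 1, W - 1)
    wr = (r - r0).astype(img.data.dtype)
    wc = (c - c0).astype(img.data.dtype)
    w00 = (1 - wr) * (1 - wc)
    w01 = (1 - wr) * wc
    w10 = wr * (1 - wc)
    w11 = wr * wc
    d = img.data
    out = (w00 * d[r0, c0] + w01 * d[r0, c1]
           + w10 * d[r1, c0] + w11 * d[r1, c1])

    def bwd(g):
        gx = np.zeros_like(d)
        np.add.at(gx, (r0, c0), g * w00)
        np.add.at(gx, (r0, c1), g * w01)
        np.add.at(gx, (r1, c0), g * w10)
        np.add.at(gx, (r1, c1), g * w11)
        _acc(img, gx)

    return Tensor(out, parents=(img,), backward=bwd)


# ---------------------------------------------------------------------
# testing aid
# ---------------------------------------------------------------------

def numeric_grad(f: Callable[[np.ndarray], float], x: np.ndarray,
                 eps: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of a scalar function, for unit tests."""
    x = np.asarray(x, dtype=np.float64)
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        xp = x.copy(); xp[i] += eps
        xm = x.copy(); xm[i] -= eps
        g[i] = (f(xp) - f(xm)) / (2 * eps)
        it.iternext()
    return g
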