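"""Dense interslice optical flow and backward-sampling warps.

Flow is estimated with Farnebäck's polynomial-expansion method: each
image is locally approximated by a quadratic surface via Gaussian-
weighted least squares (computed with separable correlations), and the
displacement field follows from the shift that maps one expansion onto
the other, refined iteratively over an image pyramid with windowed
averaging of the local normal equations.

Conventions
-----------
``farneback_flow(a, b)`` returns the displacement d with
``a(p) ≈ b(p + d(p))``, so ``warp(b, d) ≈ a``.  The cached field
``f_{n,k}`` is therefore the one that, applied to slice ``n`` by
backward sampling, reconstructs neighbour ``k``:
``f_{n,k} = farneback_flow(slice_k, slice_n)``.  Displacements are in
(row, col) pixel units.

Flow is always computed ahead of training on ground-truth slices,
rescaled pairwise to an 8-bit-like [0, 255] display range; it is never
re-estimated on synthesized images.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import autodiff as ad
from .config import DegenerateInputError, FlowParams, StructuralError

__all__ = ["FlowField", "FlowCache", "farneback_flow", "warp",
           "build_flow_cache", "save_flow_cache", "load_flow_cache"]


@dataclass
class FlowField:
    """Per-pixel 2-D displacement between a slice and one axial neighbour."""

    displacements: np.ndarray      # (H, W, 2), (row, col) pixel units
    direction: str                 # {"to_prev", "to_next"}
    source_index: int

    def __post_init__(self):
        self.displacements = np.asarray(self.displacements, dtype=np.float64)
        if self.displacements.ndim != 3 or self.displacements.shape[2] != 2:
            raise StructuralError("displacements must have shape (H, W, 2)")
        if self.direction not in ("to_prev", "to_next"):
            raise StructuralError(f"bad flow direction {self.direction!r}")
        if not np.all(np.isfinite(self.displacements)):
            raise StructuralError("flow field contains non-finite values")


@dataclass
class FlowCache:
    """All interslice flows of one volume, keyed by slice index.

    Slice 0 carries only ``to_next``; the last slice only ``to_prev``;
    interior slices both.
    """

    fields: dict[int, dict[str, FlowField]] = field(default_factory=dict)

    @property
    def n_fields(self) -> int:
        return sum(len(v) for v in self.fields.values())

    def get(self, index: int, direction: str) -> FlowField | None:
        return self.fields.get(index, {}).get(direction)


# ---------------------------------------------------------------------
# polynomial expansion
# ---------------------------------------------------------------------

def _poly_expand(img: np.ndarray, n: int, sigma: float):
    """Quadratic expansion f(p+x) ≈ c + b^T x + x^T A x at every pixel.

    Returns (A, b): A is (H, W, 2, 2), b is (H, W, 2).  Solved by
    weighted least squares in the basis (1, i, j, i^2, j^2, ij) with a
    Gaussian applicability of half-width ``n``; the Gram matrix is
    constant over the image, so only six separable correlations and one
    6x6 solve are needed.
    """
    t = np.arange(-n, n + 1, dtype=np.float64)
    a = np.exp(-(t * t) / (2.0 * sigma * sigma))
    k0, k1, k2 = a, a * t, a * t * t

    def corr(f, krow, kcol):
        out = ndimage.correlate1d(f, krow, axis=0, mode="nearest")
        return ndimage.correlate1d(out, kcol, axis=1, mode="nearest")

    f = img.astype(np.float64)
    v = np.stack([
        corr(f, k0, k0),   # 1
        corr(f, k1, k0),   # i
        corr(f, k0, k1),   # j
        corr(f, k2, k0),   # i^2
        corr(f, k0, k2),   # j^2
        corr(f, k1, k1),   # ij
    ], axis=-1)

    s0, s2, s4 = a.sum(), (a * t * t).sum(), (a * t ** 4).sum()
    G = np.array([
        [s0 * s0, 0, 0, s2 * s0, s0 * s2, 0],
        [0, s2 * s0, 0, 0, 0, 0],
        [0, 0, s0 * s2, 0, 0, 0],
        [s2 * s0, 0, 0, s4 * s0, s2 * s2, 0],
        [s0 * s2, 0, 0, s2 * s2, s0 * s4, 0],
        [0, 0, 0, 0, 0, s2 * s2],
    ])
    r = v @ np.linalg.inv(G).T
    b = np.stack([r[..., 1], r[..., 2]], axis=-1)
    A = np.empty(img.shape + (2, 2))
    A[..., 0, 0] = r[..., 3]
    A[..., 1, 1] = r[..., 4]
    A[..., 0, 1] = A[..., 1, 0] = r[..., 5] / 2.0
    return A, b


def _warp_field(f: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Sample scalar field f at p + d(p) with bilinear border-replicate."""
    return ad.warp_bilinear(ad.Tensor(f), d).data


def _flow_iteration(A1, b1, A2, b2, d, win: int) -> np.ndarray:
    """One fixed-point displacement update with windowed averaging."""
    A2w = np.stack([_warp_field(A2[..., i, j], d)
                    for i in range(2) for j in range(2)],
                   axis=-1).reshape(A2.shape)
    b2w = np.stack([_warp_field(b2[..., i], d) for i in range(2)], axis=-1)
    A = 0.5 * (A1 + A2w)
    # h = A d~ - (b2 - b1)/2 ; then d = (sum_w A^T A)^-1 (sum_w A^T h)
    h = np.einsum("...ij,...j->...i", A, d) - 0.5 * (b2w - b1)
    ATA = np.einsum("...ki,...kj->...ij", A, A)
    ATh = np.einsum("...ki,...k->...i", A, h)
    for i in range(2):
        for j in range(2):
            ATA[..., i, j] = ndimage.uniform_filter(ATA[..., i, j], win,
                                                    mode="nearest")
        ATh[..., i] = ndimage.uniform_filter(ATh[..., i], win,
                                             mode="nearest")
    ATA[..., 0, 0] += 1e-6
    ATA[..., 1, 1] += 1e-6
    return np.linalg.solve(ATA, ATh[..., None])[..., 0]


def _downscale(img: np.ndarray) -> np.ndarray:
    sm = ndimage.gaussian_filter(img, 1.0, mode="nearest")
    return sm[::2, ::2]


def _upscale_flow(d: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    out = np.zeros(shape + (2,))
    for i in range(2):
        zoomed = np.kron(d[..., i], np.ones((2, 2)))
        out[..., i] = zoomed[:shape[0], :shape[1]] * 2.0
    return out


def farneback_flow(slice_a: np.ndarray, slice_b: np.ndarray,
                   params: FlowParams = FlowParams()) -> FlowField:
    """Dense displacement d with slice_a(p) ≈ slice_b(p + d(p)).

    The pair is first rescaled jointly to [0, 255] (8-bit display
    range) so the estimate is independent of the stored intensity
    scale; estimation then runs coarse-to-fine over ``pyr_levels``
    halvings with ``iterations`` fixed-point updates per level.
    """
    a = np.asarray(slice_a, dtype=np.float64)
    b = np.asarray(slice_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 2:
        raise StructuralError(f"flow inputs must be equal-shape 2-D images; "
                              f"got {a.shape} and {b.shape}")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if hi > lo:
        a = (a - lo) * (255.0 / (hi - lo))
        b = (b - lo) * (255.0 / (hi - lo))
    else:                       # constant pair: no texture, no motion
        a = np.zeros_like(a)
        b = np.zeros_like(b)

    pyr_a, pyr_b = [a], [b]
    for _ in range(params.pyr_levels - 1):
        if min(pyr_a[-1].shape) // 2 < 2 * params.poly_n + 1:
            break
        pyr_a.append(_downscale(pyr_a[-1]))
        pyr_b.append(_downscale(pyr_b[-1]))

    d = np.zeros(pyr_a[-1].shape + (2,))
    for la, lb in zip(reversed(pyr_a), reversed(pyr_b)):
        if d.shape[:2] != la.shape:
            d = _upscale_flow(d, la.shape)
        A1, b1 = _poly_expand(la, params.poly_n, params.poly_sigma)
        A2, b2 = _poly_expand(lb, params.poly_n, params.poly_sigma)
        win = max(3, min(params.win_size, min(la.shape)))
        for _ in range(params.iterations):
            d = _flow_iteration(A1, b1, A2, b2, d, win)
    return FlowField(displacements=d, direction="to_next", source_index=0)


def warp(img, flow: FlowField | np.ndarray) -> np.ndarray:
    """Backward-sampling warp out(p) = img(p + flow(p)), bilinear.

    Zero flow is the bit-exact identity; border replication plus
    bilinear convexity keep outputs within [img.min(), img.max()].
    """
    d = flow.displacements if isinstance(flow, FlowField) else \
        np.asarray(flow)
    arr = np.asarray(img, dtype=np.float64)
    if d.shape != arr.shape + (2,):
        raise StructuralError(f"flow shape {d.shape} does not match image "
                              f"{arr.shape}")
    if not np.all(np.isfinite(d)):
        raise StructuralError("flow contains non-finite displacements")
    return ad.warp_bilinear(ad.Tensor(arr), d).data


def build_flow_cache(slices: np.ndarray,
                     params: FlowParams = FlowParams()) -> FlowCache:
    """Flows between every adjacent slice pair of one volume.

    ``slices`` is (Z, H, W) (a NormalizedVolume's slice stack is used
    directly).  For slice n the cache stores f_{n,n-1} ("to_prev") and
    f_{n,n+1} ("to_next") such that warping slice n through the field
    reconstructs the neighbour.
    """
    vol = np.asarray(getattr(slices, "slices", slices))
    if vol.ndim != 3:
        raise StructuralError("build_flow_cache expects a (Z, H, W) stack")
    Z = vol.shape[0]
    if Z < 2:
        raise DegenerateInputError("flow cache needs at least 2 slices")
    cache = FlowCache()
    for n in range(Z):
        entry: dict[str, FlowField] = {}
        if n > 0:
            f = farneback_flow(vol[n - 1], vol[n], params)
            entry["to_prev"] = FlowField(f.displacements, "to_prev", n)
        if n < Z - 1:
            f = farneback_flow(vol[n + 1], vol[n], params)
            entry["to_next"] = FlowField(f.displacements, "to_next", n)
        cache.fields[n] = entry
    return cache


def save_flow_cache(cache: FlowCache, path: str | Path) -> None:
    """Serialise as one compressed archive, keyed ``flow_{n}_{prev|next}``."""
    arrays = {}
    for n, entry in cache.fields.items():
        for direction, f in entry.items():
            arrays[f"flow_{n}_{direction.removeprefix('to_')}"] = \
                f.displacements
    np.savez_compressed(path, **arrays)


def load_flow_cache(path: str | Path) -> FlowCache:
    cache = FlowCache()
    with np.load(path) as data:
        for key in data.files:
            _, n, short = key.split("_")
            direction = f"to_{short}"
            cache.fields.setdefault(int(n), {})[direction] = FlowField(
                data[key], direction, int(n))
    return cache
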