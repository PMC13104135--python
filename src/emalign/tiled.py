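"""Hierarchical patch-wise elastic registration for very large slices.

Slices too large to register whole are partitioned into overlapping
patches (default 1024 px with 128 px overlap); the elastic filtering step
runs independently on each patch footprint (the same footprint across the
z-neighborhood, so each patch sees consistent content), and the per-patch
displacement fields are fused into one global field by spatially weighted
averaging with raised-cosine feather windows normalized to a partition of
unity.  The full-resolution slice is then warped exactly once by the
fused field, so a single-patch grid degenerates bit-identically to the
whole-image pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .elastic import (ElasticResult, GaussianKernel1D, _default_flow_fn,
                      _slice_field, gaussian_kernel_1d)
from .flow import FlowParams, warp
from .stack import SliceStack, as_stack_array

logger = logging.getLogger("emalign.tiled")

__all__ = ["PatchGrid", "partition_patches", "fuse_fields", "register_large_stack"]


@dataclass
class PatchGrid:
    """Overlapping-patch partition of an image plane.

    ``origins`` holds each patch's (row0, col0); all patches share the size
    ``(patch_h, patch_w)``.  ``windows`` are the per-patch fusion weights,
    normalized so they sum to one at every pixel of the image.
    """

    height: int
    width: int
    patch_h: int
    patch_w: int
    overlap: int
    origins: list
    windows: list

    def extent(self, k: int) -> tuple:
        r0, c0 = self.origins[k]
        return slice(r0, r0 + self.patch_h), slice(c0, c0 + self.patch_w)

    def __len__(self) -> int:
        return len(self.origins)


def _axis_origins(size: int, patch: int, stride: int) -> list:
    if patch >= size:
        return [0]
    origins = list(range(0, size - patch + 1, stride))
    if origins[-1] + patch < size:
        origins.append(size - patch)   # clamp the last patch into bounds
    return origins


def _feather_profile(length: int, ramp: int, ramp_lo: bool, ramp_hi: bool) -> np.ndarray:
    """Separable raised-cosine feather: 1 in the core, cosine ramps over the
    overlap margins that face a neighboring patch."""
    w = np.ones(length)
    ramp = min(ramp, length)
    if ramp > 0:
        ramp_vals = 0.5 - 0.5 * np.cos(np.pi * (np.arange(ramp) + 0.5) / ramp)
        if ramp_lo:
            w[:ramp] = ramp_vals
        if ramp_hi:
            w[-ramp:] = np.minimum(w[-ramp:], ramp_vals[::-1])
    return w


def partition_patches(height: int, width: int, patch: int = 1024,
                      overlap: int = 128) -> PatchGrid:
    """Partition an image plane into overlapping patches at stride
    ``patch - overlap``; the last row/column of patches is clamped into
    bounds so every pixel is covered.  An image smaller than ``patch``
    yields a single patch covering it."""
    if not patch > overlap >= 0:
        raise ValueError("need patch > overlap >= 0")
    stride = patch - overlap
    ph, pw = min(patch, height), min(patch, width)
    rows = _axis_origins(height, ph, stride)
    cols = _axis_origins(width, pw, stride)
    origins = [(r, c) for r in rows for c in cols]

    raw = []
    for r0, c0 in origins:
        wr = _feather_profile(ph, overlap, ramp_lo=r0 > 0, ramp_hi=r0 + ph < height)
        wc = _feather_profile(pw, overlap, ramp_lo=c0 > 0, ramp_hi=c0 + pw < width)
        raw.append(np.outer(wr, wc))

    # Normalize to an exact partition of unity.
    acc = np.zeros((height, width))
    for (r0, c0), w in zip(origins, raw):
        acc[r0:r0 + ph, c0:c0 + pw] += w
    windows = [w / acc[r0:r0 + ph, c0:c0 + pw]
               for (r0, c0), w in zip(origins, raw)]
    return PatchGrid(height, width, ph, pw, overlap, origins, windows)


def fuse_fields(grid: PatchGrid, patch_fields) -> np.ndarray:
    """Fuse per-patch displacement fields into one global field by the
    grid's partition-of-unity feather windows."""
    patch_fields = list(patch_fields)
    if len(patch_fields) != len(grid):
        raise ValueError(f"expected {len(grid)} patch fields, got {len(patch_fields)}")
    out = np.zeros((2, grid.height, grid.width))
    for k, f in enumerate(patch_fields):
        f = np.asarray(f, dtype=np.float64)
        if f.shape != (2, grid.patch_h, grid.patch_w):
            raise ValueError(
                f"patch field {k} has shape {f.shape}, expected "
                f"{(2, grid.patch_h, grid.patch_w)}")
        rs, cs = grid.extent(k)
        out[:, rs, cs] += grid.windows[k] * f
    return out


def register_large_stack(stack, patch: int = 1024, overlap: int = 128,
                         kernel: GaussianKernel1D | None = None,
                         flow_params: FlowParams | None = None,
                         sweeps: int = 1, flow_fn=None,
                         boundary: str = "one-sided") -> ElasticResult:
    """Patch-wise elastic registration of a stack of large slices.

    Per slice, the Gaussian-filter registration step runs on every patch
    footprint of its z-neighborhood, the patch fields are fused into one
    global field, and the original full-resolution slice is warped once.
    Semantics (Jacobi sweeps, boundary handling) match
    :func:`emalign.elastic.register_stack_elastic`, to which this reduces
    bit-identically when a single patch covers the image.
    """
    kernel = kernel or gaussian_kernel_1d(1, 1.0)
    if kernel.radius != 1:
        raise ValueError("patch registration supports kernel radius 1 only")
    if boundary not in ("one-sided", "fixed"):
        raise ValueError("boundary must be 'one-sided' or 'fixed'")
    data = as_stack_array(stack).copy()
    n, h, w = data.shape
    if n < 3:
        raise ValueError("need at least 3 slices for elastic registration")
    flow_fn = flow_fn or _default_flow_fn(flow_params)
    grid = partition_patches(h, w, patch, overlap)
    logger.info("tiled registration: %d patches of %dx%d (overlap %d)",
                len(grid), grid.patch_h, grid.patch_w, overlap)

    fields = np.zeros((n, 2, h, w))
    for _ in range(sweeps):
        frozen = data.copy()
        for i in range(n):
            patch_fields = []
            for k in range(len(grid)):
                rs, cs = grid.extent(k)
                lo, hi = max(0, i - 1), min(n, i + 2)
                block = frozen[lo:hi, rs, cs]
                phi, _ = _slice_field(block, i - lo, kernel, flow_fn, boundary)
                patch_fields.append(phi)
            phi = fuse_fields(grid, patch_fields)
            fields[i] = phi
            if np.any(phi):
                data[i] = warp(frozen[i], phi)
            else:
                data[i] = frozen[i]

    out = stack.with_data(data) if isinstance(stack, SliceStack) else data
    return ElasticResult(stack=out, fields=fields, intermediates=[])
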