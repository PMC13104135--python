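"""Dense displacement-field estimation and field algebra.

A displacement field is a ``(2, H, W)`` float array in the backward-warp
convention: channel 0 holds row displacements, channel 1 column
displacements, and ``warp(image, field)`` samples ``image`` at
``p + field(p)`` for every output pixel ``p``.  All field arithmetic used
by the elastic stage (scaling, weighted combination) is plain elementwise
algebra on these arrays.

The estimator is a classical coarse-to-fine scheme: a Gaussian image
pyramid, a linearized brightness-constancy solve with a quadratic
smoothness penalty at each level (Horn–Schunck iterations), and
upsample-and-refine with a few outer warping iterations per level.  It is
deliberately pluggable — any callable ``flow_fn(fixed, moving) -> field``
honoring the same contract (e.g. a learned estimator) can be substituted
wherever a flow function is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import pyramid_reduce, resize

__all__ = [
    "FlowParams",
    "warp",
    "scale_field",
    "combine_fields",
    "estimate_flow",
    "oracle_flow",
]

# Weighted 8-neighbor average used by the Horn–Schunck update.
_HS_KERNEL = np.array(
    [[1 / 12, 1 / 6, 1 / 12],
     [1 / 6, 0.0, 1 / 6],
     [1 / 12, 1 / 6, 1 / 12]],
    dtype=np.float32,
)


@dataclass
class FlowParams:
    """Tuning knobs of the coarse-to-fine estimator.

    levels : pyramid depth; ``None`` picks the deepest pyramid whose
        coarsest level is still at least ``min_level_size`` pixels.
    outer_iters : warping (re-linearization) iterations per level.
    inner_iters : Horn–Schunck relaxation sweeps per linearization.
    smoothness : quadratic smoothness weight (lambda); larger values give
        smoother fields. Expressed for images scaled to [0, 1].
    """

    levels: int | None = None
    outer_iters: int = 3
    inner_iters: int = 50
    smoothness: float = 0.01
    min_level_size: int = 32

    def __post_init__(self) -> None:
        if self.levels is not None and self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.outer_iters < 1:
            raise ValueError("outer_iters must be >= 1")
        if self.inner_iters < 1:
            raise ValueError("inner_iters must be >= 1")
        if self.smoothness <= 0:
            raise ValueError("smoothness must be > 0")


def _check_field(field: np.ndarray) -> np.ndarray:
    field = np.asarray(field, dtype=np.float64)
    if field.ndim != 3 or field.shape[0] != 2:
        raise ValueError(f"displacement field must have shape (2, H, W), got {field.shape}")
    return field


def warp(image: np.ndarray, field: np.ndarray) -> np.ndarray:
    """Backward-warp ``image`` by ``field``: output(p) = image(p + field(p)).

    Bilinear interpolation, edge-clamped outside the image bounds.
    """
    image = np.asarray(image, dtype=np.float64)
    field = _check_field(field)
    if field.shape[1:] != image.shape:
        raise ValueError(f"field shape {field.shape[1:]} does not match image {image.shape}")
    rows, cols = np.meshgrid(
        np.arange(image.shape[0], dtype=np.float64),
        np.arange(image.shape[1], dtype=np.float64),
        indexing="ij",
    )
    coords = np.stack([rows + field[0], cols + field[1]])
    return ndimage.map_coordinates(image, coords, order=1, mode="nearest")


def scale_field(field: np.ndarray, c: float) -> np.ndarray:
    """Elementwise scaling ``c * field``."""
    return _check_field(field) * float(c)


def combine_fields(fields, weights) -> np.ndarray:
    """Weighted elementwise sum of displacement fields, ``sum_k w_k * field_k``."""
    fields = [_check_field(f) for f in fields]
    weights = np.asarray(weights, dtype=np.float64)
    if len(fields) != weights.size:
        raise ValueError("one weight per field required")
    if not np.all(np.isfinite(weights)):
        raise ValueError("weights must be finite")
    shapes = {f.shape for f in fields}
    if len(shapes) != 1:
        raise ValueError(f"field shape mismatch: {sorted(shapes)}")
    out = np.zeros(fields[0].shape, dtype=np.float64)
    for w, f in zip(weights, fields):
        out += w * f
    return out


def oracle_flow(shape, shift=None, field=None) -> np.ndarray:
    """Exact displacement field for a synthetic fixture with known ground truth.

    Either a constant ``shift = (dr, dc)`` or a full ``field`` may be given;
    this is a test double that bypasses estimation entirely so downstream
    field algebra can be verified independently of estimator error.
    """
    if (shift is None) == (field is None):
        raise ValueError("give exactly one of shift or field")
    if field is not None:
        out = _check_field(field)
        if out.shape[1:] != tuple(shape):
            raise ValueError("field shape does not match requested shape")
        return out.copy()
    dr, dc = float(shift[0]), float(shift[1])
    out = np.empty((2,) + tuple(shape), dtype=np.float64)
    out[0] = dr
    out[1] = dc
    return out


def _warp32(image: np.ndarray, field: np.ndarray) -> np.ndarray:
    rows, cols = np.meshgrid(
        np.arange(image.shape[0], dtype=np.float32),
        np.arange(image.shape[1], dtype=np.float32),
        indexing="ij",
    )
    coords = np.stack([rows + field[0], cols + field[1]])
    return ndimage.map_coordinates(image, coords, order=1, mode="nearest", output=np.float32)


def _hs_refine(fixed: np.ndarray, moving: np.ndarray, field: np.ndarray,
               lam: float, n_inner: int) -> np.ndarray:
    """One linearization + Horn–Schunck relaxation on the total field."""
    warped = _warp32(moving, field)
    avg = 0.5 * (warped + fixed)
    gr, gc = np.gradient(avg)
    # Residual constancy around the current warp point, expressed so the
    # relaxation acts on the *total* field (smoothness applies to it too).
    b = (warped - fixed) - gr * field[0] - gc * field[1]
    denom = lam + gr * gr + gc * gc
    u, v = field[0], field[1]
    for _ in range(n_inner):
        ub = ndimage.convolve(u, _HS_KERNEL, mode="nearest")
        vb = ndimage.convolve(v, _HS_KERNEL, mode="nearest")
        r = (gr * ub + gc * vb + b) / denom
        u = ub - gr * r
        v = vb - gc * r
    return np.stack([u, v])


def estimate_flow(fixed: np.ndarray, moving: np.ndarray,
                  params: FlowParams | None = None) -> np.ndarray:
    """Estimate the backward-warp field aligning ``moving`` onto ``fixed``.

    Returns a field such that ``warp(moving, field)`` approximates
    ``fixed``.  Deterministic given inputs and parameters.
    """
    params = params or FlowParams()
    fixed = np.asarray(fixed, dtype=np.float64)
    moving = np.asarray(moving, dtype=np.float64)
    if fixed.shape != moving.shape:
        raise ValueError("fixed and moving slices must share one shape")
    if fixed.ndim != 2:
        raise ValueError("slices must be 2D grayscale images")
    if min(fixed.shape) < params.min_level_size:
        raise ValueError(
            f"images smaller than min_level_size={params.min_level_size} px"
        )

    if params.levels is None:
        levels = 1
        while min(fixed.shape) / 2 ** levels >= params.min_level_size:
            levels += 1
    else:
        levels = params.levels

    pyr_f = [fixed.astype(np.float32)]
    pyr_m = [moving.astype(np.float32)]
    for _ in range(levels - 1):
        pyr_f.append(pyramid_reduce(pyr_f[-1], downscale=2, preserve_range=True).astype(np.float32))
        pyr_m.append(pyramid_reduce(pyr_m[-1], downscale=2, preserve_range=True).astype(np.float32))

    lam = np.float32(params.smoothness)
    field = np.zeros((2,) + pyr_f[-1].shape, dtype=np.float32)
    for level in range(levels - 1, -1, -1):
        f_l, m_l = pyr_f[level], pyr_m[level]
        if field.shape[1:] != f_l.shape:
            scale_r = f_l.shape[0] / field.shape[1]
            scale_c = f_l.shape[1] / field.shape[2]
            up = np.stack([
                resize(field[0], f_l.shape, order=1, preserve_range=True,
                       anti_aliasing=False),
                resize(field[1], f_l.shape, order=1, preserve_range=True,
                       anti_aliasing=False),
            ]).astype(np.float32)
            up[0] *= scale_r
            up[1] *= scale_c
            field = up
        for _ in range(params.outer_iters):
            field = _hs_refine(f_l, m_l, field, lam, params.inner_iters)
    return field.astype(np.float64)
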