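"""Synthetic serial-section stacks with recorded ground truth.

The generator produces a procedural phantom volume — smooth cell-like
blobs with darker membrane boundaries, axially continuous and slowly
drifting along z to emulate natural biological deformation — and then
degrades it with the standard distortion protocol: slice-interval
subsampling, per-slice rigid jitter, smooth random elastic distortion
scaled by a level ``alpha``, and additive Gaussian noise.  Every
distortion records its exact ground truth (rigid transforms or
displacement fields) so each registration stage can be tested by
parameter recovery, without downloading any real data.

Composition order is fixed: ``slice_volume`` -> ``apply_rigid_jitter`` ->
``apply_elastic_distortion`` -> ``add_gaussian_noise`` (ideal stack first,
then degradations).  All generators are bit-reproducible given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .flow import warp
from .rigid import RigidTransform, apply_rigid
from .stack import SliceStack, as_stack_array

__all__ = [
    "DistortionGroundTruth",
    "generate_phantom",
    "slice_volume",
    "apply_rigid_jitter",
    "apply_elastic_distortion",
    "add_gaussian_noise",
    "make_translation_stack",
]

#: Base elastic-distortion amplitude in pixels; the distortion level
#: ``alpha`` scales it, so alpha=1.0 means an 8 px peak displacement.
DEFAULT_A0 = 8.0


@dataclass
class DistortionGroundTruth:
    """Exact record of an injected distortion.

    ``transforms`` holds the per-slice true rigid transform (rigid jitter)
    and ``fields`` the per-slice true displacement field (elastic
    distortion); whichever does not apply is ``None``.
    """

    transforms: list | None = None
    fields: np.ndarray | None = None
    noise_sigma: float = 0.0
    interval: int = 1
    alpha: float = 0.0


def generate_phantom(shape=(32, 256, 256), n_structures: int | None = None,
                     seed: int = 0, drift_px: float = 2.5) -> np.ndarray:
    """Deterministic phantom volume of cell-like blobs with dark membranes.

    Each structure is an anisotropic Gaussian bump elongated along z; the
    summed bump field is turned into bright interiors bounded by dark
    membrane shells at its level set.  Two 3D texture components are
    added: a smooth medium-scale texture and a dense fine-scale
    granularity, emulating the stain granularity that fills real EM
    micrographs (this density is what makes misregistration residuals
    noise-like, the regime the difference-filtering quality metric
    targets).  Structure centers drift slowly and smoothly along z (a few
    pixels over the whole depth), emulating natural low-frequency
    deformation; ``drift_px`` bounds the drift amplitude (0 disables it,
    giving a laterally static volume).

    ``n_structures=None`` scales the count with the slice area;
    ``n_structures=0`` returns a constant background volume.
    """
    z, y, x = shape
    if z < 16 or y < 64 or x < 64:
        raise ValueError(f"shape must be at least (16, 64, 64), got {shape}")
    if n_structures is None:
        n_structures = max(8, int(round(40 * (y / 256.0) * (x / 256.0))))
    if n_structures < 0:
        raise ValueError("n_structures must be >= 0")

    background = 0.40
    if n_structures == 0:
        return np.full(shape, background)

    rng = np.random.default_rng(seed)
    zz = np.arange(z, dtype=np.float64)[:, None, None]
    yy = np.arange(y, dtype=np.float64)[None, :, None]
    xx = np.arange(x, dtype=np.float64)[None, None, :]

    field = np.zeros(shape)
    for _ in range(n_structures):
        cz = rng.uniform(0, z)
        cy = rng.uniform(0.05 * y, 0.95 * y)
        cx = rng.uniform(0.05 * x, 0.95 * x)
        rz = rng.uniform(0.3 * z, 0.7 * z)
        ry = rng.uniform(0.06, 0.16) * min(y, x)
        rx = rng.uniform(0.06, 0.16) * min(y, x)
        # Smooth per-plane drift of the center: natural axial deformation.
        amp_y, amp_x = rng.uniform(0, drift_px, size=2)
        ph_y, ph_x = rng.uniform(0, 2 * np.pi, size=2)
        cy_z = cy + amp_y * np.sin(2 * np.pi * zz / z + ph_y)
        cx_z = cx + amp_x * np.sin(2 * np.pi * zz / z + ph_x)
        bump = np.exp(-0.5 * (((zz - cz) / rz) ** 2
                              + ((yy - cy_z) / ry) ** 2
                              + ((xx - cx_z) / rx) ** 2))
        field += bump

    level, w_in, w_mem = 0.5, 0.08, 0.035
    interior = 1.0 / (1.0 + np.exp(-(field - level) / w_in))
    membrane = np.exp(-0.5 * ((field - level) / w_mem) ** 2)
    vol = background + 0.45 * interior - 0.38 * membrane

    texture = rng.standard_normal(shape)
    texture = ndimage.gaussian_filter(texture, (3.0, 2.0, 2.0))
    texture *= 0.05 / max(texture.std(), 1e-12)
    vol += texture

    grain = rng.standard_normal(shape)
    grain = ndimage.gaussian_filter(grain, (1.0, 1.2, 1.2))
    grain *= 0.05 / max(grain.std(), 1e-12)
    vol += grain
    return np.clip(vol, 0.0, 1.0)


def slice_volume(vol: np.ndarray, interval: int = 1) -> SliceStack:
    """Take every ``interval``-th z-plane of a phantom volume as a stack.

    Larger intervals mean stronger natural slice-to-slice change.
    """
    vol = np.asarray(vol, dtype=np.float64)
    if vol.ndim != 3:
        raise ValueError("volume must be 3D (z, y, x)")
    k = int(interval)
    if k < 1:
        raise ValueError("interval must be >= 1")
    if k >= vol.shape[0]:
        raise ValueError(f"interval {k} >= volume depth {vol.shape[0]}")
    return SliceStack(vol[::k].copy())


def apply_rigid_jitter(stack, t_max: float = 100.0, theta_max: float = 35.0,
                       seed: int = 0):
    """Apply independent random rigid transforms to slices 1..n-1.

    Per jittered slice, translation components are drawn uniformly from
    ``[0, t_max]`` px and the rotation angle from ``[-theta_max,
    theta_max]`` degrees, about the image center; slice 0 is untouched.
    Each slice is resampled once with bilinear interpolation (edge clamp).

    Returns ``(jittered_stack, ground_truth)`` where the ground truth
    records the true per-slice transform (identity for slice 0).
    """
    if t_max < 0 or theta_max < 0:
        raise ValueError("t_max and theta_max must be non-negative")
    data = as_stack_array(stack)
    rng = np.random.default_rng(seed)
    center = ((data.shape[1] - 1) / 2.0, (data.shape[2] - 1) / 2.0)
    out = data.copy()
    transforms = [RigidTransform.identity(center)]
    for i in range(1, data.shape[0]):
        theta = rng.uniform(-theta_max, theta_max)
        tr = rng.uniform(0.0, t_max)
        tc = rng.uniform(0.0, t_max)
        T = RigidTransform(theta, (tr, tc), center)
        transforms.append(T)
        if theta != 0.0 or tr != 0.0 or tc != 0.0:
            out[i] = apply_rigid(data[i], T)
    gt = DistortionGroundTruth(transforms=transforms)
    result = stack.with_data(out) if isinstance(stack, SliceStack) else out
    return result, gt


def apply_elastic_distortion(stack, alpha: float = 1.0, sigma_d: float = 24.0,
                             a0: float = DEFAULT_A0, seed: int = 0):
    """Warp slices 1..n-1 by independent smooth random displacement fields.

    Each field is spatially smoothed white noise (Gaussian sigma
    ``sigma_d`` px) rescaled so its maximum displacement magnitude equals
    ``alpha * a0`` pixels.  Slice 0 stays untouched; the exact fields are
    recorded as ground truth (warping a distorted slice by the negated
    field approximately restores the original in the small-deformation
    regime).
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if sigma_d <= 0:
        raise ValueError("sigma_d must be > 0")
    data = as_stack_array(stack)
    rng = np.random.default_rng(seed)
    n, h, w = data.shape
    fields = np.zeros((n, 2, h, w))
    out = data.copy()
    target = alpha * a0
    for i in range(1, n):
        f = rng.standard_normal((2, h, w))
        f[0] = ndimage.gaussian_filter(f[0], sigma_d)
        f[1] = ndimage.gaussian_filter(f[1], sigma_d)
        mag = np.sqrt(f[0] ** 2 + f[1] ** 2).max()
        if target > 0 and mag > 0:
            f *= target / mag
        else:
            f[:] = 0.0
        fields[i] = f
        if target > 0:
            out[i] = warp(data[i], f)
    gt = DistortionGroundTruth(fields=fields, alpha=alpha)
    result = stack.with_data(out) if isinstance(stack, SliceStack) else out
    return result, gt


def add_gaussian_noise(stack, sigma: float, seed: int = 0):
    """Add i.i.d. Gaussian noise (gray-value units on [0, 1]), clipped."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    data = as_stack_array(stack)
    if sigma == 0:
        out = data.copy()
    else:
        rng = np.random.default_rng(seed)
        out = np.clip(data + rng.normal(0.0, sigma, size=data.shape), 0.0, 1.0)
    return stack.with_data(out) if isinstance(stack, SliceStack) else out


def make_translation_stack(template: np.ndarray, shifts) -> SliceStack:
    """Stack whose slice i is ``template`` with content shifted by ``shifts[i]``.

    Slice i equals the template backward-warped by the constant field
    ``-u_i`` (edge-clamped), i.e. its content moves by ``u_i = (dr, dc)``.
    This is the oracle fixture for the frequency-decoupling tests of the
    elastic stage, where the true inter-slice flow is known exactly.
    """
    template = np.asarray(template, dtype=np.float64)
    shifts = np.asarray(shifts, dtype=np.float64)
    if shifts.ndim != 2 or shifts.shape[1] != 2:
        raise ValueError("shifts must be a sequence of (dr, dc) pairs")
    if not np.all(np.isfinite(shifts)):
        raise ValueError("shifts must be finite")
    slices = []
    const = np.empty((2,) + template.shape)
    for u in shifts:
        if u[0] == 0.0 and u[1] == 0.0:
            slices.append(template.copy())
            continue
        const[0] = -u[0]
        const[1] = -u[1]
        slices.append(warp(template, const))
    return SliceStack.from_slices(slices)
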