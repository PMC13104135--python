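"""Readers and writers for stacks, rigid transforms and displacement fields.

Stacks are multi-page TIFFs or directories of lexicographically ordered
single-image files (PNG/TIFF), 8- or 16-bit grayscale; they are normalized
to float in [0, 1] on read and scaled back (clip, then round half-to-even)
on write.  Rigid transforms go to JSON (lossless for doubles), displacement
fields to 2-channel float32 TIFFs (channel 0 = row displacement, channel 1
= column displacement).  Slice order is always an explicit sort, never
filesystem order.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .rigid import RigidTransform
from .stack import SliceStack

__all__ = [
    "read_stack",
    "write_stack",
    "read_transforms",
    "write_transforms",
    "read_field",
    "write_field",
]

_IMAGE_SUFFIXES = {".png", ".tif", ".tiff"}


def _normalize(pages: list) -> SliceStack:
    if not pages:
        raise ValueError("empty input: no images found")
    arrays = []
    bit_depth = None
    for page in pages:
        a = np.asarray(page)
        if a.ndim != 2:
            raise ValueError(
                f"unsupported format: expected single-channel grayscale, got shape {a.shape}")
        if a.dtype == np.uint8:
            depth = 8
        elif a.dtype == np.uint16:
            depth = 16
        else:
            raise ValueError(f"unsupported format: dtype {a.dtype} (need uint8/uint16)")
        if bit_depth is None:
            bit_depth = depth
        elif bit_depth != depth:
            raise ValueError("unsupported format: mixed bit depths")
        arrays.append(a.astype(np.float64) / (2 ** depth - 1))
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError(f"shape mismatch among slices: {sorted(shapes)}")
    return SliceStack(np.stack(arrays), bit_depth=bit_depth)


def read_stack(path) -> SliceStack:
    """Read a stack from a multi-page TIFF or a directory of image files.

    Directory slices are ordered by filename sort; values are normalized
    to float in [0, 1] and the original bit depth is recorded for
    write-back.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in _IMAGE_SUFFIXES)
        if not files:
            raise ValueError(f"empty input: no PNG/TIFF files in {path}")
        return _normalize([iio.imread(f) for f in files])
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        pages = [arr]
    elif arr.ndim == 3 and arr.shape[-1] not in (3, 4):
        pages = list(arr)
    else:
        raise ValueError(f"unsupported format: color or odd-shaped TIFF {arr.shape}")
    return _normalize(pages)


def write_stack(stack: SliceStack, path, bit_depth: int | None = None) -> None:
    """Write a stack as a multi-page TIFF (.tif/.tiff path) or a directory
    of numbered PNGs.  Values are clipped to [0, 1], scaled to the integer
    range and rounded half-to-even."""
    if bit_depth is None:
        bit_depth = stack.bit_depth
    if bit_depth not in (8, 16):
        raise ValueError(f"bit_depth must be 8 or 16, got {bit_depth}")
    scale = 2 ** bit_depth - 1
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    arr = np.round(np.clip(stack.data, 0.0, 1.0) * scale).astype(dtype)
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, arr, photometric="minisblack")
    else:
        path.mkdir(parents=True, exist_ok=True)
        for i, page in enumerate(arr):
            iio.imwrite(path / f"s{i:04d}.png", page)


_TRANSFORM_KEYS = {"theta_deg", "tx", "ty", "cumulative"}


def write_transforms(transforms, path, cumulative: bool = True) -> None:
    """Write per-slice rigid transforms to JSON (lossless round-trip).

    ``tx``/``ty`` are the column/row translation components; the rotation
    pivot is stored under ``center`` as (row, col).
    """
    records = [
        {
            "theta_deg": T.theta_deg,
            "tx": T.t[1],
            "ty": T.t[0],
            "center": [T.center[0], T.center[1]],
            "cumulative": bool(cumulative),
        }
        for T in transforms
    ]
    with open(path, "w") as fh:
        json.dump(records, fh, indent=2)


def read_transforms(path) -> list:
    """Read a JSON transform list written by :func:`write_transforms`."""
    try:
        with open(path) as fh:
            records = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ValueError(f"schema error: malformed JSON in {path}: {exc}") from exc
    if not isinstance(records, list):
        raise ValueError("schema error: expected a JSON list of transforms")
    out = []
    for i, rec in enumerate(records):
        missing = _TRANSFORM_KEYS - set(rec)
        if missing:
            raise ValueError(f"schema error: record {i} missing fields {sorted(missing)}")
        center = tuple(rec.get("center", (0.0, 0.0)))
        out.append(RigidTransform(float(rec["theta_deg"]),
                                  (float(rec["ty"]), float(rec["tx"])), center))
    return out


def write_field(field: np.ndarray, path) -> None:
    """Write a displacement field as a 2-page float32 TIFF
    (page 0 = row displacement, page 1 = column displacement)."""
    field = np.asarray(field)
    if field.ndim != 3 or field.shape[0] != 2:
        raise ValueError(f"field must have shape (2, H, W), got {field.shape}")
    tifffile.imwrite(path, field.astype(np.float32))


def read_field(path) -> np.ndarray:
    """Read a displacement field written by :func:`write_field`."""
    arr = tifffile.imread(path)
    if arr.ndim != 3 or arr.shape[0] != 2:
        raise ValueError(f"format error: expected a 2-channel field TIFF, got shape {arr.shape}")
    if arr.dtype != np.float32:
        raise ValueError(f"format error: expected float32 field, got {arr.dtype}")
    return arr.astype(np.float64)
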