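"""Core in-memory container for serial-section image stacks.

A :class:`SliceStack` is an ordered sequence of same-shape 2D grayscale
slices, stored as a single ``(n, height, width)`` float array with values
in ``[0, 1]``.  All registration and evaluation stages consume and produce
this container; conversion to/from integer bit depths happens only at the
I/O boundary (:mod:`emalign.io`).

Axis order is ``(z, row, col)``; pixel coordinates are 0-based with pixel
centers at integer positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SliceStack", "as_stack_array"]


@dataclass
class SliceStack:
    """Ordered stack of same-shape 2D grayscale slices.

    Parameters
    ----------
    data : ndarray, shape (n, height, width)
        Gray values as floats, nominally in ``[0, 1]``.
    bit_depth : int
        Original integer bit depth (8 or 16), kept so a stack can be
        written back losslessly at the depth it was read from.
    """

    data: np.ndarray
    bit_depth: int = 8
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(
                f"stack data must be 3D (n, height, width), got shape {self.data.shape}"
            )
        if self.data.shape[0] < 1:
            raise ValueError("stack must contain at least one slice")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("stack contains non-finite values")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")

    @classmethod
    def from_slices(cls, slices, bit_depth: int = 8) -> "SliceStack":
        """Build a stack from an iterable of 2D arrays (all one shape)."""
        arrays = [np.asarray(s, dtype=np.float64) for s in slices]
        if not arrays:
            raise ValueError("empty input: no slices given")
        shapes = {a.shape for a in arrays}
        if len(shapes) != 1:
            raise ValueError(f"shape mismatch among slices: {sorted(shapes)}")
        return cls(np.stack(arrays, axis=0), bit_depth=bit_depth)

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def height(self) -> int:
        return self.data.shape[1]

    @property
    def width(self) -> int:
        return self.data.shape[2]

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def __len__(self) -> int:
        return self.n

    def __getitem__(self, i):
        return self.data[i]

    def __iter__(self):
        return iter(self.data)

    def copy(self) -> "SliceStack":
        return SliceStack(self.data.copy(), bit_depth=self.bit_depth, meta=dict(self.meta))

    def with_data(self, data: np.ndarray) -> "SliceStack":
        """Same metadata, new pixel data."""
        return SliceStack(np.asarray(data, dtype=np.float64),
                          bit_depth=self.bit_depth, meta=dict(self.meta))


def as_stack_array(stack) -> np.ndarray:
    """Coerce a SliceStack or a 3D array to a float (n, H, W) array."""
    if isinstance(stack, SliceStack):
        return stack.data
    arr = np.asarray(stack, dtype=np.float64)
    if arr.ndim != 3:
        raise ValueError(f"expected a 3D stack array, got shape {arr.shape}")
    return arr
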