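"""The in-memory 3D volume container shared by every stage of the pipeline.

A :class:`Volume` wraps a 3D array of voxel intensities indexed as
``data[x, y, z]`` with shape ``(W, H, F)`` — width, height and depth
(number of frames).  The memory layout convention throughout the package
is x-fastest: the flat index of voxel ``(x, y, z)`` in a raw file is
``x + W*y + W*H*z``.  Coordinates are 0-based and ranges half-open.

Intensities are stored as 64-bit floats: the filters accumulate many
products of squared differences, and single precision loses too much in
those sums.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = ["Volume"]


@dataclass
class Volume:
    """A 3D scalar field with dimensions ``(W, H, F)``.

    Parameters
    ----------
    data
        3D array-like of finite scalars, indexed ``[x, y, z]``.
        Converted to ``float64`` on construction.
    """

    data: np.ndarray = field()

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=np.float64)
        if arr.ndim != 3:
            raise ValidationError(
                f"volume data must be 3D, got {arr.ndim} dimension(s)"
            )
        if min(arr.shape) < 1:
            raise ValidationError(f"all dims must be >= 1, got {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValidationError("volume contains non-finite intensities")
        self.data = arr

    @property
    def dims(self) -> tuple[int, int, int]:
        """``(W, H, F)`` — width, height, depth in voxels."""
        w, h, f = self.data.shape
        return (w, h, f)

    @property
    def size(self) -> int:
        """Total number of voxels, ``W*H*F``."""
        return self.data.size

    def copy(self) -> "Volume":
        return Volume(self.data.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Volume):
            return NotImplemented
        return self.dims == other.dims and bool(np.array_equal(self.data, other.data))

    def allclose(self, other: "Volume", atol: float = 1e-12, rtol: float = 0.0) -> bool:
        return self.dims == other.dims and bool(
            np.allclose(self.data, other.data, atol=atol, rtol=rtol)
        )
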