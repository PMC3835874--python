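"""Reading and writing 3D volumes.

Three formats are supported:

* **Headerless RAW** with the dimensions embedded in the filename, e.g.
  ``baby.428x354x209.raw``.  The flat voxel order is x-fastest
  (flat index ``x + W*y + W*H*z``); scalar kinds are unsigned 8-bit or
  32-bit float, inferred from the file size when not stated.
* **NIfTI-1** (``.nii`` / ``.nii.gz``) via nibabel.
* **Multi-page TIFF** (``.tif`` / ``.tiff``) via tifffile, one page per
  frame (z slice).

DICOM is deliberately not supported, and no voxel-spacing metadata is
interpreted: the filters operate in voxel units.
"""

from __future__ import annotations

import os
import re
from typing import Optional

import nibabel as nib
import numpy as np
import tifffile

from .errors import DimensionParseError, SizeMismatchError, VolumeFormatError
from .volume import Volume

__all__ = ["parse_dims_from_filename", "read_volume", "write_volume"]

_DIMS_RE = re.compile(r"(?:^|[^0-9])(\d+)x(\d+)x(\d+)$")

_RAW_DTYPES = {"uint8": np.uint8, "float32": np.float32}


def _split_ext(path: str) -> tuple[str, str]:
    """Return (stem, extension), treating ``.nii.gz`` as one extension."""
    base = os.path.basename(path)
    if base.endswith(".nii.gz"):
        return base[: -len(".nii.gz")], ".nii.gz"
    stem, ext = os.path.splitext(base)
    return stem, ext.lower()


def parse_dims_from_filename(path: str) -> tuple[int, int, int]:
    """Extract ``(W, H, F)`` from a filename token like ``428x354x209``.

    The token must sit immediately before the extension, as in
    ``baby.428x354x209.raw``.

    Raises
    ------
    DimensionParseError
        If no such token is present.
    """
    stem, _ = _split_ext(path)
    m = _DIMS_RE.search(stem)
    if m is None:
        raise DimensionParseError(
            f"no <W>x<H>x<F> dimension token before the extension in {path!r}"
        )
    return (int(m.group(1)), int(m.group(2)), int(m.group(3)))


def _read_raw(
    path: str,
    dims: Optional[tuple[int, int, int]],
    raw_scalar_kind: Optional[str],
) -> Volume:
    if dims is None:
        dims = parse_dims_from_filename(path)
    w, h, f = dims
    nvox = w * h * f
    nbytes = os.path.getsize(path)
    if raw_scalar_kind is not None:
        try:
            dtype = _RAW_DTYPES[raw_scalar_kind]
        except KeyError:
            raise VolumeFormatError(
                f"unsupported raw scalar kind {raw_scalar_kind!r}; "
                f"choose one of {sorted(_RAW_DTYPES)}"
            ) from None
        if nbytes != nvox * np.dtype(dtype).itemsize:
            raise SizeMismatchError(
                f"{path!r}: {nbytes} bytes does not match dims {dims} "
                f"as {raw_scalar_kind} ({nvox * np.dtype(dtype).itemsize} expected)"
            )
    elif nbytes == nvox:
        dtype = np.uint8
    elif nbytes == 4 * nvox:
        dtype = np.float32
    else:
        raise SizeMismatchError(
            f"{path!r}: {nbytes} bytes matches neither uint8 ({nvox}) nor "
            f"float32 ({4 * nvox}) for dims {dims}"
        )
    flat = np.fromfile(path, dtype=dtype)
    # x-fastest flat order -> Fortran-order reshape gives data[x, y, z]
    return Volume(flat.reshape((w, h, f), order="F"))


def read_volume(
    path: str,
    dims: Optional[tuple[int, int, int]] = None,
    raw_scalar_kind: Optional[str] = None,
) -> Volume:
    """Load a volume, normalizing it to the internal float64 representation.

    Parameters
    ----------
    path
        Input file; the format is inferred from the extension.
    dims
        ``(W, H, F)`` for raw files whose filename carries no dimension
        token.  Ignored for NIfTI/TIFF (their headers are authoritative).
    raw_scalar_kind
        ``"uint8"`` or ``"float32"``, to disambiguate raw files whose
        scalar type cannot be inferred from the file size.
    """
    _, ext = _split_ext(path)
    if ext == ".raw" or ext == "":
        return _read_raw(path, dims, raw_scalar_kind)
    if ext in (".nii", ".nii.gz"):
        img = nib.load(path)
        data = np.asanyarray(img.dataobj)
        if data.ndim != 3:
            raise VolumeFormatError(f"{path!r}: expected a 3D NIfTI, got {data.ndim}D")
        return Volume(np.asarray(data, dtype=np.float64))
    if ext in (".tif", ".tiff"):
        pages = tifffile.imread(path)
        if pages.ndim == 2:
            pages = pages[None, ...]
        if pages.ndim != 3:
            raise VolumeFormatError(f"{path!r}: expected a 3D TIFF, got {pages.ndim}D")
        # tifffile yields (frames, H, W); internal layout is (W, H, F)
        return Volume(np.transpose(pages, (2, 1, 0)).astype(np.float64))
    raise VolumeFormatError(f"unsupported volume format {ext!r} for {path!r}")


def write_volume(
    vol: Volume, path: str, raw_scalar_kind: str = "float32"
) -> None:
    """Write a volume; the format is inferred from the extension.

    Raw output uses the x-fastest flat layout and ``float32`` scalars by
    default (``raw_scalar_kind="uint8"`` rounds and clips to [0, 255]).
    NIfTI output keeps full float64 precision, so write-then-read is the
    identity; TIFF stores float32 pages.
    """
    _, ext = _split_ext(path)
    if ext == ".raw" or ext == "":
        try:
            dtype = _RAW_DTYPES[raw_scalar_kind]
        except KeyError:
            raise VolumeFormatError(
                f"unsupported raw scalar kind {raw_scalar_kind!r}"
            ) from None
        data = vol.data
        if dtype is np.uint8:
            data = np.clip(np.rint(data), 0, 255)
        data.astype(dtype).ravel(order="F").tofile(path)
        return
    if ext in (".nii", ".nii.gz"):
        nib.save(nib.Nifti1Image(vol.data, affine=np.eye(4)), path)
        return
    if ext in (".tif", ".tiff"):
        tifffile.imwrite(
            path,
            np.transpose(vol.data, (2, 1, 0)).astype(np.float32),
            photometric="minisblack",
        )
        return
    raise VolumeFormatError(f"unsupported volume format {ext!r} for {path!r}")
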