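"""Integral grayscale TIFF (and raw binary) stack I/O.

Detector frames arrive as single- or multi-page grayscale TIFF stacks
(8/16/32-bit integer samples) or as headerless raw dumps with stated
dimensions.  Losslessness is the product, so anything that would force
a conversion — RGB, floating point, palette images — is rejected with a
clear error instead of being silently coerced.  One TIFF page maps to
one frame; page order and pixel values are preserved exactly.
"""

from __future__ import annotations

import os
from typing import Union

import numpy as np
import tifffile

from .errors import UnsupportedFormatError

__all__ = ["read_stack", "write_stack", "read_raw", "smallest_dtype"]

_PathLike = Union[str, os.PathLike]


def read_stack(path: _PathLike) -> np.ndarray:
    """Read a grayscale integer TIFF into a (frames, height, width) array."""
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        if page.samplesperpixel != 1:
            raise UnsupportedFormatError(
                f"{path}: {page.samplesperpixel} samples per pixel; "
                "only single-channel grayscale TIFF is supported"
            )
        arr = tf.asarray()
    if arr.dtype.kind not in "iu":
        raise UnsupportedFormatError(
            f"{path}: sample dtype {arr.dtype} is not integral; "
            "floating-point TIFF cannot be compressed losslessly as counts"
        )
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise UnsupportedFormatError(
            f"{path}: unexpected array shape {arr.shape}"
        )
    return arr


def write_stack(stack: np.ndarray, path: _PathLike, bits_per_sample=None) -> None:
    """Write a stack as uncompressed grayscale TIFF (one page per frame).

    ``bits_per_sample`` (8/16/32/64) selects the sample width; the write
    is refused before any bytes are emitted if a value would not fit —
    a lossy write is never performed.
    """
    stack = np.asarray(stack)
    if stack.dtype.kind not in "iu":
        raise ValueError(f"integral data required, got dtype {stack.dtype}")
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise ValueError(f"expected a 2-D frame or 3-D stack, got {stack.shape}")
    if bits_per_sample is None:
        dtype = stack.dtype
    else:
        if bits_per_sample not in (8, 16, 32, 64):
            raise ValueError(f"bits_per_sample must be 8/16/32/64, got {bits_per_sample}")
        kind = "i" if stack.dtype.kind == "i" else "u"
        dtype = np.dtype(f"{kind}{bits_per_sample // 8}")
        info = np.iinfo(dtype)
        if stack.size and (int(stack.min()) < info.min or int(stack.max()) > info.max):
            raise ValueError(
                f"values span [{stack.min()}, {stack.max()}], outside "
                f"{dtype.name} range [{info.min}, {info.max}]; refusing lossy write"
            )
    tifffile.imwrite(path, stack.astype(dtype), photometric="minisblack",
                     compression=None)


def read_raw(path: _PathLike, width: int, height: int, dtype) -> np.ndarray:
    """Read a headerless binary dump as a (frames, height, width) array.

    The frame count is inferred from the file size, which must be an
    exact multiple of one frame's byte size.
    """
    dtype = np.dtype(dtype)
    if dtype.kind not in "iu":
        raise UnsupportedFormatError(f"raw dtype {dtype} is not integral")
    data = np.fromfile(path, dtype=dtype)
    npix = width * height
    if npix <= 0 or data.size % npix:
        raise UnsupportedFormatError(
            f"{path}: {data.size} samples is not a multiple of "
            f"{width}x{height} = {npix}"
        )
    return data.reshape(-1, height, width)


def smallest_dtype(stack: np.ndarray, signed: bool) -> np.dtype:
    """Smallest standard integral dtype holding every value of ``stack``."""
    if stack.size == 0:
        return np.dtype("int8" if signed else "uint8")
    lo, hi = int(stack.min()), int(stack.max())
    kinds = ("int8", "int16", "int32", "int64") if signed or lo < 0 else \
            ("uint8", "uint16", "uint32", "uint64")
    for name in kinds:
        info = np.iinfo(name)
        if info.min <= lo and hi <= info.max:
            return np.dtype(name)
    raise ValueError(f"values span [{lo}, {hi}]: no 64-bit dtype holds them")
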