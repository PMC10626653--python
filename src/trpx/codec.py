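"""The TERSE/PROLIX (TRPX) block codec.

TRPX losslessly compresses integral grayscale frames by exploiting the
statistics of diffraction and counting-mode detector data: most pixels
are small counts near zero, with rare intense Bragg peaks.  Each frame
is flattened row-major and cut into fixed-size blocks (12 values by
default).  The values of a block are stripped of their shared most
significant bits — all zero for unsigned data, all identical (the sign
extension) for signed two's-complement data — and stored in the minimal
per-value bit depth.  Each block is preceded by a variable-length
descriptor of 1, 4, 6 or 12 bits:

* 1 bit set — reuse the previous block's bit depth;
* ``0`` + 3 bits — depths 0..6;
* ``0 111`` + 2 bits — depth 7 + field (7..9);
* ``0 111 11`` + 6 bits — depth 10 + field (10..64).

Encoding is a single pass with no lookahead beyond the current block,
and the compressed stream is a deterministic function of the value
sequence and the block size alone.  Decompression is the exact inverse;
when the caller requests an output dtype too narrow for the data, values
are clamped to the dtype's range with a warning (never silently
wrapped).

A multi-frame stack is one stream; the descriptor state (previous
depth) resets at every frame boundary so any frame can be decoded
independently given its bit offset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple, Union

import numpy as np

from .bitstream import BitReader, BitWriter
from .errors import CorruptStreamError, TruncatedStreamError

__all__ = [
    "DEFAULT_BLOCK_SIZE",
    "BlockDescriptor",
    "TerseStream",
    "significant_bits",
    "encode_descriptor",
    "descriptor_length",
    "decode_descriptor",
    "compress",
    "decompress",
    "compression_efficiency",
]

DEFAULT_BLOCK_SIZE = 12
MAX_BIT_DEPTH = 64

# descriptor geometry: depth ranges -> serialized length in bits
_DESC_SHORT_MAX = 6    # depths 0..6: flag + 3-bit field      (4 bits)
_DESC_MID_MAX = 9      # depths 7..9: flag + 111 + 2-bit      (6 bits)
#                        depths 10..64: flag + 111 11 + 6-bit (12 bits)


# ---------------------------------------------------------------------------
# bit depth of a block

def significant_bits(block, signed: bool = False) -> int:
    """Minimal per-value bit depth of a block after MSB stripping.

    Unsigned mode returns the smallest ``n`` with every value below
    ``2**n``; signed mode the smallest ``n`` whose two's-complement
    range ``[-2**(n-1), 2**(n-1) - 1]`` contains every value (the sign
    bit is kept).  ``n == 0`` iff all values are zero.
    """
    values = [int(v) for v in np.asarray(block).ravel()]
    if not values:
        raise ValueError("block must be non-empty")
    depth = 0
    for v in values:
        if not signed:
            if v < 0:
                raise ValueError(f"negative value {v} in unsigned block")
            n = v.bit_length()
        elif v == 0:
            n = 0
        else:
            n = ((~v).bit_length() if v < 0 else v.bit_length()) + 1
        if n > depth:
            depth = n
    if depth > MAX_BIT_DEPTH:
        raise ValueError(f"block values need {depth} bits; at most 64 supported")
    return depth


# ---------------------------------------------------------------------------
# block descriptors

@dataclass(frozen=True)
class BlockDescriptor:
    """Decoded block descriptor: the per-value bit depth, and whether it
    was encoded as a 1-bit repeat of the previous block's depth."""

    repeat_previous: bool
    bit_depth: int


def encode_descriptor(
    depth: int, previous_depth: Optional[int] = None
) -> Tuple[Tuple[int, int], ...]:
    """Bit fields of the descriptor for a block of ``depth`` bits/value.

    Returns the descriptor as ``(value, width)`` pairs ready for a
    :class:`~trpx.bitstream.BitWriter`.  ``previous_depth`` is ``None``
    for the first block of a frame, where the repeat flag must be clear.
    """
    if not 0 <= depth <= MAX_BIT_DEPTH:
        raise ValueError(f"bit depth must be in 0..64, got {depth}")
    if previous_depth is not None and depth == previous_depth:
        return ((1, 1),)
    if depth <= _DESC_SHORT_MAX:
        return ((0, 1), (depth, 3))
    if depth <= _DESC_MID_MAX:
        return ((0, 1), (0b111, 3), (depth - 7, 2))
    return ((0, 1), (0b111, 3), (0b11, 2), (depth - 10, 6))


def descriptor_length(depth: int, previous_depth: Optional[int] = None) -> int:
    """Serialized descriptor length in bits: 1, 4, 6 or 12."""
    return sum(width for _, width in encode_descriptor(depth, previous_depth))


def decode_descriptor(
    reader: BitReader, previous_depth: Optional[int] = None
) -> BlockDescriptor:
    """Exact inverse of :func:`encode_descriptor` over a bit stream."""
    if reader.read_bits(1):
        if previous_depth is None:
            raise CorruptStreamError(
                "repeat-previous flag set on the first descriptor of a frame"
            )
        return BlockDescriptor(True, previous_depth)
    base = reader.read_bits(3)
    if base != 0b111:
        return BlockDescriptor(False, base)
    ext = reader.read_bits(2)
    if ext != 0b11:
        return BlockDescriptor(False, 7 + ext)
    depth = 10 + reader.read_bits(6)
    if depth > MAX_BIT_DEPTH:
        raise CorruptStreamError(f"descriptor declares bit depth {depth} > 64")
    return BlockDescriptor(False, depth)


# ---------------------------------------------------------------------------
# compressed stream container (in memory)

@dataclass
class TerseStream:
    """A compressed frame stack: the bit-packed payload plus the metadata
    needed to invert it (the in-memory form of a .trpx record)."""

    payload: bytes
    pixel_count: int            # pixels per frame
    frame_count: int
    signed: bool
    bit_length: int             # meaningful bits in payload (rest is padding)
    block_size: int = DEFAULT_BLOCK_SIZE
    width: Optional[int] = None
    height: Optional[int] = None
    frame_bit_offsets: Tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.payload) < -(-self.bit_length // 8):
            raise TruncatedStreamError(
                f"payload holds {8 * len(self.payload)} bits, "
                f"header promises {self.bit_length}"
            )

    @property
    def frame_shape(self) -> Optional[Tuple[int, int]]:
        if self.width is not None and self.height is not None:
            return (self.height, self.width)
        # dimensionless mode: assume a square image when possible
        side = int(round(self.pixel_count ** 0.5))
        if side * side == self.pixel_count:
            return (side, side)
        return None

    @property
    def compressed_nbytes(self) -> int:
        return len(self.payload)


# ---------------------------------------------------------------------------
# vectorized helpers

def _bit_length_u64(x: np.ndarray) -> np.ndarray:
    """Per-element bit length of a uint64 array (0 for 0)."""
    x = x.astype(np.uint64, copy=True)
    out = np.zeros(x.shape, dtype=np.int64)
    for shift in (32, 16, 8, 4, 2, 1):
        s = np.uint64(shift)
        big = x >= (np.uint64(1) << s)
        out[big] += shift
        x[big] >>= s
    out += (x > 0)
    return out


def _value_depths(flat: np.ndarray, signed: bool) -> np.ndarray:
    """Minimal bit depth of each value (vectorized significant_bits)."""
    if signed:
        v = flat.astype(np.int64, copy=False)
        mag = np.where(v < 0, ~v, v).astype(np.uint64)
        per = _bit_length_u64(mag) + 1
        per[v == 0] = 0
        return per
    return _bit_length_u64(flat.astype(np.uint64, copy=False))


def _twos_complement_u64(flat: np.ndarray, signed: bool) -> np.ndarray:
    if signed:
        return flat.astype(np.int64, copy=False).view(np.uint64)
    return flat.astype(np.uint64, copy=False)


def _block_geometry(npix: int, block_size: int):
    nblocks = -(-npix // block_size)
    blens = np.full(nblocks, block_size, dtype=np.int64)
    blens[-1] = npix - (nblocks - 1) * block_size
    return nblocks, blens


def _encode_frame_bits(flat: np.ndarray, signed: bool, block_size: int) -> np.ndarray:
    """Encode one flattened frame into an array of bits (one uint8 per bit)."""
    npix = flat.size
    nblocks, blens = _block_geometry(npix, block_size)
    per = _value_depths(flat, signed)
    pad = nblocks * block_size - npix
    if pad:
        per = np.concatenate([per, np.zeros(pad, dtype=per.dtype)])
    depths = per.reshape(nblocks, block_size).max(axis=1)
    if depths.max(initial=0) > MAX_BIT_DEPTH:
        raise ValueError("values need more than 64 bits")

    prev = np.empty(nblocks, dtype=np.int64)
    prev[0] = -1  # no previous depth at frame start
    prev[1:] = depths[:-1]
    repeat = depths == prev
    dlen = np.where(
        repeat, 1, np.where(depths <= _DESC_SHORT_MAX, 4,
                            np.where(depths <= _DESC_MID_MAX, 6, 12))
    )
    block_bits = dlen + blens * depths
    starts = np.zeros(nblocks, dtype=np.int64)
    np.cumsum(block_bits[:-1], out=starts[1:])
    total = int(starts[-1] + block_bits[-1])

    bits = np.zeros(total, dtype=np.uint8)

    # descriptors --------------------------------------------------------
    bits[starts[repeat]] = 1  # repeat flag; expanded descriptors keep flag 0
    fresh_start = starts[~repeat]
    fresh_depth = depths[~repeat]

    short = fresh_depth <= _DESC_SHORT_MAX
    s, d = fresh_start[short], fresh_depth[short]
    for k in range(3):
        bits[s + 1 + k] = (d >> k) & 1

    mid = (fresh_depth > _DESC_SHORT_MAX) & (fresh_depth <= _DESC_MID_MAX)
    s, d = fresh_start[mid], fresh_depth[mid] - 7
    for k in range(3):
        bits[s + 1 + k] = 1
    for k in range(2):
        bits[s + 4 + k] = (d >> k) & 1

    big = fresh_depth > _DESC_MID_MAX
    s, d = fresh_start[big], fresh_depth[big] - 10
    for k in range(5):
        bits[s + 1 + k] = 1
    for k in range(6):
        bits[s + 6 + k] = (d >> k) & 1

    # payload ------------------------------------------------------------
    vblock = np.repeat(np.arange(nblocks), blens)
    first_pixel = np.zeros(nblocks, dtype=np.int64)
    np.cumsum(blens[:-1], out=first_pixel[1:])
    within = np.arange(npix) - first_pixel[vblock]
    voff = starts[vblock] + dlen[vblock] + within * depths[vblock]
    vdepth = depths[vblock]
    u = _twos_complement_u64(flat, signed)

    for depth in np.unique(depths):
        depth = int(depth)
        if depth == 0:
            continue
        sel = vdepth == depth
        off = voff[sel]
        vals = u[sel]
        for k in range(depth):
            bits[off + k] = ((vals >> np.uint64(k)) & np.uint64(1)).astype(np.uint8)
    return bits


# ---------------------------------------------------------------------------
# compress / decompress

def _as_stack(frames) -> np.ndarray:
    if isinstance(frames, np.ndarray):
        arr = frames
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3:
            raise ValueError(f"expected 2-D frame or 3-D stack, got {arr.ndim}-D")
        return arr
    seq = [np.asarray(f) for f in frames]
    if not seq:
        raise ValueError("empty frame stack")
    shape = seq[0].shape
    if any(f.shape != shape for f in seq):
        raise ValueError("all frames in a stack must share one shape")
    return np.stack(seq)


def compress(
    frames: Union[np.ndarray, Sequence[np.ndarray]],
    block_size: int = DEFAULT_BLOCK_SIZE,
    signed: Optional[bool] = None,
) -> TerseStream:
    """Compress a frame or a same-shaped stack into a :class:`TerseStream`.

    ``frames`` is a 2-D array (one frame) or 3-D array / sequence of 2-D
    arrays (a stack), integer dtype up to 64 bits.  ``signed`` defaults
    to the dtype's signedness; passing ``signed=False`` for data
    containing negative values is an error.  Single pass, deterministic.
    """
    stack = _as_stack(frames)
    if stack.dtype.kind not in "iu":
        raise ValueError(f"integral data required, got dtype {stack.dtype}")
    if block_size < 1:
        raise ValueError(f"block_size must be >= 1, got {block_size}")
    if signed is None:
        signed = stack.dtype.kind == "i"
    if not signed and stack.size and stack.dtype.kind == "i" and stack.min() < 0:
        raise ValueError("negative values cannot be compressed as unsigned")

    nframes, height, width = stack.shape
    pieces = []
    offsets = []
    cursor = 0
    for f in range(nframes):
        bits = _encode_frame_bits(stack[f].ravel(), signed, block_size)
        offsets.append(cursor)
        cursor += bits.size
        pieces.append(bits)
    if pieces:
        allbits = np.concatenate(pieces)
        payload = np.packbits(allbits, bitorder="little").tobytes()
    else:
        payload = b""
    return TerseStream(
        payload=payload,
        pixel_count=height * width,
        frame_count=nframes,
        signed=bool(signed),
        bit_length=cursor,
        block_size=block_size,
        width=width,
        height=height,
        frame_bit_offsets=tuple(offsets),
    )


def _walk_frame(bitlist, base: int, end: int, npix: int, block_size: int):
    """Sequentially parse one frame's descriptors.

    Returns per-block depths and the absolute bit offset of each block's
    payload.  ``bitlist`` is a plain list of 0/1 ints covering the whole
    stream; the frame occupies [base, end) and must fill it exactly.
    """
    nblocks, blens = _block_geometry(npix, block_size)
    depths = np.empty(nblocks, dtype=np.int64)
    pstarts = np.empty(nblocks, dtype=np.int64)
    cursor = base
    prev = None
    for b in range(nblocks):
        if cursor + 1 > end:
            raise TruncatedStreamError(
                f"descriptor overruns payload at bit offset {cursor}"
            )
        if bitlist[cursor]:
            cursor += 1
            if prev is None:
                raise CorruptStreamError(
                    "repeat-previous flag set on the first descriptor of a frame"
                )
            depth = prev
        else:
            cursor += 1
            if cursor + 3 > end:
                raise TruncatedStreamError(
                    f"descriptor overruns payload at bit offset {cursor}"
                )
            depth = bitlist[cursor] | bitlist[cursor + 1] << 1 | bitlist[cursor + 2] << 2
            cursor += 3
            if depth == 0b111:
                if cursor + 2 > end:
                    raise TruncatedStreamError(
                        f"descriptor overruns payload at bit offset {cursor}"
                    )
                ext = bitlist[cursor] | bitlist[cursor + 1] << 1
                cursor += 2
                if ext != 0b11:
                    depth = 7 + ext
                else:
                    if cursor + 6 > end:
                        raise TruncatedStreamError(
                            f"descriptor overruns payload at bit offset {cursor}"
                        )
                    x = 0
                    for k in range(6):
                        x |= bitlist[cursor + k] << k
                    cursor += 6
                    depth = 10 + x
                    if depth > MAX_BIT_DEPTH:
                        raise CorruptStreamError(
                            f"descriptor declares bit depth {depth} > 64"
                        )
        depths[b] = depth
        pstarts[b] = cursor
        cursor += int(blens[b]) * depth
        if cursor > end:
            raise TruncatedStreamError(
                f"block payload overruns stream at bit offset {cursor}"
            )
        prev = depth
    if cursor != end:
        raise CorruptStreamError(
            f"frame decoded to bit offset {cursor}, expected {end}"
        )
    return depths, pstarts, blens


def _decode_frame(bits: np.ndarray, bitlist, base: int, end: int,
                  npix: int, block_size: int, signed: bool) -> np.ndarray:
    depths, pstarts, blens = _walk_frame(bitlist, base, end, npix, block_size)
    nblocks = depths.size
    vblock = np.repeat(np.arange(nblocks), blens)
    first_pixel = np.zeros(nblocks, dtype=np.int64)
    np.cumsum(blens[:-1], out=first_pixel[1:])
    within = np.arange(npix) - first_pixel[vblock]
    voff = pstarts[vblock] + within * depths[vblock]
    vdepth = depths[vblock]

    out = np.zeros(npix, dtype=np.uint64)
    for depth in np.unique(depths):
        depth = int(depth)
        if depth == 0:
            continue
        sel = vdepth == depth
        off = voff[sel]
        acc = np.zeros(off.size, dtype=np.uint64)
        for k in range(depth):
            acc |= bits[off + k].astype(np.uint64) << np.uint64(k)
        if signed and depth < 64:
            # sign-extend from the block depth via two's complement
            sign = (acc >> np.uint64(depth - 1)) & np.uint64(1)
            acc = np.where(
                sign.astype(bool),
                acc | (~np.uint64(0) << np.uint64(depth)),
                acc,
            )
        out[sel] = acc
    return out.view(np.int64) if signed else out


def _cast_with_clamp(values: np.ndarray, dtype: np.dtype) -> np.ndarray:
    """Cast to the requested integral dtype, clamping out-of-range values
    to the dtype's extremes with a warning (truncate-on-unpack)."""
    dtype = np.dtype(dtype)
    if dtype.kind not in "iu":
        raise ValueError(f"output dtype must be integral, got {dtype}")
    info = np.iinfo(dtype)
    lo, hi = int(info.min), int(info.max)
    if values.dtype.kind == "u":
        over = values > np.uint64(hi) if hi < 2**64 - 1 else np.zeros(0, bool)
        under = np.zeros(0, dtype=bool)
    else:
        over = values > np.int64(hi) if hi < 2**63 - 1 else np.zeros(0, bool)
        under = values < np.int64(lo) if lo > -(2**63) else np.zeros(0, bool)
    n_clamped = int(np.count_nonzero(over)) + int(np.count_nonzero(under))
    if n_clamped:
        warnings.warn(
            f"{n_clamped} value(s) exceed the range of {dtype.name}; "
            f"clamped to [{lo}, {hi}]",
            UserWarning,
            stacklevel=3,
        )
        values = values.copy()
        if over.size:
            values[over] = hi
        if under.size:
            values[under] = lo
    return values.astype(dtype)


def decompress(
    stream: TerseStream,
    frame_index: Optional[int] = None,
    dtype=None,
) -> np.ndarray:
    """Decompress a :class:`TerseStream` back into pixel values.

    With ``frame_index=None`` the whole stack is returned as a 3-D array
    (frames, height, width); a single frame is returned 2-D.  Frames are
    square-reshaped in dimensionless mode when the pixel count permits,
    else returned flat.  ``dtype`` selects the output integral type;
    values outside its range are clamped to its extremes with a warning.
    The default dtype (int64/uint64 by signedness) is always lossless.
    """
    if frame_index is not None and not 0 <= frame_index < stream.frame_count:
        raise IndexError(
            f"frame index {frame_index} out of range for "
            f"{stream.frame_count}-frame stream"
        )
    if dtype is None:
        dtype = np.int64 if stream.signed else np.uint64

    nbytes_needed = -(-stream.bit_length // 8)
    bits = np.unpackbits(
        np.frombuffer(stream.payload[:nbytes_needed], dtype=np.uint8),
        bitorder="little",
    )
    bitlist = bits.tolist()

    offsets = list(stream.frame_bit_offsets)
    if len(offsets) != stream.frame_count:
        raise CorruptStreamError(
            f"{len(offsets)} frame offsets for {stream.frame_count} frames"
        )
    bounds = offsets + [stream.bit_length]

    indices = range(stream.frame_count) if frame_index is None else [frame_index]
    frames = []
    for f in indices:
        flat = _decode_frame(
            bits, bitlist, bounds[f], bounds[f + 1],
            stream.pixel_count, stream.block_size, stream.signed,
        )
        flat = _cast_with_clamp(flat, dtype)
        shape = stream.frame_shape
        frames.append(flat.reshape(shape) if shape is not None else flat)
    if frame_index is not None:
        return frames[0]
    return np.stack(frames) if frames else np.zeros(
        (0,) + (stream.frame_shape or (stream.pixel_count,)), dtype=dtype
    )


# ---------------------------------------------------------------------------
# metrics

def compression_efficiency(original_bytes: int, compressed_bytes: int) -> float:
    """Percentage reduction in size: ``100 * (1 - compressed/original)``."""
    if original_bytes <= 0:
        raise ValueError("original size must be positive")
    return 100.0 * (1.0 - compressed_bytes / original_bytes)


def expected_stream_bits(
    frames: Union[np.ndarray, Sequence[np.ndarray]],
    block_size: int = DEFAULT_BLOCK_SIZE,
    signed: Optional[bool] = None,
) -> int:
    """Independent closed-form size of the compressed stream in bits:
    the sum over blocks of descriptor length + block length x depth,
    computed from the descriptor rules without encoding anything."""
    stack = _as_stack(frames)
    if signed is None:
        signed = stack.dtype.kind == "i"
    total = 0
    for f in range(stack.shape[0]):
        flat = stack[f].ravel()
        prev = None
        for start in range(0, flat.size, block_size):
            block = flat[start:start + block_size]
            depth = significant_bits(block, signed=signed)
            total += descriptor_length(depth, prev) + block.size * depth
            prev = depth
    return total
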