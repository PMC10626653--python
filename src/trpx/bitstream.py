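"""Endianness-independent bit-level I/O.

Every serialized structure in this package is defined in terms of an
ordered sequence of ``(value, width)`` fields written through
:class:`BitWriter` and read back through :class:`BitReader`.  The byte
serialization is a pure function of that write history, so big- and
little-endian hosts produce identical files.

Bit-order convention (fixed, versioned in the container header):

* within each byte, fields fill from the least-significant bit upward;
* a multi-bit field is stored with its own low-order bit first.

So writing the 3-bit values 5, 0, 3 produces a 9-bit stream occupying
two bytes, ``0xC5 0x01``, on every platform.  Width-0 fields are legal
no-ops (required for bit-depth-0 blocks in the codec).  Reading past the
end of a buffer is a hard :class:`~trpx.errors.TruncatedStreamError`,
never silent zero-fill.
"""

from __future__ import annotations

from .errors import TruncatedStreamError

__all__ = ["BitWriter", "BitReader"]

_MAX_WIDTH = 64


def _check_width(width: int) -> None:
    if not 0 <= width <= _MAX_WIDTH:
        raise ValueError(f"field width must be in 0..{_MAX_WIDTH}, got {width}")


class BitWriter:
    """Append-only writer of arbitrary-width unsigned bit fields."""

    __slots__ = ("_buf", "_acc", "_nacc")

    def __init__(self) -> None:
        self._buf = bytearray()
        self._acc = 0  # pending bits not yet flushed to _buf
        self._nacc = 0

    @property
    def bit_cursor(self) -> int:
        """Total number of bits written so far (= sum of field widths)."""
        return 8 * len(self._buf) + self._nacc

    def write_bits(self, value: int, width: int) -> "BitWriter":
        """Append the ``width`` low-order bits of ``value``.

        ``value`` must satisfy ``0 <= value < 2**width``; width 0 is a
        legal no-op.  Returns self so calls can be chained.
        """
        _check_width(width)
        value = int(value)
        if value < 0 or value >> width:
            raise ValueError(f"value {value} does not fit in {width} bits")
        self._acc |= value << self._nacc
        self._nacc += width
        while self._nacc >= 8:
            self._buf.append(self._acc & 0xFF)
            self._acc >>= 8
            self._nacc -= 8
        return self

    def write_fields(self, fields) -> "BitWriter":
        """Append a sequence of ``(value, width)`` pairs in order."""
        for value, width in fields:
            self.write_bits(value, width)
        return self

    def to_bytes(self) -> bytes:
        """Serialize to bytes; the final partial byte is zero-padded.

        Does not mutate the writer: further writes continue the stream.
        """
        out = bytes(self._buf)
        if self._nacc:
            out += bytes([self._acc & 0xFF])
        return out


class BitReader:
    """Sequential reader over the bytes a :class:`BitWriter` produced."""

    __slots__ = ("_data", "_pos")

    def __init__(self, data: bytes, bit_offset: int = 0) -> None:
        self._data = bytes(data)
        if bit_offset < 0 or bit_offset > 8 * len(self._data):
            raise ValueError(f"bit offset {bit_offset} outside buffer")
        self._pos = bit_offset

    @property
    def bit_cursor(self) -> int:
        """Number of bits consumed so far."""
        return self._pos

    @property
    def bits_remaining(self) -> int:
        return 8 * len(self._data) - self._pos

    def read_bits(self, width: int) -> int:
        """Read the next ``width`` bits as an unsigned integer."""
        _check_width(width)
        if self._pos + width > 8 * len(self._data):
            raise TruncatedStreamError(
                f"read of {width} bits at bit offset {self._pos} overruns "
                f"{8 * len(self._data)}-bit buffer"
            )
        result = 0
        got = 0
        pos = self._pos
        data = self._data
        while got < width:
            byte = data[pos >> 3]
            bitoff = pos & 7
            take = min(8 - bitoff, width - got)
            result |= ((byte >> bitoff) & ((1 << take) - 1)) << got
            pos += take
            got += take
        self._pos = pos
        return result
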