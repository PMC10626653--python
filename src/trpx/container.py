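"""The .trpx on-disk container.

A .trpx file is one or more self-delimiting records.  Each record is a
small UTF-8 XML header carrying the unpacking metadata, immediately
followed by the raw bit-packed payload (no separator, no alignment).
Because every header states its own payload length in bits, records can
be appended to an existing file — or embedded inside another format's
raw-data section — and still be parsed unambiguously.

Header dialect of this implementation (version ``1.0``)::

    <trpx version="1.0" bit_order="lsb-first">
      <frames>450</frames>
      <pixels>262144</pixels>
      <width>512</width>          <!-- optional: dimensionless mode -->
      <height>512</height>        <!-- omits width/height, squares assumed -->
      <signed>0</signed>
      <block_size>12</block_size>
      <bits>2456789</bits>        <!-- payload length in bits; the payload
                                       occupies ceil(bits/8) bytes -->
      <frame_bits>0 5440 ...</frame_bits>  <!-- per-frame bit offsets -->
    </trpx>

Unknown extension elements are preserved on read and re-emitted on
write, so the header can be extended for specific use cases without
breaking older readers.  The serialization is byte-identical across
platforms for identical inputs.
"""

from __future__ import annotations

import os
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import BinaryIO, List, Optional, Tuple, Union

from .codec import TerseStream
from .errors import CorruptStreamError, TruncatedStreamError, UnsupportedFormatError

__all__ = ["FORMAT_VERSION", "BIT_ORDER", "TrpxHeader", "write_trpx", "read_trpx"]

FORMAT_VERSION = "1.0"
BIT_ORDER = "lsb-first"

_ROOT_TAG = "trpx"
_CLOSE = b"</trpx>"
_KNOWN_TAGS = ("frames", "pixels", "width", "height", "signed",
               "block_size", "bits", "frame_bits")
_MAX_HEADER_BYTES = 1 << 24  # sanity bound while scanning for the close tag


@dataclass
class TrpxHeader:
    """Parsed metadata of one .trpx record."""

    frame_count: int
    pixel_count_per_frame: int
    signed: bool
    block_size: int
    payload_bit_length: int
    width: Optional[int] = None
    height: Optional[int] = None
    frame_bit_offsets: Tuple[int, ...] = ()
    format_version: str = FORMAT_VERSION
    extensions: List[ET.Element] = field(default_factory=list)

    @classmethod
    def from_stream(cls, stream: TerseStream) -> "TrpxHeader":
        return cls(
            frame_count=stream.frame_count,
            pixel_count_per_frame=stream.pixel_count,
            signed=stream.signed,
            block_size=stream.block_size,
            payload_bit_length=stream.bit_length,
            width=stream.width,
            height=stream.height,
            frame_bit_offsets=tuple(stream.frame_bit_offsets),
        )

    def matches(self, stream: TerseStream) -> bool:
        return (
            self.frame_count == stream.frame_count
            and self.pixel_count_per_frame == stream.pixel_count
            and self.signed == stream.signed
            and self.block_size == stream.block_size
            and self.payload_bit_length == stream.bit_length
            and tuple(self.frame_bit_offsets) == tuple(stream.frame_bit_offsets)
        )


def _serialize_header(header: TrpxHeader) -> bytes:
    # built by string assembly, not a DOM serializer, so the byte layout
    # is fully pinned down by this function alone (golden-file stable)
    parts = [f'<{_ROOT_TAG} version="{header.format_version}" bit_order="{BIT_ORDER}">']
    parts.append(f"<frames>{header.frame_count}</frames>")
    parts.append(f"<pixels>{header.pixel_count_per_frame}</pixels>")
    if header.width is not None:
        parts.append(f"<width>{header.width}</width>")
    if header.height is not None:
        parts.append(f"<height>{header.height}</height>")
    parts.append(f"<signed>{int(header.signed)}</signed>")
    parts.append(f"<block_size>{header.block_size}</block_size>")
    parts.append(f"<bits>{header.payload_bit_length}</bits>")
    offsets = " ".join(str(o) for o in header.frame_bit_offsets)
    parts.append(f"<frame_bits>{offsets}</frame_bits>")
    for elem in header.extensions:
        parts.append(ET.tostring(elem, encoding="unicode"))
    parts.append(f"</{_ROOT_TAG}>")
    return "".join(parts).encode("utf-8")


def _int_child(root: ET.Element, tag: str, required: bool = True) -> Optional[int]:
    elem = root.find(tag)
    if elem is None or elem.text is None:
        if required:
            raise CorruptStreamError(f"header missing <{tag}> element")
        return None
    try:
        return int(elem.text.strip())
    except ValueError as exc:
        raise CorruptStreamError(f"header <{tag}> is not an integer") from exc


def _parse_header(blob: bytes) -> TrpxHeader:
    try:
        root = ET.fromstring(blob.decode("utf-8"))
    except (ET.ParseError, UnicodeDecodeError) as exc:
        raise CorruptStreamError(f"malformed XML header: {exc}") from exc
    if root.tag != _ROOT_TAG:
        raise CorruptStreamError(f"unexpected root element <{root.tag}>")
    version = root.get("version", "")
    if version.split(".")[0] != FORMAT_VERSION.split(".")[0]:
        raise UnsupportedFormatError(f"unsupported format version {version!r}")
    bit_order = root.get("bit_order", BIT_ORDER)
    if bit_order != BIT_ORDER:
        raise UnsupportedFormatError(f"unsupported bit order {bit_order!r}")

    frames = _int_child(root, "frames")
    pixels = _int_child(root, "pixels")
    width = _int_child(root, "width", required=False)
    height = _int_child(root, "height", required=False)
    signed = bool(_int_child(root, "signed"))
    block_size = _int_child(root, "block_size")
    bits = _int_child(root, "bits")
    fb_elem = root.find("frame_bits")
    if fb_elem is None:
        raise CorruptStreamError("header missing <frame_bits> element")
    text = (fb_elem.text or "").strip()
    offsets = tuple(int(t) for t in text.split()) if text else ()
    if len(offsets) != frames:
        raise CorruptStreamError(
            f"<frame_bits> lists {len(offsets)} offsets for {frames} frames"
        )
    if width is not None and height is not None and width * height != pixels:
        raise CorruptStreamError(
            f"width x height = {width * height} disagrees with pixels = {pixels}"
        )
    extensions = [e for e in root if e.tag not in _KNOWN_TAGS]
    return TrpxHeader(
        frame_count=frames,
        pixel_count_per_frame=pixels,
        signed=signed,
        block_size=block_size,
        payload_bit_length=bits,
        width=width,
        height=height,
        frame_bit_offsets=offsets,
        format_version=version,
        extensions=extensions,
    )


def write_trpx(
    stream: TerseStream,
    destination: Union[str, os.PathLike, BinaryIO],
    header: Optional[TrpxHeader] = None,
    append: bool = False,
) -> int:
    """Write one record (header + payload) to a path or binary sink.

    With ``append=True`` the record is written after any existing
    content, which stays untouched.  Returns the number of bytes
    written.  A ``header`` inconsistent with ``stream`` is rejected.
    """
    if header is None:
        header = TrpxHeader.from_stream(stream)
    elif not header.matches(stream):
        raise ValueError("header metadata disagrees with the compressed stream")
    payload = stream.payload[: -(-stream.bit_length // 8)]
    blob = _serialize_header(header) + payload
    if hasattr(destination, "write"):
        destination.write(blob)
    else:
        mode = "ab" if append else "wb"
        with open(destination, mode) as fh:
            fh.write(blob)
    return len(blob)


def _read_all(source: Union[str, os.PathLike, bytes, BinaryIO]) -> bytes:
    if isinstance(source, (bytes, bytearray)):
        return bytes(source)
    if hasattr(source, "read"):
        return source.read()
    with open(source, "rb") as fh:
        return fh.read()


def read_trpx(
    source: Union[str, os.PathLike, bytes, BinaryIO],
) -> List[Tuple[TrpxHeader, TerseStream]]:
    """Read every record of a .trpx file.

    Returns a list of ``(header, stream)`` pairs, one per appended
    record.  Unknown header extension elements are preserved in
    ``header.extensions``.  A payload shorter than the header's bit
    length raises :class:`~trpx.errors.TruncatedStreamError` rather than
    yielding partial data.
    """
    data = _read_all(source)
    records = []
    pos = 0
    while pos < len(data):
        end = data.find(_CLOSE, pos, pos + _MAX_HEADER_BYTES)
        if end < 0:
            raise CorruptStreamError(
                f"no closing {_CLOSE.decode()} tag after byte {pos}"
            )
        header_end = end + len(_CLOSE)
        header = _parse_header(data[pos:header_end])
        nbytes = -(-header.payload_bit_length // 8)
        payload = data[header_end:header_end + nbytes]
        if len(payload) < nbytes:
            raise TruncatedStreamError(
                f"payload truncated: header promises {nbytes} bytes, "
                f"file holds {len(payload)}"
            )
        stream = TerseStream(
            payload=payload,
            pixel_count=header.pixel_count_per_frame,
            frame_count=header.frame_count,
            signed=header.signed,
            bit_length=header.payload_bit_length,
            block_size=header.block_size,
            width=header.width,
            height=header.height,
            frame_bit_offsets=header.frame_bit_offsets,
        )
        records.append((header, stream))
        pos = header_end + nbytes
    if not records:
        raise CorruptStreamError("empty .trpx source")
    return records
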