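# The .trpx file format (dialect 1.0)

A `.trpx` file is a sequence of one or more self-delimiting **records**.
Each record is a small UTF-8 XML header immediately followed by the raw
compressed payload — no separator, no padding, no alignment.  Because a
header states its own payload length, records can be appended to an
existing file (or embedded in another format's raw-data section) and
still be parsed unambiguously, and the whole file is byte-identical
across host architectures.

## Header

```xml
<trpx version="1.0" bit_order="lsb-first">
  <frames>450</frames>          <!-- frame count in this record -->
  <pixels>262144</pixels>       <!-- pixels per frame -->
  <width>512</width>            <!-- optional; without width/height the -->
  <height>512</height>          <!--   frame is assumed square -->
  <signed>0</signed>            <!-- 1 = two's-complement signed values -->
  <block_size>12</block_size>   <!-- values per compression block -->
  <bits>2456789</bits>          <!-- meaningful payload bits; the payload
                                     occupies ceil(bits/8) bytes -->
  <frame_bits>0 5440 10881</frame_bits>  <!-- bit offset of each frame -->
</trpx>
```

* Elements appear in the order above; unknown extra elements are
  preserved by readers and re-emitted by writers (forward-compatible
  extension point).
* `bits` makes trailing pad bits in the final byte unambiguous.
* `frame_bits` lists one bit offset per frame, so any frame can be
  decoded without touching the others (descriptor state resets at every
  frame boundary, see below).
* A reader must reject an unknown major `version` or `bit_order`.

## Payload bit stream

All fields are packed **LSB-first**: the first bit written occupies the
least-significant bit of the first payload byte, and a multi-bit field
stores its own low-order bit first.  This convention is fixed by the
`bit_order` header attribute and can never drift silently.

Each frame is flattened row-major and cut into consecutive blocks of
`block_size` values (the final block of a frame may be shorter; its
length is implied by `pixels`).  Each block is encoded as a
**descriptor** followed by its values in `depth` bits each, where
`depth` is the smallest width holding every value of the block
(unsigned: all values `< 2^depth`; signed: all values in
`[-2^(depth-1), 2^(depth-1)-1]`, two's complement, sign bit kept).
Depth-0 blocks (all zeros) carry no payload bits at all.

Descriptor layout (bit 1 first in stream order):

| fields                     | total bits | meaning                      |
|----------------------------|------------|------------------------------|
| `1`                        | 1          | same depth as previous block |
| `0` + 3-bit d              | 4          | depth d = 0..6               |
| `0` + `111` + 2-bit e      | 6          | depth 7 + e  (7..9)          |
| `0` + `111` + `11` + 6-bit x | 12       | depth 10 + x (10..64)        |

The first descriptor of every frame must have the repeat flag clear;
the repeat flag compares bit depth only.  Encoding is a single pass
with no lookahead beyond the current block, so the stream is a pure
function of the value sequence and the block size.
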