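"""Naive reference encoder: the block-compression rules written out
per value over a BitWriter, independently of the vectorized codec.

Used as the bit-identical oracle for the production encoder and as the
independent closed-form size computation (sum over blocks of descriptor
bits + block length x depth).
"""

import numpy as np

from trpx.bitstream import BitWriter


def block_depth(block, signed):
    """Smallest representable bit depth, by brute-force scan over n."""
    for n in range(65):
        if signed:
            lo = -(1 << (n - 1)) if n else 0
            hi = (1 << (n - 1)) - 1 if n else 0
            if all(lo <= v <= hi for v in block):
                return n
        else:
            if all(0 <= v < (1 << n) for v in block):
                return n
    raise ValueError("block needs more than 64 bits")


def descriptor_bits(depth, prev):
    if prev is not None and depth == prev:
        return 1
    if depth <= 6:
        return 4
    if depth <= 9:
        return 6
    return 12


def expected_bits(stack, block_size, signed):
    """Independent size oracle: total compressed stream length in bits."""
    total = 0
    for frame in np.asarray(stack).reshape(len(stack), -1):
        flat = [int(v) for v in frame]
        prev = None
        for i in range(0, len(flat), block_size):
            block = flat[i:i + block_size]
            depth = block_depth(block, signed)
            total += descriptor_bits(depth, prev) + len(block) * depth
            prev = depth
    return total


def reference_compress(stack, block_size, signed):
    """Encode a stack exactly as the codec specifies, one value at a time.

    Returns (payload bytes, bit length, per-frame bit offsets).
    """
    w = BitWriter()
    offsets = []
    for frame in np.asarray(stack).reshape(len(stack), -1):
        offsets.append(w.bit_cursor)
        flat = [int(v) for v in frame]
        prev = None
        for i in range(0, len(flat), block_size):
            block = flat[i:i + block_size]
            depth = block_depth(block, signed)
            if prev is not None and depth == prev:
                w.write_bits(1, 1)
            else:
                w.write_bits(0, 1)
                if depth <= 6:
                    w.write_bits(depth, 3)
                elif depth <= 9:
                    w.write_bits(0b111, 3)
                    w.write_bits(depth - 7, 2)
                else:
                    w.write_bits(0b111, 3)
                    w.write_bits(0b11, 2)
                    w.write_bits(depth - 10, 6)
            mask = (1 << depth) - 1
            for v in block:
                w.write_bits(v & mask, depth)
            prev = depth
    return w.to_bytes(), w.bit_cursor, offsets
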