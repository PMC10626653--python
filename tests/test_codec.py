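"""The block codec: bit depths, descriptors, compression, inversion."""

import numpy as np
import pytest

import trpx
from trpx import (
    BitReader,
    BitWriter,
    CorruptStreamError,
    TerseStream,
    TruncatedStreamError,
)

import reference_codec
from conftest import random_stack


# ---------------------------------------------------------------------------
# significant_bits

@pytest.mark.parametrize(
    "block,signed,depth",
    [
        ([5, 0, 3], False, 3),
        ([0, 0, 0, 0], False, 0),
        ([0], True, 0),
        ([-1, 1], True, 2),
        ([-5, 3], True, 4),
        ([-1], True, 1),
        ([63], False, 6),
        ([64], False, 7),
        ([2**64 - 1], False, 64),
        ([-(2**63)], True, 64),
    ],
)
def test_significant_bits_examples(block, signed, depth):
    assert trpx.significant_bits(block, signed=signed) == depth


def test_significant_bits_matches_brute_force_oracle(rng):
    for _ in range(300):
        signed = bool(rng.integers(0, 2))
        d = int(rng.integers(1, 64, endpoint=True))
        block = random_stack(rng, signed=signed, max_depth=d, nframes=1,
                             npix_range=(1, 12)).ravel().tolist()
        assert trpx.significant_bits(block, signed=signed) == \
            reference_codec.block_depth(block, signed)


def test_significant_bits_rejects_empty_and_negative_unsigned():
    with pytest.raises(ValueError):
        trpx.significant_bits([])
    with pytest.raises(ValueError):
        trpx.significant_bits([-1], signed=False)


# ---------------------------------------------------------------------------
# descriptors

@pytest.mark.parametrize(
    "depth,prev,fields",
    [
        (3, None, ((0, 1), (3, 3))),                      # 4 bits
        (7, 3, ((0, 1), (0b111, 3), (0b00, 2))),          # 6 bits, ext 00 -> 7
        (8, 3, ((0, 1), (0b111, 3), (0b01, 2))),          # ext 01 -> 8
        (9, 3, ((0, 1), (0b111, 3), (0b10, 2))),          # ext 10 -> 9
        (10, 3, ((0, 1), (0b111, 3), (0b11, 2), (0, 6))),  # 12 bits
        (64, 7, ((0, 1), (0b111, 3), (0b11, 2), (54, 6))),  # 10 + 54 = 64
        (5, 5, ((1, 1),)),                                 # repeat, 1 bit
    ],
)
def test_encode_descriptor_field_layout(depth, prev, fields):
    assert trpx.encode_descriptor(depth, prev) == fields
    assert trpx.descriptor_length(depth, prev) == sum(w for _, w in fields)


def test_descriptor_lengths_are_1_4_6_or_12_and_max_is_12():
    lengths = {
        trpx.descriptor_length(d, p)
        for d in range(65)
        for p in [None] + list(range(65))
    }
    assert lengths == {1, 4, 6, 12}


def test_descriptor_round_trip_exhaustive():
    """decode(encode(d, p), p) == d over all 65 depths x 66 previous states."""
    for prev in [None] + list(range(65)):
        for depth in range(65):
            blob = BitWriter().write_fields(
                trpx.encode_descriptor(depth, prev)).to_bytes()
            desc = trpx.decode_descriptor(BitReader(blob), prev)
            assert desc.bit_depth == depth
            assert desc.repeat_previous == (prev is not None and depth == prev)


def test_decode_rejects_repeat_at_stream_start_and_depth_over_64():
    with pytest.raises(CorruptStreamError):
        trpx.decode_descriptor(BitReader(b"\x01"), None)
    # 0 111 11 110111 -> would be depth 10 + 55 = 65
    blob = BitWriter().write_fields(
        ((0, 1), (0b111, 3), (0b11, 2), (55, 6))).to_bytes()
    with pytest.raises(CorruptStreamError):
        trpx.decode_descriptor(BitReader(blob), None)


def test_encode_descriptor_range_error():
    with pytest.raises(ValueError):
        trpx.encode_descriptor(65, None)


# ---------------------------------------------------------------------------
# compress / decompress

def test_worked_example_block_5_0_3():
    """One 3-value block: depth 3, payload 101 000 011, 13 bits total."""
    frame = np.array([[5, 0, 3]], dtype=np.uint16)
    stream = trpx.compress(frame, block_size=3)
    assert stream.bit_length == 13  # 4-bit descriptor + 9 payload bits
    r = BitReader(stream.payload)
    assert r.read_bits(1) == 0
    assert r.read_bits(3) == 3          # descriptor: depth 3
    assert [r.read_bits(3) for _ in range(3)] == [5, 0, 3]
    assert trpx.decompress(stream, frame_index=0).tolist() == [[5, 0, 3]]


def test_all_zero_frame_closed_form_size():
    """512x512 zeros, block 12: one 4-bit descriptor + 21,845 repeat bits."""
    stream = trpx.compress(np.zeros((512, 512), dtype=np.uint16))
    assert stream.bit_length == 4 + 21_845
    assert len(stream.payload) == 2_732
    assert (trpx.decompress(stream) == 0).all()


def test_depth0_blocks_have_no_payload_in_signed_mode_too():
    stream = trpx.compress(np.zeros((1, 24), dtype=np.int32))
    assert stream.bit_length == 4 + 1  # two blocks: fresh depth-0 + repeat
    assert (trpx.decompress(stream) == 0).all()


def test_compressed_stream_is_deterministic(rng):
    stack = random_stack(rng, signed=False, max_depth=12, nframes=3)
    a = trpx.compress(stack, block_size=12)
    b = trpx.compress(stack.copy(), block_size=12)
    assert a.payload == b.payload and a.bit_length == b.bit_length


def test_matches_naive_reference_encoder_bit_for_bit(rng):
    """1,000 random small frames: vectorized and per-value encoders agree."""
    for _ in range(1000):
        signed = bool(rng.integers(0, 2))
        depth = int(rng.integers(0, 64, endpoint=True))
        block_size = int(rng.integers(1, 32, endpoint=True))
        stack = random_stack(rng, signed=signed, max_depth=depth, nframes=1,
                             npix_range=(1, 60))
        stream = trpx.compress(stack, block_size=block_size)
        payload, nbits, offsets = reference_codec.reference_compress(
            stack, block_size, signed)
        assert stream.bit_length == nbits
        assert stream.payload == payload
        assert list(stream.frame_bit_offsets) == offsets


def test_round_trip_with_frame_boundary_reset(rng):
    """Multi-frame stacks: descriptor state resets, frames decode alone."""
    stack = random_stack(rng, signed=True, max_depth=20, nframes=4)
    stream = trpx.compress(stack, block_size=7)
    full = trpx.decompress(stream)
    assert (full == stack).all()
    for k in range(4):
        assert (trpx.decompress(stream, frame_index=k) == stack[k]).all()


def test_signed_sign_extension_from_block_depth():
    """A depth-4 two's-complement field 1011 decodes to -5."""
    w = BitWriter()
    w.write_fields(trpx.encode_descriptor(4, None))
    w.write_bits(0b1011, 4)
    stream = TerseStream(payload=w.to_bytes(), pixel_count=1, frame_count=1,
                         signed=True, bit_length=w.bit_cursor, block_size=12,
                         width=1, height=1, frame_bit_offsets=(0,))
    assert trpx.decompress(stream)[0, 0, 0] == -5


def test_clamp_to_narrow_output_dtype_warns():
    stream = trpx.compress(np.array([[300, 5]], dtype=np.uint16))
    with pytest.warns(UserWarning, match="clamp"):
        out = trpx.decompress(stream, dtype=np.uint8)
    assert out.ravel().tolist() == [255, 5]


def test_clamp_signed_to_unsigned_floor():
    stream = trpx.compress(np.array([[-3, 7]], dtype=np.int16))
    with pytest.warns(UserWarning):
        out = trpx.decompress(stream, dtype=np.uint8)
    assert out.ravel().tolist() == [0, 7]


def test_usage_errors():
    with pytest.raises(ValueError):
        trpx.compress([np.zeros((2, 2), np.uint8), np.zeros((3, 2), np.uint8)])
    with pytest.raises(ValueError):
        trpx.compress(np.array([[-1]], dtype=np.int16), signed=False)
    with pytest.raises(ValueError):
        trpx.compress(np.zeros((2, 2), np.float32))
    with pytest.raises(ValueError):
        trpx.compress(np.zeros((2, 2), np.uint8), block_size=0)
    with pytest.raises(ValueError):
        trpx.compression_efficiency(0, 10)


def test_distinct_diagnostics_for_corrupt_and_truncated_streams():
    good = trpx.compress(np.arange(24, dtype=np.uint16).reshape(1, 24))
    with pytest.raises(IndexError):
        trpx.decompress(good, frame_index=1)
    # truncated payload: header promises more bits than the buffer holds
    with pytest.raises(TruncatedStreamError):
        TerseStream(payload=good.payload[:1], pixel_count=24, frame_count=1,
                    signed=False, bit_length=good.bit_length,
                    frame_bit_offsets=(0,))
    # corrupt: repeat flag on the first descriptor of a frame
    bad = TerseStream(payload=b"\x01", pixel_count=1, frame_count=1,
                      signed=False, bit_length=1, frame_bit_offsets=(0,))
    with pytest.raises(CorruptStreamError):
        trpx.decompress(bad)


def test_compression_efficiency_examples():
    assert trpx.compression_efficiency(237_800_000, 38_100_000) == \
        pytest.approx(84.0, abs=0.05)
    assert trpx.compression_efficiency(100, 100) == 0.0
    assert trpx.compression_efficiency(100, 15) == 85.0
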