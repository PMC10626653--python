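# Methods

## The compression model

Diffraction frames from hybrid pixel detectors, and counting-mode
cryo-EM movie frames, are integral grayscale images whose pixels are
spatially correlated: between and beyond the Bragg peaks the counts are
near zero, while peak pixels may need tens of bits.  TRPX exploits this
by coding each run of `block_size` consecutive row-major values at the
minimal shared bit depth of that block, after stripping the most
significant bits they have in common — all zero for unsigned data, all
equal to the sign extension for signed two's-complement data.  Each
block is prefixed by a variable-length descriptor (1, 4, 6 or 12 bits)
giving that depth, with a single set bit meaning "same depth as the
previous block".  The scheme is exactly invertible: no transform,
prediction or entropy stage is involved, and `decompress(compress(x))
== x` for every representable input (values up to 64 bits, signed or
unsigned).

The expected cost on sparse data follows directly: n pixels of
background needing d bits cost about `n·d + n/block_size` bits, so a
16-bit frame whose blocks mostly need 2–3 bits compresses by roughly
85 %, which is what both the real detector data this scheme targets and
the synthetic fixtures here show.  A descriptor-repeat run over an
all-zero frame is the extreme case: a 512×512 zero frame costs one
4-bit descriptor plus 21 845 repeat bits = 2 732 bytes.

## Parameters

* `block_size` (default **12** values) — the trade-off between
  descriptor overhead (one descriptor per block) and depth granularity
  (one outlier raises the whole block's depth).  The default is the
  value the algorithm was designed around; it is recorded in the file
  header, and any value ≥ 1 round-trips.
* `signed` (default: the array dtype's signedness) — signed mode keeps
  a sign bit per value and sign-extends on unpack; unsigned packing of
  non-negative data is one bit per value tighter.
* Output dtype on decompression — any integral type; values outside its
  range are clamped to the type's extremes with a warning (truncation on
  unpack), never wrapped.

## Bit-level conventions

Fields are packed LSB-first within bytes, multi-bit fields low-order
bit first (see `docs/format.md`).  The serialized stream is a pure
function of the write history, so big- and little-endian hosts produce
identical files; the convention is versioned in the container header.
The intra-byte bit order of other TRPX implementations is not public,
so interchange with files they produce is not guaranteed — the format
dialect here is self-contained and golden-file tested.

Descriptor state resets at every frame boundary of a stack and the
header stores per-frame bit offsets, so any frame is independently
decodable in O(that frame) without touching the rest of the stack.
Reading past the end of a stream is a hard error (`TruncatedStreamError`
naming the bit offset); a repeat flag on a frame's first descriptor or
a declared depth above 64 is a `CorruptStreamError`.  Zero-width fields
are legal no-ops, which is how depth-0 (all-zero) blocks carry no
payload.

The production encoder/decoder are vectorized over numpy bit arrays
for throughput; the scalar `BitWriter`/`BitReader` define the
convention and back the per-descriptor API.  The test suite keeps a
deliberately naive per-value encoder (`tests/reference_codec.py`)
written straight from the rules above and requires bit-identical
streams from both routes, plus an independent closed-form size oracle
(Σ over blocks of descriptor bits + block length × depth) that must
equal the produced stream length exactly.

## Synthetic data

The real electron-diffraction and cryo-EM test sets this codec family
is benchmarked on are not publicly deposited, so the package generates
frames with the same statistical character:

* **Diffraction** (`DiffractionModel`): a Poisson background
  (default λ = 0.5 counts/pixel on 512×512 16-bit frames) plus 20
  isotropic Gaussian Bragg spots (σ = 1.5 px) on a square lattice of
  40 px pitch with 2 px positional jitter, peak intensities drawn
  uniformly from 2 000–20 000 counts and Poisson-sampled per pixel.
  λ = 0.5 matches fine phi-sliced hybrid-pixel data where most pixels
  hold 0–2 counts; ≥ 95 % of pixels stay below 8 counts while peak
  maxima reach 10^4.
* **Counting mode** (`generate_counting_stack`): iid Poisson pixels at
  a low event rate (default 0.05 events/pixel/frame, so ~95 % zeros),
  emulating dose-fractionated direct-detector movies.

All randomness flows from one explicit seed; identical seeds give
bit-identical stacks.  The generators capture sparsity and dynamic
range, not physics: no resolution-dependent falloff, beam stop,
detector gain/pedestal, pixel cross-talk or frame-to-frame drift.
Passing the compression-efficiency checks on these fixtures therefore
demonstrates the codec's behaviour on data with the right count
statistics, not a measurement on any particular instrument's output.

On this synthetic family TRPX removes ~87 % of the bytes and beats
zlib at its default level on the same buffers, the qualitative ordering
the codec is known for.  bzip2 and LZMA reach slightly higher ratios
here — as bzip2 also does on real diffraction data — at a large speed
cost; the package benchmarks them but makes no dominance claim over
them.

## Problem sizes and numerical choices

The heavy acceptance check runs the codec end-to-end on 450 synthetic
512×512 16-bit frames (237 MB raw), the size of a typical continuous
rotation dataset; everything else runs on frames of at most a few
hundred pixels, with 1 000-stack randomized round-trip sweeps covering
depths 0–64, both signednesses, block sizes 1–32 and frame lengths not
divisible by the block size.  There is no floating-point arithmetic
anywhere in the codec path, hence no tolerances: every comparison in
the suite is exact equality on integers or bytes.

Tie-breaks and degenerate inputs: an all-zero block has depth 0 in
signed mode too (maximal compression, still invertible); the trailing
partial block of a frame uses the same descriptor rules over its
shorter length; a stack of zero frames is legal and yields an empty
payload; `block_size` may exceed the frame size (one short block).

## Known limitations

* No interchange guarantee with other TRPX implementations (bit order
  unpublished); the dialect here is fixed and documented instead.
* Wall-clock throughput is reported by `trpx bench` but is
  hardware-bound and intentionally untested.
* Only grayscale integral TIFF (and headerless raw with stated
  geometry) is ingested; RGB/float inputs are rejected rather than
  coerced, because losslessness is the product.
* The codec is single-threaded; multi-core scaling and hardware
  (FPGA/ASIC) deployment are out of scope.
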