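"""Exception hierarchy shared across the package."""


class TrpxError(Exception):
    """Base class for all trpx errors."""


class TruncatedStreamError(TrpxError):
    """A read ran past the end of a bit stream or payload.

    Raised instead of silently zero-filling: zero-fill would mask payload
    truncation and turn a corrupt file into plausible-looking pixels.
    """


class CorruptStreamError(TrpxError):
    """The stream violates the descriptor grammar (e.g. a repeat flag at
    stream start, or a descriptor declaring a bit depth above 64)."""


class UnsupportedFormatError(TrpxError):
    """An input file is not a format this package handles losslessly
    (RGB/float/compressed TIFF variants, unknown container versions)."""
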