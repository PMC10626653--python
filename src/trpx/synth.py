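"""Seeded generators of synthetic detector frames.

Two frame families cover the statistics the codec is built for:

* **Electron diffraction** — a sparse Poisson background of a fraction
  of a count per pixel, punctuated by a few tens of intense Bragg peaks.
  Peaks are isotropic Gaussian spots placed on a jittered square
  reciprocal-lattice grid; their photon counts are themselves Poisson,
  so peak pixels carry realistic counting noise.  This reproduces the
  property the codec exploits — most 12-value blocks need only a couple
  of bits, a few need many — without attempting physical diffraction
  simulation (beam stop, resolution falloff, detector gain are not
  modelled).

* **Counting-mode cryo-EM** — dose-fractionated direct-detector movie
  frames: almost all pixels zero, the rest tiny integers (Poisson with
  a low event rate per pixel per frame).

All randomness flows from one explicit integer seed; identical seeds
give bit-identical stacks on any platform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Tuple

import numpy as np

__all__ = [
    "DiffractionModel",
    "generate_diffraction_stack",
    "generate_counting_stack",
]


@dataclass
class DiffractionModel:
    """Statistical model of a sparse electron-diffraction frame.

    Defaults emulate fine phi-sliced hybrid-pixel-detector data:
    512 x 512 16-bit frames, mean background of 0.5 counts/pixel, and
    20 Bragg peaks of order 10^4 counts at their centres.
    """

    width: int = 512
    height: int = 512
    background_rate: float = 0.5     # Poisson lambda, counts / pixel
    peak_count: int = 20
    peak_amplitude_range: Tuple[float, float] = (2_000.0, 20_000.0)  # counts
    peak_sigma: float = 1.5          # Gaussian spot width, pixels
    lattice_spacing: float = 40.0    # reciprocal-lattice pitch, pixels
    lattice_jitter: float = 2.0      # per-peak positional jitter, pixels
    seed: int = 0

    def validate(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("frame dimensions must be positive")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        if self.peak_count < 0:
            raise ValueError("peak_count must be >= 0")
        if self.peak_sigma <= 0 or self.lattice_spacing <= 0:
            raise ValueError("peak_sigma and lattice_spacing must be positive")


def _lattice_sites(model: DiffractionModel) -> np.ndarray:
    """Square grid of candidate Bragg positions covering the frame."""
    xs = np.arange(model.lattice_spacing / 2, model.width, model.lattice_spacing)
    ys = np.arange(model.lattice_spacing / 2, model.height, model.lattice_spacing)
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gy.ravel(), gx.ravel()])  # (row, col)


def generate_diffraction_stack(
    model: DiffractionModel, frames: int, dtype=np.uint16
) -> np.ndarray:
    """Generate a (frames, height, width) stack from ``model``.

    Values exceeding the output dtype are clipped with a warning (the
    model, not the data, overflowed).  Deterministic under the seed.
    """
    model.validate()
    if frames < 0:
        raise ValueError("frame count must be >= 0")
    dtype = np.dtype(dtype)
    info = np.iinfo(dtype)
    rng = np.random.default_rng(model.seed)
    sites = _lattice_sites(model)
    h, w = model.height, model.width
    stack = np.empty((frames, h, w), dtype=dtype)
    halfwin = max(1, int(np.ceil(4 * model.peak_sigma)))
    clipped = 0
    for f in range(frames):
        frame = rng.poisson(model.background_rate, size=(h, w)).astype(np.int64)
        if model.peak_count and sites.size:
            take = min(model.peak_count, len(sites))
            chosen = sites[rng.choice(len(sites), size=take, replace=False)]
            centres = chosen + rng.normal(0, model.lattice_jitter, size=chosen.shape)
            lo_a, hi_a = model.peak_amplitude_range
            amps = rng.uniform(lo_a, hi_a, size=take)
            for (cy, cx), amp in zip(centres, amps):
                y0, y1 = int(max(0, np.floor(cy) - halfwin)), int(min(h, np.floor(cy) + halfwin + 1))
                x0, x1 = int(max(0, np.floor(cx) - halfwin)), int(min(w, np.floor(cx) + halfwin + 1))
                if y0 >= y1 or x0 >= x1:
                    continue
                yy, xx = np.mgrid[y0:y1, x0:x1]
                lam = amp * np.exp(
                    -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * model.peak_sigma ** 2)
                )
                frame[y0:y1, x0:x1] += rng.poisson(lam)
        over = frame > info.max
        clipped += int(np.count_nonzero(over))
        frame[over] = info.max
        stack[f] = frame.astype(dtype)
    if clipped:
        warnings.warn(
            f"{clipped} pixel(s) exceeded {dtype.name} and were clipped; "
            "lower peak_amplitude_range or widen the output dtype",
            UserWarning,
            stacklevel=2,
        )
    return stack


def generate_counting_stack(
    width: int,
    height: int,
    event_rate: float = 0.05,
    frames: int = 1,
    seed: int = 0,
    dtype=np.uint16,
) -> np.ndarray:
    """Sparse counting-mode frames: iid Poisson(``event_rate``) pixels.

    ``event_rate`` is the mean electron events per pixel per frame; at
    the default 0.05 over 99% of pixels are zero.  ``frames=0`` yields
    an empty stack.  Deterministic under the seed.
    """
    if width < 1 or height < 1:
        raise ValueError("frame dimensions must be positive")
    if event_rate < 0:
        raise ValueError("event_rate must be >= 0")
    if frames < 0:
        raise ValueError("frame count must be >= 0")
    rng = np.random.default_rng(seed)
    return rng.poisson(event_rate, size=(frames, height, width)).astype(np.dtype(dtype))
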