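"""Single-branch wavelet decomposition of heart-sound signals.

Every detector in this package works on full-length reconstructions of
individual discrete-wavelet-transform bands: the *detail* branch D_a keeps
only the level-a detail coefficients and the *approximation* branch A_a
keeps only the level-a approximation coefficients, each reconstructed back
to signal length.  Adjacent branches telescope,

    A_{a-1} = A_a + D_a,

so the input equals A_L + D_L + ... + D_1 for any depth L.

At the 4000 Hz analysis rate the ideal dyadic band of D6 is
31.25-62.5 Hz, which covers the 20-60 Hz range where S1 and S2 carry most
of their energy; this is why the detectors lean on the db6 detail branches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
import pywt

from .records import HeartSoundRecord, ValidationError

#: Daubechies bases used by the detectors.
VALID_WAVELETS = ("db5", "db6")

#: Signal-extension mode for decomposition (half-sample symmetric).
BOUNDARY_MODE = "symmetric"

MAX_LEVEL = 6


@dataclass(frozen=True)
class WaveletSpec:
    """Daubechies mother-wavelet choice, restricted to db5 / db6."""

    name: str = "db6"

    def __post_init__(self) -> None:
        if self.name not in VALID_WAVELETS:
            raise ValidationError(
                f"wavelet must be one of {VALID_WAVELETS}, got {self.name!r}")

    @property
    def filter_len(self) -> int:
        return pywt.Wavelet(self.name).dec_len


@dataclass(frozen=True)
class BranchDecomposition:
    """Full-length reconstructed detail and approximation branches.

    ``details[a]`` is D_a, ``approximations[a]`` is A_a, for a = 1..level;
    every branch has the length of the input signal.
    """

    details: Mapping[int, np.ndarray]
    approximations: Mapping[int, np.ndarray]
    fs: float
    spec: WaveletSpec

    @property
    def levels(self) -> tuple[int, ...]:
        return tuple(sorted(self.details))

    def reconstruct(self) -> np.ndarray:
        """Sum of deepest approximation and all details (equals the input)."""
        deepest = max(self.details)
        total = self.approximations[deepest].copy()
        for a in self.details:
            total += self.details[a]
        return total


def reconstruct_branch(x: np.ndarray, wavelet: str, level: int,
                       kind: Literal["detail", "approx"]) -> np.ndarray:
    """Reconstruct one wavelet band of ``x`` at full signal length.

    Decomposes to ``level``, zeroes every coefficient band except the
    requested one, and inverts the transform, truncating to ``len(x)``.
    """
    if wavelet not in VALID_WAVELETS:
        raise ValidationError(f"wavelet must be one of {VALID_WAVELETS}")
    if level < 1 or level > MAX_LEVEL:
        raise ValidationError(f"level must be in 1..{MAX_LEVEL}, got {level}")
    x = np.asarray(x, dtype=float)
    if x.size < pywt.Wavelet(wavelet).dec_len:
        raise ValidationError("signal shorter than one wavelet filter support")
    coeffs = pywt.wavedec(x, wavelet, mode=BOUNDARY_MODE, level=level)
    keep = 0 if kind == "approx" else 1  # [cA_L, cD_L, cD_{L-1}, ..., cD_1]
    coeffs = [c if i == keep else np.zeros_like(c) for i, c in enumerate(coeffs)]
    rec = pywt.waverec(coeffs, wavelet, mode=BOUNDARY_MODE)
    return rec[: x.size]


def decompose(rec: HeartSoundRecord, spec: WaveletSpec = WaveletSpec(),
              max_level: int = MAX_LEVEL) -> BranchDecomposition:
    """Branch decomposition of a record for levels 1..max_level."""
    if max_level < 1 or max_level > MAX_LEVEL:
        raise ValidationError(f"max_level must be in 1..{MAX_LEVEL}")
    details = {}
    approximations = {}
    for a in range(1, max_level + 1):
        details[a] = reconstruct_branch(rec.samples, spec.name, a, "detail")
        approximations[a] = reconstruct_branch(rec.samples, spec.name, a, "approx")
    return BranchDecomposition(details, approximations, rec.fs, spec)


def summed_details(x: np.ndarray, wavelet: str, levels: tuple[int, ...]) -> np.ndarray:
    """Sum of detail branches D_a for the given levels (one decomposition)."""
    deepest = max(levels)
    coeffs = pywt.wavedec(np.asarray(x, dtype=float), wavelet,
                          mode=BOUNDARY_MODE, level=deepest)
    # coeffs layout: [cA_L, cD_L, cD_{L-1}, ..., cD_1]; detail level a sits
    # at index deepest - a + 1.
    keep_idx = {deepest - a + 1 for a in levels}
    coeffs = [c if i in keep_idx else np.zeros_like(c)
              for i, c in enumerate(coeffs)]
    rec = pywt.waverec(coeffs, wavelet, mode=BOUNDARY_MODE)
    return rec[: np.asarray(x).size]


def dyadic_band(fs: float, level: int) -> tuple[float, float]:
    """Ideal dyadic frequency band (low, high) in Hz of detail level ``a``.

    ``(fs / 2**(level+1), fs / 2**level)`` — e.g. D6 at 4000 Hz covers
    31.25-62.5 Hz.
    """
    if level < 1:
        raise ValidationError("level must be >= 1")
    return fs / 2.0 ** (level + 1), fs / 2.0 ** level
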