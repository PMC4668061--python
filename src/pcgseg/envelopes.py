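"""Normalized Shannon-energy envelopes (envelograms).

The Shannon energy of a frame, E = -(1/N) Σ u·ln(u) with u = |x̂|^k,
emphasizes medium-intensity samples relative to both low- and
high-intensity ones, which makes the burst-like S1/S2 sounds stand out.
The 2nd-order (k = 2) and 3rd-order (k = 3) variants are the common
features of the envelope-threshold detectors.

Frames are 20 ms with a 10 ms hop by default; each envelope value is
stamped with the time of its frame center so envelope-domain decisions can
be mapped back to sample time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .records import PCGError, SilentRecordError

log = logging.getLogger(__name__)

DEFAULT_FRAME_S = 0.020
DEFAULT_HOP_S = 0.010


class DegenerateEnvelopeError(PCGError):
    """Raised when an envelope has zero variance and cannot be standardized."""


@dataclass(frozen=True)
class EnvelopeSignal:
    """Framewise envelope with frame-timing metadata.

    ``values[k]`` summarizes the frame whose center falls at
    ``t0_s + k / fs_frames`` seconds.
    """

    values: np.ndarray
    frame_len_s: float
    hop_s: float
    t0_s: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(values)):
            raise PCGError("envelope values must be finite")
        if self.frame_len_s <= 0 or not (0 < self.hop_s <= self.frame_len_s):
            raise PCGError("need frame_len_s > 0 and 0 < hop_s <= frame_len_s")
        object.__setattr__(self, "values", values)

    @property
    def fs_frames(self) -> float:
        return 1.0 / self.hop_s

    @property
    def frame_centers_s(self) -> np.ndarray:
        return self.t0_s + np.arange(self.values.size) * self.hop_s

    def replace_values(self, values: np.ndarray) -> "EnvelopeSignal":
        return EnvelopeSignal(values, self.frame_len_s, self.hop_s, self.t0_s)


def unit_normalize(x: np.ndarray) -> np.ndarray:
    """Scale a signal to unit peak magnitude, x̂ = x / max|x|.

    Raises
    ------
    SilentRecordError
        For an all-zero input ("silent feature signal").
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise SilentRecordError("empty feature signal")
    peak = np.max(np.abs(x))
    if peak == 0.0:
        raise SilentRecordError("silent feature signal")
    return x / peak


def _frame_starts(n: int, frame: int, hop: int) -> np.ndarray:
    if frame > n:
        log.warning("frame (%d samples) longer than signal (%d); "
                    "using one shortened frame", frame, n)
        return np.array([0])
    count = (n - frame) // hop + 1
    return np.arange(count) * hop


def shannon_energy(xhat: np.ndarray, order: int = 2,
                   frame_len_s: float = DEFAULT_FRAME_S,
                   hop_s: float = DEFAULT_HOP_S,
                   fs: float = 4000.0) -> EnvelopeSignal:
    """Framewise average Shannon energy of a unit-peak signal.

    Per frame of N samples, E = -(1/N) Σ u_i · ln(u_i) with u_i = |x̂_i|^order
    and the convention 0·ln 0 := 0.  Using the magnitude keeps the logarithm
    defined for odd orders (x̂³ can be negative); for order 2 the magnitude
    changes nothing.

    ``order`` must be 2 or 3 — the two variants used by the envelope
    detectors.
    """
    if order not in (2, 3):
        raise PCGError(f"Shannon-energy order must be 2 or 3, got {order}")
    xhat = np.asarray(xhat, dtype=float)
    if np.max(np.abs(xhat)) > 1.0 + 1e-12:
        raise PCGError("shannon_energy expects a unit-peak signal; "
                       "apply unit_normalize first")
    u = np.abs(xhat) ** order
    # -u·ln u, with 0·ln 0 := 0 (the integrand's continuous limit).
    terms = np.zeros_like(u)
    nz = u > 0
    terms[nz] = -u[nz] * np.log(u[nz])

    frame = max(1, int(round(frame_len_s * fs)))
    hop = max(1, int(round(hop_s * fs)))
    starts = _frame_starts(xhat.size, frame, hop)
    if xhat.size < frame:  # single shortened frame
        values = np.array([terms.mean()])
        t0 = xhat.size / (2.0 * fs)
    else:
        csum = np.concatenate([[0.0], np.cumsum(terms)])
        values = (csum[starts + frame] - csum[starts]) / frame
        t0 = frame / (2.0 * fs)
    return EnvelopeSignal(values, frame_len_s, hop_s, t0)


def standardize(env: EnvelopeSignal, ddof: int = 1) -> EnvelopeSignal:
    """Zero-mean, unit-standard-deviation envelope, Ê = (E - μ)/σ.

    μ and σ are taken over the whole recording.  ``ddof=1`` (sample
    standard deviation) is the default; set ``ddof=0`` for the population
    convention.

    Raises
    ------
    DegenerateEnvelopeError
        If the envelope is constant (σ = 0) or has fewer than 2 frames.
    """
    values = env.values
    if values.size < 2:
        raise DegenerateEnvelopeError("need at least 2 frames to standardize")
    sigma = values.std(ddof=ddof)
    if sigma == 0.0:
        raise DegenerateEnvelopeError("degenerate envelope (zero variance)")
    return env.replace_values((values - values.mean()) / sigma)
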