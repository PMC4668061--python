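"""Event-related dual-moving-average S1/S2 detector (Method V).

The detector squares the db6 D6 branch of the record, smooths the squared
signal with two centered moving averages — a short one (W1, about one
S1/S2 peak duration) and a long one (W2, about one whole heart-sound
duration) — and keeps the samples where the short average rises above the
long average plus a dynamic offset α = β·ȳ.  Maximal runs of such samples
are *blocks of interest*; blocks narrower than a minimum width are rejected
as noise, the remaining ones are localized at the extremum of |D6| and the
events are labelled S1/S2 from the inter-event intervals (systole is
shorter than diastole).

This module also hosts the region/localization/labelling primitives shared
with the envelope-threshold baseline detectors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .records import (EventTable, HeartSoundRecord, InsufficientEventsError,
                      PCGError, alternating_labels)
from .wavelets import reconstruct_branch

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Region:
    """Half-open sample-index interval [onset, offset)."""

    onset_idx: int
    offset_idx: int

    def __post_init__(self) -> None:
        if self.offset_idx <= self.onset_idx:
            raise PCGError("region offset must exceed onset")

    @property
    def width(self) -> int:
        return self.offset_idx - self.onset_idx


@dataclass(frozen=True)
class MethodVParams:
    """Tunable parameters of the dual-moving-average detector.

    w1_s
        First (peak) moving-average window in seconds; default 0.130,
        matching the typical S1/S2 duration.
    w2_s
        Second (wave) moving-average window in seconds; default 0.270.
    block_s
        Minimum surviving block width in seconds; default 0.060.
    beta
        Offset fraction of the squared-signal mean, α = β·ȳ; default 0.03.
    """

    w1_s: float = 0.130
    w2_s: float = 0.270
    block_s: float = 0.060
    beta: float = 0.03

    def __post_init__(self) -> None:
        if not (0 < self.w1_s < self.w2_s):
            raise PCGError("need 0 < w1_s < w2_s")
        if not (0 < self.block_s <= self.w1_s):
            raise PCGError("need 0 < block_s <= w1_s")
        if not (0.0 <= self.beta <= 0.10):
            raise PCGError("beta must lie in [0, 0.10]")


@dataclass(frozen=True)
class MethodVTrace:
    """Intermediate signals of a Method V run, for inspection/plotting."""

    y: np.ndarray
    ma_peak: np.ndarray
    ma_wave: np.ndarray
    y_mean: float
    alpha: float
    thr1: np.ndarray
    thr2_samples: int
    blocks: tuple[Region, ...] = field(default=())

    def to_frame(self, fs: float):
        """Per-sample trace as a DataFrame (for debugging/plotting)."""
        import pandas as pd

        in_block = np.zeros(self.y.size, dtype=bool)
        for b in self.blocks:
            in_block[b.onset_idx:b.offset_idx] = True
        return pd.DataFrame({"t_s": np.arange(self.y.size) / fs,
                             "y": self.y, "ma_peak": self.ma_peak,
                             "ma_wave": self.ma_wave, "thr1": self.thr1,
                             "block": in_block.astype(int)})


def square(x: np.ndarray) -> np.ndarray:
    """y[n] = x[n]²; emphasizes large fluctuations over small ones."""
    x = np.asarray(x, dtype=float)
    return x * x


def odd_window_samples(w_s: float, fs: float) -> int:
    """Window length in samples, rounded to the nearest odd integer (>= 1).

    Half-integer ties round up (520 samples -> 521).
    """
    n = w_s * fs
    w = 2 * int(math.floor((n - 1) / 2 + 0.5)) + 1
    return max(w, 1)


def moving_average(y: np.ndarray, w_s: float, fs: float) -> np.ndarray:
    """Centered moving mean with a window of round-to-odd(w_s·fs) samples.

    At the record edges the mean is taken over the available samples
    (shrinking window), so leading/trailing events are not suppressed by
    zero padding.
    """
    if w_s <= 0:
        raise PCGError("moving-average window must be positive")
    y = np.asarray(y, dtype=float)
    w = odd_window_samples(w_s, fs)
    if w == 1:
        log.warning("moving-average window of 1 sample; returning input")
        return y.copy()
    half = w // 2
    n = y.size
    csum = np.concatenate([[0.0], np.cumsum(y)])
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def regions_from_mask(mask: np.ndarray) -> list[Region]:
    """Maximal runs of True in a boolean mask, as half-open regions."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    edges = np.diff(mask.astype(np.int8))
    onsets = np.flatnonzero(edges == 1) + 1
    offsets = np.flatnonzero(edges == -1) + 1
    if mask[0]:
        onsets = np.concatenate([[0], onsets])
    if mask[-1]:
        offsets = np.concatenate([offsets, [mask.size]])
    return [Region(int(a), int(b)) for a, b in zip(onsets, offsets)]


def blocks_of_interest(ma_peak: np.ndarray, thr1: np.ndarray) -> list[Region]:
    """Maximal runs where MA_peak strictly exceeds THR1."""
    ma_peak = np.asarray(ma_peak, dtype=float)
    thr1 = np.asarray(thr1, dtype=float)
    if ma_peak.shape != thr1.shape:
        raise PCGError("ma_peak and thr1 must have equal length")
    return regions_from_mask(ma_peak > thr1)


def filter_blocks(blocks: Sequence[Region], thr2_samples: int) -> list[Region]:
    """Keep exactly the blocks at least ``thr2_samples`` wide."""
    if thr2_samples < 1:
        raise PCGError("minimum block width must be >= 1 sample")
    return [b for b in blocks if b.width >= thr2_samples]


def localize_peaks(blocks: Sequence[Region], x: np.ndarray) -> np.ndarray:
    """One event index per block: earliest argmax of |x| inside the block."""
    x = np.asarray(x, dtype=float)
    indices = []
    for b in blocks:
        if b.onset_idx < 0 or b.offset_idx > x.size:
            raise PCGError("block lies outside the signal")
        seg = np.abs(x[b.onset_idx:b.offset_idx])
        indices.append(b.onset_idx + int(np.argmax(seg)))
    return np.asarray(indices, dtype=int)


def label_s1_s2(event_indices: np.ndarray, fs: float) -> EventTable:
    """Assign S1/S2 labels from inter-event intervals.

    Systole (the S1→S2 interval) is shorter than diastole (S2→S1), so the
    earlier event of the shorter of two adjacent intervals is an S1.  The
    rule is applied to consecutive event pairs, stepping by two: for pair
    (e_k, e_{k+1}), if the interval e_k→e_{k+1} is shorter than the
    following interval the pair is (S1, S2), otherwise (S2, S1).  A pair
    or trailing event with no following interval is decided against the
    preceding interval instead.

    Labelling each pair locally keeps a missed or spurious event from
    corrupting labels beyond its own neighbourhood; on a complete event
    sequence the output alternates strictly.

    Raises
    ------
    InsufficientEventsError
        With fewer than 3 events no interval comparison is possible.
    """
    idx = np.asarray(event_indices, dtype=float)
    if idx.size < 3:
        raise InsufficientEventsError(
            f"insufficient events to label ({idx.size} < 3)")
    times = np.sort(idx) / fs
    intervals = np.diff(times)
    m = times.size
    labels: list[str] = [""] * m
    for k in range(0, m - 1, 2):
        if k + 1 < intervals.size:
            first_is_s1 = intervals[k] < intervals[k + 1]
        else:  # last pair: compare against the interval before it
            first_is_s1 = intervals[k] < intervals[k - 1]
        labels[k] = "S1" if first_is_s1 else "S2"
        labels[k + 1] = "S2" if first_is_s1 else "S1"
    if m % 2 == 1:  # trailing unpaired event terminates interval m-2
        last_is_systolic = intervals[m - 2] < intervals[m - 3]
        labels[m - 1] = "S2" if last_is_systolic else "S1"
    return EventTable(times, tuple(labels))


def detect_from_feature(x: np.ndarray, fs: float,
                        params: MethodVParams = MethodVParams(),
                        localize_on: np.ndarray | None = None,
                        return_trace: bool = False):
    """Run the dual-moving-average pipeline on a precomputed feature signal.

    ``x`` is normally the db6 D6 branch of the record; exposing this entry
    point lets the brute-force parameter search reuse one decomposition
    across thousands of parameter points.

    ``localize_on`` is the signal whose absolute extremum inside each
    surviving block becomes the event time; it defaults to the raw record
    samples when the caller supplies them (see :func:`detect_method_v`),
    falling back to ``x``.  Localizing on the raw waveform matches the
    annotation convention (reference points sit at the raw-signal
    extremum); the D6 branch places events on the same sounds but its
    envelope is not phase-flat, so its extremum can sit one carrier
    half-period (10-13 ms) away from the raw extremum.
    """
    x = np.asarray(x, dtype=float)
    y = square(x)
    ma_peak = moving_average(y, params.w1_s, fs)
    ma_wave = moving_average(y, params.w2_s, fs)
    y_mean = float(y.mean())
    alpha = params.beta * y_mean
    thr1 = ma_wave + alpha
    blocks = blocks_of_interest(ma_peak, thr1)
    thr2 = max(1, int(round(params.block_s * fs)))
    surviving = filter_blocks(blocks, thr2)
    trace = MethodVTrace(y, ma_peak, ma_wave, y_mean, alpha, thr1, thr2,
                         tuple(surviving))
    if not surviving:
        log.warning("no blocks survived width filtering; empty event table")
        table = EventTable.empty()
    else:
        target = x if localize_on is None else np.asarray(localize_on, float)
        indices = localize_peaks(surviving, target)
        table = label_s1_s2(indices, fs)
    return (table, trace) if return_trace else table


def detect_method_v(rec: HeartSoundRecord,
                    params: MethodVParams = MethodVParams(),
                    return_trace: bool = False):
    """Detect S1/S2 events with the dual-moving-average method.

    The record is unit-peak normalized, its db6 D6 detail branch is taken
    as the feature x, and :func:`detect_from_feature` does the rest;
    events are localized at the raw-waveform extremum inside each block.
    Raises :class:`SilentRecordError` on an all-zero record.
    """
    rec = rec.normalized()
    log.info("method V on %r: W1=%g s W2=%g s block=%g s beta=%g",
             rec.source_id, params.w1_s, params.w2_s, params.block_s,
             params.beta)
    x = reconstruct_branch(rec.samples, "db6", 6, "detail")
    return detect_from_feature(x, rec.fs, params, localize_on=rec.samples,
                               return_trace=return_trace)
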