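"""Additive white Gaussian noise and the SNR robustness sweep.

Noise is calibrated against the empirical signal power,

    P_noise = P_signal / 10^(SNR_dB / 10),

and added after unit-peak normalization, before any wavelet analysis.  The
sweep corrupts every corpus record at each SNR level, runs the selected
detectors, and pools TP/FP/FN counts per (method, level) cell.
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd

from .baselines import METHOD_NAMES, detect
from .evaluation import MatchResult, match_events, metrics
from .records import EventTable, HeartSoundRecord, PCGError, SilentRecordError
from .synth import SynthRecord

log = logging.getLogger(__name__)

#: Default SNR grid in dB, high to low.
DEFAULT_SNR_GRID = (30.0, 25.0, 20.0, 15.0, 10.0, 5.0, 0.0)

#: Sentinel for "no added noise" in a sweep.
CLEAN = math.inf


def add_awgn(rec: HeartSoundRecord, snr_db: float,
             seed: int | np.random.Generator) -> HeartSoundRecord:
    """Add zero-mean white Gaussian noise at the requested SNR.

    Deterministic given the seed.  Raises :class:`SilentRecordError` for an
    all-zero record (its SNR is undefined).
    """
    if rec.is_silent:
        raise SilentRecordError("cannot set an SNR on a silent record")
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) \
        else seed
    power = float(np.mean(rec.samples ** 2))
    noise_sd = math.sqrt(power / 10.0 ** (snr_db / 10.0))
    noisy = rec.samples + rng.normal(0.0, noise_sd, rec.samples.size)
    return HeartSoundRecord(noisy, rec.fs, f"{rec.source_id}+{snr_db:g}dB")


def _as_pairs(corpus: Sequence) -> list[tuple[HeartSoundRecord, EventTable]]:
    pairs = []
    for item in corpus:
        if isinstance(item, SynthRecord):
            pairs.append((item.record, item.annotations))
        else:
            rec, ann = item
            pairs.append((rec, ann))
    return pairs


def snr_sweep(corpus: Sequence, methods: Sequence[str] = METHOD_NAMES,
              levels: Sequence[float] = DEFAULT_SNR_GRID,
              tol_s: float = 0.005, seed: int = 0) -> pd.DataFrame:
    """Detector performance across SNR levels, pooled over the corpus.

    Every record gets an independent noise stream derived from ``seed`` and
    a (level, record) counter, so all methods at a given level see the same
    corrupted record and changing the corpus size does not reshuffle noise.
    A detector failure on a record is logged and scored as all-FN for that
    record.  The sentinel level ``math.inf`` means "no added noise".

    Returns a tidy DataFrame with one row per (method, snr_db) cell.
    """
    pairs = _as_pairs(corpus)
    if not pairs:
        raise PCGError("corpus must be non-empty")
    for m in methods:
        if m.upper() not in METHOD_NAMES:
            raise PCGError(f"unknown method {m!r}")
    rows = []
    for lvl_idx, snr_db in enumerate(levels):
        corrupted = []
        for rec_idx, (rec, ann) in enumerate(pairs):
            if math.isinf(snr_db):
                corrupted.append((rec, ann))
            else:
                rng = np.random.default_rng([seed, lvl_idx, rec_idx])
                corrupted.append((add_awgn(rec, snr_db, rng), ann))
        for method in methods:
            pooled = MatchResult(0, 0, 0)
            for rec, ann in corrupted:
                try:
                    detected = detect(rec, method)
                except PCGError as exc:
                    log.warning("method %s failed on %r at %g dB (%s); "
                                "scoring all-FN", method, rec.source_id,
                                snr_db, exc)
                    detected = None
                if detected is None:
                    pooled = pooled + MatchResult(0, 0, len(ann))
                else:
                    pooled = pooled + match_events(detected, ann, tol_s)
            mets = metrics(pooled)
            rows.append({"method": method.upper(), "snr_db": snr_db,
                         "TP": pooled.TP, "FP": pooled.FP, "FN": pooled.FN,
                         "SE": mets.SE, "PPV": mets.PPV,
                         "overall": mets.overall, "seed": seed})
    return pd.DataFrame(rows)


def min_winning_snr(table: pd.DataFrame, champion: str = "V",
                    contiguous: bool = True) -> float:
    """Smallest grid SNR at which the champion beats every other method.

    With ``contiguous=True`` (default) the returned level L additionally
    requires the champion to win at every grid level above L, i.e. it is
    the bottom of an unbroken winning streak from the top of the grid.
    With ``contiguous=False`` it is simply the lowest grid level with a
    strict win, regardless of intermediate ties.  Raises if the champion
    never wins.
    """
    levels = sorted(table["snr_db"].unique(), reverse=True)
    best: float | None = None
    for lvl in levels:
        cell = table[table["snr_db"] == lvl].set_index("method")["overall"]
        others = [m for m in cell.index if m != champion]
        if all(cell[champion] > cell[m] for m in others):
            best = lvl
        elif contiguous:
            break
    if best is None:
        raise PCGError(f"method {champion} does not lead at any SNR level")
    return float(best)
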