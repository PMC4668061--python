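"""Reading and writing WAV recordings and S1/S2 event tables.

Recordings are mono RIFF/PCM WAV files; 16/24/32-bit integer and IEEE float
encodings are accepted on read, 16-bit PCM is written.  Event tables are CSV
with columns ``time_s,label``.
"""

from __future__ import annotations

import logging
from fractions import Fraction
from os import PathLike
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly

from .records import EventTable, HeartSoundRecord, ValidationError

log = logging.getLogger(__name__)

ANALYSIS_FS = 4000.0

_FULL_SCALE = {
    np.dtype(np.int16): 2.0 ** 15,
    np.dtype(np.int32): 2.0 ** 31,
    np.dtype(np.uint8): 2.0 ** 7,
}


def read_wav(path: str | PathLike) -> HeartSoundRecord:
    """Read a mono PCM/float WAV file into a :class:`HeartSoundRecord`.

    Integer samples are scaled by the format's full-scale value so the
    result lies in [-1, 1]; float samples are taken as-is.

    Raises
    ------
    ValidationError
        If the file is multi-channel ("mono required") or unreadable.
    """
    path = Path(path)
    try:
        fs, data = wavfile.read(path)
    except ValueError as exc:
        raise ValidationError(f"unreadable WAV file {path}: {exc}") from exc
    if data.ndim != 1:
        raise ValidationError(f"mono required: {path} has {data.shape[1]} channels")
    if data.dtype in _FULL_SCALE:
        scale = _FULL_SCALE[data.dtype]
        samples = data.astype(float)
        if data.dtype == np.dtype(np.uint8):  # unsigned 8-bit is offset binary
            samples -= 128.0
        samples /= scale
    elif np.issubdtype(data.dtype, np.floating):
        samples = data.astype(float)
    else:
        raise ValidationError(f"unsupported WAV sample format {data.dtype}")
    return HeartSoundRecord(samples, float(fs), source_id=path.stem)


def write_wav(rec: HeartSoundRecord, path: str | PathLike) -> None:
    """Write a record as 16-bit PCM mono WAV (values clipped to [-1, 1])."""
    clipped = np.clip(rec.samples, -1.0, 1.0)
    quantized = np.clip(np.round(clipped * 2.0 ** 15), -(2 ** 15),
                        2 ** 15 - 1).astype(np.int16)
    wavfile.write(Path(path), int(round(rec.fs)), quantized)


def ensure_analysis_rate(rec: HeartSoundRecord,
                         target_fs: float = ANALYSIS_FS) -> HeartSoundRecord:
    """Bring a record to the analysis sampling rate and unit peak amplitude.

    The wavelet level-to-band mapping used by all detectors assumes 4000 Hz,
    so records at other rates are band-limited resampled on ingest.  The
    output has ``max(|samples|) == 1`` unless the record is all-zero, in
    which case it is passed through with a warning (there is nothing to
    rescale).
    """
    samples = rec.samples
    if rec.fs != target_fs:
        ratio = Fraction(target_fs / rec.fs).limit_denominator(1000)
        log.warning("resampling %r from %g Hz to %g Hz",
                    rec.source_id, rec.fs, target_fs)
        samples = resample_poly(samples, ratio.numerator, ratio.denominator)
    peak = np.max(np.abs(samples))
    if peak == 0.0:
        log.warning("silent record %r passed through unscaled", rec.source_id)
        return HeartSoundRecord(samples, target_fs, rec.source_id)
    return HeartSoundRecord(samples / peak, target_fs, rec.source_id)


def read_events(path: str | PathLike) -> EventTable:
    """Read an event CSV (columns ``time_s,label``) into an EventTable.

    Raises :class:`ValidationError` on non-monotone times or unknown labels.
    """
    frame = pd.read_csv(path)
    missing = {"time_s", "label"} - set(frame.columns)
    if missing:
        raise ValidationError(f"event file {path} lacks columns {sorted(missing)}")
    table = EventTable(frame["time_s"].to_numpy(dtype=float),
                       tuple(str(lab) for lab in frame["label"]))
    return table


def write_events(table: EventTable, path: str | PathLike) -> None:
    """Write an event table as CSV with millisecond-or-better precision."""
    frame = table.to_frame()
    frame["time_s"] = frame["time_s"].map(lambda t: format(t, ".6f"))
    frame.to_csv(path, index=False)
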