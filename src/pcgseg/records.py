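"""Core domain types: heart-sound records and S1/S2 event tables.

A phonocardiogram (PCG) is a digitized acoustic recording of heart sounds.
The first heart sound (S1) marks the onset of systole, the second (S2) the
onset of diastole.  All downstream analysis works on a
:class:`HeartSoundRecord` (amplitude-normalized waveform plus sampling rate)
and produces or consumes :class:`EventTable` objects (ordered, labelled
event times).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

VALID_LABELS = ("S1", "S2")


class PCGError(Exception):
    """Base class for domain errors."""


class SilentRecordError(PCGError):
    """Raised when an operation needs a non-silent (non-all-zero) signal."""


class ValidationError(PCGError):
    """Raised on malformed inputs (files, tables, parameters)."""


class InsufficientEventsError(PCGError):
    """Raised when fewer than three events prevent S1/S2 labelling."""


@dataclass(frozen=True)
class HeartSoundRecord:
    """A sampled heart-sound waveform.

    Parameters
    ----------
    samples
        Dimensionless amplitude sequence; for analysis it is scaled so that
        ``max(|samples|) == 1`` unless the record is all-zero.
    fs
        Sampling rate in Hz (must be positive).
    source_id
        Free-text identifier (file stem, synthesis seed, ...).
    """

    samples: np.ndarray
    fs: float
    source_id: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size == 0:
            raise ValidationError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(samples)):
            raise ValidationError("samples must be finite")
        if not (self.fs > 0):
            raise ValidationError("sampling rate must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    @property
    def is_silent(self) -> bool:
        return bool(np.max(np.abs(self.samples)) == 0.0)

    def normalized(self) -> "HeartSoundRecord":
        """Return a copy scaled to unit peak amplitude.

        Raises
        ------
        SilentRecordError
            If the record is all-zero (there is no peak to scale to).
        """
        peak = np.max(np.abs(self.samples))
        if peak == 0.0:
            raise SilentRecordError(f"silent record: {self.source_id!r}")
        if peak == 1.0:
            return self
        return HeartSoundRecord(self.samples / peak, self.fs, self.source_id)


@dataclass(frozen=True)
class EventTable:
    """Ordered list of (time, label) heart-sound events.

    Times are seconds from record start and must be strictly increasing.
    Labels are ``"S1"`` or ``"S2"``; in a complete table they alternate,
    but partial tables (record edges, missed detections) are permitted.
    """

    times_s: np.ndarray
    labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        times = np.asarray(self.times_s, dtype=float)
        labels = tuple(self.labels)
        if times.ndim != 1:
            raise ValidationError("event times must be 1-D")
        if len(labels) != times.size:
            raise ValidationError("times and labels must have equal length")
        if times.size and np.any(np.diff(times) <= 0):
            raise ValidationError("event times must be strictly increasing")
        for lab in labels:
            if lab not in VALID_LABELS:
                raise ValidationError(f"unknown event label {lab!r}")
        object.__setattr__(self, "times_s", times)
        object.__setattr__(self, "labels", labels)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[float, str]]) -> "EventTable":
        pairs = list(pairs)
        return cls(np.array([t for t, _ in pairs], dtype=float),
                   tuple(lab for _, lab in pairs))

    @classmethod
    def empty(cls) -> "EventTable":
        return cls(np.empty(0, dtype=float), ())

    def __len__(self) -> int:
        return int(self.times_s.size)

    def __iter__(self) -> Iterator[tuple[float, str]]:
        return iter(zip(self.times_s.tolist(), self.labels))

    def select(self, label: str) -> "EventTable":
        if label not in VALID_LABELS:
            raise ValidationError(f"unknown event label {label!r}")
        keep = [i for i, lab in enumerate(self.labels) if lab == label]
        return EventTable(self.times_s[keep], tuple(self.labels[i] for i in keep))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times_s, "label": list(self.labels)})

    def alternates(self) -> bool:
        """True when labels strictly alternate S1/S2 (vacuously for < 2)."""
        return all(a != b for a, b in zip(self.labels, self.labels[1:]))


def alternating_labels(n: int, first: str = "S1") -> tuple[str, ...]:
    """S1/S2 labels of length ``n`` alternating from ``first``."""
    if first not in VALID_LABELS:
        raise ValidationError(f"unknown event label {first!r}")
    other = "S2" if first == "S1" else "S1"
    return tuple(first if i % 2 == 0 else other for i in range(n))
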