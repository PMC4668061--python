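"""Synthetic annotated phonocardiograms.

The generator emulates the structural properties real pediatric heart-sound
recordings exhibit: beats at 65-134 bpm with a few percent RR jitter,
systole strictly shorter than diastole, S1/S2 bursts of roughly 120 ± 30 ms
duration with dominant energy in the 20-60 Hz band, variable S1:S2
amplitude ratios (including low-S1 and low-S2 morphologies), and additive
broadband background noise.  Each burst is a Gaussian-windowed cosine, the
simplest model with the right duration and frequency content; ground-truth
annotations are placed at the realized extremum of |signal| inside each
burst, so an ideal detector can score 100% at a ±5 ms tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .records import (EventTable, HeartSoundRecord, PCGError,
                      alternating_labels)

#: (s1_amp, s2_amp) morphologies cycled through a corpus: balanced,
#: low-S1 and low-S2 scenarios.
AMPLITUDE_SCENARIOS = ((1.0, 0.8), (0.3, 1.0), (1.0, 0.3))

#: Heart-rate range (bpm) spanned by a default corpus.
DEFAULT_HR_RANGE = (65.0, 134.0)


class InfeasibleBeatError(PCGError):
    """Raised when HR/duration parameters make S1 and S2 bursts collide."""


@dataclass(frozen=True)
class SynthParams:
    """Parameters of the synthetic phonocardiogram generator.

    Durations are per-beat random: each burst draws its full duration
    uniformly within ±20 ms of its configured default, keeping realized
    durations inside the observed 120 ± 30 ms range.  Burst envelopes are
    Gaussian with standard deviation duration/6, so the nominal duration
    covers ±3 sd of the envelope.
    """

    hr_bpm: float = 90.0
    hr_jitter_pct: float = 3.0
    systole_fraction: float = 0.35
    s1_freq_hz: float = 40.0
    s2_freq_hz: float = 55.0
    s1_dur_ms: float = 130.0
    s2_dur_ms: float = 110.0
    s1_amp: float = 1.0
    s2_amp: float = 0.8
    amp_jitter_pct: float = 10.0
    background_snr_db: float = 25.0
    fs: float = 4000.0
    duration_s: float = 20.0
    seed: int = 0
    dur_jitter_ms: float = 20.0

    def __post_init__(self) -> None:
        if not (40.0 <= self.hr_bpm <= 180.0):
            raise PCGError("hr_bpm must lie in 40..180")
        if not (0 < self.systole_fraction < 0.5):
            raise PCGError("systole_fraction must lie in (0, 0.5): "
                           "systole must be shorter than diastole")
        for f in (self.s1_freq_hz, self.s2_freq_hz):
            if not (20.0 <= f <= 70.0):
                raise PCGError("burst center frequencies must lie in 20..70 Hz")
        if self.s1_dur_ms <= 0 or self.s2_dur_ms <= 0:
            raise PCGError("burst durations must be positive")
        if self.fs <= 0 or self.duration_s <= 0:
            raise PCGError("fs and duration_s must be positive")


@dataclass(frozen=True)
class BeatTruth:
    """Realized per-beat parameters, for oracle checks."""

    rr_s: float
    systole_s: float
    s1_dur_s: float
    s2_dur_s: float
    s1_amp: float
    s2_amp: float


@dataclass(frozen=True)
class SynthRecord:
    """A synthetic record with its ground-truth annotations and metadata."""

    record: HeartSoundRecord
    annotations: EventTable
    truth_meta: tuple[BeatTruth, ...] = field(default=())


def _burst(t: np.ndarray, center_s: float, freq_hz: float, amp: float,
           dur_s: float) -> np.ndarray:
    sd = dur_s / 6.0
    envelope = np.exp(-0.5 * ((t - center_s) / sd) ** 2)
    return amp * envelope * np.cos(2.0 * np.pi * freq_hz * (t - center_s))


def generate_beat(params: SynthParams, rng: np.random.Generator
                  ) -> tuple[np.ndarray, int, int, BeatTruth]:
    """One beat: waveform segment of one RR interval plus S1/S2 sample times.

    The S1 burst starts at the beat onset and the S2 burst starts at
    ``systole_fraction``·RR, so the realized S1→S2 interval is close to the
    systolic fraction of the beat and always shorter than diastole.  The
    returned event indices are the realized extrema of |segment| inside
    each burst's nominal support.

    Raises
    ------
    InfeasibleBeatError
        If the two burst cores (±2 sd of the envelopes) would overlap, or
        the S2 burst would spill past the end of the beat.
    """
    fs = params.fs
    rr = (60.0 / params.hr_bpm) * (
        1.0 + params.hr_jitter_pct / 100.0 * rng.uniform(-1.0, 1.0))
    dur1 = np.clip(params.s1_dur_ms + rng.uniform(-1, 1) * params.dur_jitter_ms,
                   90.0, 150.0) / 1000.0
    dur2 = np.clip(params.s2_dur_ms + rng.uniform(-1, 1) * params.dur_jitter_ms,
                   90.0, 150.0) / 1000.0
    amp1 = params.s1_amp * (1.0 + params.amp_jitter_pct / 100.0
                            * rng.uniform(-1.0, 1.0))
    amp2 = params.s2_amp * (1.0 + params.amp_jitter_pct / 100.0
                            * rng.uniform(-1.0, 1.0))
    t1c = dur1 / 2.0
    t2c = params.systole_fraction * rr + dur2 / 2.0
    sd1, sd2 = dur1 / 6.0, dur2 / 6.0
    if t1c + 2.0 * sd1 > t2c - 2.0 * sd2:
        raise InfeasibleBeatError(
            f"infeasible beat geometry: S1/S2 cores overlap "
            f"(RR={rr:.3f} s, durations {dur1:.3f}/{dur2:.3f} s)")
    if t2c + 3.0 * sd2 > rr:
        raise InfeasibleBeatError(
            f"infeasible beat geometry: S2 spills past beat end (RR={rr:.3f} s)")

    n = int(round(rr * fs))
    t = np.arange(n) / fs
    segment = np.zeros(n)
    if amp1 != 0.0:
        segment += _burst(t, t1c, params.s1_freq_hz, amp1, dur1)
    if amp2 != 0.0:
        segment += _burst(t, t2c, params.s2_freq_hz, amp2, dur2)

    def _extremum(center: float, dur: float) -> int:
        a = max(0, int(round((center - dur / 2.0) * fs)))
        b = min(n, int(round((center + dur / 2.0) * fs)) + 1)
        return a + int(np.argmax(np.abs(segment[a:b])))

    s1_idx = _extremum(t1c, dur1) if amp1 != 0.0 else -1
    s2_idx = _extremum(t2c, dur2) if amp2 != 0.0 else -1
    truth = BeatTruth(rr_s=float(rr), systole_s=float(t2c - t1c),
                      s1_dur_s=float(dur1), s2_dur_s=float(dur2),
                      s1_amp=float(amp1), s2_amp=float(amp2))
    return segment, s1_idx, s2_idx, truth


def generate_record(params: SynthParams) -> SynthRecord:
    """Concatenate jittered beats, add background noise, normalize to unit peak.

    Annotation times are the clean-signal burst extrema; the background
    noise level (default 25 dB SNR) is low enough not to displace them.
    """
    fs = params.fs
    total = int(round(params.duration_s * fs))
    rng = np.random.default_rng(params.seed)
    signal = np.zeros(total)
    events: list[tuple[float, str]] = []
    meta: list[BeatTruth] = []
    offset = 0
    while True:
        segment, s1_idx, s2_idx, truth = generate_beat(params, rng)
        if offset + segment.size > total:
            break
        signal[offset:offset + segment.size] = segment
        if s1_idx >= 0:
            events.append(((offset + s1_idx) / fs, "S1"))
        if s2_idx >= 0:
            events.append(((offset + s2_idx) / fs, "S2"))
        meta.append(truth)
        offset += segment.size
    if len(meta) < 2:
        raise PCGError("duration too short: need at least 2 complete beats")

    peak = np.max(np.abs(signal))
    if params.background_snr_db is not None and np.isfinite(
            params.background_snr_db):
        power = np.mean(signal ** 2)
        noise_sd = np.sqrt(power / 10.0 ** (params.background_snr_db / 10.0))
        signal = signal + rng.normal(0.0, noise_sd, total)
        peak = np.max(np.abs(signal))
    record = HeartSoundRecord(signal / peak, fs,
                              source_id=f"synth-seed{params.seed}")
    table = EventTable.from_pairs(events)
    return SynthRecord(record, table, tuple(meta))


def generate_corpus(n_records: int,
                    param_ranges: Optional[dict] = None,
                    master_seed: int = 42) -> list[SynthRecord]:
    """A reproducible corpus of annotated records.

    Heart rates are drawn uniformly from ``hr_range`` (default 65-134 bpm)
    and the three amplitude scenarios (balanced, low-S1, low-S2) are cycled
    deterministically, so every corpus mixes morphologies.  ``param_ranges``
    may override ``hr_range``, ``scenarios`` or any :class:`SynthParams`
    field.
    """
    if n_records < 1:
        raise PCGError("n_records must be >= 1")
    overrides = dict(param_ranges or {})
    hr_lo, hr_hi = overrides.pop("hr_range", DEFAULT_HR_RANGE)
    scenarios: Sequence[tuple[float, float]] = overrides.pop(
        "scenarios", AMPLITUDE_SCENARIOS)
    master = np.random.default_rng(master_seed)
    corpus = []
    for i in range(n_records):
        hr = float(master.uniform(hr_lo, hr_hi))
        seed = int(master.integers(0, 2 ** 31))
        s1_amp, s2_amp = scenarios[i % len(scenarios)]
        params = SynthParams(hr_bpm=hr, s1_amp=s1_amp, s2_amp=s2_amp,
                             seed=seed, **overrides)
        corpus.append(generate_record(params))
    return corpus
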