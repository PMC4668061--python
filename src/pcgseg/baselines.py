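"""Envelope- and threshold-based S1/S2 detectors (Methods I-IV).

Four established wavelet detectors, reimplemented under one surface:

* **Method I** — 2nd-order Shannon energy of the db6 D5 branch,
  thresholded at its own mean.
* **Method II** — 2nd-order Shannon energy of the db6 D6 branch used as an
  adaptive threshold (THR1 = Ê(D6) - λ·μ_e, λ = 3) against the A5-branch
  envelope, followed by durational rules: candidate regions closer than
  50 ms are merged, and regions shorter than 30 ms or longer than 250 ms
  are discarded.
* **Method III** — 3rd-order Shannon energy of the summed db6 details
  D3+D4+D5, thresholded at its mean.
* **Method IV** — two-stage db5 procedure: binarize the unit-normalized
  |D3+D4+D5+D6| at a fixed 0.2, take the A6 approximation branch of the
  binary signal, and binarize that at 0.1.

All four share the post-processing of the dual-moving-average detector:
the event in each surviving region is the extremum of the raw waveform
inside it (the same convention the reference annotations use), and S1/S2
labels follow from the systole-shorter-than-diastole interval rule.  This
keeps the cross-method comparison about the features and thresholds, not
about divergent peak-picking conventions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .envelopes import (DEFAULT_FRAME_S, DEFAULT_HOP_S, EnvelopeSignal,
                        shannon_energy, standardize, unit_normalize)
from .event_ma import Region, label_s1_s2, localize_peaks, regions_from_mask
from .records import EventTable, HeartSoundRecord, PCGError
from .wavelets import reconstruct_branch, summed_details

log = logging.getLogger(__name__)

METHOD_NAMES = ("I", "II", "III", "IV", "V")


@dataclass(frozen=True)
class BaselineConfig:
    """Parameters of the four baseline detectors.

    Only the fields belonging to the selected method are consulted:
    ``lam``/durational thresholds for Method II, the fixed stage
    thresholds for Method IV.
    """

    lam: float = 3.0             # Method II: THR1 = Ê(D6) - lam·mean(Ê(D6))
    dur_min_s: float = 0.030     # Method II: minimum sound duration
    dur_max_s: float = 0.250     # Method II: maximum sound duration
    merge_gap_s: float = 0.050   # Method II: merge regions closer than this
    thr1_fixed: float = 0.2      # Method IV stage 1
    thr2_fixed: float = 0.1      # Method IV stage 2
    frame_len_s: float = DEFAULT_FRAME_S
    hop_s: float = DEFAULT_HOP_S


def _envelope_runs_to_sample_regions(mask: np.ndarray, env: EnvelopeSignal,
                                     fs: float, n: int) -> list[Region]:
    """Map runs of supra-threshold frames to sample regions.

    A run of frames i..j maps, via the frame centers, to the sample
    interval [center_i - hop/2, center_j + hop/2), clipped to the signal.
    """
    hop = env.hop_s
    regions = []
    for run in regions_from_mask(mask):
        t_on = env.t0_s + run.onset_idx * hop - hop / 2.0
        t_off = env.t0_s + (run.offset_idx - 1) * hop + hop / 2.0
        a = max(0, int(round(t_on * fs)))
        b = min(n, int(round(t_off * fs)) + 1)
        if b > a:
            regions.append(Region(a, b))
    return regions


def _merge_close_regions(regions: list[Region], max_gap: int) -> list[Region]:
    """Merge consecutive regions whose gap is strictly below ``max_gap``."""
    merged: list[Region] = []
    for reg in regions:
        if merged and reg.onset_idx - merged[-1].offset_idx < max_gap:
            merged[-1] = Region(merged[-1].onset_idx, reg.offset_idx)
        else:
            merged.append(reg)
    return merged


def _finalize(regions: list[Region], localize_on: np.ndarray, fs: float,
              method: str) -> EventTable:
    if not regions:
        log.warning("method %s: no candidate regions; empty event table",
                    method)
        return EventTable.empty()
    indices = localize_peaks(regions, localize_on)
    return label_s1_s2(indices, fs)


def _standardized_envelope(branch: np.ndarray, order: int, fs: float,
                           cfg: BaselineConfig) -> EnvelopeSignal:
    xhat = unit_normalize(branch)
    env = shannon_energy(xhat, order=order, frame_len_s=cfg.frame_len_s,
                         hop_s=cfg.hop_s, fs=fs)
    return standardize(env)


def detect_method_i(rec: HeartSoundRecord,
                    cfg: BaselineConfig = BaselineConfig()) -> EventTable:
    """Mean-thresholded 2nd-order Shannon energy of the db6 D5 branch."""
    rec = rec.normalized()
    d5 = reconstruct_branch(rec.samples, "db6", 5, "detail")
    env = _standardized_envelope(d5, 2, rec.fs, cfg)
    mask = env.values > env.values.mean()
    regions = _envelope_runs_to_sample_regions(mask, env, rec.fs,
                                               rec.samples.size)
    return _finalize(regions, rec.samples, rec.fs, "I")


def detect_method_ii(rec: HeartSoundRecord,
                     cfg: BaselineConfig = BaselineConfig()) -> EventTable:
    """Adaptive D6-envelope threshold on the A5 envelope, with durational rules.

    THR1 = Ê(D6) - λ·μ_e is a *signal* threshold: the A5-branch envelope
    must exceed it pointwise.  Candidate regions closer than the merge gap
    are treated as fragments of one sound and merged; regions with duration
    outside [dur_min_s, dur_max_s] are discarded as noise.
    """
    rec = rec.normalized()
    d6 = reconstruct_branch(rec.samples, "db6", 6, "detail")
    a5 = reconstruct_branch(rec.samples, "db6", 5, "approx")
    env_d6 = _standardized_envelope(d6, 2, rec.fs, cfg)
    env_a5 = _standardized_envelope(a5, 2, rec.fs, cfg)
    thr1 = env_d6.values - cfg.lam * env_d6.values.mean()
    mask = env_a5.values > thr1
    regions = _envelope_runs_to_sample_regions(mask, env_a5, rec.fs,
                                               rec.samples.size)
    regions = _merge_close_regions(regions,
                                   max_gap=int(round(cfg.merge_gap_s * rec.fs)))
    lo = cfg.dur_min_s * rec.fs
    hi = cfg.dur_max_s * rec.fs
    regions = [r for r in regions if lo <= r.width <= hi]
    return _finalize(regions, rec.samples, rec.fs, "II")


def detect_method_iii(rec: HeartSoundRecord,
                      cfg: BaselineConfig = BaselineConfig()) -> EventTable:
    """Mean-thresholded 3rd-order Shannon energy of db6 D3+D4+D5."""
    rec = rec.normalized()
    summed = summed_details(rec.samples, "db6", (3, 4, 5))
    env = _standardized_envelope(summed, 3, rec.fs, cfg)
    mask = env.values > env.values.mean()
    regions = _envelope_runs_to_sample_regions(mask, env, rec.fs,
                                               rec.samples.size)
    return _finalize(regions, rec.samples, rec.fs, "III")


def detect_method_iv(rec: HeartSoundRecord,
                     cfg: BaselineConfig = BaselineConfig()) -> EventTable:
    """Two-stage db5 sequential wavelet analysis with fixed thresholds.

    Stage 1 binarizes the unit-normalized magnitude of D3+D4+D5+D6 at
    ``thr1_fixed``; stage 2 takes the full-length A6 approximation branch
    of the binary signal and binarizes it at ``thr2_fixed``.  Runs of the
    stage-2 binary signal are the candidate regions.
    """
    rec = rec.normalized()
    summed = summed_details(rec.samples, "db5", (3, 4, 5, 6))
    xhat = np.abs(unit_normalize(summed))
    y = (xhat >= cfg.thr1_fixed).astype(float)
    if not y.any():
        log.warning("method IV: no samples above THR1; empty event table")
        return EventTable.empty()
    z = reconstruct_branch(y, "db5", 6, "approx")
    r = z >= cfg.thr2_fixed
    regions = regions_from_mask(r)
    return _finalize(regions, rec.samples, rec.fs, "IV")


def detect(rec: HeartSoundRecord, method: str, **kwargs) -> EventTable:
    """Dispatch to a detector by method name ("I".."V")."""
    from .event_ma import MethodVParams, detect_method_v

    method = method.upper()
    if method == "I":
        return detect_method_i(rec, **kwargs)
    if method == "II":
        return detect_method_ii(rec, **kwargs)
    if method == "III":
        return detect_method_iii(rec, **kwargs)
    if method == "IV":
        return detect_method_iv(rec, **kwargs)
    if method == "V":
        params = kwargs.pop("params", MethodVParams())
        return detect_method_v(rec, params, **kwargs)
    raise PCGError(f"unknown method {method!r}; choose one of "
                   f"{', '.join(METHOD_NAMES)}")
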