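"""Scoring detections against reference annotations.

A detected event is a true positive when it lies within a tolerance window
(±5 ms by default) of an unmatched reference event with the same label.
Matching is one-to-one and greedy by increasing time difference, so one
detection cannot absorb two references.  From the TP/FP/FN counts:

    SE  = 100·TP/(TP+FN)    (sensitivity)
    +P  = 100·TP/(TP+FP)    (positive predictivity)

and the overall accuracy is their mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .records import EventTable, PCGError


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching one detection table against one reference table."""

    TP: int
    FP: int
    FN: int
    pairs: tuple[tuple[float, float, str], ...] = field(default=())

    def __add__(self, other: "MatchResult") -> "MatchResult":
        return MatchResult(self.TP + other.TP, self.FP + other.FP,
                           self.FN + other.FN, self.pairs + other.pairs)


@dataclass(frozen=True)
class Metrics:
    """Sensitivity, positive predictivity and their mean, in percent.

    A metric whose denominator is zero (no reference events for SE, no
    detections for +P) is reported as None rather than a number.
    """

    SE: Optional[float]
    PPV: Optional[float]

    @property
    def overall(self) -> Optional[float]:
        if self.SE is None or self.PPV is None:
            return None
        return (self.SE + self.PPV) / 2.0


def match_events(detected: EventTable, reference: EventTable,
                 tol_s: float = 0.005, label_strict: bool = True) -> MatchResult:
    """One-to-one greedy matching of detections to references.

    Candidate pairs with |Δt| ≤ ``tol_s`` (and equal labels when
    ``label_strict``) are accepted in order of increasing |Δt|; each event
    participates in at most one pair.  Unmatched references count as FN,
    unmatched detections as FP.
    """
    if tol_s < 0:
        raise PCGError("tolerance must be non-negative")
    det_t = detected.times_s
    ref_t = reference.times_s
    candidates = []
    for i, (td, ld) in enumerate(zip(det_t, detected.labels)):
        for j, (tr, lr) in enumerate(zip(ref_t, reference.labels)):
            dt = abs(td - tr)
            if dt <= tol_s and (not label_strict or ld == lr):
                candidates.append((dt, tr, td, i, j))
    candidates.sort()
    det_used = np.zeros(len(detected), dtype=bool)
    ref_used = np.zeros(len(reference), dtype=bool)
    pairs = []
    for dt, tr, td, i, j in candidates:
        if det_used[i] or ref_used[j]:
            continue
        det_used[i] = ref_used[j] = True
        pairs.append((float(td), float(tr), reference.labels[j]))
    tp = len(pairs)
    return MatchResult(TP=tp, FP=len(detected) - tp, FN=len(reference) - tp,
                       pairs=tuple(pairs))


def metrics(match: MatchResult) -> Metrics:
    """SE, +P (percent) from pooled TP/FP/FN counts."""
    se = 100.0 * match.TP / (match.TP + match.FN) if match.TP + match.FN else None
    ppv = 100.0 * match.TP / (match.TP + match.FP) if match.TP + match.FP else None
    return Metrics(SE=se, PPV=ppv)
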