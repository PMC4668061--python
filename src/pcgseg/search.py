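"""Brute-force grid optimization of the dual-moving-average detector.

Evaluates every admissible (W1, W2, BlockSize, β) combination — W1 < W2 and
BlockSize ≤ W1 — against an annotated corpus, pooling TP/FP/FN over all
records, and returns the table sorted by overall accuracy.  The default
grid spans W1 ∈ 20-200 ms, W2 ∈ 30-400 ms, BlockSize ∈ 10-100 ms and
β ∈ 0-10%, each in steps of 10 ms / 1 percentage point.

Grid points are independent, so any execution order yields the identical
sorted table; the wavelet feature of each record is decomposed once and
shared across all points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .evaluation import MatchResult, match_events, metrics
from .event_ma import MethodVParams, detect_from_feature
from .noise import _as_pairs
from .records import PCGError
from .wavelets import reconstruct_branch

log = logging.getLogger(__name__)

_EPS = 1e-9  # slack for float grid comparisons


def _grid(start: float, stop: float, step: float) -> tuple[float, ...]:
    n = int(round((stop - start) / step)) + 1
    return tuple(round(start + i * step, 10) for i in range(n))


@dataclass(frozen=True)
class GridSpec:
    """Parameter grid with the admissibility constraint W1 < W2, block ≤ W1."""

    w1_values: tuple[float, ...] = field(
        default_factory=lambda: _grid(0.020, 0.200, 0.010))
    w2_values: tuple[float, ...] = field(
        default_factory=lambda: _grid(0.030, 0.400, 0.010))
    block_values: tuple[float, ...] = field(
        default_factory=lambda: _grid(0.010, 0.100, 0.010))
    beta_values: tuple[float, ...] = field(
        default_factory=lambda: _grid(0.00, 0.10, 0.01))

    def __post_init__(self) -> None:
        for name in ("w1_values", "w2_values", "block_values", "beta_values"):
            vals = getattr(self, name)
            if len(vals) == 0:
                raise PCGError(f"{name} must be non-empty")
            object.__setattr__(self, name, tuple(float(v) for v in vals))

    def admissible_points(self) -> list[tuple[float, float, float, float]]:
        """Cartesian product filtered by W1 < W2 and block ≤ W1, sorted."""
        points = []
        for w1 in sorted(self.w1_values):
            for w2 in sorted(self.w2_values):
                if not (w1 < w2 - _EPS):
                    continue
                for block in sorted(self.block_values):
                    if block > w1 + _EPS:
                        continue
                    for beta in sorted(self.beta_values):
                        points.append((w1, w2, block, beta))
        return points


@dataclass(frozen=True)
class GridResult:
    """Sorted evaluation table plus the number of points evaluated."""

    table: pd.DataFrame
    n_evaluated: int


def grid_search(corpus: Sequence, grid: GridSpec = GridSpec(),
                tol_s: float = 0.005) -> GridResult:
    """Exhaustive evaluation of the detector over the admissible grid.

    ``corpus`` is a sequence of :class:`~pcgseg.synth.SynthRecord` or
    (record, annotations) pairs.  Rows are sorted by overall accuracy
    descending, ties broken by (W1, W2, block, beta) ascending.  A detector
    failure on a record (e.g. too few events to label) scores that record
    as all-FN for the current point.
    """
    pairs = _as_pairs(corpus)
    if not pairs:
        raise PCGError("corpus must be non-empty and annotated")
    features = []
    for rec, ann in pairs:
        rec = rec.normalized()
        features.append((reconstruct_branch(rec.samples, "db6", 6, "detail"),
                         rec.samples, rec.fs, ann))
    points = grid.admissible_points()
    rows = []
    for w1, w2, block, beta in points:
        params = MethodVParams(w1_s=w1, w2_s=w2, block_s=block, beta=beta)
        pooled = MatchResult(0, 0, 0)
        for x, raw, fs, ann in features:
            try:
                detected = detect_from_feature(x, fs, params,
                                               localize_on=raw)
                pooled = pooled + match_events(detected, ann, tol_s)
            except PCGError as exc:
                log.debug("grid point %s failed on a record: %s",
                          (w1, w2, block, beta), exc)
                pooled = pooled + MatchResult(0, 0, len(ann))
        mets = metrics(pooled)
        rows.append({"W1_s": w1, "W2_s": w2, "block_s": block, "beta": beta,
                     "SE": mets.SE, "PPV": mets.PPV, "overall": mets.overall})
    table = pd.DataFrame(rows).sort_values(
        by=["overall", "W1_s", "W2_s", "block_s", "beta"],
        ascending=[False, True, True, True, True],
        kind="mergesort").reset_index(drop=True)
    return GridResult(table=table, n_evaluated=len(points))


def best_params(result: GridResult) -> MethodVParams:
    """Top grid point as detector parameters (ties already resolved)."""
    if result.table.empty:
        raise PCGError("empty grid result")
    top = result.table.iloc[0]
    return MethodVParams(w1_s=float(top["W1_s"]), w2_s=float(top["W2_s"]),
                         block_s=float(top["block_s"]),
                         beta=float(top["beta"]))
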