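"""Beat-by-beat comparison of detections against reference annotations.

A detection matches a reference beat when they are at most one matching
tolerance apart (default 150 ms, the standard beat-by-beat comparison
window).  Matching is one-to-one and maximum-cardinality: references are
scanned in ascending order and each takes the earliest still-unmatched
detection inside its tolerance window, which for sorted event trains
attains the maximum possible number of pairs.  Paired events are true
positives (TP), unpaired references false negatives (FN), unpaired
detections false positives (FP), giving

    SE = 100 * TP / (TP + FN)      sensitivity
    PP = 100 * TP / (TP + FP)      positive predictivity
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .detectors import DetectionResult
from .io import METRIC_COLUMNS
from .records import BeatAnnotations

__all__ = [
    "MatchCounts",
    "MetricRow",
    "match_beats",
    "sensitivity",
    "positive_predictivity",
    "metric_row",
    "rows_to_table",
    "aggregate",
]

DEFAULT_TOLERANCE_MS = 150.0


@dataclass(frozen=True)
class MatchCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_reference(self) -> int:
        return self.tp + self.fn

    @property
    def n_detected(self) -> int:
        return self.tp + self.fp


@dataclass(frozen=True)
class MetricRow:
    record_id: str
    detector: str
    noise_type: str  # "clean", "BW", "MA" or "EM"
    snr_db: float | None
    counts: MatchCounts
    se_pct: float
    pp_pct: float


def match_beats(
    reference: BeatAnnotations | np.ndarray,
    detected: DetectionResult | np.ndarray,
    tolerance_ms: float = DEFAULT_TOLERANCE_MS,
    fs: float = 360.0,
) -> MatchCounts:
    """One-to-one matching of detections to reference beats.

    ``reference`` and ``detected`` may be the domain objects or bare
    ascending index arrays.  Empty inputs are allowed.
    """
    if tolerance_ms <= 0:
        raise ValueError("tolerance_ms must be > 0")
    ref = (
        reference.sample_indices
        if isinstance(reference, BeatAnnotations)
        else np.asarray(reference, dtype=np.int64)
    )
    det = (
        detected.fiducials
        if isinstance(detected, DetectionResult)
        else np.asarray(detected, dtype=np.int64)
    )
    tol = tolerance_ms / 1000.0 * fs

    # Earliest-available greedy over sorted trains: each reference's
    # admissible detections form a contiguous run, and the runs shift right
    # with the reference, so this greedy attains maximum cardinality.
    tp = 0
    j = 0
    n_det = det.size
    for r in ref:
        while j < n_det and det[j] < r - tol:
            j += 1
        if j < n_det and abs(det[j] - r) <= tol:
            tp += 1
            j += 1
    return MatchCounts(tp=tp, fp=n_det - tp, fn=ref.size - tp)


def sensitivity(counts: MatchCounts) -> float:
    """SE = 100 * TP / (TP + FN), percent of reference beats detected."""
    if counts.tp + counts.fn == 0:
        raise ZeroDivisionError("sensitivity undefined: no reference beats")
    return 100.0 * counts.tp / (counts.tp + counts.fn)


def positive_predictivity(counts: MatchCounts) -> float:
    """PP = 100 * TP / (TP + FP), percent of detections that are true beats."""
    if counts.tp + counts.fp == 0:
        raise ZeroDivisionError("positive predictivity undefined: no detections")
    return 100.0 * counts.tp / (counts.tp + counts.fp)


def metric_row(
    record_id: str,
    detector: str,
    counts: MatchCounts,
    noise_type: str = "clean",
    snr_db: float | None = None,
) -> MetricRow:
    return MetricRow(
        record_id=record_id,
        detector=detector,
        noise_type=noise_type,
        snr_db=snr_db,
        counts=counts,
        se_pct=sensitivity(counts),
        pp_pct=positive_predictivity(counts),
    )


def rows_to_table(rows: Iterable[MetricRow]) -> pd.DataFrame:
    """Flatten MetricRows into the canonical metric-table DataFrame."""
    data = [
        {
            "record_id": r.record_id,
            "detector": r.detector,
            "noise_type": r.noise_type,
            "snr_db": np.nan if r.snr_db is None else r.snr_db,
            "tp": r.counts.tp,
            "fp": r.counts.fp,
            "fn": r.counts.fn,
            "se_pct": r.se_pct,
            "pp_pct": r.pp_pct,
        }
        for r in rows
    ]
    return pd.DataFrame(data, columns=list(METRIC_COLUMNS))


def aggregate(
    rows: Sequence[MetricRow],
    mode: Literal["per_record_mean", "gross"] = "per_record_mean",
) -> MetricRow:
    """Combine per-record rows for one (detector, noise, SNR) cell.

    ``per_record_mean`` averages SE and PP across records with equal
    weight; ``gross`` pools TP/FP/FN over all records first and applies
    the metric formulas to the totals.
    """
    if not rows:
        raise ValueError("aggregate needs at least one row")
    keys = {(r.detector, r.noise_type, r.snr_db) for r in rows}
    if len(keys) != 1:
        raise ValueError(f"rows mix detector/noise/SNR cells: {sorted(map(str, keys))}")
    detector, noise_type, snr_db = keys.pop()
    total = MatchCounts(
        tp=sum(r.counts.tp for r in rows),
        fp=sum(r.counts.fp for r in rows),
        fn=sum(r.counts.fn for r in rows),
    )
    if mode == "gross":
        se = sensitivity(total)
        pp = positive_predictivity(total)
    elif mode == "per_record_mean":
        se = float(np.mean([r.se_pct for r in rows]))
        pp = float(np.mean([r.pp_pct for r in rows]))
    else:
        raise ValueError(f"unknown aggregation mode {mode!r}")
    return MetricRow(
        record_id=f"{mode}[{len(rows)}]",
        detector=detector,
        noise_type=noise_type,
        snr_db=snr_db,
        counts=total,
        se_pct=se,
        pp_pct=pp,
    )
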