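"""Hamilton beat detector.

A descendant of Pan-Tompkins with a different pre-processing chain:
band-pass (8-16 Hz) -> derivative -> rectification (absolute value
instead of squaring) -> 80 ms moving average.  Candidates then pass three
acceptance rules: (1) at least 300 ms since the last accepted beat;
(2) amplitude above an adaptive threshold computed from the means of the
last 8 QRS peaks and last 8 noise peaks,
``mean_noise + 0.3125 * (mean_qrs - mean_noise)``; (3) if the interval
since the last beat exceeds 1.5x the running mean RR, the gap is
re-scanned and the largest rejected candidate above half threshold is
accepted.  T waves are rejected by the same slope rule as Pan-Tompkins.
"""

from __future__ import annotations

from collections import deque

import numpy as np

from ..records import EcgRecord
from . import _common
from .base import DetectionResult, DetectorConfig


def hamilton_detect(
    record: EcgRecord,
    config: DetectorConfig | None = None,
    keep_intermediates: bool = False,
) -> DetectionResult:
    cfg = config or DetectorConfig()
    fs = record.fs
    x = record.samples
    n = x.size
    learn_n = int(round(cfg.learning_s * fs))
    if n < learn_n:
        raise ValueError(
            f"record ({n / fs:.3f} s) shorter than learning phase "
            f"({cfg.learning_s} s)"
        )

    filtered = _common.bandpass(x, fs, *cfg.ham_band_hz)
    deriv = _common.five_point_derivative(filtered, fs)
    rectified = np.abs(deriv)
    win = max(1, int(round(cfg.ham_average_ms / 1000.0 * fs)))
    averaged = _common.moving_average(rectified, win)

    intermediates = (
        {
            "filtered": filtered,
            "derivative": deriv,
            "nonlinearity": rectified,
            "integrated": averaged,
        }
        if keep_intermediates
        else {}
    )

    if np.ptp(x) == 0.0:
        return DetectionResult("hamilton", np.empty(0, np.int64), intermediates)

    refractory = int(round(cfg.refractory_ms / 1000.0 * fs))
    twave_n = int(round(cfg.twave_window_ms / 1000.0 * fs))
    slope_half_win = int(round(0.075 * fs))

    candidates = _common.candidate_peaks(averaged, fs)
    candidates = candidates[(candidates >= win) & (candidates < n - win)]
    if candidates.size == 0:
        return DetectionResult("hamilton", np.empty(0, np.int64), intermediates)

    qrs_peaks: deque[float] = deque([float(np.max(averaged[:learn_n]))], maxlen=8)
    noise_peaks: deque[float] = deque([float(np.mean(averaged[:learn_n]))], maxlen=8)
    rr_buf: deque[float] = deque(maxlen=cfg.rr_history)

    beats: list[int] = []
    beat_slopes: list[float] = []
    rejected: list[int] = []

    def threshold() -> float:
        m_noise = float(np.mean(noise_peaks))
        m_qrs = float(np.mean(qrs_peaks))
        return m_noise + cfg.ham_threshold_coeff * (m_qrs - m_noise)

    def accept(p: int) -> None:
        qrs_peaks.append(float(averaged[p]))
        if beats:
            rr_buf.append(p - beats[-1])
        beats.append(p)
        beat_slopes.append(_common.max_abs_slope(deriv, p, slope_half_win))

    for p in candidates:
        # Rule 3: search back when the expected beat is overdue.
        if beats and rr_buf and rejected:
            rr_mean = float(np.mean(rr_buf))
            if p - beats[-1] > cfg.ham_searchback_rr_factor * rr_mean:
                eligible = [
                    q
                    for q in rejected
                    if q - beats[-1] >= refractory and p - q >= refractory
                ]
                if eligible:
                    q = max(eligible, key=lambda i: averaged[i])
                    if averaged[q] > cfg.searchback_threshold_factor * threshold():
                        accept(q)
                        rejected = [r for r in rejected if r > q]

        # Rule 1: refractory.
        if beats and p - beats[-1] < refractory:
            continue

        is_twave = False
        if beats and p - beats[-1] < twave_n:
            slope = _common.max_abs_slope(deriv, p, slope_half_win)
            if slope < cfg.twave_slope_fraction * beat_slopes[-1]:
                is_twave = True

        # Rule 2: adaptive amplitude threshold.
        if not is_twave and averaged[p] > threshold():
            accept(p)
            rejected = []
        else:
            noise_peaks.append(float(averaged[p]))
            rejected.append(int(p))

    lookback = win + int(round(0.05 * fs))
    fiducials: list[int] = []
    for p in beats:
        floor = fiducials[-1] + 1 if fiducials else 0
        fiducials.append(_common.map_peak_to_fiducial(filtered, p, lookback, floor))
    return DetectionResult(
        "hamilton",
        _common.enforce_refractory(fiducials, refractory),
        intermediates,
    )
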