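"""Pan-Tompkins beat detector.

Pipeline: band-pass (5-15 Hz) -> five-point derivative -> squaring ->
150 ms moving-window integration -> candidate peaks -> dual adaptive
thresholds with RR-interval tracking, search-back and T-wave rejection.

The running signal-peak (SPK) and noise-peak (NPK) estimates are updated
as ``1/8 * peak + 7/8 * previous``; the detection threshold is
``NPK + 0.25 * (SPK - NPK)``.  When no beat is found within 1.66x the
running mean RR interval (last 8 beats), the gap is re-scanned at half
threshold.  A candidate within 360 ms of the previous beat whose maximal
filtered slope is below half the previous beat's is rejected as a T wave.
All decisions are relative, so the fiducial set is invariant to amplitude
scaling of the input.
"""

from __future__ import annotations

from collections import deque

import numpy as np

from ..records import EcgRecord
from . import _common
from .base import DetectionResult, DetectorConfig


def pan_tompkins_detect(
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

    filtered = _common.bandpass(x, fs, *cfg.pt_band_hz)
    deriv = _common.five_point_derivative(filtered, fs)
    squared = deriv**2
    win = max(1, int(round(cfg.pt_integration_ms / 1000.0 * fs)))
    mwi = _common.moving_average(squared, win)

    intermediates = (
        {
            "filtered": filtered,
            "derivative": deriv,
            "nonlinearity": squared,
            "integrated": mwi,
        }
        if keep_intermediates
        else {}
    )

    if np.ptp(x) == 0.0:
        return DetectionResult("pan_tompkins", np.empty(0, np.int64), intermediates)

    refractory = int(round(cfg.refractory_ms / 1000.0 * fs))
    twave_n = int(round(cfg.twave_window_ms / 1000.0 * fs))
    slope_half_win = int(round(0.075 * fs))

    candidates = _common.candidate_peaks(mwi, fs)
    candidates = candidates[(candidates >= win) & (candidates < n - win)]
    if candidates.size == 0:
        return DetectionResult("pan_tompkins", np.empty(0, np.int64), intermediates)

    spk = float(np.max(mwi[:learn_n]))
    npk = float(np.mean(mwi[:learn_n]))
    mix = cfg.peak_mix
    rr_buf: deque[float] = deque(maxlen=cfg.rr_history)

    beats: list[int] = []  # accepted peaks, in mwi-index terms
    beat_slopes: list[float] = []
    rejected: list[int] = []  # sub-threshold candidates since the last beat

    def threshold() -> float:
        return npk + cfg.pt_threshold_coeff * (spk - npk)

    def accept(p: int, searchback: bool) -> None:
        nonlocal spk
        w = cfg.searchback_peak_mix if searchback else mix
        spk = w * float(mwi[p]) + (1.0 - w) * spk
        if beats:
            rr_buf.append(p - beats[-1])
        beats.append(p)
        beat_slopes.append(_common.max_abs_slope(deriv, p, slope_half_win))

    for p in candidates:
        # Search-back: the expected beat did not arrive within 1.66x mean RR.
        if beats and rr_buf and rejected:
            rr_mean = float(np.mean(rr_buf))
            if p - beats[-1] > cfg.pt_searchback_rr_factor * rr_mean:
                eligible = [
                    q
                    for q in rejected
                    if q - beats[-1] >= refractory and p - q >= refractory
                ]
                if eligible:
                    q = max(eligible, key=lambda i: mwi[i])
                    if mwi[q] > cfg.searchback_threshold_factor * threshold():
                        accept(q, searchback=True)
                        rejected = [r for r in rejected if r > q]

        if beats and p - beats[-1] < refractory:
            continue

        is_twave = False
        if beats and p - beats[-1] < twave_n:
            slope = _common.max_abs_slope(deriv, p, slope_half_win)
            if slope < cfg.twave_slope_fraction * beat_slopes[-1]:
                is_twave = True

        if not is_twave and mwi[p] > threshold():
            accept(p, searchback=False)
            rejected = []
        else:
            npk = mix * float(mwi[p]) + (1.0 - mix) * npk
            rejected.append(int(p))

    lookback = win + int(round(0.05 * fs))
    fiducials: list[int] = []
    for p in beats:
        floor = fiducials[-1] + 1 if fiducials else 0
        fiducials.append(_common.map_peak_to_fiducial(filtered, p, lookback, floor))
    return DetectionResult(
        "pan_tompkins",
        _common.enforce_refractory(fiducials, refractory),
        intermediates,
    )
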