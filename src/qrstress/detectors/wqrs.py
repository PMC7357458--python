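"""WQRS: beat detection by the curve-length transform.

Pipeline: low-pass (16 Hz) -> curve-length transform over a sliding
window ``w`` (default 130 ms),

    L(t) = sum_{i in window} sqrt(c^2 + dy_i^2),

with ``dy_i`` successive sample differences of the filtered trace (mV)
and ``c`` a fixed length-scale constant below which slope changes count
as flat -> adaptive threshold on the length excess ``L - w*c`` with
rising-edge (QRS onset) detection and a 300 ms eye-closing period.  Each
onset is mapped to a fiducial at the largest absolute filtered deflection
(relative to the local baseline) within 150 ms after the onset, so the
reported position is an R-position comparable with the other detectors.

The threshold tracks a signal level S (updated from onset peaks) and a
noise level N (updated from inter-beat stretches of the length signal) as
``T = N + 0.25 * (S - N)``; when no onset occurs within 1.66x the running
mean RR interval the threshold is relaxed halfway toward N.
"""

from __future__ import annotations

from collections import deque

import numpy as np

from ..records import EcgRecord
from . import _common
from .base import DetectionResult, DetectorConfig


def _curve_length(filtered: np.ndarray, window: int, c: float) -> np.ndarray:
    dy = np.diff(filtered, prepend=filtered[0])
    increments = np.sqrt(c * c + dy * dy)
    length = _common.moving_average(increments, window) * window
    return length - window * c  # excess over the flat-line baseline


def wqrs_detect(
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

    filtered = _common.lowpass(x, fs, cfg.wqrs_lowpass_hz)
    win = max(1, int(round(cfg.wqrs_window_ms / 1000.0 * fs)))
    length = _curve_length(filtered, win, cfg.wqrs_length_scale_mv)

    intermediates = (
        {"filtered": filtered, "curve_length": length} if keep_intermediates else {}
    )

    eye = max(1, int(round(cfg.wqrs_eye_closing_ms / 1000.0 * fs)))
    fid_win = max(1, int(round(cfg.wqrs_fiducial_window_ms / 1000.0 * fs)))

    s_level = float(np.max(length[:learn_n]))
    n_level = float(np.mean(length[:learn_n]))
    if s_level <= 0.0:  # constant record: zero curve-length excess
        return DetectionResult("wqrs", np.empty(0, np.int64), intermediates)
    thr = n_level + cfg.wqrs_threshold_coeff * (s_level - n_level)
    mix = cfg.peak_mix
    rr_buf: deque[float] = deque(maxlen=cfg.rr_history)

    onsets: list[int] = []
    fiducials: list[int] = []
    last_end = 0
    i = win  # onsets within one window of the record start are suppressed
    limit = n - win
    while i < limit:
        horizon = int(1.66 * (np.mean(rr_buf) if rr_buf else fs))
        end = min(limit, i + horizon)
        above = np.nonzero(length[i:end] > thr)[0]
        if above.size == 0:
            if end >= limit:
                break  # tail shorter than the search-back horizon
            if thr - n_level > 1e-12 * max(s_level, 1.0):
                # Overdue beat: relax the threshold halfway toward the noise
                # level and rescan the same stretch.
                thr = n_level + 0.5 * (thr - n_level)
            else:
                i = end
            continue
        j = i + int(above[0])
        peak = float(np.max(length[j : min(j + eye, n)]))
        s_level = mix * peak + (1.0 - mix) * s_level
        gap = length[last_end:j]
        if gap.size:
            n_level = mix * float(np.mean(gap)) + (1.0 - mix) * n_level
        thr = n_level + cfg.wqrs_threshold_coeff * (s_level - n_level)
        if onsets:
            rr_buf.append(j - onsets[-1])
        onsets.append(j)
        seg = filtered[j : min(j + fid_win, n)]
        fid = j + int(np.argmax(np.abs(seg - seg.mean())))
        if not fiducials or fid > fiducials[-1]:
            fiducials.append(fid)
        last_end = j + eye
        i = j + eye

    return DetectionResult(
        "wqrs", np.asarray(fiducials, dtype=np.int64), intermediates
    )
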