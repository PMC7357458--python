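"""Shared building blocks for the beat detectors.

All filters are causal 2nd-order Butterworth sections applied with zero
initial state at the record's native sampling rate, so detector output is
reproducible bit-exactly on fixed input.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps


def _causal(sos: np.ndarray, x: np.ndarray) -> np.ndarray:
    # state initialized to the DC steady state of x[0]: suppresses the
    # start-up transient a DC offset would otherwise inject
    zi = sps.sosfilt_zi(sos) * x[0]
    y, _ = sps.sosfilt(sos, x, zi=zi)
    return y


def bandpass(x: np.ndarray, fs: float, low: float, high: float) -> np.ndarray:
    nyq = fs / 2
    if not 0 < low < high < nyq:
        raise ValueError(f"band {low}-{high} Hz invalid for fs={fs}")
    sos = sps.butter(2, [low / nyq, high / nyq], btype="bandpass", output="sos")
    return _causal(sos, x)


def lowpass(x: np.ndarray, fs: float, cutoff: float) -> np.ndarray:
    nyq = fs / 2
    if not 0 < cutoff < nyq:
        raise ValueError(f"cutoff {cutoff} Hz invalid for fs={fs}")
    sos = sps.butter(2, cutoff / nyq, btype="lowpass", output="sos")
    return _causal(sos, x)


def five_point_derivative(x: np.ndarray, fs: float) -> np.ndarray:
    """Causal five-point derivative, H(z) ~ (1/8)(2 + z^-1 - z^-3 - 2 z^-4)."""
    b = np.array([2.0, 1.0, 0.0, -1.0, -2.0]) * (fs / 8.0)
    return sps.lfilter(b, [1.0], x)


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Causal moving average over ``window`` samples."""
    if window < 1:
        raise ValueError("window must be >= 1")
    return sps.lfilter(np.full(window, 1.0 / window), [1.0], x)


def candidate_peaks(trace: np.ndarray, fs: float, min_distance_s: float = 0.2) -> np.ndarray:
    """Local maxima of a transformed trace, at least ``min_distance_s`` apart.

    All amplitude decisions are left to the adaptive thresholds, so the
    candidate set is scale-free.
    """
    distance = max(1, int(round(min_distance_s * fs)))
    peaks, _ = sps.find_peaks(trace, distance=distance)
    return peaks


def max_abs_slope(deriv: np.ndarray, center: int, half_window: int) -> float:
    lo = max(0, center - half_window)
    hi = min(deriv.size, center + half_window + 1)
    if lo >= hi:
        return 0.0
    return float(np.max(np.abs(deriv[lo:hi])))


def map_peak_to_fiducial(
    filtered: np.ndarray, peak: int, lookback: int, floor: int = 0
) -> int:
    """R-position on the filtered trace for an accepted transformed-trace peak.

    The causal nonlinearity + integration stages delay the energy peak, so
    the R deflection is sought in a trailing window of ``lookback`` samples
    ending at ``peak`` (never before ``floor``).
    """
    lo = max(floor, peak - lookback)
    hi = min(filtered.size, peak + 1)
    if lo >= hi:
        return peak
    seg = filtered[lo:hi]
    return lo + int(np.argmax(np.abs(seg - seg.mean())))


def enforce_refractory(fiducials: list[int], refractory: int) -> np.ndarray:
    """Keep fiducials strictly ascending with minimum separation (keep earlier)."""
    out: list[int] = []
    for f in sorted(fiducials):
        if not out or f - out[-1] >= refractory:
            out.append(f)
    return np.asarray(out, dtype=np.int64)
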