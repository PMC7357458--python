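"""Detector configuration and result types."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

DETECTOR_NAMES = ("pan_tompkins", "hamilton", "wqrs")


@dataclass(frozen=True)
class DetectorConfig:
    """Tunable constants of the three detectors.

    Durations are in ms (converted to samples at the record's rate), band
    edges in Hz.  Defaults follow the classical formulations; the threshold
    bookkeeping constants (peak mix-in weights, threshold coefficients,
    search-back factors) are exposed because the algorithms are routinely
    re-tuned per application.
    """

    # shared
    refractory_ms: float = 300.0
    twave_window_ms: float = 360.0
    twave_slope_fraction: float = 0.5
    learning_s: float = 2.0
    peak_mix: float = 0.125  # 1/8 running-estimate update
    searchback_peak_mix: float = 0.25
    searchback_threshold_factor: float = 0.5
    rr_history: int = 8

    # Pan-Tompkins
    pt_band_hz: tuple[float, float] = (5.0, 15.0)
    pt_integration_ms: float = 150.0
    pt_threshold_coeff: float = 0.25
    pt_searchback_rr_factor: float = 1.66

    # Hamilton
    ham_band_hz: tuple[float, float] = (8.0, 16.0)
    ham_average_ms: float = 80.0
    ham_threshold_coeff: float = 0.3125
    ham_searchback_rr_factor: float = 1.5

    # WQRS
    wqrs_lowpass_hz: float = 16.0
    wqrs_window_ms: float = 130.0
    wqrs_eye_closing_ms: float = 300.0
    wqrs_length_scale_mv: float = 0.005  # curve-length constant c
    wqrs_threshold_coeff: float = 0.25
    wqrs_fiducial_window_ms: float = 150.0

    def __post_init__(self) -> None:
        for name in (
            "refractory_ms",
            "twave_window_ms",
            "learning_s",
            "pt_integration_ms",
            "ham_average_ms",
            "wqrs_window_ms",
            "wqrs_eye_closing_ms",
            "wqrs_fiducial_window_ms",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class DetectionResult:
    """Fiducial sample indices produced by one detector on one record."""

    detector: str
    fiducials: np.ndarray
    intermediates: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        fid = np.asarray(self.fiducials, dtype=np.int64)
        if fid.size > 1 and not np.all(np.diff(fid) > 0):
            raise ValueError("fiducials must be strictly ascending")
        object.__setattr__(self, "fiducials", fid)

    def __len__(self) -> int:
        return int(self.fiducials.size)
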