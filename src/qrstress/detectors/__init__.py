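"""Three classical QRS detectors behind one interface.

Each detector maps an :class:`~qrstress.records.EcgRecord` to a
:class:`DetectionResult` of ascending fiducial (R-position) sample
indices; intermediate pipeline traces can be retained for inspection.
"""

from __future__ import annotations

from typing import Callable

from ..records import EcgRecord
from .base import DETECTOR_NAMES, DetectionResult, DetectorConfig
from .hamilton import hamilton_detect
from .pan_tompkins import pan_tompkins_detect
from .wqrs import wqrs_detect

DETECTORS: dict[str, Callable[..., DetectionResult]] = {
    "pan_tompkins": pan_tompkins_detect,
    "hamilton": hamilton_detect,
    "wqrs": wqrs_detect,
}


def detect(
    record: EcgRecord,
    detector: str,
    config: DetectorConfig | None = None,
    keep_intermediates: bool = False,
) -> DetectionResult:
    """Run one detector by name."""
    try:
        fn = DETECTORS[detector]
    except KeyError:
        raise ValueError(
            f"unknown detector {detector!r}; choose from {sorted(DETECTORS)}"
        ) from None
    return fn(record, config=config, keep_intermediates=keep_intermediates)


__all__ = [
    "DETECTOR_NAMES",
    "DETECTORS",
    "DetectionResult",
    "DetectorConfig",
    "detect",
    "pan_tompkins_detect",
    "hamilton_detect",
    "wqrs_detect",
]
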