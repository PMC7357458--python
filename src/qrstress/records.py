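"""Core containers for single-channel ECG signals and reference beat labels.

An :class:`EcgRecord` holds one channel of an ECG in physical units (mV)
together with its sampling rate; :class:`BeatAnnotations` holds the reference
beat locations as sample indices with AAMI-style class labels.  All sample
indices throughout the package are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The five AAMI beat classes: normal, supraventricular ectopic, ventricular
#: ectopic, fusion, unknown/paced.
BEAT_CLASSES = ("N", "S", "V", "F", "Q")


@dataclass(frozen=True)
class EcgRecord:
    """A sampled single-channel ECG trace.

    Parameters
    ----------
    record_id : str
        Identifier of the record (database record name, synthesis tag, ...).
    samples : numpy.ndarray
        Amplitudes in millivolts, shape ``(n,)``, finite.
    fs : float
        Sampling rate in Hz, strictly positive.
    channel_name : str
        Name of the lead/channel the samples came from.
    """

    record_id: str
    samples: np.ndarray
    fs: float
    channel_name: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")
        if not (self.fs > 0):
            raise ValueError(f"sampling rate must be > 0, got {self.fs}")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Record duration in seconds."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.samples.size) / self.fs


@dataclass(frozen=True)
class BeatAnnotations:
    """Reference beat locations with AAMI-style class labels.

    ``sample_indices`` are strictly ascending non-negative integers;
    ``labels`` contains one of ``{"N", "S", "V", "F", "Q"}`` per index.
    """

    sample_indices: np.ndarray
    labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        idx = np.asarray(self.sample_indices, dtype=np.int64)
        if idx.ndim != 1:
            raise ValueError("sample_indices must be 1-D")
        if idx.size and idx[0] < 0:
            raise ValueError("sample_indices must be non-negative")
        if idx.size > 1 and not np.all(np.diff(idx) > 0):
            raise ValueError("sample_indices must be strictly ascending")
        labels = tuple(self.labels)
        if not labels and idx.size:
            labels = ("N",) * idx.size
        if len(labels) != idx.size:
            raise ValueError(
                f"labels ({len(labels)}) and sample_indices ({idx.size}) "
                "must have equal length"
            )
        bad = set(labels) - set(BEAT_CLASSES)
        if bad:
            raise ValueError(f"unknown beat classes: {sorted(bad)}")
        object.__setattr__(self, "sample_indices", idx)
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return int(self.sample_indices.size)

    def check_against(self, record: EcgRecord) -> None:
        """Raise if any annotated index falls outside ``record``."""
        if len(self) and self.sample_indices[-1] >= len(record):
            raise ValueError(
                "annotation index beyond record end: "
                f"{int(self.sample_indices[-1])} >= {len(record)}"
            )
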