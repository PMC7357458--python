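"""Reading and writing ECG records, beat annotations and metric tables.

Three on-disk formats are supported:

* WFDB records/annotations (``.hea``/``.dat``/``.atr``), read via the
  bundled minimal parser in :mod:`qrstress.wfdb_io`;
* plain CSV records with header ``time_s,amplitude_mv``;
* metric tables as CSV with header
  ``record_id,detector,noise_type,snr_db,tp,fp,fn,se_pct,pp_pct``.

Native annotation mnemonics are grouped into the five AAMI classes
(N/S/V/F/Q); the mapping table is :data:`AAMI_CLASS_OF`.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .records import BeatAnnotations, EcgRecord
from . import wfdb_io

__all__ = [
    "AAMI_CLASS_OF",
    "read_wfdb_record",
    "read_beat_annotations",
    "read_csv_record",
    "write_csv_record",
    "METRIC_COLUMNS",
    "empty_metric_table",
    "validate_metric_table",
    "write_metrics",
    "read_metrics",
]

# AAMI grouping of native beat mnemonics into the five classes.
# Paced (/), paced-fusion (f) and unclassifiable beats fall under Q.
AAMI_CLASS_OF: dict[str, str] = {
    # N: beats of sinus/bundle-branch origin
    "N": "N", "L": "N", "R": "N", "B": "N", "e": "N", "j": "N",
    # S: supraventricular ectopic
    "A": "S", "a": "S", "J": "S", "S": "S", "n": "S",
    # V: ventricular ectopic
    "V": "V", "E": "V", "r": "V",
    # F: fusion of ventricular and normal
    "F": "F",
    # Q: paced, fusion of paced and normal, unclassifiable
    "/": "Q", "f": "Q", "Q": "Q", "?": "Q",
}

# Mnemonics that are defined but mark no heartbeat (rhythm changes, noise
# flags, waveform boundaries, ...); these are dropped silently.
_NON_BEAT = set('~|sT*D"=p\'tu+![]@x()')


def read_wfdb_record(path_or_id: str | Path, channel: int = 0) -> EcgRecord:
    """Read one channel of a WFDB record in physical units (mV).

    ``path_or_id`` is the record path without extension (e.g.
    ``data/mitdb/100``); ``channel`` selects the signal (default 0, the
    first/modified lead in the ambulatory databases).
    """
    base = Path(path_or_id)
    header_path = base.with_suffix(".hea")
    if not header_path.exists():
        raise FileNotFoundError(f"no header file: {header_path}")
    header = wfdb_io.read_header(header_path)
    if not 0 <= channel < header.n_sig:
        raise ValueError(
            f"channel {channel} out of range for {header.n_sig}-signal record"
        )
    physical = wfdb_io.read_signal(header, base.parent)
    spec = header.signals[channel]
    return EcgRecord(
        record_id=header.record_name,
        samples=physical[:, channel],
        fs=header.fs,
        channel_name=spec.description or f"ch{channel}",
    )


def read_beat_annotations(path_or_id: str | Path) -> BeatAnnotations:
    """Read beat annotations from an MIT-format file, mapped to AAMI classes.

    ``path_or_id`` may be the annotation file itself or the record path
    without extension (``.atr`` is then appended).  Non-beat annotations are
    dropped; beat mnemonics missing from the mapping raise a warning and are
    classified Q.
    """
    path = Path(path_or_id)
    if not path.exists():
        path = path.with_suffix(".atr")
    if not path.exists():
        raise FileNotFoundError(f"no annotation file: {path_or_id}")
    indices, mnemonics = wfdb_io.read_annotations_raw(path)
    keep_idx: list[int] = []
    labels: list[str] = []
    for i, mn in zip(indices, mnemonics):
        if mn in _NON_BEAT:
            continue
        cls = AAMI_CLASS_OF.get(mn)
        if cls is None:
            warnings.warn(f"unmapped beat mnemonic {mn!r}; classified as Q")
            cls = "Q"
        keep_idx.append(int(i))
        labels.append(cls)
    return BeatAnnotations(np.asarray(keep_idx, dtype=np.int64), tuple(labels))


def read_csv_record(
    path: str | Path, record_id: str | None = None, channel_name: str = ""
) -> EcgRecord:
    """Read a CSV record with columns ``time_s,amplitude_mv``.

    The sampling rate is recovered from the median time step.
    """
    df = pd.read_csv(path)
    required = {"time_s", "amplitude_mv"}
    if not required.issubset(df.columns):
        raise ValueError(f"CSV record needs columns {sorted(required)}")
    t = df["time_s"].to_numpy(dtype=np.float64)
    if t.size < 2:
        raise ValueError("CSV record needs at least 2 samples to infer fs")
    fs = (t.size - 1) / float(t[-1] - t[0])
    return EcgRecord(
        record_id=record_id or Path(path).stem,
        samples=df["amplitude_mv"].to_numpy(dtype=np.float64),
        fs=fs,
        channel_name=channel_name,
    )


def write_csv_record(record: EcgRecord, path: str | Path) -> None:
    """Write a record as CSV (``time_s,amplitude_mv``) at full precision."""
    df = pd.DataFrame(
        {"time_s": record.times, "amplitude_mv": record.samples}
    )
    df.to_csv(path, index=False, float_format="%.10g")


METRIC_COLUMNS = (
    "record_id",
    "detector",
    "noise_type",
    "snr_db",
    "tp",
    "fp",
    "fn",
    "se_pct",
    "pp_pct",
)

_KEY_COLUMNS = ["record_id", "detector", "noise_type", "snr_db"]


def empty_metric_table() -> pd.DataFrame:
    return pd.DataFrame(columns=list(METRIC_COLUMNS))


def validate_metric_table(table: pd.DataFrame) -> None:
    """Check schema and uniqueness of (record, detector, noise, SNR) keys."""
    missing = set(METRIC_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"metric table missing columns: {sorted(missing)}")
    if len(table):
        dup = table.duplicated(subset=_KEY_COLUMNS, keep=False)
        if dup.any():
            keys = table.loc[dup, _KEY_COLUMNS].drop_duplicates()
            raise ValueError(f"duplicate metric keys:\n{keys}")


def write_metrics(table: pd.DataFrame, path: str | Path) -> None:
    """Write a metric table as CSV; percentages keep 4 decimal places."""
    validate_metric_table(table)
    out = table.loc[:, list(METRIC_COLUMNS)].copy()
    out.to_csv(path, index=False, float_format="%.4f")


def read_metrics(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, dtype={"record_id": str})
    validate_metric_table(table)
    return table
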