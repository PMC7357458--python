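"""Minimal reader for WFDB records (.hea/.dat) and MIT-format annotations (.atr).

Supports the subset of the format family needed for PhysioNet's ambulatory
ECG databases: header parsing, signal formats 212 and 16, and the MIT
annotation byte stream.  Digital samples are converted to physical units
as ``(adc - baseline) / gain``.  Writing WFDB files is out of scope.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "WfdbHeader",
    "SignalSpec",
    "read_header",
    "read_signal",
    "read_annotations_raw",
    "ANNOTATION_MNEMONICS",
]


@dataclass(frozen=True)
class SignalSpec:
    """One signal-spec line of a .hea file."""

    file_name: str
    fmt: int
    gain: float
    baseline: int
    units: str
    adc_zero: int
    description: str


@dataclass(frozen=True)
class WfdbHeader:
    record_name: str
    n_sig: int
    fs: float
    n_samples: int
    signals: tuple[SignalSpec, ...]


_SIGNAL_LINE = re.compile(
    r"^(?P<file>\S+)\s+(?P<fmt>\d+)(?:x\d+)?(?::\d+)?(?:\+\d+)?"
    r"(?:\s+(?P<gain>[-\d.]+)(?:\((?P<baseline>-?\d+)\))?(?:/(?P<units>\S+))?"
    r"(?:\s+(?P<adcres>-?\d+)(?:\s+(?P<adczero>-?\d+)"
    r"(?:\s+(?P<initval>-?\d+)(?:\s+(?P<checksum>-?\d+)"
    r"(?:\s+(?P<blocksize>-?\d+)(?:\s+(?P<desc>.*))?)?)?)?)?)?)?\s*$"
)

_DEFAULT_GAIN = 200.0  # adu/mV, the WFDB convention when gain is 0 or absent


def read_header(header_path: str | Path) -> WfdbHeader:
    """Parse a .hea file; comment lines (#) and info lines are ignored."""
    header_path = Path(header_path)
    lines = [
        ln.strip()
        for ln in header_path.read_text().splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not lines:
        raise ValueError(f"empty header file: {header_path}")
    first = lines[0].split()
    record_name = first[0].split("/")[0]
    n_sig = int(first[1])
    fs = float(first[2].split("/")[0]) if len(first) > 2 else 250.0
    n_samples = int(first[3]) if len(first) > 3 else 0
    specs: list[SignalSpec] = []
    for ln in lines[1 : 1 + n_sig]:
        m = _SIGNAL_LINE.match(ln)
        if m is None:
            raise ValueError(f"unparseable signal spec line: {ln!r}")
        gain = float(m.group("gain") or 0) or _DEFAULT_GAIN
        adc_zero = int(m.group("adczero") or 0)
        baseline = int(m.group("baseline")) if m.group("baseline") else adc_zero
        specs.append(
            SignalSpec(
                file_name=m.group("file"),
                fmt=int(m.group("fmt")),
                gain=gain,
                baseline=baseline,
                units=m.group("units") or "mV",
                adc_zero=adc_zero,
                description=(m.group("desc") or "").strip(),
            )
        )
    if len(specs) != n_sig:
        raise ValueError(
            f"header declares {n_sig} signals but has {len(specs)} spec lines"
        )
    return WfdbHeader(record_name, n_sig, fs, n_samples, tuple(specs))


def _decode_212(raw: bytes, n_values: int) -> np.ndarray:
    """Unpack format 212: two 12-bit two's-complement samples per 3 bytes."""
    b = np.frombuffer(raw, dtype=np.uint8)
    n_pairs = b.size // 3
    b = b[: n_pairs * 3].reshape(-1, 3).astype(np.int32)
    first = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
    second = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
    out = np.empty(2 * n_pairs, dtype=np.int32)
    out[0::2] = first
    out[1::2] = second
    out[out > 2047] -= 4096
    return out[:n_values]


def read_signal(header: WfdbHeader, dat_dir: str | Path) -> np.ndarray:
    """Read all channels in physical units; returns shape (n_samples, n_sig).

    All signals must live in a single .dat file (the layout used by the
    MIT-BIH databases); samples are interleaved channel-major per frame.
    """
    dat_dir = Path(dat_dir)
    file_names = {s.file_name for s in header.signals}
    if len(file_names) != 1:
        raise NotImplementedError("multi-file records are not supported")
    fmts = {s.fmt for s in header.signals}
    if len(fmts) != 1:
        raise NotImplementedError("mixed-format records are not supported")
    fmt = fmts.pop()
    raw = (dat_dir / file_names.pop()).read_bytes()
    n_sig = header.n_sig
    if fmt == 212:
        total = header.n_samples * n_sig if header.n_samples else (len(raw) // 3) * 2
        digital = _decode_212(raw, total)
    elif fmt == 16:
        digital = np.frombuffer(raw, dtype="<i2").astype(np.int32)
        if header.n_samples:
            digital = digital[: header.n_samples * n_sig]
    else:
        raise NotImplementedError(f"unsupported WFDB signal format {fmt}")
    n_frames = digital.size // n_sig
    digital = digital[: n_frames * n_sig].reshape(n_frames, n_sig)
    physical = np.empty(digital.shape, dtype=np.float64)
    for ch, spec in enumerate(header.signals):
        physical[:, ch] = (digital[:, ch] - spec.baseline) / spec.gain
    return physical


# MIT annotation type codes -> mnemonics (the subset that occurs in practice).
ANNOTATION_MNEMONICS: dict[int, str] = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A",
    9: "S", 10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|",
    18: "s", 19: "T", 20: "*", 21: "D", 22: '"', 23: "=", 24: "p",
    25: "B", 26: "'", 27: "t", 28: "+", 29: "u", 30: "?", 31: "!",
    32: "[", 33: "]", 34: "e", 35: "n", 36: "@", 37: "x", 38: "f",
    39: "(", 40: ")", 41: "r",
}

# Pseudo-annotation codes that modify the stream rather than mark an event.
_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


def read_annotations_raw(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Decode an MIT-format annotation file.

    Returns ``(sample_indices, mnemonics)`` for every true annotation in the
    stream (beat and non-beat alike), in file order.
    """
    raw = Path(path).read_bytes()
    words = np.frombuffer(raw, dtype="<u2")
    indices: list[int] = []
    mnemonics: list[str] = []
    time = 0
    i = 0
    n = words.size
    while i < n:
        word = int(words[i])
        code = word >> 10
        delta = word & 0x3FF
        i += 1
        if code == 0 and delta == 0:  # EOF
            break
        if code == _SKIP:
            if i + 1 >= n:
                raise ValueError("truncated SKIP pseudo-annotation")
            # 4-byte signed interval: high word first, then low word
            interval = (int(words[i]) << 16) | int(words[i + 1])
            if interval >= 1 << 31:
                interval -= 1 << 32
            time += interval
            i += 2
        elif code in (_NUM, _SUB, _CHN):
            continue  # attribute of the previous annotation; no time advance
        elif code == _AUX:
            i += (delta + 1) // 2  # aux string, padded to an even byte count
        else:
            time += delta
            mnemonic = ANNOTATION_MNEMONICS.get(code)
            if mnemonic is None:
                warnings.warn(f"unknown annotation code {code}; kept as 'Q'")
                mnemonic = "Q"
            indices.append(time)
            mnemonics.append(mnemonic)
    return np.asarray(indices, dtype=np.int64), mnemonics
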