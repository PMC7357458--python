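"""Test-side WFDB writers: build tiny .hea/.dat/.atr fixtures in memory.

These encoders are written independently from the byte-level format
definition (format 212 sample packing, MIT annotation words) and exist
only so the reader can be exercised without any external database.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

# mnemonic -> MIT annotation type code (inverse of the reader's table)
CODE_OF = {
    "N": 1, "L": 2, "R": 3, "a": 4, "V": 5, "F": 6, "J": 7, "A": 8,
    "S": 9, "E": 10, "j": 11, "/": 12, "Q": 13, "~": 14, "|": 16,
    "s": 18, "T": 19, "*": 20, "D": 21, '"': 22, "=": 23, "p": 24,
    "B": 25, "'": 26, "t": 27, "+": 28, "u": 29, "?": 30, "!": 31,
    "[": 32, "]": 33, "e": 34, "n": 35, "@": 36, "x": 37, "f": 38,
    "(": 39, ")": 40, "r": 41,
}


def encode_212(samples: np.ndarray) -> bytes:
    """Pack a flat int array (each in [-2048, 2047]) as WFDB format 212."""
    s = np.asarray(samples, dtype=np.int64).ravel()
    if s.size % 2:
        s = np.concatenate([s, [0]])
    if s.min() < -2048 or s.max() > 2047:
        raise ValueError("format 212 samples must fit in 12 bits")
    s = s & 0xFFF
    out = bytearray()
    for a, b in s.reshape(-1, 2):
        out.append(int(a) & 0xFF)
        out.append(((int(a) >> 8) & 0x0F) | (((int(b) >> 8) & 0x0F) << 4))
        out.append(int(b) & 0xFF)
    return bytes(out)


def write_record_212(
    directory: Path,
    name: str,
    physical: np.ndarray,
    fs: float = 360.0,
    gain: float = 200.0,
    baseline: int = 0,
    channel_names: tuple[str, ...] | None = None,
) -> Path:
    """Write a (n, n_sig) physical-unit array as a format-212 WFDB record."""
    physical = np.atleast_2d(np.asarray(physical, dtype=float))
    if physical.shape[0] < physical.shape[1]:
        physical = physical.T
    n, n_sig = physical.shape
    digital = np.round(physical * gain + baseline).astype(np.int64)
    names = channel_names or tuple(f"ch{i}" for i in range(n_sig))
    lines = [f"{name} {n_sig} {fs:g} {n}"]
    for ch in range(n_sig):
        lines.append(
            f"{name}.dat 212 {gain:g}({baseline})/mV 12 {baseline} "
            f"{digital[0, ch]} 0 0 {names[ch]}"
        )
    (directory / f"{name}.hea").write_text("\n".join(lines) + "\n")
    (directory / f"{name}.dat").write_bytes(encode_212(digital.ravel()))
    return directory / name


def write_annotations(
    directory: Path, name: str, indices: np.ndarray, mnemonics: list[str]
) -> Path:
    """Write an MIT-format .atr file (SKIP words for deltas > 1023)."""
    out = bytearray()
    prev = 0
    for idx, mn in zip(indices, mnemonics):
        delta = int(idx) - prev
        code = CODE_OF[mn]
        if delta > 1023:
            out += struct.pack("<H", 59 << 10)  # SKIP
            out += struct.pack("<H", (delta >> 16) & 0xFFFF)
            out += struct.pack("<H", delta & 0xFFFF)
            delta = 0
        out += struct.pack("<H", (code << 10) | delta)
        prev = int(idx)
    out += struct.pack("<H", 0)  # EOF
    path = directory / f"{name}.atr"
    path.write_bytes(bytes(out))
    return path
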