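"""SNR-controlled contamination of a clean ECG with a noise signal.

The signal-to-noise ratio of a mixture ``clean + a * noise`` is

    SNR = 10 * log10( P_signal / (a^2 * P_noise) )          [dB]

with ``P`` the power of each component and ``a`` a dimensionless scale
factor.  Power is defined as variance (mean removed), which makes the SNR
invariant to DC offsets in either component.  Solving for ``a`` at a target
SNR gives ``a = sqrt(P_signal / (P_noise * 10**(SNR/10)))``; substituting
back recovers the target exactly, up to floating-point rounding.

When the noise record is shorter than the clean record it is tiled
end-to-end (periodically) from the requested alignment offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import EcgRecord

__all__ = ["MixSpec", "MixResult", "signal_power", "scale_factor", "mix"]


@dataclass(frozen=True)
class MixSpec:
    """How to contaminate one record: noise class, target SNR, alignment."""

    noise_type: str
    target_snr_db: float
    alignment_offset: int | str = 0  # sample offset into the noise, or "random"
    seed: int = 0  # used only when alignment_offset == "random"

    def __post_init__(self) -> None:
        if not np.isfinite(self.target_snr_db):
            raise ValueError("target_snr_db must be finite")
        if isinstance(self.alignment_offset, str):
            if self.alignment_offset != "random":
                raise ValueError(
                    'alignment_offset must be an integer >= 0 or "random"'
                )
        elif self.alignment_offset < 0:
            raise ValueError("alignment_offset must be >= 0")


@dataclass(frozen=True)
class MixResult:
    """A contaminated record plus the bookkeeping of how it was produced."""

    noisy: EcgRecord
    scale_factor_a: float
    p_signal: float  # mV^2
    p_noise: float  # mV^2, before scaling
    achieved_snr_db: float
    alignment_offset: int = 0


def signal_power(x: np.ndarray) -> float:
    """Power of a sequence: mean squared deviation from its mean (variance)."""
    x = np.asarray(x, dtype=np.float64)
    if x.size < 2:
        raise ValueError("power needs at least 2 samples")
    return float(np.var(x))


def scale_factor(p_signal: float, p_noise: float, target_snr_db: float) -> float:
    """Noise scale ``a`` that realizes the target SNR for the given powers."""
    if not p_signal > 0:
        raise ValueError(f"p_signal must be > 0, got {p_signal}")
    if not p_noise > 0:
        raise ValueError(f"p_noise must be > 0, got {p_noise}")
    return float(np.sqrt(p_signal / (p_noise * 10.0 ** (target_snr_db / 10.0))))


def _align_noise(noise: np.ndarray, n: int, offset: int) -> np.ndarray:
    """Slice ``n`` samples starting at ``offset``, tiling periodically."""
    m = noise.size
    idx = (offset + np.arange(n)) % m
    return noise[idx]


def mix(clean: EcgRecord, noise: EcgRecord, spec: MixSpec) -> MixResult:
    """Add scaled noise to a clean record at an exact target SNR.

    Powers are computed on the clean record and on exactly the aligned
    noise segment that gets added, so the achieved SNR matches the target
    to floating-point precision.
    """
    if clean.fs != noise.fs:
        raise ValueError(
            f"sampling rates differ: clean {clean.fs} Hz vs noise {noise.fs} Hz"
            " (resample before mixing)"
        )
    if isinstance(spec.alignment_offset, str):  # "random"
        rng = np.random.default_rng(spec.seed)
        offset = int(rng.integers(0, len(noise)))
    else:
        offset = int(spec.alignment_offset)

    aligned = _align_noise(noise.samples, len(clean), offset)
    p_sig = signal_power(clean.samples)
    p_noi = signal_power(aligned)
    if p_noi == 0.0:
        raise ValueError("noise segment has zero power")
    a = scale_factor(p_sig, p_noi, spec.target_snr_db)

    noisy = EcgRecord(
        record_id=f"{clean.record_id}+{spec.noise_type}@{spec.target_snr_db:g}dB",
        samples=clean.samples + a * aligned,
        fs=clean.fs,
        channel_name=clean.channel_name,
    )
    achieved = 10.0 * np.log10(p_sig / signal_power(a * aligned))
    return MixResult(
        noisy=noisy,
        scale_factor_a=a,
        p_signal=p_sig,
        p_noise=p_noi,
        achieved_snr_db=float(achieved),
        alignment_offset=offset,
    )
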