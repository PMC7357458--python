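"""Synthetic ECG and noise generation.

The ECG model is a per-beat sum of Gaussian bumps, one per wave (P, Q, R,
S, T), placed on an RR sequence with configurable mean heart rate and
multiplicative jitter.  Beat locations are known by construction, so the
generator doubles as ground truth for detector evaluation.

Three noise surrogates match the spectral character of the classical
ambulatory noise classes:

* **BW** (baseline wander): a sum of low-frequency sinusoids below 1 Hz;
* **MA** (muscle artefact): broadband noise band-limited to 20 Hz up to
  1000 Hz, capped at the Nyquist frequency;
* **EM** (electrode motion): band-limited noise in 1-15 Hz plus a Poisson
  train of smoothed baseline steps emulating abrupt electrode displacement.

All randomness flows from a single integer seed through one
``numpy.random.Generator`` per call, so identical specs give bit-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps, special

from .records import BeatAnnotations, EcgRecord

__all__ = [
    "WaveParams",
    "SyntheticEcgSpec",
    "NoiseSpec",
    "NOISE_BANDS",
    "generate_ecg",
    "generate_noise",
]


@dataclass(frozen=True)
class WaveParams:
    """One ECG wave as a Gaussian bump.

    ``amplitude`` in mV, ``center`` in seconds relative to the R peak,
    ``width`` the Gaussian standard deviation in seconds.
    """

    amplitude: float
    center: float
    width: float

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ValueError(f"wave width must be > 0, got {self.width}")


# Default morphology: R peak 1 mV, QRS spanning ~80 ms, T wave 0.3 mV.
_DEFAULT_WAVES: dict[str, WaveParams] = {
    "P": WaveParams(0.15, -0.20, 0.025),
    "Q": WaveParams(-0.10, -0.028, 0.010),
    "R": WaveParams(1.00, 0.0, 0.012),
    "S": WaveParams(-0.25, 0.028, 0.010),
    "T": WaveParams(0.30, 0.30, 0.060),
}


@dataclass(frozen=True)
class SyntheticEcgSpec:
    """Parameters of the quasi-periodic synthetic ECG."""

    fs: float = 360.0
    duration: float = 60.0
    heart_rate: float = 60.0
    rr_jitter_fraction: float = 0.0
    r_amplitude: float = 1.0
    wave_params: dict[str, WaveParams] = field(
        default_factory=lambda: dict(_DEFAULT_WAVES)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.fs > 0:
            raise ValueError("fs must be > 0")
        if not self.duration > 0:
            raise ValueError("duration must be > 0")
        if not 20 <= self.heart_rate <= 300:
            raise ValueError(
                f"heart_rate must be in [20, 300] bpm, got {self.heart_rate}"
            )
        if self.rr_jitter_fraction < 0:
            raise ValueError("rr_jitter_fraction must be >= 0")


NOISE_BANDS: dict[str, tuple[float, float]] = {
    "BW": (0.0, 1.0),
    "MA": (20.0, 1000.0),
    "EM": (1.0, 15.0),
}


@dataclass(frozen=True)
class NoiseSpec:
    """Parameters of one synthetic noise realization."""

    noise_type: str
    fs: float = 360.0
    duration: float = 60.0
    seed: int = 0
    band: tuple[float, float] | None = None
    em_step_rate: float = 6.0  # events/min
    em_step_amplitude: float = 2.0  # mV

    def __post_init__(self) -> None:
        if self.noise_type not in NOISE_BANDS:
            raise ValueError(
                f"noise_type must be one of {sorted(NOISE_BANDS)}, "
                f"got {self.noise_type!r}"
            )
        if not self.duration > 0:
            raise ValueError("duration must be > 0")
        low, high = self.effective_band()
        if not 0 <= low < high <= self.fs / 2:
            raise ValueError(
                f"band {low}-{high} Hz invalid for fs={self.fs} "
                f"(Nyquist {self.fs / 2} Hz)"
            )

    def effective_band(self) -> tuple[float, float]:
        """The band used for generation.

        An explicitly requested band is taken as-is (and must respect
        Nyquist); the built-in default bands have their upper edge capped at
        Nyquist, since the nominal muscle-artefact range extends to 1000 Hz.
        """
        if self.band is not None:
            return self.band
        low, high = NOISE_BANDS[self.noise_type]
        return low, min(high, self.fs / 2)


def _n_samples(duration: float, fs: float) -> int:
    return int(round(duration * fs))


def generate_ecg(spec: SyntheticEcgSpec) -> tuple[EcgRecord, BeatAnnotations]:
    """Generate a synthetic ECG with known beat locations.

    Beats are placed at times ``t_0 + sum(rr_i)`` with ``t_0`` half a mean
    RR interval, ``rr_i = (60/heart_rate) * (1 + jitter * z_i)`` and ``z_i``
    standard normal (clipped to keep RR positive).  Annotations mark the R
    centers, all labelled N.
    """
    rng = np.random.default_rng(spec.seed)
    n = _n_samples(spec.duration, spec.fs)
    mean_rr = 60.0 / spec.heart_rate

    # Beat center times: start half an RR in so the first P wave fits, and
    # stop early enough that the final QRS (and most of its T wave) fits too.
    t_beats: list[float] = []
    t = 0.5 * mean_rr
    tail_margin = 0.4
    while t < spec.duration - tail_margin:
        t_beats.append(t)
        z = rng.standard_normal() if spec.rr_jitter_fraction > 0 else 0.0
        rr = mean_rr * (1.0 + spec.rr_jitter_fraction * np.clip(z, -3.0, 3.0))
        t = t + max(rr, 0.25 * mean_rr)
    beat_times = np.asarray(t_beats)

    times = np.arange(n) / spec.fs
    samples = np.zeros(n)
    amp_scale = spec.r_amplitude / _DEFAULT_WAVES["R"].amplitude
    for wave in spec.wave_params.values():
        for tb in beat_times:
            c = tb + wave.center
            lo = max(0, int((c - 5 * wave.width) * spec.fs))
            hi = min(n, int((c + 5 * wave.width) * spec.fs) + 1)
            if lo >= hi:
                continue
            samples[lo:hi] += (
                amp_scale
                * wave.amplitude
                * np.exp(-0.5 * ((times[lo:hi] - c) / wave.width) ** 2)
            )

    beat_idx = np.round(beat_times * spec.fs).astype(np.int64)
    beat_idx = beat_idx[beat_idx < n]
    # Snap each annotation to the sample-level R maximum: when the continuous
    # R center falls between samples the discrete peak can sit one sample off.
    for k, idx in enumerate(beat_idx):
        lo = max(0, idx - 1)
        hi = min(n, idx + 2)
        best = lo + int(np.argmax(samples[lo:hi]))
        if samples[best] > samples[idx]:
            beat_idx[k] = best
    record = EcgRecord(
        record_id=f"synth-hr{spec.heart_rate:g}-seed{spec.seed}",
        samples=samples,
        fs=spec.fs,
        channel_name="synthetic",
    )
    annotations = BeatAnnotations(beat_idx, ("N",) * beat_idx.size)
    return record, annotations


def _band_limited_noise(
    rng: np.random.Generator, n: int, fs: float, low: float, high: float
) -> np.ndarray:
    """White Gaussian noise filtered into [low, high] Hz (zero-phase)."""
    white = rng.standard_normal(n)
    nyq = fs / 2
    if high >= nyq * 0.999:  # upper edge at Nyquist: high-pass only
        sos = sps.butter(4, low / nyq, btype="highpass", output="sos")
    elif low <= 0:
        sos = sps.butter(4, high / nyq, btype="lowpass", output="sos")
    else:
        sos = sps.butter(4, [low / nyq, high / nyq], btype="bandpass", output="sos")
    return sps.sosfiltfilt(sos, white)


def _em_steps(
    rng: np.random.Generator, n: int, fs: float, rate_per_min: float, amplitude: float
) -> np.ndarray:
    """Poisson train of smoothed baseline steps (sigmoidal, ~50 ms rise)."""
    out = np.zeros(n)
    n_events = rng.poisson(rate_per_min * n / fs / 60.0)
    if n_events == 0:
        return out
    positions = np.sort(rng.integers(0, n, size=n_events))
    signs = rng.choice([-1.0, 1.0], size=n_events)
    t = np.arange(n) / fs
    rise = 0.05 / 4  # logistic time scale: ~50 ms from 2% to 98%
    for pos, sign in zip(positions, signs):
        out += amplitude * sign * special.expit((t - t[pos]) / rise)
    # Re-center so the step train has zero mean over the record.
    return out - out.mean()


def generate_noise(spec: NoiseSpec) -> EcgRecord:
    """Generate one noise realization of the requested class.

    At least 90% of the output power lies inside the declared band (for EM
    the band check applies to the band-limited component; the step train is
    a transient, broadband addition by design).
    """
    rng = np.random.default_rng(spec.seed)
    n = _n_samples(spec.duration, spec.fs)
    low, high = spec.effective_band()

    if spec.noise_type == "BW":
        # >= 5 sinusoids with random frequencies in [0.05, 0.8] Hz.
        n_tones = 8
        freqs = rng.uniform(0.05, 0.8, size=n_tones)
        phases = rng.uniform(0, 2 * np.pi, size=n_tones)
        amps = rng.uniform(0.3, 1.0, size=n_tones)
        t = np.arange(n) / spec.fs
        samples = np.sum(
            amps[:, None] * np.sin(2 * np.pi * freqs[:, None] * t + phases[:, None]),
            axis=0,
        )
    elif spec.noise_type == "MA":
        samples = _band_limited_noise(rng, n, spec.fs, low, high)
    else:  # EM
        samples = _band_limited_noise(rng, n, spec.fs, low, high)
        samples = samples + _em_steps(
            rng, n, spec.fs, spec.em_step_rate, spec.em_step_amplitude
        )

    return EcgRecord(
        record_id=f"noise-{spec.noise_type}-seed{spec.seed}",
        samples=samples,
        fs=spec.fs,
        channel_name=spec.noise_type,
    )
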