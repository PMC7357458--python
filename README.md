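# qrstress

Noise-stress testing of classical QRS (heartbeat) detectors.

Ambulatory ECG recordings — Holter monitors, wearables — carry far more
noise than resting ECGs: baseline wander (**BW**, respiration and
electrode drift below 1 Hz), muscle artefact (**MA**, broadband
electromyographic noise, nominally 20–1000 Hz) and electrode-motion
artefact (**EM**, 1–15 Hz with abrupt transients, morphologically the
most ECG-like of the three). `qrstress` quantifies how these noise
classes degrade beat detection: it contaminates a clean ECG with one
noise source at an exact signal-to-noise ratio, runs three classical
detectors, and scores them beat-by-beat against reference annotations.
It is aimed at engineers and researchers choosing or hardening a beat
detector for ambulatory monitoring.

## Model

**SNR-controlled mixing.** A mixture `clean + a·noise` has

```
SNR = 10 log10( P_signal / (a² · P_noise) )   [dB]
```

where `P` is the power (variance) of each component. Solving for the
scale factor `a = sqrt(P_signal / (P_noise · 10^(SNR/10)))` gives exact
SNR control; the standard stress grid runs −12 to +12 dB in 3 dB steps.

**Detectors.** Three classical algorithms behind one interface, each
reporting R-position fiducial sample indices:

* **Pan–Tompkins** — band-pass 5–15 Hz → derivative → squaring → 150 ms
  moving-window integration → dual adaptive thresholds with RR tracking,
  search-back and T-wave rejection;
* **Hamilton** — band-pass 8–16 Hz → derivative → rectification → 80 ms
  moving average → three acceptance rules (300 ms refractory, adaptive
  threshold over the last 8 QRS/noise peaks, search-back);
* **WQRS** — low-pass 16 Hz → curve-length transform
  `L(t) = Σ sqrt(c² + Δy²)` over a 130 ms window → adaptive onset
  threshold with a 300 ms eye-closing period.

**Evaluation.** Detections within 150 ms of a reference beat are true
positives (one-to-one, maximum-cardinality matching); the metrics are
sensitivity `SE = 100·TP/(TP+FN)` and positive predictivity
`PP = 100·TP/(TP+FP)`.

Records and annotations are read from WFDB files (`.hea`/`.dat`/`.atr`,
e.g. the MIT-BIH Arrhythmia and Noise Stress Test databases) or plain
CSV; a synthetic-data module generates ECG with known beat locations and
spectrally faithful surrogates of the three noise classes, so the whole
pipeline runs with no external data.

## Worked example

```python
from qrstress import (SyntheticEcgSpec, NoiseSpec, MixSpec,
                      generate_ecg, generate_noise, mix,
                      detect, match_beats, sensitivity, positive_predictivity)

record, beats = generate_ecg(SyntheticEcgSpec(
    heart_rate=72, duration=60, rr_jitter_fraction=0.05, seed=7))
noise = generate_noise(NoiseSpec("EM", duration=60, seed=0))
mixed = mix(record, noise, MixSpec("EM", target_snr_db=-12.0))
print(f"scale a = {mixed.scale_factor_a:.3f}, "
      f"achieved SNR = {mixed.achieved_snr_db:.6f} dB")
for name in ("pan_tompkins", "hamilton", "wqrs"):
    counts = match_beats(beats, detect(mixed.noisy, name))
    print(f"{name:13s} SE = {sensitivity(counts):6.2f}%  "
          f"PP = {positive_predictivity(counts):6.2f}%")
```

prints

```
scale a = 0.502, achieved SNR = -12.000000 dB
pan_tompkins  SE =  98.61%  PP =  95.95%
hamilton      SE =  95.83%  PP =  93.24%
wqrs          SE =  97.22%  PP =  65.42%
```

At −12 dB the electrode-motion artefact (16× the signal's power) costs
every detector beats; the WQRS curve-length detector loses the most
positive predictivity because EM transients mimic QRS slopes, while the
band-pass-based detectors reject more of the out-of-band energy. On the
clean record all three score SE = PP = 100%.

The same pipeline is scriptable from a shell: `qrstress synth | mix |
detect | evaluate | sweep` (see `qrstress --help`).

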