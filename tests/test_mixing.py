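"""SNR-controlled mixing: power definition, scale factor, exactness."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from qrstress import (
    EcgRecord,
    MixSpec,
    NoiseSpec,
    SyntheticEcgSpec,
    generate_ecg,
    generate_noise,
    mix,
    scale_factor,
    signal_power,
)


class TestSignalPower:
    def test_zero_mean_square_wave(self):
        assert signal_power(np.array([1.0, -1.0, 1.0, -1.0])) == 1.0

    def test_constant_sequence_has_zero_power(self):
        assert signal_power(np.array([5.0, 5.0, 5.0])) == 0.0

    def test_unit_sinusoid_half_power(self):
        t = np.arange(36000) / 360.0
        assert signal_power(np.sin(2 * np.pi * 5 * t)) == pytest.approx(0.5, abs=1e-3)

    def test_dc_offset_invariance(self):
        x = np.random.default_rng(0).normal(size=1000)
        assert signal_power(x + 17.3) == pytest.approx(signal_power(x), rel=1e-9)


class TestScaleFactor:
    def test_equal_powers_at_zero_db(self):
        assert scale_factor(1.0, 1.0, 0.0) == 1.0

    def test_back_substitution_recovers_target(self):
        a = scale_factor(4.0, 1.0, 6.0)
        assert 10 * np.log10(4.0 / (a**2 * 1.0)) == pytest.approx(6.0, abs=1e-12)

    @given(
        snr1=st.floats(-40, 40),
        snr2=st.floats(-40, 40),
        p_sig=st.floats(0.01, 100),
        p_noise=st.floats(0.01, 100),
    )
    def test_strictly_decreasing_in_target(self, snr1, snr2, p_sig, p_noise):
        if abs(snr1 - snr2) < 1e-6:
            return
        lo, hi = sorted((snr1, snr2))
        assert scale_factor(p_sig, p_noise, hi) < scale_factor(p_sig, p_noise, lo)

    def test_nonpositive_powers_rejected(self):
        with pytest.raises(ValueError):
            scale_factor(0.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            scale_factor(1.0, 0.0, 0.0)


class TestMix:
    def test_zero_db_added_power_equals_signal_power(self, clean_ecg):
        record, _ = clean_ecg
        noise = generate_noise(NoiseSpec("MA", duration=60, seed=1))
        result = mix(record, noise, MixSpec("MA", 0.0))
        added = result.noisy.samples - record.samples
        assert signal_power(added) == pytest.approx(
            signal_power(record.samples), rel=1e-9
        )

    def test_pm12_db_added_power_ratio(self, clean_ecg):
        record, _ = clean_ecg
        noise = generate_noise(NoiseSpec("BW", duration=60, seed=1))
        lo = mix(record, noise, MixSpec("BW", -12.0))
        hi = mix(record, noise, MixSpec("BW", 12.0))
        p_lo = signal_power(lo.noisy.samples - record.samples)
        p_hi = signal_power(hi.noisy.samples - record.samples)
        assert p_lo / p_hi == pytest.approx(10 ** (24 / 10), rel=1e-9)

    def test_nine_level_grid_achieves_targets(self, clean_ecg):
        record, _ = clean_ecg
        noise = generate_noise(NoiseSpec("BW", duration=60, seed=4))
        for target in range(-12, 13, 3):
            result = mix(record, noise, MixSpec("BW", float(target)))
            assert result.achieved_snr_db == pytest.approx(target, abs=1e-6)
            assert result.scale_factor_a > 0

    def test_linearity_of_added_component(self, clean_ecg):
        record, _ = clean_ecg
        noise = generate_noise(NoiseSpec("EM", duration=60, seed=2))
        result = mix(record, noise, MixSpec("EM", 3.0))
        added = result.noisy.samples - record.samples
        np.testing.assert_allclose(
            added, result.scale_factor_a * noise.samples[: len(record)], atol=1e-12
        )

    def test_short_noise_is_tiled_periodically(self):
        clean = EcgRecord("c", np.sin(np.arange(720) / 10.0), fs=360.0)
        noise = generate_noise(NoiseSpec("MA", duration=0.5, seed=3))  # 180 samples
        result = mix(clean, noise, MixSpec("MA", 0.0))
        added = result.noisy.samples - clean.samples
        np.testing.assert_allclose(added[:180], added[180:360], atol=1e-12)

    def test_random_alignment_is_seeded(self, clean_ecg):
        record, _ = clean_ecg
        noise = generate_noise(NoiseSpec("MA", duration=60, seed=5))
        r1 = mix(record, noise, MixSpec("MA", 0.0, "random", seed=9))
        r2 = mix(record, noise, MixSpec("MA", 0.0, "random", seed=9))
        r3 = mix(record, noise, MixSpec("MA", 0.0, "random", seed=10))
        assert r1.alignment_offset == r2.alignment_offset
        assert np.array_equal(r1.noisy.samples, r2.noisy.samples)
        assert r1.alignment_offset != r3.alignment_offset

    def test_fs_mismatch_rejected(self, clean_ecg):
        record, _ = clean_ecg
        noise = generate_noise(NoiseSpec("MA", fs=250.0, duration=60, seed=1))
        with pytest.raises(ValueError, match="sampling rates"):
            mix(record, noise, MixSpec("MA", 0.0))

    def test_zero_power_noise_rejected(self, clean_ecg):
        record, _ = clean_ecg
        flat = EcgRecord("flat", np.full(len(record), 2.0), fs=record.fs)
        with pytest.raises(ValueError, match="zero power"):
            mix(record, flat, MixSpec("BW", 0.0))

    @given(target=st.floats(-30, 30), seed=st.integers(0, 50))
    def test_snr_round_trip_property(self, target, seed):
        rng = np.random.default_rng(seed)
        clean = EcgRecord("c", rng.normal(size=800), fs=360.0)
        noise = EcgRecord("n", rng.normal(size=800), fs=360.0)
        result = mix(clean, noise, MixSpec("MA", target))
        recomputed = 10 * np.log10(
            signal_power(clean.samples)
            / signal_power(result.noisy.samples - clean.samples)
        )
        assert recomputed == pytest.approx(target, abs=1e-6)
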