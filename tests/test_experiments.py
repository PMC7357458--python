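"""Experiment orchestration: row-count contracts, determinism, summaries."""

import numpy as np
import pytest

from qrstress import (
    SweepConfig,
    SyntheticEcgSpec,
    run_clean_eval,
    run_noise_sweep,
    summarize,
)


@pytest.fixture(scope="module")
def small_sweep_table():
    config = SweepConfig(
        records=(SyntheticEcgSpec(duration=30, heart_rate=72, rr_jitter_fraction=0.05, seed=2),),
        snr_grid_db=(-12.0, 0.0, 12.0),
        seed=5,
    )
    return config, run_noise_sweep(config)


class TestCleanEval:
    def test_synthetic_record_rows_and_perfection(self):
        config = SweepConfig(
            records=(SyntheticEcgSpec(duration=30, seed=1),),
        )
        table = run_clean_eval(config)
        assert len(table) == 3  # one per detector, no aggregate for 1 record
        assert (table["noise_type"] == "clean").all()
        assert (table["se_pct"] == 100.0).all()
        assert (table["pp_pct"] == 100.0).all()

    def test_multi_record_adds_aggregate_rows(self):
        config = SweepConfig(
            records=(
                SyntheticEcgSpec(duration=20, seed=1),
                SyntheticEcgSpec(duration=20, heart_rate=100, seed=2),
            ),
            detectors=("wqrs",),
        )
        table = run_clean_eval(config)
        assert len(table) == 3  # 2 per-record + 1 aggregate
        assert table["record_id"].str.startswith("per_record_mean").sum() == 1

    def test_empty_detector_list_rejected(self):
        with pytest.raises(ValueError, match="detectors"):
            SweepConfig(detectors=())

    def test_unresolvable_record_lists_failures(self, tmp_path):
        config = SweepConfig(records=(str(tmp_path / "missing"),))
        with pytest.raises(ValueError, match="unresolvable"):
            run_clean_eval(config)


class TestNoiseSweep:
    def test_row_count_contract(self, small_sweep_table):
        _, table = small_sweep_table
        # 1 record x 3 noise types x 3 SNRs x 3 detectors x 1 replicate
        assert len(table) == 27

    def test_full_grid_row_count(self):
        config = SweepConfig(
            records=(SyntheticEcgSpec(duration=20, seed=3),),
            detectors=("wqrs",),
        )
        table = run_noise_sweep(config)
        assert len(table) == 3 * 9 * 1  # default 9-level grid

    def test_high_snr_is_effectively_clean(self, small_sweep_table):
        _, table = small_sweep_table
        top = table[table["snr_db"] == 12.0]
        assert (top["se_pct"] == 100.0).all()
        assert (top["pp_pct"] == 100.0).all()

    def test_deterministic_given_config(self, small_sweep_table):
        config, table = small_sweep_table
        again = run_noise_sweep(config)
        assert table.equals(again)

    def test_replicates_key_rows_by_suffix(self):
        config = SweepConfig(
            records=(SyntheticEcgSpec(duration=20, seed=4),),
            detectors=("pan_tompkins",),
            noise_types=("BW",),
            snr_grid_db=(0.0,),
            replicates=2,
        )
        table = run_noise_sweep(config)
        assert len(table) == 2
        assert set(table["record_id"].str[-3:]) == {"#r0", "#r1"}


class TestSummarize:
    def test_single_row_table(self, small_sweep_table):
        _, table = small_sweep_table
        text = summarize(table.iloc[:1])
        assert "pan_tompkins" in text or "wqrs" in text or "hamilton" in text
        assert "worst cell" in text

    def test_full_table_names_worst_cell_at_lowest_snr(self, small_sweep_table):
        _, table = small_sweep_table
        text = summarize(table)
        assert "worst cell by PP" in text
        assert "snr=-12 dB" in text

    def test_clean_only_table(self):
        config = SweepConfig(records=(SyntheticEcgSpec(duration=20, seed=1),))
        text = summarize(run_clean_eval(config))
        assert "clean" in text
        assert "worst cell" not in text

    def test_empty_table_rejected(self, small_sweep_table):
        _, table = small_sweep_table
        with pytest.raises(ValueError):
            summarize(table.iloc[:0])
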