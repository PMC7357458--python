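"""Experiment orchestration: clean evaluation and SNR noise sweeps.

A :class:`SweepConfig` names the records (database paths or synthetic
specs), the detectors, the noise classes and the SNR grid; the runners
mix, detect and evaluate every cell and return a metric table.  The
default grid spans -12 to +12 dB in 3 dB steps, the contamination grid
used throughout the noise-stress protocol.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .detectors import DETECTOR_NAMES, DetectorConfig, detect
from .evaluation import (
    DEFAULT_TOLERANCE_MS,
    MetricRow,
    aggregate,
    match_beats,
    metric_row,
    rows_to_table,
)
from .mixing import MixSpec, mix
from .records import BeatAnnotations, EcgRecord
from .synth import NoiseSpec, SyntheticEcgSpec, generate_ecg, generate_noise

logger = logging.getLogger("qrstress")

DEFAULT_SNR_GRID_DB = tuple(range(-12, 13, 3))

__all__ = [
    "DEFAULT_SNR_GRID_DB",
    "SweepConfig",
    "resolve_records",
    "run_clean_eval",
    "run_noise_sweep",
    "summarize",
]


@dataclass(frozen=True)
class SweepConfig:
    """Everything needed to reproduce one experiment run."""

    records: tuple = ("synthetic",)  # paths, or "synthetic", or SyntheticEcgSpec
    detectors: tuple[str, ...] = DETECTOR_NAMES
    noise_types: tuple[str, ...] = ("BW", "MA", "EM")
    snr_grid_db: tuple[float, ...] = DEFAULT_SNR_GRID_DB
    noise_source: str = "synthetic"  # "synthetic" or a directory of noise records
    replicates: int = 1
    tolerance_ms: float = DEFAULT_TOLERANCE_MS
    aggregation: str = "per_record_mean"
    channel: int = 0
    seed: int = 0
    detector_config: DetectorConfig = field(default_factory=DetectorConfig)
    synthetic_duration_s: float = 60.0
    synthetic_heart_rate_bpm: float = 72.0
    synthetic_rr_jitter: float = 0.05

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("records must be non-empty")
        if not self.detectors:
            raise ValueError("detectors must be non-empty")
        unknown = set(self.detectors) - set(DETECTOR_NAMES)
        if unknown:
            raise ValueError(f"unknown detectors: {sorted(unknown)}")
        if not self.noise_types:
            raise ValueError("noise_types must be non-empty")
        if not all(np.isfinite(self.snr_grid_db)):
            raise ValueError("snr_grid_db must be finite")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def resolve_records(
    config: SweepConfig,
) -> list[tuple[EcgRecord, BeatAnnotations]]:
    """Load or synthesize every record named in the config."""
    out: list[tuple[EcgRecord, BeatAnnotations]] = []
    failures: list[str] = []
    for i, entry in enumerate(config.records):
        if isinstance(entry, SyntheticEcgSpec):
            out.append(generate_ecg(entry))
        elif entry == "synthetic":
            spec = SyntheticEcgSpec(
                duration=config.synthetic_duration_s,
                heart_rate=config.synthetic_heart_rate_bpm,
                rr_jitter_fraction=config.synthetic_rr_jitter,
                seed=config.seed + i,
            )
            out.append(generate_ecg(spec))
        else:
            try:
                record = io.read_wfdb_record(entry, channel=config.channel)
                annotations = io.read_beat_annotations(entry)
                annotations.check_against(record)
                out.append((record, annotations))
            except (OSError, ValueError) as exc:
                failures.append(f"{entry}: {exc}")
    if failures:
        raise ValueError("unresolvable records:\n" + "\n".join(failures))
    return out


def _noise_record(
    config: SweepConfig, noise_type: str, fs: float, duration: float, seed: int
) -> EcgRecord:
    if config.noise_source == "synthetic":
        return generate_noise(
            NoiseSpec(noise_type=noise_type, fs=fs, duration=duration, seed=seed)
        )
    path = Path(config.noise_source) / noise_type.lower()
    return io.read_wfdb_record(path, channel=0)


def run_clean_eval(config: SweepConfig) -> pd.DataFrame:
    """Evaluate every detector on every clean record, plus aggregate rows."""
    pairs = resolve_records(config)
    rows: list[MetricRow] = []
    for detector in config.detectors:
        per_record: list[MetricRow] = []
        for record, annotations in pairs:
            result = detect(record, detector, config.detector_config)
            counts = match_beats(
                annotations, result, tolerance_ms=config.tolerance_ms, fs=record.fs
            )
            row = metric_row(record.record_id, detector, counts)
            logger.info(
                "clean %s/%s: SE=%.2f%% PP=%.2f%%",
                record.record_id,
                detector,
                row.se_pct,
                row.pp_pct,
            )
            per_record.append(row)
        rows.extend(per_record)
        if len(per_record) > 1:
            rows.append(aggregate(per_record, mode=config.aggregation))
    table = rows_to_table(rows)
    io.validate_metric_table(table)
    return table


def run_noise_sweep(config: SweepConfig) -> pd.DataFrame:
    """Mix, detect and evaluate every (record, noise, SNR, detector, replicate).

    Replicate rows (replicates > 1) use random noise alignments seeded from
    the config seed and are keyed by a ``#rep`` suffix on the record id.
    """
    pairs = resolve_records(config)
    rows: list[MetricRow] = []
    for rec_i, (record, annotations) in enumerate(pairs):
        for noise_type in config.noise_types:
            for rep in range(config.replicates):
                noise_seed = config.seed + 1000 * rec_i + 10 * rep + 1
                noise = _noise_record(
                    config, noise_type, record.fs, record.duration, noise_seed
                )
                offset: int | str = 0 if config.replicates == 1 else "random"
                for snr_db in config.snr_grid_db:
                    spec = MixSpec(
                        noise_type=noise_type,
                        target_snr_db=float(snr_db),
                        alignment_offset=offset,
                        seed=noise_seed,
                    )
                    mixed = mix(record, noise, spec)
                    logger.debug(
                        "%s %s@%+gdB rep%d: a=%.5g achieved=%.9f dB offset=%d",
                        record.record_id,
                        noise_type,
                        snr_db,
                        rep,
                        mixed.scale_factor_a,
                        mixed.achieved_snr_db,
                        mixed.alignment_offset,
                    )
                    for detector in config.detectors:
                        result = detect(mixed.noisy, detector, config.detector_config)
                        counts = match_beats(
                            annotations,
                            result,
                            tolerance_ms=config.tolerance_ms,
                            fs=record.fs,
                        )
                        rec_id = record.record_id
                        if config.replicates > 1:
                            rec_id = f"{rec_id}#r{rep}"
                        row = metric_row(
                            rec_id, detector, counts, noise_type, float(snr_db)
                        )
                        logger.info(
                            "%s %s@%+gdB %s: SE=%.2f%% PP=%.2f%%",
                            rec_id,
                            noise_type,
                            snr_db,
                            detector,
                            row.se_pct,
                            row.pp_pct,
                        )
                        rows.append(row)
    table = rows_to_table(rows)
    io.validate_metric_table(table)
    return table


def summarize(table: pd.DataFrame) -> str:
    """Text report: per-detector, per-noise SE/PP vs SNR, plus the worst cell."""
    if table.empty:
        raise ValueError("cannot summarize an empty metric table")
    lines: list[str] = []
    work = table.copy()
    work["snr_label"] = np.where(
        work["snr_db"].isna(), "clean", work["snr_db"].map("{:+g} dB".format)
    )
    for detector, det_group in work.groupby("detector", sort=True):
        lines.append(f"== {detector} ==")
        for metric in ("se_pct", "pp_pct"):
            pivot = det_group.pivot_table(
                index="noise_type",
                columns="snr_label",
                values=metric,
                aggfunc="mean",
                sort=True,
            )
            lines.append(f"-- {'SE' if metric == 'se_pct' else 'PP'} (%) --")
            lines.append(pivot.round(2).to_string())
        lines.append("")
    noisy = work[work["snr_db"].notna()]
    if len(noisy):
        cell = (
            noisy.groupby(["detector", "noise_type", "snr_db"])["pp_pct"]
            .mean()
            .idxmin()
        )
        worst = noisy.groupby(["detector", "noise_type", "snr_db"])["pp_pct"].mean()[cell]
        lines.append(
            "worst cell by PP: detector=%s noise=%s snr=%+g dB (PP=%.2f%%)"
            % (cell[0], cell[1], cell[2], worst)
        )
    return "\n".join(lines)
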