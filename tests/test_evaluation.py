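"""Beat matching and the SE/PP metrics."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, strategies as st

from qrstress import (
    MatchCounts,
    aggregate,
    match_beats,
    metric_row,
    positive_predictivity,
    sensitivity,
)


def bipartite_oracle(ref, det, tol):
    """Maximum-cardinality matching size via networkx (independent oracle)."""
    g = nx.Graph()
    g.add_nodes_from([("r", i) for i in range(len(ref))])
    g.add_nodes_from([("d", j) for j in range(len(det))])
    for i, r in enumerate(ref):
        for j, d in enumerate(det):
            if abs(int(d) - int(r)) <= tol:
                g.add_edge(("r", i), ("d", j))
    return len(
        nx.bipartite.maximum_matching(g, top_nodes=[("r", i) for i in range(len(ref))])
    ) // 2


def random_instance(rng, max_beats=12, span=5000):
    n_ref = int(rng.integers(0, max_beats + 1))
    n_det = int(rng.integers(0, max_beats + 1))
    ref = np.sort(rng.choice(span, n_ref, replace=False))
    det = np.sort(rng.choice(span, n_det, replace=False))
    return ref, det


class TestMatchBeats:
    def test_identity_is_all_tp(self):
        idx = np.array([100, 500, 900])
        counts = match_beats(idx, idx)
        assert (counts.tp, counts.fp, counts.fn) == (3, 0, 0)

    def test_spec_example_mixed_outcome(self):
        # tolerance of 54 samples at 360 Hz = 150 ms
        counts = match_beats(
            np.array([100, 500]), np.array([120, 900]), tolerance_ms=150, fs=360
        )
        assert (counts.tp, counts.fp, counts.fn) == (1, 1, 1)

    def test_no_detections_all_fn(self):
        counts = match_beats(np.array([1, 2, 3]), np.array([], dtype=np.int64))
        assert (counts.tp, counts.fp, counts.fn) == (0, 0, 3)

    def test_agrees_with_bipartite_oracle(self):
        rng = np.random.default_rng(2024)
        tol_ms, fs = 150.0, 360.0
        tol = tol_ms / 1000 * fs
        for _ in range(200):
            ref, det = random_instance(rng)
            counts = match_beats(ref, det, tolerance_ms=tol_ms, fs=fs)
            assert counts.tp == bipartite_oracle(ref, det, tol)
            assert counts.tp + counts.fn == len(ref)
            assert counts.tp + counts.fp == len(det)

    @given(st.integers(0, 10_000))
    def test_conservation_and_tolerance_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        ref, det = random_instance(rng, max_beats=10, span=2000)
        prev_tp = -1
        for tol_ms in (10.0, 50.0, 150.0, 400.0):
            c = match_beats(ref, det, tolerance_ms=tol_ms, fs=360.0)
            assert c.tp + c.fn == len(ref)
            assert c.tp + c.fp == len(det)
            assert c.tp >= prev_tp  # TP non-decreasing as tolerance widens
            prev_tp = c.tp

    def test_nonpositive_tolerance_rejected(self):
        with pytest.raises(ValueError):
            match_beats(np.array([1]), np.array([1]), tolerance_ms=0)


class TestMetrics:
    @pytest.mark.parametrize(
        "tp,fn,expected", [(10, 0, 100.0), (97, 3, 97.0)]
    )
    def test_sensitivity(self, tp, fn, expected):
        assert sensitivity(MatchCounts(tp, 0, fn)) == expected

    @pytest.mark.parametrize(
        "tp,fp,expected", [(10, 0, 100.0), (90, 10, 90.0), (1, 3, 25.0)]
    )
    def test_positive_predictivity(self, tp, fp, expected):
        assert positive_predictivity(MatchCounts(tp, fp, 0)) == expected

    def test_undefined_metrics_raise(self):
        with pytest.raises(ZeroDivisionError):
            sensitivity(MatchCounts(0, 5, 0))
        with pytest.raises(ZeroDivisionError):
            positive_predictivity(MatchCounts(0, 0, 5))


class TestAggregate:
    def test_single_row_is_identity_under_both_modes(self):
        row = metric_row("r1", "wqrs", MatchCounts(99, 1, 1))
        for mode in ("per_record_mean", "gross"):
            agg = aggregate([row], mode=mode)
            assert agg.se_pct == pytest.approx(row.se_pct)
            assert agg.pp_pct == pytest.approx(row.pp_pct)

    def test_per_record_mean_is_unweighted(self):
        rows = [
            metric_row("a", "wqrs", MatchCounts(100, 0, 0)),
            metric_row("b", "wqrs", MatchCounts(9, 0, 1)),
        ]
        agg = aggregate(rows, mode="per_record_mean")
        assert agg.se_pct == pytest.approx(95.0)

    def test_gross_pools_counts_first(self):
        rows = [
            metric_row("a", "wqrs", MatchCounts(99, 0, 1)),
            metric_row("b", "wqrs", MatchCounts(9, 0, 1)),
        ]
        agg = aggregate(rows, mode="gross")
        assert agg.se_pct == pytest.approx(100 * 108 / 110)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            aggregate([])

    def test_mixed_cells_rejected(self):
        rows = [
            metric_row("a", "wqrs", MatchCounts(9, 0, 1)),
            metric_row("a", "hamilton", MatchCounts(9, 0, 1)),
        ]
        with pytest.raises(ValueError, match="mix"):
            aggregate(rows)
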