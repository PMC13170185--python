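"""Sliding-window crossover calling: majority rule, breakpoints, 500-kb filter."""

import numpy as np
import pandas as pd
import pytest

from xomap import (
    CallerConfig,
    COEvent,
    GenomeMap,
    HET,
    HOM_P1,
    MISSING,
    MarkerSet,
    SimulationConfig,
    UNASSIGNED,
    call_population,
    detect_breakpoints,
    filter_double_crossovers,
    recovery_metrics,
    simulate_population,
    window_genotype,
)
from xomap.genotypes import GenotypeMatrix

from .conftest import make_markers


def _event(mid_kb, left_kb=None, right_kb=None, ind="I1", chrom="A01"):
    mid = mid_kb * 1000
    left = (left_kb * 1000) if left_kb is not None else mid - 1000
    right = (right_kb * 1000) if right_kb is not None else mid + 1000
    return COEvent(ind, chrom, left, right, (left + right) // 2)


class TestWindowGenotype:
    GENOME = GenomeMap({"A01": 100_000})
    MARKERS = make_markers({"A01": [10_000, 30_000, 60_000, 80_000, 90_000]})

    def test_majority_rule_hand_trace(self):
        """Windows [0,50): HOM x2; [25,75): 1-1 tie -> UNASSIGNED; [50,100): HET x3."""
        calls = np.array([HOM_P1, HOM_P1, HET, HET, HET], dtype=np.int8)
        track = window_genotype(calls, self.MARKERS, CallerConfig(), self.GENOME)
        win = track.chromosomes["A01"]
        assert list(win["start"]) == [0, 25_000, 50_000]
        assert list(win["state"]) == [HOM_P1, UNASSIGNED, HET]
        assert list(win["support"]) == [2, 2, 3]

    def test_all_missing_is_all_unassigned(self):
        calls = np.full(5, MISSING, dtype=np.int8)
        track = window_genotype(calls, self.MARKERS, CallerConfig(), self.GENOME)
        assert (track.chromosomes["A01"]["state"] == UNASSIGNED).all()

    def test_uniform_row_has_no_state_change(self):
        calls = np.full(5, HOM_P1, dtype=np.int8)
        track = window_genotype(calls, self.MARKERS, CallerConfig(), self.GENOME)
        states = track.chromosomes["A01"]["state"]
        assert set(states[states != UNASSIGNED]) == {HOM_P1}
        assert detect_breakpoints(track, calls, self.MARKERS) == []

    def test_zero_marker_chromosome_warns_with_empty_track(self):
        genome = GenomeMap({"A01": 100_000, "A02": 100_000})
        with pytest.warns(UserWarning, match="A02"):
            track = window_genotype(
                np.full(5, HOM_P1, dtype=np.int8), self.MARKERS, CallerConfig(), genome
            )
        assert track.chromosomes["A02"].empty


class TestDetectBreakpoints:
    GENOME = GenomeMap({"A01": 100_000})
    MARKERS = make_markers({"A01": [10_000, 30_000, 60_000, 80_000, 90_000]})

    def test_midpoint_between_flanking_markers(self):
        """Last HOM marker 30 kb, first HET marker 60 kb -> midpoint 45 kb."""
        calls = np.array([HOM_P1, HOM_P1, HET, HET, HET], dtype=np.int8)
        track = window_genotype(calls, self.MARKERS, CallerConfig(), self.GENOME)
        events = detect_breakpoints(track, calls, self.MARKERS, individual="I1")
        assert len(events) == 1
        e = events[0]
        assert (e.left_bound, e.right_bound, e.midpoint) == (30_000, 60_000, 45_000)
        assert (e.left_state, e.right_state) == (HOM_P1, HET)

    def test_unassigned_windows_bridged_without_transition(self):
        """HOM .. unassigned gap .. HOM produces no crossover."""
        genome = GenomeMap({"A01": 250_000})
        markers = make_markers(
            {"A01": [10_000, 20_000, 30_000, 220_000, 230_000, 240_000]}
        )
        calls = np.array([HOM_P1] * 6, dtype=np.int8)
        track = window_genotype(calls, markers, CallerConfig(), genome)
        states = track.chromosomes["A01"]["state"].to_numpy()
        assert UNASSIGNED in states  # the middle really is a gap
        assert detect_breakpoints(track, calls, markers) == []

    def test_transition_across_bridge_yields_single_event(self):
        genome = GenomeMap({"A01": 250_000})
        markers = make_markers(
            {"A01": [10_000, 20_000, 30_000, 220_000, 230_000, 240_000]}
        )
        calls = np.array([HOM_P1] * 3 + [HET] * 3, dtype=np.int8)
        track = window_genotype(calls, markers, CallerConfig(), genome)
        events = detect_breakpoints(track, calls, markers)
        assert len(events) == 1
        assert events[0].left_bound == 30_000
        assert events[0].right_bound == 220_000


class TestDoubleCOFilter:
    CONFIG = CallerConfig()

    def test_segment_300kb_removes_both_flanking_events(self):
        events = [_event(2_000), _event(2_300)]
        assert filter_double_crossovers(events, 10_000_000, self.CONFIG) == []

    def test_segment_1mb_retains_both(self):
        events = [_event(2_000), _event(3_000)]
        assert filter_double_crossovers(events, 10_000_000, self.CONFIG) == events

    def test_single_event_always_retained(self):
        events = [_event(50)]  # 50 kb from the start: terminal segments exempt
        assert filter_double_crossovers(events, 10_000_000, self.CONFIG) == events

    def test_shortest_segment_removed_first(self):
        # gaps: 600 kb, 300 kb, 600 kb -> removing the middle pair leaves
        # a 1.5 Mb gap between the outer events, so both survive
        events = [_event(1_000), _event(1_600), _event(1_900), _event(2_500)]
        kept = filter_double_crossovers(events, 10_000_000, self.CONFIG)
        assert [e.midpoint for e in kept] == [1_000_000, 2_500_000]

    def test_monotone_in_support_threshold(self):
        rng = np.random.default_rng(0)
        mids = np.sort(rng.integers(100, 9_900, size=8)) * 1000
        mids = np.unique(mids)
        events = [_event(m // 1000) for m in mids]
        previous = None
        for support in [100_000, 300_000, 500_000, 1_000_000, 3_000_000]:
            cfg = CallerConfig(min_double_co_support=support)
            n = len(filter_double_crossovers(events, 10_000_000, cfg))
            if previous is not None:
                assert n <= previous
            previous = n


class TestCallPopulation:
    def test_empty_matrix_gives_empty_table(self):
        genome = GenomeMap({"A01": 1_000_000})
        markers = make_markers({"A01": [10_000, 20_000]})
        matrix = GenotypeMatrix(
            pd.DataFrame(columns=["individual", "group", "sex"]),
            np.empty((0, 2), dtype=np.int8),
            markers,
        )
        assert len(call_population(matrix, markers, genome)) == 0

    def test_close_true_double_co_is_filtered(self):
        """Two true crossovers 300 kb apart vanish from the calls."""
        genome = GenomeMap({"A01": 5_000_000})
        positions = list(range(0, 5_000_000, 5_000))
        markers = make_markers({"A01": positions})
        pos = np.array(positions)
        calls = np.where((pos >= 2_000_000) & (pos < 2_300_000), HET, HOM_P1).astype(
            np.int8
        )
        matrix = GenotypeMatrix(
            pd.DataFrame({"individual": ["I1"], "group": "WT", "sex": "male"}),
            calls[None, :],
            markers,
        )
        assert len(call_population(matrix, markers, genome)) == 0

    def test_deterministic(self):
        cfg = SimulationConfig(
            genome=GenomeMap({"A01": 8_000_000}), n_individuals=10, seed=5
        )
        matrix, _, _ = simulate_population(cfg)
        t1 = call_population(matrix, matrix.markers, cfg.genome)
        t2 = call_population(matrix, matrix.markers, cfg.genome)
        assert t1 == t2

    def test_marker_permutation_invariance(self):
        cfg = SimulationConfig(
            genome=GenomeMap({"A01": 8_000_000}), n_individuals=6, seed=9
        )
        matrix, _, _ = simulate_population(cfg)
        baseline = call_population(matrix, matrix.markers, cfg.genome)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(matrix.markers))
        shuffled = MarkerSet(matrix.markers.table.iloc[perm].reset_index(drop=True))
        realigned_calls = matrix.calls[:, perm][:, shuffled.input_order]
        matrix2 = GenotypeMatrix(matrix.individuals, realigned_calls, shuffled)
        assert call_population(matrix2, shuffled, cfg.genome) == baseline

    def test_error_free_recovery_is_perfect_on_well_spaced_truth(self):
        """Precision = recall = 1.0 when true crossovers are mutually distant
        (>= 1 Mb apart) and callable (>= 1 window from the chromosome ends)."""
        cfg = SimulationConfig(
            genome=GenomeMap({"A01": 25_000_000}),
            n_individuals=60,
            genotyping_error=0.0,
            missing_rate=0.0,
            seed=2,
        )
        matrix, truth, _ = simulate_population(cfg)
        keep = _well_spaced_individuals(truth, 25_000_000)
        assert len(keep) >= 30
        idx = matrix.individuals["individual"].isin(keep).to_numpy()
        sub = GenotypeMatrix(
            matrix.individuals[idx].reset_index(drop=True),
            matrix.calls[idx],
            matrix.markers,
        )
        sub_truth = _subset_table(truth, keep)
        called = call_population(sub, matrix.markers, cfg.genome)
        m = recovery_metrics(called, sub_truth)
        assert m["precision"] == 1.0
        assert m["recall"] == 1.0


def _well_spaced_individuals(truth, length, min_gap=1_000_000, end_margin=50_000):
    keep = []
    for ind, sub in truth.events.groupby("individual"):
        ok = True
        for _, chrom_sub in sub.groupby("chromosome"):
            mids = chrom_sub["midpoint"].to_numpy()
            if len(mids) > 1 and np.min(np.diff(mids)) < min_gap:
                ok = False
            if len(mids) and (mids.min() < end_margin or mids.max() > length - end_margin):
                ok = False
        if ok:
            keep.append(ind)
    # individuals with zero crossovers are trivially well spaced
    zero = set(truth.individuals["individual"]) - set(truth.events["individual"])
    return sorted(set(keep) | zero)


def _subset_table(table, individuals):
    from xomap import COTable

    ind = table.individuals[table.individuals["individual"].isin(individuals)]
    ev = table.events[table.events["individual"].isin(individuals)]
    return COTable(ev.copy(), ind.copy())


def test_regression_f1_with_realistic_error():
    """F1 >= 0.95 at 0.5% genotyping error and resequencing marker density."""
    cfg = SimulationConfig(
        genome=GenomeMap({"A01": 25_000_000, "A02": 20_000_000}),
        n_individuals=60,
        genotyping_error=0.005,
        missing_rate=0.01,
        seed=3,
    )
    matrix, truth, _ = simulate_population(cfg)
    called = call_population(matrix, matrix.markers, cfg.genome)
    m = recovery_metrics(called, truth)
    assert m["f1"] >= 0.95
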