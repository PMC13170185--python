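"""Sliding-window crossover calling from BC1 genotype matrices.

Per gamete and chromosome the genotype calls are smoothed into overlapping
windows (default 50 kb, advanced by 25 kb); each window takes the strict
majority state of its non-missing calls, provided at least
``min_markers_per_window`` of them support it. Crossovers are emitted at
transitions between consecutive assigned window states, bridged across
unassigned windows, and localised between the nearest informative markers
supporting either flanking state. Finally the double-crossover support
rule removes pairs of crossovers whose intervening genotype segment spans
less than ``min_double_co_support`` (default 500 kb) — short interstitial
segments are treated as call artifacts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .crossovers import COEvent, COTable
from .errors import ConfigError
from .genome import GenomeMap, MarkerSet
from .genotypes import GenotypeMatrix, HET, HOM_P1

__all__ = [
    "CallerConfig",
    "WindowTrack",
    "UNASSIGNED",
    "window_genotype",
    "detect_breakpoints",
    "filter_double_crossovers",
    "call_population",
    "recovery_metrics",
]

UNASSIGNED: int = -2


@dataclass(frozen=True)
class CallerConfig:
    window_size: int = 50_000
    step_size: int = 25_000
    min_markers_per_window: int = 2
    min_double_co_support: int = 500_000

    def __post_init__(self) -> None:
        if min(self.window_size, self.step_size, self.min_markers_per_window,
               self.min_double_co_support) <= 0:
            raise ConfigError("all caller parameters must be > 0")
        if self.step_size > self.window_size:
            raise ConfigError("step_size must be <= window_size")


@dataclass
class WindowTrack:
    """Per-chromosome window states for one gamete.

    Each chromosome maps to a DataFrame with columns ``start``, ``end``,
    ``state`` (HOM_P1 / HET / UNASSIGNED) and ``support`` (non-missing
    marker count).
    """

    chromosomes: dict[str, pd.DataFrame] = field(default_factory=dict)


def _window_starts(length: int, config: CallerConfig) -> np.ndarray:
    n = (length - config.window_size) // config.step_size + 1
    return np.arange(max(n, 0), dtype=np.int64) * config.step_size


def window_genotype(
    calls: np.ndarray,
    markers: MarkerSet,
    config: CallerConfig,
    genome: GenomeMap,
) -> WindowTrack:
    """Assign a majority genotype state to each sliding window.

    A window is assigned only when its non-missing support reaches
    ``min_markers_per_window`` and one state holds a strict majority; ties
    and thin windows stay UNASSIGNED.
    """
    track = WindowTrack()
    for chrom in genome.names:
        idx = markers.chrom_index(chrom)
        starts = _window_starts(genome.length(chrom), config)
        if len(idx) == 0:
            warnings.warn(f"no markers on chromosome {chrom}; track left empty")
            track.chromosomes[chrom] = pd.DataFrame(
                columns=["start", "end", "state", "support"]
            )
            continue
        pos = markers.positions(chrom)
        sub = calls[idx]
        # prefix sums over markers let every window count its states in O(1)
        cum_hom = np.concatenate([[0], np.cumsum(sub == HOM_P1)])
        cum_het = np.concatenate([[0], np.cumsum(sub == HET)])
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, starts + config.window_size, side="left")
        n_hom = cum_hom[hi] - cum_hom[lo]
        n_het = cum_het[hi] - cum_het[lo]
        support = n_hom + n_het
        state = np.full(len(starts), UNASSIGNED, dtype=np.int8)
        ok = support >= config.min_markers_per_window
        state[ok & (n_hom > n_het)] = HOM_P1
        state[ok & (n_het > n_hom)] = HET
        track.chromosomes[chrom] = pd.DataFrame(
            {
                "start": starts,
                "end": starts + config.window_size,
                "state": state,
                "support": support,
            }
        )
    return track


def detect_breakpoints(
    track: WindowTrack,
    calls: np.ndarray,
    markers: MarkerSet,
    individual: str = "",
    group: str = "WT",
    sex: str = "male",
) -> list[COEvent]:
    """Emit provisional crossovers at state transitions of the window track.

    Unassigned windows are bridged: only transitions between consecutive
    *assigned* states count. The event is localised between the last marker
    supporting the left state before the transition and the first marker
    supporting the right state within the right-hand run.
    """
    events: list[COEvent] = []
    for chrom, win in track.chromosomes.items():
        assigned = win[win["state"] != UNASSIGNED]
        if assigned.empty:
            continue
        states = assigned["state"].to_numpy()
        starts = assigned["start"].to_numpy()
        change = np.flatnonzero(states[1:] != states[:-1])
        if len(change) == 0:
            continue
        idx = markers.chrom_index(chrom)
        pos = markers.positions(chrom)
        sub = calls[idx]
        for t in change:
            left_state = int(states[t])
            right_state = int(states[t + 1])
            right_run_start = starts[t + 1]
            right_candidates = pos[(sub == right_state) & (pos >= right_run_start)]
            if len(right_candidates) == 0:
                continue
            right_bound = int(right_candidates[0])
            left_candidates = pos[(sub == left_state) & (pos < right_bound)]
            if len(left_candidates) == 0:
                continue
            left_bound = int(left_candidates[-1])
            if right_bound - left_bound < 2:
                continue  # no interior base pair to localise the exchange
            events.append(
                COEvent(
                    individual=individual,
                    chromosome=chrom,
                    left_bound=left_bound,
                    right_bound=right_bound,
                    midpoint=(left_bound + right_bound) // 2,
                    left_state=left_state,
                    right_state=right_state,
                    group=group,
                    sex=sex,
                )
            )
    return events


def filter_double_crossovers(
    events: list[COEvent], chrom_length: int, config: CallerConfig
) -> list[COEvent]:
    """Apply the double-crossover support rule to one chromosome's events.

    The genotype segment between two consecutive crossovers must span at
    least ``min_double_co_support``; a shorter internal segment is treated
    as a call artifact and *both* flanking crossovers are removed, iterating
    from the shortest offending segment so the result does not depend on
    scan order. Terminal segments (to the chromosome ends) are exempt: a
    single crossover is never a double crossover.
    """
    kept = sorted(events, key=lambda e: e.midpoint)
    while len(kept) >= 2:
        gaps = np.diff([e.midpoint for e in kept])
        worst = int(np.argmin(gaps))
        if gaps[worst] >= config.min_double_co_support:
            break
        del kept[worst : worst + 2]
    return kept


def call_population(
    matrix: GenotypeMatrix,
    markers: MarkerSet,
    genome: GenomeMap,
    config: CallerConfig | None = None,
) -> COTable:
    """Call crossovers for every individual of a genotype matrix."""
    config = config or CallerConfig()
    all_events: list[COEvent] = []
    for i in range(matrix.n_individuals):
        ind, group, sex = matrix.individuals.iloc[i][["individual", "group", "sex"]]
        row = matrix.calls[i]
        track = window_genotype(row, markers, config, genome)
        provisional = detect_breakpoints(
            track, row, markers, individual=str(ind), group=str(group), sex=str(sex)
        )
        for chrom in genome.names:
            chrom_events = [e for e in provisional if e.chromosome == chrom]
            all_events.extend(
                filter_double_crossovers(chrom_events, genome.length(chrom), config)
            )
    return COTable.from_events(all_events, matrix.individuals)


def recovery_metrics(
    called: COTable, truth: COTable, tolerance: int = 50_000
) -> dict[str, float]:
    """Precision / recall / F1 of called vs true crossovers.

    Events are matched greedily per individual and chromosome when their
    midpoints lie within ``tolerance`` base pairs.
    """
    tp = 0
    n_called = len(called)
    n_truth = len(truth)
    truth_groups = {
        key: sub["midpoint"].to_numpy()
        for key, sub in truth.events.groupby(["individual", "chromosome"], sort=False)
    }
    for key, sub in called.events.groupby(["individual", "chromosome"], sort=False):
        t = truth_groups.get(key)
        if t is None:
            continue
        used = np.zeros(len(t), dtype=bool)
        for m in sub["midpoint"].to_numpy():
            dist = np.abs(t - m)
            dist[used] = tolerance + 1
            j = int(np.argmin(dist))
            if dist[j] <= tolerance:
                used[j] = True
                tp += 1
    precision = tp / n_called if n_called else 0.0
    recall = tp / n_truth if n_truth else 0.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    return {
        "n_called": float(n_called),
        "n_truth": float(n_truth),
        "true_positives": float(tp),
        "precision": precision,
        "recall": recall,
        "f1": f1,
    }
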