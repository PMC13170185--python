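"""Population-level crossover statistics.

Per-gamete counts (a BC1 individual's genotype reveals one gamete of the
F1), recombination landscapes in overlapping physical windows, distances
between adjacent crossovers, and Mann-Whitney group comparisons. Gametes
with zero crossovers are sampled units and always count in denominators.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .crossovers import COTable
from .errors import ValidationError
from .genome import GenomeMap

__all__ = [
    "CountSummary",
    "LandscapeTrack",
    "per_gamete_counts",
    "landscape",
    "inter_co_distances",
    "compare_groups",
]


@dataclass
class CountSummary:
    """Per-gamete crossover counts and their group-wise mean +- SD.

    ``counts`` has one row per individual (zero-CO gametes included);
    ``summary`` is indexed by (group, sex) with columns ``n``, ``mean``,
    ``sd`` (sample SD, n-1 denominator).
    """

    chromosomes: tuple[str, ...] | None
    counts: pd.DataFrame
    summary: pd.DataFrame


def per_gamete_counts(
    table: COTable, chromosomes: Iterable[str] | None = None
) -> CountSummary:
    """Count crossovers per gamete, optionally restricted to a chromosome set."""
    events = table.events
    if chromosomes is not None:
        chromosomes = tuple(chromosomes)
        events = events[events["chromosome"].isin(chromosomes)]
    per_ind = events.groupby("individual").size()
    counts = table.individuals.copy()
    counts["count"] = counts["individual"].map(per_ind).fillna(0).astype(int)
    summary = (
        counts.groupby(["group", "sex"])["count"]
        .agg(n="size", mean="mean", sd=lambda s: s.std(ddof=1))
        .reset_index()
    )
    return CountSummary(chromosomes, counts, summary)


@dataclass
class LandscapeTrack:
    """Windowed crossover rate along each chromosome.

    One DataFrame per chromosome with columns ``start``, ``mid``, ``value``
    (crossovers per gamete falling in the window); the genome's centromere
    annotation rides along for plotting.
    """

    chromosomes: dict[str, pd.DataFrame]
    window: int
    step: int
    n_gametes: int
    centromeres: dict[str, tuple[int, int]]


def landscape(
    table: COTable,
    genome: GenomeMap,
    n_gametes: int | None = None,
    window: int = 1_000_000,
    step: int = 50_000,
) -> LandscapeTrack:
    """Crossover landscape in overlapping windows (default 1 Mb / 50 kb step).

    Each window's value is the number of crossover midpoints inside
    [start, start + window) divided by the number of gametes; overlapping
    windows each count a crossover that falls in them.
    """
    if n_gametes is None:
        n_gametes = len(table.individuals)
    if n_gametes <= 0:
        raise ValidationError("n_gametes must be > 0")
    tracks: dict[str, pd.DataFrame] = {}
    for chrom, length in genome.chromosomes.items():
        n_win = (length - window) // step + 1
        starts = np.arange(max(n_win, 0), dtype=np.int64) * step
        mids = table.events.loc[
            table.events["chromosome"] == chrom, "midpoint"
        ].to_numpy()
        mids = np.sort(mids)
        hi = np.searchsorted(mids, starts + window, side="left")
        lo = np.searchsorted(mids, starts, side="left")
        tracks[chrom] = pd.DataFrame(
            {
                "start": starts,
                "mid": starts + window // 2,
                "value": (hi - lo) / n_gametes,
            }
        )
    return LandscapeTrack(tracks, window, step, n_gametes, dict(genome.centromeres))


def inter_co_distances(table: COTable) -> pd.DataFrame:
    """Distances between adjacent crossover midpoints on one chromosome.

    Returns one row per adjacent pair (= per double-CO event) with columns
    ``group``, ``sex``, ``individual``, ``chromosome``, ``distance``.
    """
    rows = []
    for (ind, chrom), sub in table.events.groupby(["individual", "chromosome"], sort=False):
        if len(sub) < 2:
            continue
        mids = sub["midpoint"].to_numpy()
        for d in np.diff(mids):
            rows.append((sub["group"].iloc[0], sub["sex"].iloc[0], ind, chrom, int(d)))
    return pd.DataFrame(
        rows, columns=["group", "sex", "individual", "chromosome", "distance"]
    )


def compare_groups(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test between two count samples.

    Returns (U statistic, p-value); ties are handled by the normal
    approximation with tie correction when exact p-values are unavailable.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("both samples must be non-empty")
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
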