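"""Crossover interference via the coefficient of coincidence (CoC).

Each chromosome is tiled from position 0 by fixed-size intervals (default
2 Mb; the trailing partial interval is dropped) and crossovers are assigned
to intervals by midpoint. For an interval pair (i, j) on one chromosome,

    CoC_ij = observed_ij / (f_i * f_j),

where f_i is the fraction of gametes with at least one crossover in
interval i and observed_ij the fraction with a crossover in both. Under
independent placement CoC = 1 at all distances; interference depresses CoC
for nearby intervals. Pairs with zero expected frequency are reported as
undefined, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .crossovers import COTable
from .errors import ConfigError, ValidationError
from .genome import GenomeMap

__all__ = [
    "CoCConfig",
    "IncidenceMatrix",
    "CoCResult",
    "assign_intervals",
    "coc_pairwise",
    "coc_curve",
]


@dataclass(frozen=True)
class CoCConfig:
    interval_size: int = 2_000_000
    chromosomes: tuple[str, ...] | None = None
    distance_bins: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.interval_size <= 0:
            raise ConfigError("interval_size must be > 0")
        if self.distance_bins is not None and np.any(np.diff(self.distance_bins) <= 0):
            raise ConfigError("distance_bins must be strictly increasing")


@dataclass
class IncidenceMatrix:
    """Gametes x intervals boolean incidence (>= 1 crossover by midpoint)."""

    matrix: np.ndarray  # bool, (n_gametes, n_intervals)
    intervals: pd.DataFrame  # chromosome, start, end, mid
    gametes: list[str]


@dataclass
class CoCResult:
    """Per-pair coincidence ratios.

    ``pairs`` has one row per same-chromosome interval pair with columns
    ``chromosome``, ``i``, ``j`` (interval row indices), ``f_i``, ``f_j``,
    ``observed``, ``expected``, ``coc`` (NaN where undefined), ``defined``,
    ``distance`` (between interval midpoints, bp).
    """

    pairs: pd.DataFrame
    interval_size: int
    n_gametes: int


def assign_intervals(
    table: COTable, genome: GenomeMap, config: CoCConfig | None = None
) -> IncidenceMatrix:
    """Tile chromosomes by fixed intervals and mark per-gamete incidence."""
    config = config or CoCConfig()
    chroms = config.chromosomes or tuple(genome.names)
    records = []
    for chrom in chroms:
        length = genome.length(chrom)
        n = length // config.interval_size  # trailing partial interval dropped
        for k in range(n):
            s = k * config.interval_size
            records.append((chrom, s, s + config.interval_size, s + config.interval_size // 2))
    intervals = pd.DataFrame(records, columns=["chromosome", "start", "end", "mid"])
    gametes = list(table.individuals["individual"])
    gamete_row = {g: r for r, g in enumerate(gametes)}
    matrix = np.zeros((len(gametes), len(intervals)), dtype=bool)
    offsets = {
        chrom: int(intervals.index[intervals["chromosome"] == chrom].min())
        if (intervals["chromosome"] == chrom).any()
        else None
        for chrom in chroms
    }
    n_per_chrom = intervals.groupby("chromosome").size().to_dict()
    ev = table.events[table.events["chromosome"].isin(chroms)]
    for ind, chrom, mid in zip(ev["individual"], ev["chromosome"], ev["midpoint"]):
        k = int(mid) // config.interval_size
        if k >= n_per_chrom.get(chrom, 0):
            continue  # midpoint in the dropped partial interval
        matrix[gamete_row[ind], offsets[chrom] + k] = True
    return IncidenceMatrix(matrix, intervals, gametes)


def coc_pairwise(inc: IncidenceMatrix) -> CoCResult:
    """Observed / expected double-crossover frequency for all interval pairs."""
    n = inc.matrix.shape[0]
    if n < 1:
        raise ValidationError("need at least one gamete")
    rows = []
    for chrom, sub in inc.intervals.groupby("chromosome", sort=False):
        cols = sub.index.to_numpy()
        M = inc.matrix[:, cols].astype(float)
        f = M.mean(axis=0)
        joint = (M.T @ M) / n
        mids = sub["mid"].to_numpy()
        for a in range(len(cols)):
            for b in range(a + 1, len(cols)):
                expected = f[a] * f[b]
                observed = joint[a, b]
                defined = expected > 0
                rows.append(
                    (
                        chrom,
                        int(cols[a]),
                        int(cols[b]),
                        f[a],
                        f[b],
                        observed,
                        expected,
                        observed / expected if defined else np.nan,
                        defined,
                        int(abs(mids[b] - mids[a])),
                    )
                )
    pairs = pd.DataFrame(
        rows,
        columns=[
            "chromosome", "i", "j", "f_i", "f_j",
            "observed", "expected", "coc", "defined", "distance",
        ],
    )
    return CoCResult(pairs, int(np.diff(inc.intervals[["start", "end"]].iloc[0])[0])
                     if len(inc.intervals) else 0, n)


def coc_curve(
    result: CoCResult, bins: Iterable[int] | None = None
) -> pd.DataFrame:
    """Pool pair CoC values by inter-interval distance.

    With ``bins`` (edges, bp) pairs are grouped into half-open distance bins
    [edge_k, edge_{k+1}); without, pairs sharing an exact midpoint distance
    are pooled (tiled intervals make distances exact multiples of the
    interval size). Undefined pairs are excluded; empty bins are omitted.
    Returns columns ``distance`` (bin midpoint or exact distance),
    ``mean_coc`` (average of per-pair ratios), ``pooled_coc`` (ratio of the
    bin's summed observed to summed expected frequency — the estimator is
    far less noisy when individual pairs carry few double crossovers) and
    ``n_pairs``.
    """
    defined = result.pairs[result.pairs["defined"]]
    columns = ["distance", "mean_coc", "pooled_coc", "n_pairs"]
    if defined.empty:
        return pd.DataFrame(columns=columns)

    def _pool(sub: pd.DataFrame) -> tuple[float, float, int]:
        return (
            float(sub["coc"].mean()),
            float(sub["observed"].sum() / sub["expected"].sum()),
            len(sub),
        )

    if bins is None:
        rows = [
            (dist, *_pool(sub)) for dist, sub in defined.groupby("distance")
        ]
        return pd.DataFrame(rows, columns=columns)
    edges = np.asarray(list(bins), dtype=np.int64)
    which = np.digitize(defined["distance"].to_numpy(), edges) - 1
    rows = []
    for k in range(len(edges) - 1):
        sub = defined[which == k]
        if len(sub) == 0:
            continue
        rows.append(((edges[k] + edges[k + 1]) / 2, *_pool(sub)))
    return pd.DataFrame(rows, columns=columns)
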