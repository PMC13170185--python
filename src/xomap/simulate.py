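"""Meiosis simulator: synthetic BC1 populations with known crossover truth.

The model is the diploid-like bivalent case the crossover analysis assumes.
Per bivalent (one per chromosome), crossover positions are placed either by
a Poisson process (no interference) or by a stationary gamma renewal
process (shape ``nu`` >= 1; interference grows with ``nu``, and ``nu = 1``
reduces exactly to the Poisson model). Each crossover involves one
chromatid of each homolog, drawn uniformly and independently (no chromatid
interference). A gamete inherits a single uniformly chosen chromatid, hence
on average half of the bivalent's crossovers — the thinning contract that
links per-meiocyte to per-gamete counts.

Genotypes are emitted for a backcross of the F1 to parent 1: markers on a
parent-2 ancestry segment are heterozygous, markers on a parent-1 segment
homozygous, with configurable per-call genotyping error and missingness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .crossovers import COTable, EVENT_COLUMNS
from .errors import ConfigError
from .genome import GenomeMap, MarkerSet
from .genotypes import GenotypeMatrix, HET, HOM_P1, MISSING

__all__ = [
    "SimulationConfig",
    "MeiocyteTruth",
    "GameteChromosome",
    "GameteTruth",
    "default_genome",
    "simulate_meiocyte",
    "sample_gamete",
    "emit_genotypes",
    "simulate_population",
]

#: Approximate lengths (bp) of the four B. napus A-subgenome chromosomes with
#: the densest informative-marker coverage in a Westar x J9707 cross; the
#: centromere spans are mid-chromosome placeholders used for plotting only.
_DEFAULT_CHROMOSOMES = {
    "A04": 23_000_000,
    "A07": 26_000_000,
    "A08": 22_000_000,
    "A10": 19_000_000,
}
_DEFAULT_CENTROMERES = {
    "A04": (9_000_000, 12_000_000),
    "A07": (10_000_000, 13_000_000),
    "A08": (8_000_000, 11_000_000),
    "A10": (7_000_000, 9_500_000),
}


def default_genome() -> GenomeMap:
    """Four-chromosome genome mirroring the analysed rapeseed chromosomes."""
    return GenomeMap(dict(_DEFAULT_CHROMOSOMES), dict(_DEFAULT_CENTROMERES))


RateMap = Callable[[str], "tuple[np.ndarray, np.ndarray] | None"]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated BC1 population.

    Attributes
    ----------
    genome
        Coordinate frame; one bivalent is simulated per chromosome.
    markers_per_mb
        Expected marker density (markers / Mb), a scalar or per-chromosome
        mapping; marker counts are Poisson with this rate.
    co_model
        ``"poisson"`` (independent placement) or ``"gamma"`` (renewal
        process with interference).
    lambda_c
        Mean crossovers per bivalent per chromosome.
    nu
        Gamma shape (>= 1); interference strength. Ignored by the Poisson
        model apart from the ``nu = 1`` equivalence.
    obligate_co
        Redraw zero-crossover bivalents so every bivalent has >= 1 CO.
    genotyping_error
        Per-call probability of flipping between the two legal BC1 states.
    missing_rate
        Per-call probability of a missing genotype.
    rate_map
        Optional per-chromosome recombination-rate multiplier: a callable
        returning ``(bin_edges, multipliers)`` used to warp positions from
        the uniform genetic axis onto the physical axis; ``None`` means a
        proportional genetic-physical relationship.
    """

    genome: GenomeMap = field(default_factory=default_genome)
    markers_per_mb: float | Mapping[str, float] = 200.0
    co_model: str = "poisson"
    lambda_c: float = 2.0
    nu: float = 1.0
    obligate_co: bool = False
    genotyping_error: float = 0.002
    missing_rate: float = 0.01
    n_individuals: int = 100
    group: str = "WT"
    sex: str = "male"
    seed: int = 0
    rate_map: RateMap | None = None

    def __post_init__(self) -> None:
        if self.co_model not in ("poisson", "gamma"):
            raise ConfigError(f"unknown co_model {self.co_model!r}")
        if self.lambda_c < 0:
            raise ConfigError("lambda_c must be >= 0")
        if self.nu < 1:
            raise ConfigError("nu must be >= 1")
        for name in ("genotyping_error", "missing_rate"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.n_individuals < 0:
            raise ConfigError("n_individuals must be >= 0")
        if self.obligate_co and self.lambda_c == 0:
            raise ConfigError("obligate_co requires lambda_c > 0")

    def density(self, chromosome: str) -> float:
        if isinstance(self.markers_per_mb, Mapping):
            return float(self.markers_per_mb[chromosome])
        return float(self.markers_per_mb)


@dataclass
class MeiocyteTruth:
    """Crossovers of one bivalent (one chromosome of one meiocyte).

    ``chromatids[k] = (i, j)`` records that crossover ``k`` involves
    chromatid ``i`` of homolog 1 (i in {0, 1}) and chromatid ``j`` of
    homolog 2 (j in {2, 3}).
    """

    chromosome: str
    positions: np.ndarray
    chromatids: np.ndarray


@dataclass
class GameteChromosome:
    """One chromosome of a gamete: the inherited chromatid and its ancestry."""

    chromosome: str
    chromatid: int
    start_parent: int  # 0 = parent 1, 1 = parent 2
    co_positions: np.ndarray

    def ancestry_at(self, positions: np.ndarray) -> np.ndarray:
        """Parent of origin (0/1) at each query position."""
        switches = np.searchsorted(self.co_positions, positions, side="right")
        return (self.start_parent + switches) % 2

    def segments(self, length: int) -> list[tuple[int, int, int]]:
        """(start, end, parent) segments tiling [0, length)."""
        bounds = [0, *map(int, self.co_positions), length]
        return [
            (bounds[i], bounds[i + 1], (self.start_parent + i) % 2)
            for i in range(len(bounds) - 1)
        ]


#: A full gamete: one GameteChromosome per chromosome.
GameteTruth = dict[str, GameteChromosome]


def _warp_positions(
    positions: np.ndarray, length: int, rate_map: RateMap | None, chromosome: str
) -> np.ndarray:
    """Map positions from the uniform genetic axis to the physical axis."""
    if rate_map is None:
        return positions
    spec = rate_map(chromosome)
    if spec is None:
        return positions
    edges, weights = (np.asarray(a, dtype=float) for a in spec)
    if len(edges) != len(weights) + 1 or np.any(weights < 0):
        raise ConfigError("rate map must give len(weights)+1 increasing edges, weights >= 0")
    mass = np.concatenate([[0.0], np.cumsum(weights * np.diff(edges))])
    if mass[-1] <= 0:
        raise ConfigError("rate map has zero total mass")
    targets = positions / length * mass[-1]
    return np.interp(targets, mass, edges)


def _draw_positions(
    config: SimulationConfig, chromosome: str, rng: np.random.Generator
) -> np.ndarray:
    length = config.genome.length(chromosome)
    if config.lambda_c == 0:
        return np.empty(0)
    for _ in range(10_000):
        if config.co_model == "poisson":
            k = rng.poisson(config.lambda_c)
            pos = np.sort(rng.uniform(0, length, size=k))
        else:
            # Stationary (equilibrium) gamma renewal process: the first
            # event's delay is U * length-biased gap, where the length-biased
            # gamma(nu, theta) is gamma(nu + 1, theta). This removes edge
            # bias so the expected count is exactly lambda_c.
            theta = length / (config.nu * config.lambda_c)
            points = []
            t = rng.uniform() * rng.gamma(config.nu + 1, theta)
            while t < length:
                points.append(t)
                t += rng.gamma(config.nu, theta)
            pos = np.asarray(points)
        if len(pos) == 0 and config.obligate_co:
            continue
        pos = np.floor(_warp_positions(pos, length, config.rate_map, chromosome))
        # two exchanges within 1 bp are physically meaningless and would
        # break event bracketing; redraw the (vanishingly rare) collision
        if len(pos) > 1 and np.min(np.diff(pos)) < 2:
            continue
        return pos.astype(np.int64)
    raise ConfigError("failed to draw an admissible crossover configuration")


def simulate_meiocyte(
    config: SimulationConfig, chromosome: str, rng: np.random.Generator
) -> MeiocyteTruth:
    """Simulate one bivalent's crossovers with chromatid assignments."""
    positions = _draw_positions(config, chromosome, rng)
    k = len(positions)
    chromatids = np.column_stack(
        [rng.integers(0, 2, size=k), rng.integers(2, 4, size=k)]
    ).astype(np.int8)
    return MeiocyteTruth(chromosome, positions, chromatids)


def sample_gamete(
    meiocyte: Mapping[str, MeiocyteTruth], rng: np.random.Generator
) -> GameteTruth:
    """Draw one gamete: a uniformly chosen chromatid per chromosome.

    The gamete inherits exactly the crossovers whose chromatid pair includes
    the chosen chromatid; ancestry alternates at each inherited crossover and
    starts from the chosen chromatid's homolog.
    """
    gamete: GameteTruth = {}
    for chrom, biv in meiocyte.items():
        chromatid = int(rng.integers(0, 4))
        hit = (biv.chromatids == chromatid).any(axis=1) if len(biv.positions) else np.zeros(0, bool)
        gamete[chrom] = GameteChromosome(
            chromosome=chrom,
            chromatid=chromatid,
            start_parent=0 if chromatid < 2 else 1,
            co_positions=biv.positions[hit],
        )
    return gamete


def emit_genotypes(
    gamete: GameteTruth,
    markers: MarkerSet,
    error: float,
    missing: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Genotype one gamete's backcross progeny at the marker set.

    Markers on parent-2 ancestry are HET, on parent-1 ancestry HOM_P1; each
    call is then independently dropped to MISSING with probability
    ``missing``, otherwise flipped between the two legal states with
    probability ``error``.
    """
    row = np.empty(len(markers), dtype=np.int8)
    for chrom in markers.chromosomes:
        idx = markers.chrom_index(chrom)
        if chrom not in gamete:
            row[idx] = MISSING
            continue
        anc = gamete[chrom].ancestry_at(markers.positions(chrom))
        row[idx] = np.where(anc == 1, HET, HOM_P1).astype(np.int8)
    n = len(row)
    miss_mask = rng.uniform(size=n) < missing
    err_mask = (rng.uniform(size=n) < error) & ~miss_mask
    row[err_mask] = 1 - row[err_mask]  # HOM_P1 <-> HET
    row[miss_mask] = MISSING
    return row


def draw_markers(config: SimulationConfig, rng: np.random.Generator) -> MarkerSet:
    """Draw marker positions once for a population (Poisson count, uniform)."""
    frames = []
    for chrom, length in config.genome.chromosomes.items():
        n = rng.poisson(config.density(chrom) * length / 1e6)
        pos = np.unique(rng.integers(0, length, size=n))
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "pos": pos, "allele_p1": "A", "allele_p2": "T"}
            )
        )
    table = pd.concat(frames, ignore_index=True)
    return MarkerSet(table, genome=config.genome)


def simulate_population(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, COTable, list[GameteTruth]]:
    """Simulate a BC1 population: genotypes, true-CO table, gamete truths.

    Fully reproducible from ``config.seed``. The truth table brackets each
    true crossover point p with bounds (p - 1, p + 1) so its midpoint is the
    exact position.
    """
    rng = np.random.default_rng(config.seed)
    markers = draw_markers(config, rng)
    ids = [f"{config.group}_{config.sex}_{i + 1:04d}" for i in range(config.n_individuals)]
    individuals = pd.DataFrame(
        {"individual": ids, "group": config.group, "sex": config.sex}
    )
    calls = np.empty((config.n_individuals, len(markers)), dtype=np.int8)
    gametes: list[GameteTruth] = []
    records: list[tuple] = []
    for i, ind in enumerate(ids):
        meiocyte = {
            chrom: simulate_meiocyte(config, chrom, rng)
            for chrom in config.genome.names
        }
        gamete = sample_gamete(meiocyte, rng)
        gametes.append(gamete)
        calls[i] = emit_genotypes(
            gamete, markers, config.genotyping_error, config.missing_rate, rng
        )
        for chrom, gc in gamete.items():
            anc = gc.start_parent
            for p in gc.co_positions:
                p = int(p)
                records.append(
                    (
                        ind,
                        config.group,
                        config.sex,
                        chrom,
                        p - 1,
                        p + 1,
                        p,
                        HOM_P1 if anc == 0 else HET,
                        HET if anc == 0 else HOM_P1,
                    )
                )
                anc = 1 - anc
    truth = COTable(pd.DataFrame(records, columns=EVENT_COLUMNS), individuals)
    matrix = GenotypeMatrix(individuals, calls, markers)
    return matrix, truth, gametes
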