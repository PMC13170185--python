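"""Crossover events and tables — the pipeline's central exchange format.

A crossover is localised between the last informative marker of the
preceding genotype segment (``left_bound``) and the first informative
marker of the following segment (``right_bound``); downstream statistics
use the integer ``midpoint``. Internal coordinates are 0-based; the TSV
representation is 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .genotypes import HET, HOM_P1

__all__ = ["COEvent", "COTable", "read_co_table", "write_co_table"]

EVENT_COLUMNS = [
    "individual",
    "group",
    "sex",
    "chromosome",
    "left_bound",
    "right_bound",
    "midpoint",
    "left_state",
    "right_state",
]


@dataclass(frozen=True)
class COEvent:
    """One crossover in one gamete."""

    individual: str
    chromosome: str
    left_bound: int
    right_bound: int
    midpoint: int
    left_state: int = HOM_P1
    right_state: int = HET
    group: str = "WT"
    sex: str = "male"

    def __post_init__(self) -> None:
        if not (self.left_bound < self.midpoint < self.right_bound):
            raise ValidationError(
                f"bounds must satisfy left < midpoint < right, got "
                f"({self.left_bound}, {self.midpoint}, {self.right_bound})"
            )
        if self.midpoint != (self.left_bound + self.right_bound) // 2:
            raise ValidationError("midpoint is not the floor of the bound mean")
        if self.left_state == self.right_state:
            raise ValidationError("flanking states must differ")


class COTable:
    """A population's crossover events plus its full individual roster.

    The roster matters because gametes without any crossover still count in
    per-gamete means and in coincidence denominators.
    """

    def __init__(self, events: pd.DataFrame, individuals: pd.DataFrame):
        if events is None or len(events) == 0:
            events = pd.DataFrame(columns=EVENT_COLUMNS)
        missing = [c for c in EVENT_COLUMNS if c not in events.columns]
        if missing:
            raise ValidationError(f"CO table missing columns {missing}")
        events = events.loc[:, EVENT_COLUMNS].reset_index(drop=True)
        for col in ("left_bound", "right_bound", "midpoint"):
            events[col] = events[col].astype(np.int64)
        for col in ("left_state", "right_state"):
            events[col] = events[col].astype(np.int8)
        for col in ("individual", "group", "sex"):
            if col not in individuals.columns:
                raise ValidationError(f"individuals table missing column {col!r}")
        if individuals["individual"].duplicated().any():
            raise ValidationError("duplicate individual identifiers")
        known = set(individuals["individual"])
        unknown = set(events["individual"]) - known
        if unknown:
            raise ValidationError(f"events reference unknown individuals {sorted(unknown)}")
        events = events.sort_values(
            ["individual", "chromosome", "midpoint"], kind="stable"
        ).reset_index(drop=True)
        bad = ~(
            (events["left_bound"] < events["midpoint"])
            & (events["midpoint"] < events["right_bound"])
        )
        if bad.any():
            raise ValidationError(f"{int(bad.sum())} events violate left < midpoint < right")
        # no two events of one individual/chromosome may overlap
        for (_ind, _chrom), sub in events.groupby(["individual", "chromosome"], sort=False):
            if len(sub) > 1 and np.any(
                sub["left_bound"].to_numpy()[1:] < sub["right_bound"].to_numpy()[:-1]
            ):
                raise ValidationError(
                    f"overlapping events for individual {_ind!r} on {_chrom}"
                )
        self.events = events
        self.individuals = individuals.loc[:, ["individual", "group", "sex"]].reset_index(
            drop=True
        )

    @classmethod
    def from_events(cls, events: Iterable[COEvent], individuals: pd.DataFrame) -> "COTable":
        rows = [
            (
                e.individual,
                e.group,
                e.sex,
                e.chromosome,
                e.left_bound,
                e.right_bound,
                e.midpoint,
                e.left_state,
                e.right_state,
            )
            for e in events
        ]
        frame = pd.DataFrame(rows, columns=EVENT_COLUMNS)
        return cls(frame, individuals)

    def __len__(self) -> int:
        return len(self.events)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, COTable)
            and self.events.equals(other.events)
            and self.individuals.equals(other.individuals)
        )

    @property
    def group_sizes(self) -> pd.Series:
        return self.individuals.groupby(["group", "sex"]).size()

    def subset(self, group: str | None = None, sex: str | None = None) -> "COTable":
        ind = self.individuals
        if group is not None:
            ind = ind[ind["group"] == group]
        if sex is not None:
            ind = ind[ind["sex"] == sex]
        ev = self.events[self.events["individual"].isin(ind["individual"])]
        return COTable(ev.copy(), ind.copy())

    def restrict_chromosomes(self, chromosomes: Iterable[str]) -> "COTable":
        keep = set(chromosomes)
        ev = self.events[self.events["chromosome"].isin(keep)]
        return COTable(ev.copy(), self.individuals.copy())


def write_co_table(table: COTable, path: str, individuals_path: str | None = None) -> None:
    """Write a CO table as TSV with 1-based inclusive coordinates.

    If ``individuals_path`` is given, the full roster (including zero-CO
    individuals) is written alongside, which makes the round trip lossless.
    """
    out = table.events.copy()
    for col in ("left_bound", "right_bound", "midpoint"):
        out[col] = out[col] + 1
    out.to_csv(path, sep="\t", index=False)
    if individuals_path is not None:
        table.individuals.to_csv(individuals_path, sep="\t", index=False)


def read_co_table(path: str, individuals_path: str | None = None) -> COTable:
    """Read a CO table written by :func:`write_co_table`.

    Without a roster file the individuals are reconstructed from the events,
    which loses gametes that had no crossover.
    """
    events = pd.read_csv(path, sep="\t", dtype={"individual": str, "chromosome": str})
    if list(events.columns) != EVENT_COLUMNS:
        raise FormatError(f"{path}: unexpected CO table columns {list(events.columns)}")
    for col in ("left_bound", "right_bound", "midpoint"):
        events[col] = events[col].astype(np.int64) - 1
    if individuals_path is not None:
        individuals = pd.read_csv(individuals_path, sep="\t", dtype=str)
    else:
        individuals = (
            events.loc[:, ["individual", "group", "sex"]]
            .drop_duplicates("individual")
            .reset_index(drop=True)
        )
    return COTable(events, individuals)
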