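"""BC1 genotype matrices and their tab-separated representation.

A BC1 individual (F1 backcrossed to parent 1) can only be homozygous for
the recurrent parent's allele or heterozygous at an informative marker, so
calls take three states: ``HOM_P1`` (0), ``HET`` (1) and ``MISSING`` (-1,
serialized as ``NA``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .genome import MarkerSet

__all__ = [
    "HOM_P1",
    "HET",
    "MISSING",
    "GenotypeMatrix",
    "read_genotype_table",
    "write_genotype_table",
]

HOM_P1: int = 0
HET: int = 1
MISSING: int = -1

_TOKEN_TO_CALL = {"0": HOM_P1, "1": HET, "NA": MISSING}
_CALL_TO_TOKEN = {HOM_P1: "0", HET: "1", MISSING: "NA"}

_META_COLUMNS = ("individual", "group", "sex")


@dataclass
class GenotypeMatrix:
    """Individuals x markers BC1 genotype calls.

    Attributes
    ----------
    individuals
        DataFrame with columns ``individual``, ``group`` (e.g. WT/mutant)
        and ``sex``; one row per individual, same order as ``calls`` rows.
    calls
        int8 array of shape (n individuals, n markers) with values in
        {HOM_P1, HET, MISSING}; columns ordered as ``markers``.
    markers
        The marker set the columns refer to.
    """

    individuals: pd.DataFrame
    calls: np.ndarray
    markers: MarkerSet

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValidationError("calls must be a 2-D array")
        if self.calls.shape[0] != len(self.individuals):
            raise ValidationError("row count does not match individual count")
        if self.calls.shape[1] != len(self.markers):
            raise ValidationError(
                f"column count {self.calls.shape[1]} does not match "
                f"marker count {len(self.markers)}"
            )
        legal = np.isin(self.calls, (HOM_P1, HET, MISSING))
        if not legal.all():
            bad = np.argwhere(~legal)[0]
            raise ValidationError(
                f"illegal call state {self.calls[tuple(bad)]} at row {bad[0]}, column {bad[1]}"
            )
        for col in _META_COLUMNS:
            if col not in self.individuals.columns:
                raise ValidationError(f"individuals table missing column {col!r}")
        if self.individuals["individual"].duplicated().any():
            raise ValidationError("duplicate individual identifiers")
        self.individuals = self.individuals.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    def row(self, individual: str) -> np.ndarray:
        idx = self.individuals.index[self.individuals["individual"] == individual]
        if len(idx) != 1:
            raise ValidationError(f"unknown individual {individual!r}")
        return self.calls[idx[0]]


def read_genotype_table(path: str, markers: MarkerSet) -> GenotypeMatrix:
    """Read a genotype matrix TSV.

    Layout: columns ``individual``, ``group``, ``sex``, then one column per
    marker named ``chrom:pos`` (1-based), in marker-set order; cells are
    ``0`` (homozygous recurrent parent), ``1`` (heterozygous) or ``NA``.
    """
    try:
        table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty genotype file") from None
    for col in _META_COLUMNS:
        if col not in table.columns:
            raise FormatError(f"{path}: missing metadata column {col!r}")
    marker_cols = [c for c in table.columns if c not in _META_COLUMNS]
    expected = markers.ids()
    if marker_cols != expected:
        offending = next(
            (c for c, e in zip(marker_cols, expected) if c != e),
            marker_cols[len(expected)] if len(marker_cols) > len(expected) else
            (expected[len(marker_cols)] if len(marker_cols) < len(expected) else "?"),
        )
        raise FormatError(
            f"{path}: marker columns do not match the marker set "
            f"(first mismatch at column {offending!r})"
        )
    calls = np.empty((len(table), len(expected)), dtype=np.int8)
    for j, col in enumerate(marker_cols):
        for i, token in enumerate(table[col]):
            try:
                calls[i, j] = _TOKEN_TO_CALL[token]
            except KeyError:
                raise FormatError(
                    f"{path}: unknown genotype token {token!r} at row {i + 1}, "
                    f"column {col!r}"
                ) from None
    individuals = table.loc[:, list(_META_COLUMNS)].copy()
    return GenotypeMatrix(individuals, calls, markers)


def write_genotype_table(matrix: GenotypeMatrix, path: str) -> None:
    """Write a genotype matrix in the TSV dialect of :func:`read_genotype_table`."""
    tokens = pd.DataFrame(
        np.vectorize(_CALL_TO_TOKEN.get)(matrix.calls) if matrix.calls.size else
        np.empty((matrix.n_individuals, 0), dtype=object),
        columns=matrix.markers.ids(),
    )
    out = pd.concat([matrix.individuals.reset_index(drop=True), tokens], axis=1)
    out.to_csv(path, sep="\t", index=False)
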