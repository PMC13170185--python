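"""Genome coordinate frame and marker sets.

Coordinates are 0-based half-open everywhere in memory; only serialized
tables use 1-based inclusive positions. BED input is 0-based half-open
per its standard, so centromere intervals pass through unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, ValidationError

__all__ = [
    "GenomeMap",
    "MarkerSet",
    "select_informative_markers",
    "read_centromeres_bed",
    "read_genome_yaml",
    "write_genome_yaml",
    "read_markers_tsv",
    "write_markers_tsv",
    "read_parent_genotypes_vcf",
]


@dataclass(frozen=True)
class GenomeMap:
    """Ordered chromosomes with lengths and optional centromere intervals.

    Parameters
    ----------
    chromosomes
        Mapping of chromosome name to length in base pairs, in karyotype
        order.
    centromeres
        Per-chromosome (start, end) interval, 0-based half-open. Optional;
        chromosomes without an entry simply have no centromere annotation.
    """

    chromosomes: dict[str, int]
    centromeres: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValidationError("genome must contain at least one chromosome")
        for name, length in self.chromosomes.items():
            if int(length) <= 0:
                raise ValidationError(f"chromosome {name!r} has non-positive length {length}")
        for name, (start, end) in self.centromeres.items():
            if name not in self.chromosomes:
                raise ValidationError(f"centromere on unknown chromosome {name!r}")
            if not (0 <= start < end <= self.chromosomes[name]):
                raise ValidationError(
                    f"centromere ({start}, {end}) outside chromosome {name!r} "
                    f"of length {self.chromosomes[name]}"
                )

    @property
    def names(self) -> list[str]:
        return list(self.chromosomes)

    def length(self, chromosome: str) -> int:
        try:
            return self.chromosomes[chromosome]
        except KeyError:
            raise ValidationError(f"unknown chromosome {chromosome!r}") from None

    def with_centromeres(self, centromeres: Mapping[str, tuple[int, int]]) -> "GenomeMap":
        merged = dict(self.centromeres)
        merged.update({k: (int(v[0]), int(v[1])) for k, v in centromeres.items()})
        return GenomeMap(dict(self.chromosomes), merged)


class MarkerSet:
    """Informative markers: chromosome, position, and the two parental alleles.

    Wraps a DataFrame with columns ``chrom``, ``pos``, ``allele_p1``,
    ``allele_p2``. Positions are 0-based and strictly increasing within each
    chromosome; the two parental alleles differ at every marker.
    """

    COLUMNS = ("chrom", "pos", "allele_p1", "allele_p2")

    def __init__(self, table: pd.DataFrame, genome: GenomeMap | None = None):
        missing = [c for c in self.COLUMNS if c not in table.columns]
        if missing:
            raise ValidationError(f"marker table missing columns {missing}")
        table = table.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        table["pos"] = table["pos"].astype(np.int64)
        # re-sort by position within each chromosome (chromosome blocks keep
        # their first-appearance order); callers can realign per-marker data
        # through `input_order`
        chrom_rank = {c: i for i, c in enumerate(dict.fromkeys(table["chrom"]))}
        order = np.lexsort(
            (table["pos"].to_numpy(), table["chrom"].map(chrom_rank).to_numpy())
        )
        self.input_order = order
        table = table.iloc[order].reset_index(drop=True)
        for chrom, sub in table.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValidationError(f"duplicate marker positions on {chrom}")
            if genome is not None:
                length = genome.length(str(chrom))
                if pos[0] < 0 or pos[-1] >= length:
                    raise ValidationError(f"marker position outside chromosome {chrom}")
        same = table["allele_p1"] == table["allele_p2"]
        if same.any():
            raise ValidationError("parental alleles identical at some markers")
        self.table = table

    def __len__(self) -> int:
        return len(self.table)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, MarkerSet) and self.table.equals(other.table)

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.table["chrom"]))

    def positions(self, chromosome: str) -> np.ndarray:
        return self.table.loc[self.table["chrom"] == chromosome, "pos"].to_numpy()

    def chrom_index(self, chromosome: str) -> np.ndarray:
        """Column indices of this chromosome's markers in genotype matrices."""
        return np.flatnonzero((self.table["chrom"] == chromosome).to_numpy())

    def ids(self) -> list[str]:
        """Marker identifiers ``chrom:pos1`` with 1-based positions."""
        return [f"{c}:{p + 1}" for c, p in zip(self.table["chrom"], self.table["pos"])]


def _parse_diploid(call: str | None) -> tuple[str, str] | None:
    if call is None:
        return None
    call = str(call).strip()
    if not call or call in {".", "./.", ".|."}:
        return None
    for sep in ("/", "|"):
        if sep in call:
            a, b = call.split(sep, 1)
            if a == "." or b == ".":
                return None
            return a, b
    if len(call) == 2:  # compact form, e.g. "AA"
        return call[0], call[1]
    raise FormatError(f"cannot parse diploid genotype {call!r}")


def select_informative_markers(
    sites: pd.DataFrame,
    parent1_calls: Sequence[str],
    parent2_calls: Sequence[str],
    genome: GenomeMap | None = None,
) -> MarkerSet:
    """Select markers that are polymorphic and homozygous between the parents.

    A site is retained exactly when both parents are homozygous and their
    alleles differ; sites where either parent is heterozygous, missing, or
    both parents carry the same homozygous allele are dropped. Chromosomes
    that end up with no retained marker are reported with a warning.

    Parameters
    ----------
    sites
        DataFrame with columns ``chrom`` and ``pos`` (0-based), one row per
        genotyped site, positions strictly increasing per chromosome.
    parent1_calls, parent2_calls
        Diploid genotype strings per site (``"A/A"``, ``"A|T"``, ``"./."``).
    """
    if not (len(sites) == len(parent1_calls) == len(parent2_calls)):
        raise ValidationError("sites and parental call vectors differ in length")
    keep = []
    a1l: list[str] = []
    a2l: list[str] = []
    for i, (c1, c2) in enumerate(zip(parent1_calls, parent2_calls)):
        g1 = _parse_diploid(c1)
        g2 = _parse_diploid(c2)
        if g1 is None or g2 is None:
            continue
        if g1[0] != g1[1] or g2[0] != g2[1]:
            continue
        if g1[0] == g2[0]:
            continue
        keep.append(i)
        a1l.append(g1[0])
        a2l.append(g2[0])
    out = sites.iloc[keep].reset_index(drop=True).copy()
    out["allele_p1"] = a1l
    out["allele_p2"] = a2l
    retained_chroms = set(out["chrom"])
    for chrom in dict.fromkeys(sites["chrom"]):
        if chrom not in retained_chroms:
            warnings.warn(f"no informative markers retained on chromosome {chrom}")
    return MarkerSet(out, genome=genome)


def read_centromeres_bed(path: str, genome: GenomeMap) -> GenomeMap:
    """Merge centromere intervals from a 3-column BED file into a genome map.

    Multiple records on one chromosome are merged to their spanning interval.
    Records on unknown chromosomes or exceeding the chromosome length raise a
    validation error.
    """
    spans: dict[str, tuple[int, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if chrom not in genome.chromosomes:
                raise ValidationError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if not (0 <= start < end <= genome.length(chrom)):
                raise ValidationError(
                    f"{path}:{lineno}: interval ({start}, {end}) outside chromosome {chrom}"
                )
            if chrom in spans:
                s, e = spans[chrom]
                spans[chrom] = (min(s, start), max(e, end))
            else:
                spans[chrom] = (start, end)
    return genome.with_centromeres(spans)


def read_genome_yaml(path: str) -> GenomeMap:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    chroms = {str(e["name"]): int(e["length"]) for e in doc["chromosomes"]}
    cents = {
        str(k): (int(v[0]), int(v[1])) for k, v in (doc.get("centromeres") or {}).items()
    }
    return GenomeMap(chroms, cents)


def write_genome_yaml(genome: GenomeMap, path: str) -> None:
    doc = {
        "chromosomes": [
            {"name": n, "length": int(l)} for n, l in genome.chromosomes.items()
        ],
        "centromeres": {n: [int(s), int(e)] for n, (s, e) in genome.centromeres.items()},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_markers_tsv(path: str, genome: GenomeMap | None = None) -> MarkerSet:
    """Read a marker table (chrom, pos, allele_p1, allele_p2; 1-based pos)."""
    table = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if table.empty:
        raise FormatError(f"{path}: empty marker table")
    table["pos"] = table["pos"].astype(np.int64) - 1
    return MarkerSet(table, genome=genome)


def write_markers_tsv(markers: MarkerSet, path: str) -> None:
    out = markers.table.copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", index=False)


def read_parent_genotypes_vcf(
    path: str, parent1: str, parent2: str, genome: GenomeMap | None = None
) -> MarkerSet:
    """Extract informative markers from a VCF with the two parent samples.

    Only biallelic SNP records are considered; the parental-homozygosity rule
    of :func:`select_informative_markers` is then applied.
    """
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(path)
    samples = list(vcf.samples)
    for s in (parent1, parent2):
        if s not in samples:
            raise ValidationError(f"sample {s!r} not in VCF {path}")
    i1, i2 = samples.index(parent1), samples.index(parent2)
    rows = []
    calls1 = []
    calls2 = []
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            continue
        alleles = [v.REF, v.ALT[0]]

        def fmt(idx: int) -> str:
            g = v.genotypes[idx]
            if g[0] < 0 or g[1] < 0:
                return "./."
            return f"{alleles[g[0]]}/{alleles[g[1]]}"

        rows.append((v.CHROM, v.POS - 1))
        calls1.append(fmt(i1))
        calls2.append(fmt(i2))
    sites = pd.DataFrame(rows, columns=["chrom", "pos"])
    return select_informative_markers(sites, calls1, calls2, genome=genome)
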