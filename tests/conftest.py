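import numpy as np
import pandas as pd
import pytest

from xomap import GenomeMap, MarkerSet


@pytest.fixture
def toy_genome() -> GenomeMap:
    """One 100-kb chromosome — enough for hand-traced window examples."""
    return GenomeMap({"A01": 100_000})


@pytest.fixture
def two_chrom_genome() -> GenomeMap:
    return GenomeMap(
        {"A01": 10_000_000, "A02": 8_000_000},
        {"A01": (4_000_000, 5_000_000)},
    )


def make_markers(positions_by_chrom: dict[str, list[int]]) -> MarkerSet:
    frames = [
        pd.DataFrame(
            {"chrom": chrom, "pos": pos, "allele_p1": "A", "allele_p2": "T"}
        )
        for chrom, pos in positions_by_chrom.items()
    ]
    return MarkerSet(pd.concat(frames, ignore_index=True))


@pytest.fixture
def individuals_frame():
    def _make(ids, group="WT", sex="male"):
        return pd.DataFrame({"individual": list(ids), "group": group, "sex": sex})

    return _make
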