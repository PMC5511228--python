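import numpy as np
import pandas as pd
import pytest

from insularis.core_data import (
    IncidenceMatrix,
    IslandTable,
    OccurrenceTable,
    SpeciesTraits,
)


@pytest.fixture
def tiny_islands():
    return IslandTable(table=pd.DataFrame({
        "island": ["big", "mid", "small"],
        "area_km2": [100.0, 10.0, 0.1],
    }))


@pytest.fixture
def tiny_traits():
    return SpeciesTraits(table=pd.DataFrame({
        "species": ["sp1", "sp2", "sp3", "sp4"],
        "origin": ["native", "native", "alien", "native"],
        "functional_type": ["AH", "PH", "W", "W"],
    }))


@pytest.fixture
def tiny_occurrences():
    rows = [
        ("sp1", "big", "P1"), ("sp1", "mid", "P1"), ("sp1", "small", "P1"),
        ("sp2", "big", "P1"), ("sp2", "mid", "P1"),
        ("sp3", "big", "P1"),
        ("sp1", "big", "P2"), ("sp1", "mid", "P2"),
        ("sp3", "big", "P2"), ("sp3", "mid", "P2"),
        ("sp4", "big", "P2"),
    ]
    return OccurrenceTable(records=pd.DataFrame(rows, columns=["species", "island", "period"]))


def make_matrix(cells, islands=None, species=None, period="P1", group="total"):
    """Wrap a 0/1 array-like into an IncidenceMatrix with generated labels."""
    arr = np.asarray(cells, dtype=np.int8)
    n_sp, n_is = arr.shape
    species = species or [f"s{i}" for i in range(n_sp)]
    islands = islands or [f"i{j}" for j in range(n_is)]
    return IncidenceMatrix(data=pd.DataFrame(arr, index=species, columns=islands),
                           period_id=period, group_label=group)
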