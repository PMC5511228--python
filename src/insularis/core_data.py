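"""Data model and I/O for archipelago occurrence data.

The analysis operates on three plain-text input tables:

* **occurrences** — long-format records, one row per (species, island,
  period): a species was recorded at least once on that island during
  that census period.  Duplicates are collapsed on load.
* **islands** — one row per island with its area in km².
* **traits** — one row per species with its origin (``native``/``alien``)
  and functional type (``AH`` annual herbaceous, ``PH`` perennial
  herbaceous, ``W`` woody).

From these, :func:`build_incidence` assembles the binary species-by-island
presence/absence matrix for one period and (optionally) one species group,
which is the unit every downstream statistic consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    EmptyGroupError,
    EmptyInputError,
    FormatError,
    IntegrityError,
)

logger = logging.getLogger(__name__)

ORIGINS = ("native", "alien")
FUNCTIONAL_TYPES = ("AH", "PH", "W")

OCC_COLUMNS = ("species", "island", "period")
ISLAND_COLUMNS = ("island", "area_km2")
TRAIT_COLUMNS = ("species", "origin", "functional_type")


@dataclass(frozen=True)
class OccurrenceTable:
    """Deduplicated long-format occurrence records.

    ``records`` has exactly the columns ``species``, ``island``, ``period``
    (strings); one row is the record of a single species on a single island
    in one period.
    """

    records: pd.DataFrame
    n_raw: int = field(default=-1, compare=False)

    def __post_init__(self):
        missing = set(OCC_COLUMNS) - set(self.records.columns)
        if missing:
            raise FormatError(f"occurrence table missing columns: {sorted(missing)}")
        if self.records.duplicated(list(OCC_COLUMNS)).any():
            raise FormatError("occurrence table contains duplicate (species, island, period) rows")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def periods(self) -> list[str]:
        return sorted(self.records["period"].unique())

    @property
    def species(self) -> list[str]:
        return sorted(self.records["species"].unique())

    @property
    def islands(self) -> list[str]:
        return sorted(self.records["island"].unique())

    def species_set(self, period: str, islands: list[str] | None = None) -> set[str]:
        """Species recorded in `period`, optionally restricted to some islands."""
        sub = self.records[self.records["period"] == period]
        if islands is not None:
            sub = sub[sub["island"].isin(islands)]
        return set(sub["species"])

    def write(self, path) -> None:
        self.records.to_csv(path, index=False)


@dataclass(frozen=True)
class IslandTable:
    """Island attribute table: unique ids and strictly positive areas (km²)."""

    table: pd.DataFrame

    def __post_init__(self):
        missing = set(ISLAND_COLUMNS) - set(self.table.columns)
        if missing:
            raise FormatError(f"island table missing columns: {sorted(missing)}")
        if self.table["island"].duplicated().any():
            raise FormatError("island ids are not unique")
        if not (self.table["area_km2"] > 0).all():
            raise FormatError("island areas must be strictly positive")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def island_ids(self) -> list[str]:
        return list(self.table["island"])

    @property
    def areas(self) -> pd.Series:
        return self.table.set_index("island")["area_km2"]

    def write(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass(frozen=True)
class SpeciesTraits:
    """Species attributes: origin in {native, alien}, functional type in {AH, PH, W}."""

    table: pd.DataFrame

    def __post_init__(self):
        missing = set(TRAIT_COLUMNS) - set(self.table.columns)
        if missing:
            raise FormatError(f"trait table missing columns: {sorted(missing)}")
        if self.table["species"].duplicated().any():
            raise FormatError("species appear more than once in the trait table")
        bad_origin = set(self.table["origin"]) - set(ORIGINS)
        if bad_origin:
            raise FormatError(f"unknown origin values: {sorted(bad_origin)}")
        bad_ft = set(self.table["functional_type"]) - set(FUNCTIONAL_TYPES)
        if bad_ft:
            raise FormatError(f"unknown functional types: {sorted(bad_ft)}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def species_ids(self) -> list[str]:
        return list(self.table["species"])

    def select(self, origin: str | None = None, functional_type: str | None = None) -> set[str]:
        """Species ids matching the given origin / functional-type filter."""
        t = self.table
        if origin is not None:
            if origin not in ORIGINS:
                raise FormatError(f"unknown origin filter {origin!r}")
            t = t[t["origin"] == origin]
        if functional_type is not None:
            if functional_type not in FUNCTIONAL_TYPES:
                raise FormatError(f"unknown functional-type filter {functional_type!r}")
            t = t[t["functional_type"] == functional_type]
        return set(t["species"])

    def write(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass(frozen=True)
class IncidenceMatrix:
    """Binary species-by-island matrix for one period and one species group.

    ``data`` is a 0/1 DataFrame with species ids as index and island ids as
    columns (island order taken from the IslandTable).  Only species with at
    least one occurrence in the selected period/group are rows.
    """

    data: pd.DataFrame
    period_id: str
    group_label: str = "total"

    def __post_init__(self):
        values = self.data.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise FormatError("incidence matrix cells must be 0 or 1")

    @property
    def species_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def island_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_species(self) -> int:
        return self.data.shape[0]

    @property
    def n_islands(self) -> int:
        return self.data.shape[1]

    @property
    def n_occurrences(self) -> int:
        return int(self.data.to_numpy().sum())

    @property
    def fill(self) -> float:
        """Proportion of 1s in the matrix, in (0, 1]."""
        return self.n_occurrences / (self.n_species * self.n_islands)

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=np.int8)

    def species_on(self, island_id: str) -> set[str]:
        col = self.data[island_id]
        return set(col.index[col == 1])


def _read_delimited(path, delimiter: str | None) -> pd.DataFrame:
    """Read a delimited text file; autodetect comma vs tab when not given."""
    import csv

    try:
        df = pd.read_csv(path, sep=delimiter, engine="python" if delimiter is None else "c",
                         dtype=str, skipinitialspace=True)
    except (pd.errors.EmptyDataError, csv.Error):
        raise EmptyInputError(f"{path}: file is empty or has no parsable header")
    if df.empty:
        raise EmptyInputError(f"{path}: no data rows")
    df.columns = [c.strip().lower() for c in df.columns]
    return df


def load_occurrences(path, delimiter: str | None = None) -> OccurrenceTable:
    """Load and deduplicate long-format occurrence records.

    Columns are resolved by (case-insensitive) name ``species, island,
    period``; a headerless three-column file is rejected.  The raw and
    deduplicated record counts are logged.
    """
    df = _read_delimited(path, delimiter)
    missing = set(OCC_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing occurrence columns {sorted(missing)}")
    df = df[list(OCC_COLUMNS)]
    n_raw = len(df)
    df = df.drop_duplicates().reset_index(drop=True)
    logger.info("loaded %d raw occurrence rows, %d after collapsing duplicates", n_raw, len(df))
    return OccurrenceTable(records=df, n_raw=n_raw)


def load_islands(path, delimiter: str | None = None) -> IslandTable:
    """Load the island attribute table (columns ``island, area_km2``)."""
    df = _read_delimited(path, delimiter)
    missing = set(ISLAND_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing island columns {sorted(missing)}")
    df = df[list(ISLAND_COLUMNS)].copy()
    df["area_km2"] = pd.to_numeric(df["area_km2"], errors="raise")
    return IslandTable(table=df.reset_index(drop=True))


def load_traits(path, delimiter: str | None = None) -> SpeciesTraits:
    """Load the species trait table (columns ``species, origin, functional_type``)."""
    df = _read_delimited(path, delimiter)
    missing = set(TRAIT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing trait columns {sorted(missing)}")
    return SpeciesTraits(table=df[list(TRAIT_COLUMNS)].reset_index(drop=True))


def validate_dataset(occ: OccurrenceTable, islands: IslandTable,
                     traits: SpeciesTraits, strict: bool = True) -> dict:
    """Cross-check referential integrity between the three tables.

    In strict mode (the default), any occurrence referring to an unknown
    island or species raises :class:`IntegrityError`; in lenient mode the
    offenders are returned (and logged) so the caller can decide.
    """
    unknown_islands = sorted(set(occ.records["island"]) - set(islands.island_ids))
    unknown_species = sorted(set(occ.records["species"]) - set(traits.species_ids))
    if strict and (unknown_islands or unknown_species):
        raise IntegrityError(
            f"unknown island ids {unknown_islands[:5]} / species ids {unknown_species[:5]} "
            f"({len(unknown_islands)} islands, {len(unknown_species)} species total)")
    if unknown_islands or unknown_species:
        logger.warning("lenient mode: %d unknown islands, %d unknown species",
                       len(unknown_islands), len(unknown_species))
    return {"unknown_islands": unknown_islands, "unknown_species": unknown_species}


def build_incidence(occ: OccurrenceTable, islands: IslandTable, period: str,
                    traits: SpeciesTraits | None = None,
                    origin: str | None = None,
                    functional_type: str | None = None) -> IncidenceMatrix:
    """Build the binary species-by-island matrix for one period and group.

    Rows are the species matching the origin/functional-type filter that have
    at least one record in `period` (species absent from the period are
    excluded); columns follow the island order of `islands`.  Duplicate
    occurrence records cannot inflate cells (the table is deduplicated).
    """
    if period not in set(occ.records["period"]):
        raise EmptyInputError(f"period {period!r} has no occurrence records")
    sub = occ.records[occ.records["period"] == period]
    group_label = "total"
    if origin is not None or functional_type is not None:
        if traits is None:
            raise FormatError("a trait table is required to filter by origin/functional type")
        keep = traits.select(origin=origin, functional_type=functional_type)
        sub = sub[sub["species"].isin(keep)]
        group_label = "/".join(x for x in (origin, functional_type) if x is not None)
    if sub.empty:
        raise EmptyGroupError(
            f"filter (origin={origin}, functional_type={functional_type}) selects no species "
            f"in period {period!r}")
    species_order = sorted(sub["species"].unique())
    present = sub[sub["island"].isin(islands.island_ids)]
    arr = np.zeros((len(species_order), len(islands)), dtype=np.int8)
    arr[pd.Index(species_order).get_indexer(present["species"]),
        pd.Index(islands.island_ids).get_indexer(present["island"])] = 1
    mat = pd.DataFrame(arr, index=species_order, columns=islands.island_ids)
    return IncidenceMatrix(data=mat, period_id=period, group_label=group_label)


def richness_by_island(m: IncidenceMatrix) -> pd.DataFrame:
    """Per-island species richness (column sums) as a two-column table."""
    rich = m.data.sum(axis=0)
    return pd.DataFrame({"island": rich.index, "richness": rich.to_numpy(dtype=int)})
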