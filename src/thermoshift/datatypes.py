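"""Core data containers for repeated-transect butterfly survey analysis.

All tabular containers wrap :class:`pandas.DataFrame` / :class:`pandas.Series`
objects with the pipeline's canonical CSV dialects:

* survey:   ``transect_id,habitat,year,visit,species_id,count``
* STI:      ``species_id,sti_c``
* atlas:    ``species_id,locality_id,elevation_zone``
* stations: ``station_id,year,mean_temp_c``

All files are UTF-8, comma-delimited, with a mandatory header row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SURVEY_COLUMNS = ["transect_id", "habitat", "year", "visit", "species_id", "count"]
ATLAS_COLUMNS = ["species_id", "locality_id", "elevation_zone"]
STATION_COLUMNS = ["station_id", "year", "mean_temp_c"]

#: Elevation zones of the national butterfly atlas: 0-500 m, 500-1000 m,
#: 1000-1500 m and >1500 m.  Zones 3 and 4 lie above the 1000 m split used
#: for the high/low-altitude classification.
ELEVATION_ZONES = (1, 2, 3, 4)
ZONES_ABOVE_1000M = (3, 4)


def _require_columns(df: pd.DataFrame, columns: Sequence[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing required column(s): {missing}")


@dataclass
class SurveyDataset:
    """Long-format abundance records from repeated transect walks.

    One row per (transect, year, visit, species) with a non-negative count.
    Within a habitat there are several fixed transects; each transect is
    walked repeatedly ("visits") through the flight season and all
    individuals within a standard band are counted.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _require_columns(self.data, SURVEY_COLUMNS, "survey table")
        if len(self.data) == 0:
            raise ValueError("survey table is empty")
        if (self.data["count"] < 0).any():
            raise ValueError("survey counts must be non-negative")
        self.data = self.data.reset_index(drop=True)

    # -- accessors -------------------------------------------------------
    @property
    def years(self) -> list[int]:
        return sorted(self.data["year"].unique())

    @property
    def transects(self) -> list[str]:
        return sorted(self.data["transect_id"].unique())

    @property
    def species(self) -> list[str]:
        return sorted(self.data["species_id"].unique())

    def visits_of(self, year: int) -> list[int]:
        sub = self.data[self.data["year"] == year]
        if len(sub) == 0:
            raise KeyError(f"year {year} not present in survey")
        return sorted(sub["visit"].unique())

    def subset_years(self, years: Iterable[int]) -> "SurveyDataset":
        years = list(years)
        return SurveyDataset(self.data[self.data["year"].isin(years)].copy())

    def drop_visits(self, year: int, visits: Iterable[int]) -> "SurveyDataset":
        visits = set(visits)
        mask = (self.data["year"] == year) & (self.data["visit"].isin(visits))
        return SurveyDataset(self.data[~mask].copy())

    def counts_by_transect_year(self) -> pd.DataFrame:
        """Species x (transect, year) matrix of counts pooled over visits.

        Rows indexed by (transect_id, year); columns are species.
        """
        return (
            self.data.pivot_table(
                index=["transect_id", "year"],
                columns="species_id",
                values="count",
                aggfunc="sum",
                fill_value=0,
            )
            .sort_index()
        )

    def counts_by_visit(self, years: Iterable[int] | None = None) -> pd.DataFrame:
        """Species x (transect, year, visit) count matrix (visits as samples)."""
        df = self.data if years is None else self.data[self.data["year"].isin(list(years))]
        return (
            df.pivot_table(
                index=["transect_id", "year", "visit"],
                columns="species_id",
                values="count",
                aggfunc="sum",
                fill_value=0,
            )
            .sort_index()
        )

    def totals_by_species_year(self) -> pd.DataFrame:
        """Total individuals per species per year (summed over all samples)."""
        return (
            self.data.groupby(["species_id", "year"])["count"].sum().unstack(fill_value=0)
        )

    # -- IO --------------------------------------------------------------
    @classmethod
    def from_csv(cls, path: str | Path) -> "SurveyDataset":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.data[SURVEY_COLUMNS].to_csv(path, index=False)


@dataclass
class STITable:
    """Species Temperature Index table: species -> STI in deg C.

    The STI of a species is the mean annual temperature averaged over the
    European grid squares where the species has been recorded; it is an
    input to this package, never computed here.
    """

    values: pd.Series

    def __post_init__(self) -> None:
        s = pd.Series(self.values, dtype=float)
        if s.index.has_duplicates:
            raise ValueError("duplicate species in STI table")
        if not np.isfinite(s.to_numpy()).all():
            raise ValueError("non-finite STI value")
        s.index.name = "species_id"
        self.values = s

    def __contains__(self, species_id: str) -> bool:
        return species_id in self.values.index

    def __getitem__(self, species_id: str) -> float:
        return float(self.values[species_id])

    def __len__(self) -> int:
        return len(self.values)

    @classmethod
    def from_csv(cls, path: str | Path) -> "STITable":
        df = pd.read_csv(path)
        _require_columns(df, ["species_id", "sti_c"], "STI table")
        return cls(pd.Series(df["sti_c"].to_numpy(), index=df["species_id"]))

    def to_csv(self, path: str | Path) -> None:
        df = self.values.rename("sti_c").reset_index()
        df.to_csv(path, index=False)


def _normalise_zone(z) -> int:
    """Accept zone labels 1..4 or 'Z1'..'Z4'."""
    if isinstance(z, str):
        z = z.strip().upper().lstrip("Z")
    z = int(z)
    if z not in ELEVATION_ZONES:
        raise ValueError(f"elevation zone {z!r} not in {ELEVATION_ZONES}")
    return z


@dataclass
class AtlasRecords:
    """Presence records of species in atlas localities with elevation zones.

    Atlas records are presence-based: duplicate (species, locality) pairs
    collapse to a single presence.  ``n_localities_total`` is the number of
    atlas localities surveyed nationally (occupancy fractions are computed
    against it, not against the localities that happen to hold records).
    """

    records: pd.DataFrame
    n_localities_total: int
    zone_area_km2: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        _require_columns(self.records, ATLAS_COLUMNS, "atlas table")
        if len(self.records) == 0:
            raise ValueError("atlas table is empty")
        rec = self.records.copy()
        rec["elevation_zone"] = rec["elevation_zone"].map(_normalise_zone)
        rec = rec.drop_duplicates(subset=["species_id", "locality_id"]).reset_index(drop=True)
        self.records = rec
        if self.n_localities_total < rec["locality_id"].nunique():
            raise ValueError("n_localities_total smaller than distinct localities in records")
        areas = tuple(float(a) for a in self.zone_area_km2)
        if len(areas) != 4 or any(a <= 0 for a in areas):
            raise ValueError("zone_area_km2 must be four positive areas")
        self.zone_area_km2 = areas

    @property
    def species(self) -> list[str]:
        return sorted(self.records["species_id"].unique())

    def localities_per_zone(self) -> np.ndarray:
        """Number of distinct localities appearing in each elevation zone."""
        counts = (
            self.records.drop_duplicates(subset=["locality_id"])
            .groupby("elevation_zone")["locality_id"]
            .nunique()
        )
        return np.array([int(counts.get(z, 0)) for z in ELEVATION_ZONES])

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        n_localities_total: int,
        zone_area_km2: Sequence[float],
    ) -> "AtlasRecords":
        return cls(pd.read_csv(path), n_localities_total, tuple(zone_area_km2))

    def to_csv(self, path: str | Path) -> None:
        self.records[ATLAS_COLUMNS].to_csv(path, index=False)


@dataclass
class TemperatureSeries:
    """Annual mean temperature series of one meteorological station."""

    station_id: str
    data: pd.Series  # index: year (int) -> mean annual temperature, deg C

    def __post_init__(self) -> None:
        s = pd.Series(self.data, dtype=float).sort_index()
        if s.index.has_duplicates:
            raise ValueError(f"station {self.station_id}: duplicate years")
        if len(s) == 0:
            raise ValueError(f"station {self.station_id}: empty series")
        if not np.isfinite(s.to_numpy()).all():
            raise ValueError(f"station {self.station_id}: non-finite temperature")
        self.data = s

    @property
    def years(self) -> np.ndarray:
        return self.data.index.to_numpy(dtype=int)

    @property
    def coverage(self) -> tuple[int, int]:
        return int(self.data.index.min()), int(self.data.index.max())

    def __len__(self) -> int:
        return len(self.data)

    @classmethod
    def from_csv(cls, path: str | Path, station_id: str | None = None) -> "TemperatureSeries":
        df = pd.read_csv(path)
        _require_columns(df, STATION_COLUMNS, "station table")
        if station_id is None:
            ids = df["station_id"].unique()
            if len(ids) != 1:
                raise ValueError(f"station file holds {len(ids)} stations; pass station_id")
            station_id = str(ids[0])
        sub = df[df["station_id"] == station_id]
        if len(sub) == 0:
            raise KeyError(f"station {station_id!r} not in file")
        return cls(station_id, pd.Series(sub["mean_temp_c"].to_numpy(), index=sub["year"].astype(int)))

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "station_id": self.station_id,
                "year": self.data.index.to_numpy(dtype=int),
                "mean_temp_c": self.data.to_numpy(),
            }
        )
        df.to_csv(path, index=False)
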