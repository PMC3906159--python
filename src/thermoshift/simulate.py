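"""Synthetic survey, atlas and climate-station generators.

These generators emulate the study design that the analysis modules expect:
a Mediterranean protected-area butterfly survey of 7 habitat types x 3
transects, each transect walked 15 times per season, repeated in a baseline
year and a resurvey year; a national presence atlas with four elevation
zones driving the widespread / high-altitude / low-altitude classification;
and a pair of meteorological stations (a long-running reference plus a
short-lived in-area target) for the climate-trend stage.

Warming enters as a log-linear interaction between a species' thermal index
(STI) and the survey year: in the resurvey year the expected count of
species *s* is multiplied by ``exp(delta * (STI_s - mean STI))``.  With
``delta = 0`` the two years are exchangeable in distribution, which is the
null hypothesis every downstream resampling test is calibrated against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import rng_for
from .datatypes import AtlasRecords, SurveyDataset, TemperatureSeries

#: Habitat types of the emulated survey design.
DEFAULT_HABITATS = (
    "pine_forest",
    "oak_forest",
    "mixed_forest",
    "wet_meadow",
    "dry_grassland",
    "grazed_pasture",
    "agricultural",
)

#: Atlas zone areas (km^2), decreasing with elevation the way national
#: territory does; only their proportions matter.
DEFAULT_ZONE_AREAS = (45000.0, 20000.0, 10000.0, 5500.0)


@dataclass
class SpeciesPool:
    """Species with thermal indices and ground-truth elevational classes.

    ``true_class`` is the class the atlas generator will encode, kept as
    ground truth for classification-recovery tests: HA (high-altitude),
    LA (low-altitude) or W (widespread).
    """

    table: pd.DataFrame  # columns: species_id, sti, true_class

    def __post_init__(self) -> None:
        required = {"species_id", "sti", "true_class"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"species pool needs columns {sorted(required)}")
        if len(self.table) == 0:
            raise ValueError("species pool is empty")
        if self.table["species_id"].duplicated().any():
            raise ValueError("duplicate species_id in pool")
        if not np.isfinite(self.table["sti"].to_numpy(dtype=float)).all():
            raise ValueError("non-finite STI in pool")
        bad = set(self.table["true_class"]) - {"HA", "LA", "W"}
        if bad:
            raise ValueError(f"unknown true_class values: {sorted(bad)}")

    @property
    def species_ids(self) -> np.ndarray:
        return self.table["species_id"].to_numpy()

    @property
    def sti(self) -> pd.Series:
        return pd.Series(self.table["sti"].to_numpy(dtype=float),
                         index=self.table["species_id"], name="sti_c")

    def sti_table(self):
        from .datatypes import STITable

        return STITable(self.sti)


@dataclass
class SurveyDesign:
    """Sampling design of a repeated-transect survey.

    Defaults emulate the study layout: 7 habitats x 3 transects of standard
    length, 15 visits per season, one baseline and one resurvey year.  A
    later single-visit resurvey that retains only a subset of transects is
    expressed through ``transect_subset_by_year`` / ``visits_by_year``.
    """

    habitats: Sequence[str] = DEFAULT_HABITATS
    transects_per_habitat: int = 3
    visits: int = 15
    years: Sequence[int] = (1998, 2011)
    transect_subset_by_year: Mapping[int, Sequence[str]] | None = None
    visits_by_year: Mapping[int, int] | None = None

    def __post_init__(self) -> None:
        if len(self.habitats) == 0 or len(self.years) < 2:
            raise ValueError("design needs >=1 habitat and >=2 years")
        if self.transects_per_habitat < 1 or self.visits < 1:
            raise ValueError("transects_per_habitat and visits must be positive")

    def transect_ids(self) -> list[str]:
        return [f"{h}_t{j}" for h in self.habitats
                for j in range(1, self.transects_per_habitat + 1)]

    def habitat_of(self) -> dict[str, str]:
        return {f"{h}_t{j}": h for h in self.habitats
                for j in range(1, self.transects_per_habitat + 1)}

    def transects_in_year(self, year: int) -> list[str]:
        all_ids = self.transect_ids()
        if self.transect_subset_by_year and year in self.transect_subset_by_year:
            keep = set(self.transect_subset_by_year[year])
            unknown = keep - set(all_ids)
            if unknown:
                raise ValueError(f"unknown transects for year {year}: {sorted(unknown)}")
            return [t for t in all_ids if t in keep]
        return all_ids

    def visits_in_year(self, year: int) -> int:
        if self.visits_by_year and year in self.visits_by_year:
            v = int(self.visits_by_year[year])
            if v < 1:
                raise ValueError("visits must be positive")
            return v
        return self.visits


@dataclass
class WarmingEffect:
    """Strength of the simulated warming signal.

    ``delta_log_abundance_per_sti_unit`` is the slope of log expected count
    on (STI - mean STI) applied in the final survey year; 0 encodes the
    null.  Counts are negative-binomial with the given ``dispersion``
    (size) parameter; ``numpy.inf`` gives the Poisson limit.
    """

    delta_log_abundance_per_sti_unit: float = 0.0
    baseline_mean_count: float = 0.15
    dispersion: float = 5.0

    def __post_init__(self) -> None:
        if self.baseline_mean_count <= 0:
            raise ValueError("baseline_mean_count must be positive")
        if not self.dispersion > 0:
            raise ValueError("dispersion must be positive (numpy.inf for Poisson)")


def _class_counts(n: int, mix: Sequence[float]) -> tuple[int, int, int]:
    """Largest-remainder apportionment of n species into (HA, LA, W)."""
    mix = np.asarray(mix, dtype=float)
    if mix.shape != (3,) or (mix < 0).any() or abs(mix.sum() - 1.0) > 1e-9:
        raise ValueError("class_mix must be three non-negative proportions summing to 1")
    raw = n * mix
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base))
    for i in range(rem):
        base[order[i]] += 1
    return int(base[0]), int(base[1]), int(base[2])


def generate_species_pool(
    n_species: int,
    sti_low: float = 8.0,
    sti_high: float = 15.0,
    class_mix: Sequence[float] = (0.5, 0.4, 0.1),
    seed: int = 0,
) -> SpeciesPool:
    """Draw a species pool with STI values and elevational classes.

    STI is uniform on [sti_low, sti_high].  Widespread species are chosen
    at random; the remaining species are ranked by a noise-perturbed STI
    and the coolest ranks become high-altitude, so HA species carry
    systematically lower STI than LA species (the consistency observed
    between European thermal indices and national elevational classes).
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2 (a two-class contrast is needed)")
    if not sti_low < sti_high:
        raise ValueError("degenerate STI range: sti_low must be < sti_high")
    rng = rng_for(seed, "species_pool")
    n_ha, n_la, n_w = _class_counts(n_species, class_mix)

    sti = rng.uniform(sti_low, sti_high, size=n_species)
    ids = np.array([f"sp{i:03d}" for i in range(1, n_species + 1)])
    classes = np.empty(n_species, dtype=object)

    perm = rng.permutation(n_species)
    w_idx = perm[:n_w]
    rest = perm[n_w:]
    classes[w_idx] = "W"
    # Rank-biased assignment: noisy STI score, coolest n_ha ranks -> HA.
    score = sti[rest] + rng.normal(0.0, 0.15 * (sti_high - sti_low), size=len(rest))
    rest_sorted = rest[np.argsort(score)]
    classes[rest_sorted[:n_ha]] = "HA"
    classes[rest_sorted[n_ha:]] = "LA"

    return SpeciesPool(pd.DataFrame({"species_id": ids, "sti": sti, "true_class": classes}))


def generate_atlas_records(
    pool: SpeciesPool,
    n_localities: int = 60,
    zone_areas: Sequence[float] = DEFAULT_ZONE_AREAS,
    seed: int = 0,
) -> AtlasRecords:
    """Place presence records so each species' true class is recoverable.

    Localities are apportioned to the four elevation zones proportionally
    to zone area (largest remainder, at least one per zone).  Widespread
    species receive records in strictly more than half of all localities;
    high (low) altitude species receive strictly more than half of their
    records above (below) the 1000 m split while occupying at most half of
    all localities.
    """
    zone_areas = tuple(float(a) for a in zone_areas)
    if len(zone_areas) != 4 or any(a <= 0 for a in zone_areas):
        raise ValueError("zone_areas must be four positive areas")
    if n_localities < 4:
        raise ValueError("need n_localities >= 4 (one per elevation zone)")
    rng = rng_for(seed, "atlas_records")

    areas = np.asarray(zone_areas)
    raw = n_localities * areas / areas.sum()
    n_zone = np.maximum(np.floor(raw).astype(int), 1)
    while n_zone.sum() > n_localities:
        n_zone[np.argmax(n_zone)] -= 1
    order = np.argsort(-(raw - n_zone))
    i = 0
    while n_zone.sum() < n_localities:
        n_zone[order[i % 4]] += 1
        i += 1

    zone_of = np.repeat(np.arange(1, 5), n_zone)
    loc_ids = np.array([f"L{i:04d}" for i in range(1, n_localities + 1)])
    high_locs = loc_ids[zone_of >= 3]
    low_locs = loc_ids[zone_of <= 2]

    half = n_localities // 2  # max occupancy for a non-widespread species
    rows: list[tuple[str, str, int]] = []
    zone_lookup = dict(zip(loc_ids, zone_of))

    for sp, cls in zip(pool.table["species_id"], pool.table["true_class"]):
        if cls == "W":
            k = int(np.ceil(rng.uniform(0.55, 0.80) * n_localities))
            k = min(max(k, half + 1), n_localities)
            chosen = rng.choice(loc_ids, size=k, replace=False)
        else:
            main = high_locs if cls == "HA" else low_locs
            other = low_locs if cls == "HA" else high_locs
            m = int(rng.integers(4, max(5, half) + 1))
            m = min(m, half)
            n_main = max(int(np.ceil(rng.uniform(0.65, 0.90) * m)), m // 2 + 1)
            n_main = min(n_main, len(main))
            m = min(m, 2 * n_main - 1)  # keep the main-side fraction strictly > 1/2
            n_other = min(m - n_main, len(other))
            chosen = np.concatenate([
                rng.choice(main, size=n_main, replace=False),
                rng.choice(other, size=n_other, replace=False),
            ])
        rows.extend((sp, loc, zone_lookup[loc]) for loc in chosen)

    records = pd.DataFrame(rows, columns=["species_id", "locality_id", "elevation_zone"])
    # An atlas locality is a place with at least one record: give uncovered
    # localities one record from a species whose class guarantees survive
    # the extra presence (W always; else a same-side HA/LA species whose
    # occupancy stays at most half of all localities).
    uncovered = sorted(set(loc_ids) - set(records["locality_id"]))
    if uncovered:
        occ = records.groupby("species_id")["locality_id"].nunique()
        cls_of = dict(zip(pool.table["species_id"], pool.table["true_class"]))
        extra = []
        for loc in uncovered:
            zone = zone_lookup[loc]
            side = "HA" if zone >= 3 else "LA"
            candidates = [s for s in occ.index
                          if cls_of[s] == side and occ[s] + 1 <= half]
            if not candidates:
                candidates = [s for s in occ.index if cls_of[s] == "W"]
            if not candidates:
                continue
            sp = candidates[int(rng.integers(len(candidates)))]
            occ[sp] += 1
            extra.append((sp, loc, zone))
        if extra:
            records = pd.concat(
                [records, pd.DataFrame(extra, columns=records.columns)],
                ignore_index=True)
    return AtlasRecords(records, n_localities_total=n_localities, zone_area_km2=zone_areas)


def _draw_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if np.isinf(dispersion):
        return rng.poisson(mu)
    p = dispersion / (dispersion + mu)
    return rng.negative_binomial(dispersion, p)


def generate_survey(
    pool: SpeciesPool,
    design: SurveyDesign | None = None,
    effect: WarmingEffect | None = None,
    seed: int = 0,
    habitat_sd: float = 0.6,
    transect_sd: float = 0.4,
) -> SurveyDataset:
    """Simulate counts per (transect, year, visit, species).

    log mean = log(baseline) + habitat offset + transect offset
               + I(year == last) * delta * (STI - mean STI).

    Habitat and transect offsets are drawn once per dataset and shared by
    all years, so between-transect structure is real but cancels from any
    between-year contrast.  Zero counts are not materialised as rows.
    """
    design = design or SurveyDesign()
    effect = effect or WarmingEffect()
    rng = rng_for(seed, "survey")

    sti = pool.table["sti"].to_numpy(dtype=float)
    sti_centred = sti - sti.mean()
    species = pool.table["species_id"].to_numpy()
    habitat_of = design.habitat_of()

    hab_off = dict(zip(design.habitats,
                       rng.normal(0.0, habitat_sd, size=len(design.habitats))))
    all_transects = design.transect_ids()
    tr_off = dict(zip(all_transects,
                      rng.normal(0.0, transect_sd, size=len(all_transects))))

    last_year = max(design.years)
    delta = effect.delta_log_abundance_per_sti_unit
    frames = []
    for year in design.years:
        warming = delta * sti_centred if year == last_year else np.zeros_like(sti_centred)
        for transect in design.transects_in_year(year):
            mu = effect.baseline_mean_count * np.exp(
                hab_off[habitat_of[transect]] + tr_off[transect] + warming
            )
            for visit in range(1, design.visits_in_year(year) + 1):
                counts = _draw_counts(rng, mu, effect.dispersion)
                pos = counts > 0
                if pos.any():
                    frames.append(pd.DataFrame({
                        "transect_id": transect,
                        "habitat": habitat_of[transect],
                        "year": year,
                        "visit": visit,
                        "species_id": species[pos],
                        "count": counts[pos],
                    }))
    if not frames:
        raise ValueError("simulated survey contains no individuals; raise baseline_mean_count")
    return SurveyDataset(pd.concat(frames, ignore_index=True))


def generate_station_series(
    years: Sequence[int] = tuple(range(1990, 2013)),
    trend: float = 0.0432,
    noise_sd: float = 0.4,
    calib_intercept: float = 1.5,
    calib_slope: float = 0.9,
    target_coverage: Sequence[int] = tuple(range(1994, 2005)),
    seed: int = 0,
    base_temp: float = 14.2,
) -> tuple[TemperatureSeries, TemperatureSeries]:
    """Simulate a (reference, target) pair of annual-temperature series.

    reference[y] = base + trend*(y - first year) + N(0, noise_sd);
    target, defined only on ``target_coverage``, is a linear recalibration
    of the reference plus independent noise of the same scale — the
    situation where a short-lived in-area station must be calibrated
    against a long-running reference station before a trend test.
    """
    years = np.asarray(sorted(int(y) for y in years))
    cover = np.asarray(sorted(int(y) for y in target_coverage))
    if len(years) < 3:
        raise ValueError("need at least 3 reference years")
    if len(cover) == 0 or not np.isin(cover, years).all():
        raise ValueError("target_coverage must be a non-empty subset of years")
    rng = rng_for(seed, "stations")

    ref_vals = base_temp + trend * (years - years[0]) + rng.normal(0.0, noise_sd, len(years))
    reference = TemperatureSeries("reference", pd.Series(ref_vals, index=years))
    tgt_vals = (calib_intercept + calib_slope * reference.data.loc[cover].to_numpy()
                + rng.normal(0.0, noise_sd, len(cover)))
    target = TemperatureSeries("target", pd.Series(tgt_vals, index=cover))
    return reference, target
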