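"""Elevational-shift statistics T_sp and T_ab with Monte-Carlo nulls.

Between a baseline year (1) and a resurvey year (2), and with widespread
species excluded, the two statistics measure how much the low-altitude
fraction of the community grew:

* ``T_sp = L2/(L2+H2) - L1/(L1+H1)`` on species richness (L, H = numbers
  of low- and high-altitude species observed in a year);
* ``T_ab = l2/(l2+h2) - l1/(l1+h1)`` on abundance (l, h = summed
  individuals of low- and high-altitude species).

Both are positive when low-altitude (warm-associated) species gain, and
are antisymmetric under exchanging the years.  The null — both years
equivalent, high- and low-altitude species equally likely in any sample —
is materialised by shuffling year labels without replacement across the
elementary units (individuals for T_ab, species-detection records for
T_sp), preserving each year's unit total.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from ._rng import rng_for


@dataclass
class ShiftCounts:
    """Low/high-altitude richness (L, H) and abundance (l, h) per year."""

    L1: int
    H1: int
    L2: int
    H2: int
    l1: int = 0
    h1: int = 0
    l2: int = 0
    h2: int = 0

    def __post_init__(self) -> None:
        for name in ("L1", "H1", "L2", "H2", "l1", "h1", "l2", "h2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.L1 + self.H1 == 0 or self.L2 + self.H2 == 0:
            raise ValueError("each year needs at least one low- or high-altitude species")
        # a species counted in the richness margins implies >= 1 individual
        for rich, ab in (("L1", "l1"), ("H1", "h1"), ("L2", "l2"), ("H2", "h2")):
            if getattr(self, ab) and getattr(self, ab) < getattr(self, rich):
                raise ValueError(f"{ab} < {rich}: fewer individuals than species")


def t_sp(counts: ShiftCounts) -> float:
    """Change in the low-altitude proportion of species richness."""
    d1, d2 = counts.L1 + counts.H1, counts.L2 + counts.H2
    if d1 == 0 or d2 == 0:
        raise ValueError("zero richness denominator")
    return counts.L2 / d2 - counts.L1 / d1


def t_ab(counts: ShiftCounts) -> float:
    """Change in the low-altitude proportion of total abundance."""
    d1, d2 = counts.l1 + counts.h1, counts.l2 + counts.h2
    if d1 == 0 or d2 == 0:
        raise ValueError("zero abundance denominator")
    return counts.l2 / d2 - counts.l1 / d1


@dataclass
class MonteCarloResult:
    """Observed statistic, permutation null and two-sided p-value."""

    observed: float
    null_values: np.ndarray
    p_two_sided: float
    n_perm: int
    seed: int
    statistic: str
    #: decision threshold of the published two-tailed rule
    alpha: float = 0.025

    @property
    def significant(self) -> bool:
        return self.p_two_sided < self.alpha


def shift_counts_from_records(records: pd.DataFrame, year_1: int, year_2: int) -> ShiftCounts:
    """Aggregate (species_id, cls, year, count) records into ShiftCounts.

    ``cls`` must be HA or LA only — widespread species are excluded
    upstream, before this statistic is meaningful.
    """
    bad = set(records["cls"]) - {"HA", "LA"}
    if bad:
        raise ValueError(f"records contain classes {sorted(bad)}; only HA/LA allowed "
                         "(drop widespread species first)")
    out = {}
    for tag, year in (("1", year_1), ("2", year_2)):
        sub = records[(records["year"] == year) & (records["count"] > 0)]
        by_cls = sub.groupby("cls")
        rich = by_cls["species_id"].nunique()
        ab = by_cls["count"].sum()
        out[f"L{tag}"] = int(rich.get("LA", 0))
        out[f"H{tag}"] = int(rich.get("HA", 0))
        out[f"l{tag}"] = int(ab.get("LA", 0))
        out[f"h{tag}"] = int(ab.get("HA", 0))
    return ShiftCounts(**out)


def _units(records: pd.DataFrame, year_1: int, year_2: int,
           unit: str) -> tuple[np.ndarray, np.ndarray]:
    """Elementary permutation units: (is_low flags, is_year2 flags)."""
    sub = records[records["count"] > 0]
    if unit == "individuals":
        reps = sub["count"].to_numpy(dtype=int)
        is_low = np.repeat((sub["cls"] == "LA").to_numpy(), reps)
        is_y2 = np.repeat((sub["year"] == year_2).to_numpy(), reps)
    elif unit == "detections":
        det = sub.drop_duplicates(subset=["species_id", "year"])
        is_low = (det["cls"] == "LA").to_numpy()
        is_y2 = (det["year"] == year_2).to_numpy()
    else:
        raise ValueError(f"unknown permutation unit {unit!r}")
    return is_low.astype(np.int8), is_y2


def monte_carlo_shift_test(
    records: pd.DataFrame,
    statistic: Literal["t_sp", "t_ab"],
    year_1: int,
    year_2: int,
    n_perm: int = 1000,
    seed: int = 0,
    unit: str | None = None,
) -> MonteCarloResult:
    """Permutation test of T_sp or T_ab against the equal-years null.

    ``records`` is a long table (species_id, cls, year, count) already
    restricted to HA/LA species.  Year labels are shuffled without
    replacement across the elementary units — individuals for ``t_ab``,
    species-detection records for ``t_sp`` (overridable via ``unit``) —
    so each permutation preserves the per-year unit totals and the pooled
    class margin.  p = (k+1)/(n_perm+1) with k the number of permutations
    whose |T| reaches |T_observed|; the published decision rule declares a
    shift at p < 0.025.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    counts = shift_counts_from_records(records, year_1, year_2)
    if statistic == "t_sp":
        observed = t_sp(counts)
        unit = unit or "detections"
    elif statistic == "t_ab":
        observed = t_ab(counts)
        unit = unit or "individuals"
    else:
        raise ValueError(f"unknown statistic {statistic!r}")

    is_low, is_y2 = _units(records, year_1, year_2, unit)
    n = len(is_low)
    n2 = int(is_y2.sum())
    n1 = n - n2
    if n1 == 0 or n2 == 0:
        raise ValueError("both years need at least one unit")
    total_low = int(is_low.sum())

    rng = rng_for(seed, f"shift:{statistic}:{unit}")
    null = np.empty(n_perm, dtype=float)
    # Shuffle year labels by permuting the unit class flags; the first n2
    # positions play the role of year-2 units.  Chunked to bound memory.
    chunk = max(1, int(2e7) // max(n, 1))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        mat = np.tile(is_low, (m, 1))
        mat = rng.permuted(mat, axis=1)
        low2 = mat[:, :n2].sum(axis=1)
        low1 = mat.sum(axis=1) - low2
        # conservation: per-year unit totals and the pooled class margin
        assert (mat.sum(axis=1) == total_low).all()
        null[done:done + m] = low2 / n2 - low1 / n1
        done += m

    k = int((np.abs(null) >= abs(observed) - 1e-12).sum())
    p = (k + 1) / (n_perm + 1)
    return MonteCarloResult(observed=float(observed), null_values=null,
                            p_two_sided=float(p), n_perm=n_perm, seed=seed,
                            statistic=statistic)


def records_from_survey(survey, classification, years=None) -> pd.DataFrame:
    """Long (species_id, cls, year, count) records, widespread excluded.

    Counts are pooled over transects and visits within each year.
    """
    cls = classification.class_of()
    totals = survey.totals_by_species_year()
    rows = []
    for sp, per_year in totals.iterrows():
        c = cls.get(sp)
        if c not in ("HA", "LA"):
            continue
        for year, count in per_year.items():
            if years is not None and year not in years:
                continue
            if count > 0:
                rows.append((sp, c, int(year), int(count)))
    return pd.DataFrame(rows, columns=["species_id", "cls", "year", "count"])
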