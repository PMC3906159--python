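"""Community Temperature Index (CTI) and rank-based year comparisons.

The CTI of a community sample is the abundance-weighted mean of its
species' temperature indices (STI): warm-associated species gaining
relative abundance pull the CTI up.  Transect-level CTIs of two survey
years are compared with a Wilcoxon rank-sum (Mann-Whitney) test, and a
phenology-robustness variant repeats the comparison after discarding the
season-edge visits that an advance in flight dates would affect most.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import STITable, SurveyDataset

logger = logging.getLogger(__name__)


@dataclass
class CTIResult:
    """CTI of one community sample (a transect-year, unless noted)."""

    cti: float
    total_abundance: int
    n_species_used: int
    n_species_missing_sti: int
    transect_id: str | None = None
    year: int | None = None


@dataclass
class RankSumResult:
    """Two-sample rank-sum test.

    ``statistic_w`` is the Mann-Whitney U of the *first* sample, i.e. the
    sum of the first sample's mid-ranks in the pooled data minus
    n1(n1+1)/2 — the W convention of classic statistical software, so
    published W values are directly comparable.
    """

    statistic_w: float
    n1: int
    n2: int
    p_two_sided: float
    method: str  # "exact" | "normal_approx"


def community_temperature_index(
    counts: Mapping[str, int] | pd.Series,
    sti: STITable,
    transect_id: str | None = None,
    year: int | None = None,
) -> CTIResult:
    """Abundance-weighted mean STI of one community sample.

    Species without an STI value are excluded (and counted in
    ``n_species_missing_sti``), not imputed.
    """
    s = pd.Series(counts, dtype=float)
    s = s[s > 0]
    if len(s) == 0:
        raise ValueError("all counts are zero; CTI undefined")
    known = s.index.isin(sti.values.index)
    n_missing = int((~known).sum())
    if n_missing:
        logger.warning("%d species without STI excluded from CTI", n_missing)
    s = s[known]
    if len(s) == 0:
        raise ValueError("no species with a known STI; CTI undefined")
    weights = s.to_numpy()
    stis = sti.values.loc[s.index].to_numpy()
    cti = float(np.average(stis, weights=weights))
    return CTIResult(
        cti=cti,
        total_abundance=int(round(weights.sum())),
        n_species_used=int(len(s)),
        n_species_missing_sti=n_missing,
        transect_id=transect_id,
        year=year,
    )


def rank_sum_test(x, y, method: str = "auto") -> RankSumResult:
    """Wilcoxon rank-sum / Mann-Whitney test of two independent samples.

    With ``method="auto"``: exact two-sided p by full enumeration when
    n1 + n2 <= 20 and the pooled data are tie-free; otherwise a normal
    approximation with mid-rank tie correction and continuity correction.
    ``method`` may force either branch ("exact" requires tie-free data).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if method == "auto":
        exact = (x.size + y.size) <= 20 and not has_ties
    elif method in ("exact", "normal_approx"):
        if method == "exact" and has_ties:
            raise ValueError("exact enumeration requires tie-free data")
        exact = method == "exact"
    else:
        raise ValueError(f"unknown method {method!r}")
    res = stats.mannwhitneyu(
        x, y,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return RankSumResult(
        statistic_w=float(res.statistic),
        n1=int(x.size),
        n2=int(y.size),
        p_two_sided=float(min(res.pvalue, 1.0)),
        method="exact" if exact else "normal_approx",
    )


@dataclass
class CTIComparison:
    """Transect-level CTI change between two survey years."""

    year_a: int
    year_b: int
    pairs: pd.DataFrame  # columns: transect_id, cti_a, cti_b
    test: RankSumResult

    @property
    def median_change(self) -> float:
        return float((self.pairs["cti_b"] - self.pairs["cti_a"]).median())


def cti_by_transect_year(survey: SurveyDataset, sti: STITable) -> pd.DataFrame:
    """CTI per transect-year (counts pooled over all visits of the year)."""
    mat = survey.counts_by_transect_year()
    rows = []
    for (transect, year), counts in mat.iterrows():
        r = community_temperature_index(counts, sti, transect_id=transect, year=year)
        rows.append((transect, year, r.cti, r.total_abundance,
                     r.n_species_used, r.n_species_missing_sti))
    return pd.DataFrame(rows, columns=["transect_id", "year", "cti_c", "total_abundance",
                                       "n_species_used", "n_species_missing_sti"])


def compare_cti_by_year(
    survey: SurveyDataset,
    sti: STITable,
    year_a: int,
    year_b: int,
) -> CTIComparison:
    """Rank-sum comparison of transect CTIs between two years.

    CTIs are computed from counts pooled over all visits of each year; the
    comparison is restricted to transects surveyed in both years.
    """
    years = set(survey.years)
    for y in (year_a, year_b):
        if y not in years:
            raise KeyError(f"year {y} absent from survey")
    table = cti_by_transect_year(survey.subset_years([year_a, year_b]), sti)
    wide = table.pivot(index="transect_id", columns="year", values="cti_c").dropna()
    if len(wide) < 2:
        raise ValueError("need >= 2 transects surveyed in both years")
    pairs = pd.DataFrame({
        "transect_id": wide.index,
        "cti_a": wide[year_a].to_numpy(),
        "cti_b": wide[year_b].to_numpy(),
    }).reset_index(drop=True)
    test = rank_sum_test(pairs["cti_a"], pairs["cti_b"])
    return CTIComparison(year_a=year_a, year_b=year_b, pairs=pairs, test=test)


@dataclass
class PhenologyCheckResult:
    """CTI comparison recomputed without the season-edge visits."""

    full: CTIComparison
    trimmed: CTIComparison
    direction_preserved: bool


def cti_phenology_check(
    survey: SurveyDataset,
    sti: STITable,
    drop_first_visit_of: int,
    drop_last_visit_of: int,
) -> PhenologyCheckResult:
    """Repeat the CTI year comparison after dropping season-edge visits.

    The first visit of ``drop_first_visit_of`` and the last visit of
    ``drop_last_visit_of`` are discarded before recomputation.  If a CTI
    change survives this trimming, it cannot be an artefact of species
    flying earlier in the later year (phenological advance) rather than a
    genuine composition change.
    """
    year_a, year_b = drop_first_visit_of, drop_last_visit_of
    for y in (year_a, year_b):
        if len(survey.visits_of(y)) < 2:
            raise ValueError(f"year {y} has a single visit; nothing can be dropped")
    full = compare_cti_by_year(survey, sti, year_a, year_b)
    trimmed_survey = survey.drop_visits(year_a, [min(survey.visits_of(year_a))])
    trimmed_survey = trimmed_survey.drop_visits(year_b, [max(trimmed_survey.visits_of(year_b))])
    trimmed = compare_cti_by_year(trimmed_survey, sti, year_a, year_b)
    preserved = bool(
        math.copysign(1.0, full.median_change) == math.copysign(1.0, trimmed.median_change)
        or (full.median_change == 0.0 and trimmed.median_change == 0.0)
    )
    return PhenologyCheckResult(full=full, trimmed=trimmed, direction_preserved=preserved)
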