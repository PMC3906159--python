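"""Alpha/beta diversity, Chao1 sampling efficiency and year contrasts.

Shannon entropy (natural log) is the transect-level alpha diversity;
Whittaker's ratio beta = S/abar - 1 quantifies turnover among the
transects of one habitat; Chao1 turns singleton/doubleton counts into a
richness estimate whose ratio to observed richness is the survey's
sampling efficiency.  Year contrasts on diversity values use a two-group
ordinary least-squares F test (equivalently, one-way ANOVA).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


def shannon_index(counts: Mapping[str, int] | Sequence[float] | pd.Series) -> float:
    """Shannon-Wiener H' = -sum p_i ln p_i in nats, over positive counts."""
    c = np.asarray(pd.Series(counts, dtype=float).to_numpy())
    if (c < 0).any():
        raise ValueError("negative count")
    c = c[c > 0]
    total = c.sum()
    if total <= 0:
        raise ValueError("all counts are zero; Shannon undefined")
    p = c / total
    return float(-(p * np.log(p)).sum())


def whittaker_beta(species_sets: Iterable[Iterable[str]]) -> float:
    """Whittaker beta = S/abar - 1 across the transects of one habitat.

    S is the pooled species richness, abar the mean per-transect richness.
    """
    sets = [set(s) for s in species_sets]
    if len(sets) < 2:
        raise ValueError("need >= 2 transects for beta diversity")
    empty = [i for i, s in enumerate(sets) if len(s) == 0]
    if empty:
        raise ValueError(f"transect(s) at position {empty} have zero species; "
                         "beta (S/abar - 1) is undefined for empty samples")
    union: set[str] = set().union(*sets)
    abar = float(np.mean([len(s) for s in sets]))
    return len(union) / abar - 1.0


@dataclass
class Chao1Result:
    """Chao1 richness estimate and the implied sampling efficiency."""

    s_obs: int
    f1: int
    f2: int
    chao1: float
    efficiency: float


def chao1(counts: Mapping[str, int] | Sequence[float] | pd.Series) -> Chao1Result:
    """Chao1 estimator from singletons (F1) and doubletons (F2).

    Classic form S_obs + F1^2/(2 F2); the bias-corrected form
    S_obs + F1(F1-1)/(2(F2+1)) is used when F2 = 0.  Sampling efficiency
    is S_obs / Chao1.
    """
    c = np.asarray(pd.Series(counts, dtype=float).to_numpy())
    c = c[c > 0]
    if c.sum() <= 0:
        raise ValueError("all counts are zero")
    s_obs = int(len(c))
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    if f2 > 0:
        est = s_obs + f1 * f1 / (2.0 * f2)
    else:
        est = s_obs + f1 * (f1 - 1) / 2.0
    return Chao1Result(s_obs=s_obs, f1=f1, f2=f2, chao1=float(est),
                       efficiency=float(s_obs / est))


@dataclass
class YearEffectResult:
    """Two-group OLS / one-way ANOVA contrast between survey years."""

    f: float
    p: float
    df1: int
    df2: int
    degenerate: bool = False


def year_effect_lm(values, years) -> YearEffectResult:
    """OLS of a diversity value on a two-level year indicator.

    F = MS_year / MS_residual with (1, n-2) df — identical to the squared
    pooled-variance two-sample t statistic.  Zero residual variance with a
    real year difference is reported as F = inf, p = 0, flagged degenerate.
    """
    values = np.asarray(values, dtype=float)
    years = np.asarray(years)
    levels = np.unique(years)
    if len(levels) != 2:
        raise ValueError(f"need exactly two year levels, got {levels}")
    a = values[years == levels[0]]
    b = values[years == levels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 observations per year")
    n = len(values)
    grand = values.mean()
    ss_year = len(a) * (a.mean() - grand) ** 2 + len(b) * (b.mean() - grand) ** 2
    ss_res = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    df1, df2 = 1, n - 2
    scale = max(1.0, float((values ** 2).sum()))
    if ss_res <= 1e-12 * scale:
        if ss_year <= 1e-12 * scale:
            return YearEffectResult(f=0.0, p=1.0, df1=df1, df2=df2, degenerate=True)
        return YearEffectResult(f=np.inf, p=0.0, df1=df1, df2=df2, degenerate=True)
    f = (ss_year / df1) / (ss_res / df2)
    p = float(stats.f.sf(f, df1, df2))
    return YearEffectResult(f=float(f), p=p, df1=df1, df2=df2)


def _subset_counts(counts: pd.Series, members: set[str] | None) -> pd.Series:
    if members is None:
        return counts
    keep = [s for s in counts.index if s in members]
    return counts[keep]


def diversity_change_table(survey, classification, year_a: int, year_b: int) -> pd.DataFrame:
    """Alpha (per transect) and beta (per habitat) year contrasts.

    For each species subset (all, HA-only, LA-only): mean transect-level
    Shannon alpha per year with its OLS year contrast, and mean
    habitat-level Whittaker beta per year with its contrast.  Transects
    (habitats) holding no individuals of a subset in some year are dropped
    from that subset's contrast.

    Returns a long table with columns
    ``subset, index, mean_a, mean_b, f, p, n_units``.
    """
    cls = classification.class_of()
    subsets = {
        "all": None,
        "HA": set(cls.index[cls == "HA"]),
        "LA": set(cls.index[cls == "LA"]),
    }
    data = survey.subset_years([year_a, year_b])
    mat = data.counts_by_transect_year()
    habitat_of = (
        data.data.drop_duplicates("transect_id").set_index("transect_id")["habitat"]
    )

    rows = []
    for name, members in subsets.items():
        # alpha: Shannon per transect-year
        alpha = []
        for (transect, year), counts in mat.iterrows():
            sub = _subset_counts(counts, members)
            if sub.sum() > 0:
                alpha.append((transect, year, shannon_index(sub)))
        adf = pd.DataFrame(alpha, columns=["transect_id", "year", "value"])
        wide = adf.pivot(index="transect_id", columns="year", values="value").dropna()
        res = year_effect_lm(
            np.concatenate([wide[year_a].to_numpy(), wide[year_b].to_numpy()]),
            np.array([year_a] * len(wide) + [year_b] * len(wide)),
        )
        rows.append((name, "alpha_shannon", wide[year_a].mean(), wide[year_b].mean(),
                     res.f, res.p, len(wide)))

        # beta: Whittaker per habitat-year
        beta = []
        for year in (year_a, year_b):
            ymat = mat.xs(year, level="year")
            for habitat, transects in habitat_of.groupby(habitat_of).groups.items():
                sets = []
                for t in transects:
                    if t not in ymat.index:
                        continue
                    counts = _subset_counts(ymat.loc[t], members)
                    present = set(counts.index[counts > 0])
                    if present:
                        sets.append(present)
                if len(sets) >= 2:
                    beta.append((habitat, year, whittaker_beta(sets)))
        bdf = pd.DataFrame(beta, columns=["habitat", "year", "value"])
        bwide = bdf.pivot(index="habitat", columns="year", values="value").dropna()
        if len(bwide) >= 2:
            bres = year_effect_lm(
                np.concatenate([bwide[year_a].to_numpy(), bwide[year_b].to_numpy()]),
                np.array([year_a] * len(bwide) + [year_b] * len(bwide)),
            )
            rows.append((name, "beta_whittaker", bwide[year_a].mean(), bwide[year_b].mean(),
                         bres.f, bres.p, len(bwide)))
    return pd.DataFrame(rows, columns=["subset", "index", "mean_a", "mean_b",
                                       "f", "p", "n_units"])
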