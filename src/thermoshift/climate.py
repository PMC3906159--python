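"""Station calibration and randomization trend test for annual temperature.

A short-lived in-area station is regressed on a long-running reference
station over their overlap years; the fitted line converts the full
reference record into a homogeneous in-area series, whose linear trend is
then tested by shuffling the annual values across years.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import rng_for
from .datatypes import TemperatureSeries


@dataclass
class CalibrationResult:
    """OLS calibration of a target station against a reference station."""

    intercept: float
    slope: float
    r_squared: float
    n_overlap: int
    predicted: TemperatureSeries  # target scale, over the full reference coverage


def calibrate_stations(
    target: TemperatureSeries,
    reference: TemperatureSeries,
    splice_observed: bool = False,
) -> CalibrationResult:
    """Regress target on reference over their overlap, predict all years.

    The returned series is model-predicted for *every* reference year —
    observed target values are not substituted back by default, so the
    series is homogeneous in variance; pass ``splice_observed=True`` to
    overwrite predicted values with observations where they exist.
    """
    overlap = target.data.index.intersection(reference.data.index)
    if len(overlap) < 3:
        raise ValueError(f"only {len(overlap)} overlap years; need >= 3")
    x = reference.data.loc[overlap].to_numpy()
    y = target.data.loc[overlap].to_numpy()
    if np.ptp(x) == 0:
        slope, intercept, r2 = 0.0, float(y.mean()), 0.0
    else:
        fit = stats.linregress(x, y)
        slope, intercept = float(fit.slope), float(fit.intercept)
        r2 = float(fit.rvalue ** 2)
    predicted = intercept + slope * reference.data
    if splice_observed:
        predicted.loc[overlap] = target.data.loc[overlap]
    return CalibrationResult(
        intercept=intercept,
        slope=slope,
        r_squared=r2,
        n_overlap=int(len(overlap)),
        predicted=TemperatureSeries(f"{target.station_id}_predicted", predicted),
    )


@dataclass
class TrendResult:
    """Linear temperature trend with a randomization p-value."""

    slope: float          # deg C / year
    intercept: float
    total_change: float   # slope x (last year - first year), deg C
    p_randomization: float
    n_rand: int
    seed: int
    first_year: int
    last_year: int


def trend_with_randomization(
    series: TemperatureSeries,
    n_rand: int = 1000,
    seed: int = 0,
) -> TrendResult:
    """OLS trend of temperature on year, tested by value shuffling.

    The null distribution reassigns the observed annual values to years at
    random; p = (k+1)/(n_rand+1) with k the number of shuffles whose
    |slope| reaches the observed |slope| (two-sided).  ``total_change`` is
    slope x (last year - first year).
    """
    if len(series) < 3:
        raise ValueError("need >= 3 years for a trend")
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    years = series.years.astype(float)
    temps = series.data.to_numpy()
    span = years[-1] - years[0]
    xc = years - years.mean()
    sxx = (xc ** 2).sum()
    slope = float((xc * temps).sum() / sxx)
    intercept = float(temps.mean() - slope * years.mean())

    if np.ptp(temps) == 0:
        return TrendResult(slope=0.0, intercept=float(temps[0]), total_change=0.0,
                           p_randomization=1.0, n_rand=n_rand, seed=seed,
                           first_year=int(years[0]), last_year=int(years[-1]))

    rng = rng_for(seed, "trend")
    perms = np.tile(temps, (n_rand, 1))
    perms = rng.permuted(perms, axis=1)
    null_slopes = perms @ xc / sxx
    k = int((np.abs(null_slopes) >= abs(slope) - 1e-15).sum())
    return TrendResult(
        slope=slope,
        intercept=intercept,
        total_change=float(slope * span),
        p_randomization=float((k + 1) / (n_rand + 1)),
        n_rand=n_rand,
        seed=seed,
        first_year=int(years[0]),
        last_year=int(years[-1]),
    )
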