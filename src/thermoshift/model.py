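"""Model/Results front-end orchestrating the full survey analysis.

:class:`ClimateSignalModel` bundles the inputs (survey, STI table, atlas
or ready-made classification, optional station series) the way a
statsmodels model bundles endog/exog; :meth:`ClimateSignalModel.fit` runs
the stages in dependency order — classify -> CTI -> diversity -> shift
tests -> composition -> climate trend — and returns a
:class:`ClimateSignalResults` carrying every stage's result object, a
``summary()`` table and writers for machine- and human-readable reports.

All randomness flows from the single ``seed`` passed to ``fit``; each
stage derives its own child seed from a stable label, so a stage re-run
in isolation with that child seed reproduces its in-pipeline result.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__ as _version
from ._rng import child_seed
from .atlas import SamplingAdequacy, ThermalClassification, classify_species, sampling_adequacy
from .climate import CalibrationResult, TrendResult, calibrate_stations, trend_with_randomization
from .composition import (
    AnosimResult,
    PermanovaResult,
    anosim,
    bray_curtis,
    pairwise_year_within_transect,
    permanova,
    species_change_table,
)
from .datatypes import AtlasRecords, STITable, SurveyDataset, TemperatureSeries
from .diversity import chao1, diversity_change_table
from .shift import MonteCarloResult, monte_carlo_shift_test, records_from_survey, shift_counts_from_records
from .thermal import CTIComparison, PhenologyCheckResult, cti_by_transect_year, compare_cti_by_year, cti_phenology_check

logger = logging.getLogger(__name__)


class ClimateSignalModel:
    """Climate-change signal detection on a repeated transect survey.

    Parameters
    ----------
    survey : SurveyDataset
        Long-format counts with at least two survey years.
    sti : STITable
        Species -> Species Temperature Index (deg C).
    atlas : AtlasRecords, optional
        National presence records; drives the W/HA/LA classification.
    classification : ThermalClassification, optional
        Ready-made classification; required if no atlas is given.
    target_station, reference_station : TemperatureSeries, optional
        In-area and reference annual temperature series for the
        calibration + trend stage.
    year_pair : (int, int), optional
        Baseline and resurvey year; defaults to (min, max) survey years.
    """

    def __init__(
        self,
        survey: SurveyDataset,
        sti: STITable,
        atlas: AtlasRecords | None = None,
        classification: ThermalClassification | None = None,
        target_station: TemperatureSeries | None = None,
        reference_station: TemperatureSeries | None = None,
        year_pair: tuple[int, int] | None = None,
        occupancy_threshold: float = 0.5,
        record_fraction: float = 0.5,
        alpha: float = 0.05,
        shift_alpha: float = 0.025,
    ) -> None:
        if atlas is None and classification is None:
            raise ValueError("provide an atlas or a ready-made classification")
        for name, v in (("occupancy_threshold", occupancy_threshold),
                        ("record_fraction", record_fraction),
                        ("alpha", alpha), ("shift_alpha", shift_alpha)):
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        self.survey = survey
        self.sti = sti
        self.atlas = atlas
        self.classification = classification
        self.target_station = target_station
        self.reference_station = reference_station
        years = survey.years
        if year_pair is None:
            year_pair = (years[0], years[-1])
        if year_pair[0] not in years or year_pair[1] not in years:
            raise ValueError(f"year_pair {year_pair} not in survey years {years}")
        self.year_pair = (int(year_pair[0]), int(year_pair[1]))
        self.occupancy_threshold = occupancy_threshold
        self.record_fraction = record_fraction
        self.alpha = alpha
        self.shift_alpha = shift_alpha

    # -- constructors ----------------------------------------------------
    @classmethod
    def from_csv(
        cls,
        survey_csv,
        sti_csv,
        atlas_csv=None,
        classification_csv=None,
        n_localities_total: int | None = None,
        zone_area_km2=None,
        target_station_csv=None,
        reference_station_csv=None,
        **kwargs,
    ) -> "ClimateSignalModel":
        survey = SurveyDataset.from_csv(survey_csv)
        sti = STITable.from_csv(sti_csv)
        atlas = None
        if atlas_csv is not None:
            if n_localities_total is None or zone_area_km2 is None:
                raise ValueError("atlas CSV needs n_localities_total and zone_area_km2")
            atlas = AtlasRecords.from_csv(atlas_csv, n_localities_total, zone_area_km2)
        classification = (ThermalClassification.from_csv(classification_csv)
                          if classification_csv is not None else None)
        target = (TemperatureSeries.from_csv(target_station_csv)
                  if target_station_csv is not None else None)
        reference = (TemperatureSeries.from_csv(reference_station_csv)
                     if reference_station_csv is not None else None)
        return cls(survey, sti, atlas=atlas, classification=classification,
                   target_station=target, reference_station=reference, **kwargs)

    @classmethod
    def from_simulation(
        cls,
        n_species: int = 60,
        delta: float = 0.0,
        seed: int = 0,
        design=None,
        effect=None,
        n_localities: int = 60,
        station_trend: float = 0.0432,
        **kwargs,
    ) -> "ClimateSignalModel":
        """Build model + synthetic inputs in one call (see `simulate`)."""
        from .simulate import (
            WarmingEffect,
            generate_atlas_records,
            generate_species_pool,
            generate_station_series,
            generate_survey,
        )

        pool = generate_species_pool(n_species, seed=child_seed(seed, "pool"))
        atlas = generate_atlas_records(pool, n_localities=n_localities,
                                       seed=child_seed(seed, "atlas"))
        if effect is None:
            effect = WarmingEffect(delta_log_abundance_per_sti_unit=delta)
        survey = generate_survey(pool, design=design, effect=effect,
                                 seed=child_seed(seed, "survey"))
        reference, target = generate_station_series(trend=station_trend,
                                                    seed=child_seed(seed, "stations"))
        return cls(survey, pool.sti_table(), atlas=atlas,
                   target_station=target, reference_station=reference, **kwargs)

    # -- fitting ---------------------------------------------------------
    def fit(
        self,
        seed: int = 0,
        n_perm_shift: int = 1000,
        n_perm_anosim: int = 999,
        n_perm_permanova: int = 999,
        n_rand_trend: int = 1000,
    ) -> "ClimateSignalResults":
        year_a, year_b = self.year_pair
        survey = self.survey

        classification = self.classification
        adequacy = None
        if classification is None:
            classification = classify_species(
                self.atlas,
                occupancy_threshold=self.occupancy_threshold,
                record_fraction=self.record_fraction,
            )
            adequacy = sampling_adequacy(self.atlas)

        observed = set(survey.species)
        with_sti = {s for s in observed if s in self.sti}
        if len(with_sti) < 0.5 * len(observed):
            raise ValueError(
                f"STI known for only {len(with_sti)}/{len(observed)} observed species; "
                "refusing to compute community temperature indices"
            )

        cti_table = cti_by_transect_year(survey.subset_years([year_a, year_b]), self.sti)
        cti_test = compare_cti_by_year(survey, self.sti, year_a, year_b)
        phenology = None
        if (len(survey.visits_of(year_a)) >= 2 and len(survey.visits_of(year_b)) >= 2):
            phenology = cti_phenology_check(survey, self.sti, year_a, year_b)

        diversity = diversity_change_table(survey, classification, year_a, year_b)
        totals = survey.subset_years([year_a, year_b]).totals_by_species_year()
        chao = {int(y): chao1(totals[y]) for y in (year_a, year_b)}

        records = records_from_survey(survey, classification, years=(year_a, year_b))
        shift_counts = shift_counts_from_records(records, year_a, year_b)
        shift_sp = monte_carlo_shift_test(records, "t_sp", year_a, year_b,
                                          n_perm=n_perm_shift,
                                          seed=child_seed(seed, "shift_sp"))
        shift_ab = monte_carlo_shift_test(records, "t_ab", year_a, year_b,
                                          n_perm=n_perm_shift,
                                          seed=child_seed(seed, "shift_ab"))

        pooled = survey.subset_years([year_a, year_b]).counts_by_transect_year()
        d_pooled = bray_curtis(pooled)
        year_labels = np.array([y for (_, y) in d_pooled.ids])
        transect_labels = np.array([t for (t, _) in d_pooled.ids])
        anosim_res = anosim(d_pooled, year_labels, n_perm=n_perm_anosim,
                            seed=child_seed(seed, "anosim"))

        pairwise = None
        try:
            visit_mat = survey.counts_by_visit([year_a, year_b])
            keep = visit_mat.sum(axis=1) > 0
            visit_mat = visit_mat[keep]
            d_visit = bray_curtis(visit_mat)
            vyear = np.array([y for (_, y, _) in d_visit.ids])
            vtransect = np.array([t for (t, _, _) in d_visit.ids])
            perma = permanova(d_visit, vyear, vtransect, n_perm=n_perm_permanova,
                              seed=child_seed(seed, "permanova"))
            pairwise = pairwise_year_within_transect(
                d_visit, vyear, vtransect, n_perm=n_perm_permanova,
                seed=child_seed(seed, "pairwise"))
        except ValueError as exc:
            logger.info("visit-level PERMANOVA unavailable (%s); "
                        "falling back to pooled transect-year samples", exc)
            perma = permanova(d_pooled, year_labels, transect_labels,
                              n_perm=n_perm_permanova,
                              seed=child_seed(seed, "permanova"))

        species_change = species_change_table(survey, classification, year_a, year_b,
                                              alpha=self.alpha)

        calibration = trend = None
        if self.target_station is not None and self.reference_station is not None:
            calibration = calibrate_stations(self.target_station, self.reference_station)
            trend = trend_with_randomization(calibration.predicted,
                                             n_rand=n_rand_trend,
                                             seed=child_seed(seed, "trend"))
        elif self.reference_station is not None:
            trend = trend_with_randomization(self.reference_station,
                                             n_rand=n_rand_trend,
                                             seed=child_seed(seed, "trend"))

        config = {
            "year_pair": list(self.year_pair),
            "occupancy_threshold": self.occupancy_threshold,
            "record_fraction": self.record_fraction,
            "alpha": self.alpha,
            "shift_alpha": self.shift_alpha,
            "n_perm_shift": n_perm_shift,
            "n_perm_anosim": n_perm_anosim,
            "n_perm_permanova": n_perm_permanova,
            "n_rand_trend": n_rand_trend,
        }
        provenance = {
            "seed": int(seed),
            "version": _version,
            "config": config,
            "config_hash": hashlib.sha256(
                json.dumps(config, sort_keys=True).encode()).hexdigest()[:16],
        }
        return ClimateSignalResults(
            model=self,
            classification=classification,
            adequacy=adequacy,
            cti_table=cti_table,
            cti_test=cti_test,
            phenology=phenology,
            diversity=diversity,
            chao=chao,
            shift_counts=shift_counts,
            shift_sp=shift_sp,
            shift_ab=shift_ab,
            anosim=anosim_res,
            permanova=perma,
            pairwise=pairwise,
            species_change=species_change,
            calibration=calibration,
            trend=trend,
            provenance=provenance,
        )


def _mc_summary(r: MonteCarloResult) -> dict[str, Any]:
    return {
        "statistic": r.statistic,
        "observed": r.observed,
        "p_two_sided": r.p_two_sided,
        "n_perm": r.n_perm,
        "seed": r.seed,
        "alpha": r.alpha,
        "significant": r.significant,
        "null_mean": float(np.mean(r.null_values)),
        "null_sd": float(np.std(r.null_values)),
        "null_q025": float(np.quantile(r.null_values, 0.025)),
        "null_q975": float(np.quantile(r.null_values, 0.975)),
    }


@dataclass
class ClimateSignalResults:
    """Fitted results of every stage of the survey analysis."""

    model: ClimateSignalModel
    classification: ThermalClassification
    adequacy: SamplingAdequacy | None
    cti_table: pd.DataFrame
    cti_test: CTIComparison
    phenology: PhenologyCheckResult | None
    diversity: pd.DataFrame
    chao: dict[int, Any]
    shift_counts: Any
    shift_sp: MonteCarloResult
    shift_ab: MonteCarloResult
    anosim: AnosimResult
    permanova: PermanovaResult
    pairwise: pd.DataFrame | None
    species_change: pd.DataFrame
    calibration: CalibrationResult | None
    trend: TrendResult | None
    provenance: dict[str, Any]

    # -- reporting -------------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        year_a, year_b = self.model.year_pair
        out: dict[str, Any] = {"provenance": self.provenance}
        out["classification"] = {
            "n_species": len(self.classification.table),
            "n_W": len(self.classification.species_in("W")),
            "n_HA": len(self.classification.species_in("HA")),
            "n_LA": len(self.classification.species_in("LA")),
        }
        if self.adequacy is not None:
            out["sampling_adequacy"] = {
                "ratios": list(self.adequacy.ratios),
                "spearman_rho": self.adequacy.spearman_rho,
                "tie_degenerate": self.adequacy.tie_degenerate,
            }
        out["cti"] = {
            "year_a": year_a,
            "year_b": year_b,
            "median_change_c": self.cti_test.median_change,
            "rank_sum": dataclasses.asdict(self.cti_test.test),
            "n_transects": len(self.cti_test.pairs),
        }
        if self.phenology is not None:
            out["cti"]["phenology_check"] = {
                "direction_preserved": self.phenology.direction_preserved,
                "trimmed_rank_sum": dataclasses.asdict(self.phenology.trimmed.test),
                "trimmed_median_change_c": self.phenology.trimmed.median_change,
            }
        out["diversity"] = self.diversity.to_dict(orient="records")
        out["chao1"] = {str(y): dataclasses.asdict(c) for y, c in self.chao.items()}
        out["shift_counts"] = dataclasses.asdict(self.shift_counts)
        out["shift_tests"] = {
            "t_sp": _mc_summary(self.shift_sp),
            "t_ab": _mc_summary(self.shift_ab),
        }
        out["anosim"] = dataclasses.asdict(self.anosim)
        out["permanova"] = self.permanova.to_frame().replace({np.nan: None}).to_dict(
            orient="records")
        if self.pairwise is not None:
            out["pairwise_year_within_transect"] = self.pairwise.replace(
                {np.inf: "inf"}).to_dict(orient="records")
        out["species_change"] = self.species_change.replace(
            {np.nan: None}).to_dict(orient="records")
        if self.calibration is not None:
            out["calibration"] = {
                "intercept": self.calibration.intercept,
                "slope": self.calibration.slope,
                "r_squared": self.calibration.r_squared,
                "n_overlap": self.calibration.n_overlap,
            }
        if self.trend is not None:
            out["trend"] = dataclasses.asdict(self.trend)
        return out

    def summary(self) -> str:
        """Human-readable multi-section report."""
        year_a, year_b = self.model.year_pair
        L = []
        L.append("Climate-change signal analysis of a repeated transect survey")
        L.append("=" * 62)
        L.append(f"years compared: {year_a} vs {year_b}   "
                 f"(seed {self.provenance['seed']}, thermoshift {self.provenance['version']})")
        c = self.to_dict()["classification"]
        L.append(f"species classified: {c['n_species']} "
                 f"(W {c['n_W']}, HA {c['n_HA']}, LA {c['n_LA']})")
        if self.adequacy is not None:
            L.append(f"atlas sampling adequacy: Spearman rho = {self.adequacy.spearman_rho:.2f}")
        for y, ch in self.chao.items():
            L.append(f"sampling efficiency {y}: {100 * ch.efficiency:.1f}% "
                     f"(S_obs {ch.s_obs}, Chao1 {ch.chao1:.1f})")
        L.append("")
        t = self.cti_test.test
        L.append(f"CTI change ({year_a} -> {year_b}): median {self.cti_test.median_change:+.3f} C, "
                 f"rank-sum W = {t.statistic_w:.1f} (n = {t.n1 + t.n2}), "
                 f"p = {t.p_two_sided:.4f} [{t.method}]")
        if self.phenology is not None:
            L.append(f"  phenology check: direction preserved = "
                     f"{self.phenology.direction_preserved}, trimmed p = "
                     f"{self.phenology.trimmed.test.p_two_sided:.4f}")
        L.append("")
        sc = self.shift_counts
        L.append(f"elevational shift (W excluded): "
                 f"L/H richness {sc.L1}/{sc.H1} -> {sc.L2}/{sc.H2}; "
                 f"abundance {sc.l1}/{sc.h1} -> {sc.l2}/{sc.h2}")
        for r in (self.shift_sp, self.shift_ab):
            L.append(f"  {r.statistic} = {r.observed:+.4f}, p = {r.p_two_sided:.4f} "
                     f"({r.n_perm} permutations; significant at p<{r.alpha}: {r.significant})")
        L.append("")
        L.append(f"ANOSIM (year groups): R = {self.anosim.r:.3f}, "
                 f"p = {self.anosim.p:.4f} ({self.anosim.n_perm} permutations)")
        for term in self.permanova.terms:
            L.append(f"PERMANOVA {term.name}: df {term.df}, SS {term.ss:.3f}, "
                     f"pseudo-F {term.pseudo_f if term.pseudo_f is None else round(term.pseudo_f, 3)}, "
                     f"p {term.p if term.p is None else round(term.p, 4)}")
        L.append(f"PERMANOVA residual: df {self.permanova.residual_df}, "
                 f"SS {self.permanova.residual_ss:.3f} (total {self.permanova.total_ss:.3f})")
        nsig = int(self.species_change["significant"].sum())
        L.append(f"species LR screen: {nsig}/{len(self.species_change)} species "
                 f"with P < {self.model.alpha}")
        if self.trend is not None:
            L.append("")
            L.append(f"temperature trend {self.trend.first_year}-{self.trend.last_year}: "
                     f"{self.trend.slope:+.4f} C/yr, total {self.trend.total_change:+.2f} C, "
                     f"randomization p = {self.trend.p_randomization:.4f}")
            if self.calibration is not None:
                L.append(f"  station calibration: intercept {self.calibration.intercept:.2f}, "
                         f"slope {self.calibration.slope:.3f}, "
                         f"R^2 = {self.calibration.r_squared:.3f} "
                         f"({self.calibration.n_overlap} overlap years)")
        return "\n".join(L)

    def save(self, out_dir) -> None:
        """Write report.json, summary.txt and one CSV per table."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
        (out / "summary.txt").write_text(self.summary() + "\n")
        self.classification.to_csv(out / "classification.csv")
        self.cti_table.to_csv(out / "cti.csv", index=False)
        self.diversity.to_csv(out / "diversity.csv", index=False)
        self.species_change.to_csv(out / "species_change.csv", index=False)
        self.permanova.to_frame().to_csv(out / "permanova.csv", index=False)
        if self.pairwise is not None:
            self.pairwise.to_csv(out / "pairwise.csv", index=False)
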