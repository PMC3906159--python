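"""Generator behaviour: determinism, encoded classes, null exchangeability."""

import numpy as np
import pandas as pd
import pytest

from thermoshift import (
    SurveyDesign,
    WarmingEffect,
    classify_species,
    compare_cti_by_year,
    generate_atlas_records,
    generate_species_pool,
    generate_station_series,
    generate_survey,
)
from thermoshift.thermal import cti_by_transect_year


SMALL_DESIGN = SurveyDesign(habitats=("h1", "h2"), transects_per_habitat=2,
                            visits=3, years=(1998, 2011))


class TestSpeciesPool:
    def test_single_species_pool_rejected(self):
        with pytest.raises(ValueError):
            generate_species_pool(1, seed=0)

    def test_degenerate_sti_range_rejected(self):
        with pytest.raises(ValueError):
            generate_species_pool(10, sti_low=12.0, sti_high=12.0, seed=0)

    def test_class_counts_and_thermal_ordering(self):
        pool = generate_species_pool(100, class_mix=(0.5, 0.5, 0.0), seed=7)
        by_class = pool.table.groupby("true_class")["sti"]
        assert by_class.count().to_dict() == {"HA": 50, "LA": 50}
        # high-altitude species are the cool-associated ones
        assert by_class.mean()["LA"] > by_class.mean()["HA"]

    def test_same_seed_identical_pool(self):
        a = generate_species_pool(40, seed=11).table
        b = generate_species_pool(40, seed=11).table
        pd.testing.assert_frame_equal(a, b)


class TestAtlasGeneration:
    def test_widespread_species_occupies_majority(self):
        pool = generate_species_pool(4, class_mix=(0.25, 0.25, 0.5), seed=3)
        atlas = generate_atlas_records(pool, n_localities=10, seed=3)
        occ = atlas.records.groupby("species_id")["locality_id"].nunique()
        for sp in pool.table.loc[pool.table["true_class"] == "W", "species_id"]:
            assert occ[sp] >= 6

    def test_high_altitude_species_mostly_above_1000m(self):
        pool = generate_species_pool(10, class_mix=(1.0, 0.0, 0.0), seed=5)
        atlas = generate_atlas_records(pool, n_localities=20, seed=5)
        frac = atlas.records.groupby("species_id")["elevation_zone"].apply(
            lambda z: (z >= 3).mean())
        assert (frac > 0.5).all()

    def test_locality_counts_track_zone_areas_perfectly(self):
        # areas chosen so apportionment is exact: counts (4,3,2,1)
        pool = generate_species_pool(5, seed=1)
        atlas = generate_atlas_records(pool, n_localities=10,
                                       zone_areas=(400, 300, 200, 100), seed=1)
        assert list(atlas.localities_per_zone()) == [4, 3, 2, 1]
        from thermoshift import sampling_adequacy
        assert sampling_adequacy(atlas).spearman_rho == pytest.approx(1.0)

    def test_ground_truth_recovered_for_every_species(self):
        pool = generate_species_pool(60, seed=21)
        atlas = generate_atlas_records(pool, seed=21)
        cls = classify_species(atlas).class_of()
        truth = pool.table.set_index("species_id")["true_class"]
        assert (cls.loc[truth.index] == truth).all()

    def test_zero_area_zone_rejected(self):
        pool = generate_species_pool(5, seed=0)
        with pytest.raises(ValueError):
            generate_atlas_records(pool, zone_areas=(1000, 0, 500, 100), seed=0)


class TestSurveyGeneration:
    def test_same_seed_identical_survey(self):
        pool = generate_species_pool(15, seed=2)
        a = generate_survey(pool, SMALL_DESIGN, WarmingEffect(0.1), seed=9).data
        b = generate_survey(pool, SMALL_DESIGN, WarmingEffect(0.1), seed=9).data
        pd.testing.assert_frame_equal(a, b)

    def test_null_cti_difference_centred_on_zero(self):
        # Monte-Carlo over replicate seeds: with delta = 0 the mean CTI
        # change between years is within 2 SE of zero.
        diffs = []
        for seed in range(200):
            pool = generate_species_pool(20, seed=seed)
            survey = generate_survey(pool, SMALL_DESIGN, WarmingEffect(0.0), seed=seed)
            table = cti_by_transect_year(survey, pool.sti_table())
            mean_by_year = table.groupby("year")["cti_c"].mean()
            diffs.append(mean_by_year[2011] - mean_by_year[1998])
        diffs = np.asarray(diffs)
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean()) < 2 * se

    def test_warming_raises_cti_in_final_year(self):
        signs = []
        for seed in range(20):
            pool = generate_species_pool(30, seed=seed)
            survey = generate_survey(pool, SMALL_DESIGN, WarmingEffect(0.3), seed=seed)
            cmp_ = compare_cti_by_year(survey, pool.sti_table(), 1998, 2011)
            signs.append(cmp_.median_change > 0)
        assert np.mean(signs) >= 0.9

    def test_poisson_limit_variance_equals_mean(self):
        pool = generate_species_pool(2, seed=4)
        design = SurveyDesign(habitats=("h",), transects_per_habitat=1,
                              visits=400, years=(1998, 2011))
        effect = WarmingEffect(0.0, baseline_mean_count=2.0, dispersion=np.inf)
        survey = generate_survey(pool, design, effect, seed=4,
                                 habitat_sd=0.0, transect_sd=0.0)
        counts = survey.counts_by_visit().reindex(
            columns=pool.table["species_id"], fill_value=0)
        ratio = counts.var(ddof=1) / counts.mean()
        assert np.allclose(ratio, 1.0, atol=0.25)

    def test_subset_year_design(self):
        pool = generate_species_pool(10, seed=6)
        design = SurveyDesign(
            habitats=("h1", "h2"), transects_per_habitat=2, visits=3,
            years=(1998, 2012),
            transect_subset_by_year={2012: ["h1_t1", "h2_t1"]},
            visits_by_year={2012: 1},
        )
        survey = generate_survey(pool, design, WarmingEffect(0.0,
                                 baseline_mean_count=3.0), seed=6)
        sub = survey.data[survey.data["year"] == 2012]
        assert set(sub["transect_id"]) == {"h1_t1", "h2_t1"}
        assert set(sub["visit"]) == {1}


class TestStationGeneration:
    def test_noiseless_trend_spans_expected_range(self):
        ref, _ = generate_station_series(years=range(1990, 2013), trend=0.05,
                                         noise_sd=0.0, seed=0)
        assert np.ptp(ref.data.to_numpy()) == pytest.approx(22 * 0.05)

    def test_noiseless_calibration_recovered_exactly(self):
        from thermoshift import calibrate_stations

        ref, tgt = generate_station_series(noise_sd=0.0, calib_intercept=2.0,
                                           calib_slope=0.5, seed=0)
        calib = calibrate_stations(tgt, ref)
        assert calib.intercept == pytest.approx(2.0, abs=1e-9)
        assert calib.slope == pytest.approx(0.5, abs=1e-12)
        assert calib.r_squared == pytest.approx(1.0)

    def test_same_seed_identical_series(self):
        a = generate_station_series(seed=13)
        b = generate_station_series(seed=13)
        pd.testing.assert_series_equal(a[0].data, b[0].data)
        pd.testing.assert_series_equal(a[1].data, b[1].data)

    def test_coverage_outside_years_rejected(self):
        with pytest.raises(ValueError):
            generate_station_series(years=range(1990, 2000),
                                    target_coverage=range(1995, 2005), seed=0)
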