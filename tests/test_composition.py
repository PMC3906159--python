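"""Bray-Curtis / ANOSIM / PERMANOVA / Poisson-LR screen, with oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from thermoshift import (
    DistanceMatrix,
    anosim,
    bray_curtis,
    holm_adjust,
    pairwise_year_within_transect,
    permanova,
    poisson_lr_by_species,
    proportional_change,
    species_change_table,
)


def random_counts(n, s, seed):
    return np.random.default_rng(seed).poisson(3.0, size=(n, s)).astype(float) + 1


class TestBrayCurtis:
    def test_identical_samples_distance_zero(self):
        d = bray_curtis(np.array([[1, 2, 3], [1, 2, 3]]))
        assert d.values[0, 1] == pytest.approx(0.0)

    def test_disjoint_samples_distance_one(self):
        d = bray_curtis(np.array([[5, 0, 0], [0, 3, 2]]))
        assert d.values[0, 1] == pytest.approx(1.0)

    def test_hand_value(self):
        d = bray_curtis(np.array([[1, 1, 0], [0, 1, 1]]))
        assert d.values[0, 1] == pytest.approx(0.5)

    def test_all_zero_sample_named_in_error(self):
        with pytest.raises(ValueError, match="bad"):
            bray_curtis(np.array([[1, 1], [0, 0]]), ids=["ok", "bad"])

    def test_matches_scipy_pdist(self):
        from scipy.spatial.distance import pdist, squareform

        X = random_counts(7, 10, 0)
        ours = bray_curtis(X).values
        ref = squareform(pdist(X, "braycurtis"))
        assert np.allclose(ours, ref)

    def test_symmetry_and_range(self):
        X = random_counts(6, 8, 1)
        d = bray_curtis(X).values
        assert np.allclose(d, d.T)
        assert (d >= 0).all() and (d <= 1).all()
        assert np.allclose(np.diag(d), 0)


class TestAnosim:
    def test_perfect_separation_gives_r_one(self):
        X = np.array([[10, 0, 0], [9, 1, 0], [8, 2, 0],
                      [0, 0, 10], [0, 1, 9], [0, 2, 8]], dtype=float)
        res = anosim(bray_curtis(X), ["a"] * 3 + ["b"] * 3, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_matches_skbio_statistic(self):
        from skbio.stats.distance import DistanceMatrix as SkDM
        from skbio.stats.distance import anosim as sk_anosim

        for seed in range(5):
            X = random_counts(8, 6, seed)
            d = bray_curtis(X)
            g = ["a", "a", "a", "a", "b", "b", "b", "b"]
            sk = sk_anosim(SkDM(d.values, ids=[str(i) for i in range(8)]),
                           pd.DataFrame({"g": g}, index=[str(i) for i in range(8)]),
                           column="g", permutations=9)
            assert anosim(d, g, n_perm=9, seed=0).r == pytest.approx(
                sk["test statistic"])

    def test_rank_based_invariance_to_monotone_transform(self):
        X = random_counts(8, 6, 3)
        d = bray_curtis(X)
        d_sq = DistanceMatrix(d.values ** 2, d.ids)
        g = ["a"] * 4 + ["b"] * 4
        r1 = anosim(d, g, n_perm=99, seed=5)
        r2 = anosim(d_sq, g, n_perm=99, seed=5)
        assert r1.r == pytest.approx(r2.r)
        assert r1.p == pytest.approx(r2.p)

    def test_null_r_centred_near_zero(self):
        rs = []
        for seed in range(30):
            X = random_counts(8, 6, 100 + seed)
            rs.append(anosim(bray_curtis(X), ["a"] * 4 + ["b"] * 4,
                             n_perm=49, seed=seed).r)
        assert abs(np.mean(rs)) < 0.1

    def test_singleton_group_rejected(self):
        X = random_counts(4, 5, 0)
        with pytest.raises(ValueError):
            anosim(bray_curtis(X), ["a", "b", "b", "b"], n_perm=9, seed=0)

    def test_bruteforce_rank_oracle_on_six_samples(self):
        X = random_counts(6, 5, 7)
        d = bray_curtis(X)
        g = np.array(["a", "a", "a", "b", "b", "b"])
        # oracle: explicit mid-ranks + group means over the 15 pairs
        pairs = list(itertools.combinations(range(6), 2))
        dist = np.array([d.values[i, j] for i, j in pairs])
        order = dist.argsort(kind="mergesort")
        ranks = np.empty(len(dist))
        ranks[order] = np.arange(1, len(dist) + 1)
        for v in np.unique(dist):
            ranks[dist == v] = ranks[dist == v].mean()
        within = np.array([g[i] == g[j] for i, j in pairs])
        r_oracle = (ranks[~within].mean() - ranks[within].mean()) / (len(pairs) / 2)
        assert anosim(d, g, n_perm=9, seed=0).r == pytest.approx(r_oracle)


class TestPermanova:
    def test_one_factor_matches_skbio(self):
        from skbio.stats.distance import DistanceMatrix as SkDM
        from skbio.stats.distance import permanova as sk_permanova

        for seed in range(5):
            X = random_counts(6, 5, 50 + seed)
            d = bray_curtis(X)
            g = ["a", "a", "a", "b", "b", "b"]
            sk = sk_permanova(SkDM(d.values, ids=[str(i) for i in range(6)]),
                              pd.DataFrame({"g": g}, index=[str(i) for i in range(6)]),
                              column="g", permutations=9)
            ours = permanova(d, np.array(g), n_perm=9, seed=0)
            assert ours.term("year").pseudo_f == pytest.approx(sk["test statistic"])

    def test_one_factor_bruteforce_ss_oracle(self):
        X = random_counts(6, 4, 11)
        d = bray_curtis(X)
        g = np.array(["a", "a", "a", "b", "b", "b"])
        n = 6
        d2 = d.values ** 2
        ss_total = sum(d2[i, j] for i in range(n) for j in range(i + 1, n)) / n
        ss_within = 0.0
        for lab in ("a", "b"):
            idx = np.where(g == lab)[0]
            ss_within += sum(d2[i, j] for i in idx for j in idx if i < j) / len(idx)
        res = permanova(d, g, n_perm=9, seed=0)
        assert res.total_ss == pytest.approx(ss_total)
        assert res.residual_ss == pytest.approx(ss_within)
        assert res.term("year").ss == pytest.approx(ss_total - ss_within)

    def test_two_factor_partition_sums_to_total(self):
        # 2 years x 3 transects x 2 replicate visits = 12 samples
        year = np.repeat(["y1", "y2"], 6)
        transect = np.tile(np.repeat(["t1", "t2", "t3"], 2), 2)
        X = random_counts(12, 8, 13)
        res = permanova(bray_curtis(X), year, transect, n_perm=19, seed=0)
        names = {t.name for t in res.terms}
        assert names == {"year", "transect", "year:transect"}
        ss_sum = sum(t.ss for t in res.terms) + res.residual_ss
        assert ss_sum == pytest.approx(res.total_ss, rel=1e-9)
        assert res.term("year").df == 1
        assert res.term("transect").df == 2
        assert res.term("year:transect").df == 2
        assert res.residual_df == 6

    def test_interaction_omitted_without_replicates(self):
        year = np.repeat(["y1", "y2"], 3)
        transect = np.tile(["t1", "t2", "t3"], 2)
        res = permanova(bray_curtis(random_counts(6, 5, 17)), year, transect,
                        n_perm=19, seed=0)
        assert {t.name for t in res.terms} == {"year", "transect"}

    def test_missing_cell_listed_in_error(self):
        year = np.array(["y1", "y1", "y2", "y2"])
        transect = np.array(["t1", "t2", "t1", "t1"])
        with pytest.raises(ValueError, match="t2"):
            permanova(bray_curtis(random_counts(4, 5, 19)), year, transect,
                      n_perm=9, seed=0)

    def test_identical_samples_degenerate(self):
        X = np.tile([1.0, 2.0, 3.0], (4, 1))
        res = permanova(bray_curtis(X), ["a", "a", "b", "b"], n_perm=9, seed=0)
        assert res.degenerate
        assert res.total_ss == 0.0

    def test_pure_transect_effect_leaves_year_null(self):
        # year p approximately uniform when only the transect factor is real
        rng = np.random.default_rng(0)
        rej = 0
        n_rep = 100
        for rep in range(n_rep):
            base = rng.uniform(1, 6, size=(3, 6))  # per-transect profiles
            X = np.vstack([rng.poisson(base[t], size=(1, 6))[0] + 1
                           for _ in range(2) for t in range(3) for _ in range(2)])
            year = np.repeat(["y1", "y2"], 6)
            transect = np.tile(np.repeat(["t1", "t2", "t3"], 2), 2)
            res = permanova(bray_curtis(X), year, transect, n_perm=99, seed=rep)
            if res.term("year").p < 0.05:
                rej += 1
        from scipy.stats import binom
        assert binom.ppf(0.005, n_rep, 0.05) <= rej <= binom.ppf(0.995, n_rep, 0.05)

    def test_seed_reproducibility(self):
        X = random_counts(8, 5, 23)
        g = ["a"] * 4 + ["b"] * 4
        a = permanova(bray_curtis(X), np.array(g), n_perm=99, seed=3)
        b = permanova(bray_curtis(X), np.array(g), n_perm=99, seed=3)
        assert a.term("year").p == b.term("year").p


class TestPairwise:
    def test_identical_compositions_not_significant(self):
        X = np.tile([2.0, 3.0, 1.0], (8, 1))
        X += np.random.default_rng(0).uniform(0, 1e-6, X.shape)  # break exact ties
        year = np.repeat(["y1", "y2"], 4)
        transect = np.array(["t1"] * 8)
        out = pairwise_year_within_transect(bray_curtis(X), year, transect,
                                            n_perm=99, seed=0)
        assert out.loc[0, "p"] > 0.5

    def test_disjoint_years_reach_exact_minimal_p(self):
        # 3 visits per year, disjoint compositions: of the C(6,3)=20 label
        # assignments only the true split and its mirror maximise F -> p=0.1
        X = np.array([[9, 1, 0], [8, 2, 0], [7, 3, 0],
                      [0, 1, 9], [0, 2, 8], [0, 3, 7]], dtype=float)
        year = np.repeat(["y1", "y2"], 3)
        transect = np.array(["t1"] * 6)
        out = pairwise_year_within_transect(bray_curtis(X), year, transect,
                                            n_perm=99, seed=0)
        assert out.loc[0, "method"] == "exact"
        assert out.loc[0, "p"] == pytest.approx(2 / 20)

    def test_lone_sample_transect_skipped(self):
        X = random_counts(6, 4, 29)
        year = np.array(["y1", "y2", "y1", "y1", "y2", "y2"])
        transect = np.array(["t1", "t1", "t2", "t2", "t2", "t2"])
        out = pairwise_year_within_transect(bray_curtis(X), year, transect,
                                            n_perm=49, seed=0)
        assert list(out["transect_id"]) == ["t2"]

    def test_holm_adjustment_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        p = np.array([0.01, 0.04, 0.03, 0.2, 0.9])
        ours = holm_adjust(p)
        ref = multipletests(p, method="holm")[1]
        assert np.allclose(ours, ref)


class TestPoissonLR:
    def test_equal_counts_no_change(self):
        assert poisson_lr_by_species(7, 7).lr == pytest.approx(0.0)

    def test_hand_value(self):
        assert poisson_lr_by_species(2, 8).lr == pytest.approx(3.8549, abs=1e-4)

    def test_extinction_case_zero_log_convention(self):
        r = poisson_lr_by_species(10, 0)
        assert r.lr == pytest.approx(2 * 10 * np.log(2))
        assert r.direction == -1
        assert r.pc == pytest.approx(-100.0)

    def test_exposure_offsets_rates(self):
        # same rate under different exposure -> no evidence of change
        assert poisson_lr_by_species(10, 20, exposure1=5, exposure2=10).lr == \
            pytest.approx(0.0)

    def test_matches_glm_oracle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        for _ in range(50):
            n1, n2 = int(rng.integers(1, 40)), int(rng.integers(1, 40))
            e1, e2 = rng.uniform(0.5, 3, size=2)
            ours = poisson_lr_by_species(n1, n2, e1, e2).lr
            y = np.array([n1, n2], dtype=float)
            X = sm.add_constant(np.array([0.0, 1.0]))
            off = np.log([e1, e2])
            full = sm.GLM(y, X, family=sm.families.Poisson(), offset=off).fit()
            null = sm.GLM(y, np.ones((2, 1)), family=sm.families.Poisson(),
                          offset=off).fit()
            assert ours == pytest.approx(2 * (full.llf - null.llf), abs=1e-6)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            poisson_lr_by_species(0, 0)


class TestProportionalChange:
    def test_extinction_is_minus_hundred(self):
        assert proportional_change(37, 0) == pytest.approx(-100.0)

    def test_no_change_is_zero(self):
        assert proportional_change(12, 12) == pytest.approx(0.0)

    def test_large_increase(self):
        assert proportional_change(100, 611) == pytest.approx(511.0)

    def test_colonization_undefined(self):
        with pytest.raises(ValueError):
            proportional_change(0, 5)


class TestSpeciesChangeTable:
    def test_table_shape_and_colonization_status(self, two_year_survey):
        extra = two_year_survey.data.iloc[:1].copy()
        extra[["species_id", "year", "count"]] = ["newcomer", 2011, 4]
        from conftest import build_survey
        survey = build_survey(pd.concat([two_year_survey.data, extra])
                              .itertuples(index=False, name=None))
        out = species_change_table(survey, year_a=1998, year_b=2011)
        row = out[out["species_id"] == "newcomer"].iloc[0]
        assert row["status"] == "colonization"
        assert np.isnan(row["pc_percent"])
        assert {"species_id", "lr", "pc_percent", "p", "p_holm"} <= set(out.columns)
        # spA was pushed up in 2011 in the fixture
        assert out.set_index("species_id").loc["spA", "pc_percent"] > 0
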