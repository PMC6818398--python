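"""Exact nonparametric tests, covariate grouping, and survival analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from repseq_compare.clonotype_io import read_metadata
from repseq_compare.cohort_stats import (
    DegenerateDataError,
    InsufficientDataError,
    compare_by_covariate,
    kaplan_meier,
    log_rank_test,
    mann_whitney_u,
    median_split,
    survival_stratification,
    wilcoxon_signed_rank,
)
from conftest import brute_force_mwu_p, brute_force_wilcoxon_p


class TestWilcoxonSignedRank:
    def test_all_positive_six_pairs(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        assert res.p_two_tailed == pytest.approx(2 / 64)
        assert res.method == "exact"

    def test_antisymmetric_differences_are_null_centered(self):
        res = wilcoxon_signed_rank([2.0, -2.0, 1.0, -1.0])
        assert res.p_two_tailed == 1.0

    def test_zero_differences_dropped(self):
        res = wilcoxon_signed_rank([0.0, 0.0, 1.0, 2.0, -3.0])
        assert res.n_effective == 3

    def test_all_zero_differences_degenerate(self):
        with pytest.raises(DegenerateDataError):
            wilcoxon_signed_rank([0.0, 0.0])

    def test_matches_brute_force_enumeration_with_ties(self):
        rng = np.random.default_rng(42)
        for _ in range(15):
            d = np.round(rng.normal(0, 2, size=rng.integers(3, 11)), 0)  # integer ties likely
            d = d[d != 0]
            if len(d) == 0:
                continue
            assert wilcoxon_signed_rank(d).p_two_tailed == pytest.approx(
                brute_force_wilcoxon_p(d), abs=1e-12
            )

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            d = rng.normal(0.3, 1, size=rng.integers(5, 12))
            ours = wilcoxon_signed_rank(d).p_two_tailed
            theirs = stats.wilcoxon(d, method="exact").pvalue
            assert ours == pytest.approx(theirs, abs=1e-12)

    def test_large_sample_normal_approximation_tracks_scipy(self):
        rng = np.random.default_rng(9)
        d = rng.normal(0.2, 1, size=60)
        ours = wilcoxon_signed_rank(d).p_two_tailed
        theirs = stats.wilcoxon(d, method="approx", correction=True).pvalue
        assert ours == pytest.approx(theirs, rel=1e-6)


class TestMannWhitneyU:
    def test_complete_separation_small_groups(self):
        res = mann_whitney_u([1, 2, 3], [10, 11, 12])
        assert res.statistic == 0.0
        assert res.p_two_tailed == pytest.approx(0.1)
        assert res.method == "exact"

    def test_identical_groups_give_p_one(self):
        assert mann_whitney_u([1, 2, 3], [1, 2, 3]).p_two_tailed == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            mann_whitney_u([], [1.0])

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(21)
        for _ in range(15):
            a = rng.normal(0, 1, size=rng.integers(2, 6))
            b = rng.normal(0.8, 1, size=rng.integers(2, 6))
            assert mann_whitney_u(a, b).p_two_tailed == pytest.approx(
                brute_force_mwu_p(a, b), abs=1e-12
            )

    def test_matches_scipy_exact(self):
        rng = np.random.default_rng(33)
        for _ in range(10):
            a = rng.normal(0, 1, size=6)
            b = rng.normal(0.5, 1, size=7)
            ours = mann_whitney_u(a, b).p_two_tailed
            theirs = stats.mannwhitneyu(a, b, method="exact").pvalue
            assert ours == pytest.approx(theirs, abs=1e-12)

    def test_tied_data_uses_corrected_normal_approximation(self):
        rng = np.random.default_rng(4)
        a = rng.integers(0, 5, size=15).astype(float)
        b = rng.integers(1, 6, size=18).astype(float)
        ours = mann_whitney_u(a, b)
        assert ours.method == "normal"
        theirs = stats.mannwhitneyu(a, b, method="asymptotic", use_continuity=True).pvalue
        assert ours.p_two_tailed == pytest.approx(theirs, rel=1e-6)


class TestCovariateComparison:
    def test_printed_cohort_age_split_sizes(self, clinical_table):
        meta = read_metadata(clinical_table)
        values = pd.Series(np.arange(15, dtype=float), index=meta["patient_id"])
        res = compare_by_covariate(values, meta, "age")
        sizes = sorted(n for n, _, _ in res.summaries.values())
        assert sizes == [6, 9]

    def test_planted_age_effect_recovered(self, clinical_table):
        meta = read_metadata(clinical_table)
        rng = np.random.default_rng(8)
        di = np.where(meta["age"] <= 60, 600, 250) + rng.normal(0, 40, size=15)
        res = compare_by_covariate(pd.Series(di, index=meta["patient_id"]), meta, "age")
        assert res.p_two_tailed < 0.05
        young = res.summaries["<= 60"]
        old = res.summaries["> 60"]
        assert young[1] > old[1]

    def test_constant_metric_gives_p_one(self, clinical_table):
        meta = read_metadata(clinical_table)
        values = pd.Series(5.0, index=meta["patient_id"])
        assert compare_by_covariate(values, meta, "age").p_two_tailed == 1.0

    def test_unknown_differentiation_excluded(self, clinical_table):
        meta = read_metadata(clinical_table)
        values = pd.Series(np.arange(15, dtype=float), index=meta["patient_id"])
        res = compare_by_covariate(values, meta, "differentiation")
        assert sum(n for n, _, _ in res.summaries.values()) == 14  # P6 unknown dropped
        assert res.test_name == "kruskal_wallis"


class TestMedianSplit:
    def test_odd_n_median_goes_low(self):
        labels = median_split(pd.Series([1.0, 2.0, 3.0], index=list("abc")))
        assert list(labels) == ["low", "low", "high"]

    def test_tied_median(self):
        labels = median_split(pd.Series([1.0, 1.0, 1.0, 5.0]))
        assert list(labels) == ["low", "low", "low", "high"]

    def test_all_equal_degenerates_to_low(self):
        assert set(median_split(pd.Series([2.0, 2.0]))) == {"low"}


class TestSurvival:
    def test_product_limit_hand_example(self):
        km = kaplan_meier([1, 2], [1, 1])
        assert km.survival_at(1) == pytest.approx(0.5)
        assert km.survival_at(2) == pytest.approx(0.0)

    def test_all_censored_curve_stays_at_one(self):
        km = kaplan_meier([3, 5, 7], [0, 0, 0])
        assert (km.table["survival"] == 1.0).all()

    def test_duplicated_cohort_invariance(self):
        t, e = [1, 2, 4, 6], [1, 0, 1, 1]
        single = kaplan_meier(t, e).table["survival"]
        double = kaplan_meier(t * 2, e * 2).table["survival"]
        assert np.allclose(single, double)

    def test_matches_lifelines_product_limit(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(13)
        t = rng.exponential(10, 40).round(1) + 0.1
        e = rng.integers(0, 2, 40)
        km = kaplan_meier(t, e)
        fitter = lifelines.KaplanMeierFitter().fit(t, e)
        for time in np.unique(t):
            assert km.survival_at(time) == pytest.approx(
                float(fitter.predict(time)), abs=1e-9
            )

    def test_log_rank_identical_groups_is_null(self):
        res = log_rank_test([1, 2, 3], [1, 1, 0], [1, 2, 3], [1, 1, 0])
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_log_rank_toy_hand_computation(self):
        # events at t=1 (A), t=2 (B), t=4 (B); A censors at t=3.
        # O_A=1, E_A=1/2+1/3=5/6, V=1/4+2/9=17/36 -> chi2=(1/6)^2/(17/36)=1/17
        res = log_rank_test([1, 3], [1, 0], [2, 4], [1, 1])
        assert res.chi_square == pytest.approx(1 / 17, abs=1e-12)
        assert res.observed_a == 1 and res.expected_a == pytest.approx(5 / 6)

    def test_log_rank_matches_lifelines(self):
        lifelines_stats = pytest.importorskip("lifelines.statistics")
        rng = np.random.default_rng(29)
        ta = rng.exponential(10, 25).round(1) + 0.1
        tb = rng.exponential(5, 30).round(1) + 0.1
        ea = rng.integers(0, 2, 25)
        eb = rng.integers(0, 2, 30)
        ours = log_rank_test(ta, ea, tb, eb)
        theirs = lifelines_stats.logrank_test(ta, tb, ea, eb)
        assert ours.chi_square == pytest.approx(theirs.test_statistic, rel=1e-9)
        assert ours.p_value == pytest.approx(theirs.p_value, rel=1e-9)

    def test_no_events_degenerate(self):
        with pytest.raises(DegenerateDataError):
            log_rank_test([1, 2], [0, 0], [3], [0])

    def test_stratification_recovers_planted_hazard_ratio(self):
        rng = np.random.default_rng(55)
        n = 40
        di = pd.Series(rng.uniform(10, 500, n), index=[f"P{i}" for i in range(n)])
        high = (di > di.median()).to_numpy()
        hazard = np.where(high, 0.2, 0.02)
        t_event = rng.exponential(1 / hazard)
        t_cens = rng.uniform(20, 60, n)
        meta = pd.DataFrame(
            {
                "patient_id": di.index,
                "os_time": np.minimum(t_event, t_cens),
                "os_event": (t_event <= t_cens).astype(int),
            }
        )
        strat = survival_stratification(di, meta)
        assert strat.log_rank is not None and strat.log_rank.p_value < 0.01
        # the high-DI group dies faster
        mid = float(np.median(meta["os_time"]))
        assert strat.curves["high"].survival_at(mid) < strat.curves["low"].survival_at(mid)
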