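"""2x2 contingency machinery: odds ratios, CIs, chi-square, dichotomies."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from onsetscan import (
    DegenerateInputError,
    SimulationConfig,
    bivariate_exposure_analysis,
    contingency_analysis,
    contingency_from_table,
    dichotomize_onset,
    pairwise_exposure_association,
    simulate_cohort,
    table_from_frequencies,
)


class TestDichotomize:
    def test_boundary_at_age_six(self):
        early = dichotomize_onset([2, 5.9, 6, 10])
        np.testing.assert_array_equal(early, [1.0, 1.0, 0.0, 0.0])

    def test_missing_propagates(self):
        early = dichotomize_onset([3.0, np.nan, 12.0])
        assert np.isnan(early[1])

    def test_onset_below_two_is_an_invariant_violation(self):
        with pytest.raises(DegenerateInputError):
            dichotomize_onset([1.0, 4.0, 8.0])

    def test_default_cohort_early_fraction_near_target(self):
        cohort = simulate_cohort(SimulationConfig(n_subjects=50_000, seed=4))
        early = dichotomize_onset(cohort.onset_years)
        assert np.nanmean(early) == pytest.approx(0.31, abs=0.03)

    def test_degenerate_all_late_margin_raises_downstream(self, rng):
        early = np.zeros(100)
        exposed = (rng.random(100) < 0.5).astype(float)
        with pytest.raises(DegenerateInputError, match="margin"):
            contingency_analysis(exposed, early)


class TestContingency:
    def test_hand_computed_example(self):
        res = contingency_from_table([[30, 70], [20, 80]])
        assert res.odds_ratio == pytest.approx((30 * 80) / (70 * 20), abs=1e-12)
        assert res.log_or_se == pytest.approx(
            np.sqrt(1 / 30 + 1 / 70 + 1 / 20 + 1 / 80), abs=1e-12)
        lo, hi = res.ci95
        assert lo == pytest.approx(res.odds_ratio * np.exp(-1.959964 * res.log_or_se),
                                   rel=1e-5)
        assert hi == pytest.approx(res.odds_ratio * np.exp(1.959964 * res.log_or_se),
                                   rel=1e-5)

    def test_independence_table(self):
        res = contingency_from_table([[25, 25], [25, 25]])
        assert res.odds_ratio == 1.0
        assert res.chi2 == 0.0
        assert res.p == 1.0

    def test_zero_cell_gets_haldane_correction(self):
        res = contingency_from_table([[0, 40], [20, 60]])
        assert res.haldane_adjusted
        assert np.isfinite(res.odds_ratio) and res.odds_ratio > 0
        assert np.isfinite(res.log_or_se)

    def test_zero_margin_rejected(self):
        with pytest.raises(DegenerateInputError, match="margin"):
            contingency_from_table([[0, 0], [20, 60]])

    def test_published_frequency_reconstructions(self):
        """2x2 tables rebuilt from printed exposure frequencies reproduce
        the printed odds ratios to one decimal."""
        carpet = contingency_from_table(table_from_frequencies(71, 64, 0.31, 1002))
        assert round(carpet.odds_ratio, 1) == 1.4
        smoking = contingency_from_table(table_from_frequencies(43, 56, 0.31, 1050))
        assert round(smoking.odds_ratio, 1) == 0.6
        direct = contingency_from_table(table_from_frequencies(27, 45, 0.31, 377))
        assert round(direct.odds_ratio, 1) == 0.5

    def test_chi2_matches_brute_force_expected_counts(self, rng):
        for _ in range(200):
            t = rng.integers(5, 120, size=(2, 2)).astype(float)
            res = contingency_from_table(t)
            rowsum, colsum, n = t.sum(1), t.sum(0), t.sum()
            expected = np.outer(rowsum, colsum) / n
            chi2 = float(((t - expected) ** 2 / expected).sum())
            assert res.chi2 == pytest.approx(chi2, abs=1e-10)
            assert res.p == pytest.approx(stats.chi2.sf(chi2, 1), abs=1e-12)

    def test_agrees_with_statsmodels_table2x2(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        for _ in range(20):
            t = rng.integers(5, 80, size=(2, 2))
            res = contingency_from_table(t)
            ref = sm.stats.Table2x2(t)
            assert res.odds_ratio == pytest.approx(ref.oddsratio, rel=1e-10)
            lo, hi = ref.oddsratio_confint(0.05)
            assert res.ci95[0] == pytest.approx(lo, rel=1e-6)
            assert res.ci95[1] == pytest.approx(hi, rel=1e-6)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.tuples(*[st.integers(min_value=1, max_value=200)] * 4))
    def test_or_equivariance_under_label_swaps(self, cells):
        a, b, c, d = (float(v) for v in cells)
        base = contingency_from_table([[a, b], [c, d]])
        both = contingency_from_table([[d, c], [b, a]])  # swap rows AND cols
        rows = contingency_from_table([[c, d], [a, b]])  # swap rows only
        assert both.odds_ratio == pytest.approx(base.odds_ratio, rel=1e-12)
        assert rows.odds_ratio == pytest.approx(1.0 / base.odds_ratio, rel=1e-12)
        assert rows.ci95[0] == pytest.approx(1.0 / base.ci95[1], rel=1e-9)
        assert rows.chi2 == pytest.approx(base.chi2, rel=1e-12)

    def test_ci_coverage_at_known_odds_ratio(self):
        """95% Woolf interval covers the true OR in ~95% of random tables."""
        rng = np.random.default_rng(8)
        true_or = 2.0
        p1, p2 = 0.4, (0.4 / 0.6 / true_or) / (1 + 0.4 / 0.6 / true_or)
        n_row = 200
        covered = 0
        n_tables = 2000
        for _ in range(n_tables):
            a = rng.binomial(n_row, p1)
            c = rng.binomial(n_row, p2)
            t = [[max(a, 1), max(n_row - a, 1)], [max(c, 1), max(n_row - c, 1)]]
            res = contingency_from_table(t)
            covered += res.ci95[0] <= true_or <= res.ci95[1]
        assert covered / n_tables == pytest.approx(0.95, abs=0.015)


class TestBivariate:
    def test_duplicated_exposure_reduces_to_single_exposure(self, rng):
        n = 600
        x = (rng.random(n) < 0.5).astype(float)
        early = (rng.random(n) < 0.3 + 0.1 * x).astype(float)
        joint = bivariate_exposure_analysis(x, x, early)
        single = contingency_analysis(x, early)
        np.testing.assert_array_equal(joint.table, single.table)
        assert joint.odds_ratio == pytest.approx(single.odds_ratio)

    def test_two_independent_risks_compound(self):
        """Both-exposed vs neither-exposed OR exceeds each single OR."""
        rng = np.random.default_rng(3)
        wins = 0
        n_seeds = 20
        for _ in range(n_seeds):
            n = 5000
            x1 = (rng.random(n) < 0.5).astype(float)
            x2 = (rng.random(n) < 0.5).astype(float)
            logit = -1.2 + np.log(1.5) * x1 + np.log(1.5) * x2
            early = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
            joint = bivariate_exposure_analysis(x1, x2, early).odds_ratio
            s1 = contingency_analysis(x1, early).odds_ratio
            s2 = contingency_analysis(x2, early).odds_ratio
            wins += joint > max(s1, s2)
        assert wins / n_seeds >= 0.9

    def test_disjoint_exposures_have_no_both_present_margin(self, rng):
        n = 200
        x1 = np.zeros(n)
        x1[:100] = 1.0
        x2 = 1.0 - x1  # never co-occur
        early = (rng.random(n) < 0.4).astype(float)
        with pytest.raises(DegenerateInputError):
            bivariate_exposure_analysis(x1, x2, early)


class TestPairwise:
    def test_pair_count_is_combinatorial(self, default_cohort):
        pairs = pairwise_exposure_association(default_cohort.catalog,
                                              default_cohort)
        n_binary = len(default_cohort.catalog.binary_names())
        assert len(pairs) == n_binary * (n_binary - 1) // 2

    def test_coupled_pair_or_recovered_at_large_n(self):
        cohort = simulate_cohort(SimulationConfig(n_subjects=50_000, seed=6))
        res = contingency_analysis(cohort.exposure("carpet"),
                                   cohort.exposure("brick_house"))
        assert res.odds_ratio == pytest.approx(3.2, rel=0.1)

    def test_or_symmetric_in_pair_order(self, default_cohort):
        a = contingency_analysis(default_cohort.exposure("carpet"),
                                 default_cohort.exposure("dog"))
        b = contingency_analysis(default_cohort.exposure("dog"),
                                 default_cohort.exposure("carpet"))
        assert a.odds_ratio == pytest.approx(b.odds_ratio, rel=1e-12)

    def test_independent_pair_ci_covers_one(self):
        rng = np.random.default_rng(13)
        n, seeds = 400, 300
        covered = 0
        for _ in range(seeds):
            x1 = (rng.random(n) < 0.5).astype(float)
            x2 = (rng.random(n) < 0.4).astype(float)
            res = contingency_analysis(x1, x2)
            covered += res.ci95[0] <= 1.0 <= res.ci95[1]
        rate = covered / seeds
        se = np.sqrt(0.05 * 0.95 / seeds)
        assert abs(rate - 0.95) < 3.5 * se
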