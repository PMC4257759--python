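"""Per-exposure regression scan, atopy adjustment and descriptives."""

import numpy as np
import pytest
from scipy import stats

from onsetscan import (
    DegenerateInputError,
    SimulationConfig,
    atopy_adjusted_regression,
    descriptives,
    exposure_regression,
    scan_exposures,
    simulate_cohort,
)
from onsetscan.transforms import AdjustedOnset


def _adjusted(y):
    """Wrap a plain outcome vector for direct use of the regression ops."""
    y = np.asarray(y, dtype=float)
    return AdjustedOnset(subject_ids=np.arange(len(y)), z=y, residual=y,
                         design=np.ones((len(y), 1)), design_names=["intercept"])


class TestExposureRegression:
    def test_null_t_rarely_exceeds_four(self):
        # vectorized closed form for 500 independent null draws
        rng = np.random.default_rng(5)
        n, reps = 1000, 500
        exceed = 0
        for _ in range(reps):
            x = (rng.random(n) < 0.4).astype(float)
            y = rng.normal(size=n)
            r = exposure_regression(_adjusted(y), x)
            exceed += abs(r.t_stat) > 4
        assert exceed <= 0.01 * reps

    def test_recovers_planted_slope(self, rng):
        n = 1000
        x = (rng.random(n) < 0.5).astype(float)
        y = 0.3 * x + rng.normal(size=n)
        r = exposure_regression(_adjusted(y), x)
        beta_hat = r.t_stat * np.sqrt(1.0 / (n * x.var()))  # t * SE ~ slope
        se = 1.0 / np.sqrt(n * x.var())
        assert beta_hat == pytest.approx(0.3, abs=3 * se)
        assert r.t_stat > 0  # positive t = later onset in exposed

    def test_binary_regression_matches_two_sample_t_test(self, rng):
        """Slope t on a 0/1 regressor equals the pooled two-sample t."""
        n = 200
        x = (rng.random(n) < 0.45).astype(float)
        y = rng.normal(size=n) + 0.2 * x
        r = exposure_regression(_adjusted(y), x)
        t2, p2 = stats.ttest_ind(y[x == 1], y[x == 0], equal_var=True)
        assert abs(abs(r.t_stat) - abs(t2)) < 1e-10
        assert abs(r.p_uncorrected - p2) < 1e-10

    def test_perfect_fit_is_capped_with_warning(self, rng, caplog):
        y = rng.normal(size=50)
        with caplog.at_level("WARNING"):
            r = exposure_regression(_adjusted(y), y)
        assert np.isfinite(r.t_stat)
        assert r.p_uncorrected == 0.0
        assert "degenerate" in caplog.text.lower()

    def test_constant_exposure_rejected(self, rng):
        with pytest.raises(DegenerateInputError, match="flat"):
            exposure_regression(_adjusted(rng.normal(size=40)),
                                np.ones(40), name="flat")

    def test_too_few_joint_subjects_rejected(self, rng):
        x = np.full(40, np.nan)
        x[:5] = [0, 1, 0, 1, 0]
        with pytest.raises(DegenerateInputError):
            exposure_regression(_adjusted(rng.normal(size=40)), x)


class TestScan:
    def test_seventeen_exposures_give_seventeen_results(self, default_cohort):
        results = scan_exposures(default_cohort)
        assert len(results) == 17
        assert {r.exposure for r in results} == set(default_cohort.catalog.names)
        # output sorted by |t| descending
        t_abs = [abs(r.t_stat) for r in results]
        assert t_abs == sorted(t_abs, reverse=True)

    def test_planted_exposures_occupy_top_ranks(self):
        """The five planted default effects dominate the scan ranking."""
        planted = {"carpet", "brick_house", "chest_illness",
                   "father_smoker", "father_smoking_direct"}
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            results = scan_exposures(simulate_cohort(SimulationConfig(seed=seed)))
            top5 = {r.exposure for r in results[:5]}
            hits += len(top5 & planted)
        assert hits / (5 * n_seeds) >= 0.8

    def test_all_missing_column_skipped_with_log(self, default_cohort, caplog):
        cohort = default_cohort
        ex = cohort.exposures.copy()
        ex["dog"] = np.nan
        broken = type(cohort)(phenotypes=cohort.phenotypes, exposures=ex,
                              genotypes=None, catalog=cohort.catalog)
        with caplog.at_level("INFO"):
            results = scan_exposures(broken)
        assert len(results) == 16
        assert "dog" in caplog.text

    def test_scan_invariant_to_subject_order(self, default_cohort):
        cohort = default_cohort
        rng = np.random.default_rng(0)
        perm = rng.permutation(cohort.n)
        shuffled = type(cohort)(
            phenotypes=cohort.phenotypes.iloc[perm],
            exposures=cohort.exposures.iloc[perm],
            genotypes=None, catalog=cohort.catalog)
        a = {r.exposure: r.t_stat for r in scan_exposures(cohort)}
        b = {r.exposure: r.t_stat for r in scan_exposures(shuffled)}
        for name in a:
            assert a[name] == pytest.approx(b[name], abs=1e-9)


class TestAtopyAdjustment:
    def test_independent_atopy_barely_moves_t(self, rng):
        n = 2000
        x = (rng.random(n) < 0.5).astype(float)
        atopy = (rng.random(n) < 0.8).astype(float)
        y = 0.2 * x + rng.normal(size=n)
        adj = _adjusted(y)
        t_adj = atopy_adjusted_regression(adj, x, atopy).t_stat
        # same subset, unadjusted
        t_raw = exposure_regression(adj, x).t_stat
        assert abs(t_adj - t_raw) < 0.2

    def test_fully_mediated_effect_vanishes_after_adjustment(self, rng):
        # exposure -> atopy -> outcome; no direct exposure effect
        n = 2000
        x = (rng.random(n) < 0.5).astype(float)
        p_atopy = np.where(x == 1, 0.9, 0.3)
        atopy = (rng.random(n) < p_atopy).astype(float)
        y = 0.6 * atopy + rng.normal(size=n)
        r = atopy_adjusted_regression(_adjusted(y), x, atopy)
        # exposure coefficient should be within 3 SE of zero
        assert abs(r.t_stat) < 3.0

    def test_empty_overlap_rejected(self, rng):
        n = 40
        x = np.where(np.arange(n) < 20, 1.0, np.nan)
        atopy = np.where(np.arange(n) < 20, np.nan, 1.0)
        with pytest.raises(DegenerateInputError):
            atopy_adjusted_regression(_adjusted(rng.normal(size=n)), x, atopy)


class TestDescriptives:
    def test_same_distribution_sexes_give_uniformish_kruskal_p(self):
        rng = np.random.default_rng(11)
        pvals = []
        for _ in range(200):
            cohort = None
            n = 150
            onset = np.round(rng.lognormal(2.3, 0.9, n)) + 2.0
            sex = np.where(rng.random(n) < 0.5, "male", "female")
            h, p = stats.kruskal(onset[sex == "male"], onset[sex == "female"])
            pvals.append(p)
        # KS against uniform; rank tests on tied data are approximately uniform
        stat, p = stats.kstest(pvals, "uniform")
        assert p > 0.01

    def test_kruskal_matches_brute_force_rank_computation(self):
        g1 = np.array([2.0, 3, 3, 4, 5, 5, 6, 7, 8, 9])
        g2 = np.array([10.0, 11, 12, 12, 13, 14, 15, 16, 17, 18])
        h_scipy, _ = stats.kruskal(g1, g2)
        # brute force: H = (12 / (N (N+1))) * sum n_i (Rbar_i - Rbar)^2,
        # with the standard tie correction
        pooled = np.concatenate([g1, g2])
        ranks = stats.rankdata(pooled)
        N = len(pooled)
        h = 12.0 / (N * (N + 1)) * sum(
            len(g) * (ranks[idx].mean() - (N + 1) / 2) ** 2
            for g, idx in ((g1, slice(0, 10)), (g2, slice(10, 20))))
        _, counts = np.unique(pooled, return_counts=True)
        h /= 1.0 - np.sum(counts ** 3 - counts) / (N ** 3 - N)
        assert h_scipy == pytest.approx(h, abs=1e-10)

    def test_full_descriptives_on_default_cohort(self, default_cohort):
        d = descriptives(default_cohort)
        assert d.overall.n == 1085
        assert set(d.by_study) == {1, 2}
        # generator conditions: females ~61%, early onset ~30%,
        # males earlier than females
        assert 55 < d.overall.percent_female < 67
        assert 24 < d.overall.percent_early_onset < 38
        assert d.overall.median_onset_male < d.overall.median_onset_female
        assert d.kruskal_p < 1e-4
        assert (d.by_study[2].percent_early_onset
                > d.by_study[1].percent_early_onset)

    def test_single_sex_cohort_skips_comparison(self, default_cohort, caplog):
        ph = default_cohort.phenotypes.copy()
        ph["sex"] = "female"
        cohort = type(default_cohort)(phenotypes=ph,
                                      exposures=default_cohort.exposures,
                                      genotypes=None,
                                      catalog=default_cohort.catalog)
        with caplog.at_level("INFO"):
            d = descriptives(cohort)
        assert d.kruskal_p is None
        assert "skipped" in caplog.text
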