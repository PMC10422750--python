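"""Normality-gated comparisons, Fisher's exact, reductions, power."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from plaquekit import (
    PowerSpec,
    TrialSimSpec,
    build_trial_tables,
    fisher_balance,
    percent_reduction,
    sample_size_two_groups,
    select_and_run_independent,
    select_and_run_paired,
    simulate_trial,
)
from plaquekit.trial_stats import timelines_to_frame


class TestIndependent:
    def test_normal_samples_take_t_branch(self):
        # perfectly Gaussian-shaped samples (normal quantiles), same location
        a = 50 + 10 * stats.norm.ppf((np.arange(24) + 0.5) / 24)
        b = 50 + 10 * stats.norm.ppf((np.arange(26) + 0.5) / 26)
        rep = select_and_run_independent(a, b)
        assert rep.test_used == "student_t"
        assert rep.p_value > 0.05

    def test_identical_nonnormal_samples_null_midpoint(self, rng):
        a = rng.exponential(1.0, 30)
        rep = select_and_run_independent(a, a.copy())
        assert rep.test_used == "mann_whitney"
        assert rep.p_value == 1.0

    def test_exponential_sample_routes_to_mann_whitney(self):
        """Shapiro–Wilk has high power against an exponential at n=30, so
        the nonparametric branch is taken in the vast majority of draws."""
        chosen = 0
        n_rep = 200
        for seed in range(n_rep):
            r = np.random.default_rng(seed)
            rep = select_and_run_independent(
                r.exponential(1.0, 30), r.normal(1.0, 1.0, 30)
            )
            chosen += rep.test_used == "mann_whitney"
        assert chosen / n_rep > 0.9

    def test_type_one_error_calibrated(self):
        """Under the null (one shared generator) the gated pipeline rejects
        at close to its nominal 5% level."""
        rng = np.random.default_rng(77)
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            a = rng.normal(46.6, 18.9, 24)
            b = rng.normal(46.6, 18.9, 26)
            rejections += select_and_run_independent(a, b).significant
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_degenerate_samples_flagged(self):
        rep = select_and_run_independent([5.0] * 5, [5.0] * 6)
        assert "degenerate" in rep.note
        assert rep.p_value == 1.0

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            select_and_run_independent([1.0, 2.0], [1.0, 2.0, 3.0])


class TestPaired:
    def test_zero_differences_reported_nonsignificant(self):
        vals = [3.0, 4.0, 5.0, 6.0, 7.0]
        rep = select_and_run_paired(vals, vals)
        assert rep.p_value == 1.0
        assert not rep.significant
        assert "degenerate" in rep.note

    def test_uniform_shift_is_maximal_signed_rank(self, rng):
        t1 = rng.normal(30, 10, 20)
        t2 = t1 + 4.0  # constant shift: zero-variance differences -> Wilcoxon
        rep = select_and_run_paired(t1, t2)
        assert rep.test_used == "wilcoxon"
        assert rep.p_value < 0.001

    def test_detects_day4_to_day8_increase_at_bonferroni_level(self):
        """Calibrated group-A timelines show the end-of-trial visible-area
        increase at the corrected threshold in essentially every draw."""
        significant = 0
        n_rep = 40
        for seed in range(n_rep):
            frame = timelines_to_frame(simulate_trial(TrialSimSpec(seed=seed)))
            sub = frame[frame.group == "A"].sort_values("subject_id")
            rep = select_and_run_paired(
                sub[sub.hours == 96].visible_area_abs.values,
                sub[sub.hours == 192].visible_area_abs.values,
            )
            significant += rep.significant
        assert significant / n_rep >= 0.95

    def test_unmatched_ids_rejected(self):
        with pytest.raises(ValueError, match="unmatched ids"):
            select_and_run_paired([1.0, 2.0, 3.0], [2.0, 3.0, 4.0],
                                  paired_ids=["s1", "s1", "s2"])

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            select_and_run_paired([1.0, 2.0, 3.0], [1.0, 2.0])

    def test_bonferroni_threshold_displayed_as_printed(self, rng):
        rep = select_and_run_paired(rng.normal(0, 1, 10), rng.normal(5, 1, 10))
        assert rep.significance_threshold == 0.016


class TestFisher:
    def test_gender_balance_table(self):
        # 10/6 men, 14/20 women across the two groups
        rep = fisher_balance([[10, 6], [14, 20]])
        assert rep.test_used == "fisher_exact"
        assert rep.p_value == pytest.approx(0.227, abs=0.005)
        assert not rep.significant

    def test_perfect_balance(self):
        assert fisher_balance([[5, 5], [5, 5]]).p_value == 1.0

    def test_diagonal_table_highly_significant(self):
        assert fisher_balance([[10, 0], [0, 10]]).p_value < 0.001

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            fisher_balance([[0, 0], [5, 5]])

    def test_agrees_with_hypergeometric_enumeration(self, rng):
        """Two-sided Fisher p = sum of hypergeometric probabilities of all
        tables (same margins) no more likely than the observed one."""
        for _ in range(40):
            a, b, c, d = (int(x) for x in rng.integers(0, 11, 4))
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            n, r1, c1 = a + b + c + d, a + b, a + c
            dist = stats.hypergeom(n, r1, c1)
            support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
            pmf = dist.pmf(support)
            expected = pmf[pmf <= dist.pmf(a) * (1 + 1e-9)].sum()
            got = fisher_balance([[a, b], [c, d]]).p_value
            assert got == pytest.approx(expected, abs=1e-8)


class TestPercentReduction:
    @pytest.mark.parametrize(
        "test_rate, ref_rate, expected",
        [
            (0.31, 0.43, 28),
            (0.23, 0.49, 53),
            (0.34, 0.66, 48),
            (0.39, 0.66, 41),
            (0.23, 0.36, 36),
            (0.20, 0.31, 35),
            (0.34, 0.60, 43),
            (0.5, 0.5, 0),
        ],
    )
    def test_reduction_arithmetic(self, test_rate, ref_rate, expected):
        assert percent_reduction(test_rate, ref_rate) == expected

    def test_half_rounds_away_from_zero(self):
        assert percent_reduction(0.755, 1.0) == 25  # 24.5 -> 25
        assert percent_reduction(1.245, 1.0) == -25  # -24.5 -> -25

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_reduction(0.3, 0.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        rate=st.floats(0.01, 2.0),
        ref=st.floats(0.01, 2.0),
        scale=st.floats(0.1, 50.0),
    )
    def test_scale_invariance(self, rate, ref, scale):
        assert percent_reduction(rate, ref) == percent_reduction(
            rate * scale, ref * scale
        )


class TestSampleSize:
    def test_reference_design_needs_26_per_group(self):
        assert sample_size_two_groups(PowerSpec(0.80, 0.05, 0.80)) == 26

    def test_vanishing_power_demand_gives_minimal_n(self):
        assert sample_size_two_groups(PowerSpec(0.80, 0.05, 1e-9)) == 2

    def test_monotone_in_effect_size_and_power(self):
        sizes = [sample_size_two_groups(PowerSpec(d, 0.05, 0.80))
                 for d in (0.5, 0.8, 1.0, 2.0)]
        assert sizes == sorted(sizes, reverse=True)
        powers = [sample_size_two_groups(PowerSpec(0.8, 0.05, p))
                  for p in (0.5, 0.8, 0.95)]
        assert powers == sorted(powers)

    def test_invalid_effect_size_rejected(self):
        with pytest.raises(ValueError):
            PowerSpec(0.0, 0.05, 0.8)

    @pytest.mark.parametrize("d", [0.8, 2.0])
    def test_agrees_with_monte_carlo_power_oracle(self, d):
        """The noncentral-t sample size matches a brute-force simulation of
        two-sample t-tests to within one subject."""
        n_star = sample_size_two_groups(PowerSpec(d, 0.05, 0.80))
        rng = np.random.default_rng(5150)
        reps = 40_000

        def mc_power(n):
            a = rng.normal(0.0, 1.0, (reps, n))
            b = rng.normal(d, 1.0, (reps, n))
            p = stats.ttest_ind(a, b, axis=1).pvalue
            return (p < 0.05).mean()

        candidates = range(max(2, n_star - 3), n_star + 4)
        mc_n = next(n for n in candidates if mc_power(n) >= 0.80)
        assert abs(mc_n - n_star) <= 1


class TestBuildTrialTables:
    def test_emits_all_contrasts(self, default_timelines):
        report = build_trial_tables(default_timelines)
        assert len(report.independent) == 13  # 1 baseline + 6 per later visit
        assert len(report.paired_a) == len(report.paired_b) == 7
        assert report.group_sizes == {"A": 24, "B": 26}
        for rep in report.independent + report.paired_a + report.paired_b:
            assert 0.0 <= rep.p_value <= 1.0

    def test_null_rates_give_near_zero_reduction(self):
        spec = TrialSimSpec(seed=2)
        means = dict(spec.growth_rate_means)
        sds = dict(spec.growth_rate_sds)
        for phase in (1, 2):  # identical generators in both groups
            means[("B", phase)] = means[("A", phase)]
            sds[("B", phase)] = sds[("A", phase)]
        # SE of the group-mean rate ratio is ~1.3% at n=2000, so a null
        # reduction beyond +/-5 points would signal a real asymmetry
        tls = simulate_trial(
            TrialSimSpec(seed=2, growth_rate_means=means, growth_rate_sds=sds,
                         n_group_a=2000, n_group_b=2000)
        )
        report = build_trial_tables(tls)
        assert abs(report.reductions["phase1_visible_abs_A_vs_B"]) <= 5

    def test_calibrated_simulation_recovers_headline_reduction(self):
        tls = simulate_trial(TrialSimSpec(n_group_a=500, n_group_b=500, seed=8))
        report = build_trial_tables(tls)
        assert abs(report.reductions["phase1_visible_abs_A_vs_B"] - 26) <= 5

    def test_missing_timepoint_rejected(self):
        tls = simulate_trial(TrialSimSpec(seed=4, n_group_a=4, n_group_b=4))
        tls[0].records.pop(192.0)
        with pytest.raises(ValueError, match="missing"):
            build_trial_tables(tls)
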