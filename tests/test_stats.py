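"""Screening rule, test-selection tree, correlations and sensitivity analysis."""

import itertools

import numpy as np
import pandas as pd
import pytest

from eggms.stats import (
    PowerQuery,
    ScreeningForm,
    choose_test,
    compare_levels,
    compare_trials,
    gtsssp_screen,
    paired_t_power,
    rmanova_power,
    sensitivity_paired_t,
    sensitivity_rmanova,
    simulate_paired_t_power,
    spearman,
)


def _form(diffs):
    pre = tuple(0.0 for _ in range(17))
    post = tuple(float(d) for d in diffs) + tuple(0.0 for _ in range(17 - len(diffs)))
    return ScreeningForm(pre=pre, post=post)


class TestGtssspScreen:
    def test_single_difference_above_five_fails(self):
        res = gtsssp_screen(_form([6]))
        assert not res.passed
        assert any("> 5" in r for r in res.reasons)

    def test_three_differences_above_three_fail(self):
        res = gtsssp_screen(_form([4, 4, 4]))
        assert not res.passed
        assert any("difference > 3" in r for r in res.reasons)

    def test_all_small_differences_pass(self):
        assert gtsssp_screen(_form([3, 3, 3, 3])).passed

    def test_boundary_difference_of_exactly_five_passes(self):
        assert gtsssp_screen(_form([5])).passed

    def test_two_large_plus_one_moderate(self):
        # two diffs of 4 do not trigger the simultaneity rule
        assert gtsssp_screen(_form([4, 4])).passed

    def test_malformed_form_rejected(self):
        with pytest.raises(ValueError):
            ScreeningForm(pre=(0.0,) * 16, post=(0.0,) * 17)
        with pytest.raises(ValueError):
            ScreeningForm(pre=(0.0,) * 17, post=(11.0,) + (0.0,) * 16)


class TestChooseTest:
    def test_three_normal_levels_choose_rmanova(self):
        rng = np.random.default_rng(0)
        data = rng.normal(0, 1, size=(17, 3))
        plan = choose_test(data)
        assert plan.test == "rm_anova"
        assert plan.posthoc == "bonferroni_t"
        assert plan.mauchly_p is not None

    def test_heavy_tailed_levels_choose_friedman(self):
        rng = np.random.default_rng(1)
        data = rng.standard_cauchy(size=(17, 3)) ** 3
        plan = choose_test(data)
        assert plan.test == "friedman"
        assert plan.posthoc == "bonferroni_wilcoxon"

    def test_two_normal_levels_choose_paired_t(self):
        rng = np.random.default_rng(2)
        data = rng.normal(0, 1, size=(17, 2))
        assert choose_test(data).test == "paired_t"

    def test_two_heavy_tailed_levels_choose_wilcoxon(self):
        rng = np.random.default_rng(3)
        base = rng.normal(0, 1, size=17)
        data = np.column_stack([base, base + rng.standard_cauchy(17) ** 3])
        assert choose_test(data).test == "wilcoxon"

    def test_missing_values_rejected(self):
        data = np.array([[1.0, 2.0], [3.0, np.nan], [1.0, 1.0]])
        with pytest.raises(ValueError, match="unequal subject sets"):
            choose_test(data)

    def test_deterministic_given_data(self):
        rng = np.random.default_rng(4)
        data = rng.normal(0, 1, size=(10, 3))
        assert choose_test(data) == choose_test(data)


class TestCompareLevels:
    def test_identical_values_give_p_one_no_posthoc(self):
        data = np.tile(np.arange(5, dtype=float)[:, None], (1, 3))
        out = compare_levels(data)
        assert out.p == 1.0
        assert out.posthoc == ()

    def test_strong_effect_detected_with_posthoc(self):
        rng = np.random.default_rng(5)
        base = rng.normal(0, 1, size=(17, 1))
        data = base + rng.normal(0, 0.3, size=(17, 3)) + np.array([0.0, 2.0, 0.0])
        out = compare_levels(data)
        assert out.p < 0.05
        assert len(out.posthoc) == 3
        assert all(ph["p_corrected"] >= ph["p_raw"] for ph in out.posthoc)
        assert all(ph["p_corrected"] <= 1.0 for ph in out.posthoc)

    def test_type_one_error_of_adaptive_harness(self):
        """Null cohorts rejected at alpha=0.05 close to the nominal rate.

        Quick version (200 cohorts) of the calibration run in the acceptance
        suite at 1000 cohorts.
        """
        rng = np.random.default_rng(6)
        rejections = 0
        reps = 200
        for _ in range(reps):
            data = rng.normal(0, 1, size=(17, 3))
            rejections += compare_levels(data).significant[0.05]
        assert 0.02 <= rejections / reps <= 0.09


class TestCompareTrials:
    def _table(self, values_by_segment, n=6):
        rows = []
        for s in range(n):
            for seg, vals in values_by_segment.items():
                rows.append({"subject": f"s{s}", "segment": seg, "df_cpm": vals[s]})
        return pd.DataFrame(rows)

    def test_report_structure_and_missing_subject_dropped(self):
        rng = np.random.default_rng(7)
        segs = ["trial1", "trial2", "trial3", "trial2A", "trial2B"]
        table = self._table({seg: rng.normal(3, 0.2, 7) for seg in segs}, n=7)
        # remove one subject's trial3 row -> dropped from the 3-level comparison
        table = table[~((table.subject == "s0") & (table.segment == "trial3"))]
        report = compare_trials(table)
        assert set(report.outcomes["df_cpm"]) == {"trials", "parts"}
        assert any("s0" in d for d in report.dropped)

    def test_too_few_subjects_rejected(self):
        segs = ["trial1", "trial2", "trial3", "trial2A", "trial2B"]
        table = self._table({seg: [1.0, 2.0] for seg in segs}, n=2)
        with pytest.raises(ValueError, match="fewer than 3"):
            compare_trials(table)


class TestSpearman:
    def test_monotone_sequences(self):
        x = np.arange(5, dtype=float)
        r, _ = spearman(x, x + 3)
        assert r == pytest.approx(1.0)
        r, _ = spearman(x, -x)
        assert r == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # d^2 = (1,1,1,1,0), sum 4: rho = 1 - 6*4/(5*24) = 0.8
        r, _ = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert r == pytest.approx(0.8)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant input"):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_agrees_with_rank_formula_on_all_permutations(self):
        """Exhaustive check against 1 - 6*sum(d^2)/(n(n^2-1)) for n=5."""
        x = np.arange(5, dtype=float)
        for perm in itertools.permutations(range(5)):
            y = np.asarray(perm, dtype=float)
            d2 = np.sum((x - y) ** 2)  # both already ranks 0..4
            expected = 1 - 6 * d2 / (5 * 24)
            r, _ = spearman(x, y)
            assert r == pytest.approx(expected, abs=1e-12)


class TestSensitivity:
    def test_rmanova_minimal_effect_matches_published_design(self):
        q = PowerQuery(n=17, k=3, alpha=0.05, power=0.80, rho=0.5, eps=1.0)
        assert round(sensitivity_rmanova(q), 2) == 0.09

    def test_paired_t_minimal_effect_matches_published_design(self):
        q = PowerQuery(n=17, alpha=0.05, power=0.80)
        assert round(sensitivity_paired_t(q), 2) == 0.12

    def test_paired_t_monte_carlo_power_at_returned_effect(self):
        q = PowerQuery(n=17)
        eta = sensitivity_paired_t(q)
        f = np.sqrt(eta / (1 - eta))
        emp = simulate_paired_t_power(2 * f, q, reps=5000, seed=42)
        assert emp == pytest.approx(0.80, abs=0.02)

    @pytest.mark.parametrize("sens,kw", [
        (sensitivity_rmanova, {"k": 3}),
        (sensitivity_paired_t, {}),
    ])
    def test_effect_size_decreases_with_n(self, sens, kw):
        vals = [sens(PowerQuery(n=n, **kw)) for n in (10, 17, 30, 100)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_large_n_limit(self):
        assert sensitivity_rmanova(PowerQuery(n=10**6, k=3)) < 1e-4

    def test_power_at_zero_effect_equals_alpha(self):
        q = PowerQuery(n=17)
        assert paired_t_power(0.0, q) == pytest.approx(q.alpha, abs=1e-6)
        assert rmanova_power(0.0, PowerQuery(n=17, k=3)) == pytest.approx(0.05, abs=1e-6)

    def test_unreachable_power_rejected(self):
        with pytest.raises(ValueError, match="unreachable"):
            sensitivity_paired_t(PowerQuery(n=2, power=0.999, alpha=1e-6))


class TestTrialComparisonPower:
    def test_df_shift_detected_in_most_synthetic_cohorts(self):
        """A 0.5 cpm DF rise during the driving trial is found by the harness.

        Simulation-based power check at reduced scale: 60 cohorts of 17
        subjects, trial values computed through the full generator+features
        path on 10-min trials.  The omnibus test must reject in >=80%.
        """
        from eggms.features import compute_features
        from eggms.preprocess import bandpass_filter
        from eggms.synthetic import EpisodeSpec, SimConfig, cohort_configs, generate_egg, segment_map

        hits = 0
        reps = 60
        for rep in range(reps):
            template = SimConfig(
                trial_durations=(600.0, 600.0, 600.0), part_split=(270.0, 60.0, 270.0),
                noise_sd_uv=20.0,
                episodes=(EpisodeSpec(start_s=600.0, end_s=1200.0, amp_gain=1.0,
                                      freq_shift_cpm=0.5, press_rate_per_min=0.0),),
            )
            cohort = cohort_configs(17, seed=1000 + rep, template=template)
            rows = np.empty((17, 3))
            for i, cfg in enumerate(cohort):
                rec = bandpass_filter(generate_egg(cfg))
                x = rec.samples[0]
                for j in range(3):
                    rows[i, j] = compute_features(x[1200 * j:1200 * (j + 1)], rec.acq).df_cpm
            hits += compare_levels(rows).significant[0.05]
        assert hits / reps >= 0.8


class TestCrossChecks:
    def test_rm_anova_agrees_with_statsmodels(self):
        """Our pingouin-backed RMANOVA path matches statsmodels AnovaRM."""
        from statsmodels.stats.anova import AnovaRM

        rng = np.random.default_rng(8)
        data = rng.normal(0, 1, size=(17, 3)) + np.array([0.0, 0.6, 0.1])
        out = compare_levels(data)
        assert out.plan.test == "rm_anova"
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(17), 3),
            "level": np.tile(np.arange(3), 17),
            "y": data.ravel(),
        })
        sm = AnovaRM(long, depvar="y", subject="subject", within=["level"]).fit()
        assert out.statistic == pytest.approx(float(sm.anova_table["F Value"].iloc[0]), rel=1e-6)
        if not out.plan.use_gg:
            assert out.p == pytest.approx(float(sm.anova_table["Pr > F"].iloc[0]), abs=1e-9)

    def test_analytic_rmanova_power_matches_simulation(self):
        """Noncentral-F power agrees with the data-generating simulation."""
        q = PowerQuery(n=17, k=3)
        f = 0.35
        analytic = rmanova_power(f, q)
        emp = __import__("eggms.stats", fromlist=["simulate_rmanova_power"]).simulate_rmanova_power(
            f, q, reps=5000, seed=3)
        assert emp == pytest.approx(analytic, abs=0.02)
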