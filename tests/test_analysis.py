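"""Exact tests, group summaries, mixed models, and sample-size formulas."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from maptrial.analysis import (
    LMMSpec,
    TwoByTwo,
    daily_group_means,
    fisher_exact_two_sided,
    fit_lmm,
    sample_size_two_means,
    sample_size_two_proportions,
    summarize_groups,
    wilcoxon_rank_sum,
)
from maptrial.errors import ContractError


def fisher_enumeration_oracle(a, b, c, d):
    """Exact-rational two-sided Fisher p by exhaustive table enumeration."""
    row = a + b
    col = a + c
    n = a + b + c + d

    def prob(k):
        return Fraction(math.comb(col, k) * math.comb(n - col, row - k),
                        math.comb(n, row))

    observed = prob(a)
    total = Fraction(0)
    for k in range(max(0, row + col - n), min(row, col) + 1):
        if prob(k) <= observed:
            total += prob(k)
    return float(total)


class TestFisherExact:
    @pytest.mark.parametrize(
        "a, b, c, d",
        [(3, 1, 17, 16), (4, 2, 16, 15), (2, 0, 18, 17), (1, 1, 19, 16)],
    )
    def test_matches_enumeration_oracle_on_pilot_tables(self, a, b, c, d):
        p = fisher_exact_two_sided(TwoByTwo(a, b, c, d))
        assert p == pytest.approx(fisher_enumeration_oracle(a, b, c, d), rel=1e-9)

    def test_matches_oracle_and_scipy_on_random_tables(self, rng):
        for _ in range(60):
            a, b, c, d = (int(v) for v in rng.integers(0, 16, size=4))
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            p = fisher_exact_two_sided(TwoByTwo(a, b, c, d))
            assert p == pytest.approx(fisher_enumeration_oracle(a, b, c, d), rel=1e-7)
            assert p == pytest.approx(
                stats.fisher_exact([[a, b], [c, d]])[1], rel=1e-7
            )
            assert 0.0 < p <= 1.0

    def test_invariant_under_simultaneous_row_and_column_swap(self, rng):
        for _ in range(30):
            a, b, c, d = (int(v) for v in rng.integers(0, 12, size=4))
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            assert fisher_exact_two_sided(TwoByTwo(a, b, c, d)) == pytest.approx(
                fisher_exact_two_sided(TwoByTwo(d, c, b, a)), rel=1e-12
            )

    def test_degenerate_margins_give_p_one(self):
        assert fisher_exact_two_sided(TwoByTwo(0, 0, 18, 17)) == 1.0
        assert fisher_exact_two_sided(TwoByTwo(3, 2, 0, 0)) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ContractError):
            TwoByTwo(-1, 0, 5, 5)


class TestWilcoxonRankSum:
    def test_exact_enumeration_small_samples(self):
        # most extreme split of 3 vs 3: p = 2 / C(6,3) = 0.1
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_samples_central(self):
        p = wilcoxon_rank_sum([1.0, 2.5, 3.0, 4.5], [1.5, 2.0, 3.5, 4.0])
        assert p >= 0.9

    def test_exact_and_asymptotic_branches_agree(self, rng):
        x = rng.normal(0, 1, size=10)
        y = rng.normal(0.5, 1, size=10)
        exact = float(
            stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        )
        assert wilcoxon_rank_sum(x, y) == pytest.approx(exact)
        approx = float(
            stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic"
            ).pvalue
        )
        assert abs(exact - approx) < 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ContractError):
            wilcoxon_rank_sum([], [1.0])


class TestSummarizeGroups:
    def toy_frame(self):
        return pd.DataFrame(
            {
                "arm": ["standard", "standard", "individualized", "individualized"],
                "event": [True, False, False, False],
                "metric": [10.0, 20.0, 5.0, 7.0],
            }
        )

    def test_hand_checked_medians_and_counts(self):
        table = summarize_groups(
            self.toy_frame(),
            arm_col="arm",
            binary_cols=["event"],
            continuous_cols=["metric"],
            arms=("standard", "individualized"),
        )
        assert len(table) == 2
        event_row = table[table.variable == "event"].iloc[0]
        assert event_row["standard"] == "1/2 (50%)"
        metric_row = table[table.variable == "metric"].iloc[0]
        assert metric_row["standard"] == "15.0 [12.5-17.5]"
        assert metric_row["individualized"] == "6.0 [5.5-6.5]"

    def test_binary_p_is_fisher(self):
        table = summarize_groups(
            self.toy_frame(), arm_col="arm", binary_cols=["event"],
            arms=("standard", "individualized"),
        )
        expected = fisher_exact_two_sided(TwoByTwo(1, 0, 1, 2))
        assert table.iloc[0]["p"] == pytest.approx(expected)

    def test_all_missing_column_emits_marker_row(self):
        df = self.toy_frame().assign(gone=np.nan)
        table = summarize_groups(
            df, arm_col="arm", continuous_cols=["gone"],
            arms=("standard", "individualized"),
        )
        assert table.iloc[0]["standard"] == "-"
        assert math.isnan(table.iloc[0]["p"])


def lmm_dataset(rng, n_patients=60, effect=-10.0, time_slope=0.0, sd_intercept=4.0,
                sd_noise=3.0):
    rows = []
    for i in range(n_patients):
        treat = i % 2
        intercept = 20.0 + rng.normal(0, sd_intercept)
        delay = rng.uniform(0.2, 1.5)
        for day in range(1, 6):
            rows.append(
                {
                    "patient_id": f"P{i:03d}",
                    "treatment": treat,
                    "days_t0_to_randomization": delay,
                    "days_since_randomization": float(day),
                    "pct_deficit": intercept
                    + effect * treat
                    + time_slope * day
                    + rng.normal(0, sd_noise),
                }
            )
    return pd.DataFrame(rows)


class TestFitLmm:
    def test_recovers_injected_treatment_effect(self, rng):
        data = lmm_dataset(rng, n_patients=60, effect=-10.0)
        table = fit_lmm(data, LMMSpec(outcome="pct_deficit"))
        row = table.loc["treatment"]
        assert row["ci_low"] <= -10.0 <= row["ci_high"]
        assert row["estimate"] == pytest.approx(-10.0, abs=3.0)

    def test_balanced_no_trend_matches_mean_difference(self, rng):
        data = lmm_dataset(rng, n_patients=40, effect=-6.0, sd_intercept=0.01)
        table = fit_lmm(data, LMMSpec(outcome="pct_deficit"))
        means = data.groupby("treatment")["pct_deficit"].mean()
        # without random-intercept variance the fit reduces to OLS-like means
        assert table.loc["treatment", "estimate"] == pytest.approx(
            means[1] - means[0], abs=1.0
        )

    def test_too_few_participants_rejected(self, rng):
        data = lmm_dataset(rng, n_patients=3)
        with pytest.raises(ContractError):
            fit_lmm(data, LMMSpec(outcome="pct_deficit"))


class TestSampleSize:
    def test_phase_three_total(self):
        total = sample_size_two_proportions(
            p1=0.20, p2=0.14, alpha=0.05, power=0.80, attrition=0.025
        )
        assert total == 1260

    def test_no_attrition_total(self):
        assert sample_size_two_proportions(0.20, 0.14) == 1229

    def test_monotone_in_effect_and_power(self):
        wide = sample_size_two_proportions(0.20, 0.10)
        narrow = sample_size_two_proportions(0.20, 0.14)
        assert wide < narrow
        low_power = sample_size_two_proportions(0.20, 0.14, power=0.7)
        assert low_power <= narrow

    def test_equal_proportions_diverge(self):
        with pytest.raises(ContractError):
            sample_size_two_proportions(0.2, 0.2)

    def test_two_means_pilot_inputs(self):
        per_group, total = sample_size_two_means(delta=8.0, sd=9.0)
        assert (per_group, total) == (20, 40)

    def test_doubling_sd_quadruples_n(self):
        n1, _ = sample_size_two_means(delta=8.0, sd=9.0)
        n2, _ = sample_size_two_means(delta=8.0, sd=18.0)
        assert n2 == 80  # ceil(4 * 19.867)

    def test_zero_delta_diverges(self):
        with pytest.raises(ContractError):
            sample_size_two_means(delta=0.0, sd=9.0)


class TestDailyGroupMeans:
    def test_constant_outcome_zero_width_ci(self):
        df = pd.DataFrame(
            {"day": [1] * 4, "arm": ["a"] * 2 + ["b"] * 2, "y": [5.0] * 4}
        )
        out = daily_group_means(df, "y")
        assert (out["ci_high"] - out["ci_low"]).abs().max() == pytest.approx(0.0)

    def test_hand_checked_t_interval(self):
        values = [10.0, 12.0, 14.0, 16.0]
        df = pd.DataFrame({"day": [1] * 4, "arm": ["a"] * 4, "y": values})
        out = daily_group_means(df, "y").iloc[0]
        mean = np.mean(values)
        half = stats.t.ppf(0.975, 3) * np.std(values, ddof=1) / 2.0
        assert out["mean"] == pytest.approx(mean)
        assert out["ci_low"] == pytest.approx(mean - half)
        assert out["ci_high"] == pytest.approx(mean + half)

    def test_singleton_cell_missing_ci_and_absent_days(self):
        df = pd.DataFrame({"day": [1, 3], "arm": ["a", "a"], "y": [5.0, 6.0]})
        out = daily_group_means(df, "y")
        assert set(out["day"]) == {1, 3}
        assert out["ci_low"].isna().all()
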