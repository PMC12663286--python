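"""Statistical routines against independent textbook-formula oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from thermacup.errors import ConfigurationError, DegenerateSampleError, InvalidArgumentError
from thermacup import stats


def t_test_oracle(x, mu=0.0, alpha=0.05):
    """Hand formulas: t, p, CI for the one-sample t-test."""
    x = np.asarray(x, float)
    n = len(x)
    mean, sd = x.mean(), x.std(ddof=1)
    t = (mean - mu) / (sd / np.sqrt(n))
    p = 2 * sps.t.sf(abs(t), n - 1)
    half = sps.t.ppf(1 - alpha / 2, n - 1) * sd / np.sqrt(n)
    return t, p, (mean - half, mean + half)


def anova_oracle(samples):
    """Hand formulas: between/within mean squares."""
    all_values = np.concatenate(samples)
    grand = all_values.mean()
    k, n = len(samples), len(all_values)
    ss_between = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)
    f = (ss_between / (k - 1)) / (ss_within / (n - k))
    return f, sps.f.sf(f, k - 1, n - k)


class TestOneSampleT:
    def test_symmetric_sample_gives_zero_statistic(self):
        res = stats.one_sample_t([-1.0, 0.0, 1.0])
        assert res.statistic == pytest.approx(0)
        assert res.p_value == pytest.approx(1)

    def test_hand_computed_example(self):
        res = stats.one_sample_t([1.0, 2.0, 3.0, 4.0])
        assert res.statistic == pytest.approx(2.5 / (np.std([1, 2, 3, 4], ddof=1) / 2), abs=1e-9)
        assert res.statistic == pytest.approx(3.872983, abs=1e-5)

    def test_matches_textbook_oracle_on_random_samples(self, rng):
        for _ in range(20):
            x = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2), rng.integers(5, 40))
            mu = rng.uniform(-0.5, 0.5)
            res = stats.one_sample_t(x, mu=mu)
            t, p, (lo, hi) = t_test_oracle(x, mu)
            assert res.statistic == pytest.approx(t, abs=1e-9)
            assert res.p_value == pytest.approx(p, abs=1e-9)
            assert res.ci_low == pytest.approx(lo, abs=1e-9)
            assert res.ci_high == pytest.approx(hi, abs=1e-9)
            assert res.ci_low <= res.estimate <= res.ci_high

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateSampleError):
            stats.one_sample_t([2.0, 2.0, 2.0])
        with pytest.raises(InvalidArgumentError):
            stats.one_sample_t([1.0])

    def test_type_i_error_calibration(self):
        """Null rejection rate at alpha=0.05 within the binomial 95% band."""
        rng = np.random.default_rng(2024)
        rejections = sum(
            stats.one_sample_t(rng.normal(0, 1, 35)).p_value < 0.05 for _ in range(1000)
        )
        assert 0.036 <= rejections / 1000 <= 0.064


class TestPearsonFisher:
    def test_perfect_line_flags_degenerate_ci(self):
        x = np.arange(10.0)
        res = stats.pearson_fisher(x, 2 * x + 1)
        assert res.r == 1.0
        assert res.degenerate_ci

    def test_printed_overall_interval(self):
        lo, hi = stats.fisher_ci(0.338, 245)
        assert lo == pytest.approx(0.221, abs=0.002)
        assert hi == pytest.approx(0.445, abs=0.002)

    def test_printed_stratum_interval_and_p(self):
        lo, hi = stats.fisher_ci(-0.421, 21)
        assert lo == pytest.approx(-0.721, abs=0.002)
        assert hi == pytest.approx(0.013, abs=0.002)
        assert stats.pearson_p_value(-0.421, 21) == pytest.approx(0.057, abs=0.002)

    def test_matches_closed_form_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 60))
            x = rng.normal(size=n)
            y = 0.4 * x + rng.normal(size=n)
            res = stats.pearson_fisher(x, y)
            r = np.corrcoef(x, y)[0, 1]
            t = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
            z = np.arctanh(r)
            half = sps.norm.ppf(0.975) / np.sqrt(n - 3)
            assert res.r == pytest.approx(r, abs=1e-12)
            assert res.p_value == pytest.approx(2 * sps.t.sf(abs(t), n - 2), abs=1e-9)
            assert res.ci_low == pytest.approx(np.tanh(z - half), abs=1e-9)
            assert res.ci_high == pytest.approx(np.tanh(z + half), abs=1e-9)
            assert res.ci_low <= res.r <= res.ci_high

    def test_ci_width_shrinks_with_n(self):
        widths = [np.diff(stats.fisher_ci(0.3, n))[0] for n in (10, 100, 1000, 100000)]
        assert all(a > b for a, b in zip(widths, widths[1:]))

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateSampleError):
            stats.pearson_fisher([1, 1, 1, 1], [1, 2, 3, 4])


class TestCorrelationAnalysis:
    @pytest.fixture()
    def table(self):
        """Tiny cohort table with delta_E constructed from delta_T."""
        rng = np.random.default_rng(5)
        rows = []
        cats = ["Intermediate", "IntermediateMid"]
        for i in range(8):
            cat = cats[i % 2]
            for minute in range(8):
                dt = rng.normal(-0.2, 0.4)
                for region in ("Peri-ROI", "ROI Edge", "ROI Center"):
                    rows.append(dict(subject_id=f"S{i}", modality="temperature", region=region,
                                     minute=minute, delta=dt, eumelanin_category=cat))
                rows.append(dict(subject_id=f"S{i}", modality="erythema", region=None,
                                 minute=minute, delta=1.0 + 2.0 * dt + rng.normal(0, 0.05),
                                 eumelanin_category=cat))
        return pd.DataFrame(rows)

    def test_constructed_correlation_is_strong(self, table):
        res = stats.correlation_analysis(table)
        assert res[0].stratum == "all"
        assert res[0].n == 8 * 7
        assert res[0].r > 0.9

    def test_strata_sizes_partition_overall(self, table):
        res = stats.correlation_analysis(table, stratify_by="eumelanin_category")
        assert sum(r.n for r in res[1:]) == res[0].n

    def test_small_stratum_flagged_not_dropped(self, table):
        t2 = table.copy()
        t2.loc[t2["subject_id"] == "S0", "eumelanin_category"] = "EumelaninHigh"
        t2 = t2[(t2["subject_id"] != "S0") | (t2["minute"] == 1)]
        res = stats.correlation_analysis(t2, stratify_by="eumelanin_category")
        flagged = [r for r in res if r.stratum == "EumelaninHigh"]
        assert flagged and flagged[0].insufficient


class TestOneWayAnova:
    def test_identical_groups_give_zero_f(self):
        res = stats.one_way_anova([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert res.statistic == pytest.approx(0)
        assert res.p_value == pytest.approx(1)

    def test_two_group_example_matches_hand_formula(self):
        values = np.array([1.0, 2.0, 4.0, 5.0])
        res = stats.one_way_anova(values, ["a", "a", "b", "b"])
        f, p = anova_oracle([values[:2], values[2:]])
        assert res.statistic == pytest.approx(f, abs=1e-9)
        assert res.p_value == pytest.approx(p, abs=1e-9)
        assert res.df == (1.0, 2.0)

    def test_f_equals_t_squared_for_two_groups(self, rng):
        for _ in range(10):
            a, b = rng.normal(0, 1, 12), rng.normal(0.4, 1, 15)
            f = stats.one_way_anova(np.r_[a, b], ["a"] * 12 + ["b"] * 15).statistic
            t = sps.ttest_ind(a, b).statistic
            assert f == pytest.approx(t**2, abs=1e-9)

    def test_single_or_empty_group_rejected(self):
        with pytest.raises(InvalidArgumentError):
            stats.one_way_anova([1, 2, 3], ["a", "a", "a"])
        with pytest.raises(InvalidArgumentError):
            stats.one_way_anova([1, 2, 3], ["a", "a", "b"])

    def test_type_i_error_calibration(self):
        rng = np.random.default_rng(4242)
        groups = np.repeat(["a", "b", "c"], 12)
        rejections = sum(
            stats.one_way_anova(rng.normal(0, 1, 36), groups).p_value < 0.05
            for _ in range(1000)
        )
        assert 0.036 <= rejections / 1000 <= 0.064


class TestSummariesAndClassifiers:
    def test_group_summary_reproduces_table_rows(self, noise_free_results):
        summ = noise_free_results.erythema_group_summary
        assert summ.loc["darker", "mean"] == pytest.approx(1.11, abs=1e-9)
        assert summ.loc["lighter", "mean"] == pytest.approx(3.80, abs=1e-9)

    def test_single_row_sd_is_na(self):
        df = pd.DataFrame({"v": [1.0], "g": ["a"]})
        out = stats.group_summary(df, "v", "g")
        assert np.isnan(out.loc["a", "sd"])

    def test_overall_mean_is_pooled_weighted_mean(self, rng):
        df = pd.DataFrame({"v": rng.normal(size=30), "g": rng.choice(list("abc"), 30)})
        out = stats.group_summary(df, "v", "g")
        groups = out.drop(index="__all__")
        assert out.loc["__all__", "mean"] == pytest.approx(
            stats.pooled_weighted_mean(groups["mean"], groups["n"]), abs=1e-12
        )

    @pytest.mark.parametrize(
        "means,ns,expected",
        [(((1.11, 3.80)), (30, 5), 1.49), ((1.29, 3.80), (30, 5), 1.65), ((1.02, 3.59), (30, 5), 1.39)],
    )
    def test_weighted_combination_of_group_means(self, means, ns, expected):
        assert round(stats.pooled_weighted_mean(means, ns), 2) == expected

    def test_pooled_mean_validation(self):
        with pytest.raises(InvalidArgumentError):
            stats.pooled_weighted_mean([1.0, 2.0], [3])

    @pytest.mark.parametrize("level,group", [(6, "darker"), (7, "darker"), (10, "darker"), (5, "lighter"), (1, "lighter")])
    def test_mst_grouping(self, level, group):
        assert stats.classify_mst_group(level) == group

    @pytest.mark.parametrize("level", [0, 11, 5.5])
    def test_mst_out_of_range(self, level):
        with pytest.raises(InvalidArgumentError):
            stats.classify_mst_group(level)

    @pytest.mark.parametrize(
        "mi,category",
        [(20, "EumelaninLow"), (25, "IntermediateLow"), (56, "IntermediateMid"),
         (99.9, "IntermediateHigh"), (105, "EumelaninHigh")],
    )
    def test_eumelanin_bins(self, mi, category):
        assert stats.classify_eumelanin(mi) == category

    def test_eumelanin_threshold_validation(self):
        with pytest.raises(ConfigurationError):
            stats.classify_eumelanin(50, thresholds=(25, 60, 50, 70, 100))
        with pytest.raises(ConfigurationError):
            stats.classify_eumelanin(50, thresholds=(20, 40, 50, 70, 100))

    @pytest.mark.parametrize("bmi,category", [(22, "normal"), (25.0, "overweight"), (29.9, "overweight"), (31, "obese")])
    def test_bmi_bins(self, bmi, category):
        assert stats.classify_bmi(bmi) == category

    def test_bmi_validation(self):
        with pytest.raises(InvalidArgumentError):
            stats.classify_bmi(0)
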