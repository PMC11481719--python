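import numpy as np
import pandas as pd
import pytest
from scipy import stats

import fearscope as fs


def make_long(data, subjects_per_group=None):
    """data[group][within] = list of per-subject values."""
    rows = []
    for g, within in data.items():
        levels = list(within)
        n = len(within[levels[0]])
        for i in range(n):
            for lev in levels:
                rows.append({"subject_id": f"{g}{i}", "between_factor": g,
                             "within_factor": lev, "value": within[lev][i]})
    return pd.DataFrame(rows)


class TestGrubbs:
    def test_no_outlier_in_tight_sample(self):
        kept, removed = fs.grubbs_recurrent([1, 2, 3, 4, 5], alpha=0.05)
        assert removed == []
        assert kept.tolist() == [1, 2, 3, 4, 5]
        # G = 2/sqrt(2.5) ~ 1.265 below the n=5 critical value ~1.715
        g = 2 / np.sqrt(2.5)
        assert g < fs.grubbs_critical_value(5, 0.05)

    def test_extreme_point_removed_first(self):
        kept, removed = fs.grubbs_recurrent([1, 2, 3, 4, 100], alpha=0.05)
        assert removed[0] == 4
        assert 100 not in kept

    def test_symmetric_sample_untouched(self):
        x = [-2, -1, 0, 1, 2]
        kept, removed = fs.grubbs_recurrent(x)
        assert removed == [] and kept.tolist() == x

    def test_at_most_k_removals_for_k_outliers(self, rng):
        x = np.concatenate([rng.normal(0, 0.1, 30), [50.0, -60.0]])
        _, removed = fs.grubbs_recurrent(x, alpha=0.05)
        assert set(removed) <= {30, 31}
        assert len(removed) == 2

    def test_critical_value_formula(self):
        # published two-sided critical value for n=10, alpha=0.05 is 2.290
        assert fs.grubbs_critical_value(10, 0.05) == pytest.approx(2.290, abs=0.005)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            fs.grubbs_recurrent([1.0, 2.0])


class TestChecks:
    def test_gaussian_sample_rarely_rejected(self):
        rejections = 0
        for seed in range(40):
            x = np.random.default_rng(seed).normal(size=80)
            out = fs.normality_and_variance_checks({"g": x})
            rejections += out["shapiro_p"]["g"] < 0.05
        assert rejections <= 7  # ~5% expected

    def test_heavy_tailed_sample_rejected(self):
        hits = 0
        for seed in range(20):
            x = np.random.default_rng(seed).standard_t(df=1, size=50)
            out = fs.normality_and_variance_checks({"g": x})
            hits += out["shapiro_p"]["g"] < 0.05
        assert hits >= 15

    def test_levene_calibrated_on_equal_variances(self):
        low = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            out = fs.normality_and_variance_checks(
                {"a": rng.normal(size=40), "b": rng.normal(size=40)})
            low += out["levene_p"] < 0.05
        assert low <= 7

    def test_degenerate_group_flagged(self):
        out = fs.normality_and_variance_checks({"a": np.ones(10),
                                                "b": np.arange(10.0)})
        assert np.isnan(out["shapiro_p"]["a"])
        assert out["flags"]["a"] == "degenerate"


def manual_mixed_anova_2x2(table):
    """Hand sums-of-squares decomposition for a balanced 2 (between) x 2
    (within) mixed design; the independent oracle for rm_anova_2way."""
    wide = table.pivot_table(index=["subject_id", "between_factor"],
                             columns="within_factor", values="value").reset_index()
    groups = sorted(table.between_factor.unique())
    levels = sorted(table.within_factor.unique())
    n = wide.groupby("between_factor").size().iloc[0]
    k = len(levels)
    grand = table.value.mean()
    subj_means = wide[levels].mean(axis=1)
    group_means = table.groupby("between_factor").value.mean()
    level_means = table.groupby("within_factor").value.mean()
    cell_means = table.groupby(["between_factor", "within_factor"]).value.mean()

    ss_between_subjects = k * ((subj_means - grand) ** 2).sum()
    ss_group = n * k * ((group_means - grand) ** 2).sum()
    ss_subj_within = ss_between_subjects - ss_group
    ss_within_level = n * len(groups) * ((level_means - grand) ** 2).sum()
    ss_cells = n * sum((cell_means[g, w] - grand) ** 2
                       for g in groups for w in levels)
    ss_interaction = ss_cells - ss_group - ss_within_level
    ss_total = ((table.value - grand) ** 2).sum()
    ss_error_within = (ss_total - ss_between_subjects - ss_within_level
                       - ss_interaction)

    df_group, df_within = len(groups) - 1, k - 1
    df_subj = len(groups) * (n - 1)
    df_err = df_subj * df_within
    f_group = (ss_group / df_group) / (ss_subj_within / df_subj)
    f_within = (ss_within_level / df_within) / (ss_error_within / df_err)
    f_inter = (ss_interaction / (df_group * df_within)) / (ss_error_within / df_err)
    return {"between": f_group, "within": f_within, "interaction": f_inter,
            "ss_total": ss_total,
            "ss_parts": ss_between_subjects + ss_within_level + ss_interaction
            + ss_error_within}


class TestRMAnova:
    def test_matches_hand_decomposition_on_2x2(self):
        table = make_long({
            "f": {"early": [3.1, 2.8, 3.6, 2.9], "late": [4.0, 3.7, 4.4, 3.9]},
            "m": {"early": [2.2, 2.6, 2.1, 2.4], "late": [2.3, 2.8, 2.2, 2.6]},
        })
        aov = fs.rm_anova_2way(table)
        oracle = manual_mixed_anova_2x2(table)
        got = {r.source: r.F for r in aov.itertuples()}
        assert got["between"] == pytest.approx(oracle["between"], rel=1e-10)
        assert got["within"] == pytest.approx(oracle["within"], rel=1e-10)
        assert got["interaction"] == pytest.approx(oracle["interaction"], rel=1e-10)

    def test_sums_of_squares_additive(self):
        table = make_long({
            "f": {"a": [1.0, 2.0, 1.5], "b": [2.0, 2.5, 2.2]},
            "m": {"a": [1.2, 1.9, 1.4], "b": [1.1, 1.8, 1.6]},
        })
        oracle = manual_mixed_anova_2x2(table)
        assert oracle["ss_parts"] == pytest.approx(oracle["ss_total"], rel=1e-12)

    def test_null_simulation_rarely_significant(self):
        hits = np.zeros(3)
        n_rep = 60
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            table = make_long({
                "f": {"a": rng.normal(size=6), "b": rng.normal(size=6)},
                "m": {"a": rng.normal(size=6), "b": rng.normal(size=6)},
            })
            aov = fs.rm_anova_2way(table)
            hits += (aov.p < 0.05).to_numpy()
        assert (hits <= 0.1 * n_rep + 3).all()

    def test_pure_interaction_dominates(self):
        rng = np.random.default_rng(5)
        # crossed cell means: +d for (f,a) and (m,b), -d otherwise
        d = 2.0
        table = make_long({
            "f": {"a": d + 0.01 * rng.normal(size=5),
                  "b": -d + 0.01 * rng.normal(size=5)},
            "m": {"a": -d + 0.01 * rng.normal(size=5),
                  "b": d + 0.01 * rng.normal(size=5)},
        })
        aov = fs.rm_anova_2way(table).set_index("source")
        assert aov.loc["interaction", "F"] > 10 * aov.drop("interaction").F.max()

    def test_incomplete_subject_dropped_with_warning(self):
        table = make_long({
            "f": {"a": [1.0, 2.0, 1.5], "b": [2.0, 2.5, 2.2]},
            "m": {"a": [1.2, 1.9, 1.4], "b": [1.1, 1.8, 1.6]},
        })
        table = table[~((table.subject_id == "f0") & (table.within_factor == "b"))]
        with pytest.warns(UserWarning, match="incomplete"):
            aov = fs.rm_anova_2way(table)
        assert not aov.empty

    def test_sphericity_reported_for_three_levels(self):
        rng = np.random.default_rng(9)
        table = make_long({
            "f": {"a": rng.normal(size=5), "b": rng.normal(size=5),
                  "c": rng.normal(size=5)},
            "m": {"a": rng.normal(size=5), "b": rng.normal(size=5),
                  "c": rng.normal(size=5)},
        })
        aov = fs.rm_anova_2way(table)
        assert "sphericity" in aov.attrs
        assert 0 <= aov.attrs["sphericity"]["p"] <= 1

    def test_too_few_subjects_rejected(self):
        table = make_long({"f": {"a": [1.0], "b": [2.0]},
                           "m": {"a": [1.5], "b": [2.5]}})
        with pytest.raises(ValueError):
            fs.rm_anova_2way(table)


class TestTukey:
    def test_identical_groups_large_p(self, rng):
        base = rng.normal(size=12)
        table = pd.DataFrame({
            "group": ["a"] * 12 + ["b"] * 12,
            "value": np.concatenate([base, base + 1e-9]),
        })
        out = fs.tukey_hsd(table)
        assert out.p_adj.iloc[0] > 0.9

    def test_two_levels_reduce_to_t_test(self, rng):
        a = rng.normal(size=10)
        b = rng.normal(loc=0.8, size=10)
        table = pd.DataFrame({"group": ["a"] * 10 + ["b"] * 10,
                              "value": np.concatenate([a, b])})
        out = fs.tukey_hsd(table)
        t_p = stats.ttest_ind(a, b).pvalue
        assert out.p_adj.iloc[0] == pytest.approx(t_p, rel=1e-6)
        assert out.p_unadj.iloc[0] == pytest.approx(t_p, rel=1e-6)

    def test_shifted_level_signalled(self, rng):
        table = pd.DataFrame({
            "group": ["a"] * 8 + ["b"] * 8 + ["c"] * 8,
            "value": np.concatenate([rng.normal(size=8), rng.normal(size=8),
                                     rng.normal(loc=6.0, size=8)]),
        })
        out = fs.tukey_hsd(table).set_index(["level_a", "level_b"])
        assert out.loc[("a", "c"), "p_adj"] < 0.01
        assert out.loc[("b", "c"), "p_adj"] < 0.01
        assert out.loc[("a", "b"), "p_adj"] > 0.05

    def test_adjusted_p_never_below_unadjusted(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            table = pd.DataFrame({
                "group": np.repeat(["a", "b", "c", "d"], 7),
                "value": r.normal(size=28) + np.repeat(r.normal(size=4), 7),
            })
            out = fs.tukey_hsd(table)
            assert (out.p_adj >= out.p_unadj - 1e-12).all()

    def test_single_level_rejected(self):
        table = pd.DataFrame({"group": ["a"] * 5, "value": np.arange(5.0)})
        with pytest.raises(ValueError):
            fs.tukey_hsd(table)
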