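import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from statsmodels.formula.api import ols

from secretomap.biomarker import (
    compute_mom, mom_ratio, percent_increase, summary_ttest, two_sample_ttest,
    two_way_anova,
)
from secretomap.syndata import SimConfig, generate_biomarker_cohort


def cohort_frame(concs):
    """Small long-format table: concs[group][week][analyte] = list."""
    rows = []
    for group, weeks in concs.items():
        for week, analytes in weeks.items():
            for analyte, values in analytes.items():
                for i, v in enumerate(values):
                    rows.append({"subject": f"{group}{i}", "group": group,
                                 "week": week, "analyte": analyte,
                                 "concentration": v})
    return pd.DataFrame(rows)


def test_reference_median_subject_has_mom_one():
    t = cohort_frame({"healthy": {12: {"MIF": [1.0, 2.0, 3.0]}}})
    moms = compute_mom(t)
    assert moms.loc[moms["concentration"] == 2.0, "mom"].iloc[0] == 1.0


def test_mom_invariant_to_unit_rescaling():
    t = cohort_frame({"healthy": {12: {"MIF": [1.0, 2.0, 4.0]}},
                      "GDM": {12: {"MIF": [3.0, 5.0]}}})
    m1 = compute_mom(t)["mom"].to_numpy()
    t2 = t.copy()
    t2["concentration"] *= 100.0
    m2 = compute_mom(t2)["mom"].to_numpy()
    assert np.allclose(m1, m2, atol=1e-15)


def test_healthy_mom_median_is_one_in_every_stratum():
    cfg = SimConfig(n_healthy=40, n_gdm=10, biomarker_sigma=0.4, seed=3)
    moms = compute_mom(generate_biomarker_cohort(cfg))
    healthy = moms[moms["group"] == "healthy"]
    med = healthy.groupby(["week", "analyte"])["mom"].median()
    assert np.allclose(med.to_numpy(), 1.0, atol=1e-12)


def test_empty_reference_stratum_rejected():
    t = cohort_frame({"GDM": {12: {"MIF": [1.0, 2.0]}}})
    with pytest.raises(ValueError, match="reference stratum"):
        compute_mom(t)


def test_ratio_arithmetic_and_identity():
    t = cohort_frame({"healthy": {12: {"A": [1.0, 2.0, 3.0],
                                       "B": [2.0, 4.0, 6.0]}}})
    t.loc[:, "subject"] = t["subject"]
    moms = compute_mom(t)
    r = mom_ratio(moms, "A", "B")
    same = mom_ratio(moms, "A", "A")
    assert np.allclose(same["ratio"], 1.0)
    assert len(r) == 3


def test_subject_missing_an_analyte_is_excluded():
    t = cohort_frame({"healthy": {12: {"A": [1.0, 2.0, 3.0],
                                       "B": [2.0, 4.0, 6.0]}}})
    t = t.drop(t[(t["subject"] == "healthy2") & (t["analyte"] == "B")].index)
    r = mom_ratio(compute_mom(t), "A", "B")
    assert len(r) == 2
    assert "healthy2" not in set(r["subject"])


@pytest.mark.parametrize("case, ref, expected", [
    ([2.0, 2.0], [2.0, 2.0], 0.0),
    ([3.1, 3.1], [1.0, 1.0], 210.0),
])
def test_percent_increase_arithmetic(case, ref, expected):
    assert percent_increase(case, ref) == pytest.approx(expected)


def test_percent_increase_matches_direct_formula(rng):
    a, b = rng.uniform(1, 5, 30), rng.uniform(1, 5, 40)
    assert percent_increase(a, b) == pytest.approx(
        100 * (a.mean() - b.mean()) / b.mean(), rel=1e-12)


def test_pooled_t_on_worked_example():
    """(1,2,3) vs (4,5,6): t = -3/sqrt(2/3), df = 4, p ~ 0.0214."""
    t, df, p = two_sample_ttest([1, 2, 3], [4, 5, 6], "student")
    assert t == pytest.approx(-3.0 / np.sqrt(2 / 3), rel=1e-9)
    assert df == 4
    assert p == pytest.approx(0.021312, abs=1e-5)


def test_identical_constant_samples_are_degenerate():
    t, _, p = two_sample_ttest([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
    assert (t, p) == (0.0, 1.0)


def test_welch_differs_from_student_under_variance_heterogeneity(rng):
    a = rng.normal(0, 1, 10)
    b = rng.normal(0, 5, 40)
    _, df_s, _ = two_sample_ttest(a, b, "student")
    _, df_w, _ = two_sample_ttest(a, b, "welch")
    assert df_s == 48 and df_w < 48


def test_summary_ttest_matches_moment_matched_samples(rng):
    """Agrees with the sample t-test on data built to have those summaries."""
    for _ in range(20):
        n1, n2 = int(rng.integers(3, 12)), int(rng.integers(3, 12))
        m1, m2 = rng.normal(size=2)
        s1, s2 = rng.uniform(0.5, 2, 2)

        def build(n, mean, sem):
            z = rng.normal(size=n)
            z = (z - z.mean()) / z.std(ddof=1)
            return mean + z * sem * np.sqrt(n)

        a, b = build(n1, m1, s1), build(n2, m2, s2)
        for variant in ("student", "welch"):
            t_s, df_s, p_s = summary_ttest(m1, s1, n1, m2, s2, n2, variant)
            t_f, df_f, p_f = two_sample_ttest(a, b, variant)
            assert t_s == pytest.approx(t_f, rel=1e-9)
            assert df_s == pytest.approx(df_f, rel=1e-9)
            assert p_s == pytest.approx(p_f, rel=1e-9)


def test_summary_ttest_equal_means_zero_sems_degenerate():
    t, _, p = summary_ttest(10.0, 0.0, 5, 10.0, 0.0, 5)
    assert (t, p) == (0.0, 1.0)


def test_constant_balanced_design_gives_null_result():
    y = [3.0] * 8
    groups = ["a", "a", "b", "b"] * 2
    weeks = [12, 28] * 4
    res = two_way_anova(y, groups, weeks)
    for factor in res.values():
        assert factor["F"] == 0.0 and factor["p"] == 1.0


def test_single_week_reduction_recovers_t_squared(rng):
    a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 6)
    y = np.concatenate([a, b])
    groups = ["h"] * 8 + ["g"] * 6
    res = two_way_anova(y, groups, [12] * 14)
    t, _, p_t = two_sample_ttest(a, b, "student")
    assert res["group"]["F"] == pytest.approx(t**2, rel=1e-10)
    assert res["group"]["p"] == pytest.approx(p_t, rel=1e-10)
    assert "week" not in res


def test_balanced_toy_matches_hand_decomposition():
    """Cell-mean sums of squares computed by hand match to 1e-10."""
    data = {
        ("a", 12): [1.0, 2.0], ("a", 28): [2.0, 4.0],
        ("g", 12): [5.0, 7.0], ("g", 28): [3.0, 3.0],
    }
    y, groups, weeks = [], [], []
    for (g, w), vals in data.items():
        for v in vals:
            y.append(v); groups.append(g); weeks.append(w)
    y = np.array(y)
    grand = y.mean()
    mean_g = {g: np.mean([v for (gg, _), vs in data.items() if gg == g
                          for v in vs]) for g in "ag"}
    mean_w = {w: np.mean([v for (_, ww), vs in data.items() if ww == w
                          for v in vs]) for w in (12, 28)}
    ss_a = sum(4 * (m - grand) ** 2 for m in mean_g.values())
    ss_b = sum(4 * (m - grand) ** 2 for m in mean_w.values())
    cell = {k: np.mean(v) for k, v in data.items()}
    ss_ab = sum(2 * (cell[(g, w)] - mean_g[g] - mean_w[w] + grand) ** 2
                for g in "ag" for w in (12, 28))
    res = two_way_anova(y, groups, weeks)
    assert res["group"]["ss"] == pytest.approx(ss_a, abs=1e-10)
    assert res["week"]["ss"] == pytest.approx(ss_b, abs=1e-10)
    assert res["interaction"]["ss"] == pytest.approx(ss_ab, abs=1e-10)


def test_unbalanced_type_ii_matches_statsmodels(rng):
    """Random unbalanced designs agree with anova_lm(typ=2) to 1e-8."""
    for _ in range(10):
        n = int(rng.integers(18, 30))
        df = pd.DataFrame({
            "y": rng.normal(size=n),
            "g": rng.choice(["h", "g"], size=n),
            "w": rng.choice([12, 28], size=n),
        })
        if df.groupby(["g", "w"]).size().reindex(
                [(a, b) for a in ("g", "h") for b in (12, 28)]).isna().any():
            continue
        res = two_way_anova(df["y"], df["g"], df["w"])
        fit = ols("y ~ C(g) * C(w)", data=df).fit()
        table = sm.stats.anova_lm(fit, typ=2)
        assert res["group"]["F"] == pytest.approx(table.loc["C(g)", "F"],
                                                  rel=1e-8)
        assert res["week"]["F"] == pytest.approx(table.loc["C(w)", "F"],
                                                 rel=1e-8)
        assert res["interaction"]["p"] == pytest.approx(
            table.loc["C(g):C(w)", "PR(>F)"], rel=1e-8)


def test_empty_design_cell_rejected():
    with pytest.raises(ValueError, match="cell"):
        two_way_anova([1.0, 2.0, 3.0, 4.0], ["a", "a", "b", "b"],
                      [12, 28, 12, 12])
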