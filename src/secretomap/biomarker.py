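"""Multiple-of-the-median (MoM) biomarker statistics for serum panels.

Serum analyte concentrations (long format: subject, group, gestational week,
analyte, concentration) are normalized as multiples of the healthy-group
median at the same week and analyte — the standard prenatal-screening
normalization, which makes values dimensionless and comparable across
analytes and gestational ages.  Composite biomarkers are per-subject ratios
of two analytes' MoM values; group effects are summarized as a percent
increase of the case-group mean over the reference mean and tested with
two-sample t-tests and fixed-effects two-way (group x week) ANOVA.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("secretomap")

REQUIRED_COLUMNS = ("subject", "group", "week", "analyte", "concentration")


def _check_table(table: pd.DataFrame) -> None:
    missing = set(REQUIRED_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"biomarker table missing columns {sorted(missing)}")
    if (table["concentration"] <= 0).any():
        raise ValueError("concentrations must be positive")
    if table.duplicated(["subject", "week", "analyte"]).any():
        raise ValueError("one value per (subject, week, analyte) required")


def compute_mom(table: pd.DataFrame, reference: str = "healthy") -> pd.DataFrame:
    """MoM = concentration / median(reference-group concentration) per stratum.

    The reference median is computed per (week, analyte) stratum over the
    reference group and applied to all subjects; an even-sized reference
    group uses the midpoint of the two central order statistics.
    """
    _check_table(table)
    out = table.copy()
    medians = (
        table[table["group"] == reference]
        .groupby(["week", "analyte"])["concentration"]
        .median()
    )
    empty = [
        (w, a)
        for w in table["week"].unique()
        for a in table["analyte"].unique()
        if (w, a) not in medians.index
    ]
    if empty:
        raise ValueError(f"empty reference stratum (week, analyte): {empty}")
    ref = medians.loc[
        pd.MultiIndex.from_frame(table[["week", "analyte"]])
    ].to_numpy()
    out["mom"] = table["concentration"].to_numpy() / ref
    return out


def mom_ratio(
    moms: pd.DataFrame, numerator: str, denominator: str
) -> pd.DataFrame:
    """Per-subject ratio mom(numerator)/mom(denominator) by week and group.

    Subjects missing either analyte at a week are excluded and logged.
    """
    wide = moms.pivot_table(
        index=["subject", "group", "week"], columns="analyte", values="mom"
    )
    for a in (numerator, denominator):
        if a not in wide.columns:
            raise ValueError(f"analyte {a!r} absent from MoM table")
    pair = wide[list(dict.fromkeys((numerator, denominator)))]
    complete = pair.dropna()
    n_dropped = len(pair) - len(complete)
    if n_dropped:
        logger.info("mom_ratio: %d subject-weeks missing an analyte", n_dropped)
    out = complete.reset_index()
    out["ratio"] = out[numerator] / out[denominator]
    return out[["subject", "group", "week", "ratio"]]


def percent_increase(values_case, values_ref) -> float:
    """100 * (mean(case) - mean(ref)) / mean(ref)."""
    case = np.asarray(values_case, dtype=float)
    ref = np.asarray(values_ref, dtype=float)
    if case.size == 0 or ref.size == 0:
        raise ValueError("both groups must be non-empty")
    m_ref = ref.mean()
    if m_ref <= 0:
        raise ValueError("reference mean must be positive")
    return float(100.0 * (case.mean() - m_ref) / m_ref)


def two_sample_ttest(a, b, variant: str = "student") -> tuple[float, float, float]:
    """Two-sample t-test; returns (t, df, two-sided p).

    ``variant='student'`` pools variances; ``'welch'`` uses the
    Welch-Satterthwaite degrees of freedom.  Degenerate input (both samples
    constant and equal) returns t=0, p=1 with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two observations per group")
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            logger.warning("degenerate t-test: zero variance, equal means")
            return 0.0, float(a.size + b.size - 2), 1.0
        raise ValueError("zero variance with unequal means: t undefined")
    res = stats.ttest_ind(a, b, equal_var=(variant == "student"))
    return float(res.statistic), float(res.df), float(res.pvalue)


def summary_ttest(
    mean1: float, sem1: float, n1: int,
    mean2: float, sem2: float, n2: int,
    variant: str = "student",
) -> tuple[float, float, float]:
    """t-test from summary statistics (mean, SEM, n) per group.

    The SD is recovered as SEM * sqrt(n). Both SEMs zero with equal means is
    degenerate: t=0, p=1 with a warning.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sem1 < 0 or sem2 < 0:
        raise ValueError("SEMs must be non-negative")
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    if sem1 == 0 and sem2 == 0:
        if mean1 == mean2:
            logger.warning("degenerate summary t-test: zero SEMs, equal means")
            return 0.0, float(n1 + n2 - 2), 1.0
        raise ValueError("zero SEMs with unequal means: t undefined")
    sd1, sd2 = sem1 * np.sqrt(n1), sem2 * np.sqrt(n2)
    res = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=(variant == "student")
    )
    if variant == "student":
        df = float(n1 + n2 - 2)
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def two_way_anova(
    values, factor_a, factor_b
) -> dict[str, dict[str, float]]:
    """Fixed-effects two-way ANOVA with interaction, Type II sums of squares.

    Type II SS are obtained from residual sums of squares of nested
    least-squares fits: SS(A|B) = RSS(B) - RSS(A+B), SS(B|A) analogously,
    and SS(AB|A+B) = RSS(A+B) - RSS(full); F uses the full-model MSE.
    Works for unbalanced designs (Type II = Type I = Type III when
    balanced). Every cell of the design must be occupied.

    With a single level in the second factor the model degrades to a
    one-way ANOVA on the group factor (its F then equals the squared
    pooled t statistic for two groups); factors without degrees of
    freedom are omitted from the result.
    """
    y = np.asarray(values, dtype=float)
    fa = pd.Categorical(factor_a)
    fb = pd.Categorical(factor_b)
    if len(fa.categories) < 2:
        raise ValueError("group factor needs at least two levels")
    cells = pd.crosstab(fa, fb)
    empty = [(str(i), str(c)) for i in cells.index for c in cells.columns
             if cells.at[i, c] == 0]
    if empty:
        raise ValueError(f"empty design cell(s): {empty}")

    def dummies(codes, levels):
        m = np.zeros((len(codes), levels - 1))
        for lvl in range(1, levels):
            m[codes == lvl, lvl - 1] = 1.0
        return m

    da = dummies(fa.codes, len(fa.categories))
    db = dummies(fb.codes, len(fb.categories))
    inter = np.einsum("ni,nj->nij", da, db).reshape(len(y), -1)
    ones = np.ones((len(y), 1))

    def rss(X):
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ coef
        return float(r @ r)

    tss = float(((y - y.mean()) ** 2).sum())
    rss_full = rss(np.hstack([ones, da, db, inter]))
    rss_ab = rss(np.hstack([ones, da, db]))
    rss_a = rss(np.hstack([ones, da]))
    rss_b = rss(np.hstack([ones, db]))

    df_a = len(fa.categories) - 1
    df_b = len(fb.categories) - 1
    df_ab = df_a * df_b
    df_res = len(y) - len(fa.categories) * len(fb.categories)
    if df_res < 1:
        raise ValueError("no residual degrees of freedom")
    mse = rss_full / df_res
    if tss <= 1e-12 * max(float((y**2).sum()), 1.0):
        mse = 0.0  # numerically constant response: nothing to test

    out = {}
    for name, ss, df in (
        ("group", rss_b - rss_ab, df_a),
        ("week", rss_a - rss_ab, df_b),
        ("interaction", rss_ab - rss_full, df_ab),
    ):
        if df < 1:
            continue
        ss = max(ss, 0.0)
        F = (ss / df) / mse if mse > 0 else 0.0
        p = float(stats.f.sf(F, df, df_res)) if mse > 0 else 1.0
        out[name] = {"F": float(F), "df1": float(df), "df2": float(df_res),
                     "ss": ss, "p": p}
    return out
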