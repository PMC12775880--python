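"""Omnibus and two-group tests, parametric and rank-based, with Cohen's d.

The test battery mirrors the standard one-factor selection matrix:

====================  ======================  ==========================
design                parametric              nonparametric
====================  ======================  ==========================
2 groups independent  t-test (Student/Welch)  Mann-Whitney U
2 groups dependent    paired t-test           Wilcoxon signed-rank
>2 independent        one-way ANOVA (+Welch)  Kruskal-Wallis
>2 dependent          repeated-measures ANOVA (no nonparametric fallback)
====================  ======================  ==========================

Two-way and mixed (split-plot) ANOVAs are available for two-factor designs;
they are parametric-only.  All p-values are two-sided.  Cohen's d uses the
pooled standard deviation for independent groups and the SD of the paired
differences for dependent ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assumptions import TestResult
from .dataset_io import DataError, Dataset


@dataclass
class EffectSize:
    name: str  # "cohens_d_pooled" | "cohens_d_paired"
    value: float
    numerator: float  # mean difference
    denominator: float  # pooled sd, or sd of paired differences


@dataclass
class OmnibusResult(TestResult):
    design: str = "independent"
    k_groups: int = 0
    branch: str = "parametric"
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p < self.alpha


def cohens_d_pooled(x: np.ndarray, y: np.ndarray) -> EffectSize:
    n1, n2 = x.size, y.size
    s2 = ((n1 - 1) * np.var(x, ddof=1) + (n2 - 1) * np.var(y, ddof=1)) / (n1 + n2 - 2)
    if s2 <= 0:
        raise DataError("zero pooled variance: Cohen's d undefined")
    num = float(np.mean(x) - np.mean(y))
    den = float(math.sqrt(s2))
    return EffectSize("cohens_d_pooled", num / den, num, den)


def t_test(group_a: Sequence[float], group_b: Sequence[float],
           variant: str = "student") -> tuple[TestResult, EffectSize]:
    """Two-sample t-test (pooled-variance Student or Welch-Satterthwaite).

    Cohen's d is always reported with the pooled-SD denominator, for both
    variants, so effect sizes stay comparable across the two routes.
    """
    x = np.asarray(group_a, dtype=float)
    y = np.asarray(group_b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise DataError("t-test requires n >= 2 in each group")
    if np.ptp(x) == 0.0 and np.ptp(y) == 0.0 and x[0] == y[0]:
        raise DataError("all values identical in both groups: t-test undefined")
    if variant == "student":
        t, p = stats.ttest_ind(x, y, equal_var=True)
        df = (float(x.size + y.size - 2),)
        name = "t-test"
    elif variant == "welch":
        res = stats.ttest_ind(x, y, equal_var=False)
        t, p = res.statistic, res.pvalue
        df = (float(res.df),)
        name = "Welch's t-test"
    else:
        raise ValueError(f"unknown t-test variant {variant!r}")
    d = cohens_d_pooled(x, y)
    return (TestResult(name, "t", float(t), float(p), df=df, n_used=x.size + y.size), d)


def paired_t_test(pairs: Sequence[tuple[float, float]]) -> tuple[TestResult, EffectSize]:
    """One-sample t-test on paired differences; d = mean(diff)/sd(diff)."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise DataError("paired t-test requires >= 2 (x, y) pairs")
    diff = arr[:, 0] - arr[:, 1]
    sd = float(np.std(diff, ddof=1))
    if sd == 0.0:
        raise DataError("degenerate paired design: all differences identical")
    t, p = stats.ttest_rel(arr[:, 0], arr[:, 1])
    num = float(np.mean(diff))
    es = EffectSize("cohens_d_paired", num / sd, num, sd)
    return (TestResult("paired t-test", "t", float(t), float(p),
                       df=(float(diff.size - 1),), n_used=diff.size), es)


def one_way_anova(groups: Sequence[Sequence[float]], variant: str = "classic",
                  alpha: float = 0.05) -> OmnibusResult:
    """One-way fixed-effects ANOVA; ``variant="welch"`` for heteroscedastic data."""
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2 or any(g.size < 2 for g in arrs):
        raise DataError("one-way ANOVA requires k >= 2 groups with n >= 2 each")
    pooled = np.concatenate(arrs)
    if np.ptp(pooled) == 0.0:
        raise DataError("all values identical: F undefined")
    k = len(arrs)
    n_total = int(pooled.size)
    if variant == "classic":
        f, p = stats.f_oneway(*arrs)
        df = (float(k - 1), float(n_total - k))
        name = "One-Way ANOVA"
    elif variant == "welch":
        from statsmodels.stats.oneway import anova_oneway

        res = anova_oneway(arrs, use_var="unequal", welch_correction=True)
        f, p = res.statistic, res.pvalue
        df = (float(res.df_num), float(res.df_denom))
        name = "Welch's ANOVA"
    else:
        raise ValueError(f"unknown ANOVA variant {variant!r}")
    return OmnibusResult(name, "F", float(f), float(p), df=df, n_used=n_total,
                         design="independent", k_groups=k, branch="parametric",
                         alpha=alpha)


def kruskal_wallis(groups: Sequence[Sequence[float]], alpha: float = 0.05) -> OmnibusResult:
    """Kruskal-Wallis rank test with mid-rank tie correction, chi-square p."""
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2 or any(g.size < 1 for g in arrs):
        raise DataError("Kruskal-Wallis requires k >= 2 non-empty groups")
    pooled = np.concatenate(arrs)
    if pooled.size < 3:
        raise DataError("Kruskal-Wallis requires N >= 3")
    k = len(arrs)
    if np.ptp(pooled) == 0.0:
        return OmnibusResult("Kruskal-Wallis", "H", 0.0, 1.0,
                             df=(float(k - 1),), n_used=int(pooled.size),
                             design="independent", k_groups=k,
                             branch="nonparametric", alpha=alpha,
                             notes="all values tied; H = 0 by convention")
    h, p = stats.kruskal(*arrs)
    return OmnibusResult("Kruskal-Wallis", "H", float(h), float(p),
                         df=(float(k - 1),), n_used=int(pooled.size),
                         design="independent", k_groups=k,
                         branch="nonparametric", alpha=alpha)


def _has_ties(pooled: np.ndarray) -> bool:
    return np.unique(pooled).size < pooled.size


def mann_whitney_u(group_a: Sequence[float], group_b: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U.

    Exact p by enumeration when n1 + n2 <= 12 and the pooled sample has no
    ties; otherwise the normal approximation with tie-corrected variance and
    continuity correction.
    """
    x = np.asarray(group_a, dtype=float)
    y = np.asarray(group_b, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DataError("Mann-Whitney U requires non-empty samples")
    pooled = np.concatenate([x, y])
    exact = (x.size + y.size <= 12) and not _has_ties(pooled)
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return TestResult("Mann-Whitney U", "U", float(res.statistic), float(res.pvalue),
                      n_used=int(pooled.size),
                      notes=f"{method} p ({'no ties' if exact else 'normal approximation, tie-corrected, continuity-corrected'})")


def wilcoxon_signed_rank(pairs: Sequence[tuple[float, float]]) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (count noted).  Exact p for n <= 15 with no
    tied absolute differences, else normal approximation with continuity
    correction.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 1:
        raise DataError("Wilcoxon signed-rank requires >= 1 (x, y) pair")
    diff = arr[:, 0] - arr[:, 1]
    n_zero = int(np.sum(diff == 0))
    nz = diff[diff != 0]
    if nz.size == 0:
        raise DataError("all paired differences are zero: test undefined")
    exact = nz.size <= 15 and not _has_ties(np.abs(nz))
    method = "exact" if exact else "approx"
    res = stats.wilcoxon(nz, alternative="two-sided", method=method,
                         correction=(method == "approx"))
    # scipy's two-sided statistic is min(V+, V-); report V+ (positive-rank sum)
    ranks = stats.rankdata(np.abs(nz))
    v_plus = float(np.sum(ranks[nz > 0]))
    notes = f"{method} p"
    if n_zero:
        notes += f"; {n_zero} zero difference(s) dropped"
    return TestResult("Wilcoxon signed-rank", "V", v_plus,
                      float(res.pvalue), n_used=int(nz.size), notes=notes)


def _pivot_subjects(ds: Dataset, columns: str) -> pd.DataFrame:
    df = ds.to_frame()
    wide = df.pivot_table(index="Subject", columns=columns, values="Values",
                          aggfunc="count", fill_value=0)
    return wide


def rm_anova(ds: Dataset, alpha: float = 0.05) -> OmnibusResult:
    """Univariate one-within-factor repeated-measures ANOVA.

    Requires a complete balanced design (every subject observed once in every
    group).  No sphericity correction is applied; a permanent note records
    that sphericity was not assessed.
    """
    import pingouin as pg

    if not ds.has_subjects:
        raise DataError("repeated-measures ANOVA requires subject IDs")
    counts = _pivot_subjects(ds, "Group")
    missing = [(str(s), str(g)) for s in counts.index for g in counts.columns
               if counts.loc[s, g] == 0]
    if missing:
        raise DataError(f"incomplete repeated-measures design; missing (subject, group) "
                        f"cells: {missing}")
    df = ds.to_frame()
    k = ds.k_groups
    s = counts.shape[0]
    wide = df.pivot(index="Subject", columns="Group", values="Values")
    ss_cond = s * float(((wide.mean(axis=0) - wide.values.mean()) ** 2).sum())
    if ss_cond <= 1e-12 * max(1.0, float(np.var(wide.values))):
        # flat condition profile: no within-subject effect, F = 0 by definition
        return OmnibusResult("Repeated-Measures ANOVA", "F", 0.0, 1.0,
                             df=(float(k - 1), float((k - 1) * (s - 1))),
                             n_used=len(ds.observations), design="dependent",
                             k_groups=k, branch="parametric", alpha=alpha,
                             notes="sphericity not assessed; no condition effect (F = 0)")
    aov = pg.rm_anova(data=df, dv="Values", within="Group", subject="Subject",
                      correction=False, detailed=False)
    row = aov.iloc[0]
    return OmnibusResult("Repeated-Measures ANOVA", "F", float(row["F"]),
                         float(row["p_unc"]),
                         df=(float(row["ddof1"]), float(row["ddof2"])),
                         n_used=len(ds.observations), design="dependent",
                         k_groups=k, branch="parametric", alpha=alpha,
                         notes=f"sphericity not assessed; {s} subjects x {k} conditions")


def two_way_anova(ds: Dataset, alpha: float = 0.05) -> list[OmnibusResult]:
    """Fixed-effects two-way ANOVA on (Group, Factor2): main A, main B, interaction.

    Balanced designs reduce to the classical decomposition; unbalanced designs
    use Type-II sums of squares (noted in the result).
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    if not ds.has_factor2:
        raise DataError("two-way ANOVA requires a second factor column")
    df = ds.to_frame().rename(columns={"Values": "value"})
    cells = df.groupby(["Group", "Factor2"], observed=True).size()
    levels_a = df["Group"].nunique()
    levels_b = df["Factor2"].nunique()
    if levels_a < 2 or levels_b < 2:
        raise DataError("both factors need >= 2 levels")
    if len(cells) < levels_a * levels_b:
        have = set(cells.index)
        empty = [(a, b) for a in df["Group"].unique() for b in df["Factor2"].unique()
                 if (a, b) not in have]
        raise DataError(f"empty design cell(s): {empty}")
    with_interaction = (cells >= 2).any()
    balanced = cells.nunique() == 1
    formula = "value ~ C(Group) * C(Factor2)" if with_interaction \
        else "value ~ C(Group) + C(Factor2)"
    fit = smf.ols(formula, data=df).fit()
    table = anova_lm(fit, typ=2)
    note = "" if balanced else "unbalanced design: Type-II sums of squares"
    out: list[OmnibusResult] = []
    terms = [("C(Group)", "Two-Way ANOVA: Group"), ("C(Factor2)", "Two-Way ANOVA: Factor2")]
    if with_interaction:
        terms.append(("C(Group):C(Factor2)", "Two-Way ANOVA: interaction"))
    df_resid = float(table.loc["Residual", "df"])
    for term, label in terms:
        row = table.loc[term]
        out.append(OmnibusResult(label, "F", float(row["F"]), float(row["PR(>F)"]),
                                 df=(float(row["df"]), df_resid),
                                 n_used=len(df), design="independent",
                                 k_groups=levels_a, branch="parametric",
                                 alpha=alpha, notes=note))
    return out


def mixed_anova(ds: Dataset, alpha: float = 0.05) -> list[OmnibusResult]:
    """Split-plot (mixed) ANOVA: Group between subjects, Factor2 within.

    Classical decomposition: the between-subjects error is subjects nested in
    groups; the within error is the subject-by-within-factor interaction.
    """
    import pingouin as pg

    if not ds.has_subjects or not ds.has_factor2:
        raise DataError("mixed ANOVA requires subject IDs and a second (within) factor")
    counts = _pivot_subjects(ds, "Factor2")
    missing = [(str(s), str(w)) for s in counts.index for w in counts.columns
               if counts.loc[s, w] == 0]
    if missing:
        raise DataError(f"incomplete within-subject data; missing (subject, level) "
                        f"cells: {missing}")
    df = ds.to_frame()
    aov = pg.mixed_anova(data=df, dv="Values", within="Factor2", between="Group",
                         subject="Subject", correction=False)
    aov = aov.set_index("Source")
    out: list[OmnibusResult] = []
    for source, label in [("Group", "Mixed ANOVA: between (Group)"),
                          ("Factor2", "Mixed ANOVA: within (Factor2)"),
                          ("Interaction", "Mixed ANOVA: interaction")]:
        row = aov.loc[source]
        out.append(OmnibusResult(label, "F", float(row["F"]), float(row["p_unc"]),
                                 df=(float(row["DF1"]), float(row["DF2"])),
                                 n_used=len(df), design="dependent",
                                 k_groups=ds.k_groups, branch="parametric",
                                 alpha=alpha, notes="sphericity not assessed"))
    return out
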