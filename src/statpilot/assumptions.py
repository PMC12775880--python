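"""Normality and variance-homogeneity checks driving test selection.

Two normality conventions are used at different workflow stages:

* raw stage — Shapiro-Wilk per group (any failing group fails the stage);
* post-transform stage — Shapiro-Wilk on the model residuals (observed value
  minus its group mean), which summarize all groups after removing the group
  effect and are what the ANOVA error assumption actually concerns.

Homoscedasticity is always checked with the Brown-Forsythe test, the
Levene-type test centered on the group median, chosen for its robustness to
outliers and skew; the mean-centered (classical Levene) variant is available
via ``center="mean"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .dataset_io import Dataset


@dataclass
class TestResult:
    """A named statistic with its p-value and degrees of freedom."""

    test_name: str
    statistic_name: str  # W, F, t, H, U, V, q, d-adjusted
    statistic: float
    p: float
    df: Optional[tuple[float, ...]] = None
    n_used: int = 0
    notes: str = ""

    @property
    def testable(self) -> bool:
        return "not testable" not in self.notes


@dataclass
class AssumptionReport:
    stage: str  # "raw" | "post_transform"
    alpha: float
    per_group_normality: list[tuple[str, TestResult]] = field(default_factory=list)
    residual_normality: Optional[TestResult] = None
    homoscedasticity: Optional[TestResult] = None
    normality_pass: bool = False
    homoscedasticity_pass: bool = False
    notes: list[str] = field(default_factory=list)


def shapiro_wilk(values: Sequence[float]) -> TestResult:
    """Shapiro-Wilk normality test (Royston AS R94, via scipy)."""
    x = np.asarray(values, dtype=float)
    n = int(x.size)
    if n < 3:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got n = {n}")
    if n > 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got n = {n}")
    if np.ptp(x) == 0.0:
        return TestResult("Shapiro-Wilk", "W", float("nan"), float("nan"),
                          n_used=n, notes="not testable: zero variance")
    w, p = stats.shapiro(x)
    return TestResult("Shapiro-Wilk", "W", float(w), float(p), n_used=n)


def brown_forsythe(groups: Sequence[Sequence[float]], center: str = "median") -> TestResult:
    """Brown-Forsythe homogeneity-of-variance test.

    Equivalent to a one-way fixed-effects ANOVA on the absolute deviations
    from each group's median (or mean, with ``center="mean"``).
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("Brown-Forsythe requires at least 2 groups")
    for i, g in enumerate(arrs):
        if g.size < 2:
            raise ValueError(f"group {i} has n < 2")
    k = len(arrs)
    n_total = sum(int(g.size) for g in arrs)
    centerfun = np.median if center == "median" else np.mean
    z = np.concatenate([np.abs(g - centerfun(g)) for g in arrs])
    if np.ptp(z) == 0.0:
        return TestResult("Brown-Forsythe", "F", 0.0, 1.0,
                          df=(k - 1, n_total - k), n_used=n_total,
                          notes="no dispersion")
    f, p = stats.levene(*arrs, center=center)
    return TestResult("Brown-Forsythe" if center == "median" else "Levene",
                      "F", float(f), float(p),
                      df=(k - 1, n_total - k), n_used=n_total)


def model_residuals(groups: Sequence[Sequence[float]]) -> np.ndarray:
    """Concatenated within-group mean-centered values (one-way model residuals)."""
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if not arrs or any(g.size == 0 for g in arrs):
        raise ValueError("every group must be non-empty")
    return np.concatenate([g - g.mean() for g in arrs])


def assess(ds: Dataset, stage: str = "raw", alpha: float = 0.05,
           center: str = "median") -> AssumptionReport:
    """Run the stage-appropriate normality check plus Brown-Forsythe.

    Raw stage: per-group Shapiro-Wilk; the stage passes only if every group's
    p >= alpha.  Post-transform stage: Shapiro-Wilk on model residuals.
    A "not testable" normality result (n < 3 or zero variance) conservatively
    fails the stage, pushing the engine toward the nonparametric branch.
    """
    if stage not in ("raw", "post_transform"):
        raise ValueError(f"unknown stage {stage!r}")
    report = AssumptionReport(stage=stage, alpha=alpha)
    groups = ds.group_arrays()

    if stage == "raw":
        ps = []
        for name, g in zip(ds.group_order, groups):
            if g.size < 3:
                tr = TestResult("Shapiro-Wilk", "W", float("nan"), float("nan"),
                                n_used=int(g.size),
                                notes="not testable: n < 3")
            else:
                tr = shapiro_wilk(g)
            report.per_group_normality.append((name, tr))
            if not tr.testable:
                report.notes.append(
                    f"group {name!r} normality not testable ({tr.notes}); treated as failure")
                ps.append(-1.0)  # forces failure
            else:
                ps.append(tr.p)
        report.normality_pass = bool(ps) and min(ps) >= alpha
    else:
        resid = model_residuals(groups)
        if resid.size < 3 or np.ptp(resid) == 0.0:
            tr = TestResult("Shapiro-Wilk (residuals)", "W", float("nan"), float("nan"),
                            n_used=int(resid.size), notes="not testable")
            report.notes.append("residual normality not testable; treated as failure")
            report.normality_pass = False
        else:
            tr = shapiro_wilk(resid)
            tr.test_name = "Shapiro-Wilk (residuals)"
            report.normality_pass = tr.p >= alpha
        report.residual_normality = tr

    report.homoscedasticity = brown_forsythe(groups, center=center)
    report.homoscedasticity_pass = report.homoscedasticity.p >= alpha
    return report
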