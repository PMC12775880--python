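"""Per-group descriptive statistics and outlier flagging.

Outlier candidates are *flagged*, never removed here: removal is a deliberate
opt-in handled by the workflow engine.  Two methods are offered: a single-pass
two-sided Grubbs' test and the modified Z-score (Iglewicz-Hoaglin, default
cutoff 3.5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats


@dataclass
class GroupSummary:
    group: str
    n: int
    mean: float
    median: float
    sd: Optional[float]  # n-1 denominator; None when n == 1
    sem: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    min: float
    max: float
    ci_level: float = 0.95


@dataclass
class OutlierReport:
    method: str  # "grubbs" | "modified_z"
    alpha_or_threshold: float
    per_point: list[tuple[int, float, bool]] = field(default_factory=list)
    n_flagged: int = 0
    note: str = ""

    @property
    def flagged_indices(self) -> list[int]:
        return [i for i, _, f in self.per_point if f]


def summarize_group(values: Sequence[float], group: str = "", ci_level: float = 0.95) -> GroupSummary:
    """Mean, median, SD, SEM and a t-based confidence interval for one group."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot summarize an empty group")
    n = int(x.size)
    mean = float(np.mean(x))
    if n == 1:
        return GroupSummary(group, n, mean, mean, None, None, None, None,
                            float(x.min()), float(x.max()), ci_level)
    sd = float(np.std(x, ddof=1))
    sem = sd / math.sqrt(n)
    tcrit = float(stats.t.ppf(0.5 + ci_level / 2, n - 1))
    return GroupSummary(
        group=group, n=n, mean=mean, median=float(np.median(x)), sd=sd, sem=sem,
        ci_low=mean - tcrit * sem, ci_high=mean + tcrit * sem,
        min=float(x.min()), max=float(x.max()), ci_level=ci_level,
    )


def grubbs_critical(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value G_crit(n, alpha)."""
    t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))


def grubbs_test(values: Sequence[float], alpha: float = 0.05) -> OutlierReport:
    """Single-pass two-sided Grubbs' test; flags at most one extreme point.

    G = max |x_i - mean| / sd, compared against the two-sided critical value.
    Zero-variance input is reported as not testable.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("Grubbs' test requires n >= 3")
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        return OutlierReport("grubbs", alpha,
                             per_point=[(i, math.nan, False) for i in range(x.size)],
                             note="not testable: zero variance")
    mean = float(np.mean(x))
    dev = np.abs(x - mean) / sd
    gcrit = grubbs_critical(x.size, alpha)
    imax = int(np.argmax(dev))
    flagged = bool(dev[imax] > gcrit)
    per_point = [(i, float(dev[i]), flagged and i == imax) for i in range(x.size)]
    return OutlierReport("grubbs", alpha, per_point=per_point,
                         n_flagged=int(flagged),
                         note=f"G = {dev[imax]:.4f}, G_crit = {gcrit:.4f}")


def modified_zscore(values: Sequence[float], threshold: float = 3.5) -> OutlierReport:
    """Modified Z-score outlier flags: M_i = 0.6745 (x_i - median) / MAD.

    When the MAD is zero, falls back to the mean absolute deviation about the
    median scaled by 1.253314; if that is also zero the sample is untestable.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("modified Z-score requires n >= 3")
    med = float(np.median(x))
    absdev = np.abs(x - med)
    mad = float(np.median(absdev))
    if mad > 0:
        m = 0.6745 * (x - med) / mad
    else:
        meanad = float(np.mean(absdev))
        if meanad == 0.0:
            return OutlierReport("modified_z", threshold,
                                 per_point=[(i, math.nan, False) for i in range(x.size)],
                                 note="not testable: zero dispersion")
        m = (x - med) / (1.253314 * meanad)
    per_point = [(i, float(m[i]), bool(abs(m[i]) > threshold)) for i in range(x.size)]
    return OutlierReport("modified_z", threshold, per_point=per_point,
                         n_flagged=sum(1 for _, _, f in per_point if f))
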