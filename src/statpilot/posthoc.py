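"""Branch-gated pairwise comparisons and compact-letter assignment.

Parametric branch: Tukey HSD, Dunnett (vs control), or Sidak over
user-selected pairs (pairwise t-tests).  Nonparametric branch: Dunn's test
on pooled ranks or Sidak over selected pairs (pairwise Mann-Whitney U).
Significance letters follow the compact-letter-display convention: two
groups share at least one letter exactly when their comparison is not
significant.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .dataset_io import DataError
from .inference import cohens_d_pooled, mann_whitney_u, t_test

PARAMETRIC_MENU = ("tukey", "dunnett", "sidak")
NONPARAMETRIC_MENU = ("dunn", "sidak")


@dataclass
class PairwiseComparison:
    group_a: str
    group_b: str
    estimate: float  # mean (or mean-rank) difference, a - b
    statistic: float
    p_raw: float
    p_adj: float
    method: str  # tukey | dunnett | sidak_pairs | dunn
    alpha: float = 0.05
    effect_size: Optional[object] = None  # EffectSize on the parametric branch
    notes: str = ""

    @property
    def significant(self) -> bool:
        return self.p_adj < self.alpha

    @property
    def pair(self) -> tuple[str, str]:
        return (self.group_a, self.group_b)


@dataclass
class LetterAssignment:
    letters: dict[str, str]  # group -> letter string, e.g. "ab"
    basis: dict[tuple[str, str], bool] = field(default_factory=dict)  # pair -> significant


def _groups_dict(groups: Sequence[Sequence[float]],
                 labels: Optional[Sequence[str]]) -> dict[str, np.ndarray]:
    labels = list(labels) if labels is not None else [f"g{i + 1}" for i in range(len(groups))]
    if len(labels) != len(groups):
        raise DataError("labels/groups length mismatch")
    return {lab: np.asarray(g, dtype=float) for lab, g in zip(labels, groups)}


def tukey_hsd(groups: Sequence[Sequence[float]], alpha: float = 0.05,
              labels: Optional[Sequence[str]] = None) -> list[PairwiseComparison]:
    """Tukey's HSD over all pairs, p from the studentized-range distribution.

    q = |m_a - m_b| / sqrt(MSW/2 * (1/n_a + 1/n_b)) with the Tukey-Kramer
    sample-size adjustment; the error df is N - k from the one-way model.
    """
    by = _groups_dict(groups, labels)
    arrs = list(by.values())
    if len(arrs) < 2 or any(a.size < 2 for a in arrs):
        raise DataError("Tukey HSD requires k >= 2 groups with n >= 2 each")
    n_total = sum(a.size for a in arrs)
    k = len(arrs)
    ssw = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrs)
    msw = ssw / (n_total - k)
    if msw == 0.0:
        raise DataError("zero within-group variance: Tukey HSD undefined")
    res = stats.tukey_hsd(*arrs)
    names = list(by.keys())
    out = []
    for i, j in itertools.combinations(range(k), 2):
        a, b = arrs[i], arrs[j]
        est = float(a.mean() - b.mean())
        q = abs(est) / math.sqrt(msw / 2 * (1 / a.size + 1 / b.size))
        p = float(res.pvalue[i, j])
        es = cohens_d_pooled(a, b) if (np.ptp(a) > 0 or np.ptp(b) > 0) else None
        out.append(PairwiseComparison(names[i], names[j], est, q, p, p,
                                      method="tukey", alpha=alpha, effect_size=es,
                                      notes="studentized range, family-adjusted"))
    return out


def dunnett_test(groups: Sequence[Sequence[float]], control: str,
                 alpha: float = 0.05, labels: Optional[Sequence[str]] = None,
                 seed: int = 0) -> list[PairwiseComparison]:
    """Dunnett's many-to-one comparisons against a control group.

    Adjusted p-values come from the (k-1)-variate t distribution with the
    correlation implied by the sample sizes; the integration uses a
    deterministic fixed-seed quasi-Monte-Carlo scheme so repeated runs give
    identical output.
    """
    by = _groups_dict(groups, labels)
    if control not in by:
        raise DataError(f"control label {control!r} not among groups {list(by)}")
    if len(by) < 3:
        raise DataError("Dunnett's test requires k >= 3 groups")
    ctrl = by[control]
    treat_names = [g for g in by if g != control]
    treats = [by[g] for g in treat_names]
    res = stats.dunnett(*treats, control=ctrl,
                        rng=np.random.default_rng(seed))
    out = []
    for name, arr, t_stat, p in zip(treat_names, treats, res.statistic, res.pvalue):
        est = float(arr.mean() - ctrl.mean())
        es = cohens_d_pooled(arr, ctrl)
        out.append(PairwiseComparison(name, control, est, float(t_stat),
                                      float(p), float(p), method="dunnett",
                                      alpha=alpha, effect_size=es,
                                      notes="multivariate-t adjusted (fixed-seed QMC)"))
    return out


def sidak_pairs(selected_pairs: Sequence[tuple[str, str]], branch: str,
                groups: Sequence[Sequence[float]],
                labels: Sequence[str], alpha: float = 0.05) -> list[PairwiseComparison]:
    """Sidak-adjusted user-selected pairs: p_adj = 1 - (1 - p_raw)^m.

    The raw per-pair test follows the branch: Student t-test on the
    parametric branch, Mann-Whitney U on the nonparametric branch.
    """
    by = _groups_dict(groups, labels)
    pairs = [tuple(p) for p in selected_pairs]
    if not pairs:
        raise DataError("at least one pair must be selected")
    seen = set()
    for a, b in pairs:
        if a not in by or b not in by:
            raise DataError(f"unknown group in pair ({a}, {b})")
        key = frozenset((a, b))
        if a == b or key in seen:
            raise DataError(f"duplicate or degenerate pair ({a}, {b})")
        seen.add(key)
    m = len(pairs)
    out = []
    for a, b in pairs:
        x, y = by[a], by[b]
        if branch == "parametric":
            tr, es = t_test(x, y, variant="student")
            stat, p_raw = tr.statistic, tr.p
        elif branch == "nonparametric":
            tr = mann_whitney_u(x, y)
            stat, p_raw = tr.statistic, tr.p
            es = None
        else:
            raise ValueError(f"unknown branch {branch!r}")
        p_adj = float(min(1.0, 1.0 - (1.0 - p_raw) ** m))
        out.append(PairwiseComparison(a, b, float(x.mean() - y.mean()), float(stat),
                                      float(p_raw), p_adj, method="sidak_pairs",
                                      alpha=alpha, effect_size=es,
                                      notes=f"Sidak over m = {m} selected pairs; "
                                            f"raw test: {tr.test_name}"))
    return out


def dunn_test(groups: Sequence[Sequence[float]], adjust: str = "sidak",
              alpha: float = 0.05,
              labels: Optional[Sequence[str]] = None) -> list[PairwiseComparison]:
    """Dunn's rank-based multiple comparisons after Kruskal-Wallis.

    z_ab = (Rbar_a - Rbar_b) / sqrt[(N(N+1)/12 - T/(12(N-1))) (1/n_a + 1/n_b)]
    on pooled mid-ranks, with tie correction T = sum(t^3 - t); two-sided
    normal p, Sidak-adjusted over all pairs by default.
    """
    if adjust not in ("sidak", "none"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    by = _groups_dict(groups, labels)
    arrs = list(by.values())
    if any(a.size == 0 for a in arrs):
        raise DataError("Dunn's test requires non-empty groups")
    pooled = np.concatenate(arrs)
    n_tot = int(pooled.size)
    ranks = stats.rankdata(pooled)
    mean_ranks, pos = {}, 0
    for name, a in by.items():
        mean_ranks[name] = float(ranks[pos:pos + a.size].mean())
        pos += a.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts ** 3 - counts))
    var_base = n_tot * (n_tot + 1) / 12.0 - tie_sum / (12.0 * (n_tot - 1))
    names = list(by.keys())
    m = len(names) * (len(names) - 1) // 2
    out = []
    for a, b in itertools.combinations(names, 2):
        na, nb = by[a].size, by[b].size
        se = math.sqrt(var_base * (1.0 / na + 1.0 / nb))
        est = mean_ranks[a] - mean_ranks[b]
        if se == 0.0:
            z, p_raw = 0.0, 1.0
        else:
            z = est / se
            p_raw = float(2 * stats.norm.sf(abs(z)))
        p_adj = p_raw if adjust == "none" else float(min(1.0, 1.0 - (1.0 - p_raw) ** m))
        out.append(PairwiseComparison(a, b, est, z, p_raw, p_adj, method="dunn",
                                      alpha=alpha,
                                      notes=f"mean-rank difference; {adjust} adjustment"))
    return out


# -- compact letter display ----------------------------------------------

def _insert_absorb(names: list[str], nonsig: set[frozenset]) -> list[set[str]]:
    """Insert-and-absorb heuristic: returns letter classes (cliques)."""
    classes: list[set[str]] = [set(names)]
    for a, b in itertools.combinations(names, 2):
        if frozenset((a, b)) in nonsig:
            continue
        new_classes: list[set[str]] = []
        for cls in classes:
            if a in cls and b in cls:
                new_classes.extend((cls - {a}, cls - {b}))
            else:
                new_classes.append(cls)
        # absorb duplicates / subsets
        classes = []
        for cls in sorted(new_classes, key=len, reverse=True):
            if not any(cls <= kept for kept in classes):
                classes.append(cls)
    return classes


def _exact_cover(names: list[str], nonsig: set[frozenset]) -> Optional[list[set[str]]]:
    """Minimum clique cover of vertices + nonsignificance edges (small k only)."""
    cliques: list[set[str]] = []
    for r in range(len(names), 0, -1):
        for combo in itertools.combinations(names, r):
            if all(frozenset(p) in nonsig for p in itertools.combinations(combo, 2)):
                s = set(combo)
                if not any(s <= c for c in cliques):
                    cliques.append(s)
    if len(cliques) > 20:
        return None
    must_edges = [p for p in nonsig]
    for size in range(1, len(cliques) + 1):
        for subset in itertools.combinations(cliques, size):
            covered_v = set().union(*subset)
            if covered_v != set(names):
                continue
            if all(any(set(e) <= c for c in subset) for e in must_edges):
                return list(subset)
    return None


def compact_letters(pairs: Sequence[PairwiseComparison],
                    group_order: Sequence[str]) -> LetterAssignment:
    """Assign significance letters: groups share a letter iff not significantly different.

    Uses an exact minimum clique cover for small group counts (guaranteeing a
    minimal letter count) and the insert-and-absorb heuristic otherwise.
    Groups never compared are treated as not significantly different.
    """
    names = list(group_order)
    basis: dict[tuple[str, str], bool] = {}
    for pc in pairs:
        key = tuple(sorted((pc.group_a, pc.group_b)))
        if key in basis and basis[key] != pc.significant:
            raise DataError(f"contradictory significance for pair {key}")
        basis[key] = pc.significant
    nonsig = {frozenset((a, b)) for a, b in itertools.combinations(names, 2)
              if not basis.get(tuple(sorted((a, b))), False)}

    classes = None
    if len(names) <= 12:
        classes = _exact_cover(names, nonsig)
    if classes is None:
        classes = _insert_absorb(names, nonsig)
    # deterministic ordering: by first member in group_order
    classes.sort(key=lambda c: min(names.index(g) for g in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in names}
    for letter, cls in zip(alphabet, classes):
        for g in names:
            if g in cls:
                letters[g] += letter
    return LetterAssignment(letters=letters, basis=basis)
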