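"""Seeded dataset generators emulating the two validation scenarios.

``three_group_clean`` emulates a genotype comparison (WT/KO/KI): three
normal, homoscedastic groups with means separated by >= 5 within-group SDs,
so both assumption checks pass and every pairwise contrast is significant.

``viability_dirty`` emulates a five-group cell-viability assay
(ctrl/A/B/C/D, n drawn uniformly from 8-12 per group) engineered to violate
the parametric prerequisites in a way no monotone transform can repair:
group-dependent variances (Brown-Forsythe fails), lognormal skew, and a
bimodal responder/non-responder group (residual normality keeps failing
after log10 or Box-Cox).  A ceiling effect caps values near an upper
viability plateau.

``null_k_groups`` draws i.i.d. N(0, 1) groups for operating-characteristic
(type-I error) studies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .dataset_io import Dataset, Observation


@dataclass(frozen=True)
class FixtureSpec:
    kind: str  # three_group_clean | viability_dirty | null_k_groups
    seed: int = 0
    n_per_group: Optional[int] = None  # fixed n; viability_dirty samples 8-12 if None
    k_groups: int = 3  # null_k_groups only
    effect_scale: float = 1.0  # three_group_clean: multiplies the mean separation


def _clean(rng: np.random.Generator, n: int, effect_scale: float) -> Dataset:
    sigma = 1.0
    means = {"WT": 10.0, "KO": 10.0 + 5.0 * sigma * effect_scale,
             "KI": 10.0 + 10.0 * sigma * effect_scale}
    obs = [Observation(g, float(v))
           for g in ("WT", "KO", "KI")
           for v in rng.normal(means[g], sigma, size=n)]
    return Dataset(obs, ["WT", "KO", "KI"], source="fixture:three_group_clean")


def _viability(rng: np.random.Generator, n_fixed: Optional[int]) -> Dataset:
    ceiling = 130.0  # assay plateau: values cannot exceed ~130 % of control
    obs: list[Observation] = []
    for g in ("ctrl", "A", "B", "C", "D"):
        n = n_fixed if n_fixed is not None else int(rng.integers(8, 13))
        if g == "ctrl":  # well-behaved reference, tight variance
            v = rng.normal(100.0, 3.0, n)
        elif g == "A":  # strong lognormal right-skew, inflated variance
            v = 55.0 + rng.lognormal(mean=2.2, sigma=0.9, size=n)
        elif g == "B":  # bimodal responders vs non-responders
            comp = rng.random(n) < 0.5
            v = np.where(comp, rng.normal(35.0, 3.0, n), rng.normal(95.0, 3.0, n))
        elif g == "C":  # clean mid-level group
            v = rng.normal(70.0, 4.0, n)
        else:  # D: heavy-tailed with occasional extreme survivors
            v = 45.0 + rng.standard_t(df=2, size=n) * 12.0
        v = np.clip(v, 1.0, ceiling)
        obs.extend(Observation(g, float(x)) for x in v)
    return Dataset(obs, ["ctrl", "A", "B", "C", "D"], source="fixture:viability_dirty")


def _null(rng: np.random.Generator, k: int, n: int) -> Dataset:
    labels = [f"g{i + 1}" for i in range(k)]
    obs = [Observation(g, float(v)) for g in labels for v in rng.normal(0.0, 1.0, n)]
    return Dataset(obs, labels, source="fixture:null_k_groups")


def generate(spec: FixtureSpec) -> Dataset:
    """Generate the dataset described by ``spec`` (same spec -> same data)."""
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "three_group_clean":
        return _clean(rng, spec.n_per_group or 8, spec.effect_scale)
    if spec.kind == "viability_dirty":
        return _viability(rng, spec.n_per_group)
    if spec.kind == "null_k_groups":
        return _null(rng, spec.k_groups, spec.n_per_group or 10)
    raise ValueError(f"unknown fixture kind {spec.kind!r}")
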