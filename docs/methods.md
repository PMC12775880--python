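# Methods

## The decision model

The engine treats test selection as a deterministic state machine over
assumption evidence.  Exactly two decisions are delegated to the user — the
transformation (when raw normality fails) and the post-hoc procedure (after a
significant omnibus test); everything else is forced by the data.

Normality is judged at two different granularities on purpose.  Before any
transformation, each group is tested separately with Shapiro–Wilk: a single
skewed group is enough to make the pooled parametric model suspect, and
per-group testing localizes the problem for the user.  After a
transformation, the check moves to the one-way model residuals
$x_{ij} - \bar x_{\cdot j}$: residuals pool all groups after removing the
group effect, which is the quantity the ANOVA error assumption actually
constrains, and pooling restores power that small per-group samples lack.
A group too small to test (n < 3) or with zero variance makes normality
"not testable" and is treated as a failure — the conservative direction,
pushing toward rank tests.

Homoscedasticity always uses the Brown–Forsythe variant (absolute deviations
from the group *median*, then a one-way ANOVA on those deviations).  Median
centering buys robustness to outliers and skew at a price worth documenting:
under normal data with k = 3, n = 15 the test is conservative (empirical size
≈ 0.030 at nominal α = 0.05, measured over 20 000 replicates; the
mean-centered variant sits at ≈ 0.058).  The mean-centered form is available
via `center="mean"` / `--center mean`.

Branch rule, applied to the latest assumption report:

| normality | homoscedasticity | branch |
|---|---|---|
| pass | pass | parametric (classical) |
| pass | fail | parametric, Welch variant |
| fail | — (no transform tried) | request transformation |
| fail | — (transform tried) | nonparametric |

The Welch routing is an inferred rule: Welch's t-test and ANOVA exist
precisely for the normal-but-heteroscedastic case, and the trace labels the
rule as inferred whenever it fires.  If the chosen transformation is
inapplicable to the data (non-positive values for log10/Box–Cox, values
outside [0, 1] for arcsine), the engine records the domain failure and routes
to the nonparametric branch; it never shifts, offsets, or clips data to force
a transform through.

Repeated-measures (>2 conditions), two-way, and mixed designs have no
implemented nonparametric fallback (rank-transform and Friedman-type
alternatives are known to inflate type-I error outside narrow conditions), so
a nonparametric requirement in those designs is a refusal: the run stops with
exit code 2 and the partial trace is still exported.

## Tests and conventions

- All p-values are two-sided.  α defaults to 0.05 and governs assumption
  checks, omnibus significance, and post-hoc flags uniformly.
- Mann–Whitney U: exact enumeration p when n₁+n₂ ≤ 12 with no ties,
  otherwise normal approximation with tie-corrected variance and continuity
  correction.  Wilcoxon signed-rank: zeros dropped (counted), exact for
  n ≤ 15 without tied magnitudes, else corrected normal approximation.  The
  reported statistic is V⁺, the positive-rank sum.
- Kruskal–Wallis uses mid-ranks and the tie-correction divisor
  $1 - \sum(t^3 - t)/(N^3 - N)$; an all-tied sample reports H = 0, p = 1.
- Cohen's d uses the pooled SD for independent comparisons — also for Welch
  tests, so effect sizes stay comparable across the two routes — and the SD
  of paired differences for dependent ones.
- Tukey HSD takes p from the studentized-range distribution with the
  Tukey–Kramer unequal-n adjustment.  Dunnett's adjusted p comes from the
  (k−1)-variate t distribution, integrated by a fixed-seed quasi-Monte-Carlo
  scheme so identical runs give identical workbooks.  Šídák adjustment is
  $p_{adj} = 1 - (1 - p)^m$; Dunn's test runs on pooled mid-ranks with the
  subtractive tie correction and Šídák adjustment by default.
- RM-ANOVA is the univariate one-within-factor form with error term
  MS(treatment × subject); no sphericity correction is applied and every
  result carries a "sphericity not assessed" note.  A design with no
  condition effect at all (flat profiles) reports F = 0, p = 1 rather than
  0/0.  Unbalanced two-way designs use Type-II sums of squares (noted in the
  result); balanced designs reduce to the classical decomposition.
- Box–Cox λ maximizes the profile log-likelihood over [−5, 5] with a bounded
  scalar optimizer (tolerance 1e-5), estimated once on the pooled values of
  all selected groups and applied identically to every group: per-group λ
  would destroy comparability of transformed means.
- Compact letters: for ≤ 12 groups the assignment is an exact minimum clique
  cover of the nonsignificance graph (so the letter count is provably
  minimal); beyond that the insert-and-absorb heuristic is used.  Groups
  share a letter iff their comparison is not significant.
- Displayed p-values below the floor (default 0.001) print as "p < 0.001";
  stored numbers keep full precision.

## Reproducibility and timestamps

With fixed choices and seed, a run is deterministic end to end.  Analysis-log
timestamps are therefore a logical clock (monotone step counter rendered
`T+000`, `T+001`, …) by default, making two exports of the same analysis
byte-identical in text content; `WorkflowConfig(wall_clock=True)` switches to
real ISO timestamps when an operator wants wall-clock provenance instead of
reproducibility.  SVG plots are rendered with a fixed hash salt and no
embedded date for the same reason.

## Synthetic data

The two generators emulate the *statistical structure* of typical validation
datasets, not any particular measured values:

- `three_group_clean` — three normal groups (WT/KO/KI), common σ = 1, n = 8,
  means 5σ apart: both assumption checks pass (except for the unavoidable
  α-level false-alarm rate of the checks themselves) and every pairwise
  contrast is overwhelmingly significant.  Because the raw stage runs four
  true-null tests at α = 0.05, the joint pass probability is bounded by
  0.95⁴ ≈ 0.815; the calibration suite tests against that ceiling.
- `viability_dirty` — five groups (ctrl/A/B/C/D, n ∈ [8, 12] drawn per
  group) on a 0–130 % viability scale: a tight control, a lognormally skewed
  group, a bimodal responder/non-responder group, a clean mid-level group,
  and a heavy-tailed group, all capped at an assay plateau.  Variance
  heterogeneity makes Brown–Forsythe fail, and the bimodal group defeats any
  monotone transform — log10 and pooled-λ Box–Cox leave residual normality
  failing (each violation holds with probability ≥ 0.8 over seeds, verified
  over 200 seeds).  Real viability data add features not modeled here:
  plate-edge effects, technical-replicate correlation, batch drift.  A green
  calibration test therefore establishes that the *decision logic* behaves
  correctly on data with these pathologies, not that the generator matches
  any specific assay.
- `null_k_groups` — i.i.d. N(0, 1), for operating-characteristic studies.
  The full-pipeline family-wise error rate with fixed choices (Box–Cox,
  Tukey) over 2000 null replicates lands in [0.03, 0.08]: runs that fail raw
  normality by chance cannot apply Box–Cox to negative data and are routed
  to Kruskal–Wallis + Dunn, and the mixture of both paths still controls the
  error rate.

The Box–Cox recovery suite generates data as $(1 + \lambda z)^{1/\lambda}$
with $z \sim N(\mu, \sigma)$ chosen per λ to keep the base positive.  The
Fisher information for λ scales with the data's relative spread, so per-seed
tolerances widen with the design's |λ| (from ±0.4 at λ = 0 to ±2.0 at λ = 2,
about 3.5 sampling SDs each); the mean over 50 seeds must recover λ within
±0.25 everywhere.

## Known limitations

- No sphericity assessment or Greenhouse–Geisser correction for
  repeated-measures designs (the permanent note keeps the omission visible).
- No nonparametric alternatives for RM/two-way/mixed designs — by design, a
  refusal rather than a silent fallback.
- One transformation attempt per run by default (`retry_transform` permits a
  second); Yeo–Johnson and rank-based inverse-normal transforms are out of
  scope.
- Outlier tests are applied per group, matching the per-group normality
  philosophy; pooled-sample screening is not offered.
- Effect sizes beyond Cohen's d (η², rank-biserial) are not reported.
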