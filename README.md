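# statpilot

Assumption-guided statistical analysis for long-format group data, as a
headless library and CLI.

Bench scientists comparing treatment groups (RT-qPCR, western blots,
viability or cytotoxicity assays, repeated morphology measurements) routinely
face the same decision problem: is a parametric test valid for these data,
and if not, what is the correct alternative?  Picking the wrong branch —
running an ANOVA on skewed, heteroscedastic viability data, say — produces
significances that vanish under the correct rank-based test.  `statpilot`
automates that decision and leaves a complete audit trail, so the analysis
is reproducible and the reasoning inspectable.

## The workflow

Given observations $x_{ij}$ (group $j$, replicate $i$):

1. **Screening** — per-group descriptives, optional outlier flagging by a
   single-pass two-sided Grubbs test ($G = \max_i |x_i - \bar x| / s$ vs the
   $t$-based critical value) or the modified Z-score
   ($M_i = 0.6745\,(x_i - \tilde x)/\mathrm{MAD}$, cutoff 3.5).  Flagged
   points are highlighted, never silently removed.
2. **Assumption check (raw)** — Shapiro–Wilk per group, Brown–Forsythe
   (Levene centered on the group median) across groups, both at α = 0.05.
3. **Branching** — both pass → classical parametric test; normality passes
   but variances differ → Welch variant; normality fails → the user chooses
   one transformation (log10, Box–Cox with pooled maximum-likelihood λ over
   [−5, 5], or arcsine-square-root), after which normality is re-checked on
   the model residuals $x_{ij} - \bar x_{\cdot j}$.  Still failing →
   nonparametric branch (Mann–Whitney U / Wilcoxon signed-rank /
   Kruskal–Wallis with tie correction).
4. **Designs without a valid fallback** — repeated-measures (>2 conditions),
   two-way, and mixed ANOVAs have no trustworthy nonparametric alternative;
   when their assumptions cannot be met the run is *refused* (exit code 2)
   rather than analyzed invalidly.
5. **Post-hoc** — only after a significant omnibus test, gated by branch:
   Tukey HSD, Dunnett (vs control), or Šídák over selected pairs on the
   parametric branch; Dunn's test or Šídák-adjusted Mann–Whitney pairs on the
   nonparametric branch.  Cohen's d (pooled SD, or SD of paired differences)
   accompanies parametric comparisons; compact significance letters are
   assigned so groups share a letter iff not significantly different.
6. **Export** — an eight-sheet XLSX workbook (Summary, Assumptions,
   Statistical Results, Descriptive Statistics, Decision Tree, Raw Data,
   Pairwise Comparisons, Analysis Log) plus optional bar/box/violin plots
   (SVG/PNG) with letters or significance bars.

## Worked example

```sh
statpilot fixtures --kind three_group_clean --seed 1 --out s1.csv
statpilot analyze --in s1.csv --choices transform=boxcox,posthoc=tukey --out results.xlsx
```

prints the executed decision path:

```
[plan] Design & group count: independent design, k=3, candidates: One-Way ANOVA, Kruskal-Wallis
[raw_check] Assumption check (raw): pass
[branch] Branch decision: parametric
[omnibus:One-Way ANOVA] One-Way ANOVA: p=5.16417e-18 -> significant
[posthoc] Post-hoc comparisons: tukey: 3 of 3 pairs significant
workbook written to results.xlsx
```

The three groups (WT/KO/KI, n = 8, means 5 within-group SDs apart) pass both
assumption checks, so the classical one-way ANOVA runs (F = 454.6, displayed
as "p < 0.001") and all three Tukey pairs are significant, lettered a/b/c.
The same command on `--kind viability_dirty` data (five skewed,
heteroscedastic, partly bimodal groups) fails the raw checks, fails the
residual normality check after the chosen transform, and correctly ends on
Kruskal–Wallis — the path a naive parametric analysis would have gotten wrong.

In Python the same run is:

```python
from statpilot import WorkflowConfig, run_workflow, export_workbook
from statpilot.fixtures import FixtureSpec, generate

ds = generate(FixtureSpec("three_group_clean", seed=1))
result = run_workflow(ds, WorkflowConfig(), {"posthoc": "tukey"})
export_workbook(result, "results.xlsx")
```

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
regenerates both validation-style datasets from the given seed, runs the full
workflow on each (parametric path and refused-transform nonparametric path),
exports both workbooks next to the JSON file, and writes the results object.

## Layout

- `src/statpilot/dataset_io.py` — CSV/XLSX ingestion, validation, template
- `src/statpilot/screening.py` — descriptives, Grubbs, modified Z-score
- `src/statpilot/assumptions.py` — Shapiro–Wilk, Brown–Forsythe, residuals
- `src/statpilot/transforms.py` — log10, Box–Cox (ML λ), arcsine-sqrt
- `src/statpilot/inference.py` — t/paired-t/ANOVA/Welch/KW/MWU/Wilcoxon/RM/two-way/mixed
- `src/statpilot/posthoc.py` — Tukey, Dunnett, Šídák, Dunn, compact letters
- `src/statpilot/engine.py` — the decision state machine and trace
- `src/statpilot/reporting.py` — eight-sheet workbook export
- `src/statpilot/plots.py`, `src/statpilot/fixtures.py`, `src/statpilot/cli.py`

See `docs/methods.md` for the statistical details and design decisions.
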