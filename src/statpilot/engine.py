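"""The decision engine: routes a dataset through the only valid test path.

The workflow is a small state machine.  After planning (design and group
count) and optional outlier screening, the raw assumption check runs
per-group Shapiro-Wilk plus Brown-Forsythe.  Both passing selects the
classical parametric test; normality passing with unequal variances selects
the Welch variant; a normality failure triggers the first of the two user
decisions — the transformation — after which the residual-based normality
check and Brown-Forsythe are repeated on the transformed data.  If the
transformed data still fail, the nonparametric branch is taken.  Designs
without a nonparametric fallback (dependent >2 groups, two-way, mixed) are
refused outright rather than analyzed invalidly.  The second user decision
is the branch-gated post-hoc menu after a significant omnibus test.

Every decision is recorded as a node in a replayable trace; with fixed
choices and seed the entire analysis is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable, Optional, Sequence, Union

import numpy as np

from . import screening
from .assumptions import AssumptionReport, assess
from .dataset_io import DataError, Dataset
from .inference import (
    OmnibusResult,
    kruskal_wallis,
    mann_whitney_u,
    mixed_anova,
    one_way_anova,
    paired_t_test,
    rm_anova,
    t_test,
    two_way_anova,
    wilcoxon_signed_rank,
)
from .posthoc import (
    NONPARAMETRIC_MENU,
    PARAMETRIC_MENU,
    LetterAssignment,
    PairwiseComparison,
    compact_letters,
    dunn_test,
    dunnett_test,
    sidak_pairs,
    tukey_hsd,
)
from .transforms import TransformDomainError, TransformRecord, apply_transform


class UnsupportedDesignError(RuntimeError):
    """A statistically required path does not exist for this design.

    Carries the partial :class:`AnalysisResult` (``.result``) so callers can
    still export the audit trail.
    """

    def __init__(self, message: str, result: "AnalysisResult | None" = None):
        super().__init__(message)
        self.result = result


class ChoiceNeededError(RuntimeError):
    """A required user decision was not supplied in non-interactive mode."""


@dataclass
class WorkflowConfig:
    alpha: float = 0.05
    outlier_method: str = "none"  # none | grubbs | modified_z
    outlier_alpha: float = 0.05
    modz_threshold: float = 3.5
    drop_outliers: bool = False
    percent_scale: bool = False
    center: str = "median"  # Brown-Forsythe centering
    force_posthoc: bool = False
    retry_transform: bool = False
    p_display_floor: float = 0.001
    seed: int = 0
    ci_level: float = 0.95
    wall_clock: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.p_display_floor < 1:
            raise ValueError("p_display_floor must be in (0, 1)")


@dataclass
class AnalysisPlan:
    design: str  # independent | dependent
    k_groups: int
    factors: int
    candidate_tests: list[str]


@dataclass
class DecisionNode:
    id: str
    label: str
    evidence: str
    outcome: str
    chosen: bool = True


@dataclass
class DecisionTrace:
    nodes: list[DecisionNode] = field(default_factory=list)
    config: Optional[dict] = None
    timestamps: list[str] = field(default_factory=list)

    def executed_ids(self) -> list[str]:
        return [n.id for n in self.nodes]


@dataclass
class AnalysisResult:
    dataset: Dataset
    plan: Optional[AnalysisPlan] = None
    trace: DecisionTrace = field(default_factory=DecisionTrace)
    assumption_reports: list[AssumptionReport] = field(default_factory=list)
    transform_record: Optional[TransformRecord] = None
    transformed_dataset: Optional[Dataset] = None
    omnibus: list[OmnibusResult] = field(default_factory=list)
    pairwise: list[PairwiseComparison] = field(default_factory=list)
    letters: Optional[LetterAssignment] = None
    descriptives: list[screening.GroupSummary] = field(default_factory=list)
    outlier_reports: dict[str, screening.OutlierReport] = field(default_factory=dict)
    log: list[tuple[str, str, str]] = field(default_factory=list)  # (time, level, message)
    branch: Optional[str] = None
    status: str = "running"  # running | completed | refused | error
    error_message: str = ""
    config: Optional[WorkflowConfig] = None
    _clock: int = 0

    def _now(self) -> str:
        if self.config is not None and self.config.wall_clock:
            import datetime

            return datetime.datetime.now().isoformat(timespec="seconds")
        t = f"T+{self._clock:03d}"
        self._clock += 1
        return t


def log_event(run: AnalysisResult, level: str, message: str) -> tuple[str, str, str]:
    """Append one entry to the analysis log (append-only, monotone timestamps)."""
    entry = (run._now(), level, message)
    run.log.append(entry)
    return entry


def _add_node(run: AnalysisResult, node_id: str, label: str, evidence: str,
              outcome: str) -> DecisionNode:
    node = DecisionNode(node_id, label, evidence, outcome)
    run.trace.nodes.append(node)
    run.trace.timestamps.append(run.log[-1][0] if run.log else "T+000")
    log_event(run, "INFO", f"{label}: {outcome}")
    return node


Choices = Union[dict, Callable[[str, Sequence[str]], str], None]


def _get_choice(choices: Choices, key: str, options: Sequence[str],
                default: Optional[str] = None) -> str:
    if callable(choices):
        return str(choices(key, list(options)))
    if isinstance(choices, dict) and key in choices:
        return str(choices[key])
    if default is not None:
        return default
    raise ChoiceNeededError(
        f"a {key!r} choice is required (options: {list(options)}) but none was supplied")


def plan_analysis(ds: Dataset) -> AnalysisPlan:
    """Determine design, group count and the candidate test family."""
    design = "dependent" if ds.has_subjects else "independent"
    factors = 2 if ds.has_factor2 else 1
    k = ds.k_groups
    if factors == 2:
        candidates = ["Mixed ANOVA"] if design == "dependent" else ["Two-Way ANOVA"]
    elif design == "independent":
        candidates = ["t-test", "Mann-Whitney U"] if k == 2 \
            else ["One-Way ANOVA", "Kruskal-Wallis"]
    else:
        candidates = ["paired t-test", "Wilcoxon signed-rank"] if k == 2 \
            else ["Repeated-Measures ANOVA"]
    return AnalysisPlan(design=design, k_groups=k, factors=factors,
                        candidate_tests=candidates)


def select_branch(raw: AssumptionReport,
                  post: Optional[AssumptionReport] = None) -> str:
    """Branch rule on the latest assumption report.

    normality && homoscedasticity -> parametric; normality only ->
    parametric_welch; no normality -> request a transform first, then
    nonparametric if the transformed data still fail.
    """
    report = post if post is not None else raw
    if report.normality_pass:
        return "parametric" if report.homoscedasticity_pass else "parametric_welch"
    return "nonparametric" if post is not None else "request_transform"


def _nonparametric_unsupported(plan: AnalysisPlan) -> Optional[str]:
    if plan.factors == 2:
        kind = "Mixed-Model ANOVA" if plan.design == "dependent" else "Two-Way ANOVA"
        return (f"nonparametric alternatives for Two-Way-, Mixed-Model- and "
                f"Repeated-Measures-ANOVAs cannot be performed (design: {kind})")
    if plan.design == "dependent" and plan.k_groups > 2:
        return ("nonparametric alternatives for Two-Way-, Mixed-Model- and "
                "Repeated-Measures-ANOVAs cannot be performed "
                "(design: dependent with >2 groups)")
    return None


def _paired_arrays(ds: Dataset) -> list[tuple[float, float]]:
    by_subject: dict[str, dict[str, float]] = {}
    for o in ds.observations:
        by_subject.setdefault(o.subject, {})[o.group] = o.value
    g1, g2 = ds.group_order
    missing = [(s, g) for s, d in by_subject.items() for g in (g1, g2) if g not in d]
    if missing:
        raise DataError(f"incomplete paired design; missing (subject, group): {missing}")
    return [(d[g1], d[g2]) for _, d in sorted(by_subject.items())]


def _run_outlier_screen(run: AnalysisResult, ds: Dataset,
                        cfg: WorkflowConfig) -> Dataset:
    reports = {}
    flagged_total = 0
    by = ds.values_by_group()
    keep_mask: dict[str, list[bool]] = {}
    for g in ds.group_order:
        vals = by[g]
        try:
            if cfg.outlier_method == "grubbs":
                rep = screening.grubbs_test(vals, alpha=cfg.outlier_alpha)
            else:
                rep = screening.modified_zscore(vals, threshold=cfg.modz_threshold)
        except ValueError as exc:
            rep = screening.OutlierReport(cfg.outlier_method, cfg.outlier_alpha,
                                          note=f"not testable: {exc}")
        reports[g] = rep
        flagged_total += rep.n_flagged
        mask = [True] * len(vals)
        for i in rep.flagged_indices:
            mask[i] = False
        keep_mask[g] = mask
    run.outlier_reports = reports
    outcome = f"{cfg.outlier_method} per group: {flagged_total} point(s) flagged"
    if cfg.drop_outliers and flagged_total:
        seen: dict[str, int] = {g: 0 for g in ds.group_order}
        kept = []
        for o in ds.observations:
            i = seen[o.group]
            seen[o.group] += 1
            if keep_mask[o.group][i]:
                kept.append(o)
        ds = Dataset(observations=kept, group_order=list(ds.group_order),
                     source=ds.source)
        outcome += "; flagged points removed before analysis (--drop-outliers)"
    elif flagged_total:
        outcome += "; flagged points highlighted only, not removed"
    _add_node(run, "outliers", "Outlier screening", cfg.outlier_method, outcome)
    return ds


def _fmt_report(rep: AssumptionReport) -> str:
    bits = []
    if rep.stage == "raw":
        ps = ", ".join(f"{g}: p={tr.p:.4f}" if tr.testable else f"{g}: not testable"
                       for g, tr in rep.per_group_normality)
        bits.append(f"Shapiro-Wilk per group [{ps}]")
    else:
        tr = rep.residual_normality
        bits.append("residual Shapiro-Wilk "
                    + (f"p={tr.p:.4f}" if tr is not None and tr.testable else "not testable"))
    bits.append(f"Brown-Forsythe p={rep.homoscedasticity.p:.4f}")
    bits.append(f"normality {'pass' if rep.normality_pass else 'FAIL'}, "
                f"homoscedasticity {'pass' if rep.homoscedasticity_pass else 'FAIL'}")
    return "; ".join(bits)


def _omnibus_for(plan: AnalysisPlan, ds: Dataset, branch: str,
                 cfg: WorkflowConfig) -> list[OmnibusResult]:
    groups = ds.group_arrays()
    a = cfg.alpha
    if plan.factors == 2:
        results = mixed_anova(ds, alpha=a) if plan.design == "dependent" \
            else two_way_anova(ds, alpha=a)
        return results
    if plan.design == "independent":
        if plan.k_groups == 2:
            if branch == "nonparametric":
                tr = mann_whitney_u(groups[0], groups[1])
                return [OmnibusResult(tr.test_name, tr.statistic_name, tr.statistic,
                                      tr.p, df=tr.df, n_used=tr.n_used, notes=tr.notes,
                                      design="independent", k_groups=2,
                                      branch="nonparametric", alpha=a)]
            variant = "welch" if branch == "parametric_welch" else "student"
            tr, es = t_test(groups[0], groups[1], variant=variant)
            om = OmnibusResult(tr.test_name, tr.statistic_name, tr.statistic, tr.p,
                               df=tr.df, n_used=tr.n_used, design="independent",
                               k_groups=2, branch="parametric", alpha=a,
                               notes=f"Cohen's d = {es.value:.4f} (pooled SD)")
            return [om]
        if branch == "nonparametric":
            return [kruskal_wallis(groups, alpha=a)]
        variant = "welch" if branch == "parametric_welch" else "classic"
        return [one_way_anova(groups, variant=variant, alpha=a)]
    # dependent designs
    if plan.k_groups == 2:
        pairs = _paired_arrays(ds)
        if branch == "nonparametric":
            tr = wilcoxon_signed_rank(pairs)
            return [OmnibusResult(tr.test_name, tr.statistic_name, tr.statistic, tr.p,
                                  df=tr.df, n_used=tr.n_used, notes=tr.notes,
                                  design="dependent", k_groups=2,
                                  branch="nonparametric", alpha=a)]
        tr, es = paired_t_test(pairs)
        return [OmnibusResult(tr.test_name, tr.statistic_name, tr.statistic, tr.p,
                              df=tr.df, n_used=tr.n_used, design="dependent",
                              k_groups=2, branch="parametric", alpha=a,
                              notes=f"Cohen's d = {es.value:.4f} (SD of differences)")]
    res = rm_anova(ds, alpha=a)
    if branch == "parametric_welch":
        res.notes += "; no Welch variant exists for repeated measures, classical form used"
    return [res]


def _run_posthoc(run: AnalysisResult, plan: AnalysisPlan, ds: Dataset, branch: str,
                 cfg: WorkflowConfig, choices: Choices) -> None:
    menu = PARAMETRIC_MENU if branch != "nonparametric" else NONPARAMETRIC_MENU
    default = "tukey" if branch != "nonparametric" else "dunn"
    choice = _get_choice(choices, "posthoc", menu, default=None)
    note = ""
    if choice not in menu:
        note = (f"requested post-hoc {choice!r} is not valid on the "
                f"{branch} branch; falling back to {default!r}")
        log_event(run, "WARNING", note)
        choice = default
    groups = ds.group_arrays()
    labels = ds.group_order
    if choice == "tukey":
        run.pairwise = tukey_hsd(groups, alpha=cfg.alpha, labels=labels)
    elif choice == "dunnett":
        control = _get_choice(choices, "control", labels, default=labels[0])
        run.pairwise = dunnett_test(groups, control=control, alpha=cfg.alpha,
                                    labels=labels, seed=cfg.seed)
    elif choice == "sidak":
        pairs_choice = None
        if isinstance(choices, dict):
            pairs_choice = choices.get("pairs")
        if pairs_choice is None:
            import itertools

            pairs_choice = list(itertools.combinations(labels, 2))
        run.pairwise = sidak_pairs(pairs_choice, branch="parametric"
                                   if branch != "nonparametric" else "nonparametric",
                                   groups=groups, labels=labels, alpha=cfg.alpha)
    elif choice == "dunn":
        run.pairwise = dunn_test(groups, adjust="sidak", alpha=cfg.alpha, labels=labels)
    outcome = f"{choice}: {sum(p.significant for p in run.pairwise)} of " \
              f"{len(run.pairwise)} pairs significant"
    if note:
        outcome += f" ({note})"
    _add_node(run, "posthoc", "Post-hoc comparisons", f"branch={branch}", outcome)
    run.letters = compact_letters(run.pairwise, labels)


def run_workflow(ds: Dataset, cfg: Optional[WorkflowConfig] = None,
                 choices: Choices = None) -> AnalysisResult:
    """Execute the full guided workflow and return a traceable result.

    ``choices`` supplies the (at most) two user decisions — the
    transformation and the post-hoc procedure — either as a dict
    (``{"transform": "log10", "posthoc": "tukey"}``) or a callback
    ``f(decision_name, options) -> str``.  Designs whose valid path would
    require an unimplemented nonparametric ANOVA raise
    :class:`UnsupportedDesignError` with the partial result attached.
    """
    cfg = cfg or WorkflowConfig()
    run = AnalysisResult(dataset=ds, config=cfg)
    run.trace.config = asdict(cfg)
    log_event(run, "INFO", f"workflow started on {ds.source} "
                           f"({len(ds.observations)} observations, {ds.k_groups} groups)")
    try:
        plan = plan_analysis(ds)
        run.plan = plan
        _add_node(run, "plan", "Design & group count",
                  f"subjects={'yes' if ds.has_subjects else 'no'}, "
                  f"factor2={'yes' if ds.has_factor2 else 'no'}",
                  f"{plan.design} design, k={plan.k_groups}, "
                  f"candidates: {', '.join(plan.candidate_tests)}")

        if cfg.outlier_method != "none":
            ds = _run_outlier_screen(run, ds, cfg)

        run.descriptives = [
            screening.summarize_group(v, group=g, ci_level=cfg.ci_level)
            for g, v in ds.values_by_group().items()
        ]

        raw = assess(ds, stage="raw", alpha=cfg.alpha, center=cfg.center)
        run.assumption_reports.append(raw)
        _add_node(run, "raw_check", "Assumption check (raw)", _fmt_report(raw),
                  "pass" if raw.normality_pass and raw.homoscedasticity_pass
                  else "at least one assumption failed")

        post: Optional[AssumptionReport] = None
        analysis_ds = ds
        branch = select_branch(raw, None)
        if branch == "request_transform":
            attempts = 2 if cfg.retry_transform else 1
            for attempt in range(attempts):
                key = "transform" if attempt == 0 else "retry_transform"
                tname = _get_choice(choices, key, ("log10", "boxcox", "arcsine"))
                pooled = np.asarray([o.value for o in ds.observations], float)
                try:
                    tvals, record = apply_transform(pooled, tname,
                                                    percent_scale=cfg.percent_scale)
                except TransformDomainError as exc:
                    record = TransformRecord("none", input_domain_note=str(exc))
                    run.transform_record = record
                    _add_node(run, "transform", "Transformation (user choice)",
                              f"choice={tname}",
                              f"not applicable: {exc}; nonparametric branch required")
                    post = None
                    branch = "nonparametric"
                    break
                run.transform_record = record
                analysis_ds = ds.with_values(tvals)
                run.transformed_dataset = analysis_ds
                lam = f", lambda={record.lambda_:.4f}" if record.lambda_ is not None else ""
                _add_node(run, "transform", "Transformation (user choice)",
                          f"choice={tname}{lam}", f"{record.name} applied to pooled values")
                post = assess(analysis_ds, stage="post_transform", alpha=cfg.alpha,
                              center=cfg.center)
                run.assumption_reports.append(post)
                _add_node(run, "post_check", "Assumption check (post-transform)",
                          _fmt_report(post),
                          "pass" if post.normality_pass else "still failing")
                branch = select_branch(raw, post)
                if branch != "nonparametric":
                    break
                if attempt + 1 < attempts:
                    log_event(run, "INFO", "transform did not rescue normality; "
                                           "second attempt permitted (--retry-transform)")
            if branch == "nonparametric" and post is not None:
                analysis_ds = ds  # rank tests run on the original values
        welch_note = ("inferred rule: normal residuals with unequal variances "
                      "route to the Welch variant")
        _add_node(run, "branch", "Branch decision",
                  f"stage={'post_transform' if post is not None else 'raw'}",
                  branch + (f" ({welch_note})" if branch == "parametric_welch" else ""))
        run.branch = branch

        if branch == "nonparametric":
            reason = _nonparametric_unsupported(plan)
            if reason is not None:
                _add_node(run, "unsupported", "Unsupported path", plan.design, reason)
                run.status = "refused"
                run.error_message = reason
                log_event(run, "ERROR", reason)
                raise UnsupportedDesignError(reason, result=run)

        omnibus = _omnibus_for(plan, analysis_ds, branch, cfg)
        run.omnibus = omnibus
        for om in omnibus:
            _add_node(run, f"omnibus:{om.test_name}", om.test_name,
                      f"{om.statistic_name}={om.statistic:.4f}, df={om.df}",
                      f"p={om.p:.6g} -> {'significant' if om.significant else 'not significant'}")

        single_factor_k3 = plan.factors == 1 and plan.k_groups > 2
        any_sig = any(om.significant for om in omnibus)
        if single_factor_k3 and (any_sig or cfg.force_posthoc):
            if not any_sig:
                log_event(run, "WARNING",
                          "post-hoc forced despite non-significant omnibus (--force-posthoc)")
            _run_posthoc(run, plan, analysis_ds, branch, cfg, choices)
        elif plan.factors == 1 and plan.k_groups == 2:
            # the omnibus is itself the pairwise comparison
            om = omnibus[0]
            g1, g2 = ds.group_order
            means = {g: float(np.mean(v)) for g, v in ds.values_by_group().items()}
            pc = PairwiseComparison(g1, g2, means[g1] - means[g2], om.statistic,
                                    om.p, om.p, method=om.test_name, alpha=cfg.alpha,
                                    notes="two-group design: omnibus is the comparison")
            run.letters = compact_letters([pc], ds.group_order)
        elif single_factor_k3:
            _add_node(run, "no_posthoc", "Post-hoc comparisons", "",
                      "skipped: omnibus not significant")

        run.status = "completed"
        log_event(run, "INFO", "workflow completed")
        return run
    except UnsupportedDesignError:
        raise
    except ChoiceNeededError as exc:
        run.status = "refused"
        run.error_message = str(exc)
        log_event(run, "ERROR", str(exc))
        raise
    except (DataError, ValueError) as exc:
        run.status = "error"
        run.error_message = str(exc)
        log_event(run, "ERROR", str(exc))
        raise


#: template decision tree: (node id, indent level, label)
TREE_TEMPLATE: list[tuple[str, int, str]] = [
    ("plan", 0, "Load data / design & group count"),
    ("outliers", 1, "Outlier screening (optional)"),
    ("raw_check", 1, "Assumption check (raw): Shapiro-Wilk per group + Brown-Forsythe"),
    ("transform", 2, "Transformation (user choice: log10 / Box-Cox / arcsine sqrt)"),
    ("post_check", 2, "Assumption check (post-transform): residual Shapiro-Wilk + Brown-Forsythe"),
    ("branch", 1, "Branch decision: parametric / parametric (Welch) / nonparametric"),
    ("unsupported", 2, "Unsupported path: no nonparametric RM / two-way / mixed ANOVA"),
    ("omnibus", 1, "Omnibus test"),
    ("posthoc", 2, "Post-hoc comparisons (user choice, branch-gated)"),
    ("no_posthoc", 2, "No post-hoc (omnibus not significant)"),
]


def render_decision_tree(trace: DecisionTrace, format: str = "text") -> str:
    """Render the template decision tree with the executed path marked.

    The text form is stable: identical traces give byte-identical output.
    """
    if not trace.nodes:
        raise ValueError("cannot render an empty trace")
    executed = {}
    for n in trace.nodes:
        key = n.id.split(":")[0]
        executed.setdefault(key, []).append(n)
    lines = ["Decision tree ([x] = executed step)"]
    for node_id, indent, label in TREE_TEMPLATE:
        mark = "[x]" if node_id in executed else "[ ]"
        line = f"{'    ' * indent}{mark} {label}"
        if node_id in executed:
            for n in executed[node_id]:
                line += f"\n{'    ' * (indent + 1)}-> {n.outcome}"
        lines.append(line)
    text = "\n".join(lines)
    if format == "text":
        return text
    if format == "svg":
        rows = text.split("\n")
        height = 20 * (len(rows) + 1)
        parts = [f'<svg xmlns="http://www.w3.org/2000/svg" width="900" height="{height}">']
        for i, row in enumerate(rows):
            esc = (row.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;"))
            parts.append(f'<text x="10" y="{20 * (i + 1)}" font-family="monospace" '
                         f'font-size="12" xml:space="preserve">{esc}</text>')
        parts.append("</svg>")
        return "\n".join(parts)
    raise ValueError(f"unknown format {format!r}")
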