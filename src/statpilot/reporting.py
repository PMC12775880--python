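"""Workbook export: the complete analysis as a traceable multi-sheet XLSX.

Every run — completed, non-significant, or refused — produces the same eight
sheets so downstream audits always find the full structure:

Summary, Assumptions, Statistical Results, Descriptive Statistics,
Decision Tree, Raw Data, Pairwise Comparisons, Analysis Log.

Numeric cells carry full precision; display strings follow the reporting
convention that p-values below the configured floor print as "p < 0.001".
"""

from __future__ import annotations

from pathlib import Path

from openpyxl import Workbook

from .engine import AnalysisResult, render_decision_tree

#: frozen workbook schema (sheet order is part of the contract)
SHEET_NAMES = (
    "Summary",
    "Assumptions",
    "Statistical Results",
    "Descriptive Statistics",
    "Decision Tree",
    "Raw Data",
    "Pairwise Comparisons",
    "Analysis Log",
)

SCHEMA_VERSION = "1"


def format_p(p: float, floor: float = 0.001) -> str:
    """Human display form of a p-value ('p < 0.001' below the floor)."""
    if p != p:  # NaN
        return "not testable"
    if p < floor:
        return f"p < {floor:g}"
    return f"p = {p:.4f}"


def _na(x, fmt: str = "{:.6g}") -> object:
    if x is None:
        return "n/a"
    if isinstance(x, float) and x != x:
        return "n/a"
    return x


def export_workbook(result: AnalysisResult, path: str | Path) -> Path:
    """Write the eight-sheet results workbook for any reachable run state."""
    path = Path(path)
    cfg = result.config
    floor = cfg.p_display_floor if cfg is not None else 0.001
    alpha = cfg.alpha if cfg is not None else 0.05
    wb = Workbook()
    wb.remove(wb.active)
    sheets = {name: wb.create_sheet(name) for name in SHEET_NAMES}

    # Summary
    ws = sheets["Summary"]
    ws.append(["Key", "Value"])
    ws.append(["Schema version", SCHEMA_VERSION])
    ws.append(["Status", result.status])
    if result.status in ("refused", "error"):
        ws.append(["Reason", result.error_message])
    ws.append(["Source", result.dataset.source])
    ws.append(["Groups", ", ".join(result.dataset.group_order)])
    ws.append(["Observations", len(result.dataset.observations)])
    if result.plan is not None:
        ws.append(["Design", result.plan.design])
        ws.append(["Factors", result.plan.factors])
        ws.append(["Candidate tests", ", ".join(result.plan.candidate_tests)])
    ws.append(["Branch", result.branch or "n/a"])
    if result.transform_record is not None:
        tr = result.transform_record
        lam = f" (lambda = {tr.lambda_:.4f})" if tr.lambda_ is not None else ""
        ws.append(["Transformation", f"{tr.name}{lam}"])
    for om in result.omnibus:
        ws.append([om.test_name,
                   f"{om.statistic_name} = {om.statistic:.4f}, {format_p(om.p, floor)}"])
    ws.append(["Alpha", alpha])

    # Assumptions
    ws = sheets["Assumptions"]
    ws.append(["Stage", "Check", "Group", "Statistic", "Value", "p (exact)",
               "p (display)", "Pass at alpha"])
    if not result.assumption_reports:
        ws.append(["(no assumption checks were reached)"])
    for rep in result.assumption_reports:
        for g, tr in rep.per_group_normality:
            ws.append([rep.stage, tr.test_name, g, tr.statistic_name,
                       _na(tr.statistic), _na(tr.p), format_p(tr.p, floor),
                       "yes" if tr.testable and tr.p >= rep.alpha else "no"])
        if rep.residual_normality is not None:
            tr = rep.residual_normality
            ws.append([rep.stage, tr.test_name, "(residuals)", tr.statistic_name,
                       _na(tr.statistic), _na(tr.p), format_p(tr.p, floor),
                       "yes" if tr.testable and tr.p >= rep.alpha else "no"])
        hm = rep.homoscedasticity
        if hm is not None:
            ws.append([rep.stage, hm.test_name, "(all)", hm.statistic_name,
                       _na(hm.statistic), _na(hm.p), format_p(hm.p, floor),
                       "yes" if rep.homoscedasticity_pass else "no"])

    # Statistical Results
    ws = sheets["Statistical Results"]
    ws.append(["Test", "Statistic", "Value", "df", "p (exact)", "p (display)",
               "Significant", "Branch", "Notes"])
    if not result.omnibus:
        ws.append(["(no omnibus test was reached)"])
    for om in result.omnibus:
        ws.append([om.test_name, om.statistic_name, om.statistic,
                   ", ".join(f"{d:g}" for d in om.df) if om.df else "",
                   om.p, format_p(om.p, floor),
                   "yes" if om.significant else "no", om.branch, om.notes])

    # Descriptive Statistics
    ws = sheets["Descriptive Statistics"]
    ws.append(["Group", "n", "Mean", "Median", "SD", "SEM",
               "CI low", "CI high", "Min", "Max"])
    if not result.descriptives:
        ws.append(["(descriptives were not reached)"])
    for d in result.descriptives:
        ws.append([d.group, d.n, d.mean, d.median, _na(d.sd), _na(d.sem),
                   _na(d.ci_low), _na(d.ci_high), d.min, d.max])

    # Decision Tree
    ws = sheets["Decision Tree"]
    if result.trace.nodes:
        for line in render_decision_tree(result.trace, format="text").split("\n"):
            ws.append([line])
    else:
        ws.append(["(empty trace)"])

    # Raw Data
    ws = sheets["Raw Data"]
    header = ["Group", "Values"]
    if result.dataset.has_subjects:
        header.append("Subject")
    if result.dataset.has_factor2:
        header.append("Factor2")
    ws.append(header)
    for o in result.dataset.observations:
        row: list[object] = [o.group, o.value]
        if result.dataset.has_subjects:
            row.append(o.subject)
        if result.dataset.has_factor2:
            row.append(o.factor2)
        ws.append(row)

    # Pairwise Comparisons
    ws = sheets["Pairwise Comparisons"]
    ws.append(["Group A", "Group B", "Method", "Estimate (A-B)", "Statistic",
               "p raw", "p adjusted", "p (display)", "Significant",
               "Cohen's d", "Letters A", "Letters B", "Notes"])
    if not result.pairwise:
        ws.append(["(no pairwise comparisons were performed)"])
    letters = result.letters.letters if result.letters else {}
    for pc in result.pairwise:
        d = pc.effect_size.value if pc.effect_size is not None else None
        ws.append([pc.group_a, pc.group_b, pc.method, pc.estimate, pc.statistic,
                   pc.p_raw, pc.p_adj, format_p(pc.p_adj, floor),
                   "yes" if pc.significant else "no", _na(d),
                   letters.get(pc.group_a, ""), letters.get(pc.group_b, ""),
                   pc.notes])

    # Analysis Log
    ws = sheets["Analysis Log"]
    ws.append(["Timestamp", "Level", "Message"])
    for t, level, message in result.log:
        ws.append([t, level, message])

    wb.save(path)
    return path


def workbook_text(path: str | Path) -> str:
    """All cell values of a workbook as one deterministic text blob (for audits)."""
    from openpyxl import load_workbook

    wb = load_workbook(path, read_only=True)
    parts = []
    for name in wb.sheetnames:
        parts.append(f"### {name}")
        for row in wb[name].iter_rows(values_only=True):
            parts.append("\t".join("" if c is None else str(c) for c in row))
    return "\n".join(parts)
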