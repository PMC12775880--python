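"""Publication plots: bar/box/violin with error bars and significance marks.

Significance can be annotated either with compact letters above each group
or with comparison bars drawn only for significant pairs.  SVG output is
deterministic (no embedded creation date), so identical runs give identical
files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .dataset_io import Dataset  # noqa: E402
from .engine import AnalysisResult  # noqa: E402


@dataclass
class PlotSpec:
    kind: str = "bar"  # bar | box | violin
    error_bar: str = "sd"  # sd | sem | ci
    annotation: str = "none"  # letters | bars | none
    title: str = ""
    ylabel: str = "Values"
    colors: Optional[Sequence[str]] = None
    output_format: str = "svg"  # svg | png
    figsize: tuple[float, float] = (6.0, 4.0)


def _error_values(result: Optional[AnalysisResult], ds: Dataset,
                  which: str) -> list[float]:
    errs = []
    by = ds.values_by_group()
    for g in ds.group_order:
        v = by[g]
        sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
        if which == "sd":
            errs.append(sd)
        elif which == "sem":
            errs.append(sd / np.sqrt(v.size))
        else:  # ci
            from scipy import stats

            sem = sd / np.sqrt(v.size)
            t = float(stats.t.ppf(0.975, v.size - 1)) if v.size > 1 else 0.0
            errs.append(t * sem)
    return errs


def make_plot(ds: Dataset, result: Optional[AnalysisResult], spec: PlotSpec,
              path: str | Path) -> Path:
    """Render the group plot described by ``spec`` and save it to ``path``."""
    path = Path(path)
    if spec.annotation == "letters" and (result is None or result.letters is None):
        raise ValueError("letter annotation requires an analysis result with letters")
    if spec.annotation == "bars" and (result is None or not result.pairwise):
        raise ValueError("bar annotation requires pairwise comparison results")

    by = ds.values_by_group()
    labels = ds.group_order
    data = [by[g] for g in labels]
    means = [float(np.mean(v)) for v in data]
    x = np.arange(len(labels))
    colors = list(spec.colors) if spec.colors else None

    fig, ax = plt.subplots(figsize=spec.figsize)
    if spec.kind == "bar":
        errs = _error_values(result, ds, spec.error_bar)
        ax.bar(x, means, yerr=errs, capsize=4, color=colors,
               edgecolor="black", linewidth=0.8)
        tops = [m + e for m, e in zip(means, errs)]
    elif spec.kind == "box":
        ax.boxplot(data, positions=x, widths=0.6)
        tops = [float(np.max(v)) for v in data]
    elif spec.kind == "violin":
        ax.violinplot(data, positions=x, widths=0.6, showmedians=True)
        tops = [float(np.max(v)) for v in data]
    else:
        raise ValueError(f"unknown plot kind {spec.kind!r}")

    ax.set_xticks(x)
    ax.set_xticklabels(labels)
    ax.set_ylabel(spec.ylabel)
    if spec.title:
        ax.set_title(spec.title)

    span = max(max(tops) - min(0.0, min(float(np.min(v)) for v in data)), 1e-9)
    if spec.annotation == "letters":
        letters = result.letters.letters
        for xi, g, top in zip(x, labels, tops):
            ax.text(xi, top + 0.04 * span, letters.get(g, ""),
                    ha="center", va="bottom", fontsize=11)
        ax.set_ylim(top=max(tops) + 0.15 * span)
    elif spec.annotation == "bars":
        sig = [pc for pc in result.pairwise if pc.significant]
        y = max(tops) + 0.06 * span
        idx = {g: i for i, g in enumerate(labels)}
        for pc in sig:
            xa, xb = idx[pc.group_a], idx[pc.group_b]
            ax.plot([xa, xa, xb, xb], [y, y + 0.02 * span, y + 0.02 * span, y],
                    color="black", linewidth=1.0, gid="sigbar")
            ax.text((xa + xb) / 2, y + 0.025 * span, _stars(pc.p_adj),
                    ha="center", va="bottom", fontsize=10)
            y += 0.08 * span
        if sig:
            ax.set_ylim(top=y + 0.05 * span)

    fig.tight_layout()
    if spec.output_format == "svg" or str(path).endswith(".svg"):
        # fixed hashsalt keeps clip-path ids, hence the whole file, reproducible
        with matplotlib.rc_context({"svg.hashsalt": "statpilot"}):
            fig.savefig(path, format="svg", metadata={"Date": None})
    else:
        fig.savefig(path, format=spec.output_format)
    plt.close(fig)
    return path


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
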