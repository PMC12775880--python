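"""Reading, validating and normalizing long-format experimental tables.

The canonical input is a long-format table with one categorical group column
and one numeric value column, plus optional subject-ID (dependent designs)
and second-factor columns.  Rows with missing or non-numeric values are
dropped and counted, never imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd


class DataError(ValueError):
    """Invalid input data or column mapping."""


@dataclass(frozen=True)
class ColumnMapping:
    """Maps source-table columns onto the group/value/subject/factor roles."""

    group_column: str = "Group"
    value_column: str = "Values"
    subject_column: Optional[str] = None
    factor2_column: Optional[str] = None
    sheet: Optional[str] = None
    decimal: str = "."

    def __post_init__(self) -> None:
        if self.group_column == self.value_column:
            raise DataError("group column and value column must differ")
        if self.decimal not in (".", ","):
            raise DataError(f"decimal must be '.' or ',', got {self.decimal!r}")


@dataclass(frozen=True)
class Observation:
    group: str
    value: float
    subject: Optional[str] = None
    factor2: Optional[str] = None


@dataclass
class ValidationReport:
    n_rows_read: int = 0
    n_rows_dropped: int = 0
    drop_reasons: list[tuple[int, str]] = field(default_factory=list)
    groups_found: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


@dataclass
class Dataset:
    """Long-format observations with an explicit group order.

    Invariants: all values finite; >= 2 distinct groups; subject labels are
    all-or-nothing across observations; ``group_order`` is a permutation of
    the distinct group labels.
    """

    observations: list[Observation]
    group_order: list[str]
    source: str = "<memory>"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if len(self.group_order) < 2:
            raise DataError("a dataset needs at least 2 distinct groups")
        present = {o.group for o in self.observations}
        if set(self.group_order) != present:
            raise DataError("group_order must be a permutation of the group labels present")
        if len(set(self.group_order)) != len(self.group_order):
            raise DataError("group_order contains duplicate labels")
        for o in self.observations:
            if not np.isfinite(o.value):
                raise DataError(f"non-finite value {o.value!r} in group {o.group!r}")
        has_subj = [o.subject is not None for o in self.observations]
        if any(has_subj) and not all(has_subj):
            raise DataError("subject labels must be present on every observation or none")
        if self.has_subjects:
            seen = set()
            for o in self.observations:
                key = (o.subject, o.group, o.factor2)
                if key in seen:
                    raise DataError(
                        f"duplicate observation for subject {o.subject!r} in group "
                        f"{o.group!r}; technical replicates must be resolved upstream"
                    )
                seen.add(key)

    @property
    def has_subjects(self) -> bool:
        return bool(self.observations) and self.observations[0].subject is not None

    @property
    def has_factor2(self) -> bool:
        return any(o.factor2 is not None for o in self.observations)

    @property
    def k_groups(self) -> int:
        return len(self.group_order)

    def values_by_group(self) -> dict[str, np.ndarray]:
        out: dict[str, list[float]] = {g: [] for g in self.group_order}
        for o in self.observations:
            out[o.group].append(o.value)
        return {g: np.asarray(v, dtype=float) for g, v in out.items()}

    def group_arrays(self) -> list[np.ndarray]:
        by = self.values_by_group()
        return [by[g] for g in self.group_order]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "Group": [o.group for o in self.observations],
                "Values": [o.value for o in self.observations],
            }
        )
        if self.has_subjects:
            df["Subject"] = [o.subject for o in self.observations]
        if self.has_factor2:
            df["Factor2"] = [o.factor2 for o in self.observations]
        return df

    def with_values(self, new_values: Sequence[float]) -> "Dataset":
        """Same design, transformed values (used after a transformation)."""
        if len(new_values) != len(self.observations):
            raise DataError("value vector length mismatch")
        obs = [replace(o, value=float(v)) for o, v in zip(self.observations, new_values)]
        ds = Dataset.__new__(Dataset)
        ds.observations = obs
        ds.group_order = list(self.group_order)
        ds.source = self.source
        ds.validate()
        return ds


def _clean_label(x: object) -> Optional[str]:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return None
    s = str(x).strip()
    return s if s else None


def _coerce_value(x: object, decimal: str) -> Optional[float]:
    if x is None:
        return None
    if isinstance(x, (int, float, np.floating, np.integer)):
        v = float(x)
        return v if np.isfinite(v) else None
    s = str(x).strip()
    if not s:
        return None
    if decimal == ",":
        if "." in s:  # thousands separators are not supported
            return None
        s = s.replace(",", ".")
    try:
        v = float(s)
    except ValueError:
        return None
    return v if np.isfinite(v) else None


def _frame_to_dataset(
    df: pd.DataFrame, mapping: ColumnMapping, source: str
) -> tuple[Dataset, ValidationReport]:
    report = ValidationReport(n_rows_read=len(df))
    needed = [mapping.group_column, mapping.value_column]
    if mapping.subject_column:
        needed.append(mapping.subject_column)
    if mapping.factor2_column:
        needed.append(mapping.factor2_column)
    for col in needed:
        if col not in df.columns:
            raise DataError(f"column {col!r} not found; available: {list(df.columns)}")

    obs: list[Observation] = []
    order: list[str] = []
    for idx, row in df.iterrows():
        group = _clean_label(row[mapping.group_column])
        value = _coerce_value(row[mapping.value_column], mapping.decimal)
        if group is None:
            report.drop_reasons.append((int(idx), "missing group label"))
            continue
        if value is None:
            report.drop_reasons.append((int(idx), "non-numeric value"))
            continue
        subject = _clean_label(row[mapping.subject_column]) if mapping.subject_column else None
        factor2 = _clean_label(row[mapping.factor2_column]) if mapping.factor2_column else None
        if group not in order:
            order.append(group)
        obs.append(Observation(group=group, value=value, subject=subject, factor2=factor2))

    report.n_rows_dropped = len(report.drop_reasons)
    if not obs:
        raise DataError("zero valid rows after validation")
    for g in order:
        report.groups_found[g] = sum(1 for o in obs if o.group == g)
    if report.n_rows_dropped:
        report.warnings.append(f"{report.n_rows_dropped} row(s) dropped (see drop_reasons)")
    ds = Dataset(observations=obs, group_order=order, source=source)
    return ds, report


def read_table(path: str | Path, mapping: ColumnMapping | None = None) -> tuple[Dataset, ValidationReport]:
    """Read a CSV or XLSX file into a validated :class:`Dataset`.

    The format is inferred from the extension.  Dropped rows are reported in
    the :class:`ValidationReport`, never silently discarded.
    """
    path = Path(path)
    mapping = mapping or ColumnMapping()
    if not path.exists():
        raise DataError(f"file not found: {path}")
    suffix = path.suffix.lower()
    if suffix == ".csv":
        df = pd.read_csv(path, dtype=object, keep_default_na=True)
    elif suffix in (".xlsx", ".xlsm"):
        try:
            df = pd.read_excel(path, sheet_name=mapping.sheet or 0, dtype=object)
        except ValueError as exc:
            raise DataError(f"sheet {mapping.sheet!r} not found in {path}") from exc
    else:
        raise DataError(f"unsupported file format {suffix!r} (expected .csv or .xlsx)")
    source = f"{path}" + (f"!{mapping.sheet}" if mapping.sheet else "")
    return _frame_to_dataset(df, mapping, source)


def select_groups(ds: Dataset, groups: Sequence[str]) -> Dataset:
    """Restrict a dataset to the given groups, in the given order."""
    groups = list(groups)
    unknown = [g for g in groups if g not in ds.group_order]
    if unknown:
        raise DataError(f"unknown group label(s): {unknown}")
    if len(groups) < 2:
        raise DataError("at least 2 groups must be selected")
    if len(set(groups)) != len(groups):
        raise DataError("duplicate group labels in selection")
    obs = [o for o in ds.observations if o.group in set(groups)]
    return Dataset(observations=obs, group_order=groups, source=ds.source)


#: worked example embedded in the template file (three groups, n = 3 each)
TEMPLATE_EXAMPLE = [
    ("WT", 10.1, "s1", ""),
    ("WT", 9.8, "s2", ""),
    ("WT", 10.4, "s3", ""),
    ("KO", 15.2, "s1", ""),
    ("KO", 14.7, "s2", ""),
    ("KO", 15.5, "s3", ""),
    ("KI", 20.3, "s1", ""),
    ("KI", 19.9, "s2", ""),
    ("KI", 20.6, "s3", ""),
]


def write_template(path: str | Path) -> Path:
    """Write the XLSX input template (Group | Values | Subject | Factor2)."""
    from openpyxl import Workbook

    path = Path(path)
    if path.exists():
        warnings.warn(f"overwriting existing file {path}", stacklevel=2)
    wb = Workbook()
    ws = wb.active
    ws.title = "Data"
    ws.append(["Group", "Values", "Subject", "Factor2"])
    for row in TEMPLATE_EXAMPLE:
        ws.append(list(row))
    wb.save(path)
    return path
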