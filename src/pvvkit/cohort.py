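"""Per-scan cohort table loading and validation.

Each row of the cohort table is one scan of one participant: cohort label,
visit number, demographics, percent-predicted pulmonary function, fibrosis
extent, and the PVV fields produced by one estimation method.  Records whose
PVV partition does not add up (pvv5 + pvv10 + pvv10plus != pvv_total) are
rejected with row-level diagnostics rather than silently kept.

Missing-value policy: blank pulmonary-function cells are allowed (the record
remains usable for PVV-only analyses); blank PVV cells reject the row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd

__all__ = ["CohortRecord", "CohortLoadReport", "load_cohort_table", "records_to_frame"]

#: canonical column -> accepted aliases (lower-cased, stripped)
_DEFAULT_COLUMN_MAP: dict[str, tuple[str, ...]] = {
    "participant_id": ("participant_id", "participant", "subject_id", "id"),
    "cohort": ("cohort", "group"),
    "visit": ("visit", "visit_number", "timepoint"),
    "sex": ("sex", "gender"),
    "age": ("age", "age_years"),
    "fvc_pct": ("fvc_pct", "fvc%", "fvc_percent"),
    "fev1_pct": ("fev1_pct", "fev1%", "fev1_percent"),
    "tlc_pct": ("tlc_pct", "tlc%", "tlc_percent"),
    "dlco_pct": ("dlco_pct", "dlco%", "dlco_percent"),
    "kco_pct": ("kco_pct", "kco%", "kco_percent"),
    "fibrosis_pct": ("fibrosis_pct", "fibrosis%", "percent_fibrosis"),
    "pvv_total": ("pvv_total", "pvv", "pvv_ml"),
    "pvv5": ("pvv5",),
    "pvv10": ("pvv10",),
    "pvv10plus": ("pvv10plus", "pvv10+", "pvv10_plus"),
    "method": ("method",),
    "lung_volume": ("lung_volume", "lung_volume_ml", "lv"),
}

_REQUIRED = ("participant_id", "cohort", "visit", "pvv_total", "pvv5", "pvv10",
             "pvv10plus", "method")
_OPTIONAL_NUMERIC = ("age", "fvc_pct", "fev1_pct", "tlc_pct", "dlco_pct",
                     "kco_pct", "fibrosis_pct", "lung_volume")


@dataclass
class CohortRecord:
    """One scan's covariates and PVV estimates."""

    participant_id: str
    cohort: str                      # "control" or "IPF"
    visit: int                       # >= 1; controls have exactly one visit
    method: str                      # "unfiltered" or "graph"
    pvv_total: float                 # mL
    pvv5: float
    pvv10: float
    pvv10plus: float
    sex: str | None = None           # "M" / "F"
    age: float | None = None
    fvc_pct: float | None = None
    fev1_pct: float | None = None
    tlc_pct: float | None = None
    dlco_pct: float | None = None
    kco_pct: float | None = None
    fibrosis_pct: float | None = None
    lung_volume: float | None = None

    def validate(self, tol: float = 1e-6) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        problems = []
        if self.visit < 1:
            problems.append(f"visit must be >= 1, got {self.visit}")
        part_sum = self.pvv5 + self.pvv10 + self.pvv10plus
        if not math.isclose(part_sum, self.pvv_total, rel_tol=1e-4, abs_tol=max(tol, 1e-3)):
            problems.append(
                f"pvv5+pvv10+pvv10plus = {part_sum:.4f} != pvv_total = {self.pvv_total:.4f}"
            )
        if self.fibrosis_pct is not None and not (0 <= self.fibrosis_pct <= 100):
            problems.append(f"fibrosis_pct {self.fibrosis_pct} outside [0, 100]")
        if self.cohort not in ("control", "IPF"):
            problems.append(f"unknown cohort label {self.cohort!r}")
        if self.method not in ("unfiltered", "graph"):
            problems.append(f"unknown method label {self.method!r}")
        return problems


@dataclass
class CohortLoadReport:
    n_read: int = 0
    n_accepted: int = 0
    rejected: list[tuple[int, str]] = field(default_factory=list)  # (row, reason)


class CohortSchemaError(ValueError):
    """A required column could not be resolved in the table header."""


def _resolve_columns(columns, column_map) -> dict[str, str]:
    lookup = {c.strip().lower(): c for c in columns}
    resolved = {}
    for canonical, aliases in column_map.items():
        for alias in aliases:
            if alias in lookup:
                resolved[canonical] = lookup[alias]
                break
    missing = [c for c in _REQUIRED if c not in resolved]
    if missing:
        raise CohortSchemaError(f"required columns not found: {missing}")
    return resolved


def _norm_cohort(value: str) -> str:
    v = str(value).strip().lower()
    if v in ("control", "controls", "healthy", "hc"):
        return "control"
    if v in ("ipf", "patient", "case"):
        return "IPF"
    return str(value).strip()


def _norm_method(value: str) -> str:
    v = str(value).strip().lower()
    if v in ("unfiltered", "slicewise", "slice-wise"):
        return "unfiltered"
    if v in ("graph", "graph-based", "graphbased"):
        return "graph"
    return v


def load_cohort_table(
    path: str | Path,
    column_map: dict[str, tuple[str, ...]] | None = None,
    sep: str | None = None,
) -> tuple[list[CohortRecord], CohortLoadReport]:
    """Load a delimited cohort table into typed, validated records.

    Returns the accepted records plus a report naming every rejected row and
    why.  Column names are resolved case-insensitively through a configurable
    alias map; the delimiter is sniffed from the suffix when not given.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    colmap = _resolve_columns(df.columns, column_map or _DEFAULT_COLUMN_MAP)

    records: list[CohortRecord] = []
    report = CohortLoadReport(n_read=len(df))
    valid_fields = {f.name for f in fields(CohortRecord)}
    for i, row in df.iterrows():
        rownum = int(i) + 2  # 1-based, after header
        try:
            kwargs: dict = {}
            for canonical, col in colmap.items():
                if canonical not in valid_fields:
                    continue
                val = row[col]
                if pd.isna(val):
                    kwargs[canonical] = None
                else:
                    kwargs[canonical] = val
            for key in ("pvv_total", "pvv5", "pvv10", "pvv10plus"):
                if kwargs.get(key) is None:
                    raise ValueError(f"missing {key}")
                kwargs[key] = float(kwargs[key])
            for key in _OPTIONAL_NUMERIC:
                if kwargs.get(key) is not None:
                    kwargs[key] = float(kwargs[key])
            kwargs["participant_id"] = str(kwargs["participant_id"])
            kwargs["visit"] = int(kwargs["visit"])
            kwargs["cohort"] = _norm_cohort(kwargs["cohort"])
            kwargs["method"] = _norm_method(kwargs["method"])
            if kwargs.get("sex") is not None:
                kwargs["sex"] = str(kwargs["sex"]).strip().upper()[:1]
            rec = CohortRecord(**kwargs)
        except (ValueError, TypeError) as exc:
            report.rejected.append((rownum, str(exc)))
            continue
        problems = rec.validate()
        if problems:
            report.rejected.append((rownum, "; ".join(problems)))
            continue
        records.append(rec)
    report.n_accepted = len(records)
    return records, report


def records_to_frame(records: list[CohortRecord]) -> pd.DataFrame:
    """Tidy DataFrame view of the records, one row per scan/method."""
    return pd.DataFrame([vars(r) for r in records])
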