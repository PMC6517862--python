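"""Reading and writing case files and per-system exports.

The case file is delimited text (CSV by default), one row per patient,
header required: ``id, t, n, m, age`` (integer years) or ``a`` (pre-coded
level), optional ``h``, then ``surv_months, event``.  Rows with unknown
level tokens, negative months or malformed numbers are rejected
individually with per-column exclusion counts, mirroring how registry
extracts drop records with missing or unknown values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .cohort import (
    A_LEVELS,
    CaseRecord,
    H_LEVELS,
    M_LEVELS,
    N_LEVELS,
    T_LEVELS,
    ValidationError,
)

logger = logging.getLogger(__name__)


@dataclass
class ReadReport:
    """Bookkeeping from a read: row counts and per-column exclusions."""

    n_rows: int = 0
    n_kept: int = 0
    exclusions: dict = field(default_factory=dict)   # column -> count
    excluded_rows: list = field(default_factory=list)  # (row index, column, reason)

    def note(self, idx: int, column: str, reason: str):
        self.exclusions[column] = self.exclusions.get(column, 0) + 1
        self.excluded_rows.append((idx, column, reason))


def _parse_row(row: pd.Series, idx: int, report: ReadReport) -> Optional[CaseRecord]:
    def token(col):
        v = row.get(col)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return None
        s = str(v).strip()
        if not s or s.lower() in ("nan", "none", "na"):
            return None
        return s

    t = token("t")
    if t not in T_LEVELS:
        report.note(idx, "t", f"unknown T level {t!r}")
        return None
    n = token("n")
    if n not in N_LEVELS:
        report.note(idx, "n", f"unknown N level {n!r}")
        return None
    m = token("m")
    if m not in M_LEVELS:
        report.note(idx, "m", f"unknown M level {m!r}")
        return None

    age = token("age")
    a = token("a")
    age_years = None
    a_level = None
    if age is not None:
        try:
            age_years = int(float(age))
        except ValueError:
            report.note(idx, "age", f"malformed age {age!r}")
            return None
        if age_years < 0:
            report.note(idx, "age", f"negative age {age_years}")
            return None
    if a is not None:
        if a not in A_LEVELS:
            report.note(idx, "a", f"unknown A level {a!r}")
            return None
        a_level = a

    h = token("h")
    if h is not None and h not in H_LEVELS:
        report.note(idx, "h", f"unknown H level {h!r}")
        return None

    sm = token("surv_months")
    try:
        surv = int(float(sm))
    except (TypeError, ValueError):
        report.note(idx, "surv_months", f"malformed surv_months {sm!r}")
        return None
    if surv < 0:
        report.note(idx, "surv_months", f"negative surv_months {surv}")
        return None

    ev = token("event")
    if ev not in ("0", "1"):
        report.note(idx, "event", f"event must be 0 or 1, got {ev!r}")
        return None

    rid = token("id") or f"row{idx}"
    return CaseRecord(id=rid, t_level=t, n_level=n, m_level=m,
                      surv_months=surv, event=int(ev),
                      age_years=age_years, a_level=a_level, h_level=h)


def read_cases(path, sep: str = ",",
               excluded_path: Optional[str] = None) -> Tuple[List[CaseRecord], ReadReport]:
    """Read and validate a case file; returns (cases, report).

    Invalid rows are dropped one by one; ``report.exclusions`` counts them
    per offending column and the counts are logged.  ``excluded_path``
    optionally receives the rejected rows with their reasons.
    """
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.empty:
        raise ValidationError(f"{path}: no case rows")
    required = {"t", "n", "m", "surv_months", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing required columns {sorted(missing)}")
    if "age" not in df.columns and "a" not in df.columns:
        raise ValidationError(f"{path}: need an 'age' or 'a' column")

    report = ReadReport(n_rows=len(df))
    cases = []
    for idx, row in df.iterrows():
        rec = _parse_row(row, idx, report)
        if rec is not None:
            cases.append(rec)
    report.n_kept = len(cases)
    if report.exclusions:
        for col, cnt in sorted(report.exclusions.items()):
            logger.info("read_cases(%s): excluded %d rows on column %r", path, cnt, col)
    if excluded_path and report.excluded_rows:
        pd.DataFrame(report.excluded_rows,
                     columns=["row", "column", "reason"]).to_csv(excluded_path, index=False)
    return cases, report


def cases_to_frame(cases: List[CaseRecord]) -> pd.DataFrame:
    rows = []
    for c in cases:
        rows.append({
            "id": c.id, "t": c.t_level, "n": c.n_level, "m": c.m_level,
            "age": c.age_years if c.age_years is not None else "",
            "a": c.a_level or "", "h": c.h_level or "",
            "surv_months": c.surv_months, "event": c.event,
        })
    return pd.DataFrame(rows)


def write_cases(cases: List[CaseRecord], path) -> None:
    cases_to_frame(cases).to_csv(path, index=False)


def records_from_frame(df: pd.DataFrame) -> List[CaseRecord]:
    """Strict conversion of a DataFrame in case-file layout (raises on any
    invalid row, unlike :func:`read_cases`)."""
    report = ReadReport(n_rows=len(df))
    out = []
    for idx, row in df.iterrows():
        rec = _parse_row(row.astype(str), idx, report)
        if rec is None:
            col, reason = report.excluded_rows[-1][1], report.excluded_rows[-1][2]
            raise ValidationError(f"row {idx}: {reason} (column {col})")
        out.append(rec)
    return out
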