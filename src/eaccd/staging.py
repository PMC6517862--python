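"""AJCC 8th-edition staging for differentiated thyroid cancer and
comparisons between a learned grouping and the AJCC stages.

The 8th edition stages papillary/follicular carcinoma by T, N, M and age
dichotomised at 55.  Bundled reference CSVs transcribe the stratification
of the SEER 2004-2010 well-differentiated thyroid cohort (39 T/N/M/A
combinations with their learned prognostic group and printed AJCC stage)
and the patient-count cross-tabulations of stage against group, overall
and by histology.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import A_LEVELS, M_LEVELS, N_LEVELS, T_LEVELS, ValidationError
from .survstats import CorrelationResult, spearman_ties


class AjccStage(enum.IntEnum):
    """Ordinal AJCC stage for differentiated thyroid cancer (8th edition)."""

    I = 1
    II = 2
    III = 3
    IVA = 4
    IVB = 5

    def __str__(self):
        return self.name


def ajcc8_stage(t_level: str, n_level: str, m_level: str, a_level: str) -> AjccStage:
    """Stage a T/N/M/age-level combination under the AJCC 8th edition.

    Under 55 (A1): M0 is stage I, M1 stage II.  55 and over (A2): M1 is
    IVB; otherwise T1/T2 N0 -> I, T1/T2 node-positive or T3 -> II,
    T4a -> III, T4b -> IVA.  T0 (no evidence of primary tumour) is not
    stageable here.
    """
    if t_level not in T_LEVELS or t_level == "T0":
        raise ValidationError(f"cannot stage T level {t_level!r}")
    if n_level not in N_LEVELS:
        raise ValidationError(f"unknown N level {n_level!r}")
    if m_level not in M_LEVELS:
        raise ValidationError(f"unknown M level {m_level!r}")
    if a_level not in A_LEVELS:
        raise ValidationError(f"unknown A level {a_level!r}")

    if a_level == "A1":
        return AjccStage.I if m_level == "M0" else AjccStage.II
    if m_level == "M1":
        return AjccStage.IVB
    if t_level in ("T1", "T2"):
        return AjccStage.I if n_level == "N0" else AjccStage.II
    if t_level == "T3":
        return AjccStage.II
    if t_level == "T4a":
        return AjccStage.III
    return AjccStage.IVA  # T4b


@dataclass
class ContingencyTable:
    """Patient counts of AJCC stage (rows) against prognostic group (columns)."""

    counts: pd.DataFrame  # index: stage names; columns: group numbers

    @property
    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def with_margins(self) -> pd.DataFrame:
        out = self.counts.copy()
        out["Total"] = self.row_totals
        out.loc["Total"] = out.sum(axis=0)
        return out


def contingency(group_of: Mapping[str, int], stage_of: Mapping[str, AjccStage],
                sizes: Mapping[str, int]) -> ContingencyTable:
    """Cross-tabulate patients by (stage, group) from per-combination maps."""
    labels = set(group_of)
    if labels != set(stage_of) or labels != set(sizes):
        raise ValidationError("group_of, stage_of and sizes must share the same labels")
    stages = sorted({AjccStage(stage_of[l]) for l in labels})
    groups = sorted({int(group_of[l]) for l in labels})
    counts = pd.DataFrame(0, index=[s.name for s in stages], columns=groups)
    for lab in labels:
        counts.loc[AjccStage(stage_of[lab]).name, int(group_of[lab])] += int(sizes[lab])
    return ContingencyTable(counts=counts)


def association(group_of: Mapping[str, int],
                stage_of: Mapping[str, AjccStage]) -> CorrelationResult:
    """Spearman correlation of group number vs ordinal stage, one observation
    per combination (unweighted)."""
    labels = sorted(group_of)
    if set(labels) != set(stage_of):
        raise ValidationError("group_of and stage_of must share the same labels")
    g = [int(group_of[l]) for l in labels]
    s = [int(AjccStage(stage_of[l])) for l in labels]
    return spearman_ties(g, s)


# ---------------------------------------------------------------------------
# Bundled reference data (SEER 2004-2010 well-differentiated thyroid cohort)
# ---------------------------------------------------------------------------

def _read_data(name: str) -> pd.DataFrame:
    with resources.files("eaccd.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_reference_grouping() -> pd.DataFrame:
    """The 39 T/N/M/A combinations with their published prognostic group and
    AJCC 8th-edition stage (columns t, n, m, a, group, stage)."""
    return _read_data("seer_thyroid_grouping.csv")


def load_reference_contingency(histology: str = "pooled") -> ContingencyTable:
    """Published stage-by-group patient counts; histology is 'follicular',
    'papillary' or 'pooled'."""
    df = _read_data("seer_thyroid_contingency.csv")
    if histology not in set(df["histology"]):
        raise ValueError(f"unknown histology {histology!r}")
    sub = df[df["histology"] == histology]
    counts = sub.pivot(index="stage", columns="group", values="count").fillna(0).astype(int)
    counts = counts.reindex([s.name for s in AjccStage if s.name in counts.index])
    counts.columns = [int(c) for c in counts.columns]
    counts = counts[sorted(counts.columns)]
    counts.index.name = None
    counts.columns.name = None
    return ContingencyTable(counts=counts)
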