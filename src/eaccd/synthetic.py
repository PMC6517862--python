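"""Synthetic registry-like survival cohorts with known latent structure.

Emulates the shape of a SEER-style well-differentiated thyroid cohort:
T/N/M/age factor cells of wildly unequal size, a handful of latent risk
groups with exponential (optionally Weibull) disease-specific hazards,
high administrative censoring from staggered diagnosis dates with a fixed
follow-up horizon, and survival recorded in whole months (which produces
the heavy tie structure the rank statistics must cope with).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .cohort import CaseRecord, FACTOR_ORDER, LEVELS, combination_label

#: 5-year disease-specific survival targets of the five latent risk groups,
#: spanning the near-certain-survival to poor-prognosis range seen in
#: well-differentiated thyroid cohorts.
DEFAULT_FIVE_YEAR = (0.995, 0.96, 0.90, 0.75, 0.45)


@dataclass
class SimCell:
    """One factor-level cell of the design: levels, size, latent risk group."""

    levels: Dict[str, str]
    size: int
    group: int

    @property
    def label(self) -> str:
        return combination_label(self.levels, tuple(self.levels))


@dataclass
class SimDesign:
    """Cohort design: cells, per-group hazards and the censoring process.

    ``hazards`` maps latent group -> monthly exponential rate, or
    -> (shape, scale_months) when ``weibull``.  Administrative censoring
    mirrors staggered accrual: each patient's horizon is uniform on
    [admin_censor_months - accrual_months, admin_censor_months] (the
    default 143/83 emulates diagnoses spread over seven years, all
    followed to one closing date).  ``random_censor_rate`` adds an
    independent exponential dropout hazard per month.
    """

    cells: List[SimCell]
    hazards: Dict[int, object]
    admin_censor_months: int = 143
    accrual_months: int = 83
    random_censor_rate: float = 0.0
    weibull: bool = False
    emit_ages: bool = False
    seed: int = 0

    def __post_init__(self):
        if any(c.size < 1 for c in self.cells):
            raise ValueError("cell sizes must be >= 1")
        groups = sorted(self.hazards)
        if not self.weibull:
            rates = [float(self.hazards[g]) for g in groups]
            if any(r <= 0 for r in rates):
                raise ValueError("hazards must be positive")
            if any(a > b for a, b in zip(rates, rates[1:])):
                raise ValueError("groups must be ordered by increasing hazard")
        missing = {c.group for c in self.cells} - set(groups)
        if missing:
            raise ValueError(f"cells reference groups without hazards: {missing}")


def _draw_event_times(rng, design: SimDesign, group: int, size: int) -> np.ndarray:
    if design.weibull:
        shape, scale = design.hazards[group]
        return scale * rng.weibull(shape, size)
    return rng.exponential(1.0 / design.hazards[group], size)


def generate(design: SimDesign) -> Tuple[List[CaseRecord], Dict[str, int]]:
    """Draw the cohort; returns (cases, truth) with truth: label -> latent group.

    Observed time = min(event, dropout, administrative horizon), floored to
    whole months; event = 1 iff the event precedes both censoring clocks.
    Same seed, same cohort.
    """
    rng = np.random.default_rng(design.seed)
    cases: List[CaseRecord] = []
    truth: Dict[str, int] = {}
    accrual = min(design.accrual_months, design.admin_censor_months)
    for ci, cell in enumerate(design.cells):
        t_event = _draw_event_times(rng, design, cell.group, cell.size)
        admin = design.admin_censor_months - rng.uniform(0.0, accrual, cell.size)
        if design.random_censor_rate > 0:
            drop = rng.exponential(1.0 / design.random_censor_rate, cell.size)
            censor = np.minimum(admin, drop)
        else:
            censor = admin
        event = (t_event <= censor).astype(int)
        months = np.floor(np.minimum(t_event, censor)).astype(int)
        months = np.maximum(months, 0)

        ages: Optional[np.ndarray] = None
        if design.emit_ages and "A" in cell.levels:
            lo, hi = (20, 54) if cell.levels["A"] == "A1" else (55, 85)
            ages = rng.integers(lo, hi + 1, cell.size)

        label = cell.label
        truth[label] = cell.group
        for i in range(cell.size):
            cases.append(
                CaseRecord(
                    id=f"{label}-{i:05d}",
                    t_level=cell.levels.get("T", "T1"),
                    n_level=cell.levels.get("N", "N0"),
                    m_level=cell.levels.get("M", "M0"),
                    surv_months=int(months[i]),
                    event=int(event[i]),
                    age_years=int(ages[i]) if ages is not None else None,
                    a_level=None if ages is not None else cell.levels.get("A"),
                    h_level=cell.levels.get("H"),
                )
            )
    return cases, truth


def hazards_from_five_year(five_year=DEFAULT_FIVE_YEAR) -> Dict[int, float]:
    """Monthly exponential rates hitting the 5-year survival targets:
    lambda = -ln(S(60)) / 60."""
    return {g: -np.log(s) / 60.0 for g, s in enumerate(five_year, start=1)}


def default_benchmark(seed: int = 0, n_cells: int = 40,
                      size_range: Tuple[int, int] = (25, 2000),
                      five_year=DEFAULT_FIVE_YEAR,
                      emit_ages: bool = False,
                      histology_split: Optional[Tuple[float, float]] = None) -> SimDesign:
    """The standard benchmark: 40 T/N/M/A cells, five latent risk groups.

    Cell sizes are log-uniform over ``size_range`` (every cell clears the
    25-case floor by construction; ~20,000 patients in total), latent
    groups are blocks of cells ordered by a clinical severity score, and
    hazards are solved from the 5-year survival targets.  With
    ``histology_split`` each cell is divided into H1/H2 subcells in the
    given proportions (same hazard), mimicking a follicular/papillary mix.
    """
    rng = np.random.default_rng(seed)
    all_cells = []
    for t in LEVELS["T"][1:]:          # T0 cells are excluded cohort-wide
        for n in LEVELS["N"]:
            for m in LEVELS["M"]:
                for a in LEVELS["A"]:
                    all_cells.append({"T": t, "N": n, "M": m, "A": a})
    pick = np.sort(rng.choice(len(all_cells), size=n_cells, replace=False))
    chosen = [all_cells[i] for i in pick]

    def severity(lv):
        return (LEVELS["T"].index(lv["T"]) + LEVELS["N"].index(lv["N"])
                + 4 * LEVELS["M"].index(lv["M"]) + 2 * LEVELS["A"].index(lv["A"]))

    order = sorted(range(n_cells), key=lambda i: (severity(chosen[i]), i))
    n_groups = len(five_year)
    bounds = np.linspace(0, n_cells, n_groups + 1).astype(int)
    group_of_rank = np.empty(n_cells, dtype=int)
    for g in range(n_groups):
        group_of_rank[bounds[g]:bounds[g + 1]] = g + 1

    lo, hi = size_range
    sizes = np.exp(rng.uniform(np.log(lo), np.log(hi), n_cells))
    sizes = np.maximum(np.round(sizes).astype(int), lo)

    cells = []
    for rank, i in enumerate(order):
        levels = dict(chosen[i])
        group = int(group_of_rank[rank])
        if histology_split is not None:
            p1, p2 = histology_split
            s1 = max(int(round(sizes[i] * p1 / (p1 + p2))), 1)
            s2 = max(int(sizes[i]) - s1, 1)
            cells.append(SimCell({**levels, "H": "H1"}, s1, group))
            cells.append(SimCell({**levels, "H": "H2"}, s2, group))
        else:
            cells.append(SimCell(levels, int(sizes[i]), group))

    return SimDesign(cells=cells, hazards=hazards_from_five_year(five_year),
                     emit_ages=emit_ages, seed=seed)
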