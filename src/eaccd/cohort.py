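"""Patient-level case records, factor combinations and cohort filters.

A *combination* is the cell of the cohort defined by one level of each
selected prognostic factor (e.g. ``T1N0M0A1``).  Combinations — not
individual patients — are the units that get clustered into prognostic
groups downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

T_LEVELS = ("T0", "T1", "T2", "T3", "T4a", "T4b")
N_LEVELS = ("N0", "N1a", "N1b")
M_LEVELS = ("M0", "M1")
A_LEVELS = ("A1", "A2")
H_LEVELS = ("H1", "H2")  # H1 follicular, H2 papillary

#: Canonical factor order used for combination labels, regardless of the
#: order in which factors are requested.
FACTOR_ORDER = ("T", "N", "M", "A", "H")

LEVELS: Mapping[str, tuple] = {
    "T": T_LEVELS,
    "N": N_LEVELS,
    "M": M_LEVELS,
    "A": A_LEVELS,
    "H": H_LEVELS,
}


class ValidationError(ValueError):
    """Raised when a record or parameter violates the declared vocabularies."""


def assign_age_level(age_years: int, cutoff: int = 55) -> str:
    """Dichotomise age at diagnosis: ``A1`` if ``age < cutoff`` else ``A2``."""
    if age_years < 0:
        raise ValidationError(f"age_years must be non-negative, got {age_years}")
    return "A1" if age_years < cutoff else "A2"


@dataclass(frozen=True)
class CaseRecord:
    """One patient: factor levels, follow-up in whole months, event flag.

    ``event`` is 1 for a death attributed to the studied cancer and 0 for
    censoring (alive, lost, or death from another cause).  Age may be given
    as raw ``age_years`` (dichotomised later against a cutoff) or as a
    pre-coded ``a_level``.
    """

    id: str
    t_level: str
    n_level: str
    m_level: str
    surv_months: int
    event: int
    age_years: Optional[int] = None
    a_level: Optional[str] = None
    h_level: Optional[str] = None

    def __post_init__(self):
        if self.t_level not in T_LEVELS:
            raise ValidationError(f"case {self.id}: unknown T level {self.t_level!r}")
        if self.n_level not in N_LEVELS:
            raise ValidationError(f"case {self.id}: unknown N level {self.n_level!r}")
        if self.m_level not in M_LEVELS:
            raise ValidationError(f"case {self.id}: unknown M level {self.m_level!r}")
        if self.a_level is not None and self.a_level not in A_LEVELS:
            raise ValidationError(f"case {self.id}: unknown A level {self.a_level!r}")
        if self.h_level is not None and self.h_level not in H_LEVELS:
            raise ValidationError(f"case {self.id}: unknown H level {self.h_level!r}")
        if self.age_years is not None and self.age_years < 0:
            raise ValidationError(f"case {self.id}: negative age {self.age_years}")
        if self.surv_months < 0:
            raise ValidationError(f"case {self.id}: negative surv_months {self.surv_months}")
        if self.event not in (0, 1):
            raise ValidationError(f"case {self.id}: event must be 0 or 1, got {self.event}")


@dataclass(frozen=True)
class FactorSet:
    """The prognostic factors defining combinations, plus the age cutoff.

    The declaration order of ``factors`` is irrelevant: labels always follow
    the canonical T, N, M, A, H order.
    """

    factors: tuple
    age_cutoff: int = 55

    def __init__(self, factors: Iterable[str], age_cutoff: int = 55):
        factors = tuple(factors)
        if not factors:
            raise ValidationError("FactorSet must name at least one factor")
        if len(set(factors)) != len(factors):
            raise ValidationError(f"duplicate factors in {factors}")
        unknown = [f for f in factors if f not in FACTOR_ORDER]
        if unknown:
            raise ValidationError(f"unknown factors {unknown}; allowed: {FACTOR_ORDER}")
        object.__setattr__(self, "factors", tuple(f for f in FACTOR_ORDER if f in factors))
        object.__setattr__(self, "age_cutoff", int(age_cutoff))

    def __iter__(self):
        return iter(self.factors)


@dataclass
class Combination:
    """A factor-level cell: its label, level map and member cases."""

    label: str
    levels: dict
    members: list = field(default_factory=list)
    _times: Optional[np.ndarray] = field(default=None, repr=False, compare=False)
    _events: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def times(self) -> np.ndarray:
        if self._times is None:
            self._times = np.array([c.surv_months for c in self.members], dtype=float)
        return self._times

    @property
    def events(self) -> np.ndarray:
        if self._events is None:
            self._events = np.array([c.event for c in self.members], dtype=int)
        return self._events


def case_level(case: CaseRecord, factor: str, age_cutoff: int = 55) -> str:
    """Resolve the level of ``factor`` for ``case``, dichotomising age on demand."""
    if factor == "A":
        if case.age_years is not None:
            return assign_age_level(case.age_years, age_cutoff)
        if case.a_level is not None:
            return case.a_level
        raise ValidationError(f"case {case.id}: no age information for factor A")
    attr = {"T": "t_level", "N": "n_level", "M": "m_level", "H": "h_level"}[factor]
    level = getattr(case, attr)
    if level is None:
        raise ValidationError(f"case {case.id}: missing value for factor {factor}")
    return level


def combination_label(levels: Mapping[str, str], factors: Sequence[str]) -> str:
    return "".join(levels[f] for f in FACTOR_ORDER if f in factors)


def build_combinations(cases: Iterable[CaseRecord], factors: FactorSet) -> list:
    """Partition cases into combinations over the requested factors.

    Combinations are returned in deterministic order (levels sorted by their
    position in the declared vocabularies).  Empty combinations are never
    emitted; the sum of sizes equals the number of input cases.
    """
    if "A" in factors.factors:
        both = [c for c in cases if c.age_years is not None and c.a_level is not None]
        if both:
            logger.warning(
                "%d cases carry both raw age and a pre-coded A level; raw age with "
                "cutoff %d takes precedence", len(both), factors.age_cutoff,
            )
    groups: dict = {}
    n_cases = 0
    for case in cases:
        n_cases += 1
        levels = {f: case_level(case, f, factors.age_cutoff) for f in factors}
        key = tuple(LEVELS[f].index(levels[f]) for f in factors)
        if key not in groups:
            groups[key] = Combination(
                label=combination_label(levels, factors.factors), levels=levels
            )
        groups[key].members.append(case)
    combos = [groups[k] for k in sorted(groups)]
    assert sum(c.size for c in combos) == n_cases
    return combos


def filter_min_count(combinations: Sequence[Combination], min_count: int = 25):
    """Split combinations into (kept, discarded) by the minimum-size rule.

    The default of 25 cases per combination is the robustness floor used when
    building prognostic systems; ``min_count=1`` keeps everything.
    """
    if min_count < 1:
        raise ValidationError(f"min_count must be >= 1, got {min_count}")
    kept = [c for c in combinations if c.size >= min_count]
    discarded = [c for c in combinations if c.size < min_count]
    if discarded:
        logger.info(
            "filter_min_count(%d): discarded %d combinations (%d cases)",
            min_count, len(discarded), sum(c.size for c in discarded),
        )
    return kept, discarded
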