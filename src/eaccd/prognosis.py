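"""From dendrogram to prognostic system.

Cut the merge tree at every possible number of groups, score each cut by
Harrell's C with ordinal group number as the predicted risk, locate the
knees of the C-index curve, and select the largest knee whose groups have
non-crossing, strictly ordered Kaplan-Meier curves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from sklearn.base import BaseEstimator, ClusterMixin

from .cluster import EACCD, Dendrogram
from .cohort import Combination, FactorSet, build_combinations, case_level, filter_min_count
from .survstats import SurvivalCurve, harrell_c, km_estimate, step_values, survival_at

logger = logging.getLogger(__name__)


@dataclass
class CIndexCurve:
    """C-index versus number of groups g = 1..n_combinations."""

    gs: np.ndarray
    cs: np.ndarray

    @property
    def points(self):
        return list(zip(self.gs.tolist(), self.cs.tolist()))

    def at(self, g: int) -> float:
        return float(self.cs[int(np.where(self.gs == g)[0][0])])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"g": self.gs, "c_index": self.cs})


@dataclass
class PrognosticSystem:
    """Group assignment, C-index and per-group survival of the selected cut.

    Group 1 is the most favourable; pooled 5-year KM survival decreases
    strictly with the group number.
    """

    factors: Optional[FactorSet]
    group_of: dict
    n_groups: int
    c_index: float
    curves: dict
    five_year: dict
    cindex_curve: CIndexCurve
    g_valid: int
    dendrogram: Dendrogram

    def groups_frame(self):
        import pandas as pd

        rows = [
            {"label": lab, "group": grp, "five_year_rate": self.five_year[grp]}
            for lab, grp in sorted(self.group_of.items(), key=lambda kv: (kv[1], kv[0]))
        ]
        return pd.DataFrame(rows)


class _CohortIndex:
    """Shared per-combination arrays and a cache of pooled cluster statistics.

    Nested cuts reuse clusters heavily (2n-1 distinct clusters across all
    cuts of one dendrogram), so pooled KM summaries are memoised on the
    frozenset of member combination indices.
    """

    def __init__(self, combinations: Sequence[Combination]):
        self.combinations = list(combinations)
        self.by_label = {c.label: i for i, c in enumerate(self.combinations)}
        self.times = np.concatenate([c.times for c in self.combinations])
        self.events = np.concatenate([c.events for c in self.combinations])
        self.case_combo = np.concatenate(
            [np.full(c.size, i) for i, c in enumerate(self.combinations)]
        )
        self._stats: dict = {}

    def cluster_stats(self, member_idx: frozenset):
        if member_idx not in self._stats:
            mask = np.isin(self.case_combo, list(member_idx))
            curve = km_estimate(self.times[mask], self.events[mask])
            five = survival_at(curve, 60.0, warn_beyond=False)
            mean_t = float(self.times[mask].mean())
            min_label = min(self.combinations[i].label for i in member_idx)
            self._stats[member_idx] = (curve, five, mean_t, min_label)
        return self._stats[member_idx]


def cut(dendrogram: Dendrogram, g: int) -> dict:
    """Partition combination labels into exactly g clusters."""
    return dendrogram.cut(g)


def _ordered_clusters(labels: Mapping[str, int], index: _CohortIndex):
    """Clusters sorted most- to least-favourable; returns per-cluster stats."""
    clusters: dict = {}
    for lab, c in labels.items():
        clusters.setdefault(c, set()).add(index.by_label[lab])
    entries = []
    for c, members in clusters.items():
        key = frozenset(members)
        curve, five, mean_t, min_label = index.cluster_stats(key)
        entries.append({"cluster": c, "members": key, "curve": curve,
                        "five_year": five, "mean_t": mean_t, "min_label": min_label})
    entries.sort(key=lambda e: (-e["five_year"], -e["mean_t"], e["min_label"]))
    return entries


def order_groups(labels: Mapping[str, int], combinations: Sequence[Combination],
                 _index: Optional[_CohortIndex] = None) -> dict:
    """Renumber clusters 1..g by decreasing pooled 5-year KM survival.

    Ties in the 5-year rate break by mean observed survival time, then by
    the lexicographically smallest member label.
    """
    index = _index or _CohortIndex(combinations)
    entries = _ordered_clusters(labels, index)
    renumber = {e["cluster"]: rank for rank, e in enumerate(entries, start=1)}
    return {lab: renumber[c] for lab, c in labels.items()}


def c_index_curve(dendrogram: Dendrogram, combinations: Sequence[Combination],
                  tied_events: bool = True,
                  _index: Optional[_CohortIndex] = None) -> CIndexCurve:
    """Patient-level Harrell C for every cut g, risk = ordinal group number."""
    index = _index or _CohortIndex(combinations)
    n = dendrogram.n_leaves
    combo_label = [c.label for c in index.combinations]
    cs = np.empty(n)
    for g in range(1, n + 1):
        labels = dendrogram.cut(g)
        grp = order_groups(labels, combinations, _index=index)
        risk_by_combo = np.array([grp[lab] for lab in combo_label], dtype=float)
        pred = risk_by_combo[index.case_combo]
        cs[g - 1] = harrell_c(pred, index.times, index.events, tied_events=tied_events).c
    return CIndexCurve(gs=np.arange(1, n + 1), cs=cs)


def overlap(curve_a: SurvivalCurve, curve_b: SurvivalCurve, tol: float = 0.0,
            strict: bool = False) -> bool:
    """True iff the two step functions cross within common follow-up.

    Crossing means S_a - S_b takes values beyond +tol and beyond -tol over
    the union of step times up to min(tmax_a, tmax_b).  With ``strict``,
    merely touching (|difference| <= tol somewhere after the curves first
    separate) also counts as overlap.
    """
    tmax = min(curve_a.tmax, curve_b.tmax)
    ts = np.union1d(curve_a.times, curve_b.times)
    ts = ts[ts <= tmax]
    if ts.size == 0:
        return False
    diff = step_values(curve_a, ts) - step_values(curve_b, ts)
    pos = bool(np.any(diff > tol))
    neg = bool(np.any(diff < -tol))
    if pos and neg:
        return True
    if strict and (pos or neg):
        separated = np.nonzero(np.abs(diff) > tol)[0]
        return bool(np.any(np.abs(diff[separated[0]:]) <= tol))
    return False


def knees(curve: CIndexCurve, threshold: float = 0.25):
    """Cut sizes g where the marginal C-index gain drops sharply.

    A knee is a discrete second difference below ``-threshold`` times the
    mean absolute first difference; returned sorted descending.
    """
    c = np.asarray(curve.cs, dtype=float)
    if c.size < 3:
        return []
    d1 = np.diff(c)
    scale = float(np.mean(np.abs(d1)))
    if scale == 0:
        return []
    d2 = np.diff(d1)  # d2[i] is the curvature at g = i + 2
    out = [int(i + 2) for i in range(d2.size) if d2[i] < -threshold * scale]
    return sorted(out, reverse=True)


def _cut_is_valid(entries, tol: float, strict: bool) -> bool:
    """Groups must be strictly ordered in 5-year rate and pairwise non-crossing."""
    fives = [e["five_year"] for e in entries]
    if any(a <= b for a, b in zip(fives, fives[1:])):
        return False
    for i in range(len(entries)):
        for j in range(i + 1, len(entries)):
            if overlap(entries[i]["curve"], entries[j]["curve"], tol=tol, strict=strict):
                return False
    return True


def select_system(dendrogram: Dendrogram, combinations: Sequence[Combination],
                  tol: float = 0.005, knee_threshold: float = 0.25,
                  tied_events: bool = True, strict: bool = False,
                  factors: Optional[FactorSet] = None) -> PrognosticSystem:
    """Assemble the prognostic system at the optimal number of groups n*.

    g_valid is the largest cut whose ordered groups have strictly decreasing
    5-year survival and pairwise non-crossing KM curves; n* is the largest
    knee of the C-index curve not exceeding g_valid (falling back to g_valid
    itself when no knee qualifies).
    """
    index = _CohortIndex(combinations)
    n = dendrogram.n_leaves
    curve = c_index_curve(dendrogram, combinations, tied_events=tied_events, _index=index)

    g_valid = 1
    for g in range(n, 0, -1):
        entries = _ordered_clusters(dendrogram.cut(g), index)
        if _cut_is_valid(entries, tol, strict):
            g_valid = g
            break

    candidates = [k for k in knees(curve, threshold=knee_threshold) if k <= g_valid]
    if candidates:
        n_star = candidates[0]
    else:
        n_star = g_valid
        logger.warning("no knee at or below g_valid=%d; falling back to n*=%d",
                       g_valid, n_star)

    labels = dendrogram.cut(n_star)
    entries = _ordered_clusters(labels, index)
    fives = [e["five_year"] for e in entries]
    if any(a <= b for a, b in zip(fives, fives[1:])):
        raise RuntimeError(
            f"cannot strictly order {n_star} groups by 5-year survival: rates {fives}"
        )
    renumber = {e["cluster"]: rank for rank, e in enumerate(entries, start=1)}
    group_of = {lab: renumber[c] for lab, c in labels.items()}
    curves = {rank: e["curve"] for rank, e in enumerate(entries, start=1)}
    five_year = {rank: e["five_year"] for rank, e in enumerate(entries, start=1)}
    return PrognosticSystem(
        factors=factors,
        group_of=group_of,
        n_groups=n_star,
        c_index=curve.at(n_star),
        curves=curves,
        five_year=five_year,
        cindex_curve=curve,
        g_valid=g_valid,
        dendrogram=dendrogram,
    )


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------

class PrognosticGrouper(BaseEstimator, ClusterMixin):
    """End-to-end prognostic grouping of a censored cohort.

    fit(X) takes patient cases (a list of :class:`~eaccd.cohort.CaseRecord`
    or a DataFrame in case-file layout), builds factor combinations,
    applies the minimum-size filter, learns the dendrogram with
    :class:`~eaccd.cluster.EACCD`, and selects the C-index-optimal number
    of prognostic groups.

    Fitted attributes: ``combinations_`` / ``discarded_`` (kept and
    filtered cells), ``eaccd_`` (the fitted clusterer), ``dendrogram_``,
    ``system_`` (the assembled :class:`PrognosticSystem`), ``n_groups_``,
    ``c_index_`` and ``labels_`` — the per-case group number, with -1 for
    cases in combinations below the size floor.

    predict(X) maps cases to group numbers by their combination label;
    combinations unseen at fit time come back as -1.
    """

    def __init__(self, factors=("T", "N", "M", "A"), age_cutoff=55, min_count=25,
                 runs=1000, k_min=2, k_max=None, overlap_tol=0.005,
                 knee_threshold=0.25, tied_events=True, strict_overlap=False,
                 random_state=None):
        self.factors = factors
        self.age_cutoff = age_cutoff
        self.min_count = min_count
        self.runs = runs
        self.k_min = k_min
        self.k_max = k_max
        self.overlap_tol = overlap_tol
        self.knee_threshold = knee_threshold
        self.tied_events = tied_events
        self.strict_overlap = strict_overlap
        self.random_state = random_state

    def _as_cases(self, X):
        import pandas as pd

        if isinstance(X, pd.DataFrame):
            from .io import records_from_frame

            return records_from_frame(X)
        return list(X)

    def fit(self, X, y=None):
        cases = self._as_cases(X)
        fs = FactorSet(self.factors, self.age_cutoff)
        combos = build_combinations(cases, fs)
        kept, discarded = filter_min_count(combos, self.min_count)
        if len(kept) < 2:
            raise ValueError(
                f"need at least two combinations of >= {self.min_count} cases; got {len(kept)}"
            )
        self.factor_set_ = fs
        self.combinations_ = kept
        self.discarded_ = discarded
        self.eaccd_ = EACCD(runs=self.runs, k_min=self.k_min, k_max=self.k_max,
                            random_state=self.random_state).fit(kept)
        self.dendrogram_ = self.eaccd_.dendrogram_
        self.system_ = select_system(
            self.dendrogram_, kept, tol=self.overlap_tol,
            knee_threshold=self.knee_threshold, tied_events=self.tied_events,
            strict=self.strict_overlap, factors=fs,
        )
        self.n_groups_ = self.system_.n_groups
        self.c_index_ = self.system_.c_index
        self.labels_ = self.predict(cases)
        return self

    def predict(self, X):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "system_")
        cases = self._as_cases(X)
        fs = self.factor_set_
        out = np.empty(len(cases), dtype=int)
        for i, case in enumerate(cases):
            label = "".join(case_level(case, f, fs.age_cutoff) for f in fs)
            out[i] = self.system_.group_of.get(label, -1)
        return out

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
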