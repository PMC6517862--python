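"""Survival statistics for censored cohorts.

Kaplan-Meier estimation, the Gehan-Wilcoxon two-sample statistic and its
effect size, Harrell's concordance index, a jackknife test for the
difference of two C-indices on the same subjects, and Spearman rank
correlation with average ranks for ties.

The concordance machinery aggregates subjects over distinct
(time, prediction) cells, so it is exact and fast on months-resolution
registry-style data where ties are pervasive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Tuple

import numpy as np
from lifelines import KaplanMeierFitter
from scipy import stats

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class SurvivalCurve:
    """Product-limit estimate: steps only at observed event times.

    ``tmax`` is the last observed follow-up time (event or censoring); it
    bounds the range over which the step function is supported by data.
    """

    times: np.ndarray
    surv: np.ndarray
    n_at_risk: np.ndarray
    n0: int
    tmax: float

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.surv = np.asarray(self.surv, dtype=float)
        self.n_at_risk = np.asarray(self.n_at_risk, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("event times must be strictly increasing")
        if np.any(np.diff(self.surv) > 1e-12):
            raise ValueError("survival probabilities must be non-increasing")

    def at(self, t: float, warn_beyond: bool = True) -> float:
        return survival_at(self, t, warn_beyond=warn_beyond)


def km_estimate(times: Sequence[float], events: Sequence[int]) -> SurvivalCurve:
    """Kaplan-Meier estimate of the survival function.

    Censored-only times do not create steps; S(0) = 1 implicitly.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("km_estimate requires at least one observation")
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    kmf = KaplanMeierFitter().fit(times, event_observed=events)
    tab = kmf.event_table
    ev = tab[tab["observed"] > 0]
    t_ev = ev.index.to_numpy(dtype=float)
    surv = kmf.survival_function_["KM_estimate"].reindex(ev.index).to_numpy(dtype=float)
    at_risk = ev["at_risk"].to_numpy(dtype=float)
    return SurvivalCurve(t_ev, surv, at_risk, n0=times.size, tmax=float(times.max()))


def step_values(curve: SurvivalCurve, ts: np.ndarray) -> np.ndarray:
    """Right-continuous step-function values S(t) at each t in ``ts``."""
    ts = np.asarray(ts, dtype=float)
    idx = np.searchsorted(curve.times, ts, side="right")
    vals = np.concatenate([[1.0], curve.surv])
    return vals[idx]


def survival_at(curve: SurvivalCurve, t: float, warn_beyond: bool = True) -> float:
    """S(t) of the step function; t = 60 gives the 5-year rate.

    Beyond the last follow-up the last value is carried forward and a
    warning is logged — the estimate is unsupported there.
    """
    if t < 0:
        raise ValueError(f"t must be non-negative, got {t}")
    if t > curve.tmax and warn_beyond:
        logger.warning(
            "survival_at(t=%g) beyond last follow-up %g; carrying last value forward",
            t, curve.tmax,
        )
    return float(step_values(curve, np.array([t]))[0])


# ---------------------------------------------------------------------------
# Gehan-Wilcoxon
# ---------------------------------------------------------------------------

@dataclass
class GehanResult:
    """Gehan-Wilcoxon two-sample statistic under censoring.

    ``w`` sums the +1/-1/0 definiteness scores over cross-sample pairs
    (+1 when the sample-1 member definitely survives longer).  ``var_w`` is
    the permutation variance computed from the pooled per-subject scores,
    ``z = w / sqrt(var_w)``, and ``effect_size`` is the scale-free
    dissimilarity used to seed the clustering.
    """

    w: float
    var_w: float
    z: float
    effect_size: float
    n1: int
    n2: int


def standardized_effect_size(w: float, var_w: float, z: float, n1: int, n2: int) -> float:
    """Default effect size: |z| / sqrt(n1 + n2), a Cohen-type standardised statistic.

    Scale-free, symmetric in the two samples and zero for identical samples.
    """
    return abs(z) / np.sqrt(n1 + n2)


def gehan_wilcoxon(
    sample1: Tuple[Sequence[float], Sequence[int]],
    sample2: Tuple[Sequence[float], Sequence[int]],
    effect_size: Optional[Callable[..., float]] = None,
) -> GehanResult:
    """Gehan's generalised Wilcoxon statistic for two censored samples.

    A pair is definite only when one subject's observed *event* time is
    strictly less than the other's observation time; ties score 0.  The
    per-subject pooled score W_i = (#subjects i definitely outlives) -
    (#subjects that definitely outlive i) gives w = sum of W_i over sample 1
    and the permutation variance n1 n2 sum(W_i^2) / (N (N-1)).
    """
    t1 = np.asarray(sample1[0], dtype=float)
    e1 = np.asarray(sample1[1], dtype=int)
    t2 = np.asarray(sample2[0], dtype=float)
    e2 = np.asarray(sample2[1], dtype=int)
    n1, n2 = t1.size, t2.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    t = np.concatenate([t1, t2])
    e = np.concatenate([e1, e2])
    N = n1 + n2

    ut, inv = np.unique(t, return_inverse=True)
    deaths_at = np.bincount(inv[e == 1], minlength=ut.size)
    total_at = np.bincount(inv, minlength=ut.size)
    deaths_before = np.concatenate([[0], np.cumsum(deaths_at)[:-1]])
    later = N - np.cumsum(total_at)  # obs time strictly greater

    W = deaths_before[inv] - e * later[inv]
    w = float(W[:n1].sum())
    var_w = float(n1 * n2 * np.sum(W.astype(float) ** 2) / (N * (N - 1))) if N > 1 else 0.0
    z = w / np.sqrt(var_w) if var_w > 0 else 0.0
    fn = effect_size or standardized_effect_size
    d = float(fn(w, var_w, z, n1, n2)) if var_w > 0 else 0.0
    return GehanResult(w=w, var_w=var_w, z=float(z), effect_size=d, n1=n1, n2=n2)


# ---------------------------------------------------------------------------
# Concordance (Harrell's C)
# ---------------------------------------------------------------------------

@dataclass
class ConcordanceResult:
    c: float
    n_comparable: float
    n_concordant: float
    n_tied: float


def _concordance_counts(pred, times, events, tied_events=True, per_subject=False):
    """Exact pair counts aggregated over distinct (time, prediction) cells.

    Comparable pairs: (i, j) with t_i < t_j and event_i = 1; tied-time pairs
    where exactly one has an event (the death is taken as earlier); and —
    when ``tied_events`` — tied-time both-event pairs with differing
    predictions, credited 0.5.  Concordant = the earlier death carries the
    strictly higher predicted risk; prediction ties credit 0.5.

    With ``per_subject`` also returns (num_i, den_i): each subject's share
    of the numerator/denominator over the pairs it participates in (each
    pair counted once per member), enabling exact leave-one-out C-indices.
    """
    pred = np.asarray(pred, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if not (pred.shape == times.shape == events.shape):
        raise ValueError("pred, times and events must have equal length")

    ut, ti = np.unique(times, return_inverse=True)
    up, pi = np.unique(pred, return_inverse=True)
    T, P = ut.size, up.size
    D = np.zeros((T, P))
    Cn = np.zeros((T, P))
    is_ev = events == 1
    np.add.at(D, (ti[is_ev], pi[is_ev]), 1.0)
    np.add.at(Cn, (ti[~is_ev], pi[~is_ev]), 1.0)
    A = D + Cn

    # subjects with strictly later observation time, by prediction
    L = np.cumsum(A[::-1], axis=0)[::-1] - A

    def low(M):  # sum over strictly lower predictions
        return np.cumsum(M, axis=1) - M

    def high(M):  # sum over strictly higher predictions
        return M.sum(axis=1, keepdims=True) - np.cumsum(M, axis=1)

    Llow, Lhigh = low(L), high(L)
    Cnlow, Cnhigh = low(Cn), high(Cn)
    Dhigh = high(D)
    Dear = np.cumsum(D, axis=0) - D  # deaths strictly earlier
    Dear_high = high(Dear)

    Dtot_t = D.sum(axis=1)
    Cntot_t = Cn.sum(axis=1)
    Lsum_t = L.sum(axis=1)
    Dear_sum_t = Dear.sum(axis=1)

    conc = float((D * (Llow + Cnlow)).sum())
    tied_pred = float((D * (L + Cn)).sum())
    disc = float((D * (Lhigh + Cnhigh)).sum())
    tied_dd = float(((Dtot_t ** 2 - (D ** 2).sum(axis=1)) / 2.0).sum()) if tied_events else 0.0
    comparable = conc + disc + tied_pred + tied_dd
    num = conc + 0.5 * (tied_pred + tied_dd)
    n_tied = tied_pred + tied_dd

    if not per_subject:
        return conc, disc, n_tied, comparable, num

    same_t_dd = (Dtot_t[ti] - D[ti, pi]) if tied_events else np.zeros(times.size)
    den_i = Dear_sum_t[ti] + np.where(
        is_ev, Lsum_t[ti] + Cntot_t[ti] + same_t_dd, Dtot_t[ti]
    )
    num_i = Dear_high[ti, pi] + 0.5 * Dear[ti, pi] + np.where(
        is_ev,
        Llow[ti, pi] + 0.5 * L[ti, pi] + Cnlow[ti, pi] + 0.5 * Cn[ti, pi] + 0.5 * same_t_dd,
        Dhigh[ti, pi] + 0.5 * D[ti, pi],
    )
    return conc, disc, n_tied, comparable, num, num_i, den_i


def harrell_c(
    pred_risk: Sequence[float],
    times: Sequence[float],
    events: Sequence[int],
    tied_events: bool = True,
) -> ConcordanceResult:
    """Harrell's concordance index: P(earlier death had higher predicted risk).

    0.5 is uninformative, 1 perfect.  ``tied_events`` controls whether
    tied-time both-event pairs with differing predictions count as
    comparable at half credit (Harrell's convention for tie-heavy data).
    """
    conc, disc, n_tied, comparable, num = _concordance_counts(
        pred_risk, times, events, tied_events=tied_events
    )
    if comparable == 0:
        raise ValueError("no comparable pairs (no events, or all observations tied)")
    return ConcordanceResult(
        c=num / comparable, n_comparable=comparable, n_concordant=conc, n_tied=n_tied
    )


def compare_c(
    pred1: Sequence[float],
    pred2: Sequence[float],
    times: Sequence[float],
    events: Sequence[int],
    tied_events: bool = True,
):
    """Test the difference of two C-indices computed on the same subjects.

    delta = c1 - c2; its variance is estimated by the jackknife over
    subjects (exact leave-one-out via per-subject pair-count shares).
    Returns (delta, z, two-sided p).
    """
    times = np.asarray(times, dtype=float)
    n = times.size
    out1 = _concordance_counts(pred1, times, events, tied_events, per_subject=True)
    out2 = _concordance_counts(pred2, times, events, tied_events, per_subject=True)
    _, _, _, den1, num1, num1_i, den1_i = out1
    _, _, _, den2, num2, num2_i, den2_i = out2
    if den1 == 0 or den2 == 0:
        raise ValueError("no comparable pairs")
    c1, c2 = num1 / den1, num2 / den2
    delta = c1 - c2

    rem1 = den1 - den1_i
    rem2 = den2 - den2_i
    if np.any(rem1 <= 0) or np.any(rem2 <= 0):
        raise ValueError("jackknife degenerate: a subject carries all comparable pairs")
    d_loo = (num1 - num1_i) / rem1 - (num2 - num2_i) / rem2
    var = (n - 1) / n * float(np.sum((d_loo - d_loo.mean()) ** 2))
    if var <= 0:
        if delta == 0:
            return 0.0, 0.0, 1.0
        raise ValueError(
            f"degenerate jackknife variance ({var:g}) with nonzero delta {delta:g}"
        )
    z = delta / np.sqrt(var)
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return float(delta), float(z), p


# ---------------------------------------------------------------------------
# Spearman with ties
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    rho: float
    t_stat: float
    df: int
    p: float


def spearman_ties(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation with average ranks for ties.

    rho is the Pearson correlation of the rank vectors; the two-sided
    p-value uses t = rho sqrt((n-2)/(1-rho^2)) on n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3 or y.size != n:
        raise ValueError("spearman_ties requires two equal-length samples with n >= 3")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise ValueError("zero variance in ranked data")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2
    if abs(rho) >= 1.0:
        return CorrelationResult(rho=float(np.sign(rho)), t_stat=float(np.inf * np.sign(rho)),
                                 df=df, p=0.0)
    t = rho * np.sqrt(df / (1.0 - rho ** 2))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return CorrelationResult(rho=rho, t_stat=float(t), df=df, p=p)
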