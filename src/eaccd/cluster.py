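"""The ensemble survival-clustering learner (EACCD).

Three steps: (1) initial dissimilarities between combinations from the
Gehan-Wilcoxon effect size; (2) learned dissimilarities from a PAM-based
consensus over many cluster counts — the fraction of runs in which two
combinations land in different clusters; (3) complete-linkage hierarchical
clustering of the learned dissimilarities into a dendrogram.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator

from .survstats import gehan_wilcoxon

logger = logging.getLogger(__name__)


@dataclass
class DissimilarityMatrix:
    """Symmetric non-negative dissimilarities over labelled combinations."""

    labels: tuple
    values: np.ndarray

    def __post_init__(self):
        self.labels = tuple(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("dissimilarity matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.values < 0):
            raise ValueError("dissimilarities must be non-negative")

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass
class PamResult:
    medoids: tuple          # label indices, sorted
    assignment: np.ndarray  # index of the assigned medoid within `medoids`
    objective: float


@dataclass
class Dendrogram:
    """Binary merge tree from agglomerative clustering (scipy linkage form).

    ``merges`` is the (n-1, 4) linkage matrix: left node, right node, merge
    height, cluster size.  Node ids < n are leaves in ``labels`` order.
    """

    merges: np.ndarray
    labels: tuple

    def __post_init__(self):
        self.merges = np.asarray(self.merges, dtype=float)
        self.labels = tuple(self.labels)

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def cut(self, g: int) -> dict:
        """Partition into exactly g clusters by undoing the top g-1 merges."""
        n = self.n_leaves
        if not 1 <= g <= n:
            raise ValueError(f"g must be in [1, {n}], got {g}")
        flat = hierarchy.cut_tree(self.merges, n_clusters=g).ravel()
        return {lab: int(c) for lab, c in zip(self.labels, flat)}

    def to_newick(self) -> str:
        """Newick string; branch lengths are merge-height differences."""
        tree = hierarchy.to_tree(self.merges)

        def rec(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        root = tree
        left = rec(root.left, root.dist)
        right = rec(root.right, root.dist)
        return f"({left},{right});"

    def merge_table(self):
        import pandas as pd

        return pd.DataFrame(self.merges[:, :3], columns=["left", "right", "height"])


# ---------------------------------------------------------------------------
# Step 1: initial dissimilarities
# ---------------------------------------------------------------------------

def initial_dissimilarities(
    combinations: Sequence, effect_size: Optional[Callable[..., float]] = None
) -> DissimilarityMatrix:
    """Pairwise Gehan-Wilcoxon effect sizes between combination survival data."""
    if len(combinations) < 2:
        raise ValueError("need at least two combinations")
    n = len(combinations)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            res = gehan_wilcoxon(
                (combinations[i].times, combinations[i].events),
                (combinations[j].times, combinations[j].events),
                effect_size=effect_size,
            )
            d[i, j] = d[j, i] = res.effect_size
    return DissimilarityMatrix(tuple(c.label for c in combinations), d)


# ---------------------------------------------------------------------------
# Step 2: PAM and ensemble learning
# ---------------------------------------------------------------------------

def pam(dm: DissimilarityMatrix, k: int, seed: int = 0) -> PamResult:
    """Partitioning Around Medoids: greedy BUILD then best-swap SWAP.

    Fully deterministic: ties in BUILD/assignment go to the lowest index;
    among equally improving swaps the first in scan order wins.  ``seed`` is
    accepted for interface stability but the algorithm draws nothing.
    """
    d = dm.values
    n = dm.n
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")

    # BUILD
    medoids = [int(np.argmin(d.sum(axis=1)))]
    dnear = d[medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(dnear[None, :] - d, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        c = int(np.argmax(gains))
        medoids.append(c)
        dnear = np.minimum(dnear, d[c])

    # SWAP
    idx = np.arange(n)
    while True:
        med = np.array(sorted(medoids))
        dsub = d[med]                       # k x n
        order = np.argsort(dsub, axis=0, kind="stable")
        nearest = order[0]
        d1 = dsub[nearest, idx]
        d2 = dsub[order[1], idx] if k > 1 else np.full(n, np.inf)
        base = d1.sum()
        best_delta = 0.0
        best_swap = None
        nonmed = [h for h in range(n) if h not in set(med.tolist())]
        for mi in range(k):
            mask = nearest == mi
            for h in nonmed:
                dh = d[h]
                new = np.where(mask, np.minimum(d2, dh), np.minimum(d1, dh)).sum()
                delta = new - base
                if delta < best_delta - 1e-12:
                    best_delta = delta
                    best_swap = (mi, h)
        if best_swap is None:
            break
        mi, h = best_swap
        medoids = med.tolist()
        medoids[mi] = h

    med = np.array(sorted(medoids))
    dsub = d[med]
    nearest = np.argsort(dsub, axis=0, kind="stable")[0]
    objective = float(dsub[nearest, idx].sum())
    return PamResult(medoids=tuple(int(m) for m in med), assignment=nearest, objective=objective)


def ensemble_learn(
    dm: DissimilarityMatrix,
    runs: int = 1000,
    k_min: int = 2,
    k_max: Optional[int] = None,
    seed: int = 0,
) -> DissimilarityMatrix:
    """Consensus dissimilarities: fraction of PAM runs separating each pair.

    Run b draws its cluster count k_b uniformly from [k_min, k_max] using a
    counter-based seed stream (SeedSequence(seed, spawn_key=(b,))), so
    increasing ``runs`` extends, never reshuffles, earlier draws.  PAM is
    deterministic given k, so the consensus is computed once per distinct k
    and weighted by its draw count.
    """
    n = dm.n
    if k_max is None:
        k_max = n - 1
    if runs < 1:
        raise ValueError("runs must be >= 1")
    if not 2 <= k_min <= k_max <= n - 1:
        raise ValueError(f"need 2 <= k_min <= k_max <= n-1, got [{k_min}, {k_max}] with n={n}")

    ks = np.empty(runs, dtype=int)
    for b in range(runs):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(b,)))
        ks[b] = rng.integers(k_min, k_max + 1)

    co_same = np.zeros((n, n))
    for k in np.unique(ks):
        count = int((ks == k).sum())
        lab = pam(dm, int(k), seed=seed).assignment
        co_same += count * (lab[:, None] == lab[None, :])
    learned = 1.0 - co_same / runs
    np.fill_diagonal(learned, 0.0)
    learned = (learned + learned.T) / 2.0  # exact symmetry against fp noise
    return DissimilarityMatrix(dm.labels, learned)


# ---------------------------------------------------------------------------
# Step 3: complete linkage
# ---------------------------------------------------------------------------

def complete_linkage(dm: DissimilarityMatrix) -> Dendrogram:
    """Agglomerative clustering with max-pairwise inter-cluster distance."""
    if dm.n < 2:
        raise ValueError("need at least two leaves")
    condensed = squareform(dm.values, checks=False)
    Z = hierarchy.linkage(condensed, method="complete")
    return Dendrogram(Z, dm.labels)


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------

class EACCD(BaseEstimator):
    """Ensemble survival-clustering estimator.

    fit(X) accepts a list of combinations (cohort cells with ``times`` and
    ``events`` arrays) or a precomputed :class:`DissimilarityMatrix` and
    produces ``initial_dissimilarity_``, ``learned_dissimilarity_`` and
    ``dendrogram_``.

    Parameters
    ----------
    runs : ensemble size (consensus runs).
    k_min, k_max : range of PAM cluster counts sampled per run
        (k_max=None means n-1).
    effect_size : optional callable ``f(w, var_w, z, n1, n2)`` replacing the
        default standardised Gehan effect size.
    random_state : integer master seed for the ensemble's k draws.
    """

    def __init__(self, runs=1000, k_min=2, k_max=None, effect_size=None, random_state=None):
        self.runs = runs
        self.k_min = k_min
        self.k_max = k_max
        self.effect_size = effect_size
        self.random_state = random_state

    def fit(self, X, y=None):
        if isinstance(X, DissimilarityMatrix):
            self.initial_dissimilarity_ = X
        else:
            self.initial_dissimilarity_ = initial_dissimilarities(X, self.effect_size)
        seed = 0 if self.random_state is None else int(self.random_state)
        self.learned_dissimilarity_ = ensemble_learn(
            self.initial_dissimilarity_,
            runs=self.runs,
            k_min=self.k_min,
            k_max=self.k_max,
            seed=seed,
        )
        self.dendrogram_ = complete_linkage(self.learned_dissimilarity_)
        return self

    def cut(self, g: int) -> dict:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "dendrogram_")
        return self.dendrogram_.cut(g)
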