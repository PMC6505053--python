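"""Jenks natural-breaks classification (Fisher's exact optimal univariate
partition) for mapping area prevalences into legend classes.

The classifier minimizes the total within-class sum of squared deviations
over all partitions of the *sorted* values into k contiguous classes, by
dynamic programming — an exact optimum, not the iterative-reallocation
heuristic. Ties between optimal partitions are broken deterministically
toward the lexicographically smallest class-size sequence (smallest first
class, then smallest second class, ...).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = ["BreaksResult", "jenks_breaks", "classify_areas", "JenksClassifier"]

#: Default legend grouping: five classes collapsed into three bands
#: (two low shades, one moderate, two high shades).
DEFAULT_GROUPS: list[tuple[str, int]] = [("low", 2), ("moderate", 1), ("high", 2)]


@dataclass
class BreaksResult:
    """Optimal contiguous k-partition of a value set."""

    k: int
    breaks: list[float]        # k-1 interior cuts, reported as class maxima
    assignment: np.ndarray     # class index 1..k per input value (input order)
    gvf: float                 # goodness of variance fit, 1 - SSDW/SSDT
    class_sizes: list[int]
    ssd_within: float


def _prefix_ssd(x: np.ndarray):
    """ssd(i, j) = within-SSD of sorted x[i:j], via prefix sums."""
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def ssd(i: int, j: int) -> float:
        n = j - i
        su = s1[j] - s1[i]
        return float(s2[j] - s2[i] - su * su / n)

    return ssd


def jenks_breaks(values, k: int) -> BreaksResult:
    """Exact natural-breaks partition of ``values`` into ``k`` classes."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    if k < 1:
        raise ValueError("k must be >= 1")
    n_distinct = np.unique(x).size
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct values")

    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = xs.size
    ssd = _prefix_ssd(xs)

    # C[j][i] = min cost of partitioning xs[i:] into j classes
    INF = float("inf")
    C = np.full((k + 1, n + 1), INF)
    C[0][n] = 0.0
    for j in range(1, k + 1):
        # a class needs >= 1 element and must leave room for j-1 more
        for i in range(n - j, -1, -1):
            best = INF
            for m in range(i + 1, n - (j - 1) + 1):
                c = ssd(i, m) + C[j - 1][m]
                if c < best:
                    best = c
            C[j][i] = best

    # front-to-back backtrack: smallest feasible class size on cost ties
    bounds = [0]
    i, j = 0, k
    total = C[k][0]
    while j > 0:
        for m in range(i + 1, n - (j - 1) + 1):
            if ssd(i, m) + C[j - 1][m] <= C[j][i] + 1e-12:
                bounds.append(m)
                i, j = m, j - 1
                break
    sizes = list(np.diff(bounds))

    cls_sorted = np.empty(n, dtype=int)
    for c, (lo, hi) in enumerate(zip(bounds[:-1], bounds[1:]), start=1):
        cls_sorted[lo:hi] = c
    assignment = np.empty(n, dtype=int)
    assignment[order] = cls_sorted

    ssd_total = ssd(0, n)
    gvf = 1.0 if ssd_total == 0 else 1.0 - total / ssd_total
    breaks = [float(xs[b - 1]) for b in bounds[1:-1]]
    return BreaksResult(k=k, breaks=breaks, assignment=assignment,
                        gvf=float(gvf), class_sizes=sizes,
                        ssd_within=float(total))


def classify_areas(estimates: pd.DataFrame, k: int = 5,
                   groups: list[tuple[str, int]] | None = None,
                   labels: list[str] | None = None) -> pd.DataFrame:
    """Classify per-area estimates into k natural-breaks classes and an
    optional coarser band grouping.

    ``labels`` names each of the k classes directly; ``groups`` is a list of
    (band label, number of classes) collapsing the k classes into bands and
    must sum to k. Default: 5 classes into low/moderate/high bands (2/1/2).
    Returns a frame (area_id, estimate, class, label) where class is
    monotone in the estimate.
    """
    if labels is not None and len(labels) != k:
        raise ValueError(f"labels must have length k={k}")
    if labels is None:
        groups = DEFAULT_GROUPS if groups is None and k == 5 else groups
        if groups is not None:
            if sum(g[1] for g in groups) != k:
                raise ValueError("group sizes must sum to k")
            labels = [name for name, sz in groups for _ in range(sz)]
        else:
            labels = [f"class_{c}" for c in range(1, k + 1)]

    res = jenks_breaks(estimates["estimate"].to_numpy(), k)
    out = pd.DataFrame({
        "area_id": estimates["domain_id"].to_numpy(),
        "estimate": estimates["estimate"].to_numpy(),
        "class": res.assignment,
    })
    out["label"] = [labels[c - 1] for c in res.assignment]
    out.attrs["breaks"] = res.breaks
    out.attrs["gvf"] = res.gvf
    return out


class JenksClassifier(BaseEstimator):
    """Fit-shaped natural-breaks classifier over 1-d values.

    Attributes after fit: ``breaks_``, ``gvf_``, ``labels_`` (class per
    training value); ``predict`` bins new values by the fitted breaks.
    """

    def __init__(self, k: int = 5):
        self.k = k

    def fit(self, X, y=None) -> "JenksClassifier":
        x = np.asarray(X, dtype=float).ravel()
        res = jenks_breaks(x, self.k)
        self.breaks_ = res.breaks
        self.gvf_ = res.gvf
        self.labels_ = res.assignment
        self.result_ = res
        return self

    def predict(self, X) -> np.ndarray:
        x = np.asarray(X, dtype=float).ravel()
        return np.searchsorted(self.breaks_, x, side="left") + 1
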