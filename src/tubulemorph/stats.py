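"""Distribution comparison (Kruskal-Wallis) and width/intensity histograms.

Tubule width and intensity distributions are compared between conditions
with the Kruskal-Wallis rank test, the standard nonparametric choice for
the thousands-of-tubules samples this pipeline produces.  The statistic
uses mid-ranks for ties and the usual tie-correction divisor:

    H = [12 / (N (N+1))] * sum_g R_g^2 / n_g  -  3 (N + 1)
    H_corrected = H / (1 - sum_t (t^3 - t) / (N^3 - N))

with the p-value from the chi-square approximation on k-1 degrees of
freedom.  For very small groups an exact permutation null (all
assignments of the pooled values to groups enumerated) is provided.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, rankdata

__all__ = [
    "StatResult",
    "DistributionSummary",
    "kruskal_wallis",
    "exact_kruskal_pvalue",
    "width_distribution",
]


@dataclass(frozen=True)
class StatResult:
    h: float
    df: int
    pvalue: float
    group_sizes: tuple[int, ...]
    tie_correction: float


def _h_statistic(pooled: np.ndarray, sizes: tuple[int, ...]) -> tuple[float, float]:
    """Tie-corrected H for pooled values split sequentially into groups."""
    n = len(pooled)
    ranks = rankdata(pooled)  # mid-ranks for ties
    h = 0.0
    start = 0
    for size in sizes:
        rg = ranks[start : start + size].sum()
        h += rg * rg / size
        start += size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - float(((counts**3 - counts).sum()) / (n**3 - n))
    if correction == 0.0:
        # every value identical: no rank variation at all
        return 0.0, 0.0
    return h / correction, correction


def kruskal_wallis(groups: list, pvalue_method: str = "auto") -> StatResult:
    """Kruskal-Wallis H test across two or more samples.

    Returns the tie-corrected statistic, degrees of freedom (k - 1) and a
    p-value.  ``pvalue_method`` is ``"chi2"`` (the large-sample
    chi-square approximation, standard for samples of hundreds to
    thousands of tubules), ``"exact"`` (the enumerated permutation null,
    feasible for pooled n up to ~10), or ``"auto"`` (exact when the
    pooled sample has at most 10 values -- where the chi-square
    approximation is known to be poor -- chi-square otherwise).  When
    every pooled value is identical the distributions are
    indistinguishable by rank: H = 0, p = 1.
    """
    arrays = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(a) == 0 for a in arrays):
        raise ValueError("every group must be non-empty")
    sizes = tuple(len(a) for a in arrays)
    pooled = np.concatenate(arrays)
    h, correction = _h_statistic(pooled, sizes)
    df = len(arrays) - 1
    if correction == 0.0:
        return StatResult(h=0.0, df=df, pvalue=1.0, group_sizes=sizes, tie_correction=0.0)
    if pvalue_method == "auto":
        pvalue_method = "exact" if len(pooled) <= 10 else "chi2"
    if pvalue_method == "exact":
        p = exact_kruskal_pvalue([a for a in arrays])
    elif pvalue_method == "chi2":
        p = float(chi2.sf(h, df))
    else:
        raise ValueError(f"unknown pvalue_method: {pvalue_method!r}")
    return StatResult(h=float(h), df=df, pvalue=p, group_sizes=sizes, tie_correction=correction)


def exact_kruskal_pvalue(groups: list) -> float:
    """Exact permutation p-value for the Kruskal-Wallis statistic.

    Enumerates every assignment of the pooled values to groups of the
    observed sizes and returns the fraction with H >= the observed H.
    Intended for tiny samples (total n <= ~12); the number of assignments
    is the multinomial coefficient.
    """
    arrays = [np.asarray(g, dtype=float).ravel() for g in groups]
    sizes = tuple(len(a) for a in arrays)
    pooled = np.concatenate(arrays)
    h_obs, _ = _h_statistic(pooled, sizes)

    n = len(pooled)
    indices = set(range(n))
    count = 0
    total = 0

    def recurse(remaining: frozenset, gi: int, chosen: list) -> None:
        nonlocal count, total
        if gi == len(sizes) - 1:
            perm = list(itertools.chain.from_iterable(chosen)) + sorted(remaining)
            h, _ = _h_statistic(pooled[perm], sizes)
            total += 1
            if h >= h_obs - 1e-12:
                count += 1
            return
        for combo in itertools.combinations(sorted(remaining), sizes[gi]):
            recurse(remaining - set(combo), gi + 1, chosen + [list(combo)])

    recurse(frozenset(indices), 0, [])
    return count / total


@dataclass(frozen=True)
class DistributionSummary:
    """Per-condition normalized histogram of a morphometric quantity."""

    bin_edges: np.ndarray
    probabilities: dict[str, np.ndarray]  # condition -> per-bin probability
    counts: dict[str, np.ndarray]
    n: dict[str, int]  # in-range sample size per condition
    overflow: dict[str, int]  # values outside the edge range

    def to_dict(self) -> dict:
        return {
            "bin_edges": self.bin_edges.tolist(),
            "probabilities": {k: v.tolist() for k, v in self.probabilities.items()},
            "counts": {k: v.tolist() for k, v in self.counts.items()},
            "n": dict(self.n),
            "overflow": dict(self.overflow),
        }


def width_distribution(
    records: pd.DataFrame,
    bin_edges: np.ndarray,
    value: str = "width_nm",
    by: str = "condition",
) -> DistributionSummary:
    """Normalized per-condition histogram of ``value`` (default width).

    Bins are half-open with the last bin closed (numpy convention).
    Values outside the edge range are counted as overflow and reported;
    in-range probabilities sum to 1 per condition.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if len(records) == 0:
        raise ValueError("records table is empty")
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be strictly increasing with >= 2 edges")

    probabilities: dict[str, np.ndarray] = {}
    counts: dict[str, np.ndarray] = {}
    n: dict[str, int] = {}
    overflow: dict[str, int] = {}
    for cond, sub in records.groupby(by, sort=True):
        vals = sub[value].to_numpy(dtype=float)
        hist, _ = np.histogram(vals, bins=edges)
        out = int(((vals < edges[0]) | (vals > edges[-1])).sum())
        total = int(hist.sum())
        counts[cond] = hist
        probabilities[cond] = hist / total if total else hist.astype(float)
        n[cond] = total
        overflow[cond] = out
    return DistributionSummary(
        bin_edges=edges, probabilities=probabilities, counts=counts, n=n,
        overflow=overflow,
    )
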