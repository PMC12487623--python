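"""Partitioning Around Medoids (PAM) on a wavenumber dissimilarity matrix.

Clusters the p wavenumbers (variables, not subjects) into G groups whose
representative — the medoid — is itself an observed wavenumber, so each
cluster can be summarized by one interpretable spectral position.  The
algorithm is the classical Kaufman–Rousseeuw two-phase procedure:

* build: the first medoid minimizes the sum of dissimilarities to all
  other points; each further medoid is the non-medoid whose addition
  decreases the total cost the most.
* swap: all (medoid, non-medoid) exchanges are evaluated and the single
  best-improving swap is applied, repeating until no swap lowers the cost.

Everything is deterministic: all ties (build selection, swap gains,
nearest-medoid assignment) break toward the lowest column index, and swap
gains below 1e-12 are treated as zero to avoid floating-point cycling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data_io import DataError, MatrixKind, PairwiseMatrix

__all__ = ["Partition", "total_cost", "pam_build", "pam_swap", "pam"]

GAIN_TOL = 1e-12

_DISSIMILARITY_KINDS = (MatrixKind.DISSIMILARITY, MatrixKind.PEARSON_DISSIMILARITY)


@dataclass
class Partition:
    """Result of a PAM run on p points.

    ``medoids`` are the G medoid column indices (ascending); ``assignment``
    maps every point to the cluster id of its nearest medoid (cluster g is
    the cluster of ``medoids[g]``); ``cost_history`` records the total cost
    after the build phase and after each applied swap.
    """

    medoids: list[int]
    assignment: np.ndarray
    total_cost: float
    n_swaps: int
    converged: bool
    cost_history: list[float] = field(default_factory=list)

    @property
    def g(self) -> int:
        return len(self.medoids)

    def cluster_members(self, g: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == g)


def _dissimilarity_values(D) -> np.ndarray:
    if isinstance(D, PairwiseMatrix):
        if D.kind not in _DISSIMILARITY_KINDS:
            raise DataError(f"PAM requires a dissimilarity matrix, got kind={D.kind.value!r}")
        return D.values
    arr = np.asarray(D, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise DataError("dissimilarity matrix must be square")
    return arr


def _check_medoids(medoids: Sequence[int], p: int) -> list[int]:
    med = [int(m) for m in medoids]
    if not med:
        raise ValueError("medoid list must not be empty")
    if len(set(med)) != len(med):
        raise ValueError("medoid indices must be distinct")
    if any(not 0 <= m < p for m in med):
        raise ValueError("medoid index out of range")
    return med


def total_cost(D, medoids: Sequence[int]) -> float:
    """Sum over points of the dissimilarity to the nearest medoid."""
    Dv = _dissimilarity_values(D)
    med = _check_medoids(medoids, Dv.shape[0])
    return float(Dv[:, med].min(axis=1).sum())


def pam_build(D, G: int) -> list[int]:
    """Deterministic greedy initialisation; returns G medoids, ascending."""
    Dv = _dissimilarity_values(D)
    p = Dv.shape[0]
    if not 1 <= G <= p:
        raise ValueError(f"G must lie in [1, {p}], got {G}")
    first = int(np.argmin(Dv.sum(axis=0)))
    med = [first]
    d_near = Dv[:, first].copy()
    while len(med) < G:
        # cost after adding each candidate; argmin = max cost decrease,
        # ties fall to the lowest index
        cand_cost = np.minimum(d_near[:, None], Dv).sum(axis=0)
        cand_cost[med] = np.inf
        h = int(np.argmin(cand_cost))
        med.append(h)
        d_near = np.minimum(d_near, Dv[:, h])
    return sorted(med)


def _assignment(Dv: np.ndarray, med: np.ndarray) -> np.ndarray:
    assign = np.argmin(Dv[:, med], axis=1)
    # a medoid always belongs to its own cluster, even under zero-distance ties
    assign[med] = np.arange(med.size)
    return assign


def pam_swap(D, medoids: Sequence[int], max_iter: int | None = None) -> Partition:
    """Best-improvement swap phase from a given medoid set.

    Evaluates every (medoid, non-medoid) exchange, applies the single swap
    with the largest cost decrease, and repeats until no swap improves the
    cost (gains below ``GAIN_TOL`` count as zero) or ``max_iter`` swaps
    were applied.
    """
    Dv = _dissimilarity_values(D)
    p = Dv.shape[0]
    med = sorted(_check_medoids(medoids, p))
    G = len(med)
    if max_iter is None:
        max_iter = max(p * G, 1)
    if max_iter < 1:
        raise ValueError("max_iter must be at least 1")

    cost = total_cost(Dv, med)
    history = [cost]
    n_swaps = 0
    converged = False
    idx = np.arange(p)
    while n_swaps < max_iter:
        med_arr = np.array(med)
        Dm = Dv[:, med_arr]
        nearest = np.argmin(Dm, axis=1)
        d1 = Dm[idx, nearest]
        Dm2 = Dm.copy()
        Dm2[idx, nearest] = np.inf
        d2 = Dm2.min(axis=1) if G > 1 else np.full(p, np.inf)

        best_gain = 0.0
        best_swap = None
        for gi, m in enumerate(med):
            # nearest-medoid distance once m is removed
            d_wo = np.where(nearest == gi, d2, d1)
            new_costs = np.minimum(d_wo[:, None], Dv).sum(axis=0)
            new_costs[med] = np.inf
            h = int(np.argmin(new_costs))
            gain = cost - new_costs[h]
            if gain > best_gain + GAIN_TOL or (best_swap is None and gain > GAIN_TOL):
                best_gain = gain
                best_swap = (m, h)
        if best_swap is None:
            converged = True
            break
        m, h = best_swap
        med.remove(m)
        med.append(h)
        med.sort()
        cost = total_cost(Dv, med)
        history.append(cost)
        n_swaps += 1
    else:
        warnings.warn(
            f"PAM swap phase stopped after max_iter={max_iter} without converging",
            stacklevel=2,
        )

    med_arr = np.array(med)
    assign = _assignment(Dv, med_arr)
    final_cost = float(Dv[idx, med_arr[assign]].sum())
    return Partition(
        medoids=med,
        assignment=assign,
        total_cost=final_cost,
        n_swaps=n_swaps,
        converged=converged,
        cost_history=history,
    )


def pam(D, G: int, max_iter: int | None = None) -> Partition:
    """Full PAM: deterministic build followed by best-improvement swaps."""
    return pam_swap(D, pam_build(D, G), max_iter=max_iter)
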