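"""Silhouette widths and silhouette-based choice of the cluster count G.

The silhouette width of point i contrasts its cohesion a(i) — the mean
dissimilarity to the other members of its own cluster — with its
separation b(i), the smallest mean dissimilarity to any other cluster:

    s(i) = (b(i) - a(i)) / max(a(i), b(i)),

with s(i) = 0 for singleton clusters (Rousseeuw's convention).  G is
chosen by running PAM over a candidate range and keeping the G with the
largest average silhouette; ties go to the smallest G.  Negative s(i)
values are legitimate and reported — they flag points sitting closer to a
neighbouring cluster than to their own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import MatrixKind, PairwiseMatrix
from .pam import Partition, pam, _dissimilarity_values

__all__ = ["ClusterSummary", "SelectionReport", "silhouette_widths", "select_g", "plot_silhouette_profile"]


@dataclass
class ClusterSummary:
    """Per-cluster descriptives computed on the normalized-MI scale."""

    cluster_id: int
    medoid_index: int
    medoid_wavenumber: float
    size: int
    min_norm_mi: float
    mean_norm_mi: float
    singleton: bool = False


@dataclass
class SelectionReport:
    """Silhouette profile over candidate G plus the chosen partition."""

    candidate_g: list[int]
    avg_silhouette: list[float]
    chosen_g: int
    per_point_silhouette: np.ndarray
    cluster_summaries: list[ClusterSummary]
    partition: Partition = None

    def to_dict(self) -> dict:
        return {
            "candidate_g": list(self.candidate_g),
            "avg_silhouette": [float(v) for v in self.avg_silhouette],
            "chosen_g": int(self.chosen_g),
            "per_point_silhouette": [float(v) for v in self.per_point_silhouette],
            "cluster_summaries": [vars(c) for c in self.cluster_summaries],
            "medoids": [int(m) for m in self.partition.medoids],
            "assignment": [int(a) for a in self.partition.assignment],
            "total_cost": float(self.partition.total_cost),
        }


def silhouette_widths(D, assignment) -> np.ndarray:
    """Per-point silhouette widths for a partition on a dissimilarity matrix."""
    Dv = _dissimilarity_values(D)
    assignment = np.asarray(assignment, dtype=int)
    p = Dv.shape[0]
    if assignment.shape != (p,):
        raise ValueError("assignment length must match the matrix dimension")
    clusters = np.unique(assignment)
    if clusters.size < 2:
        raise ValueError("silhouette is undefined for fewer than 2 clusters")
    sizes = np.array([(assignment == c).sum() for c in clusters])
    # sums of dissimilarities from every point to each cluster
    sums = np.stack([Dv[:, assignment == c].sum(axis=1) for c in clusters], axis=1)
    own = np.searchsorted(clusters, assignment)
    idx = np.arange(p)
    own_size = sizes[own]
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(own_size > 1, sums[idx, own] / np.maximum(own_size - 1, 1), 0.0)
        means = sums / sizes[None, :]
        means[idx, own] = np.inf
        b = means.min(axis=1)
        denom = np.maximum(a, b)
        s = np.where(denom > 0, (b - a) / denom, 0.0)
    s[own_size == 1] = 0.0
    return s


def _norm_mi_from_dissimilarity(Dv: np.ndarray) -> np.ndarray:
    # d = 1 - I_norm off-diagonal (for the Pearson comparator this is |r|)
    return 1.0 - Dv


def select_g(D, g_min: int = 2, g_max: int = 40) -> SelectionReport:
    """Sweep PAM over G in [g_min, g_max] and keep the silhouette maximizer.

    Cluster summaries of the chosen partition report, per cluster, the
    minimum and mean pairwise normalized MI among its members (recovered
    from the dissimilarity as 1 - d); singleton clusters report
    min = mean = 1 by convention and are flagged.
    """
    Dv = _dissimilarity_values(D)
    p = Dv.shape[0]
    if not 2 <= g_min <= g_max <= p - 1:
        raise ValueError(f"need 2 <= g_min <= g_max <= p-1 = {p - 1}")
    labels = D.labels if isinstance(D, PairwiseMatrix) else np.arange(p, dtype=float)

    candidates = list(range(g_min, g_max + 1))
    partitions = []
    avgs = []
    for G in candidates:
        part = pam(Dv, G)
        partitions.append(part)
        avgs.append(float(np.mean(silhouette_widths(Dv, part.assignment))))
    best = int(np.argmax(avgs))  # first occurrence -> smallest G on ties
    part = partitions[best]
    s = silhouette_widths(Dv, part.assignment)

    inorm = _norm_mi_from_dissimilarity(Dv)
    summaries = []
    for g, m in enumerate(part.medoids):
        members = part.cluster_members(g)
        size = members.size
        if size == 1:
            mn = mean = 1.0
            singleton = True
        else:
            sub = inorm[np.ix_(members, members)]
            vals = sub[np.triu_indices(size, k=1)]
            mn, mean = float(vals.min()), float(vals.mean())
            singleton = False
        summaries.append(
            ClusterSummary(
                cluster_id=g,
                medoid_index=int(m),
                medoid_wavenumber=float(labels[m]),
                size=int(size),
                min_norm_mi=mn,
                mean_norm_mi=mean,
                singleton=singleton,
            )
        )
    return SelectionReport(
        candidate_g=candidates,
        avg_silhouette=avgs,
        chosen_g=candidates[best],
        per_point_silhouette=s,
        cluster_summaries=summaries,
        partition=part,
    )


def plot_silhouette_profile(report: SelectionReport, path) -> None:
    """Save a simple average-silhouette vs G profile plot."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(report.candidate_g, report.avg_silhouette, "o-")
    ax.axvline(report.chosen_g, color="grey", ls="--", lw=1)
    ax.set_xlabel("number of clusters G")
    ax.set_ylabel("average silhouette width")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
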