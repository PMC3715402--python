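"""Threshold-based RMSD conformational clustering (Daura/GROMOS algorithm).

Reduces a structure ensemble to ranked representative centroids: the member
with the most neighbours (pairwise RMSD <= threshold, self included) seeds a
cluster, it and its neighbours are removed, and the count is repeated on the
remainder.  Rank 1 is the most populated cluster.  This is the algorithm of
the GROMACS ``g_cluster`` "gromos" method.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .structure_io import Ensemble, SelectionExpr
from .superpose import align_ensemble, fit_then_rmsd, rmsd, _coords_at

__all__ = [
    "RmsdMatrix",
    "Cluster",
    "ClusterResult",
    "pairwise_rmsd_matrix",
    "cluster_daura",
    "extract_centroids",
    "threshold_scan",
    "write_cluster_report",
]


@dataclass
class RmsdMatrix:
    """Symmetric pairwise RMSD matrix in Å with a zero diagonal."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("RMSD matrix must be square")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("RMSD matrix must be symmetric within 1e-9")
        if np.any(np.diag(v) != 0.0):
            raise ValueError("RMSD matrix diagonal must be exactly zero")
        if np.any(v < 0):
            raise ValueError("RMSD matrix entries must be non-negative")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class Cluster:
    centroid: int          # member index of the representative structure
    members: list[int]     # member indices, centroid included

    @property
    def population(self) -> int:
        return len(self.members)


@dataclass
class ClusterResult:
    """Clusters in rank order (rank 1 = most populated)."""

    threshold: float
    clusters: list[Cluster] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def populations(self) -> list[int]:
        return [c.population for c in self.clusters]

    def membership(self) -> dict[int, int]:
        """member index -> 1-based cluster rank."""
        return {m: r for r, c in enumerate(self.clusters, start=1) for m in c.members}


def pairwise_rmsd_matrix(
    e: Ensemble,
    fit_sel: str | SelectionExpr = "all",
    rmsd_sel: str | SelectionExpr = "all",
    mode: str = "pairwise",
) -> RmsdMatrix:
    """All-against-all RMSDs over ``rmsd_sel`` atoms.

    mode="pairwise" (default): each pair is independently least-squares
    fitted on ``fit_sel`` before the RMSD is taken — the convention of
    trajectory clustering tools.  mode="prealigned": one global alignment to
    the first member, then raw RMSDs; exposed because published protocols
    often describe a single mutual alignment step and the two differ only
    when internal motion is large.
    """
    n = len(e)
    v = np.zeros((n, n), dtype=float)
    if mode == "pairwise":
        for i in range(n):
            for j in range(i + 1, n):
                v[i, j] = v[j, i] = fit_then_rmsd(
                    e.members[j], e.members[i], fit_sel, rmsd_sel
                )
    elif mode == "prealigned":
        aligned, _ = align_ensemble(e, reference_index=0, fit_sel=fit_sel)
        coords = [_coords_at(m, rmsd_sel) for m in aligned.members]
        for i in range(n):
            for j in range(i + 1, n):
                v[i, j] = v[j, i] = rmsd(coords[i], coords[j])
    else:
        raise ValueError(f"unknown mode {mode!r}; use 'pairwise' or 'prealigned'")
    return RmsdMatrix(v)


def cluster_daura(m: RmsdMatrix, threshold: float) -> ClusterResult:
    """Greedy neighbour-count clustering at an inclusive RMSD threshold.

    Each round, among the still-unassigned members the one with the most
    unassigned neighbours (RMSD <= threshold, itself included) becomes a
    centroid; it and its neighbours form a cluster and are removed.  Ties on
    neighbour count go to the lowest member index, which makes the result
    deterministic and platform independent.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    n = m.n
    adj = m.values <= threshold
    np.fill_diagonal(adj, True)
    unassigned = np.ones(n, dtype=bool)
    clusters: list[Cluster] = []
    while unassigned.any():
        counts = (adj & unassigned[None, :]).sum(axis=1)
        counts[~unassigned] = -1
        centroid = int(np.argmax(counts))  # argmax returns the lowest index on ties
        members = np.nonzero(adj[centroid] & unassigned)[0]
        clusters.append(Cluster(centroid=centroid, members=[int(i) for i in members]))
        unassigned[members] = False
    clusters.sort(key=lambda c: (-c.population, c.centroid))
    return ClusterResult(threshold=float(threshold), clusters=clusters)


def extract_centroids(e: Ensemble, result: ClusterResult) -> Ensemble:
    """Centroid structures in rank order, annotated with (rank, population).

    The returned ensemble's ``metadata`` carries, per member, the centroid
    rank, its cluster population, and the index of the source member.
    """
    members = []
    metadata = []
    for rank, c in enumerate(result.clusters, start=1):
        if not (0 <= c.centroid < len(e)):
            raise IndexError(f"centroid index {c.centroid} out of range")
        src = e.members[c.centroid]
        members.append(src.with_coords(src.coords(), label=src.label))
        metadata.append(
            {"rank": rank, "population": c.population, "source_index": c.centroid}
        )
    return Ensemble(members=members, metadata=metadata)


def threshold_scan(m: RmsdMatrix, thresholds: Sequence[float]) -> pd.DataFrame:
    """Cluster at each threshold; returns (threshold, n_clusters, top_population).

    Used to choose a similarity threshold by scanning a range and watching
    the cluster count collapse.  For distance-like (metric) matrices — which
    pairwise-fitted RMSDs closely approximate — the count is non-increasing
    in the threshold; strongly non-metric matrices can violate this.
    """
    thresholds = list(thresholds)
    if any(t <= 0 for t in thresholds):
        raise ValueError("thresholds must be positive")
    if sorted(thresholds) != thresholds:
        raise ValueError("thresholds must be sorted ascending")
    rows = []
    for t in thresholds:
        res = cluster_daura(m, t)
        rows.append(
            {
                "threshold": float(t),
                "n_clusters": res.n_clusters,
                "top_population": res.clusters[0].population,
            }
        )
    return pd.DataFrame(rows)


def intra_cluster_max_rmsd(m: RmsdMatrix, c: Cluster) -> float:
    sub = m.values[np.ix_(c.members, c.members)]
    return float(sub.max()) if sub.size else 0.0


def write_cluster_report(
    result: ClusterResult, e: Ensemble, m: RmsdMatrix, path: str | Path
) -> pd.DataFrame:
    """TSV report: rank, centroid model id, population, intra-cluster max RMSD."""
    rows = []
    for rank, c in enumerate(result.clusters, start=1):
        rows.append(
            {
                "rank": rank,
                "centroid_model_id": e.members[c.centroid].model_id,
                "centroid_index": c.centroid,
                "population": c.population,
                "max_intra_rmsd_A": round(intra_cluster_max_rmsd(m, c), 4),
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df
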