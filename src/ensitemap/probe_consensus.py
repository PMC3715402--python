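"""Fragment-probe pose clustering and consensus sites.

Consumes docked small-molecule probe poses (from FTMap-style probe-PDB
files, where each probe copy is one HETATM residue whose resname is the
probe type and whose B-factor column carries the docking score, lower =
better) and reproduces the post-docking half of the fragment-mapping
procedure: per-probe truncation to the top-scoring poses, greedy distance
clustering of pose centers (default 3 Å cutoff), and pooling of the
per-probe cluster representatives of all probe types into ranked consensus
sites.  A consensus site's rank reflects how many probe clusters converge
there; its midpoint is the unweighted mean of the member cluster centers.

The docking itself is out of scope — poses come from files or from the
synthetic generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .structure_io import read_pdb

__all__ = [
    "ProbePose",
    "ProbeCluster",
    "ConsensusSite",
    "read_probe_pdb",
    "truncate_top_poses",
    "cluster_probe_poses",
    "build_consensus_sites",
    "top_consensus_sites",
    "write_cs_report",
]


@dataclass
class ProbePose:
    """One docked copy of a rigid probe; the center is recomputed from atoms."""

    probe_type: str
    coords: np.ndarray            # (M, 3), M >= 1
    score: float | None = None    # lower = better
    center: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if self.coords.shape[0] < 1 or self.coords.shape[1] != 3:
            raise ValueError("pose needs at least one atom with xyz coordinates")
        self.center = self.coords.mean(axis=0)


@dataclass
class ProbeCluster:
    """Greedy cluster of same-type poses around a best-scoring representative."""

    probe_type: str
    members: list[ProbePose]
    representative: ProbePose

    @property
    def center(self) -> np.ndarray:
        return self.representative.center

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ConsensusSite:
    """A ranked group of probe clusters (mixed probe types) at one location."""

    clusters: list[ProbeCluster]
    rank: int = 0
    provenance: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def n_probe_types(self) -> int:
        return len({c.probe_type for c in self.clusters})

    @property
    def midpoint(self) -> np.ndarray:
        return np.mean([c.center for c in self.clusters], axis=0)


def read_probe_pdb(path: str | Path, scored: bool | str = "auto") -> list[ProbePose]:
    """Read probe poses: one pose per HETATM/ATOM residue, resname = probe type.

    The score is taken from the B-factor of the pose's first atom.  With
    ``scored="auto"`` (default) a file whose B-factor column is identically
    zero — the placeholder emitted when no scores exist — yields unscored
    poses (score ``None``); pass ``scored=True``/``False`` to force either
    interpretation.
    """
    ens = read_pdb(path)
    poses: list[ProbePose] = []
    for member in ens.members:
        coords = member.coords()
        for _key, resname, idx in member.residues():
            poses.append(
                ProbePose(
                    probe_type=resname,
                    coords=coords[idx],
                    score=member.atoms[idx[0]].bfactor,
                )
            )
    if scored == "auto":
        scored = any(p.score for p in poses)
    if not scored:
        for p in poses:
            p.score = None
    return poses


def truncate_top_poses(poses: list[ProbePose], k: int) -> list[ProbePose]:
    """Per probe type, keep the k best-scoring (lowest score) poses.

    Relative input order is preserved among the kept poses.  Raises if any
    pose is unscored — callers with unscored poses should skip truncation.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    if any(p.score is None for p in poses):
        raise ValueError(
            "poses without scores cannot be truncated; skip truncation for unscored sets"
        )
    keep: set[int] = set()
    by_type: dict[str, list[int]] = {}
    for i, p in enumerate(poses):
        by_type.setdefault(p.probe_type, []).append(i)
    for idx in by_type.values():
        best = sorted(idx, key=lambda i: (poses[i].score, i))[:k]
        keep.update(best)
    return [p for i, p in enumerate(poses) if i in keep]


def cluster_probe_poses(
    poses: list[ProbePose], cutoff: float = 3.0
) -> list[ProbeCluster]:
    """Greedy per-type clustering of pose centers at an inclusive distance cutoff.

    Within each probe type the best-scoring unassigned pose seeds a cluster
    and collects every unassigned pose whose center lies within ``cutoff`` of
    the seed's center; the seed is the representative.  Unscored poses seed
    in input order.  Deterministic by construction.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    clusters: list[ProbeCluster] = []
    type_order: list[str] = []
    by_type: dict[str, list[int]] = {}
    for i, p in enumerate(poses):
        if p.probe_type not in by_type:
            type_order.append(p.probe_type)
        by_type.setdefault(p.probe_type, []).append(i)
    for t in type_order:
        idx = by_type[t]
        scored = all(poses[i].score is not None for i in idx)
        order = sorted(idx, key=lambda i: (poses[i].score, i)) if scored else list(idx)
        unassigned = set(idx)
        for seed in order:
            if seed not in unassigned:
                continue
            seed_center = poses[seed].center
            members = [
                i for i in idx
                if i in unassigned
                and np.linalg.norm(poses[i].center - seed_center) <= cutoff
            ]
            unassigned.difference_update(members)
            clusters.append(
                ProbeCluster(
                    probe_type=t,
                    members=[poses[i] for i in members],
                    representative=poses[seed],
                )
            )
    return clusters


def build_consensus_sites(
    clusters: list[ProbeCluster],
    cs_cutoff: float = 3.0,
    provenance: dict | None = None,
) -> list[ConsensusSite]:
    """Pool probe-cluster representatives of all types into ranked consensus sites.

    The same greedy rule is applied to cluster representatives, seeded by
    descending member count (ties: input order); a site collects every
    unassigned cluster whose representative center lies within ``cs_cutoff``
    of the seed's.  Sites are then ranked by member-cluster count descending,
    ties broken by more distinct probe types, then by lexicographically
    smaller midpoint.
    """
    if cs_cutoff <= 0:
        raise ValueError("cs_cutoff must be positive")
    order = sorted(range(len(clusters)), key=lambda i: (-clusters[i].size, i))
    unassigned = set(range(len(clusters)))
    sites: list[ConsensusSite] = []
    for seed in order:
        if seed not in unassigned:
            continue
        seed_center = clusters[seed].center
        members = [
            i for i in range(len(clusters))
            if i in unassigned
            and np.linalg.norm(clusters[i].center - seed_center) <= cs_cutoff
        ]
        unassigned.difference_update(members)
        sites.append(
            ConsensusSite(
                clusters=[clusters[i] for i in members],
                provenance=dict(provenance or {}),
            )
        )
    sites.sort(
        key=lambda s: (
            -s.n_clusters,
            -s.n_probe_types,
            tuple(np.round(s.midpoint, 9)),
        )
    )
    for rank, s in enumerate(sites, start=1):
        s.rank = rank
    return sites


def top_consensus_sites(sites: list[ConsensusSite], n: int) -> list[ConsensusSite]:
    """The first ``n`` consensus sites by rank."""
    if n < 0:
        raise ValueError("n must be non-negative")
    return sorted(sites, key=lambda s: s.rank)[:n]


def write_cs_report(sites: list[ConsensusSite], path: str | Path) -> pd.DataFrame:
    """TSV report: rank, midpoint, member count, probe-type count, provenance."""
    rows = []
    for s in sites:
        mp = s.midpoint
        rows.append(
            {
                "rank": s.rank,
                "midpoint_x": round(float(mp[0]), 3),
                "midpoint_y": round(float(mp[1]), 3),
                "midpoint_z": round(float(mp[2]), 3),
                "n_probe_clusters": s.n_clusters,
                "n_probe_types": s.n_probe_types,
                "provenance": ";".join(f"{k}={v}" for k, v in sorted(s.provenance.items())),
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df
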