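"""Map per-member binding sites onto a reference structure and report hotspots.

An ensemble of representative structures (e.g. MD centroids, each carrying
its own consensus sites and pocket sites) is aligned to one reference
member; every member's site coordinates are carried into the reference frame
by the same rigid transform.  Consensus sites are displayed as spheres sized
by their rank (the largest sphere radius defaults to the number of spheres
displayed, in Å, shrinking linearly by rank) and coloured by the rank of the
centroid they came from, on a linear red→blue ramp (red = rank 1, the most
populated cluster).  Pocket sites are displayed as point-cloud surfaces with
the same centroid colouring.

Residue-level reporting (the *select-residues* logic) collects, across all
ensemble members and with duplicates removed, the residues within a cutoff
(default 3 Å) of any consensus-site midpoint, of any pocket site point, and
of both.  Distances are evaluated in each member's own frame — residue
identity is frame-invariant, distances are not — while mapping to the
reference is display-only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist

from .pocket_grid import PocketSite
from .probe_consensus import ConsensusSite
from .structure_io import Ensemble, SelectionExpr, Structure
from .superpose import align_ensemble

__all__ = [
    "SceneStyle",
    "MappedSite",
    "MappedSites",
    "SphereGlyph",
    "ResidueSelection",
    "centroid_color",
    "map_sites_to_reference",
    "style_spheres",
    "select_residues",
    "emit_scene",
    "parse_scene",
    "region_report",
]

# A residue key for reporting: (chain, resseq, icode, resname)
ResidueId = tuple[str, int, str, str]


@dataclass
class SceneStyle:
    """Display parameters for hotspot scenes.

    The largest sphere radius defaults to ``n_spheres_displayed`` (in Å) and
    decreases by ``radius_decrement`` per consensus-site rank, floored at
    ``min_radius``; centroid colours run red (rank 1) to blue (last rank).
    """

    n_spheres_displayed: int = 5
    largest_sphere_radius: float | None = None
    radius_decrement: float = 1.0
    min_radius: float = 0.5
    isovalue: float = 0.5

    def __post_init__(self) -> None:
        if self.n_spheres_displayed < 1:
            raise ValueError("n_spheres_displayed must be >= 1")
        if self.largest_sphere_radius is None:
            self.largest_sphere_radius = float(self.n_spheres_displayed)
        if self.largest_sphere_radius <= 0 or self.min_radius <= 0:
            raise ValueError("sphere radii must be positive")

    def radius_for_rank(self, cs_rank: int) -> float:
        r = self.largest_sphere_radius - (cs_rank - 1) * self.radius_decrement
        return max(r, self.min_radius)


def centroid_color(rank: int, n_centroids: int) -> tuple[float, float, float]:
    """Linear RGB ramp from pure red (rank 1) to pure blue (rank n)."""
    if not (1 <= rank <= n_centroids):
        raise ValueError(f"rank {rank} outside 1..{n_centroids}")
    t = 0.0 if n_centroids == 1 else (rank - 1) / (n_centroids - 1)
    return (1.0 - t, 0.0, t)


@dataclass
class MappedSite:
    """One site expressed in the reference frame, with provenance."""

    kind: str                     # "consensus" | "pocket"
    center: np.ndarray            # CS midpoint or pocket centroid
    site_rank: int                # rank within its member's site list
    member_index: int
    centroid_rank: int
    n_clusters: int = 0           # consensus: member probe-cluster count
    point_count: int = 0          # pocket: retained grid points
    points: np.ndarray | None = None  # pocket: transformed site points


@dataclass
class MappedSites:
    reference_label: str
    n_centroids: int
    sites: list[MappedSite] = field(default_factory=list)

    @property
    def consensus(self) -> list[MappedSite]:
        return [s for s in self.sites if s.kind == "consensus"]

    @property
    def pockets(self) -> list[MappedSite]:
        return [s for s in self.sites if s.kind == "pocket"]


@dataclass
class SphereGlyph:
    center: np.ndarray
    radius: float
    rgb: tuple[float, float, float]
    cs_rank: int


def _centroid_rank(e: Ensemble, i: int) -> int:
    if e.metadata is not None and "rank" in e.metadata[i]:
        return int(e.metadata[i]["rank"])
    return i + 1  # unannotated ensembles: member order stands in for rank


def map_sites_to_reference(
    e: Ensemble,
    member_consensus: Sequence[Sequence[ConsensusSite]],
    member_pockets: Sequence[Sequence[PocketSite]],
    reference_index: int = 0,
    fit_sel: str | SelectionExpr = "name CA",
) -> MappedSites:
    """Carry every member's sites into the reference member's frame.

    Each member's alignment transform (from :func:`align_ensemble`) is applied
    to that member's consensus-site midpoints and pocket-site points; the
    reference member's own sites are unchanged.  Provenance (member index and
    centroid rank) is preserved on every mapped site.
    """
    if len(member_consensus) != len(e) or len(member_pockets) != len(e):
        raise ValueError("per-member site lists must match the ensemble length")
    _, transforms = align_ensemble(e, reference_index=reference_index, fit_sel=fit_sel)
    mapped = MappedSites(
        reference_label=e.members[reference_index].label or str(reference_index),
        n_centroids=len(e),
    )
    for i, (t, cs_list, pocket_list) in enumerate(
        zip(transforms, member_consensus, member_pockets)
    ):
        crank = _centroid_rank(e, i)
        for k, cs in enumerate(cs_list):
            mapped.sites.append(
                MappedSite(
                    kind="consensus",
                    center=t.apply(_site_center(cs)),
                    site_rank=_site_rank(cs, fallback=k + 1),
                    member_index=i,
                    centroid_rank=crank,
                    n_clusters=getattr(cs, "n_clusters", 0),
                )
            )
        for p in pocket_list:
            pts = t.apply(p.points)
            mapped.sites.append(
                MappedSite(
                    kind="pocket",
                    center=pts.mean(axis=0),
                    site_rank=p.rank,
                    member_index=i,
                    centroid_rank=crank,
                    point_count=p.point_count,
                    points=pts,
                )
            )
    return mapped


def _site_center(site) -> np.ndarray:
    # duck-typed: MappedSite carries .center, ConsensusSite .midpoint, and
    # site records loaded from TSV reports may carry either
    for attr in ("center", "midpoint"):
        v = getattr(site, attr, None)
        if v is not None:
            return np.asarray(v, dtype=float)
    return np.asarray(site, dtype=float)


def _site_rank(site, fallback: int) -> int:
    rank = getattr(site, "site_rank", None)
    if rank is None:
        rank = getattr(site, "rank", None)
    return int(rank) if rank else fallback


def style_spheres(
    cs_list: Sequence,
    style: SceneStyle,
    centroid_rank: int,
    n_centroids: int,
) -> list[SphereGlyph]:
    """Sphere glyphs for consensus sites of one member.

    Rank k gets radius ``largest − (k−1)·decrement`` (floored at the minimum
    radius); all spheres of the member share the colour of its centroid rank.
    Only the top ``n_spheres_displayed`` ranks are emitted.
    """
    rgb = centroid_color(centroid_rank, n_centroids)
    glyphs: list[SphereGlyph] = []
    for i, cs in enumerate(cs_list):
        rank = _site_rank(cs, fallback=i + 1)
        if rank > style.n_spheres_displayed:
            continue
        glyphs.append(
            SphereGlyph(
                center=_site_center(cs),
                radius=style.radius_for_rank(rank),
                rgb=rgb,
                cs_rank=rank,
            )
        )
    return glyphs


@dataclass
class ResidueSelection:
    """The three display categories of residue-level hotspot reporting.

    ``probe_only`` holds residues near any consensus-site midpoint,
    ``pocket_only`` residues near any pocket site point, and ``both`` their
    intersection; each set is deduplicated across all ensemble members.
    """

    cutoff: float
    probe_only: set[ResidueId] = field(default_factory=set)
    pocket_only: set[ResidueId] = field(default_factory=set)
    both: set[ResidueId] = field(default_factory=set)


def select_residues(
    members: Sequence[Structure],
    member_consensus: Sequence[Sequence[ConsensusSite]],
    member_pockets: Sequence[Sequence[PocketSite]],
    cutoff: float = 3.0,
) -> ResidueSelection:
    """Residues within ``cutoff`` Å of sites, deduplicated across the ensemble.

    A residue enters the probe set iff, in ANY member, one of its atoms lies
    within ``cutoff`` of a consensus-site midpoint in that member's own
    frame; the pocket set is analogous against pocket site points.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    near_probe: set[ResidueId] = set()
    near_pocket: set[ResidueId] = set()
    for s, cs_list, pocket_list in zip(members, member_consensus, member_pockets):
        coords = s.coords()
        targets_probe = (
            np.array([_site_center(cs) for cs in cs_list]) if cs_list else None
        )
        pocket_points = (
            np.vstack([p.points for p in pocket_list]) if pocket_list else None
        )
        probe_tree = cKDTree(targets_probe) if targets_probe is not None else None
        pocket_tree = cKDTree(pocket_points) if pocket_points is not None else None
        for key, resname, idx in s.residues():
            rid: ResidueId = (*key, resname)
            if probe_tree is not None and rid not in near_probe:
                d, _ = probe_tree.query(coords[idx], workers=-1)
                if np.any(d <= cutoff):
                    near_probe.add(rid)
            if pocket_tree is not None and rid not in near_pocket:
                d, _ = pocket_tree.query(coords[idx], workers=-1)
                if np.any(d <= cutoff):
                    near_pocket.add(rid)
    return ResidueSelection(
        cutoff=float(cutoff),
        probe_only=near_probe,
        pocket_only=near_pocket,
        both=near_probe & near_pocket,
    )


# ---------------------------------------------------------------------------
# Scene emission
# ---------------------------------------------------------------------------

def _fmt_vec(v: np.ndarray) -> str:
    return ",".join(f"{x:.3f}" for x in v)


def emit_scene(
    mapped: MappedSites,
    style: SceneStyle,
    out_dir: str | Path,
    scene_name: str = "scene",
) -> tuple[Path, Path]:
    """Write a machine-readable scene file and a Tcl viewer script.

    The scene file lists one ``element=`` line per graphical element
    (consensus spheres limited to the top ``n_spheres_displayed`` ranks per
    member, pocket surfaces with their point clouds referenced by centroid);
    both outputs are deterministic byte-for-byte for identical input.
    Returns (scene_path, tcl_path).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scene_path = out / f"{scene_name}.txt"
    tcl_path = out / f"{scene_name}.tcl"

    lines = [
        "# ensitemap scene v1",
        f"# reference {mapped.reference_label}",
        f"# n_centroids {mapped.n_centroids}",
        f"# isovalue {style.isovalue}",
    ]
    tcl = [
        "# ensitemap viewer scene (Tcl, VMD graphics primitives)",
        "draw delete all",
    ]
    color_index = 1057  # start of user-definable color slots in common viewers
    for site in mapped.sites:
        rgb = centroid_color(site.centroid_rank, mapped.n_centroids)
        if site.kind == "consensus":
            if site.site_rank > style.n_spheres_displayed:
                continue
            radius = style.radius_for_rank(site.site_rank)
            lines.append(
                "element=sphere kind=consensus "
                f"center={_fmt_vec(site.center)} radius={radius:.3f} "
                f"rgb={_fmt_vec(np.array(rgb))} cs_rank={site.site_rank} "
                f"member={site.member_index} centroid_rank={site.centroid_rank} "
                f"n_clusters={site.n_clusters}"
            )
            tcl.append(f"color change rgb {color_index} {rgb[0]:.3f} {rgb[1]:.3f} {rgb[2]:.3f}")
            tcl.append(f"draw color {color_index}")
            c = site.center
            tcl.append(
                f"draw sphere {{{c[0]:.3f} {c[1]:.3f} {c[2]:.3f}}} "
                f"radius {radius:.3f} resolution 24"
            )
            color_index += 1
        else:
            lines.append(
                "element=surface kind=pocket "
                f"center={_fmt_vec(site.center)} n_points={site.point_count} "
                f"rgb={_fmt_vec(np.array(rgb))} site_rank={site.site_rank} "
                f"member={site.member_index} centroid_rank={site.centroid_rank} "
                f"isovalue={style.isovalue}"
            )
            tcl.append(f"color change rgb {color_index} {rgb[0]:.3f} {rgb[1]:.3f} {rgb[2]:.3f}")
            tcl.append(f"draw color {color_index}")
            if site.points is not None:
                for p in site.points:
                    tcl.append(f"draw point {{{p[0]:.3f} {p[1]:.3f} {p[2]:.3f}}}")
            color_index += 1
    scene_path.write_text("\n".join(lines) + "\n")
    tcl_path.write_text("\n".join(tcl) + "\n")
    return scene_path, tcl_path


def parse_scene(path: str | Path) -> list[dict]:
    """Re-read a scene file into element dictionaries (numbers parsed)."""
    elements: list[dict] = []
    for line in Path(path).read_text().splitlines():
        if not line.startswith("element="):
            continue
        entry: dict = {}
        for token in line.split():
            k, v = token.split("=", 1)
            if "," in v:
                entry[k] = tuple(float(x) for x in v.split(","))
            else:
                try:
                    entry[k] = int(v)
                except ValueError:
                    try:
                        entry[k] = float(v)
                    except ValueError:
                        entry[k] = v
        elements.append(entry)
    return elements


# ---------------------------------------------------------------------------
# Region report
# ---------------------------------------------------------------------------

_REGION_NAMES = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def region_report(
    selection: ResidueSelection,
    reference: Structure,
    which: str = "both",
    link_cutoff: float = 8.0,
    names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Group selected residues into named spatial regions (single linkage).

    Residue positions are their mean atom coordinates on the reference
    structure; residues closer than ``link_cutoff`` merge into one region.
    Regions are named A, B, C, ... (or ``names``) in order of descending
    residue count; the table lists region, chain and residue list per chain.
    """
    categories = {
        "both": selection.both,
        "probe": selection.probe_only,
        "pocket": selection.pocket_only,
    }
    if which not in categories:
        raise ValueError("which must be 'both', 'probe' or 'pocket'")
    chosen: set[ResidueId] = categories[which]
    if not chosen:
        return pd.DataFrame(columns=["region", "chain", "residues"])
    coords = reference.coords()
    pos: dict[ResidueId, np.ndarray] = {}
    for key, resname, idx in reference.residues():
        rid: ResidueId = (*key, resname)
        if rid in chosen:
            pos[rid] = coords[idx].mean(axis=0)
    rids = sorted(pos)  # residues absent from the reference cannot be placed
    xyz = np.array([pos[r] for r in rids])
    if len(rids) == 1:
        assignments = np.array([1])
    else:
        z = linkage(pdist(xyz), method="single")
        assignments = fcluster(z, t=link_cutoff, criterion="distance")
    groups: dict[int, list[ResidueId]] = {}
    for rid, a in zip(rids, assignments):
        groups.setdefault(int(a), []).append(rid)
    ordered = sorted(groups.values(), key=lambda g: (-len(g), sorted(g)[0]))
    rows = []
    for i, group in enumerate(ordered):
        name = names[i] if names is not None and i < len(names) else (
            _REGION_NAMES[i] if i < len(_REGION_NAMES) else f"R{i + 1}"
        )
        by_chain: dict[str, list[ResidueId]] = {}
        for rid in group:
            by_chain.setdefault(rid[0], []).append(rid)
        for chain in sorted(by_chain):
            residues = sorted(by_chain[chain], key=lambda r: (r[1], r[2]))
            rows.append(
                {
                    "region": name,
                    "chain": chain,
                    "residues": ", ".join(
                        f"{r[3].capitalize()}{r[1]}{r[2]}" for r in residues
                    ),
                }
            )
    return pd.DataFrame(rows)
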