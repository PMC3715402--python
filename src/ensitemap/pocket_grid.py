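"""Grid-based pocket detection around the receptor van der Waals surface.

Candidate site points are laid on a regular grid (default 0.35 Å spacing)
covering the receptor's van der Waals envelope plus padding.  A point is
retained when it lies outside every atom's van der Waals sphere and, for its
nearest receptor atom, the ratio d²/r_vdW² stays below a cutoff (default
2.5, strict), so points hugging the surface survive while points drifting
into bulk solvent are eliminated.  Retained points with neighbouring
retained points are grouped into connected components — pocket sites — under
a configurable grid connectivity (face/edge/vertex).

Sites carry simple geometric/compositional descriptors (point count, volume,
contacting residues, hydrophobic fraction); no energetic probe maps are
computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .structure_io import AtomRecord, Structure, write_pdb

__all__ = [
    "Grid",
    "RetentionParams",
    "SitePointSet",
    "PocketSite",
    "build_grid",
    "retain_site_points",
    "group_site_points",
    "characterize_site",
    "find_pockets",
    "export_sites_pdb",
    "export_density_grid",
    "write_site_report",
]

HYDROPHOBIC_RESNAMES = frozenset({"ALA", "VAL", "LEU", "ILE", "PRO", "PHE", "MET", "TRP"})

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}  # neighbours -> ndimage structure rank


@dataclass
class Grid:
    """Axis-aligned regular grid: point(i,j,k) = origin + spacing * (i,j,k)."""

    origin: np.ndarray
    spacing: float
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if any(d < 1 for d in self.dims):
            raise ValueError("grid dims must be >= 1")
        self.dims = tuple(int(d) for d in self.dims)

    @property
    def n_points(self) -> int:
        return int(np.prod(self.dims))

    def points(self) -> np.ndarray:
        """All grid points, C-ordered (k fastest), shape (n_points, 3)."""
        idx = np.indices(self.dims).reshape(3, -1).T
        return self.origin + self.spacing * idx

    def unravel(self, flat: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return np.unravel_index(flat, self.dims)


@dataclass
class RetentionParams:
    """Knobs of the retention and grouping steps.

    ratio_max: strict upper bound on d²/r_vdW² for the reference atom.
    mode: which atom the ratio is evaluated against — "nearest" (default,
        the strictest reading that still eliminates solvent-exposed points)
        or "any" (retain if any atom satisfies the ratio).
    min_site_points: components smaller than this are dropped.
    connectivity: 6 (face), 18 (edge) or 26 (vertex) grid neighbourhoods.
    """

    ratio_max: float = 2.5
    min_site_points: int = 15
    connectivity: int = 26
    mode: str = "nearest"

    def __post_init__(self) -> None:
        if self.ratio_max <= 1:
            raise ValueError("ratio_max must exceed 1")
        if self.connectivity not in _CONNECTIVITY_RANK:
            raise ValueError("connectivity must be one of 6, 18, 26")
        if self.mode not in ("nearest", "any"):
            raise ValueError("mode must be 'nearest' or 'any'")


@dataclass
class SitePointSet:
    """Retained grid points with their nearest receptor atom and distance."""

    grid: Grid
    retained: np.ndarray        # flat grid indices, increasing
    nearest_atom: np.ndarray    # per retained point
    nearest_dist: np.ndarray    # Å, per retained point

    @property
    def n_retained(self) -> int:
        return len(self.retained)

    def coords(self) -> np.ndarray:
        idx = np.stack(self.grid.unravel(self.retained), axis=1)
        return self.grid.origin + self.grid.spacing * idx


@dataclass
class PocketSite:
    """A connected component of retained site points."""

    points: np.ndarray               # (k, 3) coordinates, Å
    point_count: int
    volume: float                    # Å³ = point_count * spacing³
    centroid: np.ndarray
    rank: int = 0                    # 1-based after ordering
    contact_residues: list[tuple] = field(default_factory=list)
    hydrophobic_fraction: float | None = None
    no_contacts: bool = False
    provenance: dict = field(default_factory=dict)


def build_grid(s: Structure, spacing: float = 0.35, padding: float = 3.0) -> Grid:
    """Grid covering the bounding box of (atom centers ± vdW radius) + padding."""
    if spacing <= 0:
        raise ValueError("grid spacing must be positive")
    if not s.atoms:
        raise ValueError("cannot build a grid around an empty structure")
    coords = s.coords()
    radii = s.vdw_radii()
    lo = (coords - radii[:, None]).min(axis=0) - padding
    hi = (coords + radii[:, None]).max(axis=0) + padding
    dims = tuple(int(np.ceil((hi[a] - lo[a]) / spacing)) + 1 for a in range(3))
    return Grid(origin=lo, spacing=float(spacing), dims=dims)


def retain_site_points(
    grid: Grid, s: Structure, params: RetentionParams | None = None
) -> SitePointSet:
    """Apply the sheltered-point retention criterion to every grid point.

    A point is retained iff (a) it lies outside every atom's van der Waals
    sphere and (b) the squared-distance ratio d²/r_vdW² to the reference atom
    (nearest atom by default) is strictly below ``ratio_max``.
    """
    params = params or RetentionParams()
    coords = s.coords()
    radii = s.vdw_radii()
    pts = grid.points()
    tree = cKDTree(coords)
    d_nn, i_nn = tree.query(pts, workers=-1)
    r_nn = radii[i_nn]
    max_r = float(radii.max())

    inside_nn = d_nn <= r_nn  # inside (or on) the nearest atom's sphere
    if params.mode == "nearest":
        ratio_ok = d_nn * d_nn < params.ratio_max * r_nn * r_nn
        candidate = ~inside_nn & ratio_ok
    else:
        # "any" reading: some atom may satisfy the ratio; prefilter by reach
        reach = float(np.sqrt(params.ratio_max)) * max_r
        candidate = ~inside_nn & (d_nn < reach)

    # Resolve clause (a) exactly: a point outside its nearest atom can still
    # sit inside a farther atom with a larger radius.  Only candidates whose
    # nearest-atom distance is below the largest radius need the full scan.
    flags = np.zeros(len(pts), dtype=bool)
    cand_idx = np.nonzero(candidate)[0]
    flags[cand_idx] = True
    needs = cand_idx[d_nn[cand_idx] < max_r]
    if len(needs):
        for i, neigh in zip(needs, tree.query_ball_point(pts[needs], max_r, workers=-1)):
            d = np.linalg.norm(coords[neigh] - pts[i], axis=1)
            if np.any(d <= radii[neigh]):
                flags[i] = False
    if params.mode == "any":
        reach = float(np.sqrt(params.ratio_max)) * max_r
        outside = np.nonzero(flags)[0]
        for i, neigh in zip(outside, tree.query_ball_point(pts[outside], reach, workers=-1)):
            d2 = ((coords[neigh] - pts[i]) ** 2).sum(axis=1)
            if not np.any(d2 < params.ratio_max * radii[neigh] ** 2):
                flags[i] = False

    retained = np.nonzero(flags)[0]
    return SitePointSet(
        grid=grid,
        retained=retained,
        nearest_atom=i_nn[retained],
        nearest_dist=d_nn[retained],
    )


def group_site_points(
    sp: SitePointSet, params: RetentionParams | None = None
) -> list[PocketSite]:
    """Group retained points into connected components under the grid connectivity.

    Components smaller than ``min_site_points`` are dropped; sites are
    ordered by point count descending, ties broken by lexicographically
    smaller centroid.
    """
    params = params or RetentionParams()
    grid = sp.grid
    mask = np.zeros(grid.dims, dtype=bool)
    mask[grid.unravel(sp.retained)] = True
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[params.connectivity])
    labels, n_labels = ndimage.label(mask, structure=structure)
    sites: list[PocketSite] = []
    spacing = grid.spacing
    for lab in range(1, n_labels + 1):
        ijk = np.argwhere(labels == lab)
        if len(ijk) < params.min_site_points:
            continue
        pts = grid.origin + spacing * ijk
        centroid = pts.mean(axis=0)
        sites.append(
            PocketSite(
                points=pts,
                point_count=len(pts),
                volume=len(pts) * spacing**3,
                centroid=centroid,
            )
        )
    sites.sort(key=lambda s: (-s.point_count, tuple(np.round(s.centroid, 9))))
    for rank, site in enumerate(sites, start=1):
        site.rank = rank
    return sites


def characterize_site(
    site: PocketSite, s: Structure, contact_cutoff: float = 4.0
) -> PocketSite:
    """Fill compositional descriptors on a site (in place; also returned).

    Contacting residues are those with any atom within ``contact_cutoff`` of
    any site point; the hydrophobic fraction is the fraction of contacting
    residues with apolar side chains (ALA/VAL/LEU/ILE/PRO/PHE/MET/TRP).  A
    site with no contacts reports fraction 0 with ``no_contacts`` set.
    """
    tree = cKDTree(site.points)
    coords = s.coords()
    contacts: list[tuple] = []
    for key, resname, idx in s.residues():
        d, _ = tree.query(coords[idx], workers=-1)
        if np.any(d <= contact_cutoff):
            contacts.append((*key, resname))
    site.contact_residues = contacts
    if contacts:
        n_hyd = sum(1 for c in contacts if c[3] in HYDROPHOBIC_RESNAMES)
        site.hydrophobic_fraction = n_hyd / len(contacts)
        site.no_contacts = False
    else:
        site.hydrophobic_fraction = 0.0
        site.no_contacts = True
    return site


def find_pockets(
    s: Structure,
    spacing: float = 0.35,
    padding: float = 3.0,
    params: RetentionParams | None = None,
    contact_cutoff: float = 4.0,
    provenance: dict | None = None,
) -> list[PocketSite]:
    """Convenience pipeline: grid -> retention -> grouping -> descriptors."""
    params = params or RetentionParams()
    grid = build_grid(s, spacing=spacing, padding=padding)
    sp = retain_site_points(grid, s, params)
    sites = group_site_points(sp, params)
    for site in sites:
        characterize_site(site, s, contact_cutoff=contact_cutoff)
        site.provenance = dict(provenance or {"label": s.label})
    return sites


def export_sites_pdb(
    sites: list[PocketSite], s: Structure, path: str | Path
) -> None:
    """Merge receptor and site points into one PDB: sites as HETATM pseudo-atoms.

    Each site becomes one residue (resname SIT, chain 'z', resseq = rank)
    whose pseudo-atoms carry the site rank in the B-factor column; the file
    re-reads with :func:`ensitemap.structure_io.read_pdb`.
    """
    def _b36(n: int) -> str:
        digits = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZ"
        out = ""
        while True:
            n, r = divmod(n, 36)
            out = digits[r] + out
            if n == 0:
                return out

    atoms = list(s.atoms)
    serial = len(atoms)
    for site in sites:
        for k, p in enumerate(site.points):
            serial += 1
            atoms.append(
                AtomRecord(
                    serial=serial,
                    # unique fixed-width base-36 name per point so identities
                    # survive re-reading
                    name=_b36(k).rjust(4, "0"),
                    altloc="",
                    resname="SIT",
                    chain="z",
                    resseq=site.rank,
                    icode="",
                    x=float(p[0]),
                    y=float(p[1]),
                    z=float(p[2]),
                    element="C",
                    occupancy=1.0,
                    bfactor=float(site.rank),
                    het=True,
                )
            )
    write_pdb(path, Structure(atoms=atoms, model_id=s.model_id, label=s.label))


def export_density_grid(sp: SitePointSet, path: str | Path, isovalue: float = 0.5) -> None:
    """Plain-text occupancy grid (1 = retained, 0 = eliminated), one value/line.

    Values follow the grid's C ordering (k fastest); the header records
    origin, spacing, dims and the suggested rendering isovalue (default 0.5).
    """
    grid = sp.grid
    flags = np.zeros(grid.n_points, dtype=int)
    flags[sp.retained] = 1
    with open(path, "w") as fh:
        fh.write(f"# origin {grid.origin[0]:.4f} {grid.origin[1]:.4f} {grid.origin[2]:.4f}\n")
        fh.write(f"# spacing {grid.spacing:.4f}\n")
        fh.write(f"# dims {grid.dims[0]} {grid.dims[1]} {grid.dims[2]}\n")
        fh.write(f"# isovalue {isovalue}\n")
        fh.write("\n".join(map(str, flags)))
        fh.write("\n")


def write_site_report(sites: list[PocketSite], path: str | Path) -> pd.DataFrame:
    """TSV site table: rank, point count, volume, centroid, contacting residues."""
    rows = []
    for site in sites:
        rows.append(
            {
                "rank": site.rank,
                "point_count": site.point_count,
                "volume_A3": round(site.volume, 3),
                "centroid_x": round(float(site.centroid[0]), 3),
                "centroid_y": round(float(site.centroid[1]), 3),
                "centroid_z": round(float(site.centroid[2]), 3),
                "hydrophobic_fraction": (
                    round(site.hydrophobic_fraction, 3)
                    if site.hydrophobic_fraction is not None
                    else ""
                ),
                "contact_residues": ";".join(
                    f"{c[3]}{c[1]}{c[0]}" for c in site.contact_residues
                ),
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df
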