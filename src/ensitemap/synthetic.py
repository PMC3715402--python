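"""Seeded generators for toy proteins, hinge ensembles and probe-pose clouds.

These fixtures provide, at desk scale, the statistical and geometric
structure the pipeline assumes of real inputs: a compact serpentine
poly-alanine-like backbone (idealised geometry — 3.8 Å Cα spacing, fixed
N/C/O offsets; only distances and topology matter to the pipeline, not
chemistry), an ensemble with a rigid hinge rotation between two domains plus
optional Gaussian coordinate noise, a transient surface pocket that is open
only in a declared subset of members (lining side-chain atoms pushed
outward from the pocket anchor), and isotropic Gaussian probe-pose clouds
whose scores grow linearly with distance from the planted center.

Everything is deterministic under the seed; distributions are documented so
statistical tolerances in downstream tests are computable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .probe_consensus import ProbePose
from .structure_io import AtomRecord, Ensemble, Structure, write_pdb

__all__ = [
    "PoseCloudSpec",
    "HingeSpec",
    "HingeFixture",
    "make_toy_protein",
    "make_hinge_ensemble",
    "make_probe_poses",
    "write_probe_pdb",
    "default_pose_clouds",
]

_BACKBONE_OFFSETS = {
    "N": np.array([-1.2, 0.0, 0.9]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([1.2, 0.0, 0.9]),
    "O": np.array([1.4, 0.0, 2.1]),
}
_CA_SPACING = 3.8   # Å between consecutive Cα along a row
_ROW_SPACING = 5.0  # Å between serpentine rows

# Pocket lining: 3 LEU + 1 SER contribute 14 side-chain pseudo-atoms that
# tile a sphere around the pocket anchor.
_LINING_SIDECHAINS = [
    ("LEU", ["CB", "CG", "CD1", "CD2"]),
    ("LEU", ["CB", "CG", "CD1", "CD2"]),
    ("LEU", ["CB", "CG", "CD1", "CD2"]),
    ("SER", ["CB", "OG"]),
]
POCKET_OPEN_RADIUS = 2.4    # Å, lining-atom distance from anchor when open
POCKET_CLOSED_RADIUS = 1.1  # Å, when closed (anchor buried inside vdW spheres)


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately evenly spread unit vectors (golden-spiral lattice)."""
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def make_toy_protein(
    n_residues: int = 24,
    seed: int = 0,
    resnames: dict[int, str] | None = None,
    chain: str = "A",
    row_length: int = 8,
) -> Structure:
    """A compact serpentine backbone of N/CA/C/O atoms, ALA by default.

    Residues are numbered 1..n; ``resnames`` overrides residue names by
    0-based residue index.  The seed is recorded for reproducibility but the
    backbone itself is noise-free; identical calls are byte-identical.
    """
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    resnames = resnames or {}
    atoms: list[AtomRecord] = []
    serial = 0
    for i in range(n_residues):
        row, col = divmod(i, row_length)
        x = col if row % 2 == 0 else (row_length - 1 - col)  # serpentine
        ca = np.array([x * _CA_SPACING, row * _ROW_SPACING, 0.0])
        resname = resnames.get(i, "ALA")
        for name, offset in _BACKBONE_OFFSETS.items():
            serial += 1
            p = ca + offset
            atoms.append(
                AtomRecord(
                    serial=serial,
                    name=name,
                    altloc="",
                    resname=resname,
                    chain=chain,
                    resseq=i + 1,
                    icode="",
                    x=float(p[0]),
                    y=float(p[1]),
                    z=float(p[2]),
                    element=name[0],
                )
            )
    return Structure(atoms=atoms, model_id=1, label=f"toy{n_residues}_seed{seed}")


@dataclass
class HingeSpec:
    """Conditions of the hinge/transient-pocket ensemble.

    Defaults model one slow clamp-like degree of freedom sampled by a small
    representative ensemble: seven members, two hinge states (0° and 25°,
    split 4/3) and a surface pocket open in five of the seven members —
    noise-free, so every downstream decision is deterministic.
    """

    seed: int = 0
    n_residues: int = 24
    row_length: int = 8
    n_members: int = 7
    angles_deg: tuple[float, ...] | None = None   # default: 4 x 0°, 3 x 25°
    hinge_start: int = 16          # 0-based residue index where domain 2 begins
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    noise_sigma: float = 0.0       # Å, isotropic Gaussian per coordinate
    pocket_residues: tuple[int, ...] = (2, 3, 4, 5)  # 0-based, on domain 1
    pocket_open_members: tuple[int, ...] = (0, 1, 2, 3, 4)
    pocket_offset: tuple[float, float, float] = (0.0, -6.0, 0.0)

    def __post_init__(self) -> None:
        if self.angles_deg is None:
            n_closed_hinge = (self.n_members + 1) // 2  # e.g. 4 of 7 at 0°
            self.angles_deg = tuple(
                0.0 if i < n_closed_hinge else 25.0 for i in range(self.n_members)
            )
        if len(self.angles_deg) != self.n_members:
            raise ValueError("angle schedule length must equal member count")
        if max(self.pocket_residues) >= self.hinge_start:
            raise ValueError("pocket residues must sit on the fixed domain")
        if any(not 0 <= i < self.n_members for i in self.pocket_open_members):
            raise ValueError("pocket_open_members out of range")


@dataclass
class HingeFixture:
    """A hinge ensemble plus the ground truth planted in it."""

    ensemble: Ensemble
    pocket_anchor: np.ndarray
    open_members: tuple[int, ...]
    angles_deg: tuple[float, ...]
    spec: HingeSpec = field(repr=False, default=None)


def _rotation_about(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    a = np.deg2rad(angle_deg)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)


def _base_with_lining(spec: HingeSpec) -> tuple[Structure, np.ndarray, list[int]]:
    """Toy protein with pocket-lining residues mutated and side chains added."""
    if len(spec.pocket_residues) != len(_LINING_SIDECHAINS):
        raise ValueError(f"exactly {len(_LINING_SIDECHAINS)} pocket residues required")
    overrides = {
        i: resname
        for i, (resname, _) in zip(spec.pocket_residues, _LINING_SIDECHAINS)
    }
    base = make_toy_protein(
        n_residues=spec.n_residues,
        seed=spec.seed,
        resnames=overrides,
        row_length=spec.row_length,
    )
    # anchor sits below the mean Cα of the lining residues, clear of the body
    ca_pos = []
    for a in base.atoms:
        if a.name == "CA" and (a.resseq - 1) in spec.pocket_residues:
            ca_pos.append(a.coords)
    anchor = np.mean(ca_pos, axis=0) + np.asarray(spec.pocket_offset, dtype=float)

    atoms = list(base.atoms)
    serial = len(atoms)
    lining_idx: list[int] = []
    for res_i, (resname, names) in zip(spec.pocket_residues, _LINING_SIDECHAINS):
        for name in names:
            serial += 1
            lining_idx.append(len(atoms))
            atoms.append(
                AtomRecord(
                    serial=serial,
                    name=name,
                    altloc="",
                    resname=resname,
                    chain="A",
                    resseq=res_i + 1,
                    icode="",
                    x=0.0,  # placed per member (open/closed radius)
                    y=0.0,
                    z=0.0,
                    element="O" if name.startswith("O") else "C",
                )
            )
    s = Structure(atoms=atoms, model_id=1, label=base.label)
    return s, anchor, lining_idx


def make_hinge_ensemble(spec: HingeSpec | None = None) -> HingeFixture:
    """Build the hinge ensemble with its transient planted pocket.

    Member i is the toy protein with domain 2 (residues >= ``hinge_start``)
    rotated by ``angles_deg[i]`` about the hinge axis through the pivot (the
    Cα of the first domain-2 residue), plus Gaussian coordinate noise of
    width ``noise_sigma``.  The pocket-lining side-chain atoms sit on a
    sphere around the pocket anchor: radius 2.4 Å ("open", a sheltered
    cavity the grid detector can retain) in the declared member subset and
    1.1 Å ("closed", the anchor buried inside the lining van der Waals
    spheres) elsewhere.
    """
    spec = spec or HingeSpec()
    base, anchor, lining_idx = _base_with_lining(spec)
    directions = _fibonacci_sphere(len(lining_idx))
    base_coords = base.coords()
    pivot = None
    domain2 = []
    for j, a in enumerate(base.atoms):
        if (a.resseq - 1) >= spec.hinge_start:
            domain2.append(j)
        if a.name == "CA" and (a.resseq - 1) == spec.hinge_start:
            pivot = a.coords
    if pivot is None:
        raise ValueError("hinge_start residue has no CA atom")
    members = []
    rng = np.random.default_rng(spec.seed)
    for i in range(spec.n_members):
        coords = base_coords.copy()
        radius = (
            POCKET_OPEN_RADIUS
            if i in spec.pocket_open_members
            else POCKET_CLOSED_RADIUS
        )
        coords[lining_idx] = anchor + radius * directions
        R = _rotation_about(np.array(spec.axis), spec.angles_deg[i])
        coords[domain2] = (coords[domain2] - pivot) @ R.T + pivot
        if spec.noise_sigma > 0:
            coords += rng.normal(0.0, spec.noise_sigma, size=coords.shape)
        m = base.with_coords(coords, label=f"member{i}")
        m.model_id = i + 1
        members.append(m)
    return HingeFixture(
        ensemble=Ensemble(members=members),
        pocket_anchor=anchor,
        open_members=tuple(spec.pocket_open_members),
        angles_deg=tuple(spec.angles_deg),
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Probe-pose clouds
# ---------------------------------------------------------------------------

@dataclass
class PoseCloudSpec:
    """One planted cloud: isotropic Gaussian pose centers around ``center``.

    Scores follow a linear law, score = |pose center − planted center| (Å),
    so the best-scoring pose is always the one nearest the planted center.
    """

    center: tuple[float, float, float]
    n_poses: int = 30
    sigma: float = 0.5
    probe_type: str = "EOH"


# A small rigid 3-atom probe whose atom mean is exactly the pose center.
_PROBE_GEOMETRY = np.array(
    [[0.5, 0.0, 0.0], [-0.25, 0.433, 0.0], [-0.25, -0.433, 0.0]]
)


def make_probe_poses(
    clouds: list[PoseCloudSpec], seed: int = 0
) -> list[ProbePose]:
    """Generate seeded probe poses for the given clouds (order preserved)."""
    rng = np.random.default_rng(seed)
    poses: list[ProbePose] = []
    for cloud in clouds:
        center = np.asarray(cloud.center, dtype=float)
        offsets = rng.normal(0.0, cloud.sigma, size=(cloud.n_poses, 3)) \
            if cloud.sigma > 0 else np.zeros((cloud.n_poses, 3))
        for off in offsets:
            c = center + off
            poses.append(
                ProbePose(
                    probe_type=cloud.probe_type,
                    coords=c + _PROBE_GEOMETRY,
                    score=float(np.linalg.norm(off)),
                )
            )
    return poses


def default_pose_clouds(
    fixture: HingeFixture, member_index: int
) -> list[PoseCloudSpec]:
    """The study-condition clouds for one hinge-ensemble member.

    Two probe types converge on the pocket anchor (populations 18 and 12)
    and a third, smaller cloud (population 10) sits on the far side of the
    mobile domain, so consensus ranking, multi-type pooling and provenance
    are all exercised.
    """
    member = fixture.ensemble.members[member_index]
    top_row_ca = [
        a.coords
        for a in member.atoms
        if a.name == "CA" and (a.resseq - 1) >= fixture.spec.hinge_start
    ]
    far = np.mean(top_row_ca, axis=0) + np.array([0.0, 6.0, 0.0])
    anchor = tuple(fixture.pocket_anchor)
    return [
        PoseCloudSpec(center=anchor, n_poses=18, sigma=0.4, probe_type="EOH"),
        PoseCloudSpec(center=anchor, n_poses=12, sigma=0.4, probe_type="IPA"),
        PoseCloudSpec(center=tuple(far), n_poses=10, sigma=0.4, probe_type="ACN"),
    ]


def write_probe_pdb(poses: list[ProbePose], path: str | Path) -> None:
    """Write poses in the probe-PDB dialect (one residue per pose, score in B)."""
    atoms: list[AtomRecord] = []
    serial = 0
    for n, pose in enumerate(poses):
        chain = chr(ord("A") + (n // 9999))
        resseq = n % 9999 + 1
        for j, p in enumerate(pose.coords, start=1):
            serial += 1
            atoms.append(
                AtomRecord(
                    serial=serial,
                    name=f"C{j}",
                    altloc="",
                    resname=pose.probe_type,
                    chain=chain,
                    resseq=resseq,
                    icode="",
                    x=float(p[0]),
                    y=float(p[1]),
                    z=float(p[2]),
                    element="C",
                    occupancy=1.0,
                    bfactor=float(pose.score) if pose.score is not None else 0.0,
                    het=True,
                )
            )
    write_pdb(path, Structure(atoms=atoms, model_id=1, label="probes"))
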