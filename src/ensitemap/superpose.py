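"""Rigid-body least-squares superposition (Kabsch) and RMSD.

Fitting is unweighted (every selected atom has weight 1) and restricted to
proper rotations: a reflection that would lower the residual is rejected by
flipping the sign of the smallest singular direction, since molecular mirror
images are non-physical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import Ensemble, SelectionExpr, Structure, select_atoms

__all__ = [
    "RigidTransform",
    "DegenerateGeometryError",
    "kabsch_fit",
    "rmsd",
    "fit_then_rmsd",
    "transform_structure",
    "align_ensemble",
]


class DegenerateGeometryError(ValueError):
    """Raised when point sets are too small or too degenerate to define a fit."""


@dataclass(frozen=True)
class RigidTransform:
    """x -> rotation @ x + translation, with a proper orthogonal rotation."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthogonal within 1e-9")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ValueError("rotation determinant is not +1 within 1e-9 (improper)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Apply to an (n, 3) array (or a single 3-vector)."""
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def is_identity(self, atol: float = 1e-8) -> bool:
        return bool(
            np.allclose(self.rotation, np.eye(3), atol=atol)
            and np.allclose(self.translation, 0.0, atol=atol)
        )


def kabsch_fit(mobile: np.ndarray, reference: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping ``mobile`` onto ``reference``.

    Standard Kabsch SVD solution; both inputs are (N, 3) with N >= 3 and must
    not be collinear.  Returns the transform minimizing the sum of squared
    deviations, restricted to proper rotations.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError(f"shape mismatch: {P.shape} vs {Q.shape}")
    n = P.shape[0]
    if n < 3:
        raise DegenerateGeometryError(f"need at least 3 points to fit, got {n}")
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    P0 = P - pc
    Q0 = Q - qc
    H = P0.T @ Q0
    # Collinear (rank < 2 after centering) point sets leave a rotation axis free.
    if min(np.linalg.matrix_rank(P0, tol=1e-9), np.linalg.matrix_rank(Q0, tol=1e-9)) < 2:
        raise DegenerateGeometryError("point set is collinear after centering")
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    return RigidTransform(R, t)


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square deviation between two equal-length coordinate sets."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"coordinate shape mismatch: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("empty coordinate sets")
    d = a - b
    return float(np.sqrt((d * d).sum() / len(a)))


def _coords_at(s: Structure, sel: str | SelectionExpr, min_atoms: int = 1) -> np.ndarray:
    idx = select_atoms(s, sel, min_atoms=min_atoms)
    return s.coords()[idx]


def fit_then_rmsd(
    mobile: Structure,
    reference: Structure,
    fit_sel: str | SelectionExpr = "all",
    rmsd_sel: str | SelectionExpr = "all",
) -> float:
    """Superpose on ``fit_sel`` atoms, then measure RMSD over ``rmsd_sel`` atoms.

    This mirrors the common trajectory-analysis convention of least-squares
    fitting on a rigid core (e.g. "name CA and resseq 171-427") while the
    deviation itself is evaluated on a possibly different atom set.
    """
    t = kabsch_fit(_coords_at(mobile, fit_sel, min_atoms=3),
                   _coords_at(reference, fit_sel, min_atoms=3))
    moved = t.apply(_coords_at(mobile, rmsd_sel))
    return rmsd(moved, _coords_at(reference, rmsd_sel))


def transform_structure(s: Structure, t: RigidTransform) -> Structure:
    return s.with_coords(t.apply(s.coords()))


def align_ensemble(
    e: Ensemble,
    reference_index: int = 0,
    fit_sel: str | SelectionExpr = "all",
) -> tuple[Ensemble, list[RigidTransform]]:
    """Superpose every member onto the reference member.

    Returns the aligned ensemble and the per-member transforms (identity for
    the reference), so that site coordinates attached to each member can be
    carried into the reference frame with the same transform.
    """
    if not (0 <= reference_index < len(e)):
        raise IndexError(f"reference index {reference_index} out of range")
    ref = e.members[reference_index]
    ref_fit = _coords_at(ref, fit_sel, min_atoms=3)
    members: list[Structure] = []
    transforms: list[RigidTransform] = []
    for i, m in enumerate(e.members):
        if i == reference_index:
            t = RigidTransform.identity()
            members.append(m)
        else:
            t = kabsch_fit(_coords_at(m, fit_sel, min_atoms=3), ref_fit)
            members.append(transform_structure(m, t))
        transforms.append(t)
    return Ensemble(members=members, metadata=e.metadata), transforms
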