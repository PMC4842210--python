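"""Backbone dihedrals, mirror reflection, and Kabsch superposition.

Sign conventions follow IUPAC: a torsion is positive when, looking along
the central bond, the far bond rotates clockwise from the near bond.
Angles are degrees in the half-open interval (-180, 180]; an exact -180
is mapped to +180.  Undefined angles (termini, chain breaks) are NaN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .structure_io import StructureModel

logger = logging.getLogger(__name__)


class GeometryError(ValueError):
    """Degenerate geometry (coincident or collinear points)."""


def _wrap_angle(deg: float) -> float:
    """Map to (-180, 180]."""
    wrapped = ((deg + 180.0) % 360.0) - 180.0
    return 180.0 if wrapped == -180.0 else wrapped


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle p1-p2-p3-p4 in degrees, IUPAC convention."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b0 = p1 - p2
    b1 = p3 - p2
    b2 = p4 - p3
    nb1 = np.linalg.norm(b1)
    if nb1 < 1e-12:
        raise GeometryError("central bond p2-p3 has zero length")
    b1 = b1 / nb1
    # projections of the outer bonds onto the plane normal to the central bond
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    if np.linalg.norm(v) < 1e-9 or np.linalg.norm(w) < 1e-9:
        raise GeometryError("collinear points: torsion undefined")
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return _wrap_angle(np.degrees(np.arctan2(y, x)))


@dataclass
class DihedralSeries:
    """Per-residue phi/psi/omega in degrees; NaN marks undefined angles."""

    phi: np.ndarray
    psi: np.ndarray
    omega: np.ndarray

    def __len__(self) -> int:
        return len(self.phi)

    @property
    def defined_phi(self) -> np.ndarray:
        return self.phi[~np.isnan(self.phi)]

    @property
    def defined_psi(self) -> np.ndarray:
        return self.psi[~np.isnan(self.psi)]


def _dihedral_batch(p1, p2, p3, p4) -> np.ndarray:
    """Vectorised torsions for stacked (m, 3) point quadruples, degrees."""
    b0 = p1 - p2
    b1 = p3 - p2
    b1 = b1 / np.linalg.norm(b1, axis=1, keepdims=True)
    b2 = p4 - p3
    v = b0 - np.sum(b0 * b1, axis=1, keepdims=True) * b1
    w = b2 - np.sum(b2 * b1, axis=1, keepdims=True) * b1
    x = np.sum(v * w, axis=1)
    y = np.sum(np.cross(b1, v) * w, axis=1)
    out = np.degrees(np.arctan2(y, x))
    wrapped = ((out + 180.0) % 360.0) - 180.0
    wrapped[wrapped == -180.0] = 180.0
    return wrapped


def backbone_dihedrals(model: StructureModel) -> DihedralSeries:
    """Compute phi/psi/omega for every residue.

    phi(i) = C(i-1)-N(i)-CA(i)-C(i); psi(i) = N(i)-CA(i)-C(i)-N(i+1);
    omega(i) = CA(i)-C(i)-N(i+1)-CA(i+1).  Angles spanning a chain break
    or a terminus are NaN.
    """
    n = len(model)
    if n < 3:
        raise ValueError("model must have at least 3 residues")
    res = model.residues
    atom_n = np.array([r.coord("N") for r in res])
    atom_ca = np.array([r.coord("CA") for r in res])
    atom_c = np.array([r.coord("C") for r in res])
    intact = np.array([not r.chain_break_after for r in res])

    phi = np.full(n, np.nan)
    psi = np.full(n, np.nan)
    omega = np.full(n, np.nan)
    phi[1:] = _dihedral_batch(atom_c[:-1], atom_n[1:], atom_ca[1:], atom_c[1:])
    psi[:-1] = _dihedral_batch(atom_n[:-1], atom_ca[:-1], atom_c[:-1], atom_n[1:])
    omega[:-1] = _dihedral_batch(atom_ca[:-1], atom_c[:-1], atom_n[1:], atom_ca[1:])
    phi[1:][~intact[:-1]] = np.nan
    psi[:-1][~intact[:-1]] = np.nan
    omega[:-1][~intact[:-1]] = np.nan
    return DihedralSeries(phi=phi, psi=psi, omega=omega)


def mirror_reflect(model: StructureModel) -> StructureModel:
    """Ideal mirror image: negate every x coordinate (reflection in yz).

    All improper operations are equivalent up to a rotation, which any
    subsequent superposition absorbs, so one canonical plane suffices.
    """
    out = model.copy(new_id=f"{model.id}_mirror")
    for r in out.residues:
        for coords in r.atoms.values():
            coords[0] = -coords[0]
    return out


@dataclass
class Superposition:
    """Least-squares rigid transform mapping mobile onto target."""

    rotation: np.ndarray  # 3x3, proper (det = +1)
    translation: np.ndarray  # 3-vector
    rmsd: float

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray) -> Superposition:
    """Optimal proper rotation + translation of mobile onto target.

    Points are paired by index.  The reflection branch of the SVD solution
    is excluded by the usual determinant sign correction, so the rotation
    is always proper even for mirror-related point sets.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape:
        raise ValueError(f"point count mismatch: {mobile.shape} vs {target.shape}")
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise ValueError("need >= 3 paired 3-D points")

    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    m0 = mobile - mc
    t0 = target - tc
    if np.linalg.matrix_rank(m0, tol=1e-9) < 2 or np.linalg.matrix_rank(t0, tol=1e-9) < 2:
        logger.warning("degenerate (collinear) point set: superposition not unique")

    h = m0.T @ t0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T

    residual = m0 @ rot.T - t0
    rmsd = float(np.sqrt(np.mean(np.sum(residual ** 2, axis=1))))
    translation = tc - rot @ mc
    return Superposition(rotation=rot, translation=translation, rmsd=rmsd)


def ca_rmsd(model_a: StructureModel, model_b: StructureModel) -> float:
    """CA-only RMSD after optimal proper superposition."""
    if len(model_a) != len(model_b):
        raise ValueError(
            f"length mismatch: {len(model_a)} vs {len(model_b)} residues"
        )
    return kabsch_superpose(model_a.ca_coords(), model_b.ca_coords()).rmsd
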