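"""Rigid-body superposition, RMSD, inter-domain rotations and the two
reaction coordinates of the swiveling analysis.

The two reaction coordinates are C-alpha/C-alpha distances in the canonical
frame: H456–H565 tracks the central-domain (CD) swiveling between the
nucleotide- and PEP-binding domains, and S215–E272 tracks the opening and
closing of the N-terminal nucleotide-binding domain (NBD1 vs NBD3).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .structures import DomainDefinition, StructureModel

logger = logging.getLogger(__name__)

#: canonical landmark residues of the two reaction coordinates
CD_PBD_PAIR = (456, 565)
NBD1_NBD3_PAIR = (215, 272)


@dataclass
class SuperpositionResult:
    rotation: np.ndarray      # (3, 3), det = +1
    translation: np.ndarray   # (3,)
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class DomainRotation:
    angle: float              # degrees, [0, 180]
    axis: np.ndarray          # unit vector
    screw_translation: float  # Angstrom along the axis


@dataclass
class ReactionCoordinates:
    distance_cd_pbd: float | None
    distance_nbd1_nbd3: float | None

    @property
    def cd_pbd_resolved(self) -> bool:
        return self.distance_cd_pbd is not None

    @property
    def nbd1_nbd3_resolved(self) -> bool:
        return self.distance_nbd1_nbd3 is not None


def superpose(mobile: np.ndarray, target: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition (Kabsch), reflections excluded.

    Returns the transform that maps ``mobile`` onto ``target`` and the RMSD
    after applying it.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape:
        raise ValueError(f"shape mismatch: {mobile.shape} vs {target.shape}")
    if mobile.shape[0] < 3:
        raise ValueError("superposition needs at least 3 paired points")
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    a, b = mobile - mc, target - tc
    # rank < 2 means collinear (or coincident) points: rotation ill-defined
    if np.linalg.matrix_rank(b, tol=1e-9) < 2 or np.linalg.matrix_rank(a, tol=1e-9) < 2:
        raise ValueError("degenerate geometry: points are collinear")
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = tc - rot @ mc
    diff = (mobile @ rot.T + trans) - target
    rmsd = float(np.sqrt((diff ** 2).sum() / len(mobile)))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd)


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Best-fit RMSD between two paired coordinate sets."""
    return superpose(a, b).rmsd


def rotation_angle_axis(rot: np.ndarray) -> tuple[float, np.ndarray]:
    """Angle (degrees, [0, 180]) and unit axis of a rotation matrix."""
    rv = Rotation.from_matrix(rot).as_rotvec()
    angle = float(np.degrees(np.linalg.norm(rv)))
    if angle < 1e-12:
        return 0.0, np.array([0.0, 0.0, 1.0])
    return angle, rv / np.linalg.norm(rv)


def _paired_domain_ca(state1: StructureModel, state2: StructureModel,
                      residues: list[int]) -> tuple[np.ndarray, np.ndarray]:
    keys1 = {k for k in state1.ca_residues()}
    keys2 = {k for k in state2.ca_residues()}
    common = [(r, "") for r in residues if (r, "") in keys1 and (r, "") in keys2]
    missing = [r for r in residues if (r, "") not in keys1 or (r, "") not in keys2]
    if missing:
        logger.debug("dropping %d unresolved residues from paired set", len(missing))
    if len(common) < 3:
        raise ValueError(f"domain unresolved: only {len(common)} residues of "
                         f"{len(residues)} present in both structures; "
                         f"missing {missing[:10]}...")
    return state1.ca_coords(common), state2.ca_coords(common)


def domain_rotation(state1: StructureModel, state2: StructureModel,
                    anchor: str, moving: str,
                    domains: DomainDefinition | None = None) -> DomainRotation:
    """Rotation of the ``moving`` domain between two states, measured after
    superposing the states over the ``anchor`` domain.

    The angle comes from the trace of the residual best-fit rotation of the
    moving domain, the axis from its rotation vector, and the screw
    translation is the centroid displacement projected on the axis.
    """
    domains = domains or DomainDefinition()
    a1, a2 = _paired_domain_ca(state1, state2, domains.residues(anchor))
    sup_anchor = superpose(a2, a1)
    m1, m2 = _paired_domain_ca(state1, state2, domains.residues(moving))
    m2 = sup_anchor.apply(m2)
    sup_moving = superpose(m2, m1)
    angle, axis = rotation_angle_axis(sup_moving.rotation)
    centroid_shift = m1.mean(axis=0) - m2.mean(axis=0)
    screw = float(np.dot(centroid_shift, axis))
    return DomainRotation(angle=angle, axis=axis, screw_translation=screw)


def pair_distance(s: StructureModel, atom1: tuple[int, str],
                  atom2: tuple[int, str], hetero2: bool | None = None) -> float:
    """Euclidean distance between two named atoms (Angstrom)."""
    a = s.get_atom(atom1[0], atom1[1])
    b = s.get_atom(atom2[0], atom2[1], hetero=hetero2)
    return float(np.linalg.norm(a.xyz - b.xyz))


def _ca_distance(s: StructureModel, pair: tuple[int, int]) -> float | None:
    try:
        a = s.get_atom(pair[0], "CA", hetero=False)
        b = s.get_atom(pair[1], "CA", hetero=False)
    except KeyError:
        return None
    return float(np.linalg.norm(a.xyz - b.xyz))


def reaction_coordinates(s: StructureModel) -> ReactionCoordinates:
    """Evaluate both reaction coordinates; unresolved landmarks give None."""
    return ReactionCoordinates(
        distance_cd_pbd=_ca_distance(s, CD_PBD_PAIR),
        distance_nbd1_nbd3=_ca_distance(s, NBD1_NBD3_PAIR))


def landmark_displacement(state1: StructureModel, state2: StructureModel,
                          residue: int, align_set: list[int],
                          ) -> float:
    """C-alpha displacement of a landmark residue between two states after
    aligning state2 onto state1 over ``align_set`` residues."""
    a1, a2 = _paired_domain_ca(state1, state2, align_set)
    sup = superpose(a2, a1)
    p1 = state1.get_atom(residue, "CA", hetero=False).xyz
    p2 = sup.rotation @ state2.get_atom(residue, "CA", hetero=False).xyz + sup.translation
    return float(np.linalg.norm(p1 - p2))
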