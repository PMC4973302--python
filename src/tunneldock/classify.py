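"""Portal-penetration and ring-orientation classification of docked poses.

A portal is "penetrated" when at least one ligand heavy atom lies beyond the
portal's gate plane (positive signed distance along the outward normal); the
atom-count threshold is configurable. Ring orientation compares the
epsilon-ring centroid's distance to the two gate points: a pose is
``epsilon_in`` when the epsilon (small) ring sits nearer the deep portal 2.
Gate planes are flat by design: a plane test is deterministic and invariant
under joint rigid motion of protein, portals and pose.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .ensemble import Pose, PoseSet
from .scoring import ScoreRecord
from .structures import ProteinStructure, StructureError

__all__ = [
    "PortalDefinition",
    "ClassifiedScore",
    "define_portals",
    "classify_portal",
    "classify_orientation",
    "classify_ensemble",
    "classified_to_table",
    "PORTAL_CLASSES",
    "ORIENTATION_CLASSES",
]

PORTAL_CLASSES = ("one_portal", "two_portals", "portal2_only", "none")
ORIENTATION_CLASSES = ("epsilon_in", "beta_in")


@dataclass
class PortalDefinition:
    """A cavity opening: lining residues, gate plane and nominal aperture."""

    label: str
    point: np.ndarray
    normal: np.ndarray
    residues: list[tuple[str, int]] = field(default_factory=list)
    aperture: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float).reshape(3)
        normal = np.asarray(self.normal, dtype=float).reshape(3)
        norm = np.linalg.norm(normal)
        if norm < 1e-12:
            raise ValueError("portal normal must be nonzero")
        self.normal = normal / norm

    def signed_distances(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        return (coords - self.point) @ self.normal

    def to_json(self) -> dict:
        return {
            "label": self.label,
            "point": [float(x) for x in self.point],
            "normal": [float(x) for x in self.normal],
            "residues": [[c, int(r)] for c, r in self.residues],
            "aperture": list(self.aperture) if self.aperture else None,
        }


def define_portals(
    protein: ProteinStructure,
    portal1_residues: Sequence[tuple[str, int]],
    portal2_residues: Sequence[tuple[str, int]],
    cavity_centroid: np.ndarray | None = None,
) -> tuple[PortalDefinition, PortalDefinition]:
    """Derive gate planes from portal-lining residue selections.

    Each gate point is the centroid of the lining atoms; normals point away
    from the cavity centroid (defaulting to the midpoint of the two gate
    points, which guarantees opposing normals).
    """
    def centroid(residues):
        missing = [r for r in residues if tuple(r) not in protein.residue_index]
        if missing:
            raise StructureError(f"portal residues missing from structure: {missing}")
        pts = []
        for chain_id, seq in residues:
            pts.extend(a.position for a in protein.residue(chain_id, seq))
        return np.mean(np.array(pts), axis=0)

    c1 = centroid(portal1_residues)
    c2 = centroid(portal2_residues)
    if cavity_centroid is None:
        cavity_centroid = 0.5 * (c1 + c2)
    cavity_centroid = np.asarray(cavity_centroid, dtype=float)
    n1 = c1 - cavity_centroid
    n2 = c2 - cavity_centroid
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise StructureError("portal centroid coincides with the cavity centroid")
    p1 = PortalDefinition("portal1", c1, n1, residues=list(map(tuple, portal1_residues)))
    p2 = PortalDefinition("portal2", c2, n2, residues=list(map(tuple, portal2_residues)))
    if float(np.dot(p1.normal, p2.normal)) >= 0:
        raise StructureError("portal normals do not oppose; check residue selections")
    return p1, p2


def classify_portal(
    p: Pose | np.ndarray,
    portals: tuple[PortalDefinition, PortalDefinition],
    min_atoms_beyond: int = 1,
) -> str:
    """Which gate planes the pose breaches: ``two_portals``, ``one_portal``
    (portal 1 only), ``portal2_only`` or ``none``."""
    coords = p.coords if isinstance(p, Pose) else np.asarray(p, dtype=float)
    p1, p2 = portals
    breach1 = int(np.sum(p1.signed_distances(coords) > 0)) >= min_atoms_beyond
    breach2 = int(np.sum(p2.signed_distances(coords) > 0)) >= min_atoms_beyond
    if breach1 and breach2:
        return "two_portals"
    if breach1:
        return "one_portal"
    if breach2:
        return "portal2_only"
    return "none"


def classify_orientation(
    p: Pose,
    portals: tuple[PortalDefinition, PortalDefinition],
) -> str:
    """``epsilon_in`` when the epsilon-ring centroid is nearer portal 2's gate
    point than portal 1's; ``beta_in`` otherwise. Ties break to epsilon_in."""
    conf = p.conformer
    if "epsilon" not in conf.ring_labels:
        raise StructureError("conformer lacks ring labels")
    eps_centroid = p.coords[conf.ring_labels["epsilon"]].mean(axis=0)
    p1, p2 = portals
    d1 = float(np.linalg.norm(eps_centroid - p1.point))
    d2 = float(np.linalg.norm(eps_centroid - p2.point))
    return "epsilon_in" if d2 <= d1 else "beta_in"


@dataclass
class ClassifiedScore:
    """A :class:`ScoreRecord` augmented with portal and orientation classes."""

    record: ScoreRecord
    portal_class: str
    orientation_class: str

    def __post_init__(self) -> None:
        if self.portal_class not in PORTAL_CLASSES:
            raise ValueError(f"unknown portal class {self.portal_class!r}")
        if self.orientation_class not in ORIENTATION_CLASSES:
            raise ValueError(f"unknown orientation class {self.orientation_class!r}")

    # membership flags for the four overlapping analysis sets
    @property
    def in_two_portals(self) -> bool:
        return self.portal_class == "two_portals"

    @property
    def in_one_portal(self) -> bool:
        return self.portal_class == "one_portal"

    @property
    def epsilon_toward_portal2(self) -> bool:
        return self.orientation_class == "epsilon_in"

    @property
    def epsilon_toward_portal1(self) -> bool:
        return self.orientation_class == "beta_in"

    @property
    def pose_id(self) -> str:
        return self.record.pose_id

    @property
    def clashes(self) -> int:
        return self.record.clashes

    @property
    def hbonds(self) -> int:
        return self.record.hbonds


def classify_ensemble(
    ps: PoseSet,
    records: Sequence[ScoreRecord],
    portals: tuple[PortalDefinition, PortalDefinition],
    min_atoms_beyond: int = 1,
) -> list[ClassifiedScore]:
    if len(records) != len(ps):
        raise ValueError("records and poses differ in length")
    out = []
    for pose, record in zip(ps, records):
        if pose.pose_id != record.pose_id:
            raise ValueError("records out of order with respect to poses")
        out.append(
            ClassifiedScore(
                record=record,
                portal_class=classify_portal(pose, portals, min_atoms_beyond),
                orientation_class=classify_orientation(pose, portals),
            )
        )
    return out


def classified_to_table(classified: Sequence[ClassifiedScore]) -> pd.DataFrame:
    rows = []
    for c in classified:
        r = c.record
        rows.append(
            {
                "pose_id": r.pose_id,
                "template": r.template_index,
                "conformer": r.conformer_index,
                "orientation": r.orientation,
                "clashes": r.clashes,
                "hbonds": r.hbonds,
                "portal_class": c.portal_class,
                "orientation_class": c.orientation_class,
            }
        )
    return pd.DataFrame(rows)
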