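"""Least-squares rigid-body superposition (Kabsch algorithm).

Implements proper-rotation least-squares fitting between corresponding point
sets, the shared-numbering C-alpha RMSD between two protein models, and the
end-to-end *inverted* atom correspondence used to dock a two-ring ligand in
its flipped orientation. Reflections are excluded by the standard SVD sign
correction (the axis of the smallest singular value is flipped when the
determinant would be negative).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structures import LigandConformer, ProteinStructure, StructureError

__all__ = [
    "RigidTransform",
    "Correspondence",
    "DegenerateGeometryError",
    "kabsch_fit",
    "ca_rmsd",
    "direct_correspondence",
    "inverted_correspondence",
]


class DegenerateGeometryError(ValueError):
    """Point sets too degenerate (collinear/coincident) for a defined fit."""


@dataclass
class RigidTransform:
    """A proper rotation plus translation, in Angstrom."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise ValueError("rotation determinant must be +1")
        if not np.allclose(
            self.rotation.T @ self.rotation, np.eye(3), atol=1e-9
        ):
            raise ValueError("rotation must be orthogonal")

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.rotation @ other.translation + self.translation,
        )

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(rotation=np.eye(3), translation=np.zeros(3))

    def to_json(self) -> dict:
        return {
            "rotation": [float(x) for x in self.rotation.ravel()],
            "translation": [float(x) for x in self.translation],
        }

    @classmethod
    def from_json(cls, record: dict) -> "RigidTransform":
        return cls(
            rotation=np.asarray(record["rotation"], dtype=float).reshape(3, 3),
            translation=np.asarray(record["translation"], dtype=float),
        )


@dataclass
class Correspondence:
    """Ordered pairing (moving index, target index) with an orientation label."""

    pairs: np.ndarray
    label: str = "direct"

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        if self.label not in ("direct", "inverted"):
            raise ValueError(f"unknown correspondence label {self.label!r}")
        for col in (0, 1):
            if len(np.unique(self.pairs[:, col])) != len(self.pairs):
                raise ValueError("correspondence indices must be unique per column")
        if len(self.pairs) < 3:
            raise ValueError("correspondence needs at least 3 pairs")

    def __len__(self) -> int:
        return len(self.pairs)


def direct_correspondence(n: int) -> Correspondence:
    idx = np.arange(n)
    return Correspondence(pairs=np.stack([idx, idx], axis=1), label="direct")


def inverted_correspondence(c: LigandConformer) -> Correspondence:
    """Pair each ligand atom with its end-to-end inversion partner.

    Applying the resulting index mapping twice recovers the direct
    correspondence (the inversion map is an involution).
    """
    if c.inversion_map is None:  # pragma: no cover - dataclass enforces presence
        raise StructureError("conformer lacks an inversion map")
    idx = np.arange(c.n_atoms)
    return Correspondence(
        pairs=np.stack([idx, c.inversion_map], axis=1), label="inverted"
    )


def _check_nondegenerate(points: np.ndarray, which: str) -> None:
    centered = points - points.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    scale = max(sv[0], 1.0)
    if sv[0] < 1e-8 or sv[1] / scale < 1e-8:
        raise DegenerateGeometryError(
            f"{which} point set is {'coincident' if sv[0] < 1e-8 else 'collinear'}"
        )


def kabsch_fit(
    moving: np.ndarray,
    target: np.ndarray,
    c: Correspondence | None = None,
) -> tuple[RigidTransform, float]:
    """Least-squares proper-rotation fit of ``moving`` onto ``target``.

    Returns the optimal :class:`RigidTransform` and the RMSD (A) over the
    corresponding pairs after transformation. Without an explicit
    correspondence, points are paired by index.
    """
    moving = np.asarray(moving, dtype=float).reshape(-1, 3)
    target = np.asarray(target, dtype=float).reshape(-1, 3)
    if c is None:
        if len(moving) != len(target):
            raise ValueError("point sets differ in size and no correspondence given")
        c = direct_correspondence(len(moving))
    mov = moving[c.pairs[:, 0]]
    tgt = target[c.pairs[:, 1]]
    _check_nondegenerate(mov, "moving")
    _check_nondegenerate(tgt, "target")

    mov_centroid = mov.mean(axis=0)
    tgt_centroid = tgt.mean(axis=0)
    P = mov - mov_centroid
    Q = tgt - tgt_centroid
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = tgt_centroid - R @ mov_centroid
    transform = RigidTransform(rotation=R, translation=t)
    moved = transform.apply(mov)
    rmsd = float(np.sqrt(np.mean(np.sum((moved - tgt) ** 2, axis=1))))
    return transform, rmsd


def ca_rmsd(
    a: ProteinStructure,
    b: ProteinStructure,
    selection: list[tuple[str, int]] | None = None,
    altloc: str = "A",
) -> tuple[float, int]:
    """Optimal-superposition RMSD over shared C-alpha atoms.

    Residues are paired by shared (chain, residue number); an optional
    ``selection`` restricts the pairing. Returns (rmsd in A, number of
    paired C-alpha atoms).
    """
    ca_a = a.ca_atoms(altloc=altloc)
    ca_b = b.ca_atoms(altloc=altloc)
    keys = sorted(set(ca_a) & set(ca_b))
    if selection is not None:
        wanted = set(selection)
        keys = [k for k in keys if k in wanted]
    if not keys:
        raise StructureError("no shared C-alpha atoms between the two structures")
    pa = np.array([ca_a[k].position for k in keys])
    pb = np.array([ca_b[k].position for k in keys])
    _, rmsd = kabsch_fit(pa, pb)
    return rmsd, len(keys)
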