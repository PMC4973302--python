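"""Docked pose ensemble construction.

Every library conformer is superposed onto every docked template in both the
direct and the end-to-end inverted atom correspondence, yielding one rigid
pose per (template, conformer, orientation) combination. Poses carry full
provenance (indices, orientation, fitted transform) and the set records a
manifest sufficient to regenerate it bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .structures import LigandConformer, ProteinStructure, StructureError, write_structure, Atom
from .superpose import (
    Correspondence,
    RigidTransform,
    direct_correspondence,
    inverted_correspondence,
    kabsch_fit,
)

__all__ = ["Pose", "PoseSet", "build_ensemble", "write_pose"]

ORIENTATIONS = ("direct", "inverted")


@dataclass
class Pose:
    """One rigid placement of a library conformer in the protein frame."""

    pose_id: str
    template_index: int
    conformer_index: int
    orientation: str
    transform: RigidTransform
    coords: np.ndarray
    fit_rmsd: float
    conformer: LigandConformer

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def placed_conformer(self) -> LigandConformer:
        """The conformer annotation carried onto the placed coordinates."""
        return self.conformer.with_coords(self.coords)


@dataclass
class PoseSet:
    poses: list[Pose]
    protein_id: str
    manifest: dict

    def __post_init__(self) -> None:
        ids = [p.pose_id for p in self.poses]
        if len(set(ids)) != len(ids):
            raise StructureError("pose ids must be unique")

    def __len__(self) -> int:
        return len(self.poses)

    def __iter__(self):
        return iter(self.poses)


def _coords_digest(arrays: Sequence[np.ndarray]) -> str:
    h = hashlib.sha256()
    for arr in arrays:
        h.update(np.ascontiguousarray(arr, dtype=np.float64).tobytes())
    return h.hexdigest()


def build_ensemble(
    templates: Sequence[LigandConformer],
    library: Sequence[LigandConformer],
    orientations: Sequence[str] = ORIENTATIONS,
    protein_id: str = "",
) -> PoseSet:
    """Superpose every library conformer onto every template.

    Pose ordering is lexicographic in (template index, conformer index,
    orientation) so regeneration from the same inputs is deterministic.
    """
    if not templates:
        raise StructureError("no templates supplied")
    if not library:
        raise StructureError("empty conformer library")
    orientations = tuple(orientations)
    for o in orientations:
        if o not in ORIENTATIONS:
            raise StructureError(f"unknown orientation {o!r}")

    poses: list[Pose] = []
    for ti, template in enumerate(templates):
        tgt = template.coords
        for ci, conformer in enumerate(library):
            if conformer.n_atoms != template.n_atoms:
                raise StructureError(
                    f"conformer {ci} atom count {conformer.n_atoms} != "
                    f"template {ti} atom count {template.n_atoms}"
                )
            mov = conformer.coords
            for orientation in orientations:
                if orientation == "direct":
                    corr = direct_correspondence(conformer.n_atoms)
                else:
                    corr = inverted_correspondence(template)
                transform, rmsd = kabsch_fit(mov, tgt, corr)
                placed = transform.apply(mov)
                poses.append(
                    Pose(
                        pose_id=f"t{ti:03d}_c{ci:03d}_{orientation}",
                        template_index=ti,
                        conformer_index=ci,
                        orientation=orientation,
                        transform=transform,
                        coords=placed,
                        fit_rmsd=rmsd,
                        conformer=conformer,
                    )
                )
    manifest = {
        "n_templates": len(templates),
        "n_conformers": len(library),
        "orientations": list(orientations),
        "species": library[0].species,
        "template_digest": _coords_digest([t.coords for t in templates]),
        "library_digest": _coords_digest([c.coords for c in library]),
        "protein_id": protein_id,
    }
    return PoseSet(poses=poses, protein_id=protein_id, manifest=manifest)


def write_pose(
    p: Pose,
    protein: ProteinStructure,
    path: str | Path,
    ligand_chain: str | None = None,
) -> None:
    """Write protein plus one ligand pose as a PDB file.

    The ligand is appended as a HETATM block on a chain id distinct from all
    protein chains.
    """
    if p.n_atoms == 0:
        raise StructureError("pose has no ligand atoms")
    used = {a.chain_id for a in protein.atoms}
    if ligand_chain is None:
        for cand in "LXYZ0123456789":
            if cand not in used:
                ligand_chain = cand
                break
        else:  # pragma: no cover
            raise StructureError("no free chain id for the ligand")
    elif ligand_chain in used:
        raise StructureError(f"ligand chain {ligand_chain!r} collides with protein")

    atoms = [a.copy() for a in protein.atoms]
    serial = max((a.serial for a in atoms), default=0)
    for template_atom, xyz in zip(p.conformer.atoms, p.coords):
        serial += 1
        atoms.append(
            Atom(
                serial=serial,
                name=template_atom.name,
                element=template_atom.element,
                residue_name=template_atom.residue_name,
                chain_id=ligand_chain,
                residue_seq=1,
                position=np.asarray(xyz, dtype=float),
                occupancy=1.0,
                is_hetero=True,
            )
        )
    combined = ProteinStructure(atoms, id=f"{protein.id}_{p.pose_id}")
    write_structure(combined, path)


def manifest_to_json(ps: PoseSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(ps.manifest, fh, indent=1)
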