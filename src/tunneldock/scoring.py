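"""Pose scoring: steric clashes and potential hydrogen bonds.

A clash is a (ligand heavy atom, protein heavy atom) pair strictly closer
than 3 A. A potential hydrogen bond is a ligand hydroxyl oxygen within the
closed window [2.0, 4.2] A of a protein donor or acceptor atom; the criterion
is purely distance-based (no angle term) and deliberately generous, since no
structural relaxation is permitted in rigid-body docking. Both thresholds are
configurable with these values as defaults.

Two implementations are provided and must agree exactly: an accelerated
neighbor-lookup path (:class:`ProteinScorer`, backed by a k-d tree) and an
exhaustive all-pairs oracle (``method="bruteforce"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .ensemble import Pose, PoseSet
from .structures import ProteinStructure, StructureError

__all__ = [
    "ScoreRecord",
    "ProteinScorer",
    "clash_score",
    "hbond_score",
    "score_ensemble",
    "pick_winner",
    "records_to_table",
    "DEFAULT_CLASH_THRESHOLD",
    "DEFAULT_HBOND_WINDOW",
]

DEFAULT_CLASH_THRESHOLD = 3.0
DEFAULT_HBOND_WINDOW = (2.0, 4.2)


@dataclass
class ScoreRecord:
    """Clash and hydrogen-bond scores for one pose."""

    pose_id: str
    clashes: int
    hbonds: int
    hbond_partners: list[tuple[str, str, float]] = field(default_factory=list)
    protein_label: str = ""
    template_index: int = -1
    conformer_index: int = -1
    orientation: str = ""

    def __post_init__(self) -> None:
        if self.clashes < 0 or self.hbonds < 0:
            raise ValueError("scores must be non-negative")


class ProteinScorer:
    """Precomputed scoring context for one protein conformer model.

    Builds k-d trees over the in-scope heavy atoms and the polar (donor or
    acceptor) subset. Waters and crystallization additives are excluded from
    the docking atom set by default; ``include_solvent=True`` re-includes
    them.
    """

    def __init__(
        self,
        protein: ProteinStructure,
        include_solvent: bool = False,
        clash_threshold: float = DEFAULT_CLASH_THRESHOLD,
        hbond_window: tuple[float, float] = DEFAULT_HBOND_WINDOW,
        clash_mode: str = "pair",
        label: str = "",
    ):
        if clash_mode not in ("pair", "atom"):
            raise ValueError("clash_mode must be 'pair' or 'atom'")
        if len(protein) == 0:
            raise StructureError("protein has no atoms")
        self.protein = protein
        self.clash_threshold = float(clash_threshold)
        self.hbond_window = (float(hbond_window[0]), float(hbond_window[1]))
        self.clash_mode = clash_mode
        self.label = label or protein.id

        idx = protein.atom_indices(exclude_solvent=not include_solvent)
        if len(idx) == 0:
            raise StructureError("no protein heavy atoms in scoring scope")
        coords = protein.coords
        self.heavy_indices = idx
        self.heavy_coords = coords[idx]
        polar = [
            i for i in idx if protein.atoms[i].polar_role in ("donor", "acceptor", "both")
        ]
        self.polar_indices = np.asarray(polar, dtype=int)
        self.polar_coords = coords[self.polar_indices] if polar else np.empty((0, 3))
        self._heavy_tree = cKDTree(self.heavy_coords)
        self._polar_tree = cKDTree(self.polar_coords) if polar else None
        self._polar_assigned = any(
            a.polar_role != "none" for a in protein.atoms
        )

    # -- clash ---------------------------------------------------------------

    def clash(self, ligand_coords: np.ndarray, method: str = "grid") -> int:
        """Count ligand/protein heavy-atom pairs strictly closer than threshold.

        ``clash_mode="atom"`` instead counts ligand atoms having at least one
        close protein contact.
        """
        ligand_coords = np.asarray(ligand_coords, dtype=float).reshape(-1, 3)
        thr = self.clash_threshold
        if method == "grid":
            neighbor_lists = self._heavy_tree.query_ball_point(ligand_coords, thr)
            per_atom = np.zeros(len(ligand_coords), dtype=int)
            for k, neighbors in enumerate(neighbor_lists):
                if not neighbors:
                    continue
                d = np.linalg.norm(
                    self.heavy_coords[neighbors] - ligand_coords[k], axis=1
                )
                per_atom[k] = int(np.sum(d < thr))  # strict inequality
        elif method == "bruteforce":
            d = cdist(ligand_coords, self.heavy_coords)
            per_atom = np.sum(d < thr, axis=1)
        else:
            raise ValueError(f"unknown method {method!r}")
        if self.clash_mode == "atom":
            return int(np.sum(per_atom > 0))
        return int(per_atom.sum())

    # -- hydrogen bonds ------------------------------------------------------

    def hbond(
        self,
        hydroxyl_coords: np.ndarray,
        hydroxyl_names: Sequence[str] | None = None,
        method: str = "grid",
    ) -> tuple[int, list[tuple[str, str, float]]]:
        """Count (hydroxyl O, polar protein atom) pairs inside the closed window."""
        if not self._polar_assigned:
            raise StructureError(
                "protein polar roles not assigned; run assign_polar_roles first"
            )
        hydroxyl_coords = np.asarray(hydroxyl_coords, dtype=float).reshape(-1, 3)
        if hydroxyl_names is None:
            hydroxyl_names = [f"O{k + 1}" for k in range(len(hydroxyl_coords))]
        lo, hi = self.hbond_window
        partners: list[tuple[str, str, float]] = []
        if len(self.polar_coords) == 0:
            return 0, partners
        if method == "grid":
            neighbor_lists = self._polar_tree.query_ball_point(hydroxyl_coords, hi)
        elif method == "bruteforce":
            d = cdist(hydroxyl_coords, self.polar_coords)
            neighbor_lists = [list(np.nonzero(row <= hi)[0]) for row in d]
        else:
            raise ValueError(f"unknown method {method!r}")
        for k, neighbors in enumerate(neighbor_lists):
            for j in neighbors:
                dist = float(
                    np.linalg.norm(self.polar_coords[j] - hydroxyl_coords[k])
                )
                if lo <= dist <= hi:  # closed window
                    atom = self.protein.atoms[int(self.polar_indices[j])]
                    partners.append(
                        (
                            str(hydroxyl_names[k]),
                            f"{atom.residue_name}{atom.residue_seq}:{atom.name}",
                            dist,
                        )
                    )
        partners.sort(key=lambda t: (t[0], t[2], t[1]))
        return len(partners), partners

    # -- whole poses ---------------------------------------------------------

    def score_pose(self, p: Pose, method: str = "grid") -> ScoreRecord:
        i, j = p.conformer.hydroxyl_indices
        names = [p.conformer.atoms[i].name, p.conformer.atoms[j].name]
        n_h, partners = self.hbond(p.coords[[i, j]], names, method=method)
        return ScoreRecord(
            pose_id=p.pose_id,
            clashes=self.clash(p.coords, method=method),
            hbonds=n_h,
            hbond_partners=partners,
            protein_label=self.label,
            template_index=p.template_index,
            conformer_index=p.conformer_index,
            orientation=p.orientation,
        )


def clash_score(
    p: Pose,
    protein: ProteinStructure,
    threshold: float = DEFAULT_CLASH_THRESHOLD,
    method: str = "grid",
    include_solvent: bool = False,
    clash_mode: str = "pair",
) -> int:
    scorer = ProteinScorer(
        protein,
        include_solvent=include_solvent,
        clash_threshold=threshold,
        clash_mode=clash_mode,
    )
    return scorer.clash(p.coords, method=method)


def hbond_score(
    p: Pose,
    protein: ProteinStructure,
    window: tuple[float, float] = DEFAULT_HBOND_WINDOW,
    method: str = "grid",
    include_solvent: bool = False,
) -> tuple[int, list[tuple[str, str, float]]]:
    scorer = ProteinScorer(protein, include_solvent=include_solvent, hbond_window=window)
    i, j = p.conformer.hydroxyl_indices
    names = [p.conformer.atoms[i].name, p.conformer.atoms[j].name]
    return scorer.hbond(p.coords[[i, j]], names, method=method)


def score_ensemble(
    ps: PoseSet,
    protein: ProteinStructure,
    method: str = "grid",
    scorer: ProteinScorer | None = None,
    **scorer_kwargs,
) -> list[ScoreRecord]:
    """One :class:`ScoreRecord` per pose, in pose order (deterministic)."""
    if scorer is None:
        scorer = ProteinScorer(protein, **scorer_kwargs)
    return [scorer.score_pose(p, method=method) for p in ps]


def pick_winner(
    records: Iterable[ScoreRecord],
    eligibility=None,
) -> ScoreRecord:
    """The record with fewest clashes; ties broken by more hydrogen bonds,
    then lexicographic pose id."""
    pool = [r for r in records if eligibility is None or eligibility(r)]
    if not pool:
        raise ValueError("no records remain after the eligibility filter")
    return min(pool, key=lambda r: (r.clashes, -r.hbonds, r.pose_id))


def records_to_table(records: Sequence[ScoreRecord]) -> pd.DataFrame:
    """Score table with one row per pose (TSV-friendly)."""
    return pd.DataFrame(
        {
            "pose_id": [r.pose_id for r in records],
            "template": [r.template_index for r in records],
            "conformer": [r.conformer_index for r in records],
            "orientation": [r.orientation for r in records],
            "clashes": [r.clashes for r in records],
            "hbonds": [r.hbonds for r in records],
        }
    )
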