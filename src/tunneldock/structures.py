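"""Macromolecular coordinate handling for tunnel-cavity docking.

This module reads and writes PDB/mmCIF coordinate files (via :mod:`gemmi`),
models crystallographic alternate conformations (altloc labels with fractional
occupancies), extracts rigid ligand conformers annotated with ring membership
and an end-to-end inversion map, and tags protein N/O atoms with hydrogen-bond
donor/acceptor roles.

All geometry downstream (clash counting, hydrogen-bond windows, superposition)
operates on heavy atoms only: crystal structures at typical resolution carry no
hydrogens, and the scoring criteria are defined on heavy-atom distances.
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Atom",
    "ProteinStructure",
    "ConformerModel",
    "LigandConformer",
    "StructureError",
    "StructureParseError",
    "read_structure",
    "write_structure",
    "select_model",
    "collapse_altlocs",
    "extract_ligand_conformers",
    "assign_polar_roles",
    "hydroxyl_span",
    "register_ligand_dictionary",
    "get_ligand_dictionary",
    "register_polar_extras",
    "SOLVENT_RESIDUES",
]

POLAR_ROLES = ("donor", "acceptor", "both", "none")

#: Residue names treated as solvent / crystallization additives. These are
#: excluded from the docking atom set by default: the ligand displaces the
#: solvent occupying the cavity.
SOLVENT_RESIDUES = frozenset({"HOH", "WAT", "DOD", "EDO", "SO4", "TLA"})

#: Alanine heavy-atom set kept by the truncate-to-alanine modification.
_ALANINE_ATOMS = frozenset({"N", "CA", "C", "O", "CB"})


class StructureError(ValueError):
    """Invalid structural data or selection."""


class StructureParseError(StructureError):
    """A coordinate file could not be parsed."""


@dataclass
class Atom:
    """One heavy atom of a macromolecular model.

    ``altloc`` is the alternate-location indicator (``''`` for a sole
    conformer); atoms sharing (chain, residue, name) but differing in altloc
    are mutually exclusive conformations whose occupancies sum to at most 1.
    """

    serial: int
    name: str
    element: str
    residue_name: str
    chain_id: str
    residue_seq: int
    position: np.ndarray
    altloc: str = ""
    icode: str = ""
    occupancy: float = 1.0
    polar_role: str = "none"
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise StructureError(f"atom {self.name}: position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise StructureError(f"atom {self.name}: non-finite coordinates")
        if not 0.0 <= self.occupancy <= 1.0:
            raise StructureError(
                f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]"
            )
        if self.polar_role not in POLAR_ROLES:
            raise StructureError(f"unknown polar role {self.polar_role!r}")

    @property
    def residue_key(self) -> tuple[str, int]:
        return (self.chain_id, self.residue_seq)

    def copy(self) -> "Atom":
        a = copy.copy(self)
        a.position = self.position.copy()
        return a


class ProteinStructure:
    """An ordered atom list with a (chain, residue) index.

    The residue index maps ``(chain_id, residue_seq)`` to the list of atom
    indices of that residue, covering every atom exactly once.
    """

    def __init__(self, atoms: Sequence[Atom], id: str = ""):
        self.atoms: list[Atom] = list(atoms)
        self.id = id
        self._build_index()
        self._check_occupancies()

    def _build_index(self) -> None:
        index: dict[tuple[str, int], list[int]] = {}
        for i, atom in enumerate(self.atoms):
            index.setdefault(atom.residue_key, []).append(i)
        self.residue_index = index

    def _check_occupancies(self) -> None:
        sums: dict[tuple, float] = {}
        for atom in self.atoms:
            if atom.altloc:
                key = (atom.chain_id, atom.residue_seq, atom.icode, atom.name)
                sums[key] = sums.get(key, 0.0) + atom.occupancy
        for key, total in sums.items():
            if total > 1.001:
                raise StructureError(
                    f"altloc occupancies for {key} sum to {total:.3f} > 1"
                )

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float).reshape(-1, 3)

    def residue(self, chain_id: str, residue_seq: int) -> list[Atom]:
        try:
            idx = self.residue_index[(chain_id, residue_seq)]
        except KeyError:
            raise StructureError(
                f"residue ({chain_id}, {residue_seq}) not in structure {self.id!r}"
            ) from None
        return [self.atoms[i] for i in idx]

    def residue_names(self) -> set[str]:
        return {a.residue_name for a in self.atoms}

    def atom_indices(
        self,
        *,
        exclude_solvent: bool = True,
        elements: Iterable[str] | None = None,
    ) -> np.ndarray:
        """Indices of atoms in docking scope (heavy atoms, solvent optional)."""
        elements = None if elements is None else {e.upper() for e in elements}
        keep = []
        for i, a in enumerate(self.atoms):
            if a.element.upper() == "H":
                continue
            if exclude_solvent and a.residue_name in SOLVENT_RESIDUES:
                continue
            if elements is not None and a.element.upper() not in elements:
                continue
            keep.append(i)
        return np.asarray(keep, dtype=int)

    def ca_atoms(self, altloc: str = "A") -> dict[tuple[str, int], Atom]:
        """One C-alpha per ordinary residue, preferring ``''`` then ``altloc``."""
        out: dict[tuple[str, int], Atom] = {}
        for a in self.atoms:
            if a.name != "CA" or a.element.upper() != "C":
                continue
            if a.altloc not in ("", altloc):
                continue
            key = a.residue_key
            if key in out and out[key].altloc == "":
                continue
            if key not in out or a.altloc == "":
                out[key] = a
        return out

    def copy(self, atoms: Sequence[Atom] | None = None) -> "ProteinStructure":
        if atoms is None:
            atoms = [a.copy() for a in self.atoms]
        return ProteinStructure(atoms, id=self.id)


@dataclass
class ConformerModel:
    """A choice of alternate conformations plus optional modifications.

    ``groups`` names residue selections (label -> list of (chain, residue_seq));
    ``choices`` picks one altloc character per group; ``modifications`` lists
    (operation, group-label) pairs with operation in ``{"delete_group",
    "truncate_to_alanine"}``.
    """

    structure_id: str = ""
    groups: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    choices: dict[str, str] = field(default_factory=dict)
    modifications: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for op, label in self.modifications:
            if op not in ("delete_group", "truncate_to_alanine"):
                raise StructureError(f"unknown modification {op!r}")
            if label not in self.groups:
                raise StructureError(f"modification names unknown group {label!r}")
        for label in self.choices:
            if label not in self.groups:
                raise StructureError(f"choice names unknown group {label!r}")


@dataclass
class LigandConformer:
    """A rigid ligand conformer with ring/hydroxyl annotations.

    ``inversion_map`` is an involutive permutation of atom indices that
    exchanges the two ends of the molecule (chemically analogous atoms paired,
    hydroxyl oxygen to hydroxyl oxygen), used to dock in the flipped
    orientation.
    """

    atoms: list[Atom]
    hydroxyl_indices: tuple[int, int]
    ring_labels: dict[str, list[int]]
    inversion_map: np.ndarray
    source: tuple[str, str, int] = ("", "", 0)
    species: str = ""

    def __post_init__(self) -> None:
        n = len(self.atoms)
        self.inversion_map = np.asarray(self.inversion_map, dtype=int)
        if self.inversion_map.shape != (n,):
            raise StructureError("inversion_map length must equal atom count")
        if not np.array_equal(self.inversion_map[self.inversion_map], np.arange(n)):
            raise StructureError("inversion_map must be an involution")
        if set(self.ring_labels) != {"beta", "epsilon"}:
            raise StructureError("ring_labels must label exactly beta and epsilon")
        near_beta = self.ring_labels_closure("beta")[-1]
        near_eps = self.ring_labels_closure("epsilon")[-1]
        if near_beta == near_eps:
            raise StructureError("each hydroxyl oxygen must belong to a distinct ring")

    def ring_labels_closure(self, ring: str) -> list[int]:
        """Ring atom indices plus the hydroxyl nearest that ring's centroid."""
        members = list(self.ring_labels[ring])
        coords = self.coords
        centroid = coords[self.ring_labels[ring]].mean(axis=0)
        nearest = min(
            self.hydroxyl_indices,
            key=lambda h: float(np.linalg.norm(coords[h] - centroid)),
        )
        members.append(nearest)
        return members

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def atom_names(self) -> list[str]:
        return [a.name for a in self.atoms]

    def ring_centroid(self, ring: str) -> np.ndarray:
        return self.coords[self.ring_labels[ring]].mean(axis=0)

    def with_coords(self, coords: np.ndarray) -> "LigandConformer":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise StructureError("coordinate array shape mismatch")
        atoms = [a.copy() for a in self.atoms]
        for a, xyz in zip(atoms, coords):
            a.position = xyz.copy()
        return LigandConformer(
            atoms=atoms,
            hydroxyl_indices=self.hydroxyl_indices,
            ring_labels={k: list(v) for k, v in self.ring_labels.items()},
            inversion_map=self.inversion_map.copy(),
            source=self.source,
            species=self.species,
        )


# ---------------------------------------------------------------------------
# Chemical dictionary (ring membership / hydroxyls / inversion) per species
# ---------------------------------------------------------------------------

def _load_builtin_dictionaries() -> dict:
    with resources.files("tunneldock.data").joinpath(
        "ligand_dictionaries.json"
    ).open() as fh:
        return json.load(fh)


_LIGAND_DICTIONARIES: dict[str, dict] = _load_builtin_dictionaries()


def register_ligand_dictionary(residue_name: str, entry: Mapping) -> None:
    """Register a chemical-dictionary entry for a (possibly synthetic) species.

    The entry schema matches ``data/ligand_dictionaries.json``: keys
    ``heavy_atoms`` (ordered names), ``hydroxyl_oxygens`` (ring -> name),
    ``rings`` (ring -> names) and ``inversion_pairs`` (list of name pairs).
    """
    required = {"heavy_atoms", "hydroxyl_oxygens", "rings", "inversion_pairs"}
    missing = required - set(entry)
    if missing:
        raise StructureError(f"dictionary entry missing keys: {sorted(missing)}")
    _LIGAND_DICTIONARIES[residue_name] = dict(entry)


def get_ligand_dictionary(residue_name: str) -> dict:
    try:
        return _LIGAND_DICTIONARIES[residue_name]
    except KeyError:
        raise StructureError(
            f"no chemical dictionary for residue {residue_name!r}; "
            f"known: {sorted(_LIGAND_DICTIONARIES)}"
        ) from None


# ---------------------------------------------------------------------------
# Reading / writing
# ---------------------------------------------------------------------------

def _prescan_pdb(path: Path) -> None:
    """Light well-formedness scan so parse errors can name a line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise StructureParseError(
                    f"{path}: line {lineno}: truncated coordinate record"
                )
            try:
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
            except ValueError:
                raise StructureParseError(
                    f"{path}: line {lineno}: unparseable coordinates"
                ) from None


def read_structure(path: str | Path, dialect: str = "pdb") -> ProteinStructure:
    """Read a coordinate file into a :class:`ProteinStructure`.

    Altloc labels, occupancies and insertion codes are preserved. ``dialect``
    is ``"pdb"`` or ``"mmcif"``.
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    if dialect not in ("pdb", "mmcif"):
        raise StructureError(f"unknown dialect {dialect!r}")
    if dialect == "pdb":
        _prescan_pdb(path)
        try:
            st = gemmi.read_pdb(str(path))
        except (RuntimeError, ValueError) as exc:
            raise StructureParseError(f"{path}: {exc}") from exc
    else:
        try:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        except (RuntimeError, ValueError) as exc:
            raise StructureParseError(f"{path}: {exc}") from exc

    atoms: list[Atom] = []
    if len(st) == 0:
        raise StructureParseError(f"{path}: no models")
    model = st[0]
    for chain in model:
        for residue in chain:
            het = residue.het_flag == "H"
            for at in residue:
                element = at.element.name.upper()
                if element in ("", "X"):
                    raise StructureParseError(
                        f"{path}: unknown element for atom {at.name!r} in "
                        f"{residue.name} {chain.name}{residue.seqid.num}"
                    )
                atoms.append(
                    Atom(
                        serial=at.serial,
                        name=at.name,
                        element=element,
                        residue_name=residue.name,
                        chain_id=chain.name,
                        residue_seq=residue.seqid.num,
                        icode=(residue.seqid.icode or "").strip(),
                        altloc=at.altloc if at.altloc != "\0" else "",
                        occupancy=float(at.occ),
                        position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        is_hetero=het,
                    )
                )
    return ProteinStructure(atoms, id=path.stem)


def write_structure(s: ProteinStructure, path: str | Path) -> None:
    """Write a structure as a PDB file (coordinates at format precision)."""
    import gemmi

    st = gemmi.Structure()
    st.name = s.id or "model"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for atom in s.atoms:
        chain = chains.get(atom.chain_id)
        if chain is None:
            chain = gemmi.Chain(atom.chain_id)
            chains[atom.chain_id] = chain
            model.add_chain(chain)
            chain = model[-1]
            chains[atom.chain_id] = chain
        res = None
        if len(chain) > 0:
            last = chain[-1]
            if last.seqid.num == atom.residue_seq and last.name == atom.residue_name:
                res = last
        if res is None:
            res = gemmi.Residue()
            res.name = atom.residue_name
            res.seqid = gemmi.SeqId(atom.residue_seq, atom.icode or " ")
            res.het_flag = "H" if atom.is_hetero else "A"
            chain.add_residue(res)
            res = chain[-1]
        at = gemmi.Atom()
        at.name = atom.name
        at.element = gemmi.Element(atom.element.capitalize())
        at.altloc = atom.altloc or "\0"
        at.occ = atom.occupancy
        at.pos = gemmi.Position(*atom.position)
        at.serial = atom.serial
        res.add_atom(at)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Alternate-conformation model selection
# ---------------------------------------------------------------------------

def _group_atom_indices(
    s: ProteinStructure, residues: Sequence[tuple[str, int]]
) -> list[int]:
    idx: list[int] = []
    for chain_id, seq in residues:
        if (chain_id, seq) not in s.residue_index:
            raise StructureError(
                f"group residue ({chain_id}, {seq}) absent from structure {s.id!r}"
            )
        idx.extend(s.residue_index[(chain_id, seq)])
    return idx


def select_model(s: ProteinStructure, m: ConformerModel) -> ProteinStructure:
    """Apply a :class:`ConformerModel`: pick altlocs, delete, or truncate.

    Exactly one altloc is retained per named group (the chosen conformer's
    atoms get altloc ``''`` and occupancy 1); deletions and alanine
    truncations are applied; atoms outside the named groups are untouched.
    """
    delete_groups = {label for op, label in m.modifications if op == "delete_group"}
    truncate_groups = {
        label for op, label in m.modifications if op == "truncate_to_alanine"
    }

    drop: set[int] = set()
    retag: set[int] = set()
    for label, residues in m.groups.items():
        indices = _group_atom_indices(s, residues)
        if not indices:
            raise StructureError(f"group {label!r} resolves to no atoms")
        if label in delete_groups:
            drop.update(indices)
            continue
        if label in truncate_groups:
            for i in indices:
                if s.atoms[i].name not in _ALANINE_ATOMS:
                    drop.add(i)
            indices = [i for i in indices if i not in drop]
        if label in m.choices:
            chosen = m.choices[label]
            available = sorted({s.atoms[i].altloc for i in indices if s.atoms[i].altloc})
            if available and chosen not in available:
                raise StructureError(
                    f"group {label!r}: altloc {chosen!r} absent "
                    f"(available: {available})"
                )
            for i in indices:
                alt = s.atoms[i].altloc
                if alt and alt != chosen:
                    drop.add(i)
                elif alt == chosen:
                    retag.add(i)

    atoms = []
    for i, a in enumerate(s.atoms):
        if i in drop:
            continue
        a = a.copy()
        if i in retag:
            a.altloc = ""
            a.occupancy = 1.0
        atoms.append(a)
    out = ProteinStructure(atoms, id=s.id)
    if truncate_groups:
        for label in truncate_groups:
            for chain_id, seq in m.groups[label]:
                names = {a.name for a in out.residue(chain_id, seq)}
                residue = out.residue(chain_id, seq)
                for a in residue:
                    a.residue_name = "ALA"
    return out


def collapse_altlocs(s: ProteinStructure, prefer: str = "occupancy") -> ProteinStructure:
    """Retain a single conformer for every alternate-conformation atom.

    ``prefer="occupancy"`` keeps the highest-occupancy altloc per atom site,
    breaking ties toward the altloc labelled 'A'; ``prefer`` may also be a
    single altloc character.
    """
    best: dict[tuple, tuple] = {}
    for i, a in enumerate(s.atoms):
        if not a.altloc:
            continue
        key = (a.chain_id, a.residue_seq, a.icode, a.name)
        if prefer == "occupancy":
            rank = (a.occupancy, -ord(a.altloc))
        else:
            rank = (1.0 if a.altloc == prefer else 0.0, -ord(a.altloc))
        if key not in best or rank > best[key][0]:
            best[key] = (rank, i)
    keep_alt = {i for _, i in best.values()}
    atoms = []
    for i, a in enumerate(s.atoms):
        if a.altloc and i not in keep_alt:
            continue
        a = a.copy()
        if a.altloc:
            a.altloc = ""
            a.occupancy = 1.0
        atoms.append(a)
    return ProteinStructure(atoms, id=s.id)


# ---------------------------------------------------------------------------
# Ligand conformer extraction
# ---------------------------------------------------------------------------

def _conformer_from_atoms(
    residue_atoms: list[Atom],
    entry: Mapping,
    source: tuple[str, str, int],
    residue_name: str,
) -> LigandConformer | None:
    """Build an annotated conformer; None if heavy atoms are missing."""
    by_name = {a.name: a for a in residue_atoms}
    order = list(entry["heavy_atoms"])
    if any(name not in by_name for name in order):
        return None
    atoms = [by_name[name].copy() for name in order]
    pos = {name: i for i, name in enumerate(order)}
    inversion = np.arange(len(order))
    for a_name, b_name in entry["inversion_pairs"]:
        inversion[pos[a_name]] = pos[b_name]
        inversion[pos[b_name]] = pos[a_name]
    hydroxyls = entry["hydroxyl_oxygens"]
    ring_of_hydroxyl = {v: k for k, v in hydroxyls.items()}
    h_beta = pos[hydroxyls["beta"]]
    h_eps = pos[hydroxyls["epsilon"]]
    rings = {
        "beta": [pos[n] for n in entry["rings"]["beta"]],
        "epsilon": [pos[n] for n in entry["rings"]["epsilon"]],
    }
    return LigandConformer(
        atoms=atoms,
        hydroxyl_indices=(h_beta, h_eps),
        ring_labels=rings,
        inversion_map=inversion,
        source=source,
        species=residue_name,
    )


def extract_ligand_conformers(
    paths: Sequence[str | Path],
    residue_name: str,
    dialect: str = "pdb",
) -> tuple[list[LigandConformer], int]:
    """Extract every instance of a ligand species from coordinate files.

    Returns ``(conformers, n_excluded)`` where conformers with missing heavy
    atoms (relative to the chemical dictionary) are excluded and counted.
    Raises if no instance of the species is found at all.
    """
    entry = get_ligand_dictionary(residue_name)
    conformers: list[LigandConformer] = []
    excluded = 0
    found_any = False
    for path in paths:
        s = read_structure(path, dialect=dialect)
        groups: dict[tuple[str, int], list[Atom]] = {}
        for a in s.atoms:
            if a.residue_name == residue_name:
                groups.setdefault(a.residue_key, []).append(a)
        for (chain_id, seq), residue_atoms in sorted(groups.items()):
            found_any = True
            conf = _conformer_from_atoms(
                residue_atoms, entry, (s.id, chain_id, seq), residue_name
            )
            if conf is None:
                excluded += 1
            else:
                conformers.append(conf)
    if not found_any:
        raise StructureError(
            f"no residue {residue_name!r} found in {len(paths)} file(s)"
        )
    return conformers, excluded


# ---------------------------------------------------------------------------
# Polar (donor/acceptor) role assignment
# ---------------------------------------------------------------------------

# Side-chain roles for the 20 standard amino acids (heavy atoms only).
_SIDECHAIN_ROLES: dict[str, dict[str, str]] = {
    "SER": {"OG": "both"},
    "THR": {"OG1": "both"},
    "TYR": {"OH": "both"},
    "ASP": {"OD1": "acceptor", "OD2": "acceptor"},
    "GLU": {"OE1": "acceptor", "OE2": "acceptor"},
    "ASN": {"OD1": "acceptor", "ND2": "donor"},
    "GLN": {"OE1": "acceptor", "NE2": "donor"},
    "LYS": {"NZ": "donor"},
    "ARG": {"NE": "donor", "NH1": "donor", "NH2": "donor"},
    "HIS": {"ND1": "both", "NE2": "both"},
    "TRP": {"NE1": "donor"},
}

_STANDARD_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

_WATER_RESIDUES = frozenset({"HOH", "WAT", "DOD"})

# Registry letting synthetic/non-standard residues declare polar roles.
_POLAR_EXTRAS: dict[str, dict[str, str]] = {}


def register_polar_extras(residue_name: str, roles: Mapping[str, str]) -> None:
    """Declare donor/acceptor roles for atoms of a non-standard residue."""
    for role in roles.values():
        if role not in POLAR_ROLES:
            raise StructureError(f"unknown polar role {role!r}")
    _POLAR_EXTRAS[residue_name] = dict(roles)


def assign_polar_roles(s: ProteinStructure) -> ProteinStructure:
    """Tag every N and O atom donor/acceptor/both per a fixed residue table.

    Backbone amide N is a donor (proline excepted), backbone carbonyl O (and
    OXT) an acceptor; side chains follow canonical chemistry; water oxygen is
    both. Atoms of unrecognized residues are tagged ``none`` with a warning
    (unless roles were registered via :func:`register_polar_extras`).
    """
    out = s.copy()
    warned: set[str] = set()
    for a in out.atoms:
        element = a.element.upper()
        a.polar_role = "none"
        if element not in ("N", "O"):
            continue
        res = a.residue_name
        if res in _WATER_RESIDUES:
            a.polar_role = "both"
        elif res in _STANDARD_RESIDUES:
            if a.name == "N":
                a.polar_role = "none" if res == "PRO" else "donor"
            elif a.name in ("O", "OXT"):
                a.polar_role = "acceptor"
            else:
                a.polar_role = _SIDECHAIN_ROLES.get(res, {}).get(a.name, "none")
        elif res in _POLAR_EXTRAS:
            a.polar_role = _POLAR_EXTRAS[res].get(a.name, "none")
        else:
            if res not in warned:
                warned.add(res)
                warnings.warn(
                    f"no polar-role entry for residue {res!r}; atoms tagged 'none'",
                    stacklevel=2,
                )
    return out


def hydroxyl_span(c: LigandConformer) -> float:
    """Euclidean distance (A) between the two terminal hydroxyl oxygens."""
    i, j = c.hydroxyl_indices
    return float(np.linalg.norm(c.atoms[i].position - c.atoms[j].position))
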