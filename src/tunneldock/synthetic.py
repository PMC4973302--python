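"""Synthetic tunnel proteins and rigid two-ring diol ligands.

Generators for fully parameterized test systems with known ground truth:

* a tunnel-shaped pseudo-protein whose interior is ~20 A long with two
  unequal portals, built from carbon wall atoms plus designated polar sites
  near the deep portal (an asymmetry "pocket" at the deep end admits only the
  small-ring ligand end, planting a known orientation preference);
* a library of rigid, curved, two-ring diol conformers ~30.5 A between the
  terminal hydroxyl oxygens, with a labelled large ("beta") and small
  ("epsilon") ring and a valid end-to-end inversion map;
* axis-aligned docked templates standing in for manually positioned ones.

All dimensions are interior (solvent-accessible) sizes: wall atoms are
offset outward by one carbon vdW radius plus a water probe (3.1 A), so the
generated cavity measures what the spec says.

Regeneration from the same spec and seed is bit-exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .classify import PortalDefinition
from .structures import (
    Atom,
    LigandConformer,
    ProteinStructure,
    StructureError,
    register_ligand_dictionary,
    register_polar_extras,
)

__all__ = [
    "TunnelSpec",
    "LigandSpec",
    "make_tunnel_protein",
    "make_ligand_library",
    "make_templates",
    "make_hollow_sphere",
    "make_hollow_tube",
]

#: carbon vdW radius (1.7) + water probe (1.4): wall offset so interior
#: dimensions are solvent-accessible dimensions.
WALL_OFFSET = 3.1

POLAR_RESIDUE = "PLR"
WALL_RESIDUE = "WAL"

register_polar_extras(POLAR_RESIDUE, {"O": "both"})


@dataclass(frozen=True)
class TunnelSpec:
    """Interior geometry of a synthetic tunnel protein.

    ``length`` is the end-to-end interior length (portal 1 gate at +length/2
    on the z axis, portal 2 gate at -length/2). ``pocket_radius`` narrows the
    deep ``pocket_length`` of the tunnel so that only the small ligand ring
    fits without steric clashes -- the planted ground-truth asymmetry;
    ``None`` disables the pocket. Portal radii are aperture radii
    (portal 1 >= portal 2).

    ``polar_sites="gates"`` places one polar oxygen on the axis
    ``polar_deep_offset`` beyond the deep gate (at the portal-2 mouth, where
    a deeply docked hydroxyl finds a partner) and one ``polar_far_offset``
    beyond portal 1 (where the hydroxyl of a ligand protruding through
    portal 1 ends up). Both sit 3.4-4.0 A from the docked hydroxyl
    positions: inside the hydrogen-bond window, outside clash range of
    either ring size.
    """

    length: float = 20.0
    radius: float = 3.5
    pocket_length: float = 5.0
    pocket_radius: float | None = 1.6
    portal1_radius: float = 2.5
    portal2_radius: float = 1.2
    wall_spacing: float = 1.4
    polar_sites: str = "gates"
    polar_deep_offset: float = 3.2
    polar_far_offset: float = 14.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length <= 0 or self.radius <= 0:
            raise StructureError("tunnel length and radius must be positive")
        if not self.portal1_radius >= self.portal2_radius > 0:
            raise StructureError("portal radii must satisfy r1 >= r2 > 0")
        if self.portal1_radius >= self.radius:
            raise StructureError("portal 1 aperture must be narrower than the bore")
        if self.pocket_radius is not None:
            if not 0 < self.pocket_radius < self.radius:
                raise StructureError("pocket radius must lie in (0, radius)")
            if not 0 < self.pocket_length < self.length:
                raise StructureError("pocket length must lie in (0, length)")
            if self.portal2_radius >= self.pocket_radius:
                raise StructureError("portal 2 aperture must fit inside the pocket")
        if self.polar_sites not in ("gates", "none"):
            raise StructureError(f"unknown polar_sites mode {self.polar_sites!r}")

    @classmethod
    def symmetric(cls, **overrides) -> "TunnelSpec":
        """An unpocketed tunnel with equal portals: the null condition."""
        defaults = dict(
            pocket_radius=None,
            portal1_radius=2.5,
            portal2_radius=2.5,
        )
        defaults.update(overrides)
        return cls(**defaults)

    @property
    def z_top(self) -> float:
        return self.length / 2.0

    @property
    def z_deep(self) -> float:
        return -self.length / 2.0

    def interior_radius(self, z: float) -> float:
        """Interior free radius at axial station z (clamped beyond the ends)."""
        z = min(max(z, self.z_deep), self.z_top)
        if self.pocket_radius is not None and z < self.z_deep + self.pocket_length:
            return self.pocket_radius
        return self.radius


@dataclass(frozen=True)
class LigandSpec:
    """A rigid, curved, two-ring diol conformer family.

    ``span`` is the hydroxyl O-O distance (the chord of the circular-arc
    backbone); ``sagitta`` the bow height of the arc. Rings of
    ``large_ring_radius`` ("beta") and ``small_ring_radius`` ("epsilon") sit
    near the two ends, each capped by a hydroxyl oxygen. Conformers are the
    canonical geometry plus isotropic Gaussian jitter of ``jitter`` A per
    atom.
    """

    span: float = 30.5
    sagitta: float = 1.5
    large_ring_radius: float = 2.0
    small_ring_radius: float = 1.0
    n_backbone: int = 18
    n_ring_atoms: int = 6
    n_conformers: int = 40
    jitter: float = 0.2
    residue_name: str = "SLG"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.span <= 0 or self.sagitta < 0:
            raise StructureError("span must be positive, sagitta non-negative")
        if not self.large_ring_radius > self.small_ring_radius > 0:
            raise StructureError("ring radii must satisfy large > small > 0")
        if self.n_backbone < 2 or self.n_ring_atoms < 3 or self.n_conformers < 1:
            raise StructureError("too few atoms or conformers")
        if self.jitter < 0:
            raise StructureError("jitter must be non-negative")
        if self.jitter >= 0.5 * (self.large_ring_radius - self.small_ring_radius):
            raise StructureError(
                "jitter too large: large/small ring labels become ambiguous"
            )

    @property
    def n_atoms(self) -> int:
        return 2 * self.n_ring_atoms + self.n_backbone + 2


# ---------------------------------------------------------------------------
# Tunnel protein
# ---------------------------------------------------------------------------

def _ring_of_points(radius: float, z: float, spacing: float, phase: float = 0.0):
    n = max(6, int(math.ceil(2 * math.pi * radius / spacing)))
    angles = phase + 2 * math.pi * np.arange(n) / n
    return np.stack(
        [radius * np.cos(angles), radius * np.sin(angles), np.full(n, z)], axis=1
    )


def _disk_of_points(r_inner: float, r_outer: float, z: float, spacing: float):
    points = []
    r = r_inner
    k = 0
    while r <= r_outer + 1e-9:
        points.append(_ring_of_points(max(r, spacing / 2), z, spacing, phase=0.35 * k))
        r += spacing
        k += 1
    return np.concatenate(points, axis=0) if points else np.empty((0, 3))


def _polar_circle(radius: float, z: float, n: int = 6, phase: float = 0.0):
    angles = phase + 2 * math.pi * np.arange(n) / n
    return np.stack(
        [radius * np.cos(angles), radius * np.sin(angles), np.full(n, z)], axis=1
    )


def make_tunnel_protein(
    spec: TunnelSpec,
) -> tuple[ProteinStructure, tuple[PortalDefinition, PortalDefinition], dict]:
    """Generate wall pseudo-atoms, portal definitions and ground truth.

    Wall atoms are carbons on a cylindrical lattice offset ``WALL_OFFSET``
    outside the interior radius profile; end caps leave portal apertures of
    the specified radii. Polar sites (oxygen, donor+acceptor) sit on the
    tunnel axis just past each gate so that deeply docked and protruding
    hydroxyls both find hydrogen-bond partners without steric contact.
    """
    off = WALL_OFFSET
    sp = spec.wall_spacing
    z_lo = spec.z_deep - off
    z_hi = spec.z_top + off

    walls = []
    n_stations = int(math.ceil((z_hi - z_lo) / sp)) + 1
    for i in range(n_stations):
        z = z_lo + i * (z_hi - z_lo) / (n_stations - 1)
        radius = spec.interior_radius(z) + off
        walls.append(_ring_of_points(radius, z, sp, phase=0.5 * i))
    # end caps with portal apertures
    walls.append(
        _disk_of_points(
            spec.portal1_radius + off, spec.interior_radius(spec.z_top) + off, z_hi, sp
        )
    )
    walls.append(
        _disk_of_points(
            spec.portal2_radius + off,
            spec.interior_radius(spec.z_deep) + off,
            z_lo,
            sp,
        )
    )
    wall_coords = np.concatenate(walls, axis=0)

    if spec.polar_sites == "gates":
        # one axial site past each gate, in H-bond reach of docked hydroxyls
        # but beyond clash range of both ring sizes
        polar_coords = np.array(
            [
                [0.0, 0.0, spec.z_deep - spec.polar_deep_offset],
                [0.0, 0.0, spec.z_top + spec.polar_far_offset],
            ]
        )
    else:
        polar_coords = np.empty((0, 3))

    atoms = []
    for i, xyz in enumerate(wall_coords):
        atoms.append(
            Atom(
                serial=i + 1,
                name="C",
                element="C",
                residue_name=WALL_RESIDUE,
                chain_id="W",
                residue_seq=i + 1,
                position=xyz,
            )
        )
    for j, xyz in enumerate(polar_coords):
        atoms.append(
            Atom(
                serial=len(wall_coords) + j + 1,
                name="O",
                element="O",
                residue_name=POLAR_RESIDUE,
                chain_id="P",
                residue_seq=j + 1,
                position=xyz,
                polar_role="both",
            )
        )
    protein = ProteinStructure(atoms, id="synthetic_tunnel")

    p1 = PortalDefinition(
        "portal1",
        point=np.array([0.0, 0.0, spec.z_top]),
        normal=np.array([0.0, 0.0, 1.0]),
        aperture=(2 * spec.portal1_radius, 2 * spec.portal1_radius),
    )
    p2 = PortalDefinition(
        "portal2",
        point=np.array([0.0, 0.0, spec.z_deep]),
        normal=np.array([0.0, 0.0, -1.0]),
        aperture=(2 * spec.portal2_radius, 2 * spec.portal2_radius),
    )

    metadata = {
        "spec": asdict(spec),
        "axis": [0.0, 0.0, 1.0],
        "portal1_point": [0.0, 0.0, spec.z_top],
        "portal2_point": [0.0, 0.0, spec.z_deep],
        "favored_orientation": "epsilon_in" if spec.pocket_radius is not None else None,
        "template_depth_range": [spec.z_deep - 0.6, spec.z_deep + 0.8],
        "n_wall_atoms": len(wall_coords),
        "n_polar_atoms": len(polar_coords),
    }
    return protein, (p1, p2), metadata


# ---------------------------------------------------------------------------
# Ligand library
# ---------------------------------------------------------------------------

def _arc_frame(spec: LigandSpec):
    """Circular arc through (0,0,0) and (0,0,span), bowing toward +x.

    Returns a function s -> (point, tangent) with s the arc length from the
    small-ring (epsilon) end at the origin, plus the total arc length.
    """
    c = spec.span
    h = spec.sagitta
    if h < 1e-9:
        total = c

        def at(s: float):
            return np.array([0.0, 0.0, s]), np.array([0.0, 0.0, 1.0])

        return at, total

    R = c * c / (8 * h) + h / 2
    theta0 = math.asin((c / 2) / R)
    center = np.array([h - R, 0.0, c / 2])
    total = 2 * R * theta0

    def at(s: float):
        # s=0 at z=0 end -> angle -theta0; s=total at z=c end -> +theta0
        theta = -theta0 + s / R
        point = center + R * np.array([math.cos(theta), 0.0, math.sin(theta)])
        tangent = np.array([-math.sin(theta), 0.0, math.cos(theta)])
        return point, tangent

    return at, total


def _canonical_coords(spec: LigandSpec) -> np.ndarray:
    """Atom coordinates in the canonical frame (epsilon end at the origin,
    long axis along +z), in dictionary atom order."""
    at, total = _arc_frame(spec)
    ring_inset = 1.5  # arc length from each hydroxyl to its ring center
    backbone_inset = 3.5

    def ring(center_s: float, radius: float, phase: float) -> np.ndarray:
        center, tangent = at(center_s)
        b = np.array([0.0, 1.0, 0.0])  # binormal of the planar arc
        u = np.cross(b, tangent)
        u /= np.linalg.norm(u)
        angles = phase + 2 * math.pi * np.arange(spec.n_ring_atoms) / spec.n_ring_atoms
        return center + radius * (
            np.outer(np.cos(angles), u) + np.outer(np.sin(angles), b)
        )

    coords = []
    # order: beta hydroxyl, beta ring, backbone (beta->epsilon), epsilon ring,
    # epsilon hydroxyl
    coords.append(at(total)[0][None, :])  # O1 (beta, large end)
    coords.append(ring(total - ring_inset, spec.large_ring_radius, 0.1))
    stations = np.linspace(total - backbone_inset, backbone_inset, spec.n_backbone)
    coords.append(np.stack([at(s)[0] for s in stations], axis=0))
    coords.append(ring(ring_inset, spec.small_ring_radius, 0.1))
    coords.append(at(0.0)[0][None, :])  # O2 (epsilon, small end)
    return np.concatenate(coords, axis=0)


def _ligand_dictionary_entry(spec: LigandSpec) -> dict:
    nr = spec.n_ring_atoms
    nb = spec.n_backbone
    beta_ring = [f"C{i + 1}" for i in range(nr)]
    backbone = [f"C{nr + i + 1}" for i in range(nb)]
    eps_ring = [f"C{nr + nb + i + 1}" for i in range(nr)]
    names = ["O1"] + beta_ring + backbone + eps_ring + ["O2"]
    pairs = [["O1", "O2"]]
    pairs += [[beta_ring[i], eps_ring[i]] for i in range(nr)]
    pairs += [[backbone[i], backbone[nb - 1 - i]] for i in range(nb // 2)]
    return {
        "residue_name": spec.residue_name,
        "description": "synthetic rigid two-ring diol (large beta / small epsilon)",
        "heavy_atoms": names,
        "hydroxyl_oxygens": {"beta": "O1", "epsilon": "O2"},
        "rings": {"beta": beta_ring, "epsilon": eps_ring},
        "inversion_pairs": pairs,
    }


def _conformer_from_coords(
    spec: LigandSpec, coords: np.ndarray, index: int
) -> LigandConformer:
    entry = _ligand_dictionary_entry(spec)
    names = entry["heavy_atoms"]
    pos = {n: i for i, n in enumerate(names)}
    inversion = np.arange(len(names))
    for a, b in entry["inversion_pairs"]:
        inversion[pos[a]], inversion[pos[b]] = pos[b], pos[a]
    atoms = [
        Atom(
            serial=i + 1,
            name=name,
            element="O" if name.startswith("O") else "C",
            residue_name=spec.residue_name,
            chain_id="L",
            residue_seq=1,
            position=coords[i],
            is_hetero=True,
        )
        for i, name in enumerate(names)
    ]
    return LigandConformer(
        atoms=atoms,
        hydroxyl_indices=(pos["O1"], pos["O2"]),
        ring_labels={
            "beta": [pos[n] for n in entry["rings"]["beta"]],
            "epsilon": [pos[n] for n in entry["rings"]["epsilon"]],
        },
        inversion_map=inversion,
        source=("synthetic", "L", index),
        species=spec.residue_name,
    )


def make_ligand_library(spec: LigandSpec) -> list[LigandConformer]:
    """Generate ``n_conformers`` jittered copies of the canonical diol.

    Registers the species' chemical-dictionary entry so generated PDB files
    round-trip through :func:`tunneldock.structures.extract_ligand_conformers`.
    """
    register_ligand_dictionary(spec.residue_name, _ligand_dictionary_entry(spec))
    canonical = _canonical_coords(spec)
    rng = np.random.default_rng(spec.seed)
    conformers = []
    for k in range(spec.n_conformers):
        noise = rng.normal(0.0, spec.jitter, canonical.shape) if spec.jitter else 0.0
        conformers.append(_conformer_from_coords(spec, canonical + noise, k))
    return conformers


# ---------------------------------------------------------------------------
# Templates
# ---------------------------------------------------------------------------

def make_templates(
    metadata: dict,
    n_depths: int = 4,
    n_rolls: int = 3,
    ligand_spec: LigandSpec | None = None,
) -> list[LigandConformer]:
    """Axis-aligned placements standing in for manually docked templates.

    The canonical (jitter-free) ligand is placed with its small (epsilon) end
    at evenly spaced depths near the deep gate and rotated about the tunnel
    axis by evenly spaced rolls. Deterministic: same inputs, same templates.
    """
    if n_depths < 1 or n_rolls < 1:
        raise StructureError("need at least one depth and one roll")
    if ligand_spec is None:
        ligand_spec = LigandSpec()
    base_spec = LigandSpec(
        **{
            **asdict(ligand_spec),
            "n_conformers": 1,
            "jitter": 0.0,
        }
    )
    canonical = _canonical_coords(base_spec)

    lo, hi = metadata["template_depth_range"]
    depths = np.linspace(lo, hi, n_depths) if n_depths > 1 else np.array([(lo + hi) / 2])
    rolls = 2 * math.pi * np.arange(n_rolls) / n_rolls

    templates = []
    idx = 0
    for depth in depths:
        for roll in rolls:
            c, s = math.cos(roll), math.sin(roll)
            Rz = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
            coords = canonical @ Rz.T + np.array([0.0, 0.0, depth])
            templates.append(_conformer_from_coords(base_spec, coords, idx))
            idx += 1
    return templates


# ---------------------------------------------------------------------------
# Analytic test bodies for cavity detection
# ---------------------------------------------------------------------------

def make_hollow_sphere(
    inner_radius: float = 6.2,
    atom_spacing: float = 1.0,
    offset: float = WALL_OFFSET,
) -> ProteinStructure:
    """A closed shell of carbons whose accessible interior is a ball of
    ``inner_radius`` (atom centers sit ``offset`` further out)."""
    shell_r = inner_radius + offset
    n = max(64, int(math.ceil(4 * math.pi * shell_r**2 / atom_spacing**2)))
    # Fibonacci sphere: near-uniform coverage
    k = np.arange(n)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * k
    cz = 1.0 - 2.0 * (k + 0.5) / n
    sz = np.sqrt(1.0 - cz**2)
    pts = shell_r * np.stack([sz * np.cos(phi), sz * np.sin(phi), cz], axis=1)
    atoms = [
        Atom(
            serial=i + 1,
            name="C",
            element="C",
            residue_name=WALL_RESIDUE,
            chain_id="W",
            residue_seq=i + 1,
            position=p,
        )
        for i, p in enumerate(pts)
    ]
    return ProteinStructure(atoms, id="hollow_sphere")


def make_hollow_tube(
    centerline: np.ndarray,
    inner_radius: float,
    atom_spacing: float = 1.0,
    offset: float = WALL_OFFSET,
    capped: bool = True,
) -> ProteinStructure:
    """A tube of carbons around a polyline centerline with closed ends.

    The accessible interior is a tube of ``inner_radius`` whose length equals
    the centerline length (end caps sit ``offset`` beyond the ends).
    """
    centerline = np.asarray(centerline, dtype=float).reshape(-1, 3)
    if len(centerline) < 2:
        raise StructureError("centerline needs at least two points")
    seg = np.diff(centerline, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = arc[-1]
    wall_r = inner_radius + offset

    def frame(s: float):
        s = min(max(s, 0.0), total)
        i = min(int(np.searchsorted(arc, s, side="right")) - 1, len(seg) - 1)
        t = seg[i] / seg_len[i]
        point = centerline[i] + (s - arc[i]) * t
        ref = np.array([0.0, 1.0, 0.0])
        if abs(np.dot(ref, t)) > 0.9:
            ref = np.array([1.0, 0.0, 0.0])
        u = np.cross(ref, t)
        u /= np.linalg.norm(u)
        v = np.cross(t, u)
        return point, t, u, v

    pts = []
    n_st = int(math.ceil((total + 2 * offset) / atom_spacing)) + 1
    for i in range(n_st):
        s = -offset + i * (total + 2 * offset) / (n_st - 1)
        point, t, u, v = frame(s)
        if s < 0:
            point = centerline[0] + s * (seg[0] / seg_len[0])
        elif s > total:
            point = centerline[-1] + (s - total) * (seg[-1] / seg_len[-1])
        n_ring = max(6, int(math.ceil(2 * math.pi * wall_r / atom_spacing)))
        ang = 0.5 * i + 2 * math.pi * np.arange(n_ring) / n_ring
        pts.append(point + wall_r * (np.outer(np.cos(ang), u) + np.outer(np.sin(ang), v)))
    if capped:
        for s_end, direction in ((0.0, -1.0), (total, 1.0)):
            point, t, u, v = frame(s_end)
            cap_center = point + direction * offset * t
            r = atom_spacing / 2
            while r <= wall_r + 1e-9:
                n_ring = max(4, int(math.ceil(2 * math.pi * r / atom_spacing)))
                ang = 2 * math.pi * np.arange(n_ring) / n_ring
                pts.append(
                    cap_center + r * (np.outer(np.cos(ang), u) + np.outer(np.sin(ang), v))
                )
                r += atom_spacing
    coords = np.concatenate(pts, axis=0)
    atoms = [
        Atom(
            serial=i + 1,
            name="C",
            element="C",
            residue_name=WALL_RESIDUE,
            chain_id="W",
            residue_seq=i + 1,
            position=p,
        )
        for i, p in enumerate(coords)
    ]
    return ProteinStructure(atoms, id="hollow_tube")
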