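"""Grid-based cavity detection and tunnel geometry.

A regular voxel grid is laid over the structure. Voxels within
``vdW radius + probe`` of any heavy atom are *protein*; solvent reachable
from the grid boundary by a larger probe (``bulk_probe``) is *bulk*; what
remains is *cavity*. The two-probe scheme means openings narrower than the
bulk probe are treated as sealed, so tunnel interiors connected to the
outside only through small portals are still reported as cavities.

Tunnel length is the graph geodesic through cavity voxels between the two
portal-adjacent patches (or, by default, between the extreme voxels along
the cavity's principal axis).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

from .structures import Atom, ProteinStructure, SOLVENT_RESIDUES, StructureError

__all__ = [
    "CavityGrid",
    "detect_cavity",
    "tunnel_length",
    "count_enclosed_solvent",
    "cavity_report",
    "export_cavity_pdb",
    "vdw_radius",
]

LABEL_BULK = 0
LABEL_PROTEIN = 1
LABEL_CAVITY = 2


def _load_vdw() -> dict[str, float]:
    with resources.files("tunneldock.data").joinpath("vdw_radii.json").open() as fh:
        return {k.upper(): float(v) for k, v in json.load(fh).items()}


_VDW = _load_vdw()


def vdw_radius(element: str) -> float:
    """Van der Waals radius (A) from the shipped element table."""
    return _VDW.get(element.upper(), _VDW["DEFAULT"])


@dataclass
class CavityGrid:
    """Voxelized occupancy labels plus cavity component map."""

    origin: np.ndarray
    spacing: float
    probe: float
    bulk_probe: float
    labels: np.ndarray  # uint8: 0 bulk, 1 protein, 2 cavity
    components: np.ndarray  # int32: 0 = not cavity, 1..k components by size

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def n_cavity_voxels(self, component: int | None = 1) -> int:
        if component is None:
            return int(np.sum(self.labels == LABEL_CAVITY))
        return int(np.sum(self.components == component))

    def cavity_volume(self, component: int | None = 1) -> float:
        """Volume (A^3) of a cavity component (default: largest)."""
        return self.n_cavity_voxels(component) * self.spacing**3

    def voxel_centers(self, mask: np.ndarray) -> np.ndarray:
        idx = np.argwhere(mask)
        return self.origin + (idx + 0.5) * self.spacing

    def point_to_index(self, point: np.ndarray) -> tuple[int, int, int] | None:
        idx = np.floor((np.asarray(point) - self.origin) / self.spacing).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.array(self.labels.shape)):
            return None
        return tuple(idx)

    def label_at(self, point: np.ndarray) -> int | None:
        idx = self.point_to_index(point)
        return None if idx is None else int(self.labels[idx])


def detect_cavity(
    protein: ProteinStructure,
    spacing: float = 0.5,
    probe: float = 1.4,
    bulk_probe: float = 4.5,
    include_solvent: bool = False,
) -> CavityGrid:
    """Label a voxel grid over the structure as protein / bulk / cavity.

    ``probe`` (default 1.4 A, water) inflates the protein surface;
    ``bulk_probe`` sets the minimum opening through which outside solvent can
    flood in. Finding no interior component is not an error: the grid simply
    has zero cavity voxels.
    """
    if not 0.2 < spacing <= 1.5:
        raise ValueError("spacing must lie in (0.2, 1.5] A")
    if len(protein) == 0:
        raise StructureError("empty structure")

    idx = protein.atom_indices(exclude_solvent=not include_solvent)
    coords = protein.coords[idx]
    elements = [protein.atoms[i].element for i in idx]
    radii = np.array([vdw_radius(e) for e in elements])

    pad = bulk_probe + radii.max() + 2 * spacing
    lo = coords.min(axis=0) - pad
    hi = coords.max(axis=0) + pad
    shape = np.ceil((hi - lo) / spacing).astype(int)
    origin = lo

    axes = [origin[d] + (np.arange(shape[d]) + 0.5) * spacing for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    centers = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)

    # protein mask: within vdW+probe of any atom, per-element radii
    protein_mask = np.zeros(len(centers), dtype=bool)
    for r in np.unique(radii):
        tree = cKDTree(coords[radii == r])
        d, _ = tree.query(centers, k=1, distance_upper_bound=r + probe + 1e-9)
        protein_mask |= np.isfinite(d)
    protein_mask = protein_mask.reshape(shape)
    free = ~protein_mask

    # clearance of each free voxel from the inflated protein surface
    edt_free = ndimage.distance_transform_edt(free, sampling=spacing)
    extra = bulk_probe - probe
    core = edt_free >= extra

    # exterior solvent core: core components reaching the grid boundary
    structure = np.ones((3, 3, 3), dtype=bool)
    core_labels, n_core = ndimage.label(core, structure=structure)
    boundary_labels = set()
    for axis in range(3):
        for face in (0, -1):
            sl = [slice(None)] * 3
            sl[axis] = face
            boundary_labels.update(np.unique(core_labels[tuple(sl)]))
    boundary_labels.discard(0)
    ext_core = np.isin(core_labels, sorted(boundary_labels))

    # bulk = exterior core plus free voxels within reach of it
    if ext_core.any():
        d_ext = ndimage.distance_transform_edt(~ext_core, sampling=spacing)
        bulk = free & (d_ext <= extra + 1e-9)
    else:  # fully enclosed grid (shouldn't happen with padding)
        bulk = np.zeros_like(free)

    cavity = free & ~bulk

    # a cavity must at least accommodate a probe sphere; smaller crumbs
    # (surface crevices just beyond the bulk-dilation reach) are bulk
    min_voxels = (4.0 / 3.0) * np.pi * probe**3 / spacing**3
    comp_labels, n_comp = ndimage.label(cavity, structure=structure)
    components = np.zeros(tuple(shape), dtype=np.int32)
    if n_comp:
        sizes = ndimage.sum_labels(cavity, comp_labels, index=np.arange(1, n_comp + 1))
        keep = [k + 1 for k in np.argsort(sizes)[::-1] if sizes[k] >= min_voxels]
        for rank, old in enumerate(keep, start=1):
            components[comp_labels == old] = rank
        cavity &= components > 0

    labels = np.zeros(tuple(shape), dtype=np.uint8)
    labels[protein_mask] = LABEL_PROTEIN
    labels[cavity] = LABEL_CAVITY

    return CavityGrid(
        origin=origin,
        spacing=spacing,
        probe=probe,
        bulk_probe=bulk_probe,
        labels=labels,
        components=components,
    )


_NEIGHBOR_OFFSETS = np.array(
    [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) > (0, 0, 0)
    ],
    dtype=int,
)  # 13 unique offsets; graph is undirected


def _cavity_geodesic(
    g: CavityGrid, source_idx: int, target_idx: int, voxels: np.ndarray
) -> float:
    """Shortest through-cavity path length (A).

    Dijkstra on the Euclidean-weighted 26-connected voxel graph, followed by
    taut-string straightening of the returned path (greedy line-of-sight
    shortcuts that stay inside the cavity) to remove the lattice-metric
    overestimate.
    """
    key = {tuple(v): i for i, v in enumerate(voxels)}
    rows, cols, weights = [], [], []
    for off in _NEIGHBOR_OFFSETS:
        w = float(np.linalg.norm(off)) * g.spacing
        shifted = voxels + off
        for i, sv in enumerate(map(tuple, shifted)):
            j = key.get(sv)
            if j is not None:
                rows.append(i)
                cols.append(j)
                weights.append(w)
    n = len(voxels)
    graph = coo_matrix((weights, (rows, cols)), shape=(n, n))
    dist, pred = dijkstra(
        graph, directed=False, indices=source_idx, return_predecessors=True
    )
    if not np.isfinite(dist[target_idx]):
        return float("inf")

    path = [target_idx]
    while path[-1] != source_idx:
        path.append(int(pred[path[-1]]))
    points = (voxels[path[::-1]] + 0.5) * g.spacing + g.origin

    voxel_set = set(map(tuple, voxels))

    def clear(a: np.ndarray, b: np.ndarray) -> bool:
        span = float(np.linalg.norm(b - a))
        n_samples = max(2, int(math.ceil(span / (g.spacing / 2))) + 1)
        for t in np.linspace(0.0, 1.0, n_samples):
            p = a + t * (b - a)
            v = tuple(np.floor((p - g.origin) / g.spacing).astype(int))
            if v in voxel_set:
                continue
            # tolerate boundary-hugging segments: accept 6-neighbors
            if any(
                (v[0] + dx, v[1] + dy, v[2] + dz) in voxel_set
                for dx, dy, dz in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                                   (0, -1, 0), (0, 0, 1), (0, 0, -1))
            ):
                continue
            return False
        return True

    total = 0.0
    i = 0
    last = len(points) - 1
    while i < last:
        j = last
        while j > i + 1 and not clear(points[i], points[j]):
            j -= 1
        total += float(np.linalg.norm(points[j] - points[i]))
        i = j
    return total


def tunnel_length(
    g: CavityGrid,
    portal_points: tuple[np.ndarray, np.ndarray] | None = None,
    component: int = 1,
) -> float:
    """Through-cavity geodesic (A) between the two portal-adjacent patches.

    With explicit ``portal_points`` (e.g. gate points), the endpoints are the
    cavity voxels nearest each point. Otherwise endpoints are the extreme
    voxels along the cavity's principal axis.
    """
    mask = g.components == component
    if not mask.any():
        raise StructureError("no cavity voxels in the requested component")
    voxels = np.argwhere(mask)
    centers = g.origin + (voxels + 0.5) * g.spacing

    if portal_points is not None:
        pa, pb = (np.asarray(p, dtype=float) for p in portal_points)
        source = int(np.argmin(np.linalg.norm(centers - pa, axis=1)))
        target = int(np.argmin(np.linalg.norm(centers - pb, axis=1)))
        if source == target:
            raise StructureError("portal patches coincide; need two distinct patches")
    else:
        centered = centers - centers.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        proj = centered @ vt[0]
        perp = np.linalg.norm(centered - np.outer(proj, vt[0]), axis=1)
        lo_band = proj <= proj.min() + g.spacing / 2
        hi_band = proj >= proj.max() - g.spacing / 2
        source = int(np.flatnonzero(lo_band)[np.argmin(perp[lo_band])])
        target = int(np.flatnonzero(hi_band)[np.argmin(perp[hi_band])])
        if source == target:
            raise StructureError("cavity too small to define two end patches")

    length = _cavity_geodesic(g, source, target, voxels)
    if not np.isfinite(length):
        raise StructureError("portal patches are not connected through the cavity")
    return length


def count_enclosed_solvent(g: CavityGrid, structure: ProteinStructure) -> int:
    """Number of solvent molecules whose representative atom sits in cavity
    voxels (any component). Waters use their O atom; multi-atom additives use
    their centroid."""
    count = 0
    for (chain_id, seq), indices in structure.residue_index.items():
        atoms = [structure.atoms[i] for i in indices]
        if atoms[0].residue_name not in SOLVENT_RESIDUES:
            continue
        oxygens = [a for a in atoms if a.element.upper() == "O" and a.name in ("O", "OW")]
        if len(atoms) == 1:
            point = atoms[0].position
        elif oxygens and atoms[0].residue_name in ("HOH", "WAT", "DOD"):
            point = oxygens[0].position
        else:
            point = np.mean([a.position for a in atoms], axis=0)
        if g.label_at(point) == LABEL_CAVITY:
            count += 1
    return count


def cavity_report(g: CavityGrid, max_components: int = 5) -> dict:
    """JSON-serializable volume summary."""
    n = int(g.components.max())
    return {
        "spacing": g.spacing,
        "probe": g.probe,
        "bulk_probe": g.bulk_probe,
        "n_components": n,
        "volumes": [g.cavity_volume(k) for k in range(1, min(n, max_components) + 1)],
        "largest_volume": g.cavity_volume(1) if n else 0.0,
    }


def export_cavity_pdb(g: CavityGrid, path: str | Path, component: int = 1) -> None:
    """Write cavity voxel centers as pseudo-atoms for visualization."""
    centers = g.voxel_centers(g.components == component)
    atoms = [
        Atom(
            serial=i + 1,
            name="DUM",
            element="C",
            residue_name="CAV",
            chain_id="V",
            residue_seq=i + 1,
            position=c,
            is_hetero=True,
        )
        for i, c in enumerate(centers)
    ]
    from .structures import write_structure

    write_structure(ProteinStructure(atoms, id="cavity"), path)
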