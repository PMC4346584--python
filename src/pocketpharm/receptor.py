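"""Transmembrane-only receptor models: template threading, rotamer ensembles
and geometric pocket detection.

The modelling contract mirrors classical TM-bundle homology modelling: the
template backbone is kept rigid, loops are never modelled, target side-chain
identities are threaded onto BW-numbered template positions, and side-chain
flexibility is represented by a small weighted rotamer ensemble rather than
by enumerating full side-chain combinatorics.

Pocket detection is alpha-shape-like: Delaunay tetrahedralization over heavy
atoms, removal of tetrahedra with any edge longer than ``edge_cutoff``
(8.0 A by default), and retention of "interstitial" tetrahedra whose
circumcenter keeps a probe radius clear of every atom's van der Waals
sphere.  The pocket is the largest connected interstitial component lined
by at least three distinct helices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay, QhullError, cKDTree

from .alignment import ResidueRef


class GeometryError(ValueError):
    """Degenerate geometry (coplanar points, too few atoms)."""


class ThreadingError(ValueError):
    """Template/target mismatch during homology threading."""


class RotamerLibraryError(KeyError):
    """Residue type missing from the rotamer library."""


# van der Waals radii (A) for the elements occurring in protein heavy atoms
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.10}
DEFAULT_VDW = 1.70


@dataclass
class Residue:
    res_id: int
    helix: int
    amino_acid: str
    bw_label: str | None
    backbone: dict[str, np.ndarray]
    axis_point: np.ndarray | None = None  # helix axis point nearest the CA
    axis_dir: np.ndarray | None = None

    @property
    def ca(self) -> np.ndarray:
        return self.backbone["CA"]

    def ref(self) -> ResidueRef:
        return ResidueRef(
            bw_label=self.bw_label or f"0.{self.res_id}",
            target_index=self.res_id,
            amino_acid=self.amino_acid,
        )


@dataclass
class TemplateStructure:
    """TM-helix residues with backbone coordinates; loops are absent."""

    residues: list[Residue]

    def __post_init__(self) -> None:
        for r in self.residues:
            for coord in r.backbone.values():
                if not np.all(np.isfinite(coord)):
                    raise GeometryError(f"non-finite coordinate at residue {r.res_id}")
        if any(r.axis_dir is None for r in self.residues):
            _fit_helix_axes(self.residues)

    def helices(self) -> dict[int, list[Residue]]:
        out: dict[int, list[Residue]] = {}
        for r in self.residues:
            out.setdefault(r.helix, []).append(r)
        return out

    def by_label(self) -> dict[str, Residue]:
        return {r.bw_label: r for r in self.residues if r.bw_label}

    def backbone_coords(self) -> np.ndarray:
        return np.array([c for r in self.residues for c in r.backbone.values()])


BackboneModel = TemplateStructure  # threading preserves the container shape


def _fit_helix_axes(residues: list[Residue]) -> None:
    """Per-helix principal-axis fit over CA positions; fills axis fields."""
    by_helix: dict[int, list[Residue]] = {}
    for r in residues:
        by_helix.setdefault(r.helix, []).append(r)
    for group in by_helix.values():
        cas = np.array([r.ca for r in group])
        center = cas.mean(axis=0)
        if len(group) < 2:
            axis = np.array([0.0, 0.0, 1.0])
        else:
            _, _, vt = np.linalg.svd(cas - center)
            axis = vt[0] / np.linalg.norm(vt[0])
        for r in group:
            t = float(np.dot(r.ca - center, axis))
            r.axis_point = center + t * axis
            r.axis_dir = axis.copy()


def residue_frame(residue: Residue) -> np.ndarray:
    """Local frame (columns x,y,z): x points outward from the helix axis,
    z along the axis.  Side-chain templates are expressed in this frame."""
    z = residue.axis_dir / np.linalg.norm(residue.axis_dir)
    out = residue.ca - residue.axis_point
    out = out - np.dot(out, z) * z
    norm = np.linalg.norm(out)
    if norm < 1e-9:  # CA on the axis: pick any perpendicular
        out = np.cross(z, [1.0, 0.0, 0.0])
        if np.linalg.norm(out) < 1e-9:
            out = np.cross(z, [0.0, 1.0, 0.0])
        norm = np.linalg.norm(out)
    x = out / norm
    y = np.cross(z, x)
    return np.column_stack([x, y, z])


# --------------------------------------------------------------------------
# Threading
# --------------------------------------------------------------------------

def thread_target(
    template: TemplateStructure,
    bw_map: dict[str, ResidueRef],
    length_tolerance: int = 5,
) -> tuple[BackboneModel, list[str]]:
    """Replace template residue identities with target residues by BW label.

    Backbone coordinates are carried over bit-exactly.  Returns the model
    and the list of template labels with no target residue (reported, not
    fatal).  A helix whose unmatched count exceeds ``length_tolerance``
    raises :class:`ThreadingError`.
    """
    unmatched: list[str] = []
    new_residues: list[Residue] = []
    per_helix_unmatched: dict[int, int] = {}
    for r in template.residues:
        if r.bw_label is None:
            raise ThreadingError(f"template residue {r.res_id} lacks a BW label")
        target = bw_map.get(r.bw_label)
        if target is None:
            unmatched.append(r.bw_label)
            per_helix_unmatched[r.helix] = per_helix_unmatched.get(r.helix, 0) + 1
            aa = r.amino_acid
        else:
            aa = target.amino_acid
        new_residues.append(
            Residue(
                res_id=r.res_id,
                helix=r.helix,
                amino_acid=aa,
                bw_label=r.bw_label,
                backbone={k: v.copy() for k, v in r.backbone.items()},
                axis_point=None if r.axis_point is None else r.axis_point.copy(),
                axis_dir=None if r.axis_dir is None else r.axis_dir.copy(),
            )
        )
    for helix, count in per_helix_unmatched.items():
        if count > length_tolerance:
            raise ThreadingError(
                f"helix {helix}: {count} template positions have no target "
                f"residue (tolerance {length_tolerance})"
            )
    return TemplateStructure(residues=new_residues), unmatched


# --------------------------------------------------------------------------
# Rotamer library
# --------------------------------------------------------------------------

def _chain(*names: str) -> list[tuple[str, str, np.ndarray]]:
    """Linear side chain along +x with a slight zig-zag, 1.5 A spacing."""
    atoms = []
    for i, name in enumerate(names):
        element = name[0] if name[0] in ("C", "N", "O", "S") else "C"
        pos = np.array([1.53 + 1.35 * i, 0.45 * (-1) ** i, 0.0])
        atoms.append((name, element, pos))
    return atoms


def _branch(base: list, *tips: str, spread: float = 1.1) -> list:
    """Two terminal atoms fanning out from the chain tip."""
    atoms = list(base)
    tip_x = atoms[-1][2][0] if atoms else 1.53
    for i, name in enumerate(tips):
        element = name[0]
        y = spread * (1 if i % 2 == 0 else -1)
        atoms.append((name, element, np.array([tip_x + 0.95, y, 0.0])))
    return atoms


def _ring(*, offset: float = 2.4, radius: float = 1.39, prefix: str = "C") -> list:
    """Planar six-ring in the xz-plane, centered ``offset`` A out along x."""
    atoms = []
    for i in range(6):
        ang = math.pi * i / 3.0
        pos = np.array(
            [offset + radius * math.cos(ang), 0.0, radius * math.sin(ang)]
        )
        atoms.append((f"{prefix}R{i+1}", "C", pos))
    return atoms


# Coarse backbone-independent side-chain templates in the local residue
# frame.  ``polar_tips`` name the heavy atoms used as hydrogen-bond anchors.
SIDECHAIN_TEMPLATES: dict[str, dict] = {
    "G": {"atoms": [], "polar_tips": []},
    "A": {"atoms": _chain("CB"), "polar_tips": []},
    "V": {"atoms": _branch(_chain("CB"), "CG1", "CG2"), "polar_tips": []},
    "L": {"atoms": _branch(_chain("CB", "CG"), "CD1", "CD2"), "polar_tips": []},
    "I": {"atoms": _branch(_chain("CB", "CG1"), "CG2", "CD1"), "polar_tips": []},
    "M": {"atoms": _chain("CB", "CG", "SD", "CE"), "polar_tips": []},
    "P": {"atoms": _chain("CB", "CG", "CD"), "polar_tips": []},
    "C": {"atoms": _chain("CB", "SG"), "polar_tips": []},
    "F": {"atoms": _chain("CB") + _ring(), "polar_tips": []},
    "W": {"atoms": _chain("CB", "CG") + _ring(offset=3.6), "polar_tips": []},
    "Y": {
        "atoms": _chain("CB") + _ring() + [("OH", "O", np.array([5.2, 0.0, 0.0]))],
        "polar_tips": ["OH"],
    },
    "S": {"atoms": _chain("CB", "OG"), "polar_tips": ["OG"]},
    "T": {"atoms": _branch(_chain("CB"), "OG1", "CG2"), "polar_tips": ["OG1"]},
    "N": {"atoms": _branch(_chain("CB", "CG"), "OD1", "ND2"), "polar_tips": ["OD1", "ND2"]},
    "Q": {"atoms": _branch(_chain("CB", "CG", "CD"), "OE1", "NE2"), "polar_tips": ["OE1", "NE2"]},
    "D": {"atoms": _branch(_chain("CB", "CG"), "OD1", "OD2"), "polar_tips": ["OD1", "OD2"]},
    "E": {"atoms": _branch(_chain("CB", "CG", "CD"), "OE1", "OE2"), "polar_tips": ["OE1", "OE2"]},
    "H": {"atoms": _branch(_chain("CB", "CG"), "ND1", "NE2"), "polar_tips": ["ND1", "NE2"]},
    "K": {"atoms": _chain("CB", "CG", "CD", "CE", "NZ"), "polar_tips": ["NZ"]},
    "R": {"atoms": _branch(_chain("CB", "CG", "CD", "NE"), "NH1", "NH2"), "polar_tips": ["NH1", "NH2"]},
    "X": {"atoms": _chain("CB"), "polar_tips": []},
}

# Azimuthal rotamer states (rotation about the local helix axis, degrees)
# with occurrence weights; single-state residues get one rotamer.
DEFAULT_ROTAMER_STATES: dict[str, list[tuple[float, float]]] = {}
for _aa in SIDECHAIN_TEMPLATES:
    if _aa in ("G", "A"):
        DEFAULT_ROTAMER_STATES[_aa] = [(1.0, 0.0)]
    elif _aa in ("S", "T", "C", "V"):
        DEFAULT_ROTAMER_STATES[_aa] = [(0.5, 0.0), (0.3, 40.0), (0.2, -40.0)]
    else:
        DEFAULT_ROTAMER_STATES[_aa] = [(0.45, 0.0), (0.25, 35.0), (0.2, -35.0), (0.1, 70.0)]


@dataclass
class Rotamer:
    weight: float
    atoms: list[tuple[str, str, np.ndarray]]  # (name, element, world coords)

    def coords(self) -> np.ndarray:
        if not self.atoms:
            return np.empty((0, 3))
        return np.array([a[2] for a in self.atoms])


@dataclass
class RotamerEnsemble:
    """Weighted side-chain states per residue; weights sum to 1."""

    states: dict[int, list[Rotamer]]  # res_id -> rotamers

    def best(self, res_id: int) -> Rotamer:
        return max(self.states[res_id], key=lambda r: r.weight)


def _rot_z(angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def attach_rotamers(
    model: BackboneModel,
    library: dict[str, list[tuple[float, float]]] | None = None,
) -> RotamerEnsemble:
    """Attach weighted side-chain rotamers to every modelled residue.

    ``library`` maps residue type to ``(weight, azimuth_deg)`` states;
    weights are renormalized to sum to 1.  Glycine keeps a single empty
    state so every residue has >= 1 rotamer.
    """
    library = library if library is not None else DEFAULT_ROTAMER_STATES
    states: dict[int, list[Rotamer]] = {}
    for res in model.residues:
        aa = res.amino_acid
        if aa not in library or aa not in SIDECHAIN_TEMPLATES:
            raise RotamerLibraryError(
                f"residue type {aa!r} (residue {res.res_id}) missing from rotamer library"
            )
        template = SIDECHAIN_TEMPLATES[aa]["atoms"]
        frame = residue_frame(res)
        raw = library[aa]
        total = sum(w for w, _ in raw)
        if total <= 0:
            raise RotamerLibraryError(f"non-positive rotamer weights for {aa!r}")
        rotamers = []
        for weight, angle in raw:
            rz = _rot_z(angle)
            atoms = [
                (name, element, res.ca + frame @ (rz @ local))
                for name, element, local in template
            ]
            rotamers.append(Rotamer(weight=weight / total, atoms=atoms))
        states[res.res_id] = rotamers
    return RotamerEnsemble(states=states)


def model_heavy_atoms(
    model: BackboneModel,
    ensemble: RotamerEnsemble | None = None,
    all_rotamers: bool = False,
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Heavy-atom coordinates fed to pocket detection.

    Backbone atoms plus, when an ensemble is given, side-chain atoms of the
    highest-weight rotamer (or of every rotamer with ``all_rotamers``).
    Returns (coords, elements, per-atom helix ids).
    """
    coords, elements, helices = [], [], []
    for res in model.residues:
        for name, c in res.backbone.items():
            coords.append(c)
            elements.append(name[0] if name[0] in VDW_RADII else "C")
            helices.append(res.helix)
        if ensemble is not None:
            rots = (
                ensemble.states[res.res_id]
                if all_rotamers
                else [ensemble.best(res.res_id)]
            )
            for rot in rots:
                for name, element, c in rot.atoms:
                    coords.append(c)
                    elements.append(element)
                    helices.append(res.helix)
    return np.array(coords), elements, np.array(helices)


# --------------------------------------------------------------------------
# Pocket detection
# --------------------------------------------------------------------------

@dataclass
class PocketVolume:
    delaunay: Delaunay
    retained: np.ndarray       # simplex indices passing the edge filter
    interstitial: np.ndarray   # retained and probe-accessible
    pocket_simplices: np.ndarray  # the selected connected component
    cloud: np.ndarray          # interstitial sample points (tetra centroids)

    @property
    def tetrahedra(self) -> np.ndarray:
        """(n, 4, 3) vertex coordinates of the pocket tetrahedra."""
        pts = self.delaunay.points
        return pts[self.delaunay.simplices[self.pocket_simplices]]

    def volume(self) -> float:
        total = 0.0
        for tet in self.tetrahedra:
            total += abs(np.linalg.det(tet[1:] - tet[0])) / 6.0
        return total

    def contains(self, points: np.ndarray) -> np.ndarray:
        """True where a query point lies inside a pocket tetrahedron."""
        points = np.atleast_2d(points)
        simplex = self.delaunay.find_simplex(points)
        pocket = set(int(i) for i in self.pocket_simplices)
        return np.array([int(s) in pocket for s in simplex])


def _simplex_edge_ok(pts: np.ndarray, simplices: np.ndarray, cutoff: float) -> np.ndarray:
    """Boolean mask: all 6 edges of each tetrahedron are <= cutoff."""
    v = pts[simplices]  # (n, 4, 3)
    ok = np.ones(len(simplices), dtype=bool)
    for i in range(4):
        for j in range(i + 1, 4):
            d = np.linalg.norm(v[:, i] - v[:, j], axis=1)
            ok &= d <= cutoff
    return ok


def prune_tetrahedra(points: np.ndarray, edge_cutoff: float = 8.0):
    """Delaunay tetrahedralization with long-edged tetrahedra removed.

    Returns the triangulation and the indices of retained simplices.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 4:
        raise GeometryError("need at least 4 points for tetrahedralization")
    try:
        tri = Delaunay(points)
    except QhullError as e:
        raise GeometryError(f"degenerate point set: {e}") from None
    mask = _simplex_edge_ok(points, tri.simplices, edge_cutoff)
    return tri, np.flatnonzero(mask)


def _circumcenters(pts: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    v = pts[simplices]  # (n, 4, 3)
    a = v[:, 0]
    rhs = np.einsum("nij,nij->ni", v[:, 1:], v[:, 1:]) - np.einsum(
        "ni,ni->n", a, a
    )[:, None]
    mat = 2.0 * (v[:, 1:] - a[:, None, :])
    centers = np.empty((len(simplices), 3))
    for i in range(len(simplices)):
        try:
            centers[i] = np.linalg.solve(mat[i], rhs[i])
        except np.linalg.LinAlgError:
            centers[i] = v[i].mean(axis=0)
    return centers


def detect_pocket(
    atom_coordinates: np.ndarray,
    edge_cutoff: float = 8.0,
    *,
    elements: list[str] | None = None,
    atom_helices: np.ndarray | None = None,
    probe_radius: float = 1.4,
    min_helices: int = 3,
) -> PocketVolume:
    """Detect the binding cavity of an atom cloud.

    Tetrahedra with any edge > ``edge_cutoff`` are discarded; a retained
    tetrahedron is interstitial when its circumcenter clears every atom's
    van der Waals sphere by ``probe_radius``; the pocket is the largest
    connected interstitial component (largest by volume) whose vertex atoms
    span at least ``min_helices`` distinct helices (when helix ids are
    given).
    """
    atom_coordinates = np.asarray(atom_coordinates, dtype=float)
    if len(atom_coordinates) < 5:
        raise GeometryError("need at least 5 atoms for pocket detection")
    tri, retained = prune_tetrahedra(atom_coordinates, edge_cutoff)
    if elements is None:
        vdw = np.full(len(atom_coordinates), DEFAULT_VDW)
    else:
        vdw = np.array([VDW_RADII.get(e, DEFAULT_VDW) for e in elements])

    centers = _circumcenters(atom_coordinates, tri.simplices[retained])
    tree = cKDTree(atom_coordinates)
    # clearance check against the nearest candidates (max vdw bounds the search)
    k = min(len(atom_coordinates), 16)
    dist, idx = tree.query(centers, k=k)
    clearance = dist - vdw[idx]
    interstitial_mask = clearance.min(axis=1) >= probe_radius
    if atom_helices is not None:
        # a cavity tetrahedron sits between helices, not inside the wall of
        # one or in the thin slab between an adjacent pair: require vertices
        # from >= min_helices distinct helices
        vert_helices = atom_helices[tri.simplices[retained]]
        n_distinct = np.array(
            [len(set(row.tolist())) for row in vert_helices]
        )
        interstitial_mask &= n_distinct >= min_helices
    interstitial = retained[interstitial_mask]

    # connected components over shared facets
    inter_set = {int(s): i for i, s in enumerate(interstitial)}
    n = len(interstitial)
    seen = np.zeros(n, dtype=bool)
    components: list[list[int]] = []
    for start in range(n):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            cur = stack.pop()
            comp.append(cur)
            simplex = int(interstitial[cur])
            for nb in tri.neighbors[simplex]:
                j = inter_set.get(int(nb))
                if j is not None and not seen[j]:
                    seen[j] = True
                    stack.append(j)
        components.append(comp)

    def comp_volume(comp: list[int]) -> float:
        tets = atom_coordinates[tri.simplices[interstitial[comp]]]
        return sum(abs(np.linalg.det(t[1:] - t[0])) / 6.0 for t in tets)

    def comp_helices(comp: list[int]) -> int:
        if atom_helices is None:
            return min_helices  # no helix info: every component qualifies
        verts = np.unique(tri.simplices[interstitial[comp]])
        return len(set(atom_helices[verts].tolist()))

    eligible = [c for c in components if comp_helices(c) >= min_helices]
    if eligible:
        # the TM binding cavity threads between the helices: prefer the
        # component lined by the most distinct helices, then the largest
        best = max(eligible, key=lambda c: (comp_helices(c), comp_volume(c)))
        pocket_simplices = np.sort(interstitial[best])
    else:
        pocket_simplices = np.array([], dtype=int)

    if len(pocket_simplices):
        cloud = atom_coordinates[tri.simplices[pocket_simplices]].mean(axis=1)
    else:
        cloud = np.empty((0, 3))
    return PocketVolume(
        delaunay=tri,
        retained=np.sort(retained),
        interstitial=np.sort(interstitial),
        pocket_simplices=pocket_simplices,
        cloud=cloud,
    )


def lining_residues(
    pocket: PocketVolume,
    model: BackboneModel,
    ensemble: RotamerEnsemble,
    contact_distance: float = 4.5,
) -> set[ResidueRef]:
    """Residues with any rotamer (or backbone) atom within ``contact_distance``
    of a pocket sample point."""
    if len(pocket.cloud) == 0:
        raise GeometryError("empty pocket")
    if contact_distance <= 0:
        return set()
    tree = cKDTree(pocket.cloud)
    lining: set[ResidueRef] = set()
    for res in model.residues:
        coords = [c for c in res.backbone.values()]
        for rot in ensemble.states[res.res_id]:
            coords.extend(a[2] for a in rot.atoms)
        d, _ = tree.query(np.array(coords))
        if np.min(d) <= contact_distance:
            lining.add(res.ref())
    return lining


# --------------------------------------------------------------------------
# Structure IO: PDB via biotite, minimal TRIPOS MOL2
# --------------------------------------------------------------------------

_THREE_OF = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL", "X": "UNK",
}
_ONE_OF = {v: k for k, v in _THREE_OF.items()}


def write_pdb(model: BackboneModel, path, ensemble: RotamerEnsemble | None = None) -> None:
    """Export the TM-only model (best rotamer side chains) as PDB."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    rows = []
    for res in model.residues:
        for name, coord in res.backbone.items():
            rows.append((res, name, name[0], coord))
        if ensemble is not None:
            for name, element, coord in ensemble.best(res.res_id).atoms:
                rows.append((res, name, element, coord))
    arr = struc.AtomArray(len(rows))
    arr.coord = np.array([r[3] for r in rows])
    arr.res_id = np.array([r[0].res_id for r in rows])
    arr.res_name = np.array([_THREE_OF.get(r[0].amino_acid, "UNK") for r in rows])
    arr.atom_name = np.array([r[1] for r in rows])
    arr.element = np.array([r[2] for r in rows])
    arr.chain_id = np.array(["A"] * len(rows))
    arr.hetero = np.zeros(len(rows), dtype=bool)
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def write_mol2(model: BackboneModel, path, ensemble: RotamerEnsemble | None = None) -> None:
    """Minimal TRIPOS MOL2 export (ATOM records, 3-decimal coordinates)."""
    lines = ["@<TRIPOS>MOLECULE", "tm_model"]
    rows = []
    for res in model.residues:
        for name, coord in res.backbone.items():
            rows.append((res, name, name[0], coord))
        if ensemble is not None:
            for name, element, coord in ensemble.best(res.res_id).atoms:
                rows.append((res, name, element, coord))
    lines.append(f"{len(rows)} 0 {len(model.residues)} 0 0")
    lines.append("PROTEIN")
    lines.append("NO_CHARGES")
    lines.append("@<TRIPOS>ATOM")
    for i, (res, name, element, coord) in enumerate(rows, start=1):
        res_name = _THREE_OF.get(res.amino_acid, "UNK")
        lines.append(
            f"{i:>7d} {name:<6s} {coord[0]:>10.3f} {coord[1]:>10.3f} "
            f"{coord[2]:>10.3f} {element:<4s} {res.res_id:>4d} "
            f"{res_name}{res.res_id} 0.0000"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_mol2_atoms(path) -> tuple[np.ndarray, list[str], list[int], list[str]]:
    """Read ATOM records of a TRIPOS MOL2 file.

    Returns (coords, atom names, residue ids, residue names).  Tolerant of
    the column variations seen in protein MOL2 exports.
    """
    coords, names, res_ids, res_names = [], [], [], []
    in_atoms = False
    with open(path) as fh:
        for line in fh:
            stripped = line.strip()
            if stripped.startswith("@<TRIPOS>"):
                in_atoms = stripped == "@<TRIPOS>ATOM"
                continue
            if not in_atoms or not stripped:
                continue
            parts = stripped.split()
            if len(parts) < 6:
                continue
            names.append(parts[1])
            coords.append([float(parts[2]), float(parts[3]), float(parts[4])])
            res_ids.append(int(parts[6]) if len(parts) > 6 else 0)
            res_names.append(parts[7] if len(parts) > 7 else "UNK")
    return np.array(coords), names, res_ids, res_names


def read_pdb(path) -> TemplateStructure:
    """Read a PDB into a TM template (helix ids from contiguous chain runs).

    Residues are grouped into helices by gaps in residue numbering; files
    exported by :func:`write_pdb` round-trip.
    """
    from biotite.structure.io.pdb import PDBFile

    arr = PDBFile.read(str(path)).get_structure(model=1)
    residues: list[Residue] = []
    helix, prev_id = 1, None
    for res_id in sorted(set(arr.res_id.tolist())):
        mask = arr.res_id == res_id
        sub = arr[mask]
        backbone = {}
        for name in ("N", "CA", "C", "O"):
            sel = sub[sub.atom_name == name]
            if len(sel):
                backbone[name] = np.array(sel.coord[0], dtype=float)
        if "CA" not in backbone:
            continue
        if prev_id is not None and res_id > prev_id + 1:
            helix += 1
        prev_id = res_id
        residues.append(
            Residue(
                res_id=int(res_id),
                helix=helix,
                amino_acid=_ONE_OF.get(str(sub.res_name[0]), "X"),
                bw_label=None,
                backbone=backbone,
            )
        )
    return TemplateStructure(residues=residues)
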