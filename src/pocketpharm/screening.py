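"""Compound preparation, pharmacophore typing and combinatorial subset matching.

Compounds arrive as SMILES tables or SDF with binary activity labels;
unspecified tetrahedral centers are stereo-enumerated (racemates in the
source assays were mixtures, so every enantiomer is screened and a parent
compound counts as a hit when any stereoisomer's conformer matches).
Conformers come from RDKit's distance-geometry embedding with force-field
minimization, capped at the conformation limit (200).

A conformer matches a k-feature subset (k in {5, 6}) when some injective,
type-compatible assignment of its typed points to the features admits a
rigid superposition placing every point within its feature's radius.  The
superposition is radius-weighted Kabsch, refined by direct minimization of
the maximum normalized deviation when the least-squares pose is just
infeasible -- the min-max criterion makes matching monotone: a conformer
matching a 6-subset matches every contained 5-subset.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .pharmacophore import Feature, Pharmacophore

ACTIVITY_LABELS = {"active", "inactive", "blocker", "unknown"}

DEFAULT_CONFORMER_PARAMS = {
    "rejection_limit": 100,
    "iteration_limit": 1000,
    "rms_gradient": 0.005,
    "mm_iteration_limit": 200,
    "conformation_limit": 200,
}
DEDUP_RMSD = 0.25
ASSIGNMENT_LIMIT = 5000


@dataclass(frozen=True)
class TypedPoint:
    type: str  # donor | acceptor | hydrophobic
    position: np.ndarray
    source_atoms: tuple[int, ...] = ()


@dataclass
class Compound:
    """One screening entry: a parent compound or one of its enantiomers."""

    identifier: str
    parent_id: str
    activity: str = "unknown"
    smiles: str | None = None
    mol: object | None = None  # RDKit Mol (chemical mode)
    point_sets: list[list[TypedPoint]] = field(default_factory=list)  # geometric mode
    stereo: str = ""

    def __post_init__(self) -> None:
        if self.activity not in ACTIVITY_LABELS:
            raise ValueError(f"unknown activity label {self.activity!r}")


@dataclass
class MatchResult:
    matched: bool
    assignment: dict[int, int] | None  # feature index -> point index
    max_normalized_deviation: float
    rmsd: float


# --------------------------------------------------------------------------
# Loading and preparation (RDKit)
# --------------------------------------------------------------------------

def load_compounds(
    source: str,
    fmt: str = "auto",
    activity_column: str = "activity",
) -> tuple[list[Compound], list[str]]:
    """Load compounds from a SMILES TSV/CSV (id, smiles, activity columns)
    or an SDF file.  Unspecified tetrahedral centers are enumerated into
    stereoisomer entries sharing the parent id.  Unparsable records are
    collected into the returned error list, never aborting the load.
    """
    from rdkit import Chem

    if fmt == "auto":
        fmt = "sdf" if str(source).lower().endswith(".sdf") else "table"
    records: list[tuple[str, object, str]] = []
    errors: list[str] = []
    if fmt == "table":
        sep = "\t" if "\t" in open(source).readline() else ","
        df = pd.read_csv(source, sep=sep)
        cols = {c.lower(): c for c in df.columns}
        for i, row in df.iterrows():
            ident = str(row[cols.get("id", df.columns[0])])
            smiles = str(row[cols["smiles"]])
            activity = str(row[cols.get(activity_column, activity_column)]).lower() \
                if activity_column in cols else "unknown"
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:
                errors.append(f"{ident}: unparsable SMILES {smiles!r}")
                continue
            records.append((ident, mol, activity))
    else:
        supplier = Chem.SDMolSupplier(str(source))
        for i, mol in enumerate(supplier):
            if mol is None:
                errors.append(f"record {i}: unparsable SDF entry")
                continue
            ident = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{i}"
            activity = (
                mol.GetProp(activity_column).lower()
                if mol.HasProp(activity_column)
                else "unknown"
            )
            records.append((ident, mol, activity))

    compounds: list[Compound] = []
    for ident, mol, activity in records:
        compounds.extend(_expand_stereo(ident, mol, activity))
    return compounds, errors


def _expand_stereo(ident: str, mol, activity: str) -> list[Compound]:
    from rdkit import Chem
    from rdkit.Chem.EnumerateStereoisomers import (
        EnumerateStereoisomers,
        StereoEnumerationOptions,
    )

    opts = StereoEnumerationOptions(onlyUnassigned=True, unique=True, maxIsomers=8)
    isomers = list(EnumerateStereoisomers(mol, options=opts))
    out = []
    if len(isomers) <= 1:
        out.append(
            Compound(
                identifier=ident,
                parent_id=ident,
                activity=activity,
                smiles=Chem.MolToSmiles(mol),
                mol=mol,
            )
        )
    else:
        for iso in isomers:
            Chem.AssignStereochemistry(iso, cleanIt=True, force=True)
            centers = Chem.FindMolChiralCenters(iso, includeUnassigned=False)
            tag = "".join(code for _, code in centers) or "iso"
            out.append(
                Compound(
                    identifier=f"{ident}_{tag}",
                    parent_id=ident,
                    activity=activity,
                    smiles=Chem.MolToSmiles(iso),
                    mol=iso,
                    stereo=tag,
                )
            )
    return out


def generate_conformers(
    compound: Compound,
    params: dict | None = None,
    seed: int = 0,
):
    """Embed and minimize up to ``conformation_limit`` conformers.

    Deterministic for a fixed seed.  Returns the hydrogenated RDKit mol
    whose conformers survived RMSD deduplication, or raises on embedding
    failure.
    """
    from rdkit import Chem
    from rdkit.Chem import AllChem

    p = dict(DEFAULT_CONFORMER_PARAMS)
    if params:
        p.update(params)
    mol = Chem.AddHs(Chem.Mol(compound.mol))
    ps = AllChem.ETKDGv3()
    ps.randomSeed = int(seed) % (2**31 - 1)
    ps.pruneRmsThresh = DEDUP_RMSD
    ps.useRandomCoords = False
    n_rot = AllChem.CalcNumRotatableBonds(mol) if hasattr(AllChem, "CalcNumRotatableBonds") else 3
    n_confs = min(p["conformation_limit"], max(1, 10 * (n_rot + 1)))
    ids = AllChem.EmbedMultipleConfs(mol, numConfs=n_confs, params=ps)
    if len(ids) == 0:
        raise ValueError(f"{compound.identifier}: conformer embedding failed")
    AllChem.MMFFOptimizeMoleculeConfs(mol, maxIters=p["mm_iteration_limit"])
    return mol


def assign_types(
    mol,
    conf_id: int = 0,
    fluorine_acceptor: bool = True,
) -> list[TypedPoint]:
    """Pharmacophore-type the atoms of one conformer.

    Donors: N/O bearing a hydrogen.  Acceptors: RDKit's standard acceptor
    definition, optionally extended with organic fluorine as a weak
    acceptor.  Hydrophobic: one point per carbon-dominated ring centroid,
    one per fused ring-system centroid, and one per aliphatic carbon
    cluster.
    """
    conf = mol.GetConformer(conf_id)
    pos = lambda i: np.array(conf.GetAtomPosition(i))
    points: list[TypedPoint] = []

    factory = _feature_factory()
    for feat in factory.GetFeaturesForMol(mol):
        family = feat.GetFamily()
        if family == "Donor":
            for a in feat.GetAtomIds():
                points.append(TypedPoint("donor", pos(a), (a,)))
        elif family == "Acceptor":
            for a in feat.GetAtomIds():
                points.append(TypedPoint("acceptor", pos(a), (a,)))
    if fluorine_acceptor:
        for atom in mol.GetAtoms():
            if atom.GetSymbol() == "F":
                points.append(
                    TypedPoint("acceptor", pos(atom.GetIdx()), (atom.GetIdx(),))
                )

    # hydrophobic: ring centroids
    ring_info = mol.GetRingInfo()
    ring_atom_sets = []
    for ring in ring_info.AtomRings():
        carbons = sum(1 for a in ring if mol.GetAtomWithIdx(a).GetSymbol() == "C")
        if carbons >= 4:
            ring_atom_sets.append(tuple(sorted(ring)))
            centroid = np.mean([pos(a) for a in ring], axis=0)
            points.append(TypedPoint("hydrophobic", centroid, tuple(sorted(ring))))
    # fused ring-system centroids
    systems = _ring_systems(ring_atom_sets)
    for system in systems:
        if len(system) > 6:  # more than one ring's worth of atoms
            centroid = np.mean([pos(a) for a in system], axis=0)
            points.append(TypedPoint("hydrophobic", centroid, tuple(sorted(system))))
    # aliphatic carbon clusters (>= 2 connected non-ring sp3 carbons)
    aliphatic = {
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetSymbol() == "C"
        and not a.GetIsAromatic()
        and not a.IsInRing()
        and all(n.GetSymbol() in ("C", "H") for n in a.GetNeighbors())
    }
    for cluster in _connected_clusters(mol, aliphatic):
        if len(cluster) >= 2:
            centroid = np.mean([pos(a) for a in cluster], axis=0)
            points.append(TypedPoint("hydrophobic", centroid, tuple(sorted(cluster))))
    return points


_FACTORY = None


def _feature_factory():
    global _FACTORY
    if _FACTORY is None:
        import os
        from rdkit import RDConfig
        from rdkit.Chem import ChemicalFeatures

        _FACTORY = ChemicalFeatures.BuildFeatureFactory(
            os.path.join(RDConfig.RDDataDir, "BaseFeatures.fdef")
        )
    return _FACTORY


def _ring_systems(ring_atom_sets: list[tuple[int, ...]]) -> list[set[int]]:
    systems: list[set[int]] = []
    for ring in ring_atom_sets:
        ring_set = set(ring)
        merged = [s for s in systems if s & ring_set]
        for s in merged:
            ring_set |= s
            systems.remove(s)
        systems.append(ring_set)
    return systems


def _connected_clusters(mol, atom_ids: set[int]) -> list[set[int]]:
    clusters: list[set[int]] = []
    todo = set(atom_ids)
    while todo:
        start = todo.pop()
        comp = {start}
        stack = [start]
        while stack:
            a = stack.pop()
            for nb in mol.GetAtomWithIdx(a).GetNeighbors():
                i = nb.GetIdx()
                if i in todo:
                    todo.remove(i)
                    comp.add(i)
                    stack.append(i)
        clusters.append(comp)
    return clusters


def conformer_point_sets(
    compound: Compound,
    params: dict | None = None,
    seed: int = 0,
    fluorine_acceptor: bool = True,
) -> list[list[TypedPoint]]:
    """Typed point sets, one per conformer; geometric-mode compounds
    return their stored point sets unchanged."""
    if compound.point_sets:
        return compound.point_sets
    mol = generate_conformers(compound, params=params, seed=seed)
    return [
        assign_types(mol, conf.GetId(), fluorine_acceptor=fluorine_acceptor)
        for conf in mol.GetConformers()
    ]


# --------------------------------------------------------------------------
# Matching
# --------------------------------------------------------------------------

def _weighted_kabsch(P: np.ndarray, Q: np.ndarray, w: np.ndarray):
    """Rigid transform (R, t) minimizing sum w_i |R p_i + t - q_i|^2."""
    wsum = w.sum()
    cp = (w[:, None] * P).sum(axis=0) / wsum
    cq = (w[:, None] * Q).sum(axis=0) / wsum
    H = (w[:, None] * (P - cp)).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = cq - R @ cp
    return R, t


def _max_norm_dev(x, P, Q, radii):
    R = Rotation.from_rotvec(x[:3]).as_matrix()
    moved = P @ R.T + x[3:]
    d = np.linalg.norm(moved - Q, axis=1)
    return float(np.max(d / radii))


def _evaluate_assignment(P, Q, radii, refine: bool = True):
    """Best max normalized deviation for one assignment; returns
    (max_norm_dev, rmsd at that pose)."""
    w = 1.0 / radii**2
    R, t = _weighted_kabsch(P, Q, w)
    moved = P @ R.T + t
    d = np.linalg.norm(moved - Q, axis=1)
    best = float(np.max(d / radii))
    best_rmsd = float(np.sqrt(np.mean(d**2)))
    if refine and 1.0 < best < 2.5:
        x0 = np.concatenate([Rotation.from_matrix(R).as_rotvec(), t])
        res = minimize(
            _max_norm_dev,
            x0,
            args=(P, Q, radii),
            method="Nelder-Mead",
            options={"maxiter": 400, "xatol": 1e-5, "fatol": 1e-6},
        )
        if res.fun < best:
            best = float(res.fun)
            Rm = Rotation.from_rotvec(res.x[:3]).as_matrix()
            d = np.linalg.norm(P @ Rm.T + res.x[3:] - Q, axis=1)
            best_rmsd = float(np.sqrt(np.mean(d**2)))
    return best, best_rmsd


def _type_assignments(points: list[TypedPoint], features: list[Feature]):
    """Yield injective type-compatible assignments as tuples of point
    indices aligned with ``features``."""
    by_type: dict[str, list[int]] = {}
    for i, p in enumerate(points):
        by_type.setdefault(p.type, []).append(i)
    groups: list[tuple[list[int], list[int]]] = []  # (feature slots, point ids)
    for ftype in ("acceptor", "donor", "hydrophobic"):
        slots = [i for i, f in enumerate(features) if f.type == ftype]
        if not slots:
            continue
        cands = by_type.get(ftype, [])
        if len(cands) < len(slots):
            return
        groups.append((slots, cands))
    per_group = [itertools.permutations(cands, len(slots)) for slots, cands in groups]
    for combo in itertools.product(*per_group):
        assignment = [None] * len(features)
        for (slots, _), perm in zip(groups, combo):
            for slot, point_idx in zip(slots, perm):
                assignment[slot] = point_idx
        yield tuple(assignment)


def _count_assignments(points: list[TypedPoint], features: list[Feature]) -> int:
    from math import perm

    total = 1
    counts: dict[str, int] = {}
    for p in points:
        counts[p.type] = counts.get(p.type, 0) + 1
    for ftype in ("acceptor", "donor", "hydrophobic"):
        k = sum(1 for f in features if f.type == ftype)
        n = counts.get(ftype, 0)
        if k == 0:
            continue
        if n < k:
            return 0
        total *= perm(n, k)
    return total


def match_subset(
    points: list[TypedPoint],
    features: list[Feature],
    exact: bool = True,
    assignment_limit: int = ASSIGNMENT_LIMIT,
    rng: np.random.Generator | None = None,
) -> MatchResult:
    """Match one conformer's typed points against a 5- or 6-feature subset.

    Searches injective type-compatible assignments; each is scored by the
    best rigid superposition's maximum feature-normalized deviation;
    matched when the best assignment brings every point within its
    feature's radius.  With ``exact=False`` and more than
    ``assignment_limit`` assignments, a seeded stochastic search with
    pairwise swap refinement replaces exhaustive enumeration.
    """
    if len(features) not in (5, 6):
        raise ValueError("subset size must be 5 or 6")
    n_assign = _count_assignments(points, features)
    if n_assign == 0:
        return MatchResult(False, None, math.inf, math.inf)
    Q = np.array([f.center for f in features])
    radii = np.array([f.radius for f in features])
    positions = np.array([p.position for p in points])

    best = (math.inf, math.inf, None)
    if exact or n_assign <= assignment_limit:
        iterator = _type_assignments(points, features)
    else:
        iterator = _sampled_assignments(
            points, features, assignment_limit, rng or np.random.default_rng(0)
        )
    for assignment in iterator:
        P = positions[list(assignment)]
        dev, rmsd = _evaluate_assignment(P, Q, radii)
        if dev < best[0]:
            best = (dev, rmsd, assignment)
        if best[0] <= 1e-9:
            break
    dev, rmsd, assignment = best
    matched = dev <= 1.0 + 1e-9
    return MatchResult(
        matched=matched,
        assignment=None if assignment is None else dict(enumerate(assignment)),
        max_normalized_deviation=dev,
        rmsd=rmsd,
    )


def _sampled_assignments(points, features, limit, rng):
    """Seeded random draws of type-compatible injective assignments plus
    within-type swap neighbours of the incumbent (greedy seeding + local
    swaps)."""
    by_type: dict[str, list[int]] = {}
    for i, p in enumerate(points):
        by_type.setdefault(p.type, []).append(i)
    seen = set()
    for _ in range(limit):
        assignment = [None] * len(features)
        ok = True
        used: set[int] = set()
        for ftype in ("acceptor", "donor", "hydrophobic"):
            slots = [i for i, f in enumerate(features) if f.type == ftype]
            cands = [c for c in by_type.get(ftype, []) if c not in used]
            if len(cands) < len(slots):
                ok = False
                break
            pick = rng.choice(len(cands), size=len(slots), replace=False)
            for slot, j in zip(slots, pick):
                assignment[slot] = cands[j]
                used.add(cands[j])
        if not ok:
            return
        key = tuple(assignment)
        if key not in seen:
            seen.add(key)
            yield key


def enumerate_subsets(n_features: int = 9, k_values=(5, 6)) -> dict[int, list[tuple]]:
    """All k-of-n feature index subsets, per k (C(9,5)=126, C(9,6)=84)."""
    return {
        k: list(itertools.combinations(range(n_features), k)) for k in k_values
    }


def screen_library(
    compounds: list[Compound],
    pharmacophore: Pharmacophore,
    k_values=(5, 6),
    conformer_params: dict | None = None,
    seed: int = 0,
    exact: bool = True,
    fluorine_acceptor: bool = True,
) -> pd.DataFrame:
    """Screen every compound against every k-of-9 feature subset.

    Returns a tidy hit table with one row per (stereoisomer, subset):
    columns compound (parent id), stereo, subset (sorted index tuple), k,
    matched, best_rmsd.  A parent counts as a hit for a subset when any
    conformer of any of its stereoisomers matches.
    """
    subsets = enumerate_subsets(9, k_values)
    rows = []
    for compound in compounds:
        point_sets = conformer_point_sets(
            compound,
            params=conformer_params,
            seed=seed,
            fluorine_acceptor=fluorine_acceptor,
        )
        for k, subset_list in subsets.items():
            for subset in subset_list:
                features = pharmacophore.subset(subset)
                matched = False
                best_rmsd = math.inf
                for points in point_sets:
                    result = match_subset(points, features, exact=exact)
                    if result.rmsd < best_rmsd:
                        best_rmsd = result.rmsd
                    if result.matched:
                        matched = True
                        break
                rows.append(
                    {
                        "compound": compound.parent_id,
                        "stereo": compound.stereo,
                        "entry": compound.identifier,
                        "subset": subset,
                        "k": k,
                        "matched": matched,
                        "best_rmsd": best_rmsd,
                    }
                )
    return pd.DataFrame(rows)


def write_hit_table(hits: pd.DataFrame, path) -> None:
    out = hits.copy()
    out["subset"] = out["subset"].map(lambda s: "|".join(map(str, s)))
    out.to_csv(path, sep="\t", index=False)


def read_hit_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["subset"] = df["subset"].map(
        lambda s: tuple(int(x) for x in str(s).split("|"))
    )
    return df
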