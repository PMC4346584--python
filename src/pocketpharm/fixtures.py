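"""Seeded synthetic inputs for every pipeline stage.

Every generator is a pure function of (parameters, seed): toy family /
subfamily alignments with planted conserved columns, ideal seven-helix
bundles with inward-pointing binding residues (standing in for a TM-bundle
template), planted compound libraries with guaranteed hits, decoys and a
blocker-like entry, and a fully wired "planted scenario" whose ground
truth the downstream screen must recover.

The bundle emulates a GPCR TM domain at the level the pipeline needs --
ideal alpha-helix geometry (1.5 A rise, 100 deg/residue), helices parallel
on a circle, chosen residues phased to face the central cavity.  It does
not emulate helix tilts, kinks or loops.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .alignment import (
    AlignedSequence,
    Alignment,
    DEFAULT_BW_SPANS,
    HelixSpan,
    TMLayout,
)
from .pharmacophore import Pharmacophore
from .receptor import Residue, TemplateStructure
from .screening import Compound, TypedPoint, match_subset

HELIX_RISE = 1.5       # A per residue
HELIX_TWIST = 100.0    # degrees per residue
HELIX_RADIUS = 2.3     # CA ring radius of an ideal alpha-helix

_BACKGROUND = "ACDEFGHIKLMNPQRSTVWY"
_MEMBRANE_FACING = "LAVIF"

#: Pocket-lining residues of the bitter-receptor-like fixture, keyed by
#: (helix, BW position): polar residues seeding donor/acceptor features,
#: hydrophobics seeding the hydrophobic features.
TAS2R39_LIKE_KEYS: dict[tuple[int, int], str] = {
    (3, 32): "F", (3, 33): "I", (3, 36): "N", (3, 37): "F", (3, 40): "L",
    (4, 56): "H",
    (5, 40): "N", (5, 41): "L", (5, 44): "V", (5, 45): "T",
    (6, 48): "I", (6, 51): "A", (6, 52): "V", (6, 55): "F", (6, 56): "I",
    (7, 35): "Q", (7, 39): "N", (7, 45): "Y",
}


class FixtureError(ValueError):
    """Contradictory generator parameters or impossible geometry."""


# --------------------------------------------------------------------------
# Toy alignments
# --------------------------------------------------------------------------

def make_toy_alignment(
    n_family: int,
    n_subfamily: int,
    planted_columns: list[int],
    seed: int,
    length: int = 40,
    anchor_columns: list[int] | None = None,
    target_sequence: str | None = None,
) -> tuple[Alignment, Alignment, dict]:
    """Family + subfamily alignments with planted subfamily-conserved columns.

    Planted columns carry one amino acid across the subfamily and random
    background across the rest of the family; ``anchor_columns`` (if given)
    are conserved family-wide, emulating structural x.50 anchors that must
    score low.  The first subfamily row is the target and is gapless.
    Returns (family, subfamily, manifest).
    """
    rng = np.random.default_rng(seed)
    anchor_columns = anchor_columns or []
    if n_subfamily > n_family:
        raise FixtureError("n_subfamily must be <= n_family")
    if n_subfamily < 1:
        raise FixtureError("need at least one subfamily member")
    bad = [c for c in list(planted_columns) + anchor_columns if not 0 <= c < length]
    if bad:
        raise FixtureError(f"columns outside alignment length {length}: {bad}")
    if set(planted_columns) & set(anchor_columns):
        raise FixtureError("planted and anchor columns must be disjoint")

    if target_sequence is not None:
        if len(target_sequence) != length:
            raise FixtureError("target_sequence length mismatch")
        target = list(target_sequence)
    else:
        target = [
            _BACKGROUND[rng.integers(len(_BACKGROUND))] for _ in range(length)
        ]
    anchor_aa = {c: target[c] for c in anchor_columns}
    planted_aa = {c: target[c] for c in planted_columns}

    rows = []
    for i in range(n_family):
        in_subfamily = i < n_subfamily
        if i == 0:
            seq = list(target)
        else:
            seq = [
                _BACKGROUND[rng.integers(len(_BACKGROUND))] for _ in range(length)
            ]
            for c, aa in anchor_aa.items():
                seq[c] = aa
            if in_subfamily:
                for c, aa in planted_aa.items():
                    seq[c] = aa
        prefix = "sub" if in_subfamily else "fam"
        rows.append(AlignedSequence(identifier=f"{prefix}{i:03d}", residues="".join(seq)))

    family = Alignment(sequences=rows)
    sub_ids = [r.identifier for r in rows[:n_subfamily]]
    subfamily = Alignment(sequences=rows[:n_subfamily])
    manifest = {
        "planted_columns": sorted(planted_columns),
        "anchor_columns": sorted(anchor_columns),
        "target_id": rows[0].identifier,
        "subfamily_ids": sub_ids,
        "seed": int(seed),
    }
    return family, subfamily, manifest


# --------------------------------------------------------------------------
# Ideal helical bundles
# --------------------------------------------------------------------------

def make_helical_bundle(
    n_helices: int = 7,
    bundle_radius: float = 9.0,
    inward_residues: dict[tuple[int, int], str] | None = None,
    seed: int = 0,
    spans: dict[int, tuple[int, int]] | None = None,
    z_refs: dict[int, float] | None = None,
) -> TemplateStructure:
    """Ideal parallel-helix bundle with chosen residues facing the center.

    Helix ``h`` occupies its BW span (``spans`` defaults to the canonical
    TM spans); residue BW labels are assigned directly.  For each helix the
    phase is chosen so that its inward residues (mean phase) point at the
    bundle axis, and the depth offset centers those residues near z = 0 so
    they line one cavity.  Radii below the steric limit (adjacent helices
    touching) raise :class:`FixtureError`.

    The central cavity closes against the 8 A tetrahedron-edge pruning for
    radii far above the default; pocket-volume monotonicity with radius
    holds on the supported range (roughly 9-12 A for seven helices).
    """
    rng = np.random.default_rng(seed)
    spans = spans or {h: DEFAULT_BW_SPANS[h] for h in range(1, n_helices + 1)}
    inward = dict(inward_residues or {})
    bad = [k for k in inward if k[0] not in spans or not spans[k[0]][0] <= k[1] <= spans[k[0]][1]]
    if bad:
        raise FixtureError(f"inward residues outside helix spans: {bad}")
    min_radius = (2 * HELIX_RADIUS + 3.0) / (2 * math.sin(math.pi / n_helices))
    if bundle_radius < min_radius:
        raise FixtureError(
            f"bundle_radius {bundle_radius:.1f} below steric limit {min_radius:.1f}"
        )

    residues: list[Residue] = []
    res_id = 0
    for h in sorted(spans):
        bw_start, bw_end = spans[h]
        phi = 2 * math.pi * (h - 1) / n_helices
        center_xy = bundle_radius * np.array([math.cos(phi), math.sin(phi)])
        inward_angle = phi + math.pi
        keys = sorted(pos for (hh, pos) in inward if hh == h)
        # phase the helix so the (circular-mean) key residue faces inward;
        # helices without designated pocket residues face x.50 to the
        # membrane so they do not stuff the cavity
        if keys:
            ref_positions = keys
            ref_angle = inward_angle
        else:
            ref_positions = [50]
            ref_angle = phi
        angles = []
        for pos in ref_positions:
            i = pos - bw_start
            angles.append(ref_angle - math.radians(HELIX_TWIST) * i)
        theta0 = math.atan2(
            np.mean([math.sin(a) for a in angles]),
            np.mean([math.cos(a) for a in angles]),
        )
        # depth reference: the BW position placed at z = 0 (pocket mid-height)
        if z_refs and h in z_refs:
            z_ref = float(z_refs[h])
        else:
            z_ref = float(np.mean(ref_positions))
        for pos in range(bw_start, bw_end + 1):
            i = pos - bw_start
            theta = theta0 + math.radians(HELIX_TWIST) * i
            z = HELIX_RISE * (pos - z_ref)
            ca = np.array(
                [
                    center_xy[0] + HELIX_RADIUS * math.cos(theta),
                    center_xy[1] + HELIX_RADIUS * math.sin(theta),
                    z,
                ]
            )
            axis_dir = np.array([0.0, 0.0, 1.0])
            if (h, pos) in inward:
                # aim the side-chain frame of designated pocket residues at
                # the bundle axis (the inward-pointing rotamer choice); the
                # CA stays on the ideal helix
                center_dir = np.array([-ca[0], -ca[1], 0.0])
                center_dir /= np.linalg.norm(center_dir)
                axis_point = ca - HELIX_RADIUS * center_dir
            else:
                axis_point = np.array([center_xy[0], center_xy[1], z])
            aa = inward.get(
                (h, pos), _MEMBRANE_FACING[rng.integers(len(_MEMBRANE_FACING))]
            )
            backbone = {
                "N": ca + np.array([0.0, 0.0, -0.6]),
                "CA": ca,
                "C": ca + np.array([0.0, 0.0, 0.6]),
            }
            residues.append(
                Residue(
                    res_id=res_id,
                    helix=h,
                    amino_acid=aa,
                    bw_label=f"{h}.{pos}",
                    backbone=backbone,
                    axis_point=axis_point,
                    axis_dir=axis_dir,
                )
            )
            res_id += 1
    return TemplateStructure(residues=residues)


#: Depth references (BW position at pocket mid-height) tiering the polar
#: residues along the pocket axis so donor/acceptor hot-spots separate:
#: N5.40 deep, T5.45/N3.36/H4.56/Q7.35 mid, N7.39 shallow.
TAS2R39_LIKE_Z_REFS: dict[int, float] = {
    1: 45.0, 2: 52.0, 3: 36.0, 4: 56.0, 5: 44.5, 6: 52.0, 7: 35.0,
}


def make_tas2r39_like_bundle(
    bundle_radius: float = 9.0, seed: int = 0
) -> TemplateStructure:
    """Seven-helix bundle whose inward residues mirror the bitter-receptor
    pocket lining (T5.45, N3.36, N5.40, N7.39, Q7.35, H4.56, F6.55, ...)."""
    return make_helical_bundle(
        n_helices=7,
        bundle_radius=bundle_radius,
        inward_residues=TAS2R39_LIKE_KEYS,
        seed=seed,
        z_refs=TAS2R39_LIKE_Z_REFS,
    )


# --------------------------------------------------------------------------
# Planted compound libraries (geometric mode)
# --------------------------------------------------------------------------

def _random_rigid_motion(rng: np.random.Generator):
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=int(rng.integers(2**31 - 1))).as_matrix()
    t = rng.uniform(-20, 20, size=3)
    return R, t


def _apply(points: list[TypedPoint], R: np.ndarray, t: np.ndarray) -> list[TypedPoint]:
    return [
        TypedPoint(p.type, R @ p.position + t, p.source_atoms) for p in points
    ]


def make_planted_library(
    pharmacophore: Pharmacophore,
    hit_subset: tuple[int, ...] = (0, 3, 6, 7, 8),
    n_hits: int = 40,
    n_decoys: int = 40,
    seed: int = 0,
    include_blocker: bool = True,
    blocker_subset: tuple[int, ...] = (0, 1, 2, 7, 8),
) -> tuple[list[Compound], dict]:
    """Rigid typed-point "compounds" with guaranteed screening outcomes.

    Hits carry points exactly on the planted subset's feature centers
    (each under its own random rigid motion -- matching is motion
    invariant), labelled active.  Decoys are labelled inactive and either
    lack the subset's donor/acceptor type or have every point displaced
    well beyond twice the largest feature radius; each decoy is verified
    at generation time to fail the planted subset.  The blocker-like entry
    carries acceptor and hydrophobic points only, on features
    ``blocker_subset``, so it can never satisfy a donor feature.
    """
    if not set(hit_subset) <= set(range(9)):
        raise FixtureError("hit_subset must index features 0-8")
    rng = np.random.default_rng(seed)
    features = pharmacophore.subset(hit_subset)
    base = [
        TypedPoint(f.type, f.center.copy(), (i,))
        for i, f in enumerate(features)
    ]
    max_radius = max(f.radius for f in pharmacophore.features)

    compounds: list[Compound] = []
    for i in range(n_hits):
        R, t = _random_rigid_motion(rng)
        compounds.append(
            Compound(
                identifier=f"hit{i:03d}",
                parent_id=f"hit{i:03d}",
                activity="active",
                point_sets=[_apply(base, R, t)],
            )
        )

    polar_types = {f.type for f in features} & {"donor", "acceptor"}
    for i in range(n_decoys):
        kind = "typeless" if (i % 2 == 0 and polar_types) else "perturbed"
        for attempt in range(50):
            if kind == "typeless":
                drop = sorted(polar_types)[i % len(polar_types)]
                pts = [p for p in base if p.type != drop]
                # keep the body 5 points large with a far-away extra point
                extra = TypedPoint(
                    "hydrophobic",
                    base[0].position + rng.normal(scale=3.0, size=3) + 30.0,
                    (99,),
                )
                pts = pts + [extra]
            else:
                displacement = rng.normal(size=(len(base), 3))
                displacement /= np.linalg.norm(displacement, axis=1, keepdims=True)
                scale = rng.uniform(2.0, 4.0, size=(len(base), 1)) * max_radius
                pts = [
                    TypedPoint(p.type, p.position + d, p.source_atoms)
                    for p, d in zip(base, displacement * scale)
                ]
            R, t = _random_rigid_motion(rng)
            pts = _apply(pts, R, t)
            if not match_subset(pts, features).matched:
                break
        else:
            raise FixtureError("could not generate a failing decoy")
        compounds.append(
            Compound(
                identifier=f"decoy{i:03d}",
                parent_id=f"decoy{i:03d}",
                activity="inactive",
                point_sets=[pts],
            )
        )

    if include_blocker:
        bfeatures = pharmacophore.subset(blocker_subset)
        if any(f.type == "donor" for f in bfeatures):
            raise FixtureError("blocker subset must not contain donor features")
        R, t = _random_rigid_motion(rng)
        bpoints = _apply(
            [
                TypedPoint(f.type, f.center.copy(), (i,))
                for i, f in enumerate(bfeatures)
            ],
            R,
            t,
        )
        compounds.append(
            Compound(
                identifier="blocker000",
                parent_id="blocker000",
                activity="blocker",
                point_sets=[bpoints],
            )
        )

    manifest = {
        "hit_subset": sorted(hit_subset),
        "blocker_subset": sorted(blocker_subset) if include_blocker else None,
        "n_hits": n_hits,
        "n_decoys": n_decoys,
        "seed": int(seed),
    }
    return compounds, manifest


# --------------------------------------------------------------------------
# Chemical-mode example compounds
# --------------------------------------------------------------------------

#: Real flavonoid scaffolds for integration tests: (id, SMILES, activity).
CHEMICAL_EXAMPLES: list[tuple[str, str, str]] = [
    ("kaempferol", "O=c1c(O)c(-c2ccc(O)cc2)oc2cc(O)cc(O)c12", "active"),
    ("luteolin", "O=c1cc(-c2ccc(O)c(O)c2)oc2cc(O)cc(O)c12", "active"),
    ("naringenin", "O=C1CC(c2ccc(O)cc2)Oc2cc(O)cc(O)c21", "active"),
    ("epicatechin", "OC1Cc2c(O)cc(O)cc2OC1c1ccc(O)c(O)c1", "active"),
    ("flavone", "O=c1cc(-c2ccccc2)oc2ccccc12", "active"),
    ("6-methoxyflavanone", "O=C1CC(c2ccccc2)Oc2ccc(OC)cc21", "blocker"),
    (
        "4'-fluoro-6-methoxyflavanone",
        "O=C1CC(c2ccc(F)cc2)Oc2ccc(OC)cc21",
        "blocker",
    ),
    (
        "6,3'-dimethoxyflavanone",
        "O=C1CC(c2cccc(OC)c2)Oc2ccc(OC)cc21",
        "blocker",
    ),
    ("xanthone", "O=c1c2ccccc2oc2ccccc12", "active"),
]


# --------------------------------------------------------------------------
# The end-to-end planted scenario
# --------------------------------------------------------------------------

@dataclass
class PlantedScenario:
    family: Alignment
    subfamily: Alignment
    layout: TMLayout
    target_id: str
    template: TemplateStructure
    hit_subset: tuple[int, ...]
    manifest: dict
    seed: int


def make_planted_scenario(
    seed: int = 0,
    bundle_radius: float = 9.0,
    n_family: int = 30,
    n_subfamily: int = 8,
) -> PlantedScenario:
    """Wire alignment, layout and bundle into one consistent ground truth.

    The bundle's residues define the target sequence; the key binding
    residues are planted as subfamily-conserved columns, the x.50 anchors
    as family-wide conserved columns, so conservation scoring recovers the
    pocket lining.  The scenario layout uses explicit per-helix spans with
    zero start-shift (the shift machinery is exercised separately).
    """
    template = make_tas2r39_like_bundle(bundle_radius=bundle_radius, seed=seed)
    residues = template.residues
    target_seq = "".join(r.amino_acid for r in residues)
    col_of_label = {r.bw_label: i for i, r in enumerate(residues)}

    planted_cols = [col_of_label[f"{h}.{p}"] for (h, p) in sorted(TAS2R39_LIKE_KEYS)]
    anchor_cols = [col_of_label[f"{h}.50"] for h in range(1, 8)]
    family, subfamily, manifest = make_toy_alignment(
        n_family=n_family,
        n_subfamily=n_subfamily,
        planted_columns=planted_cols,
        seed=seed + 1,
        length=len(target_seq),
        anchor_columns=anchor_cols,
        target_sequence=target_seq,
    )

    helices: dict[int, HelixSpan] = {}
    pos = 0
    for h in range(1, 8):
        bw_start, bw_end = DEFAULT_BW_SPANS[h]
        width = bw_end - bw_start + 1
        helices[h] = HelixSpan(
            start_col=pos,
            end_col=pos + width - 1,
            anchor_col=pos + (50 - bw_start),
            bw_start=bw_start,
            bw_end=bw_end,
            shift=0,
        )
        pos += width
    layout = TMLayout(helices=helices)

    manifest.update(
        {
            "key_residues": [f"{h}.{p}" for (h, p) in sorted(TAS2R39_LIKE_KEYS)],
            "bundle_radius": bundle_radius,
            "hit_subset": [0, 3, 6, 7, 8],
        }
    )
    return PlantedScenario(
        family=family,
        subfamily=subfamily,
        layout=layout,
        target_id=manifest["target_id"],
        template=template,
        hit_subset=(0, 3, 6, 7, 8),
        manifest=manifest,
        seed=seed,
    )


def write_scenario(scenario: PlantedScenario, outdir) -> None:
    """Write scenario inputs (FASTA, layout YAML, MOL2 template, manifest)."""
    import os

    from .alignment import write_alignment
    from .receptor import attach_rotamers, write_mol2

    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "family.fasta"), "w") as fh:
        fh.write(write_alignment(scenario.family))
    with open(os.path.join(outdir, "subfamily.fasta"), "w") as fh:
        fh.write(write_alignment(scenario.subfamily))
    with open(os.path.join(outdir, "layout.yaml"), "w") as fh:
        fh.write(scenario.layout.to_yaml())
    write_mol2(
        scenario.template,
        os.path.join(outdir, "template.mol2"),
        attach_rotamers(scenario.template),
    )
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(scenario.manifest, fh, indent=2)
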