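"""Interaction-point placement, fuzzy feature clustering and the 9-feature
pharmacophore.

Receptor side chains project typed interaction points into the pocket:
hydrogen-bond donors/acceptors along an idealized H-bond axis 2.9 A beyond
the polar heavy atom, hydrophobic points at the side-chain carbon centroid.
Each point is weighted by rotamer likelihood x residue binding score.
Points of one type are grouped by weighted mean-shift with a Gaussian
kernel of bandwidth Rc (2.5 A by default); the top three clusters per type
(acceptor, donor, hydrophobic) form the final pharmacophore, indexed
acceptor 0-2, donor 3-5, hydrophobic 6-8 in descending cluster score.
Per-feature residue contribution fractions always sum to 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .alignment import ResidueRef
from .conservation import ConservationProfile
from .receptor import (
    BackboneModel,
    PocketVolume,
    Residue,
    RotamerEnsemble,
    SIDECHAIN_TEMPLATES,
)

FEATURE_TYPES = ("acceptor", "donor", "hydrophobic")

# Residue typing: which side chains can seed which feature type.
DONOR_RESIDUES = set("STYNQKRWH")
ACCEPTOR_RESIDUES = set("STYNQDEH")
HYDROPHOBIC_RESIDUES = set("AVLIFMPWYC")

DEFAULT_RC = 2.5
DEFAULT_HBOND_LENGTH = 2.9
DEFAULT_MIN_RADIUS = 0.8
# offset from the side-chain carbon centroid toward the pocket; places the
# point one vdW contact beyond the outermost side-chain carbons
DEFAULT_HYDROPHOBIC_CONTACT = 3.0


class PharmacophoreError(ValueError):
    """Raised when a 9-feature pharmacophore cannot be assembled."""


@dataclass(frozen=True)
class InteractionPoint:
    type: str
    position: np.ndarray
    weight: float
    source_residue: ResidueRef
    source_rotamer: int


@dataclass
class Feature:
    index: int
    type: str
    center: np.ndarray
    radius: float
    contributions: list[tuple[ResidueRef, float]]  # descending fraction
    score: float = 0.0

    def contribution_sum(self) -> float:
        return sum(f for _, f in self.contributions)


@dataclass
class Pharmacophore:
    """Exactly nine typed spherical features, three per type."""

    features: list[Feature]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.features) != 9:
            raise PharmacophoreError(f"expected 9 features, got {len(self.features)}")
        if [f.index for f in self.features] != list(range(9)):
            raise PharmacophoreError("feature indices must be 0..8 in order")
        for ftype, lo in (("acceptor", 0), ("donor", 3), ("hydrophobic", 6)):
            if any(self.features[lo + i].type != ftype for i in range(3)):
                raise PharmacophoreError(f"features {lo}..{lo+2} must be {ftype}")

    def __getitem__(self, index: int) -> Feature:
        return self.features[index]

    def subset(self, indices) -> list[Feature]:
        return [self.features[i] for i in indices]

    def centers(self) -> np.ndarray:
        return np.array([f.center for f in self.features])


# --------------------------------------------------------------------------
# Interaction point placement
# --------------------------------------------------------------------------

def residue_feature_types(amino_acid: str) -> set[str]:
    types = set()
    if amino_acid in DONOR_RESIDUES:
        types.add("donor")
    if amino_acid in ACCEPTOR_RESIDUES:
        types.add("acceptor")
    if amino_acid in HYDROPHOBIC_RESIDUES:
        types.add("hydrophobic")
    return types


def place_interaction_points(
    residue: Residue,
    ensemble: RotamerEnsemble,
    pocket: PocketVolume,
    binding_score: float,
    hbond_length: float = DEFAULT_HBOND_LENGTH,
    hydrophobic_contact: float = DEFAULT_HYDROPHOBIC_CONTACT,
) -> list[InteractionPoint]:
    """Project typed interaction points of one residue into ligand space.

    Donor/acceptor points extend the CA->polar-tip axis by ``hbond_length``
    (where an H-bond partner atom would sit); hydrophobic points extend the
    CA->side-chain-carbon-centroid axis by ``hydrophobic_contact`` (where a
    ligand carbon in vdW contact would sit).  Points outside the pocket
    volume are discarded; the returned list may be empty.
    """
    types = residue_feature_types(residue.amino_acid)
    if not types or binding_score <= 0:
        return []
    tips = SIDECHAIN_TEMPLATES[residue.amino_acid]["polar_tips"]
    ref = residue.ref()
    points: list[InteractionPoint] = []
    for rot_idx, rot in enumerate(ensemble.states[residue.res_id]):
        weight = rot.weight * binding_score
        if weight <= 0 or not rot.atoms:
            continue
        by_name = {name: coord for name, _, coord in rot.atoms}
        candidates: list[tuple[str, np.ndarray]] = []
        if tips and ({"donor", "acceptor"} & types):
            for tip_name in tips:
                tip = by_name[tip_name]
                axis = tip - residue.ca
                norm = np.linalg.norm(axis)
                if norm < 1e-9:
                    continue
                pos = tip + axis / norm * hbond_length
                for t in ("donor", "acceptor"):
                    if t in types:
                        candidates.append((t, pos))
        if "hydrophobic" in types:
            carbons = np.array(
                [coord for name, element, coord in rot.atoms if element == "C"]
            )
            if len(carbons):
                centroid = carbons.mean(axis=0)
                axis = centroid - residue.ca
                norm = np.linalg.norm(axis)
                if norm >= 1e-9:
                    candidates.append(
                        ("hydrophobic", centroid + axis / norm * hydrophobic_contact)
                    )
        for ptype, pos in candidates:
            if pocket.contains(pos)[0]:
                points.append(
                    InteractionPoint(
                        type=ptype,
                        position=np.asarray(pos, dtype=float),
                        weight=weight,
                        source_residue=ref,
                        source_rotamer=rot_idx,
                    )
                )
    return points


def collect_interaction_points(
    model: BackboneModel,
    ensemble: RotamerEnsemble,
    pocket: PocketVolume,
    profile: ConservationProfile | dict[str, float],
    lining: set[ResidueRef] | None = None,
    hbond_length: float = DEFAULT_HBOND_LENGTH,
    hydrophobic_contact: float = DEFAULT_HYDROPHOBIC_CONTACT,
) -> list[InteractionPoint]:
    """All interaction points of the (lining) residues, in deterministic
    (BW label, rotamer index) order."""
    def score_of(label: str) -> float:
        if isinstance(profile, ConservationProfile):
            return profile.score(label) if label in profile.rows else 0.0
        return profile.get(label, 0.0)

    lining_labels = None if lining is None else {r.bw_label for r in lining}
    points: list[InteractionPoint] = []
    for res in sorted(model.residues, key=lambda r: r.bw_label or ""):
        if res.bw_label is None:
            continue
        if lining_labels is not None and res.bw_label not in lining_labels:
            continue
        points.extend(
            place_interaction_points(
                res, ensemble, pocket, score_of(res.bw_label),
                hbond_length, hydrophobic_contact,
            )
        )
    return points


# --------------------------------------------------------------------------
# Fuzzy clustering (weighted mean-shift)
# --------------------------------------------------------------------------

@dataclass
class Cluster:
    type: str
    center: np.ndarray
    radius: float
    score: float
    members: list[InteractionPoint]


def _mean_shift_modes(
    positions: np.ndarray, weights: np.ndarray, rc: float
) -> np.ndarray:
    """Weighted mean-shift with a Gaussian kernel truncated at ``rc``;
    modes closer than rc/2 are merged (weight-descending order kept).

    The hard truncation is what makes the kernel scale Rc a true locality
    bound: interaction hot-spots farther apart than Rc can never pull each
    other's modes together, however unequal their weights.
    """
    modes = []
    for start in positions:
        x = start.copy()
        for _ in range(200):
            d2 = np.sum((positions - x) ** 2, axis=1)
            k = weights * np.exp(-0.5 * d2 / rc**2)
            k[d2 > rc**2] = 0.0
            if k.sum() <= 0:
                break
            new = (k[:, None] * positions).sum(axis=0) / k.sum()
            if np.linalg.norm(new - x) < 1e-6:
                x = new
                break
            x = new
        modes.append(x)
    modes = np.array(modes)
    merged: list[np.ndarray] = []
    for m in modes:
        for other in merged:
            if np.linalg.norm(m - other) < rc / 2.0:
                break
        else:
            merged.append(m)
    return np.array(merged)


def fuzzy_cluster(
    points: list[InteractionPoint],
    rc: float = DEFAULT_RC,
    min_radius: float = DEFAULT_MIN_RADIUS,
) -> dict[str, list[Cluster]]:
    """Group interaction points into typed spherical clusters.

    Per type: density modes via weighted mean-shift at kernel scale ``rc``;
    each point joins its nearest mode; cluster center = weighted mean of
    members, radius = weighted RMS member distance floored at
    ``min_radius``, score = summed weight.  Clusters are returned in
    descending score order.
    """
    out: dict[str, list[Cluster]] = {t: [] for t in FEATURE_TYPES}
    for ftype in FEATURE_TYPES:
        members = [p for p in points if p.type == ftype]
        if not members:
            continue
        pos = np.array([p.position for p in members])
        w = np.array([p.weight for p in members])
        modes = _mean_shift_modes(pos, w, rc)
        assignment = np.argmin(
            np.linalg.norm(pos[:, None, :] - modes[None, :, :], axis=2), axis=1
        )
        clusters = []
        for mode_idx in range(len(modes)):
            sel = assignment == mode_idx
            if not np.any(sel):
                continue
            cw = w[sel]
            cp = pos[sel]
            center = (cw[:, None] * cp).sum(axis=0) / cw.sum()
            rms = math.sqrt(
                float((cw * np.sum((cp - center) ** 2, axis=1)).sum() / cw.sum())
            )
            clusters.append(
                Cluster(
                    type=ftype,
                    center=center,
                    radius=max(rms, min_radius),
                    score=float(cw.sum()),
                    members=[m for m, s in zip(members, sel) if s],
                )
            )
        clusters.sort(
            key=lambda c: (-c.score, c.radius, tuple(np.round(c.center, 6)))
        )
        out[ftype] = clusters
    return out


def build_pharmacophore(
    clusters: dict[str, list[Cluster]], metadata: dict | None = None
) -> Pharmacophore:
    """Select the top three clusters per type and assemble the pharmacophore.

    Indices: acceptor 0-2, donor 3-5, hydrophobic 6-8, each in descending
    cluster score (ties: smaller radius, then lexicographic center).
    Contributions are each residue's share of the cluster weight.
    """
    deficient = [t for t in FEATURE_TYPES if len(clusters.get(t, [])) < 3]
    if deficient:
        raise PharmacophoreError(
            f"need >= 3 clusters per type; deficient: {deficient}"
        )
    features: list[Feature] = []
    index = 0
    for ftype in FEATURE_TYPES:
        ranked = sorted(
            clusters[ftype],
            key=lambda c: (-c.score, c.radius, tuple(np.round(c.center, 6))),
        )
        for cluster in ranked[:3]:
            shares: dict[ResidueRef, float] = {}
            for m in cluster.members:
                shares[m.source_residue] = shares.get(m.source_residue, 0.0) + m.weight
            total = sum(shares.values())
            contributions = sorted(
                ((res, wt / total) for res, wt in shares.items()),
                key=lambda rf: (-rf[1], rf[0].bw_label),
            )
            features.append(
                Feature(
                    index=index,
                    type=ftype,
                    center=cluster.center.copy(),
                    radius=cluster.radius,
                    contributions=contributions,
                    score=cluster.score,
                )
            )
            index += 1
    return Pharmacophore(features=features, metadata=metadata or {})


def feature_distances(pharm: Pharmacophore) -> np.ndarray:
    """Symmetric 9x9 matrix of pairwise feature-center distances (A)."""
    centers = pharm.centers()
    diff = centers[:, None, :] - centers[None, :, :]
    return np.linalg.norm(diff, axis=2)


# --------------------------------------------------------------------------
# Text format: `index type x y z radius [bw_label:fraction,...]`
# --------------------------------------------------------------------------

def write_pharmacophore(pharm: Pharmacophore, path=None) -> str:
    lines = ["# index type x y z radius contributions"]
    for f in pharm.features:
        contrib = ",".join(
            f"{res.bw_label}:{frac:.2f}" for res, frac in f.contributions
        )
        lines.append(
            f"{f.index} {f.type} {f.center[0]:.3f} {f.center[1]:.3f} "
            f"{f.center[2]:.3f} {f.radius:.3f} {contrib}"
        )
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def read_pharmacophore(text_or_path) -> Pharmacophore:
    """Read the pharmacophore text format (whitespace- or comma-delimited).

    Contribution columns are optional; unknown residue labels are kept as
    opaque ResidueRefs with index -1.
    """
    import os

    if isinstance(text_or_path, (str, os.PathLike)) and os.path.exists(
        str(text_or_path)
    ):
        with open(text_or_path) as fh:
            text = fh.read()
    else:
        text = str(text_or_path)
    features = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        index = int(parts[0])
        ftype = parts[1].lower()
        if ftype not in FEATURE_TYPES:
            raise PharmacophoreError(f"unknown feature type {ftype!r}")
        x, y, z, radius = map(float, parts[2:6])
        contributions = []
        for token in parts[6:]:
            if ":" not in token:
                continue
            label, frac = token.rsplit(":", 1)
            contributions.append(
                (ResidueRef(bw_label=label, target_index=-1, amino_acid="X"),
                 float(frac))
            )
        features.append(
            Feature(
                index=index,
                type=ftype,
                center=np.array([x, y, z]),
                radius=radius,
                contributions=contributions
                or [(ResidueRef("0.0", -1, "X"), 1.0)],
            )
        )
    features.sort(key=lambda f: f.index)
    return Pharmacophore(features=features)
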