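"""Conservation-based ligand-binding-likelihood scoring of pocket residues.

The premise: residues that bind subfamily-specific ligands are conserved
within the subfamily but variable across the wider receptor family, whereas
residues conserved family-wide serve structure or activation and score low.

Conservation of a column is the normalized Shannon-entropy complement
``1 - H/log(20)`` over its non-gap symbols.  The binding score combines the
two levels as ``sub * (1 - fam**gamma)`` with ``gamma = 2`` by default; it
is a documented surrogate for the tree-based scoring method the original
pipeline cites, guaranteed qualitatively (monotone in subfamily
conservation, penalizing family-wide conservation), not numerically.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .alignment import Alignment, ResidueRef, GAP_CHARS

_ALPHABET_SIZE = 20
_LOW_COVERAGE = 0.5


def column_conservation(alignment: Alignment, column: int) -> float:
    """Entropy-complement conservation of one column, in [0, 1].

    Gaps and 'X' are excluded from the frequency counts; an all-gap column
    is defined as 0 with a warning.
    """
    symbols = [
        c
        for c in alignment.column(column)
        if c not in GAP_CHARS and c != "-" and c != "X"
    ]
    if not symbols:
        warnings.warn(f"column {column} has no scoreable symbols; conservation 0")
        return 0.0
    counts = Counter(symbols)
    n = len(symbols)
    entropy = -sum((k / n) * math.log(k / n) for k in counts.values())
    value = 1.0 - entropy / math.log(_ALPHABET_SIZE)
    return min(max(value, 0.0), 1.0)


def column_coverage(alignment: Alignment, column: int) -> float:
    col = alignment.column(column)
    return sum(1 for c in col if c != "-") / len(col)


def binding_score(
    family: Alignment,
    subfamily: Alignment,
    column: int,
    gamma: float = 2.0,
) -> float:
    """Ligand-binding likelihood of the residue at an alignment column.

    High when the column is conserved in the subfamily but variable in the
    family; zero when subfamily-variable or (via the ``1 - fam**gamma``
    factor) fully conserved family-wide.
    """
    sub = column_conservation(subfamily, column)
    fam = column_conservation(family, column)
    return sub * (1.0 - fam**gamma)


@dataclass
class ConservationProfile:
    """Per-residue conservation and binding scores, exportable as a table."""

    rows: dict[str, dict]  # bw_label -> {residue, sub, fam, score}
    gamma: float = 2.0

    @classmethod
    def from_alignments(
        cls,
        family: Alignment,
        subfamily: Alignment,
        bw_map: dict[str, ResidueRef],
        target_id: str,
        gamma: float = 2.0,
    ) -> "ConservationProfile":
        """Score every BW-numbered residue of the target.

        ``bw_map`` indexes ungapped target positions; scoring needs the
        alignment column, recovered by walking the gapped target sequence.
        """
        target = family[target_id]
        # ungapped index -> alignment column
        col_of: dict[int, int] = {}
        u = 0
        for col, c in enumerate(target.residues):
            if c != "-":
                col_of[u] = col
                u += 1
        rows = {}
        for label, ref in sorted(bw_map.items()):
            col = col_of[ref.target_index]
            sub = column_conservation(subfamily, col)
            fam = column_conservation(family, col)
            if column_coverage(subfamily, col) < _LOW_COVERAGE:
                warnings.warn(f"{label}: subfamily column coverage < 50%")
            rows[label] = {
                "residue": ref,
                "subfamily_conservation": sub,
                "family_conservation": fam,
                "binding_score": sub * (1.0 - fam**gamma),
            }
        return cls(rows=rows, gamma=gamma)

    def score(self, bw_label: str) -> float:
        return self.rows[bw_label]["binding_score"]

    def to_frame(self) -> pd.DataFrame:
        recs = [
            {
                "bw_label": label,
                "amino_acid": row["residue"].amino_acid,
                "subfamily_conservation": row["subfamily_conservation"],
                "family_conservation": row["family_conservation"],
                "binding_score": row["binding_score"],
            }
            for label, row in self.rows.items()
        ]
        return pd.DataFrame.from_records(recs)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def rank_pocket_residues(
    profile: ConservationProfile, pocket_residues: list[ResidueRef]
) -> list[ResidueRef]:
    """Order pocket residues by descending binding score.

    Ties break deterministically by lexicographic BW label.
    """
    if not pocket_residues:
        raise ValueError("empty pocket residue list")
    return sorted(
        pocket_residues,
        key=lambda r: (-profile.score(r.bw_label), r.bw_label),
    )
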