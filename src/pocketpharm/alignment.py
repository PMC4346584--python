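"""Family alignments, transmembrane helix layout and Ballesteros-Weinstein numbering.

GPCR transmembrane residues are referred to by Ballesteros-Weinstein (BW)
labels ``helix.position``: helices are numbered 1-7 and the most conserved
residue of each helix is fixed at position 50, counting down toward the
N-terminus and up toward the C-terminus.  The layout (alignment column span
and anchor column per helix) is configuration, not inference: anchors come
from a :class:`TMLayout`, optionally loaded from a YAML file.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP_CHARS = set("-.~")
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: Default BW label spans of the seven TM helices (start and end positions).
DEFAULT_BW_SPANS: dict[int, tuple[int, int]] = {
    1: (33, 56),
    2: (40, 65),
    3: (25, 51),
    4: (43, 64),
    5: (38, 63),
    6: (37, 59),
    7: (34, 56),
}


class AlignmentError(ValueError):
    """Raised for malformed alignments (ragged records, empty input)."""


class NumberingError(ValueError):
    """Raised when BW numbering cannot be assigned (e.g. anchor on a gap)."""


@dataclass(frozen=True)
class AlignedSequence:
    identifier: str
    residues: str  # gapped, one-letter codes with '-' gaps

    def ungapped(self) -> str:
        return "".join(c for c in self.residues if c not in GAP_CHARS)


@dataclass
class Alignment:
    """An ordered multiple sequence alignment with unique identifiers."""

    sequences: list[AlignedSequence]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise AlignmentError("alignment has no sequences")
        lengths = {len(s.residues) for s in self.sequences}
        if len(lengths) != 1:
            raise AlignmentError(f"ragged alignment: lengths {sorted(lengths)}")
        ids = [s.identifier for s in self.sequences]
        if len(set(ids)) != len(ids):
            raise AlignmentError("duplicate sequence identifiers")

    @property
    def width(self) -> int:
        return len(self.sequences[0].residues)

    def __len__(self) -> int:
        return len(self.sequences)

    def __getitem__(self, identifier: str) -> AlignedSequence:
        for s in self.sequences:
            if s.identifier == identifier:
                return s
        raise KeyError(identifier)

    def ids(self) -> list[str]:
        return [s.identifier for s in self.sequences]

    def column(self, col: int) -> str:
        if not 0 <= col < self.width:
            raise IndexError(f"column {col} outside alignment of width {self.width}")
        return "".join(s.residues[col] for s in self.sequences)


@dataclass(frozen=True)
class HelixSpan:
    """Column span and anchor of one TM helix in the alignment.

    ``anchor_col`` is the alignment column of the x.50 residue.  ``shift``
    moves the numbering origin toward the N-terminus by that many (ungapped)
    residues, so a positive shift increases the label of a fixed residue.
    """

    start_col: int
    end_col: int
    anchor_col: int
    bw_start: int
    bw_end: int
    shift: int = 0

    def __post_init__(self) -> None:
        if not self.start_col <= self.anchor_col <= self.end_col:
            raise ValueError(
                f"anchor column {self.anchor_col} outside span "
                f"[{self.start_col}, {self.end_col}]"
            )
        if not self.bw_start <= 50 <= self.bw_end:
            raise ValueError("BW span must contain position 50")


@dataclass
class TMLayout:
    """Seven helix spans; TM V carries a start-shift of 3 by default."""

    helices: dict[int, HelixSpan]

    def __post_init__(self) -> None:
        bad = set(self.helices) - set(range(1, 8))
        if bad:
            raise ValueError(f"invalid helix numbers: {sorted(bad)}")

    @classmethod
    def from_yaml(cls, text: str) -> "TMLayout":
        raw = yaml.safe_load(text)
        helices = {}
        for key, h in raw["helices"].items():
            span = DEFAULT_BW_SPANS[int(key)]
            helices[int(key)] = HelixSpan(
                start_col=int(h["start_col"]),
                end_col=int(h["end_col"]),
                anchor_col=int(h["anchor_col"]),
                bw_start=int(h.get("bw_start", span[0])),
                bw_end=int(h.get("bw_end", span[1])),
                shift=int(h.get("shift", 3 if int(key) == 5 else 0)),
            )
        return cls(helices=helices)

    def to_yaml(self) -> str:
        raw = {
            "helices": {
                hx: {
                    "start_col": s.start_col,
                    "end_col": s.end_col,
                    "anchor_col": s.anchor_col,
                    "bw_start": s.bw_start,
                    "bw_end": s.bw_end,
                    "shift": s.shift,
                }
                for hx, s in sorted(self.helices.items())
            }
        }
        return yaml.safe_dump(raw, sort_keys=False)

    def with_shift(self, helix: int, shift: int) -> "TMLayout":
        helices = dict(self.helices)
        helices[helix] = replace(helices[helix], shift=shift)
        return TMLayout(helices=helices)


@dataclass(frozen=True, order=True)
class ResidueRef:
    """A target residue addressed by BW label and ungapped sequence index."""

    bw_label: str
    target_index: int  # 0-based index into the ungapped target sequence
    amino_acid: str

    @property
    def helix(self) -> int:
        return int(self.bw_label.split(".")[0])

    @property
    def position(self) -> int:
        return int(self.bw_label.split(".")[1])


def parse_alignment(fasta_text: str) -> Alignment:
    """Parse a gapped FASTA alignment; gap symbols are normalized to ``-``."""
    records = list(SeqIO.parse(io.StringIO(fasta_text), "fasta"))
    if not records:
        raise AlignmentError("no FASTA records found")
    seqs = []
    for rec in records:
        residues = "".join(
            "-" if c in GAP_CHARS else c for c in str(rec.seq).upper()
        )
        seqs.append(AlignedSequence(identifier=rec.id, residues=residues))
    return Alignment(sequences=seqs)


def write_alignment(alignment: Alignment) -> str:
    """Serialize back to FASTA, preserving record order."""
    buf = io.StringIO()
    records = [
        SeqRecord(Seq(s.residues), id=s.identifier, description="")
        for s in alignment.sequences
    ]
    SeqIO.write(records, buf, "fasta")
    return buf.getvalue()


def select_subfamily(alignment: Alignment, member_ids: list[str]) -> Alignment:
    """Extract a sub-alignment with exactly the listed members, columns untouched."""
    if not member_ids:
        raise AlignmentError("empty subfamily member list")
    present = set(alignment.ids())
    missing = [m for m in member_ids if m not in present]
    if missing:
        raise KeyError(f"ids not in alignment: {missing}")
    wanted = set(member_ids)
    return Alignment(
        sequences=[s for s in alignment.sequences if s.identifier in wanted]
    )


def _ungapped_index_at_column(residues: str, col: int) -> int:
    """0-based ungapped index of the residue at alignment column ``col``."""
    if residues[col] in GAP_CHARS or residues[col] == "-":
        raise NumberingError(f"column {col} is a gap in the target")
    return sum(1 for c in residues[:col] if c != "-")


def assign_bw_numbers(
    alignment: Alignment, target_id: str, layout: TMLayout
) -> dict[str, ResidueRef]:
    """Map every BW label of every helix span to a target residue.

    Positions count ungapped target residues only: label ``h.p`` resolves to
    the residue ``p - 50`` ungapped steps from the (shift-corrected) anchor.
    Labels that would fall outside the target sequence are omitted.
    """
    target = alignment[target_id]
    ungapped = target.ungapped()
    n = len(ungapped)
    out: dict[str, ResidueRef] = {}
    for hx, span in sorted(layout.helices.items()):
        try:
            anchor_idx = _ungapped_index_at_column(target.residues, span.anchor_col)
        except NumberingError as e:
            raise NumberingError(f"helix {hx}: {e}") from None
        origin = anchor_idx - span.shift  # index labelled hx.50
        for pos in range(span.bw_start, span.bw_end + 1):
            idx = origin + (pos - 50)
            if not 0 <= idx < n:
                continue
            label = f"{hx}.{pos}"
            out[label] = ResidueRef(
                bw_label=label, target_index=idx, amino_acid=ungapped[idx]
            )
    return out


def propose_anchors(alignment: Alignment, layout: TMLayout) -> dict[int, int]:
    """Suggest per-helix anchor columns as the most conserved column in each span.

    Advisory only -- proposals never override the configured anchors.
    """
    from .conservation import column_conservation

    proposals = {}
    for hx, span in sorted(layout.helices.items()):
        cols = range(span.start_col, span.end_col + 1)
        proposals[hx] = max(
            cols, key=lambda c: (column_conservation(alignment, c), -c)
        )
    return proposals
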