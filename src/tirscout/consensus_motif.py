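"""Degenerate IUPAC consensus construction and flexible-gap protein motifs.

The consensus builder summarizes a set of aligned TIR sequences column by
column with IUPAC degeneracy codes. The motif scanner matches zinc-finger
style C/H patterns written in a small text language, e.g. ``Cx2Cx3GHx4C``
(anchor residues separated by fixed or ranged spacer runs like ``x4-7``),
and is used to classify PHD-finger C/H arrangements as invertebrate-type or
vertebrate-type.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .seq_model import GAP, ProteinSeq

IUPAC_CODES: dict[frozenset, str] = {
    frozenset(s): c
    for c, s in {
        "A": "A", "C": "C", "G": "G", "T": "T",
        "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
        "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
    }.items()
}

IUPAC_SETS: dict[str, frozenset] = {c: s for s, c in IUPAC_CODES.items()}


@dataclass
class IUPACConsensus:
    consensus: str
    column_counts: list[Counter]
    n_sequences: int
    trimmed: tuple[int, int] = (0, 0)  # columns removed from (left, right) ends

    def __str__(self) -> str:
        return self.consensus


def left_anchor_align(tirs: Sequence[str]) -> list[str]:
    """Terminal alignment: anchor at the 5'-CAC terminus, pad ends with gaps.

    Inter-species TIR similarity is confined to the outer terminus, so the
    consensus is built without internal gaps, simply left-anchoring every
    sequence at its first base.
    """
    width = max(len(t) for t in tirs)
    return [t.upper() + GAP * (width - len(t)) for t in tirs]


def build_consensus(
    aligned_tirs: Sequence[str], include_threshold: float = 0.25
) -> IUPACConsensus:
    """Column-wise degenerate consensus of equal-length aligned sequences.

    Per column, the IUPAC code covers every base whose frequency among
    non-gap entries is >= ``include_threshold``; if no base reaches the
    threshold the modal base is used (ties broken alphabetically). Columns
    whose gap fraction exceeds 0.5 are trimmed from the ends only. The
    caller is expected to pass a pre-deduplicated ("nonredundant") set.
    """
    if len(aligned_tirs) < 2:
        raise ValueError("need >= 2 sequences")
    width = len(aligned_tirs[0])
    if any(len(t) != width for t in aligned_tirs):
        raise ValueError("aligned sequences must have equal length")
    seqs = [t.upper() for t in aligned_tirs]

    gap_frac = [
        sum(1 for s in seqs if s[c] == GAP) / len(seqs) for c in range(width)
    ]
    lo, hi = 0, width
    while lo < hi and gap_frac[lo] > 0.5:
        lo += 1
    while hi > lo and gap_frac[hi - 1] > 0.5:
        hi -= 1
    if lo >= hi:
        raise ValueError("all columns are gap-dominated")

    codes = []
    counts: list[Counter] = []
    for c in range(lo, hi):
        col = Counter(
            s[c] for s in seqs if s[c] != GAP and s[c] in "ACGT"
        )
        counts.append(col)
        total = sum(col.values())
        if total == 0:
            codes.append("N")
            continue
        included = frozenset(
            b for b, n in col.items() if n / total >= include_threshold
        )
        if not included:
            top = max(col.values())
            included = frozenset([min(b for b, n in col.items() if n == top)])
        codes.append(IUPAC_CODES[included])
    return IUPACConsensus(
        consensus="".join(codes),
        column_counts=counts,
        n_sequences=len(seqs),
        trimmed=(lo, width - hi),
    )


def consensus_matches(consensus: str, sequence: str) -> bool:
    """Whether a plain sequence is compatible with an IUPAC consensus."""
    if len(consensus) < len(sequence):
        return False
    return all(
        b == GAP or b in IUPAC_SETS[c]
        for c, b in zip(consensus, sequence)
    )


# ---------------------------------------------------------------------------
# Flexible-gap motif patterns
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MotifPattern:
    """Ordered anchors with the allowed spacer range before each.

    ``elements`` is a list of ``(residue_set, min_gap, max_gap)`` triples;
    the gap is the number of arbitrary residues between the previous anchor
    and this one (0 for the first anchor).
    """

    elements: tuple
    text: str = ""

    def __post_init__(self) -> None:
        if not self.elements:
            raise ValueError("empty motif pattern")
        for residues, lo, hi in self.elements:
            if not residues or lo > hi or lo < 0:
                raise ValueError("invalid motif element")


_TOKEN = re.compile(r"\[([A-Z]+)\]|([A-Z])|x(\d+)(?:-(\d+))?", re.X)


def parse_motif(text: str) -> MotifPattern:
    """Parse patterns like ``Cx2Cx3GHx4C`` or ``C x4-7 C x14-16 ... Cx2C``.

    Upper-case letters are anchors (``[CH]`` for alternatives); ``xN`` or
    ``xN-M`` are spacer runs of arbitrary residues. Whitespace and
    underscores are ignored.
    """
    cleaned = text.replace("_", "").replace(" ", "")
    elements = []
    pending = (0, 0)
    pos = 0
    while pos < len(cleaned):
        m = _TOKEN.match(cleaned, pos)
        if m is None:
            raise ValueError(f"cannot parse motif at {cleaned[pos:]!r}")
        alt, single, lo, hi = m.groups()
        if lo is not None:
            lo_i = int(lo)
            hi_i = int(hi) if hi is not None else lo_i
            pending = (pending[0] + lo_i, pending[1] + hi_i)
        else:
            residues = frozenset(alt if alt else single)
            elements.append((residues, pending[0], pending[1]))
            pending = (0, 0)
        pos = m.end()
    if pending != (0, 0):
        raise ValueError("motif may not end with a spacer run")
    return MotifPattern(elements=tuple(elements), text=text)


@dataclass
class MotifHit:
    protein_id: str
    start: int  # offset of the first anchor
    end: int  # offset one past the last anchor
    matched_anchor_positions: list[int] = field(default_factory=list)


def scan_protein_motif(
    protein: ProteinSeq, pattern: MotifPattern
) -> list[MotifHit]:
    """All placements of a flexible-gap motif in a protein.

    Every combination of anchor positions whose inter-anchor gaps lie
    within the declared ranges is reported; overlapping matches are
    allowed. Hits are ordered by start, then by gap lengths
    (shortest-gap placements first).
    """
    seq = protein.residues
    elements = pattern.elements
    hits: list[MotifHit] = []

    def extend(anchor_idx: int, positions: list[int]) -> None:
        if anchor_idx == len(elements):
            hits.append(
                MotifHit(
                    protein_id=protein.id,
                    start=positions[0],
                    end=positions[-1] + 1,
                    matched_anchor_positions=list(positions),
                )
            )
            return
        residues, lo, hi = elements[anchor_idx]
        prev = positions[-1]
        for gap in range(lo, hi + 1):
            pos = prev + 1 + gap
            if pos >= len(seq):
                break
            if seq[pos] in residues:
                extend(anchor_idx + 1, positions + [pos])

    first_residues = elements[0][0]
    for start in range(len(seq)):
        if seq[start] in first_residues:
            extend(1, [start])
    return hits


#: C/H zinc-coordination pattern of invertebrate PHD fingers.
INVERTEBRATE_PHD = parse_motif("Cx4-7Cx14-16Cx2-4Cx4Hx2Cx11-18Cx2C")
#: C/H pattern of jawed-vertebrate PHD fingers (note the CC start and H end).
VERTEBRATE_PHD = parse_motif("CCx2Cx22Cx5-6Hx2Hx2Cx19Cx2H")

#: Zinc-binding motif of the RAG1L C-terminal tail (CTT*).
CTT_MOTIF = parse_motif("Cx2Cx3GHx4C")


@dataclass
class PHDClassification:
    label: str  # invertebrate_type | vertebrate_type | neither
    ambiguous: bool = False  # both patterns matched


def classify_phd(protein_segment: ProteinSeq) -> PHDClassification:
    """Classify a PHD-finger segment by its C/H zinc-coordination pattern.

    ``invertebrate_type`` when only the invertebrate pattern matches,
    ``vertebrate_type`` for the converse; ``neither`` otherwise (a segment
    matching both is flagged ambiguous).
    """
    if len(protein_segment) > 200:
        raise ValueError("PHD segment must be <= 200 residues")
    inv = bool(scan_protein_motif(protein_segment, INVERTEBRATE_PHD))
    ver = bool(scan_protein_motif(protein_segment, VERTEBRATE_PHD))
    if inv and not ver:
        return PHDClassification("invertebrate_type")
    if ver and not inv:
        return PHDClassification("vertebrate_type")
    if inv and ver:
        return PHDClassification("neither", ambiguous=True)
    return PHDClassification("neither")
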