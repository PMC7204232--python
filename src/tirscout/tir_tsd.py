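"""TIR-pair calling, TSD validation, and element assembly/classification.

A candidate cassette is promoted to a transposable element only when three
stringent conditions hold: (1) an inter-copy homology drop on both sides of
the cassette, (2) an inverted repeat with > 50% identity at the two drop
sites, and (3) a 3-8 bp target-site duplication flush against the inverted
repeat termini. Condition 3 discriminates true TIRs from a premature end of
a shared cassette.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import pandas as pd

from .align import PairwiseAlignment, ScoringScheme, align_local
from .boundary import LEFT, RIGHT, BoundaryCall
from .seq_model import CandidateLocus, GenomicContig, Interval, revcomp

Configuration = str  # complete | missing_one_tir | missing_both_tirs |
#                      solitary_gene | non_autonomous | solitary_tir
Status = str  # potentially_active | fossilized | candidate_domesticated | unknown


@dataclass
class TIRPair:
    """A called terminal-inverted-repeat pair.

    ``ir_identity`` is identical columns / alignment columns of ``tir5``
    aligned against ``revcomp(tir3)`` (gaps count against identity).
    """

    tir5: Interval
    tir3: Interval
    seq5: str
    seq3: str
    ir_identity: float
    ir_alignment: PairwiseAlignment
    score: float

    @property
    def length5(self) -> int:
        return len(self.tir5)

    @property
    def length3(self) -> int:
        return len(self.tir3)

    @property
    def cac_termini(self) -> int:
        """How many of the two outer termini begin with 5'-CAC."""
        n = 0
        if self.seq5.startswith("CAC"):
            n += 1
        if revcomp(self.seq3).startswith("CAC"):
            n += 1
        return n


@dataclass
class TSDCall:
    left_seq: str
    right_seq: str
    length: int
    mismatches: int
    left_interval: Optional[Interval] = None
    right_interval: Optional[Interval] = None
    reason: Optional[str] = None

    def __post_init__(self) -> None:
        if self.length and not (3 <= self.length <= 8):
            raise ValueError("TSD length must be in [3, 8]")


@dataclass
class ElementAnnotation:
    """An assembled element: locus, TIR pair, TSD, configuration, status."""

    locus: Optional[CandidateLocus]
    tir_pair: Optional[TIRPair] = None
    tsd: Optional[TSDCall] = None
    configuration: Configuration = "missing_both_tirs"
    status: Status = "unknown"
    element_span: Optional[Interval] = None
    boundaries: Optional[dict] = None
    notes: str = ""

    @property
    def locus_id(self) -> str:
        if self.locus is not None:
            return self.locus.locus_id
        return self.notes or "scan_element"


def find_inverted_repeat(
    left_window: str,
    right_window: str,
    scheme: ScoringScheme,
    min_identity: float = 0.5,
    len_range: tuple[int, int] = (10, 1000),
    search_radius: int = 150,
    contig_id: str = "window",
    left_offset: int = 0,
    right_offset: int = 0,
    max_reports: int = 5,
) -> list[TIRPair]:
    """Search two boundary windows for an inverted-repeat pair.

    ``left_window`` is aligned locally against ``revcomp(right_window)``;
    candidates whose identity exceeds ``min_identity`` and whose arm lengths
    fall within ``len_range`` are returned best-first. Ranking is by
    alignment score, then by the number of outer termini starting with
    5'-CAC (the conserved first 3 bp of the heptamer-like terminus, used
    only as a tie-break), then by total length.

    ``left_offset``/``right_offset`` place the windows on a contig so the
    reported intervals are in contig coordinates.
    """
    ir_min, ir_max = len_range
    if min(len(left_window), len(right_window)) < ir_min:
        raise ValueError("search window shorter than minimum TIR length")
    rc_right = revcomp(right_window)
    candidates: list[TIRPair] = []
    for aln in align_local(left_window, rc_right, scheme, max_reports=max_reports):
        identity = aln.identity()
        len5 = aln.a_end - aln.a_start
        len3 = aln.b_end - aln.b_start
        if identity <= min_identity:
            continue
        if not (ir_min <= len5 <= ir_max and ir_min <= len3 <= ir_max):
            continue
        # b coordinates are in revcomp(right_window); map back
        t3_start = len(right_window) - aln.b_end
        t3_end = len(right_window) - aln.b_start
        tir5 = Interval(
            contig_id, left_offset + aln.a_start, left_offset + aln.a_end
        )
        tir3 = Interval(contig_id, right_offset + t3_start, right_offset + t3_end)
        candidates.append(
            TIRPair(
                tir5=tir5,
                tir3=tir3,
                seq5=left_window[aln.a_start : aln.a_end],
                seq3=right_window[t3_start:t3_end],
                ir_identity=identity,
                ir_alignment=aln,
                score=aln.score,
            )
        )
    candidates.sort(
        key=lambda c: (c.score, c.cac_termini, c.length5 + c.length3), reverse=True
    )
    return candidates


def _hamming(a: str, b: str) -> int:
    # N never matches, including N vs N
    return sum(1 for x, y in zip(a, b) if x != y or x == "N" or y == "N")


def find_tsd(
    contig: GenomicContig,
    element_span: Interval,
    len_range: tuple[int, int] = (3, 8),
    max_mismatch: int = 0,
) -> Optional[TSDCall]:
    """Direct-repeat check flush against the element ends, longest k first.

    Compares the k-mer immediately left of the element with the k-mer
    immediately right of it for k from ``len_range[1]`` down to
    ``len_range[0]``; returns the longest k with <= ``max_mismatch``
    mismatches, or None. Insufficient flanking sequence yields None with
    reason ``"contig_edge"``.
    """
    k_min, k_max = len_range
    seq = contig.residues
    flank = min(element_span.start, len(seq) - element_span.end)
    if flank < k_min:
        return TSDCall("", "", 0, 0, reason="contig_edge") if flank >= 0 else None
    for k in range(min(k_max, flank), k_min - 1, -1):
        left = seq[element_span.start - k : element_span.start]
        right = seq[element_span.end : element_span.end + k]
        mm = _hamming(left, right)
        if mm <= max_mismatch:
            return TSDCall(
                left_seq=left,
                right_seq=right,
                length=k,
                mismatches=mm,
                left_interval=Interval(
                    contig.id, element_span.start - k, element_span.start
                ),
                right_interval=Interval(
                    contig.id, element_span.end, element_span.end + k
                ),
            )
    return None


def refine_element_termini(
    contig: GenomicContig,
    tir_pair: TIRPair,
    len_range: tuple[int, int] = (3, 8),
    max_mismatch: int = 0,
    slack_out: int = 4,
    slack_in: int = 3,
    left_edge_hint: Optional[int] = None,
    right_edge_hint: Optional[int] = None,
    hint_tolerance: int = 6,
) -> tuple[TIRPair, Optional[TSDCall]]:
    """Fine-tune element termini so a TSD can sit flush against them.

    The inverted-repeat alignment fixes the element ends only to within a
    few bp: a substitution near the tip of a TIR is trimmed by local
    alignment (the true termini lie outward), while a chance match into the
    duplicated target site extends it (the true termini lie inward). The
    outermost alignment column pairs the 5' TIR start with the 3' TIR end,
    so either effect moves *both* element edges by the same column count;
    only diagonal adjustments ``d`` (positive = outward) are scanned, and
    for each the longest flush TSD wins.

    To keep chance direct repeats from exploiting the enlarged search
    space, the required duplication length grows with the adjustment:
    flush termini (d = 0) accept any TSD in ``len_range``, small
    adjustments (|d| <= 2) require >= 4 bp, larger ones >= 5 bp (the
    modal TSD length of this transposon superfamily).

    When single-base boundary estimates are supplied as edge hints, the
    adjustment range is derived from them, and the hints must agree with
    the inverted-repeat diagonal (within ``hint_tolerance``) - otherwise
    the repeat is inconsistent with the homology drops and only flush
    termini (d = 0) are tried. Without hints a fixed
    ``[-slack_in, +slack_out]`` range is scanned.

    Qualifying adjustments are ranked by how many termini begin with the
    conserved 5'-CAC, then by closeness to the boundary-implied shift,
    then by TSD length. CAC ranks first because an inward mis-adjustment
    by one base manufactures a spurious longer duplication out of the
    repeat's own complementary tips (the C and G it strips from the two
    ends rejoin the flanks), and such termini never retain the CAC;
    hint proximity ranks above length because a chance longer duplication
    at some other adjustment must not outrank the duplication sitting
    where the homology drops say the element ends. Returns the adjusted
    pair and its TSD, or the original pair and None.
    """
    center = 0.0
    if left_edge_hint is not None and right_edge_hint is not None:
        d_left = tir_pair.tir5.start - left_edge_hint  # outward shift per hint
        d_right = right_edge_hint - tir_pair.tir3.end
        if abs(d_left - d_right) <= hint_tolerance:
            center = min(max((d_left + d_right) / 2.0, -slack_in), slack_out)
            c = round(center)
            # the hinted window plus a symmetric core: the repeat can
            # overrun a near-palindromic duplication in either direction
            # even when the boundary hints point elsewhere
            d_values = sorted(
                {*range(c - 4, c + 5), *range(-6, 7)}
                & set(range(-slack_in, slack_out + 1))
            )
        else:
            d_values = list(range(-slack_in, slack_out + 1))
    else:
        d_values = list(range(-slack_in, slack_out + 1))
    span0_start = tir_pair.tir5.start
    span0_end = tir_pair.tir3.end
    contig_id = tir_pair.tir5.contig_id
    k_min, k_max = len_range

    def required_k(d: int) -> int:
        if d == 0:
            return k_min
        return max(k_min, 4 if abs(d) <= 2 else 5)

    candidates: list[tuple[int, int, int, "TSDCall"]] = []
    for d in d_values:
        start = span0_start - d
        end = span0_end + d
        if start < 0 or end > len(contig) or start >= end:
            continue
        tsd = find_tsd(
            contig, Interval(contig_id, start, end), len_range, max_mismatch
        )
        if tsd is None or tsd.length < required_k(d):
            continue
        seq = contig.residues
        cac = int(seq[start : start + 3] == "CAC") + int(
            revcomp(seq[end - 3 : end]) == "CAC"
        )
        candidates.append((tsd.length, cac, d, tsd))
    if not candidates:
        return tir_pair, None
    candidates.sort(key=lambda c: (-c[1], abs(c[2] - center), -c[0], c[2] < center))
    _, _, d, tsd = candidates[0]
    if d == 0:
        return tir_pair, tsd
    start = span0_start - d
    end = span0_end + d
    tir5 = Interval(contig_id, start, max(tir_pair.tir5.end, start + 1))
    tir3 = Interval(contig_id, min(tir_pair.tir3.start, end - 1), end)
    adjusted = replace(
        tir_pair,
        tir5=tir5,
        tir3=tir3,
        seq5=contig.residues[tir5.start : tir5.end],
        seq3=contig.residues[tir3.start : tir3.end],
    )
    return adjusted, tsd


def boundary_anchored_ir(
    contig: GenomicContig,
    left_edge: int,
    right_edge: int,
    scheme: ScoringScheme,
    min_identity: float = 0.5,
    len_range: tuple[int, int] = (10, 1000),
    max_probe_len: int = 40,
) -> Optional[TIRPair]:
    """Qualify an inverted repeat anchored directly at the homology drops.

    A heavily diverged repeat can fail local-alignment retrieval (its
    high-identity fragments fall below the minimum repeat length), yet
    still satisfy the >50%-identity criterion over its full extent. This
    probe aligns the terminal segments starting at the two boundary edges
    globally for a range of lengths and reports the best-identity probe
    above ``min_identity``, with termini at the edges; exact termini are
    settled later by the TSD search. Returns None when no probe length
    qualifies.
    """
    from .align import align_global  # local import avoids cycle at module load

    best: Optional[TIRPair] = None
    hi = min(max_probe_len, len_range[1])
    for length in range(len_range[0], hi + 1):
        if left_edge + length > len(contig) or right_edge - length < 0:
            break
        seq5 = contig.residues[left_edge : left_edge + length]
        seq3 = contig.residues[right_edge - length : right_edge]
        aln = align_global(seq5, revcomp(seq3), scheme)
        identity = aln.identity()
        if identity <= min_identity:
            continue
        if best is None or (identity, aln.score) > (
            best.ir_identity,
            best.score,
        ):
            best = TIRPair(
                tir5=Interval(contig.id, left_edge, left_edge + length),
                tir3=Interval(contig.id, right_edge - length, right_edge),
                seq5=seq5,
                seq3=seq3,
                ir_identity=identity,
                ir_alignment=aln,
                score=aln.score,
            )
    return best


def assemble_element(
    locus: CandidateLocus,
    boundary_calls: dict[str, Optional[BoundaryCall]],
    tir_candidates: Sequence[TIRPair],
    tsd: Optional[TSDCall],
) -> ElementAnnotation:
    """Apply the three-condition rule and assign a configuration.

    complete requires a homology drop on both sides, a qualifying TIR pair,
    and a TSD. A qualifying TIR pair around an interior with no annotated
    gene is a non-autonomous element. Partial evidence downgrades to
    missing_one_tir / missing_both_tirs; a locus carrying a single gene and
    no complete element evidence is a solitary_gene record.
    """
    left = boundary_calls.get(LEFT)
    right = boundary_calls.get(RIGHT)
    n_drops = sum(c is not None and c.confident for c in (left, right))
    tir_pair = tir_candidates[0] if tir_candidates else None
    has_tsd = tsd is not None and tsd.length > 0

    span = None
    if tir_pair is not None:
        span = Interval(
            tir_pair.tir5.contig_id, tir_pair.tir5.start, tir_pair.tir3.end
        )

    n_genes = len(locus.genes)
    if n_drops == 2 and tir_pair is not None and has_tsd:
        configuration = "non_autonomous" if n_genes == 0 else "complete"
    elif n_genes == 1:
        configuration = "solitary_gene"
        span = None
    elif n_drops == 1:
        configuration = "missing_one_tir"
        span = None
    else:
        configuration = "missing_both_tirs"
        span = None

    ann = ElementAnnotation(
        locus=locus,
        tir_pair=tir_pair if configuration in ("complete", "non_autonomous") else None,
        tsd=tsd if configuration in ("complete", "non_autonomous") else None,
        configuration=configuration,
        element_span=span,
        boundaries={LEFT: left, RIGHT: right},
    )
    ann.status = classify_status(ann)
    return ann


def classify_status(annotation: ElementAnnotation) -> Status:
    """Element status from configuration and gene intactness.

    Any disrupted gene (premature stop or truncation) marks the copy as
    fossilized. A complete element with both genes intact is potentially
    active. An intact convergent gene pair with no detectable TIRs is a
    candidate for molecular domestication. Everything else is unknown.
    """
    locus = annotation.locus
    if locus is None:
        return "unknown"
    intactness = []
    if locus.gene1 is not None:
        intactness.append(locus.gene1_intactness)
    if locus.gene2 is not None:
        intactness.append(locus.gene2_intactness)
    if any(i in ("stop_disrupted", "truncated") for i in intactness):
        return "fossilized"
    both_intact = len(intactness) == 2 and all(i == "intact" for i in intactness)
    if annotation.configuration == "complete" and both_intact:
        return "potentially_active"
    if annotation.configuration == "missing_both_tirs" and both_intact:
        return "candidate_domesticated"
    return "unknown"


def element_table(annotations: Sequence[ElementAnnotation]) -> pd.DataFrame:
    rows = []
    for ann in annotations:
        tp = ann.tir_pair
        rows.append(
            {
                "locus_id": ann.locus_id,
                "configuration": ann.configuration,
                "status": ann.status,
                "element_start": ann.element_span.start if ann.element_span else -1,
                "element_end": ann.element_span.end if ann.element_span else -1,
                "tir5_len": tp.length5 if tp else 0,
                "tir3_len": tp.length3 if tp else 0,
                "ir_identity": round(tp.ir_identity, 4) if tp else float("nan"),
                "tsd_seq": ann.tsd.left_seq if ann.tsd else "",
                "tsd_len": ann.tsd.length if ann.tsd else 0,
            }
        )
    return pd.DataFrame(rows)
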