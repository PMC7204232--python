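"""Element/host boundary detection by inter-copy homology drop.

Copies of a transposable element inserted at different genomic sites share
sequence inside the element but not in the flanking host DNA. Aligning the
margins of two candidate cassettes therefore shows high windowed identity
from the cassette edge outward until the element ends, then an abrupt drop
("homology drop") at the transition into unrelated flanks. The boundary is
detected on each side of the cassette, once per partner copy, and the
per-partner calls are consolidated by clustering.

Margins are always oriented outward from the cassette: position 0 is the
base adjacent to the cassette edge, increasing away from the element
interior. For the left side this means the reverse complement of the top
strand. Margins are taken from the cassette's outermost gene coordinates,
not from any prior TIR guess, so the TIRs themselves fall inside the
homologous run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .align import PairwiseAlignment, ScoringScheme, align_global, identity_profile
from .seq_model import CandidateLocus, GenomicContig, revcomp

LEFT = "left_of_cassette"
RIGHT = "right_of_cassette"

#: Sides shorter than this after contig truncation are marked unknown rather
#: than force-called (WGS loci can sit at the margin of a scaffold).
MIN_USABLE_MARGIN = 500


@dataclass
class MarginPair:
    """Two outward-oriented margins from the same side of two cassette copies."""

    locus_a: CandidateLocus
    locus_b: CandidateLocus
    side: str
    seq_a: str
    seq_b: str
    margin_len: int = 3000
    truncated_a: bool = False
    truncated_b: bool = False

    def __post_init__(self) -> None:
        if self.side not in (LEFT, RIGHT):
            raise ValueError(f"invalid side {self.side!r}")
        if len(self.seq_a) > self.margin_len or len(self.seq_b) > self.margin_len:
            raise ValueError("margin sequence exceeds margin_len")


@dataclass
class BoundaryCall:
    locus_id: str
    side: str
    boundary_pos: int  # 0-based offset from the cassette edge into the margin
    inside_identity: float
    outside_identity: float
    support_count: int = 1
    confident: bool = False
    partner_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.boundary_pos < 0:
            raise ValueError("boundary_pos must be >= 0")

    @property
    def contrast(self) -> float:
        return self.inside_identity - self.outside_identity


def extract_margin(
    contig: GenomicContig, locus: CandidateLocus, side: str, margin_len: int = 3000
) -> tuple[str, bool]:
    """Outward-oriented margin adjacent to a cassette edge.

    Returns ``(sequence, truncated)``; ``truncated`` is True when the contig
    ends before ``margin_len`` bases.
    """
    cas = locus.cassette
    if side == LEFT:
        start = max(0, cas.start - margin_len)
        seq = revcomp(contig.residues[start : cas.start])
        truncated = (cas.start - start) < margin_len
    elif side == RIGHT:
        end = min(len(contig), cas.end + margin_len)
        seq = contig.residues[cas.end : end]
        truncated = (end - cas.end) < margin_len
    else:
        raise ValueError(f"invalid side {side!r}")
    return seq, truncated


def make_margin_pair(
    contig_a: GenomicContig,
    locus_a: CandidateLocus,
    contig_b: GenomicContig,
    locus_b: CandidateLocus,
    side: str,
    margin_len: int = 3000,
) -> MarginPair:
    seq_a, trunc_a = extract_margin(contig_a, locus_a, side, margin_len)
    seq_b, trunc_b = extract_margin(contig_b, locus_b, side, margin_len)
    return MarginPair(
        locus_a=locus_a,
        locus_b=locus_b,
        side=side,
        seq_a=seq_a,
        seq_b=seq_b,
        margin_len=margin_len,
        truncated_a=trunc_a,
        truncated_b=trunc_b,
    )


def _column_to_seq_a_pos(aln: PairwiseAlignment, column: int) -> int:
    """Alignment column -> position in seq_a (gap columns skipped)."""
    prefix = aln.aligned_a[:column]
    return aln.a_start + len(prefix) - prefix.count("-")


def _column_to_seq_b_pos(aln: PairwiseAlignment, column: int) -> int:
    prefix = aln.aligned_b[:column]
    return aln.b_start + len(prefix) - prefix.count("-")


def detect_homology_drop(
    pair: MarginPair,
    scheme: ScoringScheme,
    window: int = 31,
    t_high: float = 0.7,
    t_low: float = 0.4,
    min_run: int = 100,
) -> Optional[BoundaryCall]:
    """Locate the identity drop along a pair of outward-oriented margins.

    The two margins are aligned globally and profiled with a centered
    window. A call requires (i) a homologous run: windowed identity
    sustained at >= ``t_high`` for >= ``min_run`` columns starting at the
    cassette edge, and (ii) a drop: a later column where the profile falls
    below ``t_low`` and stays below ``t_high`` for >= ``min_run``/2 columns.
    The boundary is placed at the last column at or above ``t_high`` before
    that drop and reported in ``seq_a`` margin coordinates.

    Returns ``None`` when either margin is unusable, there is no homologous
    run at the edge, or the homology never drops.
    """
    if not (0 <= t_low < t_high <= 1):
        raise ValueError("need 0 <= t_low < t_high <= 1")
    if min(len(pair.seq_a), len(pair.seq_b)) < max(window, MIN_USABLE_MARGIN):
        if min(len(pair.seq_a), len(pair.seq_b)) < window:
            raise ValueError("margin shorter than profiling window")
        return None
    for seq in (pair.seq_a, pair.seq_b):
        if set(seq) <= {"N"}:
            return None

    aln = align_global(pair.seq_a, pair.seq_b, scheme)
    profile = identity_profile(aln, window)
    n = len(profile)

    high = profile >= t_high
    # homologous run must begin at (or within one window of) the cassette edge
    start = 0
    while start < min(window, n) and not high[start]:
        start += 1
    if start >= min(window, n) or not high[start]:
        return None
    run_end = start
    while run_end < n and high[run_end]:
        run_end += 1
    if run_end - start < min_run:
        return None

    # find the drop: first column after the run below t_low that stays
    # below t_high for at least min_run/2 columns
    stay = max(1, min_run // 2)
    drop_col = None
    i = run_end
    while i < n:
        if profile[i] < t_low:
            j_end = min(n, i + stay)
            if not high[i:j_end].any() and (j_end - i) >= min(stay, n - i):
                drop_col = i
                break
        i += 1
    if drop_col is None:
        return None

    # boundary = outer end of the last homologous stretch before the drop
    boundary_col = drop_col
    while boundary_col > start and not high[boundary_col - 1]:
        boundary_col -= 1

    # refine to single-base precision: the windowed profile blurs the
    # transition by ~window/2, and the gapped alignment inflates apparent
    # host-host identity by chasing chance matches with gaps. An ungapped
    # comparison at the offset the alignment implies at the coarse
    # boundary keeps unrelated flanks at background identity, so a
    # two-segment changepoint MLE pins the transition sharply.
    a_pos = _column_to_seq_a_pos(aln, boundary_col)
    b_pos = _column_to_seq_b_pos(aln, boundary_col)
    refined_pos = _refine_changepoint_ungapped(
        pair.seq_a, pair.seq_b, a_pos, b_pos - a_pos
    )

    # identities summarized over bounded windows flanking the boundary so
    # that a boundary mistakenly called inside the element shows a high
    # "outside" identity and loses on contrast during consolidation
    span = 300
    inside = (
        float(profile[max(0, boundary_col - span) : boundary_col].mean())
        if boundary_col
        else 0.0
    )
    outside = (
        float(profile[boundary_col : boundary_col + span].mean())
        if boundary_col < n
        else 0.0
    )
    return BoundaryCall(
        locus_id=pair.locus_a.locus_id,
        side=pair.side,
        boundary_pos=refined_pos,
        inside_identity=inside,
        outside_identity=outside,
        partner_id=pair.locus_b.locus_id,
    )


def _refine_changepoint_ungapped(
    seq_a: str, seq_b: str, a_pos: int, offset: int, radius: int = 150
) -> int:
    """Single-base boundary estimate by ungapped changepoint analysis.

    Compares ``seq_a[p]`` with ``seq_b[p + offset]`` around the coarse
    boundary ``a_pos``, modelling matches as Bernoulli(p_in) inside the
    element and Bernoulli(p_out) in the flanks, and returns the
    maximum-likelihood transition. Rates are estimated from the two sides
    of the coarse call and clipped away from 0/1.
    """
    lo = max(0, a_pos - radius, -offset)
    hi = min(len(seq_a), len(seq_b) - offset, a_pos + radius)
    if hi - lo < 10 or not (lo <= a_pos <= hi):
        return a_pos
    a_arr = np.frombuffer(seq_a[lo:hi].encode(), dtype="S1")
    b_arr = np.frombuffer(seq_b[lo + offset : hi + offset].encode(), dtype="S1")
    m = ((a_arr == b_arr) & (a_arr != b"N")).astype(np.float64)
    rel = a_pos - lo
    p_in = float(np.clip(m[:rel].mean() if rel else 0.9, 0.55, 0.995))
    p_out = float(np.clip(m[rel:].mean() if rel < len(m) else 0.25, 0.05, 0.45))
    if p_out >= p_in:
        return a_pos
    gain = m * np.log(p_in / p_out) + (1 - m) * np.log((1 - p_in) / (1 - p_out))
    scores = np.concatenate([[0.0], np.cumsum(gain)])
    best = lo + int(np.argmax(scores))
    if best <= lo + 3 or best >= hi - 3:  # degenerate fit at the window edge
        return a_pos
    return best


def consolidate_boundaries(
    calls: Sequence[BoundaryCall], tolerance: int = 25
) -> BoundaryCall:
    """Merge per-partner boundary calls for one locus/side.

    Positions are clustered by single linkage with gap <= ``tolerance``; the
    call at the median of the largest cluster is returned with
    ``support_count`` = cluster size. Ties between equally large clusters go
    to the cluster whose best call has the larger inside/outside identity
    contrast. A call is confident with support >= 2, or alone with
    contrast >= 0.3.
    """
    if not calls:
        raise ValueError("no boundary calls to consolidate")
    ordered = sorted(calls, key=lambda c: c.boundary_pos)
    clusters: list[list[BoundaryCall]] = [[ordered[0]]]
    for call in ordered[1:]:
        if call.boundary_pos - clusters[-1][-1].boundary_pos <= tolerance:
            clusters[-1].append(call)
        else:
            clusters.append([call])
    best = max(
        clusters, key=lambda cl: (len(cl), max(c.contrast for c in cl))
    )
    median_call = sorted(best, key=lambda c: c.boundary_pos)[(len(best) - 1) // 2]
    support = len(best)
    confident = support >= 2 or median_call.contrast >= 0.3
    return BoundaryCall(
        locus_id=median_call.locus_id,
        side=median_call.side,
        boundary_pos=median_call.boundary_pos,
        inside_identity=median_call.inside_identity,
        outside_identity=median_call.outside_identity,
        support_count=support,
        confident=confident,
        partner_id=median_call.partner_id,
    )


def boundary_table(calls: Sequence[BoundaryCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "locus_id": c.locus_id,
                "side": c.side,
                "boundary_pos": c.boundary_pos,
                "inside_identity": round(c.inside_identity, 4),
                "outside_identity": round(c.outside_identity, 4),
                "support_count": c.support_count,
                "confident": c.confident,
            }
            for c in calls
        ]
    )
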