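"""Genome scan with short TIR-containing margin queries.

Re-implements the nucleotide rescans used to find solitary TIRs and
non-autonomous elements as an internal seed-and-extend search: exact-word
seeding on both strands, X-drop ungapped extension, gapped refinement with
the local aligner, and Karlin-Altschul e-values.

E-values use ``E = K * m * n * exp(-lambda * S)`` with the ungapped
(lambda, K) of the scoring scheme computed from its score distribution
under uniform base composition; the same parameters stand in for the
gapped search (a documented approximation), so e-values are comparable
within a run but not bit-identical to any external search tool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .align import ScoringScheme, align_local
from .seq_model import GenomicContig, Interval, revcomp
from .tir_tsd import ElementAnnotation, TIRPair, find_tsd


@dataclass
class ScanHit:
    query_id: str
    target: Interval  # forward-strand coordinates; strand records orientation
    score: float
    identity: float
    evalue: float
    q_start: int = 0
    q_end: int = 0

    def __post_init__(self) -> None:
        if self.score <= 0:
            raise ValueError("hit score must be > 0")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")


@lru_cache(maxsize=16)
def karlin_altschul_params(
    match: int, mismatch: int, p_match: float = 0.25
) -> tuple[float, float, float]:
    """Ungapped (lambda, K, H) for a match/mismatch scheme.

    lambda solves ``sum_s p(s) exp(lambda s) = 1`` over the score
    distribution of random letter pairs; K follows the classical series
    formula evaluated by convolving the score distribution (the same route
    the standard search tools take for ungapped statistics).
    """
    probs = {match: p_match, mismatch: 1.0 - p_match}

    def moment(lam: float) -> float:
        return sum(p * math.exp(lam * s) for s, p in probs.items()) - 1.0

    lam = brentq(moment, 1e-9, 20.0)
    scores = sorted(probs)
    lo, hi = scores[0], scores[-1]
    delta = math.gcd(*(abs(s) for s in scores))
    H = lam * sum(s * p * math.exp(lam * s) for s, p in probs.items())

    base = np.zeros(hi - lo + 1)
    for s, p in probs.items():
        base[s - lo] = p
    sigma = 0.0
    cur = None
    cur_lo = 0
    for k in range(1, 61):
        if cur is None:
            cur, cur_lo = base.copy(), lo
        else:
            cur, cur_lo = np.convolve(cur, base), cur_lo + lo
        vals = np.arange(cur_lo, cur_lo + len(cur))
        pos = cur[vals >= 0].sum()
        neg = vals < 0
        sigma += (pos + (cur[neg] * np.exp(lam * vals[neg])).sum()) / k
    K = math.exp(-2.0 * sigma) * delta * lam / (H * (1.0 - math.exp(-lam * delta)))
    return lam, K, H


def evalue(score: float, m: int, n: int, scheme: ScoringScheme) -> float:
    lam, K, _ = karlin_altschul_params(scheme.match, scheme.mismatch)
    return K * m * n * math.exp(-lam * score)


def _ungapped_extend(
    query: str, target: str, qpos: int, tpos: int, word: int,
    match: int, mismatch: int, x_drop: int,
) -> tuple[int, int, int]:
    """Extend an exact word seed in both directions with X-drop.

    Returns (q_start, q_end, score) of the best-scoring ungapped segment.
    """
    score = word * match
    best = score
    # rightward
    qi, ti = qpos + word, tpos + word
    best_right = qi
    while qi < len(query) and ti < len(target):
        a, b = query[qi], target[ti]
        score += match if (a == b and a != "N") else mismatch
        if score > best:
            best, best_right = score, qi + 1
        if best - score > x_drop:
            break
        qi += 1
        ti += 1
    # leftward
    score = best
    qi, ti = qpos - 1, tpos - 1
    best_left = qpos
    while qi >= 0 and ti >= 0:
        a, b = query[qi], target[ti]
        score += match if (a == b and a != "N") else mismatch
        if score > best:
            best, best_left = score, qi
        if best - score > x_drop:
            break
        qi -= 1
        ti -= 1
    return best_left, best_right, best


def _index_words(seq: str, word: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - word + 1):
        w = seq[i : i + word]
        if "N" in w:
            continue
        index.setdefault(w, []).append(i)
    return index


def scan_margins(
    queries: Sequence[tuple[str, str] | str],
    genome: Sequence[GenomicContig],
    scheme: Optional[ScoringScheme] = None,
    word_size: int = 11,
    evalue_max: float = 1e-3,
    x_drop: int = 20,
) -> list[ScanHit]:
    """Search TIR-containing margin queries against a genome.

    ``queries`` are (id, sequence) pairs (or bare sequences, auto-named) of
    50-300 bp; both strands are searched. Hits with e-value <=
    ``evalue_max`` are returned sorted by ascending e-value; overlapping
    hits of one query on one strand keep only the best score.
    """
    scheme = scheme or ScoringScheme()
    named = [
        q if isinstance(q, tuple) else (f"query_{i}", q)
        for i, q in enumerate(queries)
    ]
    for qid, seq in named:
        if len(seq) < word_size:
            raise ValueError(f"query {qid!r} shorter than word size {word_size}")
        if not (50 <= len(seq) <= 300):
            raise ValueError(f"query {qid!r} must be 50-300 bp")

    total_n = sum(len(c) for c in genome)
    indexes = [(c, _index_words(c.residues, word_size)) for c in genome]

    raw_hits: list[ScanHit] = []
    for qid, qseq in named:
        for strand in "+-":
            oriented = qseq if strand == "+" else revcomp(qseq)
            for contig, index in indexes:
                target = contig.residues
                covered: list[tuple[int, int]] = []  # extended target segments
                for qpos in range(len(oriented) - word_size + 1):
                    w = oriented[qpos : qpos + word_size]
                    for tpos in index.get(w, ()):
                        # a seed inside an already-extended segment cannot
                        # yield a better non-overlapping hit (overlaps are
                        # merged best-first downstream anyway)
                        if any(s <= tpos < e for s, e in covered):
                            continue
                        q_lo, q_hi, seg_score = _ungapped_extend(
                            oriented, target, qpos, tpos, word_size,
                            scheme.match, scheme.mismatch, x_drop,
                        )
                        t_lo = tpos - (qpos - q_lo)
                        t_hi = tpos + (q_hi - qpos)
                        covered.append((t_lo, t_hi))
                        if seg_score <= 0:
                            continue
                        # gapped refinement on a padded window
                        w_lo = max(0, t_lo - 50)
                        w_hi = min(len(target), t_hi + 50)
                        local = align_local(
                            oriented, target[w_lo:w_hi], scheme, max_reports=1
                        )
                        if not local:
                            continue
                        aln = local[0]
                        ev = evalue(aln.score, len(qseq), total_n, scheme)
                        if ev > evalue_max:
                            continue
                        t_start = w_lo + aln.b_start
                        t_end = w_lo + aln.b_end
                        if strand == "+":
                            q_start, q_end = aln.a_start, aln.a_end
                        else:
                            q_start = len(qseq) - aln.a_end
                            q_end = len(qseq) - aln.a_start
                        raw_hits.append(
                            ScanHit(
                                query_id=qid,
                                target=Interval(contig.id, t_start, t_end, strand),
                                score=aln.score,
                                identity=aln.identity(),
                                evalue=ev,
                                q_start=q_start,
                                q_end=q_end,
                            )
                        )
    return _merge_hits(raw_hits)


def _merge_hits(hits: list[ScanHit]) -> list[ScanHit]:
    """Drop hits overlapping a better hit of the same query and strand."""
    hits = sorted(hits, key=lambda h: (-h.score, h.evalue))
    kept: list[ScanHit] = []
    for h in hits:
        if any(
            k.query_id == h.query_id
            and k.target.strand == h.target.strand
            and k.target.overlaps(h.target)
            for k in kept
        ):
            continue
        kept.append(h)
    kept.sort(key=lambda h: (h.evalue, -h.score))
    return kept


def pair_solitary_tirs(
    hits: Sequence[ScanHit],
    tir_annotations: Sequence[ElementAnnotation],
    max_span: int = 20_000,
    genome: Optional[Sequence[GenomicContig]] = None,
    scheme: Optional[ScoringScheme] = None,
    tsd_len_range: tuple[int, int] = (3, 8),
    query_ends: Optional[dict[str, str]] = None,
) -> list[ElementAnnotation]:
    """Pair opposite-orientation TIR hits into non-autonomous elements.

    Hits overlapping an already-annotated element are ignored. Each hit is
    assigned the element end it represents: with ``query_ends`` mapping
    query ids to ``"tir5"``/``"tir3"`` (which end of the source element the
    query came from), a forward hit of a 5'-end query is a left element
    end, a reverse hit a right end, and vice versa for 3'-end queries;
    without the mapping, forward means left. Within one contig, each
    left-end hit is paired with the nearest following right-end hit within
    ``max_span``; each pair is TSD-checked (a pair is reported as
    non_autonomous whether or not a TSD is found, with the TSD recorded
    when present). Hits with no partner become solitary_TIR records.
    """
    scheme = scheme or ScoringScheme()
    known_spans = [
        a.element_span for a in tir_annotations if a.element_span is not None
    ]
    contigs = {c.id: c for c in genome} if genome else {}

    def end_of(h: ScanHit) -> str:
        source_end = (query_ends or {}).get(h.query_id, "tir5")
        if source_end == "tir5":
            return "left" if h.target.strand == "+" else "right"
        return "right" if h.target.strand == "+" else "left"

    usable: list[ScanHit] = []
    for h in sorted(hits, key=lambda h: (-h.score, h.evalue)):
        if any(h.target.overlaps(s) for s in known_spans):
            continue
        # queries from different source copies (and both element ends)
        # hit the same TIR occurrence; keep the best
        if any(h.target.overlaps(k.target) for k in usable):
            continue
        usable.append(h)
    by_contig: dict[str, list[ScanHit]] = {}
    for h in usable:
        by_contig.setdefault(h.target.contig_id, []).append(h)

    annotations: list[ElementAnnotation] = []
    for contig_id, contig_hits in sorted(by_contig.items()):
        contig_hits.sort(key=lambda h: h.target.start)
        used: set[int] = set()
        for i, h5 in enumerate(contig_hits):
            if i in used or end_of(h5) != "left":
                continue
            partner = None
            for j in range(i + 1, len(contig_hits)):
                h3 = contig_hits[j]
                if j in used or end_of(h3) != "right":
                    continue
                if h3.target.end - h5.target.start > max_span:
                    break
                if h3.target.start >= h5.target.end:
                    partner = j
                    break
            if partner is None:
                continue
            h3 = contig_hits[partner]
            used.update((i, partner))
            span = Interval(contig_id, h5.target.start, h3.target.end)
            tsd = None
            tir_pair = None
            contig = contigs.get(contig_id)
            if contig is not None:
                # hit extents are alignment-trimmed by a few bp; look for a
                # flush TSD at small terminus adjustments (stronger
                # duplication evidence required off the flush position)
                found = []
                for d5 in range(-6, 7):
                    for d3 in range(-6, 7):
                        start, end = span.start - d5, span.end + d3
                        if start < 0 or end > len(contig) or start >= end:
                            continue
                        total = abs(d5) + abs(d3)
                        required = (
                            tsd_len_range[0]
                            if total == 0
                            else (4 if total <= 2 else 5)
                        )
                        cand = find_tsd(
                            contig, Interval(contig_id, start, end), tsd_len_range
                        )
                        if cand is not None and cand.length >= required:
                            found.append((cand.length, -total, start, end, cand))
                if found:
                    found.sort(reverse=True)
                    _, _, start, end, tsd = found[0]
                    span = Interval(contig_id, start, end)
                left = contig.residues[h5.target.start : h5.target.end]
                right = contig.residues[h3.target.start : h3.target.end]
                local = align_local(left, revcomp(right), scheme, max_reports=1)
                if local:
                    tir_pair = TIRPair(
                        tir5=h5.target,
                        tir3=h3.target,
                        seq5=left,
                        seq3=right,
                        ir_identity=local[0].identity(),
                        ir_alignment=local[0],
                        score=local[0].score,
                    )
            annotations.append(
                ElementAnnotation(
                    locus=None,
                    tir_pair=tir_pair,
                    tsd=tsd,
                    configuration="non_autonomous",
                    status="unknown",
                    element_span=span,
                    notes=f"scan:{h5.query_id}",
                )
            )
        for i, h in enumerate(contig_hits):
            if i in used:
                continue
            annotations.append(
                ElementAnnotation(
                    locus=None,
                    configuration="solitary_tir",
                    status="unknown",
                    element_span=h.target,
                    notes=f"scan:{h.query_id}",
                )
            )
    return annotations


def hit_table(hits: Sequence[ScanHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "query_id": h.query_id,
                "contig_id": h.target.contig_id,
                "start": h.target.start,
                "end": h.target.end,
                "strand": h.target.strand,
                "score": h.score,
                "identity": round(h.identity, 4),
                "evalue": h.evalue,
            }
            for h in hits
        ]
    )
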