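"""Pipeline orchestration: boundaries -> TIR/TSD -> status -> rescans.

Stage order follows the comparative detection procedure: inter-copy
homology-drop boundaries first, then inverted-repeat calling at the drop
sites, TSD validation, element assembly and status classification, and
finally a genome-wide rescan with TIR-containing margins to pick up
solitary TIRs and non-autonomous elements. All stages are pure functions
of (inputs, config), so reruns are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import boundary as bd
from . import consensus_motif as cm
from . import margin_scan as ms
from . import tir_tsd as tt
from .align import ScoringScheme
from .seq_model import (
    CandidateLocus,
    GenomicContig,
    Interval,
    revcomp,
    write_gff3,
)

logger = logging.getLogger("tirscout")


@dataclass
class PipelineConfig:
    """Every tunable of the detection pipeline, serializable to YAML.

    Margin length defaults to 3000 bp (comparative margins of 2-3 kb);
    TIR identity must exceed 0.5; TSDs are 3-8 bp exact matches; rescan
    queries are 150 bp TIR-containing margins by default.
    """

    # margins / boundary detection
    margin_len: int = 3000
    window: int = 31
    t_high: float = 0.7
    t_low: float = 0.4
    min_run: int = 100
    tolerance: int = 25
    max_partners: int = 2  # partner copies compared per locus/side
    # DNA scoring
    match: int = 2
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    # TIR calling
    min_identity: float = 0.5
    ir_min_len: int = 10
    ir_max_len: int = 1000
    search_radius: int = 150
    terminus_slack_out: int = 12
    terminus_slack_in: int = 12
    boundary_agreement: int = 30  # max distance TIR termini may sit from the drops
    ir_max_reports: int = 30  # local IR alignments examined per boundary pair
    ir_refine_candidates: int = 3  # agreeing candidates tried for a flush TSD
    family_rescue: bool = True  # second pass with the recovered family TIR
    family_min_score_frac: float = 0.5  # of a perfect consensus self-match
    family_grid: int = 3  # per-side terminus adjustments tried in the rescue
    family_weak_score: int = 12  # weak consensus matches need positional support
    family_weak_radius: int = 25
    # TSD
    tsd_min_len: int = 3
    tsd_max_len: int = 8
    tsd_max_mismatch: int = 0
    # rescan
    query_len: int = 150
    word_size: int = 11
    evalue_max: float = 1e-3
    x_drop: int = 20
    max_pair_span: int = 20_000
    # consensus
    include_threshold: float = 0.25
    # conservation
    background: str = "blosum62"
    gap_penalty: int = 1
    conservation_window: int = 0
    seed: int = 0

    def scheme(self) -> ScoringScheme:
        return ScoringScheme(
            match=self.match,
            mismatch=self.mismatch,
            gap_open=self.gap_open,
            gap_extend=self.gap_extend,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class PipelineResult:
    annotations: list[tt.ElementAnnotation]
    boundary_calls: list[bd.BoundaryCall]
    scan_hits: list[ms.ScanHit]
    consensus: Optional[cm.IUPACConsensus]
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for ann in self.annotations:
            out[ann.configuration] = out.get(ann.configuration, 0) + 1
        return out


def detect_boundaries(
    contigs: dict[str, GenomicContig],
    loci: Sequence[CandidateLocus],
    config: PipelineConfig,
) -> dict[str, dict[str, Optional[bd.BoundaryCall]]]:
    """Consolidated boundary calls per locus and side.

    Each locus is compared against up to ``max_partners`` other copies
    (nearest in input order, wrapping around) on each side.
    """
    scheme = config.scheme()
    results: dict[str, dict[str, Optional[bd.BoundaryCall]]] = {}
    n = len(loci)
    for i, locus in enumerate(loci):
        partners = [
            loci[(i + k) % n] for k in range(1, min(config.max_partners, n - 1) + 1)
        ]
        results[locus.locus_id] = {}
        for side in (bd.LEFT, bd.RIGHT):
            calls = []
            for partner in partners:
                pair = bd.make_margin_pair(
                    contigs[locus.cassette.contig_id],
                    locus,
                    contigs[partner.cassette.contig_id],
                    partner,
                    side,
                    config.margin_len,
                )
                try:
                    call = bd.detect_homology_drop(
                        pair,
                        scheme,
                        window=config.window,
                        t_high=config.t_high,
                        t_low=config.t_low,
                        min_run=config.min_run,
                    )
                except ValueError:
                    call = None
                if call is not None:
                    calls.append(call)
            results[locus.locus_id][side] = (
                bd.consolidate_boundaries(calls, config.tolerance) if calls else None
            )
            if calls:
                c = results[locus.locus_id][side]
                logger.info(
                    "boundary %s/%s: pos=%d support=%d contrast=%.2f",
                    locus.locus_id, side, c.boundary_pos, c.support_count, c.contrast,
                )
    return results


def call_elements(
    contigs: dict[str, GenomicContig],
    loci: Sequence[CandidateLocus],
    boundaries: dict[str, dict[str, Optional[bd.BoundaryCall]]],
    config: PipelineConfig,
) -> list[tt.ElementAnnotation]:
    """TIR/TSD calling and assembly at previously detected boundaries."""
    scheme = config.scheme()
    annotations = []
    for locus in loci:
        contig = contigs[locus.cassette.contig_id]
        calls = boundaries.get(locus.locus_id, {})
        left, right = calls.get(bd.LEFT), calls.get(bd.RIGHT)
        candidates: list[tt.TIRPair] = []
        tsd = None
        if left is not None and right is not None:
            r = config.search_radius
            left_edge = locus.cassette.start - left.boundary_pos
            right_edge = locus.cassette.end + right.boundary_pos
            lw_lo = max(0, left_edge - r)
            rw_lo = max(0, right_edge - r)
            left_window = contig.residues[lw_lo : left_edge + r]
            right_window = contig.residues[rw_lo : right_edge + r]
            if (
                len(left_window) >= config.ir_min_len
                and len(right_window) >= config.ir_min_len
            ):
                candidates = tt.find_inverted_repeat(
                    left_window,
                    right_window,
                    scheme,
                    min_identity=config.min_identity,
                    len_range=(config.ir_min_len, config.ir_max_len),
                    search_radius=r,
                    contig_id=contig.id,
                    left_offset=lw_lo,
                    right_offset=rw_lo,
                    max_reports=config.ir_max_reports,
                )
            # the inverted repeat must sit at the observed homology drops:
            # keep candidates whose outer termini agree with the boundaries
            candidates = [
                c
                for c in candidates
                if abs(c.tir5.start - left_edge) <= config.boundary_agreement
                and abs(c.tir3.end - right_edge) <= config.boundary_agreement
            ]
            # the short, degenerate repeat does not always outscore window
            # noise, so the top few agreeing candidates each get a chance
            # to produce a flush TSD; the best-supported one wins
            best: Optional[tuple] = None
            for cand in candidates[: config.ir_refine_candidates]:
                refined, tsd_c = tt.refine_element_termini(
                    contig,
                    cand,
                    len_range=(config.tsd_min_len, config.tsd_max_len),
                    max_mismatch=config.tsd_max_mismatch,
                    slack_out=config.terminus_slack_out,
                    slack_in=config.terminus_slack_in,
                    left_edge_hint=left_edge,
                    right_edge_hint=right_edge,
                )
                if tsd_c is None:
                    continue
                drift = abs(refined.tir5.start - left_edge) + abs(
                    refined.tir3.end - right_edge
                )
                key = (refined.cac_termini, -drift, tsd_c.length, refined.score)
                if best is None or key > best[0]:
                    best = (key, refined, tsd_c)
            if best is None:
                # diverged repeats can fail local retrieval outright; probe
                # the repeat directly at the boundary edges
                anchored = tt.boundary_anchored_ir(
                    contig,
                    left_edge,
                    right_edge,
                    scheme,
                    min_identity=max(config.min_identity, 0.65),
                    len_range=(config.ir_min_len, config.ir_max_len),
                )
                if anchored is not None:
                    # the probe carries no terminus information of its own
                    # (its ends ARE the boundary edges), so only a flush
                    # TSD counts; anything else is left to the family pass
                    refined, tsd_c = tt.refine_element_termini(
                        contig,
                        anchored,
                        len_range=(config.tsd_min_len, config.tsd_max_len),
                        max_mismatch=config.tsd_max_mismatch,
                        slack_out=0,
                        slack_in=0,
                    )
                    if tsd_c is not None:
                        best = (
                            (refined.cac_termini, tsd_c.length, refined.score),
                            refined,
                            tsd_c,
                        )
            if best is not None:
                candidates = [best[1]] + [c for c in candidates if c is not best[1]]
                tsd = best[2]
        ann = tt.assemble_element(
            locus, {bd.LEFT: left, bd.RIGHT: right}, candidates, tsd
        )
        annotations.append(ann)
    return annotations


def _majority_consensus(seqs: Sequence[str]) -> str:
    """Plain per-column majority of left-anchored sequences (modal length)."""
    lengths = sorted(len(s) for s in seqs)
    width = lengths[len(lengths) // 2]
    out = []
    for c in range(width):
        column = [s[c] for s in seqs if c < len(s)]
        counts = {}
        for base in column:
            counts[base] = counts.get(base, 0) + 1
        out.append(min(b for b, n in counts.items() if n == max(counts.values())))
    return "".join(out)


def family_rescue(
    contigs: dict[str, GenomicContig],
    loci: Sequence[CandidateLocus],
    boundaries: dict[str, dict[str, Optional[bd.BoundaryCall]]],
    annotations: list[tt.ElementAnnotation],
    config: PipelineConfig,
) -> list[tt.ElementAnnotation]:
    """Second detection pass using the genome's recovered family TIR.

    Copies diverge from the family consensus only half as much as they
    diverge from each other, so the consensus of the TIRs recovered in
    the first pass pins element termini more sharply than any single
    copy's evidence. Every locus with boundary drops is re-probed with
    the consensus: loci the first pass missed are rescued, and a
    first-pass call whose termini disagree with the consensus-implied
    ones is overridden when the consensus termini carry a flush TSD. A
    rescue still demands the full three conditions: both boundary drops,
    a consensus match at each drop (above ``family_min_score_frac`` of a
    perfect match), an actual inverted-repeat identity above the
    threshold, and a flush TSD within ``family_grid`` bp of the
    consensus-implied termini.
    """
    from .align import align_global, align_local

    scheme = config.scheme()
    tir_seqs: list[str] = []
    for ann in annotations:
        if ann.configuration == "complete" and ann.tir_pair is not None:
            tir_seqs.append(ann.tir_pair.seq5)
            tir_seqs.append(revcomp(ann.tir_pair.seq3))
    if len(tir_seqs) < 2:
        return annotations
    cons = _majority_consensus(tir_seqs)
    cons_rc = revcomp(cons)
    min_score = config.family_min_score_frac * config.match * len(cons)
    loci_by_id = {loc.locus_id: loc for loc in loci}

    for idx, ann in enumerate(annotations):
        if ann.locus is None:
            continue
        locus = loci_by_id.get(ann.locus.locus_id)
        calls = boundaries.get(ann.locus.locus_id, {})
        left, right = calls.get(bd.LEFT), calls.get(bd.RIGHT)
        if locus is None or left is None or right is None:
            continue
        contig = contigs[locus.cassette.contig_id]
        # wider search window and looser agreement than the first pass:
        # the consensus gate carries the specificity, and the boundary
        # call itself is occasionally off by ~100 bp on one side
        r = config.search_radius + 100
        agree = 200
        left_edge = locus.cassette.start - left.boundary_pos
        right_edge = locus.cassette.end + right.boundary_pos
        lw_lo = max(0, left_edge - r)
        rw_lo = max(0, right_edge - r)
        left_window = contig.residues[lw_lo : left_edge + r]
        right_window = contig.residues[rw_lo : right_edge + r]
        if min(len(left_window), len(right_window)) < len(cons):
            continue

        hits5 = align_local(cons, left_window, scheme, max_reports=3)
        hits3 = align_local(cons_rc, right_window, scheme, max_reports=3)

        def pick(hits, edge, implied_of):
            # a strong consensus match may sit far from a misplaced
            # boundary call; a moderate one must coincide with it
            best = None
            for h in hits:
                implied = implied_of(h)
                delta = abs(implied - edge)
                if (h.score >= min_score and delta <= agree) or (
                    h.score >= config.family_weak_score
                    and delta <= config.family_weak_radius
                ):
                    if best is None or delta < best[0]:
                        best = (delta, implied)
            return None if best is None else best[1]

        edge5 = pick(hits5, left_edge, lambda h: lw_lo + h.b_start - h.a_start)
        edge3 = pick(
            hits3,
            right_edge,
            lambda h: rw_lo + h.b_end + (len(cons_rc) - h.a_end),
        )
        if edge5 is None or edge3 is None:
            continue

        g = config.family_grid
        k_min, k_max = config.tsd_min_len, config.tsd_max_len
        found = None
        for total in range(0, 4 * g + 1):
            if found:
                break
            for d5 in range(-g, g + 1):
                d3 = None
                for d3 in range(-g, g + 1):
                    if abs(d5) + abs(d3) != total:
                        continue
                    start, end = edge5 - d5, edge3 + d3
                    if start < 0 or end > len(contig) or end - start < 2 * len(cons):
                        continue
                    required = k_min if total == 0 else (4 if total <= 2 else 5)
                    tsd = tt.find_tsd(
                        contig,
                        Interval(contig.id, start, end),
                        (k_min, k_max),
                        config.tsd_max_mismatch,
                    )
                    if tsd is not None and tsd.length >= required:
                        found = (start, end, tsd)
                        break
                if found:
                    break
        if not found:
            continue
        start, end, tsd = found
        length = len(cons)
        seq5 = contig.residues[start : start + length]
        seq3 = contig.residues[end - length : end]
        ir_aln = align_global(seq5, revcomp(seq3), scheme)
        identity = ir_aln.identity()
        if identity <= config.min_identity:
            continue
        tir_pair = tt.TIRPair(
            tir5=Interval(contig.id, start, start + length),
            tir3=Interval(contig.id, end - length, end),
            seq5=seq5,
            seq3=seq3,
            ir_identity=identity,
            ir_alignment=ir_aln,
            score=ir_aln.score,
        )
        if (
            ann.configuration == "complete"
            and ann.element_span is not None
            and (ann.element_span.start, ann.element_span.end) == (start, end)
        ):
            continue  # first pass already agrees with the family evidence
        rescued = tt.assemble_element(
            locus, {bd.LEFT: left, bd.RIGHT: right}, [tir_pair], tsd
        )
        if rescued.configuration in ("complete", "non_autonomous"):
            rescued.notes = "family_rescue"
            annotations[idx] = rescued
    return annotations


def tir_margin_queries(
    contigs: dict[str, GenomicContig],
    annotations: Sequence[tt.ElementAnnotation],
    query_len: int = 150,
) -> list[tuple[str, str]]:
    """TIR-containing margin queries from complete elements.

    For each complete element two queries are emitted, one per element
    end, each a ``query_len`` window centered on the TIR (half inside the
    element, half in the flank). Query ids end in ``_tir5``/``_tir3`` so
    the scan can tell which element end a hit represents.
    """
    queries = []
    for ann in annotations:
        if ann.configuration != "complete" or ann.tir_pair is None:
            continue
        for end, tir in (("tir5", ann.tir_pair.tir5), ("tir3", ann.tir_pair.tir3)):
            contig = contigs[tir.contig_id]
            center = (tir.start + tir.end) // 2
            lo = max(0, center - query_len // 2)
            seq = contig.residues[lo : lo + query_len]
            if len(seq) >= 50:
                queries.append((f"{ann.locus_id}_{end}", seq))
    return queries


def run_pipeline(
    contigs: Sequence[GenomicContig],
    loci: Sequence[CandidateLocus],
    config: Optional[PipelineConfig] = None,
    run_scan: bool = True,
) -> PipelineResult:
    """Run every stage on a genome plus candidate-locus table."""
    config = config or PipelineConfig()
    contig_map = {c.id: c for c in contigs}
    for locus in loci:
        if locus.cassette.contig_id not in contig_map:
            raise ValueError(
                f"locus {locus.locus_id} references unknown contig "
                f"{locus.cassette.contig_id}"
            )

    if len(loci) >= 2:
        boundaries = detect_boundaries(contig_map, loci, config)
    else:
        if loci:
            logger.warning(
                "only one candidate locus: comparative boundary detection "
                "needs >= 2 copies; skipping"
            )
        boundaries = {}
    annotations = call_elements(contig_map, loci, boundaries, config)
    if config.family_rescue:
        annotations = family_rescue(
            contig_map, loci, boundaries, annotations, config
        )

    scan_hits: list[ms.ScanHit] = []
    scan_annotations: list[tt.ElementAnnotation] = []
    if run_scan:
        queries = tir_margin_queries(contig_map, annotations, config.query_len)
        if queries:
            scan_hits = ms.scan_margins(
                queries,
                list(contigs),
                config.scheme(),
                word_size=config.word_size,
                evalue_max=config.evalue_max,
                x_drop=config.x_drop,
            )
            ends = {qid: qid.rsplit("_", 1)[1] for qid, _ in queries}
            scan_annotations = ms.pair_solitary_tirs(
                scan_hits,
                annotations,
                max_span=config.max_pair_span,
                genome=list(contigs),
                scheme=config.scheme(),
                tsd_len_range=(config.tsd_min_len, config.tsd_max_len),
                query_ends=ends,
            )

    tir5_seqs = [
        a.tir_pair.seq5
        for a in annotations
        if a.configuration == "complete" and a.tir_pair is not None
    ]
    consensus = None
    if len(tir5_seqs) >= 2:
        consensus = cm.build_consensus(
            cm.left_anchor_align(tir5_seqs), config.include_threshold
        )

    all_annotations = annotations + scan_annotations
    flat_calls = [
        call
        for per_locus in boundaries.values()
        for call in per_locus.values()
        if call is not None
    ]
    tables = {
        "boundaries": bd.boundary_table(flat_calls),
        "elements": tt.element_table(all_annotations),
        "scan_hits": ms.hit_table(scan_hits),
    }
    return PipelineResult(
        annotations=all_annotations,
        boundary_calls=flat_calls,
        scan_hits=scan_hits,
        consensus=consensus,
        tables=tables,
    )


def write_reports(
    result: PipelineResult,
    outdir: str | Path,
    contigs: Optional[Sequence[GenomicContig]] = None,
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, table in result.tables.items():
        table.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
    lengths = {c.id: len(c) for c in contigs} if contigs else None
    write_gff3(result.annotations, outdir / "elements.gff3", lengths)
    if result.consensus is not None:
        (outdir / "tir_consensus.txt").write_text(result.consensus.consensus + "\n")
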