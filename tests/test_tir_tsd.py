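import pytest

from tirscout.boundary import LEFT, RIGHT, BoundaryCall
from tirscout.seq_model import CandidateLocus, GenomicContig, Interval, revcomp
from tirscout.tir_tsd import (
    assemble_element,
    classify_status,
    find_inverted_repeat,
    find_tsd,
    refine_element_termini,
)

from conftest import random_dna

TIR = "CACTATCAAACGTTTGG"  # 17 bp, CAC terminus


class TestFindInvertedRepeat:
    def test_planted_perfect_ir(self, rng, dna_scheme):
        left = random_dna(rng, 140) + TIR + random_dna(rng, 143)
        right = random_dna(rng, 143) + revcomp(TIR) + random_dna(rng, 140)
        cands = find_inverted_repeat(left, right, dna_scheme)
        top = cands[0]
        assert top.ir_identity == 1.0
        # chance context matches may extend the repeat by a base or two
        assert TIR in left[top.tir5.start : top.tir5.end]
        assert revcomp(TIR) in right[top.tir3.start : top.tir3.end]

    def test_degenerate_ir_detected(self, rng, dna_scheme):
        mutated = list(revcomp(TIR))
        for pos, base in ((4, "A"), (9, "T"), (13, "C")):
            mutated[pos] = base
        right_tir = "".join(mutated)
        left = random_dna(rng, 140) + TIR + random_dna(rng, 143)
        right = random_dna(rng, 143) + right_tir + random_dna(rng, 140)
        cands = find_inverted_repeat(left, right, dna_scheme)
        assert cands and cands[0].ir_identity > 0.5

    def test_unrelated_windows_mostly_empty(self, rng, dna_scheme):
        hits = 0
        for _ in range(5):
            cands = find_inverted_repeat(
                random_dna(rng, 300), random_dna(rng, 300), dna_scheme,
                max_reports=1,
            )
            hits += bool(cands)
        # short spurious inverted repeats do occur in random DNA; the
        # planted-IR signal must not rely on their absence, but a clean
        # >50%-identity >=10 bp pair should not appear every time
        assert hits <= 4

    def test_strand_symmetry(self, rng, dna_scheme):
        left = random_dna(rng, 100) + TIR + random_dna(rng, 100)
        right = random_dna(rng, 100) + revcomp(TIR) + random_dna(rng, 100)
        fwd = find_inverted_repeat(left, right, dna_scheme)[0]
        swapped = find_inverted_repeat(
            revcomp(right), revcomp(left), dna_scheme
        )[0]
        n = len(right)
        assert (swapped.tir5.start, swapped.tir5.end) == (
            n - fwd.tir3.end,
            n - fwd.tir3.start,
        )
        assert swapped.seq5 == revcomp(fwd.seq3)

    def test_short_window_rejected(self, dna_scheme):
        with pytest.raises(ValueError):
            find_inverted_repeat("ACGTA", "ACGTA", dna_scheme)


class TestFindTsd:
    def _contig(self, rng, left_flank, right_flank, element_len=40):
        elem = random_dna(rng, element_len)
        residues = (
            random_dna(rng, 20) + left_flank + elem + right_flank + random_dna(rng, 20)
        )
        start = 20 + len(left_flank)
        span = Interval("c", start, start + element_len)
        return GenomicContig("c", residues), span

    def test_planted_five_bp_duplication(self, rng):
        contig, span = self._contig(rng, "GGAATGC", "AATGCTT")
        tsd = find_tsd(contig, span)
        assert tsd is not None and (tsd.left_seq, tsd.length) == ("AATGC", 5)
        assert tsd.mismatches == 0

    def test_unrelated_flanks_give_none(self, rng):
        contig, span = self._contig(rng, "TTTTTTTT", "GGGGGGGG")
        assert find_tsd(contig, span) is None

    def test_longest_k_preference(self, rng):
        # flanks share an 8-mer (and therefore its internal 5-mer)
        contig, span = self._contig(rng, "ACGTACGT", "ACGTACGT")
        tsd = find_tsd(contig, span)
        assert tsd is not None and tsd.length == 8

    def test_contig_edge(self, rng):
        contig = GenomicContig("c", random_dna(rng, 50))
        tsd = find_tsd(contig, Interval("c", 1, 49))
        assert tsd is not None and tsd.reason == "contig_edge"


class TestRefineTermini:
    def test_tip_trimmed_terminus_recovered(self, rng, dna_scheme):
        # plant a full element whose 5' TIR tip is mutated so the local
        # alignment trims it; the flush TSD pins the true terminus back
        tsd = "AATGC"
        tir5 = "G" + TIR[1:]  # mutated outer tip
        interior = random_dna(rng, 200)
        elem = tir5 + interior + revcomp(TIR)
        residues = random_dna(rng, 150) + tsd + elem + tsd + random_dna(rng, 150)
        contig = GenomicContig("c", residues)
        start = 155  # true element start
        end = start + len(elem)
        left_win = residues[start - 100 : start + 100]
        right_win = residues[end - 100 : end + 100]
        cands = find_inverted_repeat(
            left_win, right_win, dna_scheme,
            contig_id="c", left_offset=start - 100, right_offset=end - 100,
        )
        assert cands
        refined, found = refine_element_termini(
            contig, cands[0], left_edge_hint=start, right_edge_hint=end
        )
        assert found is not None and found.left_seq == tsd
        assert (refined.tir5.start, refined.tir3.end) == (start, end)


def _locus(gene1=True, gene2=True, intact="intact"):
    cas = Interval("c", 200, 800)
    return CandidateLocus(
        "L",
        cas,
        gene1=Interval("c", 200, 450, "+") if gene1 else None,
        gene2=Interval("c", 500, 800, "-") if gene2 else None,
        gene1_intactness=intact if gene1 else "unknown",
        gene2_intactness=intact if gene2 else "unknown",
    )


def _tir_pair():
    from tirscout.align import PairwiseAlignment

    aln = PairwiseAlignment(TIR, TIR, 30, 0, 17, 0, 17, "local")
    from tirscout.tir_tsd import TIRPair

    return TIRPair(
        tir5=Interval("c", 100, 117),
        tir3=Interval("c", 883, 900),
        seq5=TIR,
        seq3=revcomp(TIR),
        ir_identity=1.0,
        ir_alignment=aln,
        score=30,
    )


def _tsd():
    from tirscout.tir_tsd import TSDCall

    return TSDCall("AATGC", "AATGC", 5, 0)


def _boundaries(left=True, right=True):
    mk = lambda side: BoundaryCall("L", side, 417, 0.9, 0.3, 2, True)
    return {
        LEFT: mk(LEFT) if left else None,
        RIGHT: mk(RIGHT) if right else None,
    }


class TestAssembleAndStatus:
    def test_three_conditions_met(self):
        ann = assemble_element(_locus(), _boundaries(), [_tir_pair()], _tsd())
        assert ann.configuration == "complete"
        assert ann.status == "potentially_active"

    def test_missing_tsd_downgrades(self):
        ann = assemble_element(_locus(), _boundaries(), [_tir_pair()], None)
        assert ann.configuration != "complete"

    def test_no_gene_interior_is_non_autonomous(self):
        locus = CandidateLocus("L", Interval("c", 200, 800))
        ann = assemble_element(locus, _boundaries(), [_tir_pair()], _tsd())
        assert ann.configuration == "non_autonomous"

    def test_one_drop_is_missing_one_tir(self):
        ann = assemble_element(
            _locus(), _boundaries(right=False), [], None
        )
        assert ann.configuration == "missing_one_tir"

    def test_solitary_gene(self):
        ann = assemble_element(
            _locus(gene2=False), _boundaries(left=False, right=False), [], None
        )
        assert ann.configuration == "solitary_gene"

    def test_status_fossilized(self):
        ann = assemble_element(
            _locus(intact="stop_disrupted"), _boundaries(), [_tir_pair()], _tsd()
        )
        assert ann.configuration == "complete"
        assert ann.status == "fossilized"

    def test_status_candidate_domesticated(self):
        ann = assemble_element(_locus(), _boundaries(False, False), [], None)
        assert ann.configuration == "missing_both_tirs"
        assert ann.status == "candidate_domesticated"

    def test_classify_requires_both_genes_for_active(self):
        ann = assemble_element(
            _locus(gene2=False), _boundaries(), [_tir_pair()], _tsd()
        )
        assert classify_status(ann) != "potentially_active"
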