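import math

import pytest

from tirscout.margin_scan import (
    ScanHit,
    evalue,
    karlin_altschul_params,
    pair_solitary_tirs,
    scan_margins,
)
from tirscout.seq_model import GenomicContig, Interval, revcomp

from conftest import random_dna


class TestKarlinAltschul:
    @pytest.mark.parametrize(
        "match, mismatch, lam_ref, k_ref",
        [(1, -2, 1.33, 0.621), (1, -3, 1.374, 0.711), (2, -3, 0.634, 0.408)],
    )
    def test_published_ungapped_values(self, match, mismatch, lam_ref, k_ref):
        lam, K, H = karlin_altschul_params(match, mismatch)
        assert lam == pytest.approx(lam_ref, abs=0.01)
        assert K == pytest.approx(k_ref, abs=0.01)
        assert H > 0

    def test_evalue_monotonic_in_score(self, dna_scheme):
        evals = [evalue(s, 150, 100_000, dna_scheme) for s in range(20, 200, 10)]
        assert all(a > b for a, b in zip(evals, evals[1:]))


def _genome_with_copy(rng, query, divergence=0.0, length=30_000):
    bases = "ACGT"
    copy = list(query)
    n_mut = int(round(divergence * len(copy)))
    for pos in rng.choice(len(copy), size=n_mut, replace=False):
        copy[pos] = bases[(bases.index(copy[pos]) + 1) % 4]
    copy = "".join(copy)
    insert_at = length // 2
    residues = random_dna(rng, insert_at) + copy + random_dna(rng, length - insert_at)
    return GenomicContig("g", residues), insert_at, copy


class TestScanMargins:
    def test_exact_copy_found(self, rng, dna_scheme):
        query = random_dna(rng, 150)
        genome, pos, _ = _genome_with_copy(rng, query)
        hits = scan_margins([("q", query)], [genome], dna_scheme)
        assert hits
        top = hits[0]
        assert (top.target.start, top.target.end) == (pos, pos + 150)
        assert top.identity == 1.0 and top.evalue < 1e-10

    def test_reverse_strand_copy_found(self, rng, dna_scheme):
        query = random_dna(rng, 150)
        genome, pos, _ = _genome_with_copy(rng, revcomp(query))
        hits = scan_margins([("q", query)], [genome], dna_scheme)
        assert hits and hits[0].target.strand == "-"
        assert (hits[0].target.start, hits[0].target.end) == (pos, pos + 150)

    def test_random_genome_negative_control(self, rng, dna_scheme):
        zero = 0
        for _ in range(5):
            query = random_dna(rng, 150)
            genome = GenomicContig("g", random_dna(rng, 100_000))
            hits = scan_margins([("q", query)], [genome], dna_scheme)
            zero += not hits
        assert zero >= 4  # occasional marginal hit tolerated, not the norm

    def test_degenerate_copy_identity(self, rng, dna_scheme):
        query = random_dna(rng, 150)
        genome, pos, _ = _genome_with_copy(rng, query, divergence=0.10)
        hits = scan_margins([("q", query)], [genome], dna_scheme)
        assert hits
        assert hits[0].identity == pytest.approx(0.90, abs=0.03)

    def test_sensitivity_to_degenerate_copies(self, rng, dna_scheme):
        # planted copies at <= 15% divergence, >= 120 bp must be found
        found = 0
        for _ in range(10):
            query = random_dna(rng, 150)
            genome, pos, _ = _genome_with_copy(
                rng, query[:130], divergence=0.15, length=20_000
            )
            hits = scan_margins([("q", query)], [genome], dna_scheme)
            found += any(
                h.target.start < pos + 130 and h.target.end > pos for h in hits
            )
        assert found >= 9

    def test_short_query_rejected(self, dna_scheme):
        with pytest.raises(ValueError):
            scan_margins([("q", "ACGTACGTAC" * 6)], [], dna_scheme, word_size=80)


def _hit(qid, contig, start, end, strand, score=60.0):
    return ScanHit(
        query_id=qid,
        target=Interval(contig, start, end, strand),
        score=score,
        identity=0.95,
        evalue=1e-9,
    )


class TestPairing:
    def test_opposite_orientation_within_span_paired(self, rng):
        residues = random_dna(rng, 5000)
        tsd = residues[995:1000]
        residues = residues[:1100] + tsd + residues[1105:]  # no-op placeholder
        contig = GenomicContig("c", residues)
        hits = [
            _hit("q", "c", 1000, 1100, "+"),
            _hit("q", "c", 2900, 3000, "-"),
        ]
        anns = pair_solitary_tirs(hits, [], max_span=20_000, genome=[contig])
        assert len(anns) == 1
        assert anns[0].configuration == "non_autonomous"
        span = anns[0].element_span
        assert span.start <= 1006 and span.end >= 2994

    def test_single_hit_is_solitary(self):
        anns = pair_solitary_tirs([_hit("q", "c", 1000, 1100, "+")], [])
        assert [a.configuration for a in anns] == ["solitary_tir"]

    def test_same_orientation_not_paired(self):
        hits = [
            _hit("q", "c", 1000, 1100, "+"),
            _hit("q", "c", 3000, 3100, "+"),
        ]
        anns = pair_solitary_tirs(hits, [])
        assert {a.configuration for a in anns} == {"solitary_tir"}

    def test_hits_in_annotated_elements_ignored(self):
        from tirscout.tir_tsd import ElementAnnotation

        known = ElementAnnotation(
            locus=None,
            configuration="complete",
            element_span=Interval("c", 900, 3200),
        )
        hits = [
            _hit("q", "c", 1000, 1100, "+"),
            _hit("q", "c", 2900, 3000, "-"),
        ]
        assert pair_solitary_tirs(hits, [known]) == []

    def test_query_end_mapping(self):
        # two forward hits, one from each element end, still form a pair
        hits = [
            _hit("l_tir5", "c", 1000, 1100, "+"),
            _hit("l_tir3", "c", 2900, 3000, "+"),
        ]
        anns = pair_solitary_tirs(
            hits, [], query_ends={"l_tir5": "tir5", "l_tir3": "tir3"}
        )
        assert [a.configuration for a in anns] == ["non_autonomous"]
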