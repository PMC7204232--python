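import pytest
from hypothesis import given
from hypothesis import strategies as st

from tirscout.seq_model import (
    CandidateLocus,
    FastaParseError,
    GenomicContig,
    Interval,
    read_fasta,
    read_gff3_intervals,
    read_locus_table,
    revcomp,
    write_fasta,
    write_gff3,
    write_locus_table,
)
from tirscout.tir_tsd import ElementAnnotation, TSDCall, TIRPair
from tirscout.align import PairwiseAlignment

dna = st.text(alphabet="ACGTN", min_size=1, max_size=1000)


class TestFasta:
    def test_case_normalisation(self, tmp_path):
        p = tmp_path / "x.fa"
        p.write_text(">c1\nacgt\n")
        (rec,) = read_fasta(p)
        assert rec.id == "c1" and rec.residues == "ACGT"

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.fa"
        p.write_text("")
        assert read_fasta(p) == []

    def test_duplicate_ids_kept_with_warning(self, tmp_path):
        p = tmp_path / "dup.fa"
        p.write_text(">a\nACGT\n>a\nTTTT\n")
        with pytest.warns(UserWarning, match="duplicate"):
            records = read_fasta(p)
        assert [r.residues for r in records] == ["ACGT", "TTTT"]

    @pytest.mark.parametrize(
        "content, message",
        [
            (">a\nACGX\n", "line 2"),
            ("ACGT\n", "line 1"),
            (">\nACGT\n", "line 1"),
        ],
    )
    def test_parse_errors_name_line(self, tmp_path, content, message):
        p = tmp_path / "bad.fa"
        p.write_text(content)
        with pytest.raises(FastaParseError, match=message):
            read_fasta(p)

    def test_round_trip(self, tmp_path):
        recs = [GenomicContig("a", "ACGTN" * 40), GenomicContig("b", "TTT")]
        p = tmp_path / "rt.fa"
        write_fasta(recs, p)
        back = read_fasta(p)
        assert [(r.id, r.residues) for r in back] == [
            (r.id, r.residues) for r in recs
        ]


class TestRevcomp:
    def test_known_values(self):
        assert revcomp("CAC") == "GTG"
        assert revcomp("CACAGTG") == "CACTGTG"

    @given(dna)
    def test_involution_and_length(self, seq):
        assert revcomp(revcomp(seq)) == seq
        assert len(revcomp(seq)) == len(seq)

    def test_illegal_character(self):
        with pytest.raises(ValueError):
            revcomp("ACGU")


class TestIntervalsAndLoci:
    def test_interval_validation(self):
        with pytest.raises(ValueError):
            Interval("c", 5, 5)
        with pytest.raises(ValueError):
            Interval("c", -1, 3)

    def test_convergent_gene_pair_required(self):
        cas = Interval("c", 100, 500)
        with pytest.raises(ValueError, match="convergent"):
            CandidateLocus(
                "l1",
                cas,
                gene1=Interval("c", 100, 200, "+"),
                gene2=Interval("c", 300, 500, "+"),
            )

    def test_locus_table_round_trip(self, tmp_path):
        loci = [
            CandidateLocus(
                "l1",
                Interval("c", 100, 500),
                gene1=Interval("c", 100, 250, "+"),
                gene2=Interval("c", 300, 500, "-"),
                gene1_intactness="intact",
                gene2_intactness="stop_disrupted",
            ),
            CandidateLocus("l2", Interval("c", 900, 1200)),
        ]
        p = tmp_path / "loci.tsv"
        write_locus_table(loci, p)
        back = read_locus_table(p)
        assert back[0].gene2_intactness == "stop_disrupted"
        assert back[0].gene1 == loci[0].gene1
        assert back[1].gene1 is None and back[1].cassette == loci[1].cassette


def _annotation():
    aln = PairwiseAlignment("CACTA", "CACTA", 10, 0, 5, 0, 5, "local")
    pair = TIRPair(
        tir5=Interval("c", 100, 117),
        tir3=Interval("c", 583, 600),
        seq5="C" * 17,
        seq3="G" * 17,
        ir_identity=0.9,
        ir_alignment=aln,
        score=20,
    )
    tsd = TSDCall(
        "AATGC",
        "AATGC",
        5,
        0,
        left_interval=Interval("c", 95, 100),
        right_interval=Interval("c", 600, 605),
    )
    locus = CandidateLocus(
        "l1",
        Interval("c", 150, 550),
        gene1=Interval("c", 150, 300, "+"),
        gene2=Interval("c", 350, 550, "-"),
    )
    return ElementAnnotation(
        locus=locus,
        tir_pair=pair,
        tsd=tsd,
        configuration="complete",
        status="potentially_active",
        element_span=Interval("c", 100, 600),
    )


class TestGFF3:
    def test_coordinate_convention(self, tmp_path):
        p = tmp_path / "x.gff3"
        write_gff3([_annotation()], p)
        df = read_gff3_intervals(p)
        element = df[df.type == "mobile_genetic_element"].iloc[0]
        # 0-based [100, 600) must print as 1-based inclusive 101..600
        raw = p.read_text().splitlines()[1].split("\t")
        assert (raw[3], raw[4]) == ("101", "600")
        assert (element.start, element.end) == (100, 600)

    def test_empty_list(self, tmp_path):
        p = tmp_path / "empty.gff3"
        write_gff3([], p)
        assert p.read_text() == "##gff-version 3\n"

    def test_round_trip_intervals(self, tmp_path):
        ann = _annotation()
        p = tmp_path / "rt.gff3"
        write_gff3([ann], p)
        df = read_gff3_intervals(p)
        tirs = df[df.type == "terminal_inverted_repeat"]
        assert set(zip(tirs.start, tirs.end)) == {(100, 117), (583, 600)}
        tsds = df[df.type == "target_site_duplication"]
        assert set(zip(tsds.start, tsds.end)) == {(95, 100), (600, 605)}

    def test_out_of_bounds_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="bounds"):
            write_gff3([_annotation()], tmp_path / "x.gff3", {"c": 550})
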