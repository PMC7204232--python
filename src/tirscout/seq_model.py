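"""Sequence and coordinate data model plus FASTA/GFF3/TSV readers and writers.

All internal coordinates are 0-based half-open on the top strand; only GFF3
emission converts to the 1-based inclusive convention. DNA is normalized to
upper-case ``ACGTN``; ``N`` never counts as a match anywhere downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import pandas as pd

DNA_ALPHABET = set("ACGTN")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*")
GAP = "-"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

Intactness = Literal["intact", "stop_disrupted", "truncated", "unknown"]


class FastaParseError(ValueError):
    """Raised for malformed FASTA input; message names the offending line."""


@dataclass(frozen=True)
class GenomicContig:
    """A DNA contig: identifier, residues over ``ACGTN``, free-text description."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"contig {self.id!r}: empty sequence")
        bad = set(self.residues) - DNA_ALPHABET
        if bad:
            raise ValueError(f"contig {self.id!r}: illegal characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ProteinSeq:
    """An amino-acid sequence (20 standard letters plus X and ``*``)."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(self.residues) - PROTEIN_ALPHABET - {GAP}
        if bad:
            raise ValueError(f"protein {self.id!r}: illegal characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Interval:
    """0-based half-open interval on a contig."""

    contig_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "Interval") -> bool:
        return (
            self.contig_id == other.contig_id
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.contig_id == other.contig_id
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class CandidateLocus:
    """A candidate transposon cassette: the convergent gene-pair interval.

    ``gene1``/``gene2`` are the two transposase-like genes inside the cassette
    (convergent, tail-to-tail, when both present); either may be absent for
    solitary loci. Gene intactness is input metadata (gene prediction is out
    of scope for this package).
    """

    locus_id: str
    cassette: Interval
    gene1: Optional[Interval] = None
    gene2: Optional[Interval] = None
    gene1_intactness: Intactness = "unknown"
    gene2_intactness: Intactness = "unknown"

    def __post_init__(self) -> None:
        for g in (self.gene1, self.gene2):
            if g is not None and not self.cassette.contains(g):
                raise ValueError(f"locus {self.locus_id}: gene outside cassette")
        if self.gene1 is not None and self.gene2 is not None:
            if self.gene1.strand == self.gene2.strand:
                raise ValueError(
                    f"locus {self.locus_id}: gene pair must be convergent "
                    "(opposite strands)"
                )

    @property
    def genes(self) -> list[Interval]:
        return [g for g in (self.gene1, self.gene2) if g is not None]


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over ``ACGTN`` (N maps to N)."""
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(f"illegal DNA characters {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def _validated_record(kind, rec_id, desc, seq, line_no):
    seq = seq.upper()
    if kind == "dna":
        bad = set(seq) - DNA_ALPHABET
        cls = GenomicContig
    else:
        bad = set(seq) - PROTEIN_ALPHABET - {GAP}
        cls = ProteinSeq
    if bad:
        raise FastaParseError(
            f"line {line_no}: illegal {kind} characters {sorted(bad)} "
            f"in record {rec_id!r}"
        )
    if not seq:
        raise FastaParseError(f"line {line_no}: record {rec_id!r} has no sequence")
    return cls(id=rec_id, residues=seq, description=desc)


def read_fasta(
    path: str | Path, alphabet: str = "dna", allow_gaps: bool = False
) -> list:
    """Read a FASTA file into :class:`GenomicContig` or :class:`ProteinSeq`.

    Sequences are upper-cased; record order is preserved; duplicate ids are
    kept (a warning is emitted). Parse errors name the offending line.

    Parameters
    ----------
    alphabet:
        ``"dna"`` (contigs over ACGTN) or ``"protein"``.
    allow_gaps:
        Accept ``-`` in sequences (aligned FASTA). Gap columns are preserved.
    """
    if alphabet not in ("dna", "protein"):
        raise ValueError("alphabet must be 'dna' or 'protein'")
    records: list = []
    seen: set[str] = set()
    rec_id = None
    desc = ""
    chunks: list[str] = []
    rec_line = 0
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                if rec_id is not None:
                    records.append(
                        _validated_record(
                            alphabet, rec_id, desc, "".join(chunks), rec_line
                        )
                    )
                header = line[1:].strip()
                if not header:
                    raise FastaParseError(f"line {line_no}: empty FASTA header")
                parts = header.split(None, 1)
                rec_id = parts[0]
                desc = parts[1] if len(parts) > 1 else ""
                if rec_id in seen:
                    warnings.warn(f"duplicate FASTA id {rec_id!r}; both records kept")
                seen.add(rec_id)
                chunks = []
                rec_line = line_no
            else:
                if rec_id is None:
                    raise FastaParseError(
                        f"line {line_no}: sequence data before first '>' header"
                    )
                seq = line.strip().upper()
                if not allow_gaps and GAP in seq:
                    raise FastaParseError(
                        f"line {line_no}: gap character in unaligned FASTA"
                    )
                allowed = DNA_ALPHABET if alphabet == "dna" else PROTEIN_ALPHABET
                bad = set(seq) - allowed - {GAP}
                if bad:
                    raise FastaParseError(
                        f"line {line_no}: illegal {alphabet} characters "
                        f"{sorted(bad)} in record {rec_id!r}"
                    )
                chunks.append(seq)
        if rec_id is not None:
            records.append(
                _validated_record(alphabet, rec_id, desc, "".join(chunks), rec_line)
            )
    return records


def write_fasta(records: Iterable, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Locus tables
# ---------------------------------------------------------------------------

LOCUS_TABLE_COLUMNS = [
    "locus_id",
    "contig_id",
    "cassette_start",
    "cassette_end",
    "gene1_start",
    "gene1_end",
    "gene1_strand",
    "gene1_intactness",
    "gene2_start",
    "gene2_end",
    "gene2_strand",
    "gene2_intactness",
]


def loci_to_table(loci: Sequence[CandidateLocus]) -> pd.DataFrame:
    rows = []
    for loc in loci:
        row = {
            "locus_id": loc.locus_id,
            "contig_id": loc.cassette.contig_id,
            "cassette_start": loc.cassette.start,
            "cassette_end": loc.cassette.end,
        }
        for name, gene, intact in (
            ("gene1", loc.gene1, loc.gene1_intactness),
            ("gene2", loc.gene2, loc.gene2_intactness),
        ):
            row[f"{name}_start"] = gene.start if gene else -1
            row[f"{name}_end"] = gene.end if gene else -1
            row[f"{name}_strand"] = gene.strand if gene else "."
            row[f"{name}_intactness"] = intact
        rows.append(row)
    return pd.DataFrame(rows, columns=LOCUS_TABLE_COLUMNS)


def write_locus_table(loci: Sequence[CandidateLocus], path: str | Path) -> None:
    loci_to_table(loci).to_csv(path, sep="\t", index=False)


def read_locus_table(path: str | Path) -> list[CandidateLocus]:
    df = pd.read_csv(path, sep="\t", dtype={"locus_id": str, "contig_id": str})
    loci = []
    for _, row in df.iterrows():
        genes = {}
        for name in ("gene1", "gene2"):
            if int(row[f"{name}_start"]) >= 0:
                genes[name] = Interval(
                    row["contig_id"],
                    int(row[f"{name}_start"]),
                    int(row[f"{name}_end"]),
                    row[f"{name}_strand"],
                )
            else:
                genes[name] = None
        loci.append(
            CandidateLocus(
                locus_id=row["locus_id"],
                cassette=Interval(
                    row["contig_id"],
                    int(row["cassette_start"]),
                    int(row["cassette_end"]),
                ),
                gene1=genes["gene1"],
                gene2=genes["gene2"],
                gene1_intactness=row["gene1_intactness"],
                gene2_intactness=row["gene2_intactness"],
            )
        )
    return loci


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def _gff3_cols(interval: Interval) -> tuple[int, int]:
    """0-based half-open -> GFF3 1-based inclusive (bijective)."""
    return interval.start + 1, interval.end


def _gff3_to_interval(contig_id: str, start: int, end: int, strand: str) -> Interval:
    return Interval(contig_id, start - 1, end, strand)


def write_gff3(annotations, path: str | Path, contig_lengths=None) -> None:
    """Write element annotations as GFF3.

    Each element becomes a ``mobile_genetic_element`` feature with child
    features for its TIRs, TSDs, and genes. ``contig_lengths`` (optional
    mapping id -> bp) enables bounds checking.
    """
    lines = ["##gff-version 3"]
    for i, ann in enumerate(annotations):
        span = ann.element_span
        if span is None:
            continue
        if contig_lengths is not None:
            limit = contig_lengths.get(span.contig_id)
            if limit is not None and span.end > limit:
                raise ValueError(
                    f"element {ann.locus_id} exceeds contig {span.contig_id} bounds"
                )
        start, end = _gff3_cols(span)
        eid = f"element_{i:04d}"
        attrs = (
            f"ID={eid};Name={ann.locus_id};configuration={ann.configuration};"
            f"status={ann.status}"
        )
        if ann.tir_pair is not None:
            attrs += f";ir_identity={ann.tir_pair.ir_identity:.3f}"
        if ann.tsd is not None:
            attrs += f";tsd_seq={ann.tsd.left_seq}"
        src = "tirscout"
        lines.append(
            "\t".join(
                [
                    span.contig_id,
                    src,
                    "mobile_genetic_element",
                    str(start),
                    str(end),
                    ".",
                    "+",
                    ".",
                    attrs,
                ]
            )
        )

        def child(feature: str, iv: Interval, suffix: str) -> str:
            s, e = _gff3_cols(iv)
            return "\t".join(
                [
                    iv.contig_id,
                    src,
                    feature,
                    str(s),
                    str(e),
                    ".",
                    iv.strand,
                    ".",
                    f"ID={eid}.{suffix};Parent={eid}",
                ]
            )

        if ann.tir_pair is not None:
            lines.append(child("terminal_inverted_repeat", ann.tir_pair.tir5, "tir5"))
            lines.append(child("terminal_inverted_repeat", ann.tir_pair.tir3, "tir3"))
        if ann.tsd is not None and ann.tsd.left_interval is not None:
            lines.append(child("target_site_duplication", ann.tsd.left_interval, "tsd5"))
            lines.append(
                child("target_site_duplication", ann.tsd.right_interval, "tsd3")
            )
        if ann.locus is not None:
            for j, gene in enumerate(ann.locus.genes, start=1):
                lines.append(child("gene", gene, f"gene{j}"))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3_intervals(path: str | Path) -> pd.DataFrame:
    """Read a GFF3 file back into a table of 0-based half-open intervals."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            contig, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            iv = _gff3_to_interval(
                contig, int(start), int(end), strand if strand in "+-" else "+"
            )
            rows.append(
                {
                    "contig_id": contig,
                    "type": ftype,
                    "start": iv.start,
                    "end": iv.end,
                    "strand": iv.strand,
                    "attributes": attrs,
                }
            )
    return pd.DataFrame(rows)
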