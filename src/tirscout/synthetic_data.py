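"""Seeded genomes with planted transposon copies, plus ground truth.

The generator emulates the genomic situation the comparative TIR/TSD
detector exploits: several copies of one element share a highly similar
internal cassette (a convergent transposase-like gene pair with short
untranslated pads), are bounded by partially degenerate terminal inverted
repeats whose outer terminus begins 5'-CAC, and are flanked by exact
target-site duplications created by duplicating the insertion target site.
The flanking host DNA is independent random sequence, so inter-copy
homology collapses exactly at the element edge.

Copy classes: ``complete`` (intact genes, TIRs, TSD), ``fossilized``
(degraded cassette, stop-disrupted genes), ``non_autonomous`` (TIR pair
around an unrelated interior, MITE-like), ``solitary_tir`` (a single
unpaired TIR), and ``tir_less_pair`` (intact gene pair, no TIRs or TSD -
the domestication-candidate configuration).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .seq_model import CandidateLocus, GenomicContig, Interval, revcomp

#: Protostome-style TIR template: 17 bp, 5'-CAC terminus, A-rich positions
#: 8-10, drawn to match the degenerate consensus shape of the family.
DEFAULT_TIR_TEMPLATE = "CACTAACAAACGTCTGG"

COPY_CLASSES = (
    "complete",
    "fossilized",
    "non_autonomous",
    "solitary_tir",
    "tir_less_pair",
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class PlantSpec:
    """Parameters of one simulated genome with planted element copies."""

    n_copies: int = 5
    cassette_len: int = 2600
    cassette_divergence: float = 0.05
    tir_template: str = DEFAULT_TIR_TEMPLATE
    tir_divergence: float = 0.1
    tsd_len: Optional[int] = 5
    copy_class: str = "complete"
    #: optional per-copy classes (length n_copies); copies of every class
    #: share one master cassette/pad/TIR set, so e.g. non-autonomous
    #: copies are internal-deletion derivatives of the same family
    copy_classes: Optional[tuple[str, ...]] = None
    background_len: int = 50_000
    gc: float = 0.42
    seed: int = 0
    # layout details
    utr_pad: int = 400  # element-internal pad between TIR and the gene pair
    gene_spacer: int = 200  # between the two convergent genes
    min_host_gap: int = 3400  # host DNA guaranteed between planted copies
    na_interior_len: int = 2000  # interior length of non-autonomous copies
    indel_rate: float = 0.0  # opt-in; substitutions only by default

    def __post_init__(self) -> None:
        if self.copy_class not in COPY_CLASSES:
            raise ValueError(f"unknown copy_class {self.copy_class!r}")
        if self.copy_classes is not None:
            if len(self.copy_classes) != self.n_copies:
                raise ValueError("copy_classes must have one entry per copy")
            for cls in self.copy_classes:
                if cls not in COPY_CLASSES:
                    raise ValueError(f"unknown copy_class {cls!r}")
        for rate in (self.cassette_divergence, self.tir_divergence):
            if not (0 <= rate <= 0.5):
                raise ValueError("divergence rates must be in [0, 0.5]")
        if len(self.tir_template) < 10:
            raise ValueError("tir_template must be >= 10 bp")
        if not self.tir_template.startswith("CAC"):
            raise ValueError("tir_template must begin with CAC")
        if self.tsd_len is not None and not (3 <= self.tsd_len <= 8):
            raise ValueError("tsd_len must be in [3, 8] or None")


@dataclass
class PlantedCopy:
    copy_id: str
    copy_class: str
    contig_id: str
    element: Optional[Interval]
    tir5: Optional[Interval]
    tir3: Optional[Interval]
    tir5_seq: Optional[str]
    tir3_seq: Optional[str]
    tsd: Optional[str]
    n_substitutions: int


@dataclass
class SyntheticTruth:
    """Ground-truth planting record for recovery testing."""

    copies: list[PlantedCopy] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        def encode(copy: PlantedCopy) -> dict:
            d = asdict(copy)
            for key in ("element", "tir5", "tir3"):
                iv = d[key]
                if iv is not None:
                    d[key] = [iv["contig_id"], iv["start"], iv["end"], iv["strand"]]
            return d

        Path(path).write_text(
            json.dumps([encode(c) for c in self.copies], indent=1) + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        raw = json.loads(Path(path).read_text())
        copies = []
        for d in raw:
            for key in ("element", "tir5", "tir3"):
                if d[key] is not None:
                    cid, s, e, st = d[key]
                    d[key] = Interval(cid, s, e, st)
            copies.append(PlantedCopy(**d))
        return cls(copies=copies)


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p).tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> tuple[str, int]:
    """Substitute each base independently at ``rate`` (to one of the other 3)."""
    if rate <= 0 or not seq:
        return seq, 0
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    mask = rng.random(len(arr)) < rate
    n = int(mask.sum())
    if n:
        base_index = {b: i for i, b in enumerate(_BASES)}
        for pos in np.nonzero(mask)[0]:
            cur = base_index[arr[pos]]
            arr[pos] = _BASES[(cur + rng.integers(1, 4)) % 4]
    return arr.tobytes().decode(), n


def _break_flush_repeats(
    background: str, p: int, rng: np.random.Generator, len_range=(3, 8)
) -> str:
    """Ensure no flush k-mer direct repeat straddles insertion point ``p``."""
    k_min, k_max = len_range
    chars = list(background)
    for _ in range(20):
        broken = True
        for k in range(k_min, k_max + 1):
            if p - k < 0 or p + k > len(chars):
                continue
            if chars[p - k : p] == chars[p : p + k]:
                pos = p + k - 1
                current = chars[pos]
                chars[pos] = str(
                    rng.choice([b for b in "ACGT" if b != current])
                )
                broken = False
        if broken:
            break
    return "".join(chars)


def _placements(
    rng: np.random.Generator, n: int, genome_len: int, gap: int
) -> list[int]:
    """n insertion points, pairwise (and edge) separated by >= ``gap``."""
    free = genome_len - (n + 1) * gap
    if free <= 0:
        raise ValueError("copies do not fit in background at the required spacing")
    offsets = np.sort(rng.uniform(0, free, size=n))
    return [int(offsets[i]) + (i + 1) * gap for i in range(n)]


def simulate_genome(
    spec: PlantSpec,
) -> tuple[list[GenomicContig], SyntheticTruth, list[CandidateLocus]]:
    """Build one background contig with ``n_copies`` planted element copies.

    Returns the contigs, the planting truth, and the candidate-locus table
    (cassette/gene coordinates with intactness metadata) that serves as the
    pipeline's input. Deterministic for a fixed spec (including seed).
    """
    rng = np.random.default_rng(spec.seed)
    label = "mixed" if spec.copy_classes else spec.copy_class
    contig_id = f"synth_{label}_{spec.seed}"

    background = _random_dna(rng, spec.background_len, spec.gc)
    master_cassette = _random_dna(rng, spec.cassette_len, spec.gc)
    master_pad5 = _random_dna(rng, spec.utr_pad, spec.gc)
    master_pad3 = _random_dna(rng, spec.utr_pad, spec.gc)
    tir5_t = spec.tir_template
    tir3_t = revcomp(spec.tir_template)

    points = _placements(
        rng, spec.n_copies, spec.background_len, spec.min_host_gap
    )

    pieces: list[str] = []
    cursor = 0  # position in original background coordinates
    offset = 0  # accumulated inserted length
    truth = SyntheticTruth()
    loci: list[CandidateLocus] = []

    for i, p in enumerate(points):
        copy_id = f"{contig_id}_copy{i}"
        cls = spec.copy_classes[i] if spec.copy_classes else spec.copy_class
        use_tsd = spec.tsd_len is not None and cls in (
            "complete",
            "fossilized",
            "non_autonomous",
        )
        has_tirs = cls in ("complete", "fossilized", "non_autonomous")
        n_sub = 0

        cassette_rate = spec.cassette_divergence * (
            3.0 if cls == "fossilized" else 1.0
        )
        if cls == "non_autonomous":
            # internal-deletion derivative: subterminal pads are retained
            # (mutated), the transposase cassette is replaced by unrelated
            # DNA, as in MITE-like elements
            pad5, a = _mutate(rng, master_pad5, spec.cassette_divergence)
            pad3, c = _mutate(rng, master_pad3, spec.cassette_divergence)
            core_len = max(0, spec.na_interior_len - 2 * spec.utr_pad)
            interior = pad5 + _random_dna(rng, core_len, spec.gc) + pad3
            n_sub += a + c
        elif cls == "solitary_tir":
            interior = ""
        else:
            pad5, a = _mutate(rng, master_pad5, spec.cassette_divergence)
            cas, b = _mutate(rng, master_cassette, cassette_rate)
            pad3, c = _mutate(rng, master_pad3, spec.cassette_divergence)
            interior = pad5 + cas + pad3
            n_sub += a + b + c

        if has_tirs:
            t5, a = _mutate(rng, tir5_t, spec.tir_divergence)
            t3, b = _mutate(rng, tir3_t, spec.tir_divergence)
            n_sub += a + b
        elif cls == "solitary_tir":
            t5, a = _mutate(rng, tir5_t, spec.tir_divergence)
            t3 = ""
            n_sub += a
        else:  # tir_less_pair
            t5 = t3 = ""

        element = t5 + interior + t3
        k = spec.tsd_len if use_tsd else 0
        tsd_seq = background[p : p + k] if k else None
        if not use_tsd and cls == "tir_less_pair":
            # decoys are TSD-free by contract: break any chance flush
            # direct repeat (3-8 bp) at the element edges
            background = _break_flush_repeats(background, p, rng)

        # emitted layout: ... bg[cursor:p+k] | element | bg[p:] ...
        pieces.append(background[cursor : p + k])
        pieces.append(element)
        cursor = p

        elem_start = offset + p + k  # final coordinates
        elem_end = elem_start + len(element)
        offset += len(element) + k

        tir5_iv = (
            Interval(contig_id, elem_start, elem_start + len(t5)) if t5 else None
        )
        tir3_iv = (
            Interval(contig_id, elem_end - len(t3), elem_end) if t3 else None
        )
        truth.copies.append(
            PlantedCopy(
                copy_id=copy_id,
                copy_class=cls,
                contig_id=contig_id,
                element=Interval(contig_id, elem_start, elem_end),
                tir5=tir5_iv,
                tir3=tir3_iv,
                tir5_seq=t5 or None,
                tir3_seq=t3 or None,
                tsd=tsd_seq,
                n_substitutions=n_sub,
            )
        )

        if cls in ("complete", "fossilized", "tir_less_pair"):
            gene_len = (spec.cassette_len - spec.gene_spacer) // 2
            cas_start = elem_start + len(t5) + spec.utr_pad
            cas_end = cas_start + spec.cassette_len
            intact = "intact" if cls != "fossilized" else "stop_disrupted"
            loci.append(
                CandidateLocus(
                    locus_id=copy_id,
                    cassette=Interval(contig_id, cas_start, cas_end),
                    gene1=Interval(contig_id, cas_start, cas_start + gene_len, "+"),
                    gene2=Interval(contig_id, cas_end - gene_len, cas_end, "-"),
                    gene1_intactness=intact,
                    gene2_intactness=intact,
                )
            )

    pieces.append(background[cursor:])
    contig = GenomicContig(
        id=contig_id,
        residues="".join(pieces),
        description=f"synthetic genome, {spec.n_copies}x {spec.copy_class}",
    )
    return [contig], truth, loci


def simulate_msa(
    n_seqs: int,
    length: int,
    conserved_columns: set[int],
    background: dict[str, float],
    seed: int = 0,
):
    """Protein MSA with designed conservation structure (no gaps).

    Conserved columns carry one fixed residue across all rows; the other
    columns are drawn i.i.d. from ``background``. Returns
    ``(ProteinMSA, truth)`` where truth maps conserved column -> residue.
    """
    from .conservation import ProteinMSA  # local import avoids a cycle

    if any(c < 0 or c >= length for c in conserved_columns):
        raise ValueError("conserved_columns outside [0, length)")
    rng = np.random.default_rng(seed)
    letters = np.array(sorted(background), dtype="U1")
    probs = np.array([background[a] for a in letters], dtype=float)
    probs = probs / probs.sum()

    truth = {
        int(c): str(rng.choice(letters, p=probs)) for c in sorted(conserved_columns)
    }
    rows = []
    for i in range(n_seqs):
        draw = rng.choice(letters, size=length, p=probs)
        for c, res in truth.items():
            draw[c] = res
        rows.append("".join(draw))
    ids = [f"synth_seq_{i}" for i in range(n_seqs)]
    return ProteinMSA(ids=ids, rows=rows), truth
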