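# Methods

This note documents the models, algorithms, parameter choices, and known
limitations of `tirscout`. Defaults live in `tirscout.pipeline.PipelineConfig`
and are all serializable to YAML.

## Comparative boundary detection

**Model.** Two copies of a transposable element inserted at different
genomic sites share the element interior (including both TIRs) but have
unrelated flanking host DNA. For each candidate locus and side, margins of
`margin_len` bp (default 3000; the classic comparative range is 2–3 kb) are
taken from the cassette's outermost gene coordinates, oriented outward
(position 0 adjacent to the cassette), and aligned globally
(Needleman–Wunsch, affine gaps) against the corresponding margin of a
partner copy. The windowed identity profile (centered window of 31
columns; a match requires both residues non-gap, identical, and neither
`N`) must sustain ≥ `t_high` = 0.7 over ≥ `min_run` = 100 columns starting
at the cassette edge, then fall below `t_low` = 0.4 and stay below
`t_high` for ≥ 50 columns. These thresholds operationalize "significant
homology drop"; they are not sharp — the defaults separate the ~90%
identity expected inside a young element family from the ~25% pointwise
identity of unrelated DNA by a wide margin.

**Single-base refinement.** The windowed profile blurs the transition by
roughly half a window, and the *gapped* alignment inflates apparent
host–host identity to ~0.40 per projected position because the optimizer
chases chance matches with gaps. The boundary is therefore refined by an
ungapped changepoint fit: sequences are compared base-by-base at the
offset the alignment implies at the coarse boundary, matches are modelled
as Bernoulli(p_in) inside and Bernoulli(p_out) outside (both rates
estimated from the two sides of the coarse call and clipped to
[0.55, 0.995] and [0.05, 0.45]), and the maximum-likelihood transition
within ±150 bp is taken. A fit that lands at its own window edge is
rejected in favour of the coarse call. The refinement assumes
substitution-dominated divergence; with many indels the implied offset
can be wrong, in which case accuracy degrades gracefully to the coarse
call (the indel-free default of the generator matches young element
families; real WGS data with indel-rich flanks will see coarser
boundaries).

**Consolidation.** Per-partner calls for one locus/side are clustered by
single linkage with `tolerance` = 25 bp; the call at the median of the
largest cluster wins, with ties between equal clusters going to the larger
inside-vs-outside identity contrast. The contrast is computed over bounded
300-column windows flanking the boundary: a call mistakenly placed inside
the element then shows a high "outside" identity and loses the tie. A call
is confident with support ≥ 2, or alone with contrast ≥ 0.3. Each locus is
compared against `max_partners` = 2 other copies per side; margins
truncated below 500 bp by a contig end are not force-called.

## TIR and TSD calling

**Inverted-repeat retrieval.** Windows of 2 × `search_radius` = 300 bp
centered on the two boundary calls are compared: the left window against
the reverse complement of the right window, with a Waterman–Eggert style
local-alignment enumeration (an in-package Gotoh dynamic program that
keeps the full score matrices and reports up to 30 non-overlapping local
optima — destructive masking of previously reported alignments would
delete degenerate true repeats that overlap spurious ones). Candidates
need identity > `min_identity` = 0.5 (identical columns / alignment
columns, so gaps count against identity) and arm lengths in
[`ir_min_len` = 10, `ir_max_len` = 1000], and their outer termini must lie
within `boundary_agreement` = 30 bp of the homology drops ("an inverted
repeat *at the sites of the observed homology drops*"). When no candidate
survives — heavily diverged repeats can shatter into sub-10 bp fragments —
a fallback probe aligns the terminal segments anchored directly at the
boundary edges globally over lengths 10–40 and qualifies the best probe
above identity 0.65.

**Terminus refinement by the TSD.** Local alignment fixes the element ends
only to within a few bp: a substitution near a TIR tip gets trimmed (the
true terminus lies outward), while chance complementarity between the two
copies of a near-palindromic TSD extends the alignment through it (the
true terminus lies inward). The outermost alignment column pairs the 5'
TIR start with the 3' TIR end, so either effect shifts *both* element
edges by the same column count; only diagonal adjustments `d` are
scanned (range derived from the refined boundary hints plus a symmetric
core, within ±12). The duplication check (`find_tsd`) compares the k-mers
flush against the proposed termini for k = 8 down to 3 with 0 mismatches
(`N` never matches). To keep chance direct repeats from exploiting the
search space, the required TSD length grows with the adjustment (flush:
any k ≥ 3; |d| ≤ 2: k ≥ 4; beyond: k ≥ 5, the modal TSD length of this
superfamily). Qualifying adjustments are ranked by how many termini begin
with the conserved 5'-CAC — used strictly as a tie-break, never a
requirement — then by closeness to the boundary hints, then by TSD
length. CAC outranks length because trimming one base inward manufactures
a spurious longer duplication out of the repeat's own complementary tips,
and such termini never retain the CAC. The boundary-anchored fallback
probe carries no terminus information of its own, so it only accepts a
flush TSD.

**Family-informed second pass.** Copies diverge from their family
consensus only about half as much as from each other, so after the first
pass the majority consensus of all recovered TIRs re-probes every locus:
a local match of the consensus on each side (score ≥ 0.5 of a perfect
match within 200 bp of the boundary, or ≥ 12 within 25 bp) pins the
termini, a TSD is sought within ±3 bp per side (evidence tiers as above),
and the actual inverted-repeat identity must still exceed 0.5. A
first-pass call whose termini disagree with the consensus-implied ones is
overridden when the consensus termini carry a flush TSD. This mirrors the
iterative reuse of detected margins that comparative TIR studies perform
by hand; it raises exact-terminus recovery from ~80% to ~99% at the
default study conditions. Genomes with no recoverable copy build no
consensus, so decoy-only inputs are untouched by this pass.

**Assembly and status.** `complete` requires drops on both sides, a
qualifying TIR pair, and a TSD; a qualifying pair around an interior with
no annotated gene is `non_autonomous`; partial evidence downgrades to
`missing_one_tir` / `missing_both_tirs`; a single-gene locus is
`solitary_gene`. Status: any stop-disrupted or truncated gene →
`fossilized`; complete with both genes intact → `potentially_active`;
an intact convergent pair with no detectable TIRs →
`candidate_domesticated`; otherwise `unknown`. Gene intactness is input
metadata — gene prediction is out of scope.

## Margin rescan

Queries are `query_len` = 150 bp windows centered on each TIR of every
complete element (both ends, so both termini of internal-deletion copies
are findable). The scan does exact 11-mer seeding on both strands,
ungapped X-drop (20) extension, gapped refinement with the local aligner,
and e-values `E = K·m·n·e^(−λS)` with the ungapped (λ, K) of the scoring
scheme: λ solves `Σ p(s)·e^(λs) = 1` over the score distribution of
random base pairs, and K follows the classical series formula evaluated
by convolving the score distribution (the implementation reproduces the
published ungapped values for standard nucleotide schemes, e.g.
λ = 1.33, K = 0.621 for +1/−2). Using ungapped parameters for the gapped
search means e-values are comparable within a run but not bit-identical
to external tools. Hits ≤ `evalue_max` = 10⁻³ are kept; overlapping hits
keep the best score. Opposite-end hits within 20 kb on one contig are
paired into non-autonomous candidates; their spans are fine-tuned over a
±6 bp per-side grid preferring the longest flush TSD (tiers as above);
unpaired hits become solitary-TIR records.

## Consensus and motifs

TIR sets are left-anchored at the 5'-CAC terminus (no internal gaps —
between families similarity is confined to the outer ~13–15 bp, so
terminal alignment is the meaningful frame). Per column, the IUPAC code
covers every base at frequency ≥ `include_threshold` = 0.25 among non-gap
entries (empty set → modal base); columns more than half gap are trimmed
from the ends only. The motif language writes anchors and spacer runs
(`Cx2Cx3GHx4C`, `Cx4-7Cx14-16…`, `[CH]` for alternatives); the scanner
enumerates every placement whose gaps lie in the declared ranges
(overlaps allowed, shortest gaps first per start), and PHD classification
demands that exactly one of the two C/H grammars (invertebrate:
`Cx4-7Cx14-16Cx2-4Cx4Hx2Cx11-18Cx2C`; vertebrate:
`CCx2Cx22Cx5-6Hx2Hx2Cx19Cx2H`) matches.

## Conservation statistics

Identity(i, j) = 100 × (columns where both non-gap and identical) /
min(ungapped lengths of i and j in the analysis window); columns where
exactly one sequence is gapped count in neither numerator nor denominator
beyond shortening the ungapped length; `X` and `*` are never identical.
Similarity counts instead every pair with a positive BLOSUM62 score
(identities included), so similarity ≥ identity elementwise. Cells where a
sequence has no residues in the window are NaN, not 0.

The JSD track uses the base-2 Jensen–Shannon divergence between a
column's residue distribution (uniform sequence weights, pseudocount
1/(20·n), gaps excluded) and the BLOSUM62 background — the standard
marginal residue frequencies of that matrix, stored as a named constant
(A 0.074 … V 0.073, summing to 1). JSD is bounded by 1 bit, so scores are
already in [0, 1]; with gap penalty 1 each score is multiplied by the
column's non-gap fraction; window > 0 applies the half-weight smoothing
of the original conservation-scoring method (default 0, no smoothing).
Relative-entropy logo data report `Σ p·log2(p/q)` bits per column with
letter heights proportional to p. Non-redundant subsets are greedy in
input order: keep a sequence iff its identity to every kept sequence is
below the threshold.

## Synthetic data generator

A genome is i.i.d. background DNA (GC 0.42) with `n_copies` = 5 planted
copies: each copy is TSD + mutated TIR (17 bp template
`CACTAACAAACGTCTGG` — 5'-CAC terminus and A-rich positions 8–10, matching
the family's consensus shape) + mutated 400 bp pad + mutated 2600 bp
gene-pair cassette + pad + mutated reverse-complement TIR + the same TSD,
the TSD being an exact duplication of the 5 bp at the insertion site.
Default divergence: 10% per TIR copy, 5% elsewhere, substitutions only
(indels are opt-in and untested at depth). Copies are placed uniformly
with ≥ 3.4 kb of host between them so comparative margins never cross a
neighbouring copy. Fossilized copies triple the cassette divergence and
are labelled stop-disrupted; non-autonomous copies keep mutated
subterminal pads around an unrelated interior (internal-deletion
derivatives — fully unrelated interiors would leave nothing ≥ 120 bp for
a margin query to find); solitary-TIR copies plant one bare TIR;
TIR-less decoys plant the cassette alone and are made literally TSD-free
(any chance flush 3–8-mer direct repeat at their edges is broken by
patching one flank base — otherwise ~2% of decoys would satisfy the TSD
condition at their true edges by chance and no detector could keep them
out). A per-copy class mixture (`copy_classes`) shares one master
cassette/pad/TIR set across classes, so derived copies belong to the same
family. Everything is deterministic under the seed.

**What passing on this generator does and does not show.** The generator
reproduces the *information structure* the comparative method relies on —
shared interior, degenerate short TIRs, exact TSDs, unrelated flanks — at
realistic divergences, but not assembly gaps, segmental duplications,
nested insertions, indel-rich host evolution, or cross-species margin
comparisons. High recovery here demonstrates the statistical machinery;
on real WGS data boundary accuracy will degrade with indels and the
status calls inherit whatever gene-intactness metadata is supplied.

## Problem sizes in the bundled runs

Tests and the acceptance script run the pipeline with `margin_len` = 2000
(the lower end of the 2–3 kb comparative range; the extra kilobase adds
alignment cost but no information on these genomes) on 50 seeded genomes
of 5 copies each for recovery, 10 decoy genomes for specificity, 8 mixed
genomes for the rescan, and 15 replicates for scan sensitivity. Kernel
oracles run on inputs up to 300 bp (alignment), 80 residues (motifs), and
5×30 columns (JSD, agreement to 1e-9).

## Known limitations

- Boundary detection needs ≥ 2 copies (or a close relative's copy); a
  single locus yields only scan and conservation results, as in the
  underlying comparative design.
- Indel handling is approximate: the ungapped changepoint and the
  diagonal terminus search both assume substitution-dominated divergence
  near the element edges.
- The flush-TSD condition accepts 3 bp duplications, so a premature
  cassette end adjacent to a chance 3-mer direct repeat passes all three
  conditions ~1.6% of the time even in principle; the evidence tiers and
  consensus pass push the realized false-complete rate well below 1% per
  locus but cannot make it zero.
- E-values are internal statistics, not calibrated against any external
  search tool.
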