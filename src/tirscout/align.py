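"""Pairwise alignment (global and local) and windowed identity profiling.

Global alignment is end-to-end Needleman-Wunsch with affine gaps, backed
by Biopython's ``PairwiseAligner`` C kernel (margins of a few kb align in
well under a second). Local alignment is a Waterman-Eggert style search
for successive non-overlapping locally optimal alignments, built on an
in-package Gotoh dynamic program (numba-accelerated) that keeps the full
score matrices so suboptimal alignments are enumerated exactly rather
than by destructive masking. Both honour two conventions:

* ``N`` never matches anything, including another ``N`` (assembly gap runs
  must not create phantom homology), and
* a gap run of length L costs ``gap_open + L * gap_extend``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

import numpy as np
from numba import njit
from Bio import Align
from Bio.Align import substitution_matrices

from .seq_model import DNA_ALPHABET, revcomp

#: Sentinel accepted in sequences but scored against everything.
MASK_CHAR = "!"
_MASK_SCORE = -(10**6)
_NEG_INF = np.int32(-(2**30))


@dataclass(frozen=True)
class ScoringScheme:
    """Affine-gap scoring. Penalties are stored positive and subtracted.

    The DNA default (+2/-3, gap open 5, extend 2) is blastn-like. For
    proteins set ``substitution_matrix_name`` (e.g. ``"BLOSUM62"``); match
    and mismatch are then ignored.
    """

    match: int = 2
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    substitution_matrix_name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.substitution_matrix_name is None and not (
            self.match > 0 > self.mismatch
        ):
            raise ValueError("need match > 0 > mismatch")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")

    @property
    def is_protein(self) -> bool:
        return self.substitution_matrix_name is not None


@lru_cache(maxsize=32)
def _dna_matrix(match: int, mismatch: int):
    alphabet = "ACGTN" + MASK_CHAR
    m = substitution_matrices.Array(alphabet=alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            if a in "N" + MASK_CHAR or b in "N" + MASK_CHAR:
                m[a, b] = _MASK_SCORE if MASK_CHAR in (a, b) else mismatch
            else:
                m[a, b] = match if a == b else mismatch
    return m


@lru_cache(maxsize=8)
def _protein_matrix(name: str):
    base = substitution_matrices.load(name)
    alphabet = str(base.alphabet)
    if MASK_CHAR not in alphabet:
        ext = substitution_matrices.Array(alphabet=alphabet + MASK_CHAR, dims=2)
        for a in alphabet:
            for b in alphabet:
                ext[a, b] = base[a, b]
        for a in alphabet + MASK_CHAR:
            ext[a, MASK_CHAR] = _MASK_SCORE
            ext[MASK_CHAR, a] = _MASK_SCORE
        return ext
    return base


def _make_aligner(scheme: ScoringScheme, mode: str = "global") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    if scheme.is_protein:
        aligner.substitution_matrix = _protein_matrix(scheme.substitution_matrix_name)
    else:
        aligner.substitution_matrix = _dna_matrix(scheme.match, scheme.mismatch)
    # our convention: gap run of length L costs gap_open + L * gap_extend
    aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    aligner.extend_gap_score = -scheme.gap_extend
    return aligner


@dataclass
class PairwiseAlignment:
    """An alignment of two (sub)sequences.

    ``aligned_a``/``aligned_b`` are equal-length strings with ``-`` gaps and
    no gap/gap column; ungapping ``aligned_a`` reproduces
    ``a[a_start:a_end]`` (likewise for b).
    """

    aligned_a: str
    aligned_b: str
    score: float
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    mode: str  # "global" | "local"

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings differ in length")

    def __len__(self) -> int:
        return len(self.aligned_a)

    @property
    def columns(self) -> int:
        return len(self.aligned_a)

    def match_columns(self) -> np.ndarray:
        """Boolean per column: both non-gap, identical, and neither N."""
        a = np.frombuffer(self.aligned_a.encode(), dtype="S1")
        b = np.frombuffer(self.aligned_b.encode(), dtype="S1")
        ok = (a != b"-") & (b != b"-") & (a != b"N") & (b != b"N")
        return ok & (a == b)

    def identity(self) -> float:
        """Identical pairs / alignment columns (gaps count against identity)."""
        return float(self.match_columns().sum()) / self.columns


def _check_inputs(a: str, b: str, scheme: ScoringScheme) -> None:
    if not a or not b:
        raise ValueError("empty sequence")
    if not scheme.is_protein:
        for name, s in (("a", a), ("b", b)):
            bad = set(s) - DNA_ALPHABET - {MASK_CHAR}
            if bad:
                raise ValueError(f"sequence {name}: illegal characters {sorted(bad)}")


def _extract_global(aln) -> PairwiseAlignment:
    return PairwiseAlignment(
        aligned_a=str(aln[0]),
        aligned_b=str(aln[1]),
        score=float(aln.score),
        a_start=0,
        a_end=len(aln.sequences[0]),
        b_start=0,
        b_end=len(aln.sequences[1]),
        mode="global",
    )


def align_global(a: str, b: str, scheme: ScoringScheme) -> PairwiseAlignment:
    """Optimal end-to-end alignment under affine-gap scoring.

    Tie-breaking among co-optimal alignments is delegated to the aligner's
    deterministic first traceback, so repeated runs give identical output.
    """
    _check_inputs(a, b, scheme)
    aligner = _make_aligner(scheme, "global")
    return _extract_global(aligner.align(a, b)[0])


@njit(cache=True)
def _gotoh_fill(a, b, sub, o, e):  # pragma: no cover - exercised via wrapper
    n, m = a.shape[0], b.shape[0]
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), _NEG_INF, dtype=np.int32)
    F = np.full((n + 1, m + 1), _NEG_INF, dtype=np.int32)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            up_open = H[i - 1, j] - o
            up_ext = E[i - 1, j] - e
            E[i, j] = up_open if up_open >= up_ext else up_ext
            left_open = H[i, j - 1] - o
            left_ext = F[i, j - 1] - e
            F[i, j] = left_open if left_open >= left_ext else left_ext
            s = H[i - 1, j - 1] + sub[a[i - 1], b[j - 1]]
            best = np.int32(0)
            if s > best:
                best = s
            if E[i, j] > best:
                best = E[i, j]
            if F[i, j] > best:
                best = F[i, j]
            H[i, j] = best
    return H, E, F


@lru_cache(maxsize=32)
def _dna_sub_array(match: int, mismatch: int) -> np.ndarray:
    # indices: A=0 C=1 G=2 T=3, N=4, mask=5; N/mask never match
    sub = np.full((6, 6), np.int32(mismatch))
    for i in range(4):
        sub[i, i] = match
    sub[5, :] = _MASK_SCORE
    sub[:, 5] = _MASK_SCORE
    return sub


@lru_cache(maxsize=8)
def _protein_sub_array(name: str) -> tuple[str, np.ndarray]:
    base = substitution_matrices.load(name)
    alphabet = str(base.alphabet)
    sub = np.array(base, dtype=np.int32)
    return alphabet, sub


_DNA_INDEX = {c: i for i, c in enumerate("ACGTN" + MASK_CHAR)}


def _encode(seq: str, scheme: ScoringScheme) -> tuple[np.ndarray, np.ndarray]:
    if scheme.is_protein:
        alphabet, sub = _protein_sub_array(scheme.substitution_matrix_name)
        index = {c: i for i, c in enumerate(alphabet)}
    else:
        index = _DNA_INDEX
        sub = _dna_sub_array(scheme.match, scheme.mismatch)
    try:
        codes = np.array([index[c] for c in seq], dtype=np.int64)
    except KeyError as exc:  # pragma: no cover - guarded by _check_inputs
        raise ValueError(f"residue {exc} outside scoring alphabet") from exc
    return codes, sub


def align_local(
    a: str,
    b: str,
    scheme: ScoringScheme,
    max_reports: int = 1,
    min_score: int = 1,
) -> list[PairwiseAlignment]:
    """Up to ``max_reports`` non-overlapping local alignments, best first.

    Alignments are enumerated from the full Smith-Waterman/Gotoh matrices
    in descending score order; an alignment whose path touches a cell
    already used by a previously reported alignment is skipped, so
    reported alignments never overlap as aligned pairs (Waterman-Eggert).
    Only alignments with score >= ``min_score`` (> 0) are reported.
    """
    _check_inputs(a, b, scheme)
    if max_reports < 1:
        raise ValueError("max_reports must be >= 1")
    min_score = max(int(min_score), 1)
    a_codes, sub = _encode(a, scheme)
    b_codes, _ = _encode(b, scheme)
    o = np.int32(scheme.gap_open + scheme.gap_extend)
    e = np.int32(scheme.gap_extend)
    H, E, F = _gotoh_fill(a_codes, b_codes, sub, o, e)

    order = np.argsort(H, axis=None, kind="stable")[::-1]
    claimed = np.zeros(H.shape, dtype=bool)
    results: list[PairwiseAlignment] = []
    for flat in order:
        if len(results) >= max_reports:
            break
        i0, j0 = divmod(int(flat), H.shape[1])
        score = int(H[i0, j0])
        if score < min_score:
            break
        if claimed[i0, j0]:
            continue
        path = _trace_local(H, E, F, a, b, a_codes, b_codes, sub, int(o), i0, j0)
        if path is None:
            continue
        aligned_a, aligned_b, a_start, b_start, cells = path
        if any(claimed[ci, cj] for ci, cj in cells):
            continue
        for ci, cj in cells:
            claimed[ci, cj] = True
        results.append(
            PairwiseAlignment(
                aligned_a=aligned_a,
                aligned_b=aligned_b,
                score=float(score),
                a_start=a_start,
                a_end=i0,
                b_start=b_start,
                b_end=j0,
                mode="local",
            )
        )
    return results


def _trace_local(H, E, F, a, b, a_codes, b_codes, sub, o, i, j):
    """Traceback of one local alignment ending at (i, j).

    Move preference on ties: diagonal, then gap consuming ``a``, then gap
    consuming ``b`` (high-road determinism). Returns aligned strings, the
    start coordinates, and the H-cells on the path.
    """
    out_a: list[str] = []
    out_b: list[str] = []
    cells: list[tuple[int, int]] = []
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            h = H[i, j]
            if h == 0:
                break
            cells.append((i, j))
            diag = H[i - 1, j - 1] + sub[a_codes[i - 1], b_codes[j - 1]]
            if h == diag:
                out_a.append(a[i - 1])
                out_b.append(b[j - 1])
                i -= 1
                j -= 1
            elif h == E[i, j]:
                state = "E"
            elif h == F[i, j]:
                state = "F"
            else:  # pragma: no cover - inconsistent matrices
                return None
        elif state == "E":
            out_a.append(a[i - 1])
            out_b.append("-")
            opened = H[i - 1, j] - o
            extended = E[i, j]
            i -= 1
            if extended == opened:
                state = "H"
        else:  # state == "F"
            out_a.append("-")
            out_b.append(b[j - 1])
            opened = H[i, j - 1] - o
            extended = F[i, j]
            j -= 1
            if extended == opened:
                state = "H"
    return "".join(reversed(out_a)), "".join(reversed(out_b)), i, j, cells


def identity_profile(aln: PairwiseAlignment, window: int) -> np.ndarray:
    """Windowed identity fraction per alignment column.

    The window is centered and shrunk at the edges; the value at column i is
    (matching columns in the window) / (columns in the window). Matching
    requires both residues non-gap, identical, and neither ``N``.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 1")
    n = aln.columns
    if window > n:
        raise ValueError("window exceeds alignment length")
    matches = aln.match_columns().astype(np.float64)
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(matches)])
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)
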