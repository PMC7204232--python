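"""Protein-MSA conservation statistics.

Gap-excluded identity and similarity percentage matrices, per-column
Jensen-Shannon divergence (JSD) conservation tracks against the BLOSUM62
background distribution, relative-entropy logo data, and greedy
non-redundant subset selection.

Identity between two aligned sequences is the count of columns where both
are non-gap and identical, divided by the smaller of the two ungapped
lengths (within the analysis window). Similarity counts instead every
column whose residue pair has a positive BLOSUM62 score, which includes all
identities, so similarity >= identity always holds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from .seq_model import GAP, ProteinSeq, read_fasta

AA = "ACDEFGHIKLMNPQRSTVWY"

#: Background amino-acid frequencies associated with BLOSUM62 (the marginal
#: residue probabilities of the matrix's target frequencies), normalized to
#: sum exactly to 1.
BLOSUM62_BACKGROUND: dict[str, float] = {
    "A": 0.074, "R": 0.052, "N": 0.045, "D": 0.054, "C": 0.025,
    "Q": 0.034, "E": 0.054, "G": 0.074, "H": 0.026, "I": 0.068,
    "L": 0.099, "K": 0.058, "M": 0.025, "F": 0.047, "P": 0.039,
    "S": 0.057, "T": 0.051, "W": 0.013, "Y": 0.032, "V": 0.073,
}

BACKGROUNDS = {
    "blosum62": BLOSUM62_BACKGROUND,
    "uniform": {a: 1.0 / 20 for a in AA},
}


def _background_vector(background) -> np.ndarray:
    if isinstance(background, str):
        background = BACKGROUNDS[background]
    q = np.array([background[a] for a in AA], dtype=float)
    if (q < 0).any() or not np.isfinite(q).all():
        raise ValueError("malformed background distribution")
    total = q.sum()
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError("background must sum to 1")
    return q / total


@dataclass
class ProteinMSA:
    """Aligned protein sequences with an optional core analysis window.

    ``core_window`` is a 0-based half-open column interval restricting every
    statistic (e.g. the core region from the first to the last conserved
    domain); ``None`` means all columns.
    """

    ids: list[str]
    rows: list[str]
    core_window: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows) or not self.rows:
            raise ValueError("MSA needs >= 1 sequence with matching ids")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError("aligned sequences must have equal length")
        if self.core_window is not None:
            s, e = self.core_window
            if not (0 <= s < e <= self.n_columns):
                raise ValueError("core_window outside alignment")

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def window_slice(self) -> slice:
        if self.core_window is None:
            return slice(0, self.n_columns)
        return slice(*self.core_window)

    def windowed_rows(self) -> list[str]:
        sl = self.window_slice()
        return [r[sl] for r in self.rows]

    @classmethod
    def from_fasta(
        cls, path: str | Path, core_window: Optional[tuple[int, int]] = None
    ) -> "ProteinMSA":
        records = read_fasta(path, alphabet="protein", allow_gaps=True)
        return cls(
            ids=[r.id for r in records],
            rows=[r.residues for r in records],
            core_window=core_window,
        )

    def subset(self, indices: Sequence[int]) -> "ProteinMSA":
        return ProteinMSA(
            ids=[self.ids[i] for i in indices],
            rows=[self.rows[i] for i in indices],
            core_window=self.core_window,
        )


@dataclass
class PairwiseMatrix:
    ids: list[str]
    values: np.ndarray  # square, percentages; NaN marks undefined cells
    metric: str  # "identity" | "similarity"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass
class ConservationTrack:
    scores: np.ndarray  # one value per analysed column, in [0, 1]
    background_name: str
    gap_penalty: int
    window: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"column": np.arange(len(self.scores)), "score": self.scores}
        )


_B62 = substitution_matrices.load("BLOSUM62")


def _pair_counts(row_i: str, row_j: str, similar: bool) -> tuple[int, int, int]:
    """(counted columns, ungapped_i, ungapped_j) for one aligned pair."""
    count = 0
    len_i = len_j = 0
    for a, b in zip(row_i, row_j):
        ga, gb = a == GAP, b == GAP
        if not ga:
            len_i += 1
        if not gb:
            len_j += 1
        if ga or gb:
            continue
        if similar:
            try:
                if _B62[a, b] > 0:
                    count += 1
            except IndexError:  # residue outside matrix alphabet
                continue
        else:
            if a == b and a != "X" and a != "*":
                count += 1
    return count, len_i, len_j


def _pairwise_matrix(msa: ProteinMSA, similar: bool) -> PairwiseMatrix:
    rows = msa.windowed_rows()
    n = len(rows)
    values = np.full((n, n), np.nan)
    np.fill_diagonal(values, 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            count, len_i, len_j = _pair_counts(rows[i], rows[j], similar)
            denom = min(len_i, len_j)
            if denom == 0:
                continue  # undefined cell stays NaN, not 0
            values[i, j] = values[j, i] = 100.0 * count / denom
    return PairwiseMatrix(
        ids=list(msa.ids),
        values=values,
        metric="similarity" if similar else "identity",
    )


def identity_matrix(msa: ProteinMSA) -> PairwiseMatrix:
    """Gap-excluded identity percentages over the core window.

    value(i, j) = 100 * identical non-gap column pairs /
    min(ungapped length of i, ungapped length of j).
    """
    return _pairwise_matrix(msa, similar=False)


def similarity_matrix(msa: ProteinMSA) -> PairwiseMatrix:
    """Like :func:`identity_matrix` but counting BLOSUM62-positive pairs."""
    return _pairwise_matrix(msa, similar=True)


def _entropy_bits(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def _column_distribution(
    column: Sequence[str], pseudocount: float
) -> tuple[np.ndarray, float]:
    """Empirical residue distribution of one column (gaps excluded).

    Returns (p over the 20 standard residues, non-gap fraction). A uniform
    pseudocount is added to every residue before normalization.
    """
    counts = np.full(20, pseudocount)
    non_gap = 0
    index = {a: i for i, a in enumerate(AA)}
    for res in column:
        if res == GAP:
            continue
        non_gap += 1
        i = index.get(res)
        if i is not None:  # X / * carry no distributional information
            counts[i] += 1.0
    return counts / counts.sum(), non_gap / len(column)


def jsd_conservation(
    msa: ProteinMSA,
    background="blosum62",
    gap_penalty: int = 1,
    window: int = 0,
) -> ConservationTrack:
    """Per-column Jensen-Shannon divergence conservation scores.

    For column distribution p and background q,
    ``JSD = H(p/2 + q/2) - H(p)/2 - H(q)/2`` with base-2 entropies, which is
    bounded by 1 bit, so scores already lie in [0, 1]. With
    ``gap_penalty=1`` each score is multiplied by the column's non-gap
    fraction. ``window > 0`` smooths with the half-weight window average
    used by the original conservation-scoring method (window = columns on
    each side); 0 means no smoothing. Sequences are weighted uniformly;
    pseudocount 1/(20 n).
    """
    if gap_penalty not in (0, 1):
        raise ValueError("gap_penalty must be 0 or 1")
    q = _background_vector(background)
    hq = _entropy_bits(q)
    rows = msa.windowed_rows()
    n_cols = len(rows[0])
    pseudocount = 1.0 / (20.0 * msa.n_sequences)
    raw = np.zeros(n_cols)
    for c in range(n_cols):
        column = [r[c] for r in rows]
        p, non_gap_frac = _column_distribution(column, pseudocount)
        if non_gap_frac == 0.0 and gap_penalty == 1:
            raw[c] = 0.0
            continue
        mixture = 0.5 * (p + q)
        jsd = _entropy_bits(mixture) - 0.5 * _entropy_bits(p) - 0.5 * hq
        jsd = min(max(jsd, 0.0), 1.0)
        if gap_penalty == 1:
            jsd *= non_gap_frac
        raw[c] = jsd
    if window > 0:
        smoothed = raw.copy()
        for c in range(n_cols):
            lo, hi = max(0, c - window), min(n_cols, c + window + 1)
            neighbours = np.concatenate([raw[lo:c], raw[c + 1 : hi]])
            if len(neighbours):
                smoothed[c] = 0.5 * raw[c] + 0.5 * neighbours.mean()
        raw = smoothed
    name = background if isinstance(background, str) else "custom"
    return ConservationTrack(
        scores=raw, background_name=name, gap_penalty=gap_penalty, window=window
    )


def relative_entropy_logo(msa: ProteinMSA, background="blosum62") -> pd.DataFrame:
    """Per-column relative-entropy (bits) and letter heights for a logo.

    Total column height is ``sum_a p(a) log2(p(a)/q(a))`` over observed
    residues; letter heights are proportional to ``p(a)``. Output is a tidy
    table (column, residue, height, total_bits) consumable by logo tools.
    """
    q = _background_vector(background)
    rows = msa.windowed_rows()
    n_cols = len(rows[0])
    index = {a: i for i, a in enumerate(AA)}
    records = []
    for c in range(n_cols):
        counts = np.zeros(20)
        for r in rows:
            i = index.get(r[c])
            if i is not None:
                counts[i] += 1
        total_res = counts.sum()
        if total_res == 0:
            records.append(
                {"column": c, "residue": GAP, "height": 0.0, "total_bits": 0.0}
            )
            continue
        p = counts / total_res
        nz = p > 0
        total_bits = float((p[nz] * np.log2(p[nz] / q[nz])).sum())
        total_bits = max(total_bits, 0.0)
        for i in np.nonzero(nz)[0]:
            records.append(
                {
                    "column": c,
                    "residue": AA[i],
                    "height": float(p[i] * total_bits),
                    "total_bits": total_bits,
                }
            )
    return pd.DataFrame(records)


def select_nonredundant(msa: ProteinMSA, max_identity: float = 0.5) -> ProteinMSA:
    """Greedy non-redundant subset in input order.

    A sequence is kept iff its core-window identity to every already-kept
    sequence is below ``max_identity`` (fraction).
    """
    ident = identity_matrix(msa).values
    kept: list[int] = []
    for i in range(msa.n_sequences):
        if all(
            np.isnan(ident[i, j]) or ident[i, j] < max_identity * 100.0 for j in kept
        ):
            kept.append(i)
    return msa.subset(kept)


def matrix_report(identity: PairwiseMatrix, similarity: PairwiseMatrix) -> pd.DataFrame:
    """Single table with identity above the diagonal, similarity below."""
    if identity.ids != similarity.ids:
        raise ValueError("matrices computed on different sequence sets")
    n = len(identity.ids)
    combined = np.full((n, n), 100.0)
    iu = np.triu_indices(n, k=1)
    il = np.tril_indices(n, k=-1)
    combined[iu] = identity.values[iu]
    combined[il] = similarity.values[il]
    return pd.DataFrame(combined, index=identity.ids, columns=identity.ids)
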