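"""Independent reference implementations used only by the tests.

Deliberately naive: exhaustive enumeration and plain dynamic programs with
no shared code with the package, so they can serve as oracles.
"""

from __future__ import annotations

import itertools
import math


def score_alignment(aligned_a, aligned_b, match, mismatch, gap_open, gap_extend):
    """Score a pair of aligned strings; gap run of length L costs
    gap_open + L * gap_extend; N matches nothing."""
    score = 0
    run_a = run_b = 0
    for x, y in zip(aligned_a, aligned_b):
        if x == "-":
            score -= gap_extend + (gap_open if run_a == 0 else 0)
            run_a += 1
            run_b = 0
        elif y == "-":
            score -= gap_extend + (gap_open if run_b == 0 else 0)
            run_b += 1
            run_a = 0
        else:
            run_a = run_b = 0
            score += match if (x == y and x != "N") else mismatch
    return score


def brute_global_score(a, b, match, mismatch, gap_open, gap_extend):
    """Optimal global score by exhaustive enumeration of all alignments."""
    best = [-math.inf]

    def rec(i, j, col_a, col_b):
        if i == len(a) and j == len(b):
            best[0] = max(
                best[0],
                score_alignment(col_a, col_b, match, mismatch, gap_open, gap_extend),
            )
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, col_a + a[i], col_b + b[j])
        if i < len(a):
            rec(i + 1, j, col_a + a[i], col_b + "-")
        if j < len(b):
            rec(i, j + 1, col_a + "-", col_b + b[j])

    rec(0, 0, "", "")
    return best[0]


def gotoh_scores(a, b, match, mismatch, gap_open, gap_extend, local):
    """Plain affine-gap DP; returns (global score, best local score)."""
    NEG = -10**9
    o = gap_open + gap_extend
    e = gap_extend
    n, m = len(a), len(b)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    if not local:
        for i in range(1, n + 1):
            E[i][0] = -(gap_open + gap_extend * i)
            H[i][0] = E[i][0]
        for j in range(1, m + 1):
            F[0][j] = -(gap_open + gap_extend * j)
            H[0][j] = F[0][j]
    best_local = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] - o, E[i - 1][j] - e)
            F[i][j] = max(H[i][j - 1] - o, F[i][j - 1] - e)
            s = match if (a[i - 1] == b[j - 1] and a[i - 1] != "N") else mismatch
            h = max(H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if local:
                h = max(h, 0)
            H[i][j] = h
            best_local = max(best_local, h)
    return H[n][m], best_local


def jsd_direct(counts, background, n_sequences, gap_fraction, gap_penalty):
    """Direct 20-term summation of the Jensen-Shannon conservation score.

    ``counts`` maps residue -> count for one column (gaps excluded).
    """
    aa = "ACDEFGHIKLMNPQRSTVWY"
    eps = 1.0 / (20.0 * n_sequences)
    p = [counts.get(x, 0) + eps for x in aa]
    total = sum(p)
    p = [v / total for v in p]
    q = [background[x] for x in aa]
    qs = sum(q)
    q = [v / qs for v in q]

    def h(dist):
        return -sum(v * math.log2(v) for v in dist if v > 0)

    m = [(x + y) / 2 for x, y in zip(p, q)]
    jsd = h(m) - 0.5 * h(p) - 0.5 * h(q)
    jsd = min(max(jsd, 0.0), 1.0)
    if gap_penalty == 1:
        jsd *= 1.0 - gap_fraction
    return jsd


def motif_placements(sequence, elements):
    """All anchor placements of a flexible-gap motif, by brute force.

    ``elements`` is a list of (residue_set, min_gap, max_gap); returns a
    sorted list of anchor-position tuples.
    """
    gap_ranges = [range(lo, hi + 1) for _, lo, hi in elements[1:]]
    hits = []
    for start in range(len(sequence)):
        if sequence[start] not in elements[0][0]:
            continue
        for gaps in itertools.product(*gap_ranges):
            pos = start
            positions = [start]
            ok = True
            for (residues, _, _), gap in zip(elements[1:], gaps):
                pos = pos + 1 + gap
                if pos >= len(sequence) or sequence[pos] not in residues:
                    ok = False
                    break
                positions.append(pos)
            if ok:
                hits.append(tuple(positions))
    return sorted(set(hits))
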