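"""Independent brute-force oracles used only by the test suite.

These re-derive, by direct definition, the quantities the library computes
with optimized code paths: Gotoh affine-gap local alignment (for identity
and coverage) and maximal colinear chain decomposition (for synteny runs).
"""

from __future__ import annotations

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

NEG = float("-inf")


def sw_align(
    a: str, b: str, gap_open: float = -11.0, gap_extend: float = -1.0
) -> tuple[float, float, float]:
    """Smith-Waterman with affine gaps; returns (score, identity%, coverage).

    Gap scoring convention: the first gap residue costs ``gap_open``, each
    further residue ``gap_extend``.  Traceback prefers diagonal, then gaps
    in ``a``, then gaps in ``b``.
    """
    n, m = len(a), len(b)
    M = [[0.0] * (m + 1) for _ in range(n + 1)]  # match/mismatch state
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    best, bi, bj = 0.0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = float(_BLOSUM62[a[i - 1], b[j - 1]])
            M[i][j] = max(
                0.0, s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            )
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend)
            if M[i][j] > best:
                best, bi, bj = M[i][j], i, j
    if best == 0.0:
        return 0.0, 0.0, 0.0
    # traceback from the best M cell until the running score hits 0
    i, j, state = bi, bj, "M"
    cols = matches = 0
    ei, ej = bi, bj
    while i > 0 and j > 0:
        if state == "M":
            if M[i][j] == 0.0:
                break
            cols += 1
            if a[i - 1] == b[j - 1]:
                matches += 1
            s = float(_BLOSUM62[a[i - 1], b[j - 1]])
            prev = M[i][j] - s
            if abs(prev - M[i - 1][j - 1]) < 1e-9 or prev <= 1e-9:
                state = "M"
            elif abs(prev - X[i - 1][j - 1]) < 1e-9:
                state = "X"
            else:
                state = "Y"
            i, j = i - 1, j - 1
            if state == "M" and M[i][j] == 0.0:
                break
        elif state == "X":
            cols += 1
            if abs(X[i][j] - (M[i - 1][j] + (-11.0))) < 1e-9:
                state = "M"
            i -= 1
        else:
            cols += 1
            if abs(Y[i][j] - (M[i][j - 1] + (-11.0))) < 1e-9:
                state = "M"
            j -= 1
    span_a, span_b = ei - i, ej - j
    identity = 100.0 * matches / cols
    span_short = span_a if n <= m else span_b
    coverage = span_short / min(n, m)
    return best, identity, coverage


def maximal_colinear_chains(
    links: list[tuple[int, int]], max_gap: int
) -> list[list[tuple[int, int]]]:
    """Decompose (rank_a, rank_b) pairs into maximal colinear chains.

    Whole-segment validity check by definition: a contiguous slice of the
    rank_a-sorted pair list is a valid chain iff every consecutive step
    moves forward by at most ``max_gap + 1`` on the reference, by at most
    ``max_gap + 1`` in absolute value on the partner, and all partner steps
    share one sign.  The decomposition takes the longest valid prefix
    starting at each unassigned pair.
    """
    pairs = sorted(links)

    def valid(seg: list[tuple[int, int]]) -> bool:
        sign = 0
        for (a1, b1), (a2, b2) in zip(seg, seg[1:]):
            da, db = a2 - a1, b2 - b1
            if not 0 < da <= max_gap + 1:
                return False
            if db == 0 or abs(db) > max_gap + 1:
                return False
            s = 1 if db > 0 else -1
            if sign and s != sign:
                return False
            sign = sign or s
        return True

    chains: list[list[tuple[int, int]]] = []
    i = 0
    while i < len(pairs):
        j = i + 1
        while j <= len(pairs) and valid(pairs[i:j]):
            j += 1
        chains.append(pairs[i : j - 1])
        i = j - 1
    return chains
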