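"""Independent oracles used by the test suite.

These deliberately avoid the package's own dynamic-programming code paths:
the local-alignment oracle enumerates every alignment path explicitly, and
the interval-merge oracle works by pointwise base marking.
"""

from __future__ import annotations

import sys


def brute_local_score(query: str, subject: str, scheme) -> int:
    """Best local alignment score by exhaustive path enumeration.

    Considers every substring pair and every global alignment path between
    the substrings, charging ``gap_open + g * gap_extend`` per gap run.
    Exponential; only usable for sequences of length <= ~6.
    """
    go, ge = scheme.gap_open, scheme.gap_extend
    first = go + ge
    best = 0  # the empty alignment scores 0
    sys.setrecursionlimit(10000)

    def rec(a: str, b: str, i: int, j: int, prev: str, score: int) -> None:
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            rec(a, b, i + 1, j + 1, "M", score + scheme.score(a[i], b[j]))
        if i < len(a):
            rec(a, b, i + 1, j, "X", score - (ge if prev == "X" else first))
        if j < len(b):
            rec(a, b, i, j + 1, "Y", score - (ge if prev == "Y" else first))

    for i1 in range(len(query)):
        for i2 in range(i1 + 1, len(query) + 1):
            for j1 in range(len(subject)):
                for j2 in range(j1 + 1, len(subject) + 1):
                    rec(query[i1:i2], subject[j1:j2], 0, 0, "M", 0)
    return best


def biopython_local_score(query: str, subject: str, scheme) -> float:
    """Local score via Biopython's independent PairwiseAligner."""
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    aligner.extend_gap_score = -scheme.gap_extend
    return aligner.score(query, subject)


def merge_intervals_oracle(intervals, max_gap):
    """Merge intervals within max_gap by sorting and sweeping."""
    out = []
    for start, end in sorted(intervals):
        if out and start - out[-1][1] <= max_gap:
            out[-1][1] = max(out[-1][1], end)
        else:
            out.append([start, end])
    return [tuple(x) for x in out]
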