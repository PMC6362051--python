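"""Pairwise local protein alignment and Karlin-Altschul E-values.

This module is the in-package replacement for BLAST-style searching: an
affine-gap Smith-Waterman (Gotoh three-state recurrence) with a substitution
matrix, percent identity, query coverage, and the Karlin-Altschul expectation
``E = K * m * n * exp(-lambda * S)`` used to gate hits.

Determinism contract
--------------------
The traceback is bit-reproducible: the highest-scoring cell is chosen by
smallest subject index, then smallest query index; within the traceback ties
prefer the diagonal, then gap-in-subject, then gap-in-query, and a tied gap
state prefers closing the gap (shorter gaps).  A gap of length ``g`` costs
``gap_open + g * gap_extend`` (the BLAST "11/1" convention, so the first gap
position costs 12 with the defaults).

No effective-length (edge) correction and no compositional adjustment is
applied to E-values, so absolute values differ from NCBI BLAST output; the
coarse cut-offs used for discovery (1e-06) and surveys (1e-04) remain
meaningful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

from .seqio import ProteinSeq

__all__ = [
    "ScoringScheme",
    "AlignmentResult",
    "default_scheme",
    "read_matrix",
    "sw_align",
    "evalue",
    "min_score_for_evalue",
    "percent_identity",
    "query_coverage",
]

# published gapped BLOSUM62 / 11 / 1 Karlin-Altschul constants
DEFAULT_LAMBDA = 0.267
DEFAULT_KAPPA = 0.041


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix, affine gap penalties and K-A constants."""

    alphabet: str
    matrix: np.ndarray  # square integer table over `alphabet`
    gap_open: int = 11
    gap_extend: int = 1
    lambda_: float = DEFAULT_LAMBDA
    kappa: float = DEFAULT_KAPPA
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.int64)
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] != len(self.alphabet):
            raise ValueError("matrix must be square over the alphabet")
        if not np.array_equal(m, m.T):
            raise ValueError("substitution matrix must be symmetric")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")
        if self.lambda_ <= 0 or self.kappa <= 0:
            raise ValueError("Karlin-Altschul constants must be positive")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(
            self, "_index", {c: i for i, c in enumerate(self.alphabet)}
        )

    def encode(self, residues: str) -> np.ndarray:
        try:
            return np.array([self._index[c] for c in residues], dtype=np.int64)
        except KeyError as exc:
            raise ValueError(
                f"residue {exc.args[0]!r} absent from matrix alphabet"
            ) from None

    def score(self, a: str, b: str) -> int:
        return int(self.matrix[self._index[a], self._index[b]])


def read_matrix(path: str | Path) -> tuple[str, np.ndarray]:
    """Read an NCBI-style whitespace-separated substitution matrix file."""
    arr = substitution_matrices.read(str(path))
    return "".join(arr.alphabet), np.asarray(arr, dtype=np.int64)


def default_scheme(gap_open: int = 11, gap_extend: int = 1,
                   lambda_: float = DEFAULT_LAMBDA,
                   kappa: float = DEFAULT_KAPPA) -> ScoringScheme:
    """BLOSUM62 / 11 / 1 with published gapped Karlin-Altschul constants."""
    ref = resources.files("tapairscan.data") / "BLOSUM62.txt"
    with resources.as_file(ref) as p:
        alphabet, matrix = read_matrix(p)
    return ScoringScheme(alphabet=alphabet, matrix=matrix, gap_open=gap_open,
                         gap_extend=gap_extend, lambda_=lambda_, kappa=kappa)


@dataclass
class AlignmentResult:
    """A scored local alignment between a query and a subject protein."""

    query_id: str
    subject_id: str
    score: int
    query_span: tuple[int, int]  # half-open on the query
    subject_span: tuple[int, int]  # half-open on the subject
    columns: list[tuple[str, str]]  # (query symbol, subject symbol), '-' = gap
    query_len: int
    subject_len: int
    evalue: float | None = None

    @property
    def is_empty(self) -> bool:
        return not self.columns

    @property
    def alignment_length(self) -> int:
        return len(self.columns)

    @property
    def identities(self) -> int:
        return sum(1 for a, b in self.columns if a == b and a != "-")

    @property
    def gap_opens(self) -> int:
        n = 0
        prev = None
        for a, b in self.columns:
            state = "q" if a == "-" else ("s" if b == "-" else None)
            if state is not None and state != prev:
                n += 1
            prev = state
        return n

    @property
    def mismatches(self) -> int:
        return sum(1 for a, b in self.columns if a != "-" and b != "-" and a != b)

    @property
    def percent_identity(self) -> float:
        return percent_identity(self)

    @property
    def query_coverage(self) -> float:
        return query_coverage(self)


def percent_identity(aln: AlignmentResult) -> float:
    """Identical columns over ALL alignment columns (gaps in denominator), %."""
    if aln.is_empty:
        raise ValueError("percent identity undefined for an empty alignment")
    return round(100.0 * aln.identities / aln.alignment_length, 1)


def query_coverage(aln: AlignmentResult, query_len: int | None = None) -> float:
    """Aligned query span over full query length, %."""
    qlen = aln.query_len if query_len is None else query_len
    return 100.0 * (aln.query_span[1] - aln.query_span[0]) / qlen


def evalue(score: int, query_len: int, db_len: int,
           scheme: ScoringScheme) -> float:
    """Karlin-Altschul expectation ``K * m * n * exp(-lambda * S)``."""
    if score < 0:
        raise ValueError("score must be non-negative")
    if query_len < 1 or db_len < 1:
        raise ValueError("lengths must be >= 1")
    return scheme.kappa * query_len * db_len * math.exp(-scheme.lambda_ * score)


def min_score_for_evalue(cutoff: float, query_len: int, db_len: int,
                         scheme: ScoringScheme) -> int:
    """Smallest integer score whose E-value is <= ``cutoff``."""
    s = math.log(scheme.kappa * query_len * db_len / cutoff) / scheme.lambda_
    smin = max(0, math.ceil(s))
    # guard against floating-point boundary effects
    while smin > 0 and evalue(smin - 1, query_len, db_len, scheme) <= cutoff:
        smin -= 1
    while evalue(smin, query_len, db_len, scheme) > cutoff:
        smin += 1
    return smin


# ---------------------------------------------------------------------------
# Gotoh three-state local alignment

_NEG = np.int64(-(10**9))


@njit(cache=True)
def _gotoh_best(q: np.ndarray, s: np.ndarray, matrix: np.ndarray,
                gap_first: int, gap_extend: int) -> tuple[int, int, int]:
    """Score-only Gotoh pass: best local score and its end cell.

    Ties on the best score are broken by smallest subject index ``j`` then
    smallest query index ``i``.  ``gap_first`` is the cost of the first gap
    position (open + extend).  Returns (score, i, j) with 1-based end cell.
    """
    m, n = len(q), len(s)
    H = np.zeros(n + 1, dtype=np.int64)
    Iy = np.full(n + 1, -(10**9), dtype=np.int64)
    best = 0
    bi = 0
    bj = 0
    Ix_col = np.full(n + 1, -(10**9), dtype=np.int64)
    for i in range(1, m + 1):
        diag = H[0]
        H[0] = 0
        iy = -(10**9)
        for j in range(1, n + 1):
            ix = Ix_col[j] - gap_extend
            alt = H[j] - gap_first
            if alt > ix:
                ix = alt
            Ix_col[j] = ix
            iy_ext = iy - gap_extend
            iy_open = H[j - 1] - gap_first
            iy = iy_open if iy_open > iy_ext else iy_ext
            h = diag + matrix[q[i - 1], s[j - 1]]
            if ix > h:
                h = ix
            if iy > h:
                h = iy
            if h < 0:
                h = 0
            diag = H[j]
            H[j] = h
            if h > best or (h == best and h > 0 and
                            (j < bj or (j == bj and i < bi))):
                best = h
                bi = i
                bj = j
    return best, bi, bj


def gotoh_score(query: str | np.ndarray, subject: str | np.ndarray,
                scheme: ScoringScheme) -> int:
    """Best local alignment score only (fast path used by the search layer)."""
    q = scheme.encode(query) if isinstance(query, str) else query
    s = scheme.encode(subject) if isinstance(subject, str) else subject
    best, _, _ = _gotoh_best(q, s, scheme.matrix,
                             scheme.gap_open + scheme.gap_extend,
                             scheme.gap_extend)
    return int(best)


def _fill_matrices(q: np.ndarray, s: np.ndarray, scheme: ScoringScheme):
    m, n = len(q), len(s)
    gap_first = scheme.gap_open + scheme.gap_extend
    ge = scheme.gap_extend
    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    Ix = np.full((m + 1, n + 1), _NEG, dtype=np.int64)  # gap in subject
    Iy = np.full((m + 1, n + 1), _NEG, dtype=np.int64)  # gap in query
    sub = scheme.matrix
    for i in range(1, m + 1):
        Hi = H[i]
        Hp = H[i - 1]
        for j in range(1, n + 1):
            Ix[i, j] = max(Hp[j] - gap_first, Ix[i - 1, j] - ge)
            Iy[i, j] = max(Hi[j - 1] - gap_first, Iy[i, j - 1] - ge)
            Hi[j] = max(0, Hp[j - 1] + sub[q[i - 1], s[j - 1]], Ix[i, j], Iy[i, j])
    return H, Ix, Iy


def sw_align(query: ProteinSeq | str, subject: ProteinSeq | str,
             scheme: ScoringScheme | None = None) -> AlignmentResult:
    """Maximal-scoring local alignment under affine-gap scoring.

    Returns an empty alignment (score 0, zero-length spans) when no
    positive-scoring residue pairing exists.
    """
    if scheme is None:
        scheme = default_scheme()
    qid = query.id if isinstance(query, ProteinSeq) else "query"
    sid = subject.id if isinstance(subject, ProteinSeq) else "subject"
    qres = query.residues if isinstance(query, ProteinSeq) else query
    sres = subject.residues if isinstance(subject, ProteinSeq) else subject
    if not qres or not sres:
        raise ValueError("sequences must be non-empty")
    q = scheme.encode(qres)
    s = scheme.encode(sres)
    H, Ix, Iy = _fill_matrices(q, s, scheme)

    # best cell: smallest subject index, then smallest query index
    best = int(H.max())
    if best == 0:
        return AlignmentResult(qid, sid, 0, (0, 0), (0, 0), [],
                               len(qres), len(sres))
    cells = np.argwhere(H == best)
    order = np.lexsort((cells[:, 0], cells[:, 1]))
    bi, bj = (int(x) for x in cells[order[0]])

    gap_first = scheme.gap_open + scheme.gap_extend
    ge = scheme.gap_extend
    cols: list[tuple[str, str]] = []
    i, j, state = bi, bj, "H"
    while not (state == "H" and H[i, j] == 0):
        if state == "H":
            # tie preference: diagonal, gap-in-subject (Ix), gap-in-query (Iy)
            if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + scheme.matrix[q[i - 1], s[j - 1]]:
                cols.append((qres[i - 1], sres[j - 1]))
                i -= 1
                j -= 1
            elif H[i, j] == Ix[i, j]:
                state = "Ix"
            else:
                state = "Iy"
        elif state == "Ix":
            cols.append((qres[i - 1], "-"))
            # tie preference: close the gap (come from H)
            if H[i - 1, j] - gap_first == Ix[i, j]:
                state = "H"
            i -= 1
        else:  # Iy
            cols.append(("-", sres[j - 1]))
            if H[i, j - 1] - gap_first == Iy[i, j]:
                state = "H"
            j -= 1
    cols.reverse()
    return AlignmentResult(
        query_id=qid,
        subject_id=sid,
        score=best,
        query_span=(i, bi),
        subject_span=(j, bj),
        columns=cols,
        query_len=len(qres),
        subject_len=len(sres),
    )
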