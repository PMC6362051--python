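"""Operon-neighborhood pairing of toxin and antitoxin loci.

A neighbouring gene counts as an antitoxin candidate only if (1) it precedes
the putative toxin in the toxin's transcription direction and (2) its
distance from the toxin gene is at most ``max_separation_bp`` (default
150 bp, inclusive).  Distance is measured between nearest annotated gene
boundaries in half-open arithmetic; a negative separation denotes an overlap
by that many bases.  By default the partners must be co-oriented — type II
TA pairs are co-transcribed operons — but the requirement is a parameter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

from .search import GenomicHit
from .seqio import GeneFeature

__all__ = [
    "PairingParams",
    "TAPairCandidate",
    "intergenic_distance",
    "precedes",
    "find_antitoxin_candidates",
    "pair_hits",
]

Locus = Union[GeneFeature, GenomicHit]


def _interval(x: Locus) -> tuple[int, int]:
    if isinstance(x, GeneFeature):
        return x.start, x.end
    return x.genomic_span


def _strand(x: Locus) -> str:
    return x.strand


@dataclass(frozen=True)
class PairingParams:
    max_separation_bp: int = 150
    require_same_strand: bool = True
    allow_overlap: bool = True

    def __post_init__(self) -> None:
        if self.max_separation_bp < 0:
            raise ValueError("max_separation_bp must be >= 0")


@dataclass(frozen=True)
class TAPairCandidate:
    """A toxin locus joined to a putative upstream antitoxin."""

    toxin: Locus
    antitoxin: Locus
    separation_bp: int  # negative = overlap by that many bases
    precedes: bool  # antitoxin upstream in the toxin's transcription direction
    accepted: bool
    rejection_reason: str | None = None  # too_far | wrong_side | strand_mismatch


def intergenic_distance(a: Locus, b: Locus) -> int:
    """Signed gap between two loci: ``right.start - left.end`` in genomic order.

    Negative values indicate overlap by that many bases; identical intervals
    give ``-length``.
    """
    (a0, a1), (b0, b1) = _interval(a), _interval(b)
    # equals right.start - left.end for disjoint intervals and is symmetric
    # under coordinate mirroring for nested ones
    return max(a0, b0) - min(a1, b1)


def precedes(antitoxin: Locus, toxin: Locus) -> bool:
    """Is the candidate upstream of the toxin in its transcription direction?

    On a ``+`` strand toxin the candidate must lie genomically left; on a
    ``-`` strand toxin, genomically right.  Overlapping loci are ordered by
    midpoint; a candidate with the toxin's own interval never precedes it.
    """
    (t0, t1), (c0, c1) = _interval(toxin), _interval(antitoxin)
    if (t0, t1) == (c0, c1):
        return False
    t_mid = (t0 + t1) / 2.0
    c_mid = (c0 + c1) / 2.0
    if c1 <= t0:
        candidate_left = True
    elif c0 >= t1:
        candidate_left = False
    else:  # overlap: midpoint order, midpoint tie counts as not preceding
        if c_mid == t_mid:
            return False
        candidate_left = c_mid < t_mid
    return candidate_left if _strand(toxin) == "+" else not candidate_left


def _evaluate(toxin: Locus, candidate: Locus,
              params: PairingParams) -> TAPairCandidate:
    sep = intergenic_distance(toxin, candidate)
    up = precedes(candidate, toxin)
    reason: str | None = None
    # first failing reason, checked in order
    if not up:
        reason = "wrong_side"
    elif params.require_same_strand and _strand(candidate) != _strand(toxin):
        reason = "strand_mismatch"
    elif sep > params.max_separation_bp:
        reason = "too_far"
    elif sep < 0 and not params.allow_overlap:
        reason = "too_far"
    return TAPairCandidate(
        toxin=toxin,
        antitoxin=candidate,
        separation_bp=sep,
        precedes=up,
        accepted=reason is None,
        rejection_reason=reason,
    )


def find_antitoxin_candidates(toxin: Locus, features: Sequence[Locus],
                              params: PairingParams | None = None,
                              ) -> list[TAPairCandidate]:
    """Evaluate every other feature as a putative antitoxin for one toxin.

    Accepted candidates come first, sorted by separation ascending; rejected
    candidates follow, each carrying its first failing reason.
    """
    params = params or PairingParams()
    out = [
        _evaluate(toxin, f, params)
        for f in features
        if not (_interval(f) == _interval(toxin) and _strand(f) == _strand(toxin))
    ]
    out.sort(key=lambda c: (not c.accepted, c.separation_bp))
    return out


def pair_hits(toxin_hits: Sequence[GenomicHit],
              antitoxin_hits: Sequence[GenomicHit],
              params: PairingParams | None = None) -> list[TAPairCandidate]:
    """Evaluate all toxin x antitoxin hit pairings from one genome.

    Accepted pairs are sorted by combined E-value ascending (best first),
    then rejected pairs; the head of the list is the genome's best pairing.
    """
    params = params or PairingParams()
    out = [
        _evaluate(t, a, params)
        for t in toxin_hits
        for a in antitoxin_hits
    ]

    def key(c: TAPairCandidate):
        t, a = c.toxin, c.antitoxin
        combined = t.evalue * a.evalue  # type: ignore[union-attr]
        return (not c.accepted, combined, c.separation_bp)

    out.sort(key=key)
    return out
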