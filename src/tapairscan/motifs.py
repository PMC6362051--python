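"""Motif scanning, residue-equivalence mapping and conservation counting.

Built-in patterns cover the Walker-A / P-loop nucleotide-binding motif of
phosphotransferases, ``GXXGXXK[TS]`` (the canonical motif ends in T but the
serine variant is treated as a match — e.g. ``GPNGAGKS``), and the ``GTXR``
UNAG-binding motif of canonical zeta/PezT toxins, whose absence in a
homologue suggests an alternative substrate.

Residue positions are 1-based on the mature sequence exactly as supplied; no
offset handling for His-tags or PDB SEQRES gaps is attempted, so PDB-derived
sequences must be provided as plain FASTA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .align import AlignmentResult, ScoringScheme, default_scheme, sw_align
from .seqio import ProteinSeq

__all__ = [
    "MotifPattern",
    "MotifMatch",
    "ResidueEquivalence",
    "ConservationReport",
    "RegionIdentity",
    "parse_pattern",
    "P_LOOP",
    "GTXR",
    "scan_motif",
    "map_equivalent_residues",
    "conservation_report",
    "region_identity",
]

_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class MotifPattern:
    """A positional pattern: each position is a residue set; None = wildcard."""

    name: str
    positions: tuple[frozenset[str] | None, ...]

    def __post_init__(self) -> None:
        if not self.positions:
            raise ValueError("empty motif pattern")
        if all(p is None for p in self.positions):
            raise ValueError("motif must constrain at least one position")

    def __len__(self) -> int:
        return len(self.positions)

    def matches(self, window: str) -> bool:
        return len(window) == len(self.positions) and all(
            spec is None or c in spec for c, spec in zip(window, self.positions)
        )


def parse_pattern(name: str, spec: str) -> MotifPattern:
    """Parse a pattern string: ``X`` wildcard, ``[TS]`` residue set.

    Example: ``"GXXGXXK[TS]"`` is the generalized Walker-A motif.
    """
    positions: list[frozenset[str] | None] = []
    i = 0
    while i < len(spec):
        c = spec[i]
        if c == "X":
            positions.append(None)
            i += 1
        elif c == "[":
            j = spec.find("]", i)
            if j == -1:
                raise ValueError(f"unclosed '[' in pattern {spec!r}")
            members = spec[i + 1 : j]
            if not members or set(members) - _AA:
                raise ValueError(f"invalid residue set {members!r} in {spec!r}")
            positions.append(frozenset(members))
            i = j + 1
        elif c in _AA:
            positions.append(frozenset(c))
            i += 1
        else:
            raise ValueError(f"invalid pattern character {c!r} in {spec!r}")
    return MotifPattern(name=name, positions=tuple(positions))


#: Walker-A / P-loop, serine-terminal variant included
P_LOOP = parse_pattern("P-loop", "GXXGXXK[TS]")
#: UNAG-binding motif of canonical zeta/PezT toxins
GTXR = parse_pattern("GTXR", "GTXR")


@dataclass(frozen=True)
class MotifMatch:
    motif: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    matched: str


def scan_motif(protein: ProteinSeq | str, motif: MotifPattern) -> list[MotifMatch]:
    """All (possibly overlapping) motif occurrences, ascending start."""
    residues = protein.residues if isinstance(protein, ProteinSeq) else protein
    w = len(motif)
    return [
        MotifMatch(motif=motif.name, start=i + 1, end=i + w,
                   matched=residues[i : i + w])
        for i in range(len(residues) - w + 1)
        if motif.matches(residues[i : i + w])
    ]


@dataclass(frozen=True)
class ResidueEquivalence:
    """Where one reference residue lands in a candidate, via alignment columns."""

    reference_id: str
    reference_pos: int  # 1-based
    reference_res: str
    candidate_id: str
    candidate_pos: int | None  # 1-based, None when gapped/unaligned
    candidate_res: str | None
    status: str  # identical | similar | different | unaligned


@dataclass(frozen=True)
class ConservationReport:
    reference_positions: tuple[int, ...]
    equivalences: tuple[ResidueEquivalence, ...]

    @property
    def conserved_count(self) -> int:
        return sum(1 for e in self.equivalences if e.status == "identical")

    @property
    def similar_count(self) -> int:
        return sum(1 for e in self.equivalences if e.status == "similar")


def map_equivalent_residues(aln: AlignmentResult,
                            reference_positions: Sequence[int],
                            scheme: ScoringScheme | None = None,
                            ) -> list[ResidueEquivalence]:
    """Map 1-based reference (query) positions onto the aligned candidate.

    Walks the alignment columns; a reference position aligned to a gap column
    or lying outside the aligned span reports status ``unaligned``.  A
    non-identical pairing with a positive substitution score is ``similar``.
    """
    scheme = scheme or default_scheme()
    for p in reference_positions:
        if not 1 <= p <= aln.query_len:
            raise ValueError(f"reference position {p} outside query of length "
                             f"{aln.query_len}")
    # column walk: current 1-based positions on query/subject
    mapping: dict[int, tuple[int | None, str | None]] = {}
    qpos = aln.query_span[0]
    spos = aln.subject_span[0]
    for qc, sc in aln.columns:
        if qc != "-":
            qpos += 1
        if sc != "-":
            spos += 1
        if qc != "-":
            mapping[qpos] = (spos, sc) if sc != "-" else (None, None)
    out: list[ResidueEquivalence] = []
    qres = _query_residue_lookup(aln)
    for p in reference_positions:
        ref_res = qres(p)
        cand_pos, cand_res = mapping.get(p, (None, None))
        if cand_res is None:
            status = "unaligned"
        elif cand_res == ref_res:
            status = "identical"
        elif scheme.score(ref_res, cand_res) > 0:
            status = "similar"
        else:
            status = "different"
        out.append(
            ResidueEquivalence(
                reference_id=aln.query_id,
                reference_pos=p,
                reference_res=ref_res,
                candidate_id=aln.subject_id,
                candidate_pos=cand_pos,
                candidate_res=cand_res,
                status=status,
            )
        )
    return out


def _query_residue_lookup(aln: AlignmentResult):
    """Reconstruct query residues by position from the aligned columns.

    Positions outside the aligned span are unknown to the alignment object;
    they are reported as ``?`` (their status is necessarily ``unaligned``).
    """
    known: dict[int, str] = {}
    qpos = aln.query_span[0]
    for qc, _sc in aln.columns:
        if qc != "-":
            qpos += 1
            known[qpos] = qc

    def lookup(p: int) -> str:
        return known.get(p, "?")

    return lookup


def conservation_report(aln: AlignmentResult,
                        reference_positions: Sequence[int],
                        scheme: ScoringScheme | None = None,
                        ) -> ConservationReport:
    """Per-position equivalence status over a supplied reference residue set.

    ``conserved_count`` counts identical residues only; similar (positive
    matrix score) residues are reported alongside, never silently merged.
    """
    eqs = map_equivalent_residues(aln, reference_positions, scheme)
    return ConservationReport(
        reference_positions=tuple(reference_positions),
        equivalences=tuple(eqs),
    )


@dataclass(frozen=True)
class RegionIdentity:
    percent_identity: float
    aligned: bool
    alignment: AlignmentResult | None = None


def region_identity(seq_a: ProteinSeq, region_a: tuple[int, int] | None,
                    seq_b: ProteinSeq, region_b: tuple[int, int] | None = None,
                    scheme: ScoringScheme | None = None) -> RegionIdentity:
    """Percent identity between (sub)regions of two proteins.

    Regions are 1-based inclusive intervals, or None for the whole sequence.
    The sub-sequences are compared with the local aligner; when no
    positive-scoring alignment exists the identity is 0.0 with
    ``aligned=False``.
    """
    scheme = scheme or default_scheme()

    def cut(seq: ProteinSeq, region: tuple[int, int] | None) -> ProteinSeq:
        if region is None:
            return seq
        lo, hi = region
        if not (1 <= lo <= hi <= len(seq)):
            raise ValueError(
                f"region {region} invalid for {seq.id!r} of length {len(seq)}"
            )
        return ProteinSeq(id=f"{seq.id}[{lo}-{hi}]", residues=seq.residues[lo - 1 : hi])

    a = cut(seq_a, region_a)
    b = cut(seq_b, region_b)
    aln = sw_align(a, b, scheme)
    if aln.is_empty:
        return RegionIdentity(percent_identity=0.0, aligned=False, alignment=None)
    return RegionIdentity(
        percent_identity=aln.percent_identity, aligned=True, alignment=aln
    )
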