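"""TBLASTN-like search of protein queries against six-frame translated genomes.

Each of the six frame translations is split at stop codons (``*``) into
stop-free segments — alignments never cross an in-frame stop, matching
translated-search biology.  The query is locally aligned against each
segment; hits are gated on E-value and query coverage and mapped back to
forward-strand genomic coordinates through the frame coordinate map.

E-values use ``db_len`` = total stop-free translated residues across all
frames of every genome in the invocation, computed before any filtering, so
results are deterministic and order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .align import (AlignmentResult, ScoringScheme, default_scheme, evalue,
                    gotoh_score, min_score_for_evalue, sw_align)
from .seqio import FrameTranslation, GenomeRecord, ProteinSeq, six_frame_translate

__all__ = [
    "SearchParams",
    "GenomicHit",
    "stop_free_segments",
    "database_length",
    "search_genome",
    "merge_hits",
    "best_hit",
    "hits_to_tsv",
]


@dataclass(frozen=True)
class SearchParams:
    """Hit-filtering gates of a translated search."""

    evalue_cutoff: float = 1e-6
    coverage_cutoff: float = 60.0  # percent of the query that must align
    max_hits_per_genome: int = 50

    def __post_init__(self) -> None:
        if self.evalue_cutoff <= 0:
            raise ValueError("evalue_cutoff must be positive")
        if not 0 < self.coverage_cutoff <= 100:
            raise ValueError("coverage_cutoff must be in (0, 100]")


#: survey-mode gates (cross-genome conservation scan)
SURVEY_PARAMS = SearchParams(evalue_cutoff=1e-4, coverage_cutoff=70.0)


@dataclass(frozen=True)
class GenomicHit:
    """A filtered alignment of a protein query to a genomic locus."""

    query_id: str
    genome_id: str
    frame: int
    alignment: AlignmentResult
    genomic_span: tuple[int, int]  # 0-based half-open, forward strand
    strand: str

    @property
    def evalue(self) -> float:
        assert self.alignment.evalue is not None
        return self.alignment.evalue

    @property
    def start(self) -> int:
        return self.genomic_span[0]

    @property
    def end(self) -> int:
        return self.genomic_span[1]


@dataclass(frozen=True)
class _Segment:
    frame: FrameTranslation
    offset: int  # protein position of the segment start within the frame
    residues: str


def stop_free_segments(frames: Iterable[FrameTranslation]) -> list[_Segment]:
    """Split each frame translation at ``*`` into stop-free segments."""
    segments: list[_Segment] = []
    for ft in frames:
        pos = 0
        for part in ft.protein.residues.split("*"):
            if part:
                segments.append(_Segment(frame=ft, offset=pos, residues=part))
            pos += len(part) + 1
    return segments


def database_length(genomes: Iterable[GenomeRecord]) -> int:
    """Total stop-free translated residues across all six frames of all genomes."""
    total = 0
    for g in genomes:
        for seg in stop_free_segments(six_frame_translate(g)):
            total += len(seg.residues)
    return total


def _genomic_span(seg: _Segment, subject_span: tuple[int, int]) -> tuple[int, int]:
    """Map a segment-local residue span to a forward-strand genomic interval."""
    first = seg.offset + subject_span[0]
    last = seg.offset + subject_span[1] - 1
    a, strand = seg.frame.coord_map(first)
    b, _ = seg.frame.coord_map(last)
    if strand == "+":
        return a, b + 3
    return b, a + 3


def search_genome(query: ProteinSeq, genome: GenomeRecord,
                  params: SearchParams | None = None,
                  scheme: ScoringScheme | None = None,
                  db_len: int | None = None) -> list[GenomicHit]:
    """Search one protein query against one six-frame translated genome.

    ``db_len`` should be supplied when the invocation spans several genomes
    (see :func:`database_length`); it defaults to this genome alone.
    """
    params = params or SearchParams()
    scheme = scheme or default_scheme()
    if len(genome) < 3:
        raise ValueError(f"genome {genome.id!r} shorter than one codon")
    segments = stop_free_segments(six_frame_translate(genome))
    if db_len is None:
        db_len = sum(len(s.residues) for s in segments)
    if db_len == 0:
        return []
    smin = min_score_for_evalue(params.evalue_cutoff, len(query), db_len, scheme)
    max_pair = int(scheme.matrix.max())
    qcodes = scheme.encode(query.residues)
    hits: list[GenomicHit] = []
    for seg in segments:
        # a segment of length L cannot score above L * max matrix entry
        if len(seg.residues) * max_pair < smin:
            continue
        if gotoh_score(qcodes, scheme.encode(seg.residues), scheme) < smin:
            continue
        aln = sw_align(query, ProteinSeq(id=seg.frame.protein.id,
                                         residues=seg.residues), scheme)
        if aln.is_empty or aln.score < smin:
            continue
        if aln.query_coverage < params.coverage_cutoff:
            continue
        e = evalue(aln.score, len(query), db_len, scheme)
        if e > params.evalue_cutoff:
            continue
        aln = replace_evalue(aln, e)
        hits.append(
            GenomicHit(
                query_id=query.id,
                genome_id=genome.id,
                frame=seg.frame.frame,
                alignment=aln,
                genomic_span=_genomic_span(seg, aln.subject_span),
                strand="+" if seg.frame.frame > 0 else "-",
            )
        )
    hits.sort(key=lambda h: (h.evalue, -h.alignment.score, h.start))
    return hits[: params.max_hits_per_genome]


def replace_evalue(aln: AlignmentResult, e: float) -> AlignmentResult:
    aln.evalue = e
    return aln


def merge_hits(hits: Sequence[GenomicHit], max_gap_bp: int = 30) -> list[GenomicHit]:
    """Merge same-strand hits whose genomic spans overlap or nearly touch.

    Hits (one genome, one query) whose spans lie within ``max_gap_bp`` of
    each other on the same strand are merged into one hit carrying the best
    (lowest) E-value alignment and the union span.  Absorbs hits split by
    frameshifts without bridging distinct genes.
    """
    if not hits:
        return []
    by_strand: dict[str, list[GenomicHit]] = {}
    for h in hits:
        by_strand.setdefault(h.strand, []).append(h)
    merged: list[GenomicHit] = []
    for strand_hits in by_strand.values():
        strand_hits.sort(key=lambda h: h.start)
        current = strand_hits[0]
        span = list(current.genomic_span)
        for h in strand_hits[1:]:
            if h.start - span[1] <= max_gap_bp:
                span[1] = max(span[1], h.end)
                if (h.evalue, -h.alignment.score) < (current.evalue,
                                                     -current.alignment.score):
                    current = h
            else:
                merged.append(
                    GenomicHit(current.query_id, current.genome_id, current.frame,
                               current.alignment, (span[0], span[1]),
                               current.strand)
                )
                current = h
                span = list(h.genomic_span)
        merged.append(
            GenomicHit(current.query_id, current.genome_id, current.frame,
                       current.alignment, (span[0], span[1]), current.strand)
        )
    merged.sort(key=lambda h: (h.evalue, -h.alignment.score, h.start))
    return merged


def best_hit(hits: Sequence[GenomicHit]) -> GenomicHit | None:
    """Lowest E-value; ties broken by higher score, then smaller genomic start."""
    if not hits:
        return None
    return min(hits, key=lambda h: (h.evalue, -h.alignment.score, h.start))


_TSV_HEADER = ("qseqid\tsseqid\tpident\tlength\tmismatch\tgapopen\t"
               "qstart\tqend\tsstart\tsend\tevalue\tscore\t"
               "genome_id\tframe\tgstart\tgend\tstrand")


def hits_to_tsv(hits: Sequence[GenomicHit]) -> str:
    """BLAST outfmt-6-style report; genomic coordinates 1-based inclusive."""
    lines = [_TSV_HEADER]
    for h in hits:
        a = h.alignment
        lines.append("\t".join(str(x) for x in (
            a.query_id, a.subject_id, f"{a.percent_identity:.1f}",
            a.alignment_length, a.mismatches, a.gap_opens,
            a.query_span[0] + 1, a.query_span[1],
            a.subject_span[0] + 1, a.subject_span[1],
            f"{h.evalue:.3g}", a.score,
            h.genome_id, h.frame, h.start + 1, h.end, h.strand,
        )))
    return "\n".join(lines) + "\n"
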