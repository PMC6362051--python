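"""Cross-genome conservation survey of a toxin-antitoxin pair.

Each genome is searched with both the toxin and the antitoxin query, hits
are merged per locus, pairing is attempted under the operon-neighborhood
rule, and the genome is classified as ``pair``, ``toxin_only``,
``antitoxin_only`` or ``absent``.  Classification is existential: if any
toxin x antitoxin cross pairing is accepted, the genome carries the pair.
When both partners pass the gates but no pairing is accepted, the genome is
classified by the role of its best (lowest E-value) hit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

from .align import ScoringScheme, default_scheme
from .neighborhood import PairingParams, TAPairCandidate, pair_hits
from .search import (GenomicHit, SearchParams, SURVEY_PARAMS, best_hit,
                     database_length, merge_hits, search_genome)
from .seqio import GenomeRecord, ProteinSeq

__all__ = ["GenomeSurveyRecord", "SurveySummary", "survey_genomes",
           "summarize", "snap_hits_to_features", "classify_genome"]

STATUSES = ("pair", "toxin_only", "antitoxin_only", "absent")


@dataclass(frozen=True)
class GenomeSurveyRecord:
    genome_id: str
    status: str
    toxin_best: GenomicHit | None = None
    antitoxin_best: GenomicHit | None = None
    pair_separation_bp: int | None = None
    error: str | None = None

    def __post_init__(self) -> None:
        if self.status not in STATUSES + ("error",):
            raise ValueError(f"unknown status {self.status!r}")


@dataclass
class SurveySummary:
    records: list[GenomeSurveyRecord]
    search_params: SearchParams
    pairing_params: PairingParams

    @property
    def counts(self) -> dict[str, int]:
        out = {s: 0 for s in STATUSES}
        for r in self.records:
            if r.status in out:
                out[r.status] += 1
        return out

    def to_tsv(self) -> str:
        lines = ["genome_id\tstatus\ttoxin_evalue\tantitoxin_evalue\t"
                 "pair_separation_bp"]
        for r in self.records:
            te = f"{r.toxin_best.evalue:.3g}" if r.toxin_best else "."
            ae = f"{r.antitoxin_best.evalue:.3g}" if r.antitoxin_best else "."
            sep = r.pair_separation_bp if r.pair_separation_bp is not None else "."
            lines.append(f"{r.genome_id}\t{r.status}\t{te}\t{ae}\t{sep}")
        return "\n".join(lines) + "\n"


def snap_hits_to_features(genome: GenomeRecord,
                          hits: Sequence[GenomicHit]) -> list[GenomicHit]:
    """Snap hit spans to overlapping same-strand annotated genes.

    Translated-search hits exclude the stop codon and may be soft-trimmed at
    the termini, so raw-hit separations can differ from annotated intergenic
    distances by a few bases.  When the genome carries annotations, each hit
    adopts the interval of the same-strand gene it overlaps most (ties: the
    leftmost gene); hits overlapping no gene are kept as-is.
    """
    if not genome.features:
        return list(hits)
    out: list[GenomicHit] = []
    for h in hits:
        best_feat = None
        best_ov = 0
        for f in genome.features:
            if f.strand != h.strand:
                continue
            ov = min(f.end, h.end) - max(f.start, h.start)
            if ov > best_ov:
                best_ov = ov
                best_feat = f
        if best_feat is not None:
            h = replace(h, genomic_span=(best_feat.start, best_feat.end))
        out.append(h)
    return out


def classify_genome(toxin_hits: Sequence[GenomicHit],
                    antitoxin_hits: Sequence[GenomicHit],
                    pairing_params: PairingParams) -> GenomeSurveyRecord:
    """Classify one genome from its merged, gate-passing hits."""
    t_best = best_hit(toxin_hits)
    a_best = best_hit(antitoxin_hits)
    genome_id = (t_best or a_best).genome_id if (t_best or a_best) else ""
    if t_best and a_best:
        candidates = pair_hits(list(toxin_hits), list(antitoxin_hits),
                               pairing_params)
        accepted = [c for c in candidates if c.accepted]
        if accepted:
            best: TAPairCandidate = accepted[0]
            return GenomeSurveyRecord(
                genome_id=genome_id, status="pair",
                toxin_best=best.toxin,  # type: ignore[arg-type]
                antitoxin_best=best.antitoxin,  # type: ignore[arg-type]
                pair_separation_bp=best.separation_bp,
            )
        # both present, never pairable: the better hit's role wins
        status = ("toxin_only" if t_best.evalue <= a_best.evalue
                  else "antitoxin_only")
        return GenomeSurveyRecord(genome_id=genome_id, status=status,
                                  toxin_best=t_best, antitoxin_best=a_best)
    if t_best:
        return GenomeSurveyRecord(genome_id=genome_id, status="toxin_only",
                                  toxin_best=t_best)
    if a_best:
        return GenomeSurveyRecord(genome_id=genome_id, status="antitoxin_only",
                                  antitoxin_best=a_best)
    return GenomeSurveyRecord(genome_id=genome_id, status="absent")


def survey_genomes(toxin_query: ProteinSeq, antitoxin_query: ProteinSeq,
                   genomes: Sequence[GenomeRecord],
                   search_params: SearchParams | None = None,
                   pairing_params: PairingParams | None = None,
                   scheme: ScoringScheme | None = None,
                   merge_gap_bp: int = 30) -> SurveySummary:
    """Search, pair and classify every genome in a cohort.

    E-values are computed against the translated residue count of the whole
    cohort, so they are deterministic and independent of genome order.
    """
    search_params = search_params or SURVEY_PARAMS
    pairing_params = pairing_params or PairingParams()
    scheme = scheme or default_scheme()
    # per-genome translation failures are recorded, not fatal; db_len spans
    # the readable genomes only
    failures: dict[str, str] = {}
    db_len = 0
    for genome in genomes:
        try:
            db_len += database_length([genome])
        except Exception as exc:
            failures[genome.id] = str(exc)
    records: list[GenomeSurveyRecord] = []
    for genome in genomes:
        if genome.id in failures:
            records.append(GenomeSurveyRecord(genome_id=genome.id,
                                              status="error",
                                              error=failures[genome.id]))
            continue
        try:
            t_hits = snap_hits_to_features(genome, merge_hits(
                search_genome(toxin_query, genome, search_params, scheme,
                              db_len=db_len), merge_gap_bp))
            a_hits = snap_hits_to_features(genome, merge_hits(
                search_genome(antitoxin_query, genome, search_params, scheme,
                              db_len=db_len), merge_gap_bp))
        except Exception as exc:  # per-genome failure: record, continue
            records.append(GenomeSurveyRecord(genome_id=genome.id,
                                              status="error", error=str(exc)))
            continue
        rec = classify_genome(t_hits, a_hits, pairing_params)
        if not rec.genome_id:
            rec = GenomeSurveyRecord(genome_id=genome.id, status="absent")
        records.append(rec)
    return SurveySummary(records=records, search_params=search_params,
                         pairing_params=pairing_params)


def summarize(records: Sequence[GenomeSurveyRecord],
              search_params: SearchParams | None = None,
              pairing_params: PairingParams | None = None) -> SurveySummary:
    """Counts per status over per-genome records, stable genome ordering."""
    return SurveySummary(
        records=sorted(records, key=lambda r: r.genome_id),
        search_params=search_params or SURVEY_PARAMS,
        pairing_params=pairing_params or PairingParams(),
    )
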