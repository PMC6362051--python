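"""End-to-end orchestration: search -> pair -> motifs -> survey.

`RunConfig` holds every threshold actually applied; defaults reproduce the
standard gates of this analysis family (discovery: E <= 1e-06 and >= 60%
query coverage; survey: E <= 1e-04 and >= 70% coverage; pairing: antitoxin
upstream within 150 bp).  The effective configuration is always serialized
next to the outputs so a run can be audited and replayed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .align import ScoringScheme, default_scheme, read_matrix
from .motifs import parse_pattern, scan_motif
from .neighborhood import PairingParams, pair_hits
from .search import SearchParams, database_length, hits_to_tsv, merge_hits, \
    search_genome
from .seqio import GenomeRecord, ProteinSeq, extract_protein, read_fasta, read_gff
from .survey import survey_genomes
from .align import sw_align

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    toxin_query: str = ""
    antitoxin_query: str = ""
    genomes: list[str] = field(default_factory=list)
    annotations: list[str] = field(default_factory=list)
    references: list[str] = field(default_factory=list)  # FASTA of reference toxins
    out_dir: str = "tapairscan_out"
    seed: int = 0
    # gates
    discovery_evalue: float = 1e-6
    discovery_coverage: float = 60.0
    survey_evalue: float = 1e-4
    survey_coverage: float = 70.0
    max_separation_bp: int = 150
    require_same_strand: bool = True
    allow_overlap: bool = True
    merge_gap_bp: int = 30
    # scoring
    matrix: str = ""  # path to an NCBI-format matrix; empty = packaged BLOSUM62
    gap_open: int = 11
    gap_extend: int = 1
    lambda_: float = 0.267
    kappa: float = 0.041
    # motifs: name -> pattern string (X wildcard, [..] set)
    motif_patterns: dict[str, str] = field(
        default_factory=lambda: {"P-loop": "GXXGXXK[TS]", "GTXR": "GTXR"}
    )
    run_survey: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=True))

    def scheme(self) -> ScoringScheme:
        if self.matrix:
            alphabet, matrix = read_matrix(self.matrix)
            return ScoringScheme(alphabet=alphabet, matrix=matrix,
                                 gap_open=self.gap_open,
                                 gap_extend=self.gap_extend,
                                 lambda_=self.lambda_, kappa=self.kappa)
        return default_scheme(self.gap_open, self.gap_extend,
                              self.lambda_, self.kappa)

    def discovery_params(self) -> SearchParams:
        return SearchParams(self.discovery_evalue, self.discovery_coverage)

    def survey_params(self) -> SearchParams:
        return SearchParams(self.survey_evalue, self.survey_coverage)

    def pairing_params(self) -> PairingParams:
        return PairingParams(self.max_separation_bp, self.require_same_strand,
                             self.allow_overlap)


def _load_query(path: str) -> ProteinSeq:
    recs = read_fasta(path)
    if not recs:
        raise ValueError(f"no sequences in {path}")
    return ProteinSeq(id=recs[0].id, residues=str(recs[0].seq))


def _load_genomes(cfg: RunConfig) -> list[GenomeRecord]:
    feats: dict[str, list] = {}
    for gff in cfg.annotations:
        for gid, fl in read_gff(gff).items():
            feats.setdefault(gid, []).extend(fl)
    genomes: list[GenomeRecord] = []
    for fasta in cfg.genomes:
        for rec in read_fasta(fasta):
            genomes.append(GenomeRecord(id=rec.id, sequence=str(rec.seq),
                                        features=feats.get(rec.id, [])))
    return genomes


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis and write its report bundle.

    Returns the report dictionary; files written under ``cfg.out_dir``:
    ``effective_config.yaml``, ``toxin_hits.tsv``, ``antitoxin_hits.tsv``,
    ``pairs.tsv``, ``motifs.json``, ``survey.tsv``, ``summary.json``.
    """
    if not cfg.genomes:
        raise ValueError("config lists no genome FASTA files")
    if not cfg.toxin_query:
        raise ValueError("config lists no toxin query")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "effective_config.yaml")

    scheme = cfg.scheme()
    toxin = _load_query(cfg.toxin_query)
    antitoxin = (_load_query(cfg.antitoxin_query)
                 if cfg.antitoxin_query else None)
    genomes = _load_genomes(cfg)
    db_len = database_length(genomes)

    report: dict = {"db_len": db_len, "genomes": len(genomes)}
    disc = cfg.discovery_params()
    t_hits = []
    a_hits = []
    for g in genomes:
        t_hits += merge_hits(search_genome(toxin, g, disc, scheme,
                                           db_len=db_len), cfg.merge_gap_bp)
        if antitoxin is not None:
            a_hits += merge_hits(search_genome(antitoxin, g, disc, scheme,
                                               db_len=db_len), cfg.merge_gap_bp)
    (out / "toxin_hits.tsv").write_text(hits_to_tsv(t_hits))
    (out / "antitoxin_hits.tsv").write_text(hits_to_tsv(a_hits))
    report["toxin_hits"] = len(t_hits)
    report["antitoxin_hits"] = len(a_hits)

    # pairing per genome
    pairing = cfg.pairing_params()
    pair_rows = ["genome_id\ttoxin_span\tantitoxin_span\tseparation_bp\t"
                 "accepted\treason"]
    accepted_pairs = 0
    for g in genomes:
        gt = [h for h in t_hits if h.genome_id == g.id]
        ga = [h for h in a_hits if h.genome_id == g.id]
        for cand in pair_hits(gt, ga, pairing):
            accepted_pairs += cand.accepted
            pair_rows.append(
                f"{g.id}\t{cand.toxin.genomic_span}\t"  # type: ignore[union-attr]
                f"{cand.antitoxin.genomic_span}\t{cand.separation_bp}\t"  # type: ignore[union-attr]
                f"{cand.accepted}\t{cand.rejection_reason or '.'}"
            )
    (out / "pairs.tsv").write_text("\n".join(pair_rows) + "\n")
    report["accepted_pairs"] = accepted_pairs

    # motif analysis on the translated toxin loci + residue equivalences
    patterns = [parse_pattern(name, pat)
                for name, pat in cfg.motif_patterns.items()]
    motif_report: list[dict] = []
    genome_by_id = {g.id: g for g in genomes}
    for h in t_hits:
        g = genome_by_id[h.genome_id]
        feat = next((f for f in g.features
                     if f.start < h.end and h.start < f.end
                     and f.strand == h.strand), None)
        if feat is not None:
            prot = extract_protein(g, feat)
        else:
            from .seqio import GeneFeature
            span_len = h.end - h.start
            span_len -= span_len % 3
            tmp = GeneFeature(id=f"{h.genome_id}:{h.start}-{h.end}",
                              start=h.start, end=h.start + span_len,
                              strand=h.strand)
            prot = extract_protein(g, tmp)
        entry = {"genome_id": h.genome_id, "locus": list(h.genomic_span),
                 "motifs": {}}
        for pat in patterns:
            entry["motifs"][pat.name] = [
                {"start": m.start, "end": m.end, "matched": m.matched}
                for m in scan_motif(prot, pat)
            ]
        for ref_path in cfg.references:
            for rec in read_fasta(ref_path):
                ref = ProteinSeq(id=rec.id, residues=str(rec.seq))
                aln = sw_align(ref, prot, scheme)
                if not aln.is_empty:
                    entry.setdefault("reference_identity", {})[ref.id] = \
                        aln.percent_identity
        motif_report.append(entry)
    (out / "motifs.json").write_text(json.dumps(motif_report, indent=2))
    report["toxin_loci_with_p_loop"] = sum(
        1 for e in motif_report if e["motifs"].get("P-loop"))

    if cfg.run_survey and antitoxin is not None:
        summary = survey_genomes(toxin, antitoxin, genomes,
                                 cfg.survey_params(), pairing, scheme,
                                 cfg.merge_gap_bp)
        (out / "survey.tsv").write_text(summary.to_tsv())
        report["survey_counts"] = summary.counts

    (out / "summary.json").write_text(json.dumps(report, indent=2))
    return report
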