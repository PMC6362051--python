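"""Translated search, hit filtering and coordinate mapping."""

import pytest

from helpers import merge_intervals_oracle
from tapairscan.align import AlignmentResult
from tapairscan.search import (GenomicHit, SearchParams, best_hit,
                               database_length, merge_hits, search_genome,
                               stop_free_segments)
from tapairscan.seqio import (GeneFeature, GenomeRecord, ProteinSeq,
                              extract_protein, six_frame_translate,
                              reverse_complement, translate)
from tapairscan.synthetic import (PlantSpec, back_translate, generate_genome,
                                  mutate_protein, toxin_seed)


def _mk_hit(start, end, ev, score=100, strand="+", query="q", genome="g"):
    aln = AlignmentResult(query_id=query, subject_id="s", score=score,
                          query_span=(0, 10), subject_span=(0, 10),
                          columns=[("A", "A")] * 10, query_len=10,
                          subject_len=10, evalue=ev)
    return GenomicHit(query_id=query, genome_id=genome, frame=1,
                      alignment=aln, genomic_span=(start, end), strand=strand)


class TestSearchGenome:
    def test_verbatim_plant_found_exactly(self, scheme, toxin):
        g, feats, man = generate_genome(
            8000, 0.5, [PlantSpec(protein=toxin, target_identity=100,
                                  role="toxin")], rng_seed=13)
        (planted,) = man.planted
        hits = search_genome(toxin, g, SearchParams(1e-6, 60), scheme)
        assert hits
        top = hits[0]
        assert top.alignment.percent_identity == 100.0
        assert top.alignment.query_coverage == 100.0
        assert top.strand == planted.strand
        # the hit covers the coding part of the planted CDS; the 3 bp stop
        # codon lies outside the aligned residues
        if planted.strand == "+":
            assert top.genomic_span == (planted.start, planted.end - 3)
        else:
            assert top.genomic_span == (planted.start + 3, planted.end)

    def test_homopolymer_genome_no_hits(self, scheme):
        g = GenomeRecord(id="g", sequence="A" * 3000)
        q = ProteinSeq(id="w", residues="WWWHHWWCCW" * 12)
        assert search_genome(q, g, SearchParams(1e-6, 60), scheme) == []

    def test_degenerate_plant_single_hit(self, scheme, toxin):
        g, _, man = generate_genome(
            10000, 0.5, [PlantSpec(protein=toxin, target_identity=50,
                                   role="toxin")], rng_seed=99)
        (planted,) = man.planted
        hits = search_genome(toxin, g, SearchParams(1e-6, 60), scheme)
        assert len(hits) == 1
        h = hits[0]
        assert h.start < planted.end and planted.start < h.end  # overlap

    def test_coordinate_soundness(self, scheme, toxin):
        """Translating the genomic span of a 100%-identity hit reproduces
        the aligned subject residues."""
        for seed in (1, 2, 3):
            g, _, _ = generate_genome(
                6000, 0.5, [PlantSpec(protein=toxin, target_identity=100,
                                      role="toxin")], rng_seed=seed)
            (h,) = search_genome(toxin, g, SearchParams(1e-6, 60), scheme)
            sub = g.sequence[h.start:h.end]
            if h.strand == "-":
                sub = reverse_complement(sub)
            aligned_subject = "".join(b for _, b in h.alignment.columns
                                      if b != "-")
            assert translate(sub).residues == aligned_subject

    def test_hits_sorted_by_evalue(self, scheme, toxin):
        g, _, _ = generate_genome(
            20000, 0.5,
            [PlantSpec(protein=toxin, target_identity=95, role="decoy"),
             PlantSpec(protein=toxin, target_identity=70, role="decoy")],
            rng_seed=17)
        hits = search_genome(toxin, g, SearchParams(1e-6, 60), scheme)
        assert len(hits) == 2
        assert hits[0].evalue <= hits[1].evalue

    def test_db_len_counts_stop_free_residues(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=999))
        g = GenomeRecord(id="g", sequence=seq)
        total_residues = sum(len(f.protein) for f in six_frame_translate(g))
        stops = sum(f.protein.residues.count("*")
                    for f in six_frame_translate(g))
        assert database_length([g]) == total_residues - stops


class TestRecovery:
    def test_recovery_rate_at_70_percent_identity(self, scheme, toxin):
        """A >= 70%-identity plant is recovered with >= 70% coverage in
        >= 95% of seeded replicates."""
        n_rep, recovered = 60, 0
        for seed in range(n_rep):
            g, _, man = generate_genome(
                4000, 0.5, [PlantSpec(protein=toxin, target_identity=70,
                                      role="toxin")], rng_seed=seed + 1000)
            hits = search_genome(toxin, g, SearchParams(1e-6, 60), scheme)
            (planted,) = man.planted
            ok = any(h.start < planted.end and planted.start < h.end
                     and h.alignment.query_coverage >= 70 for h in hits)
            recovered += ok
        assert recovered / n_rep >= 0.95

    def test_monotone_dilution(self, scheme, toxin):
        """Recovery never increases as planted identity decreases."""
        rates = []
        for ident in (90, 70, 50, 30):
            hit = 0
            for seed in range(15):
                g, _, man = generate_genome(
                    4000, 0.5, [PlantSpec(protein=toxin, target_identity=ident,
                                          role="toxin")], rng_seed=seed + 50)
                hits = search_genome(toxin, g, SearchParams(1e-6, 60), scheme)
                (planted,) = man.planted
                hit += any(h.start < planted.end and planted.start < h.end
                           for h in hits)
            rates.append(hit / 15)
        assert all(a >= b for a, b in zip(rates, rates[1:])), rates
        assert rates[0] == 1.0


class TestMergeHits:
    def test_disjoint_hits_unchanged(self):
        hits = [_mk_hit(0, 100, 1e-10), _mk_hit(10_100, 10_200, 1e-8)]
        merged = merge_hits(hits, max_gap_bp=30)
        assert sorted(h.genomic_span for h in merged) == [(0, 100),
                                                          (10_100, 10_200)]

    def test_overlapping_hits_merge_to_union(self):
        hits = [_mk_hit(0, 120, 1e-8), _mk_hit(90, 300, 1e-12)]
        (m,) = merge_hits(hits, max_gap_bp=30)
        assert m.genomic_span == (0, 300)
        assert m.evalue == 1e-12  # best E-value kept

    def test_strands_never_merge(self):
        hits = [_mk_hit(0, 100, 1e-8), _mk_hit(50, 150, 1e-8, strand="-")]
        assert len(merge_hits(hits, max_gap_bp=30)) == 2

    def test_random_intervals_match_union_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 15))
            intervals = []
            for _ in range(n):
                s = int(rng.integers(0, 2000))
                intervals.append((s, s + int(rng.integers(10, 300))))
            hits = [_mk_hit(s, e, 1e-8) for s, e in intervals]
            merged = merge_hits(hits, max_gap_bp=30)
            expected = merge_intervals_oracle(intervals, 30)
            assert sorted(h.genomic_span for h in merged) == expected


class TestBestHit:
    def test_empty(self):
        assert best_hit([]) is None

    def test_lowest_evalue_wins(self):
        h1, h2 = _mk_hit(0, 100, 1e-10), _mk_hit(200, 300, 1e-5)
        assert best_hit([h2, h1]) is h1

    def test_tie_broken_by_score_then_start(self):
        h1 = _mk_hit(500, 600, 1e-10, score=80)
        h2 = _mk_hit(0, 100, 1e-10, score=90)
        assert best_hit([h1, h2]) is h2
        h3 = _mk_hit(100, 200, 1e-10, score=90)
        assert best_hit([h3, h2]) is h2  # equal E and score: smaller start


class TestSegments:
    def test_segments_are_stop_free_and_complete(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=600))
        frames = six_frame_translate(GenomeRecord(id="g", sequence=seq))
        segs = stop_free_segments(frames)
        assert all("*" not in s.residues for s in segs)
        for ft in frames:
            mine = [s for s in segs if s.frame is ft]
            reconstructed = sorted((s.offset, s.residues) for s in mine)
            for off, res in reconstructed:
                assert ft.protein.residues[off:off + len(res)] == res
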