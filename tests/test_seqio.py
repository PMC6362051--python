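"""Sequence I/O, translation and frame coordinate maps."""

import pytest
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from hypothesis import given, settings
from hypothesis import strategies as st

from tapairscan.seqio import (GeneFeature, GenomeRecord, ProteinSeq,
                              extract_protein, read_fasta, read_gff,
                              reverse_complement, six_frame_translate,
                              translate, write_fasta, write_gff)


class TestFasta:
    def test_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        assert read_fasta(p) == []

    def test_single_record(self, tmp_path):
        p = tmp_path / "one.fasta"
        p.write_text(">s1\nacgt\n")
        recs = read_fasta(p)
        assert len(recs) == 1
        assert recs[0].id == "s1"
        assert str(recs[0].seq) == "ACGT"

    def test_headerless_leading_sequence_names_line(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text("\nACGT\n>s1\nACGT\n")
        with pytest.raises(ValueError, match="line 2"):
            read_fasta(p)

    def test_round_trip_50_random_records(self, tmp_path, rng):
        records = [
            SeqRecord(
                Seq("".join(rng.choice(list("ACGT"),
                                       size=rng.integers(10, 200)))),
                id=f"r{i}", description="")
            for i in range(50)
        ]
        p = tmp_path / "rt.fasta"
        write_fasta(records, p)
        back = read_fasta(p)
        assert [r.id for r in back] == [r.id for r in records]
        assert [str(r.seq) for r in back] == [str(r.seq) for r in records]


class TestGff:
    def test_one_based_conversion(self, tmp_path):
        p = tmp_path / "a.gff"
        p.write_text("##gff-version 3\n"
                     "g1\tsrc\tgene\t1\t9\t.\t-\t.\tID=x;product=toxin\n")
        feats = read_gff(p)
        (f,) = feats["g1"]
        assert (f.start, f.end, f.strand, f.product) == (0, 9, "-", "toxin")

    def test_empty_gff(self, tmp_path):
        p = tmp_path / "empty.gff"
        p.write_text("##gff-version 3\n")
        assert read_gff(p) == {}

    def test_end_before_start_rejected(self, tmp_path):
        p = tmp_path / "bad.gff"
        p.write_text("g1\tsrc\tgene\t50\t10\t.\t+\t.\tID=x\n")
        with pytest.raises(ValueError, match="line 1"):
            read_gff(p)

    def test_unknown_strand_rejected(self, tmp_path):
        p = tmp_path / "bad.gff"
        p.write_text("g1\tsrc\tgene\t10\t50\t.\t?\t.\tID=x\n")
        with pytest.raises(ValueError, match="strand"):
            read_gff(p)

    def test_round_trip_bit_exact(self, tmp_path, rng):
        feats = {}
        for g in range(3):
            fl = []
            for i in range(20):
                start = int(rng.integers(0, 5000))
                end = start + int(rng.integers(1, 900))
                fl.append(GeneFeature(id=f"g{g}f{i}", start=start, end=end,
                                      strand="+" if rng.random() < 0.5 else "-",
                                      product=f"p{i}"))
            feats[f"genome{g}"] = fl
        p = tmp_path / "rt.gff"
        write_gff(feats, p)
        assert read_gff(p) == feats


class TestReverseComplement:
    @pytest.mark.parametrize("dna,expected", [
        ("ACGT", "ACGT"),
        ("AAC", "GTT"),
        ("NRY", "RYN"),
    ])
    def test_examples(self, dna, expected):
        assert reverse_complement(dna) == expected

    def test_non_iupac_rejected(self):
        with pytest.raises(ValueError):
            reverse_complement("ACQT")

    @settings(max_examples=100, derandomize=True)
    @given(st.text(alphabet="ACGTNRYSWKMBDHV", min_size=1, max_size=80))
    def test_involution(self, dna):
        assert reverse_complement(reverse_complement(dna)) == dna


class TestTranslate:
    def test_examples(self):
        assert translate("ATGAAA").residues == "MK"
        assert translate("TAA").residues == "*"
        assert translate("ATGAAAC").residues == "MK"  # partial codon dropped

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            translate("AT")

    def test_all_64_codons_match_independent_table(self):
        # oracle: Biopython's own translation engine, codon by codon
        for a in "ACGT":
            for b in "ACGT":
                for c in "ACGT":
                    codon = a + b + c
                    expected = str(Seq(codon).translate(table=11))
                    assert translate(codon).residues == expected, codon

    def test_ambiguity(self):
        # GCN always encodes Ala; RAT is Asn or Asp -> X
        assert translate("GCN").residues == "A"
        assert translate("RAT").residues == "X"


class TestSixFrame:
    def test_forward_frame_one(self):
        g = GenomeRecord(id="g", sequence="ATGAAATAG")
        frames = six_frame_translate(g)
        assert frames[0].frame == 1
        assert frames[0].protein.residues == "MK*"

    def test_minus_one_maps_to_last_complete_codon(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=31))
        g = GenomeRecord(id="g", sequence=seq)
        ft = next(f for f in six_frame_translate(g) if f.frame == -1)
        start, strand = ft.coord_map(0)
        assert strand == "-"
        assert (start, start + 3) == (len(seq) - 3, len(seq))

    @pytest.mark.parametrize("length", range(9, 31))
    def test_residue_counting_identity(self, length, rng):
        seq = "".join(rng.choice(list("ACGT"), size=length))
        frames = six_frame_translate(GenomeRecord(id="g", sequence=seq))
        total = sum(len(f.protein) for f in frames)
        expected = sum(2 * ((length - off) // 3) for off in range(3))
        assert total == expected

    def test_coord_map_round_trip(self, rng):
        """Re-translating the mapped codon bases reproduces every residue."""
        for _ in range(20):
            length = int(rng.integers(300, 3000))
            seq = "".join(rng.choice(list("ACGT"), size=length))
            g = GenomeRecord(id="g", sequence=seq)
            for ft in six_frame_translate(g):
                # spot-check every 7th position plus the ends
                positions = set(range(0, len(ft.protein), 7))
                positions |= {0, len(ft.protein) - 1}
                for p in positions:
                    start, strand = ft.coord_map(p)
                    codon = seq[start:start + 3]
                    if strand == "-":
                        codon = reverse_complement(codon)
                    assert translate(codon).residues == ft.protein.residues[p]


class TestExtractProtein:
    def test_plus_strand(self):
        g = GenomeRecord(id="g", sequence="ATGAAATAG")
        f = GeneFeature(id="f", start=0, end=9, strand="+")
        assert extract_protein(g, f).residues == "MK"

    def test_strand_mirror(self, rng):
        """Reverse-complementing genome + flipping features preserves proteins."""
        seq = "".join(rng.choice(list("ACGT"), size=300))
        g = GenomeRecord(id="g", sequence=seq)
        for _ in range(20):
            start = int(rng.integers(0, 250))
            end = start + 3 * int(rng.integers(2, 15))
            strand = "+" if rng.random() < 0.5 else "-"
            f = GeneFeature(id="f", start=start, end=end, strand=strand)
            mirrored = GenomeRecord(id="g2", sequence=reverse_complement(seq))
            mf = GeneFeature(id="f", start=len(seq) - end, end=len(seq) - start,
                             strand="-" if strand == "+" else "+")
            assert extract_protein(g, f).residues == \
                extract_protein(mirrored, mf).residues

    def test_planted_orf_round_trip(self):
        from tapairscan.synthetic import PlantSpec, generate_genome, toxin_seed
        tox = toxin_seed()
        g, feats, man = generate_genome(
            5000, 0.5, [PlantSpec(protein=tox, role="decoy")], rng_seed=5)
        (planted,) = man.planted
        f = next(f for f in feats if f.id == planted.id)
        assert extract_protein(g, f).residues == planted.protein


class TestInvariants:
    def test_genome_rejects_bad_feature(self):
        with pytest.raises(ValueError, match="beyond"):
            GenomeRecord(id="g", sequence="ACGT",
                         features=[GeneFeature(id="f", start=0, end=9,
                                               strand="+")])

    def test_duplicate_feature_ids_rejected(self):
        fs = [GeneFeature(id="f", start=0, end=3, strand="+"),
              GeneFeature(id="f", start=3, end=6, strand="+")]
        with pytest.raises(ValueError, match="duplicate"):
            GenomeRecord(id="g", sequence="ACGTACGT", features=fs)

    def test_protein_rejects_empty_and_whitespace(self):
        with pytest.raises(ValueError):
            ProteinSeq(id="p", residues="")
        with pytest.raises(ValueError):
            ProteinSeq(id="p", residues="MK V")
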