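"""Sequence/annotation I/O, genetic-code translation and frame coordinate maps.

Conventions used throughout the package:

* internal coordinates are 0-based, half-open ``[start, end)``; GFF3 I/O
  converts to and from the 1-based inclusive convention of the format,
* translation uses the bacterial/archaeal code (NCBI table 11) with no
  alternative-start handling: GTG/TTG are translated literally, stop codons
  become ``*`` and codons whose IUPAC ambiguity codes do not resolve to a
  unique amino acid become ``X``,
* genomes are treated as linear (no wrap-around ORFs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable, IUPACData
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.feature import Feature, feature_from_line

__all__ = [
    "GenomeRecord",
    "GeneFeature",
    "ProteinSeq",
    "FrameTranslation",
    "read_fasta",
    "write_fasta",
    "read_gff",
    "write_gff",
    "reverse_complement",
    "translate",
    "six_frame_translate",
    "extract_protein",
]

_IUPAC_DNA = set(IUPACData.ambiguous_dna_values)  # ACGT + ambiguity codes, no U
_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN"
)

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]


def _build_codon_lookup() -> dict[str, str]:
    """Codon -> amino acid for table 11, stops as ``*``."""
    lut = dict(_TABLE11.forward_table)
    for codon in _TABLE11.stop_codons:
        lut[codon] = "*"
    return lut


_CODON_LUT = _build_codon_lookup()


@dataclass(frozen=True)
class ProteinSeq:
    """A protein sequence over the 20 amino acids plus ``X`` and ``*``."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        if any(c.isspace() for c in self.residues):
            raise ValueError(f"protein {self.id!r}: internal whitespace")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GeneFeature:
    """A strand-aware gene interval in 0-based half-open coordinates."""

    id: str
    start: int
    end: int
    strand: str
    product: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"feature {self.id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.id!r}: unknown strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass
class GenomeRecord:
    """A nucleotide sequence plus its ordered gene features."""

    id: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"genome {self.id!r}: empty sequence")
        bad = set(self.sequence.upper()) - _IUPAC_DNA
        if bad:
            raise ValueError(f"genome {self.id!r}: non-IUPAC characters {sorted(bad)}")
        self.sequence = self.sequence.upper()
        seen: set[str] = set()
        for f in self.features:
            if f.end > len(self.sequence):
                raise ValueError(
                    f"feature {f.id!r} extends beyond genome {self.id!r}"
                )
            if f.id in seen:
                raise ValueError(f"duplicate feature id {f.id!r} in genome {self.id!r}")
            seen.add(f.id)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FrameTranslation:
    """One of the six reading-frame translations of a genome.

    ``frame`` is +1..+3 (forward strand, offsets 0..2) or -1..-3 (reverse
    complement, offsets 0..2).  ``coord_map(p)`` returns the forward-strand
    genomic offset of the first base of the codon encoding protein position
    ``p`` (0-based) together with the strand, satisfying the round-trip
    invariant that re-translating those three bases (reverse-complemented on
    minus frames) reproduces ``protein.residues[p]``.
    """

    frame: int
    protein: ProteinSeq
    genome_length: int

    def coord_map(self, p: int) -> tuple[int, str]:
        if not 0 <= p < len(self.protein):
            raise IndexError(f"protein position {p} outside frame {self.frame}")
        off = abs(self.frame) - 1
        if self.frame > 0:
            return off + 3 * p, "+"
        return self.genome_length - off - 3 * p - 3, "-"


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a (multi-)FASTA file; sequences are uppercased, order preserved.

    Raises ``ValueError`` naming the line number when sequence text appears
    before the first header.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise ValueError(
                    f"{path}: line {lineno}: sequence before first FASTA header"
                )
            break
    records = list(SeqIO.parse(str(path), "fasta"))
    for rec in records:
        rec.seq = Seq(str(rec.seq).upper())
    return records


def write_fasta(records: Iterable[SeqRecord | ProteinSeq | GenomeRecord],
                path: str | Path) -> None:
    """Write records as FASTA wrapped at 60 columns."""
    out: list[SeqRecord] = []
    for rec in records:
        if isinstance(rec, ProteinSeq):
            out.append(SeqRecord(Seq(rec.residues), id=rec.id, description=""))
        elif isinstance(rec, GenomeRecord):
            out.append(SeqRecord(Seq(rec.sequence), id=rec.id, description=""))
        else:
            out.append(rec)
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(out)


# ---------------------------------------------------------------------------
# GFF3

_DEFAULT_TYPES = ("gene", "CDS")


def read_gff(path: str | Path,
             feature_types: Sequence[str] = _DEFAULT_TYPES,
             ) -> dict[str, list[GeneFeature]]:
    """Read GFF3 rows into per-genome feature lists.

    Coordinates are converted from the format's 1-based inclusive convention
    to internal 0-based half-open.  Only rows whose type is in
    ``feature_types`` are retained.
    """
    path = Path(path)
    result: dict[str, list[GeneFeature]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat: Feature = feature_from_line(line)
            except Exception as exc:  # malformed row
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            if feat.featuretype not in feature_types:
                continue
            if feat.end < feat.start:
                raise ValueError(
                    f"{path}: line {lineno}: end ({feat.end}) < start ({feat.start})"
                )
            if feat.strand not in ("+", "-"):
                raise ValueError(
                    f"{path}: line {lineno}: unknown strand {feat.strand!r}"
                )
            fid = feat.attributes.get("ID", [f"{feat.seqid}:{lineno}"])[0]
            product = feat.attributes.get("product", [""])[0]
            result.setdefault(feat.seqid, []).append(
                GeneFeature(
                    id=fid,
                    start=feat.start - 1,
                    end=feat.end,
                    strand=feat.strand,
                    product=product,
                )
            )
    return result


def write_gff(features_by_genome: dict[str, list[GeneFeature]],
              path: str | Path,
              feature_type: str = "gene",
              source: str = "tapairscan") -> None:
    """Write features as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for genome_id in features_by_genome:
            for f in features_by_genome[genome_id]:
                attrs = f"ID={f.id}"
                if f.product:
                    attrs += f";product={f.product}"
                fh.write(
                    "\t".join(
                        [
                            genome_id,
                            source,
                            feature_type,
                            str(f.start + 1),
                            str(f.end),
                            ".",
                            f.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# Translation


def reverse_complement(dna: str) -> str:
    """Reverse complement of an IUPAC nucleotide string."""
    dna = dna.upper()
    bad = set(dna) - _IUPAC_DNA
    if bad:
        raise ValueError(f"non-IUPAC nucleotide characters {sorted(bad)}")
    return dna.translate(_COMPLEMENT)[::-1]


def _translate_codon(codon: str) -> str:
    aa = _CODON_LUT.get(codon)
    if aa is not None:
        return aa
    # resolve IUPAC ambiguity: unique outcome -> that amino acid, else X
    try:
        expansions = {
            _CODON_LUT[a + b + c]
            for a in IUPACData.ambiguous_dna_values[codon[0]]
            for b in IUPACData.ambiguous_dna_values[codon[1]]
            for c in IUPACData.ambiguous_dna_values[codon[2]]
        }
    except KeyError as exc:
        raise ValueError(f"non-IUPAC character in codon {codon!r}") from exc
    if len(expansions) == 1:
        return expansions.pop()
    return "X"


def translate(dna: str, seq_id: str = "translation") -> ProteinSeq:
    """Translate DNA codon-by-codon under NCBI table 11.

    No start-codon special-casing; a trailing partial codon is ignored; stop
    codons become ``*``; unresolvable ambiguous codons become ``X``.
    """
    dna = dna.upper()
    if len(dna) < 3:
        raise ValueError(f"cannot translate {len(dna)} nt (< 1 codon)")
    residues = "".join(
        _translate_codon(dna[i : i + 3]) for i in range(0, len(dna) - len(dna) % 3, 3)
    )
    return ProteinSeq(id=seq_id, residues=residues)


def six_frame_translate(genome: GenomeRecord) -> list[FrameTranslation]:
    """The six reading-frame translations of a genome.

    Frames +1..+3 start at forward offsets 0..2; frames -1..-3 start at
    offsets 0..2 of the reverse complement.
    """
    if len(genome) < 3:
        raise ValueError(f"genome {genome.id!r} shorter than one codon")
    frames: list[FrameTranslation] = []
    rc = reverse_complement(genome.sequence)
    for off in range(3):
        for frame, seq in ((off + 1, genome.sequence), (-(off + 1), rc)):
            if len(seq) - off < 3:
                continue
            prot = translate(seq[off:], seq_id=f"{genome.id}|frame{frame:+d}")
            frames.append(
                FrameTranslation(frame=frame, protein=prot, genome_length=len(genome))
            )
    frames.sort(key=lambda f: (f.frame < 0, abs(f.frame)))
    return frames


def extract_protein(genome: GenomeRecord, feature: GeneFeature) -> ProteinSeq:
    """Translate an annotated gene; a trailing stop ``*`` is stripped."""
    sub = genome.sequence[feature.start : feature.end]
    if feature.strand == "-":
        sub = reverse_complement(sub)
    prot = translate(sub, seq_id=feature.id)
    residues = prot.residues
    if residues.endswith("*"):
        residues = residues[:-1]
    if not residues:
        raise ValueError(f"feature {feature.id!r} encodes only a stop codon")
    return ProteinSeq(id=feature.id, residues=residues)
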