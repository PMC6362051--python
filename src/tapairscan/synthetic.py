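"""Synthetic genomes and cohorts with planted TA operons and ground truth.

The generator emulates the statistical structure the analysis assumes:
GC-controlled random background DNA, protein-coding ORFs planted on either
strand as degenerate copies of seed proteins at a controlled percent
identity, exact intergenic spacing for toxin-antitoxin pairs (antitoxin
upstream in the toxin's transcription direction), decoy ORFs, and cohorts
mixing pair / toxin-only / antitoxin-only / absent genomes.  Every genome
carries a manifest recording planted intervals, strands, roles and realized
identities — the ground truth for recovery tests.

Divergence is substitution-only by default (an optional indel rate exists
but defaults to 0) so realized identity is exactly controllable; replacement
residues are drawn from BLOSUM62-positive partners with probability 0.7 to
mimic homologous divergence.  All randomness flows from one explicit seed
through named sub-streams (background, mutation, codon choice, placement).

The module also provides deterministic synthetic *stand-in* seed proteins
(``toxin_seed``/``antitoxin_seed``): random sequences of the lengths typical
of zeta-family toxins (197 aa, Walker-A motif written at positions 9-16) and
their small antitoxins (129 aa).  They are synthetic constructions, not the
real Rv0366c/Rv0367c gene products.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from Bio.Data import CodonTable

from .align import default_scheme
from .seqio import GeneFeature, GenomeRecord, ProteinSeq

__all__ = [
    "PlantSpec",
    "PlantedFeature",
    "GenomeManifest",
    "CohortManifest",
    "mutate_protein",
    "back_translate",
    "generate_genome",
    "generate_cohort",
    "toxin_seed",
    "antitoxin_seed",
]

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_TABLE11 = CodonTable.unambiguous_dna_by_id[11]

# synonymous codons per residue under table 11
_CODONS: dict[str, list[str]] = {}
for codon, aa in _TABLE11.forward_table.items():
    _CODONS.setdefault(aa, []).append(codon)
for aa in _CODONS:
    _CODONS[aa].sort()


def _positive_partners() -> dict[str, list[str]]:
    """For each residue, the distinct residues with a positive BLOSUM62 score."""
    scheme = default_scheme()
    out: dict[str, list[str]] = {}
    for a in _AA20:
        out[a] = [b for b in _AA20 if b != a and scheme.score(a, b) > 0]
    return out


_POSITIVE = _positive_partners()


def _substream(seed: int, name: str) -> np.random.Generator:
    """A named, order-independent child stream of one master seed."""
    tag = int.from_bytes(name.encode(), "little") % (2**32)
    return np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                        spawn_key=(tag,)))


def mutate_protein(protein: ProteinSeq, target_identity: float,
                   rng_seed: int, indel_rate: float = 0.0) -> ProteinSeq:
    """A degenerate copy at a controlled percent identity.

    Substitutes ``round(L * (1 - identity/100))`` positions chosen without
    replacement; the replacement is a BLOSUM62-positive partner with
    probability 0.7, else uniform over the other 19 residues.  Deterministic
    per seed.
    """
    if not 0 < target_identity <= 100:
        raise ValueError("target_identity must be in (0, 100]")
    rng = _substream(rng_seed, "mutation")
    residues = list(protein.residues)
    n_sub = round(len(residues) * (1.0 - target_identity / 100.0))
    if n_sub > 0:
        sites = rng.choice(len(residues), size=n_sub, replace=False)
        for i in sorted(int(x) for x in sites):
            old = residues[i]
            partners = _POSITIVE.get(old, [])
            if partners and rng.random() < 0.7:
                residues[i] = partners[rng.integers(len(partners))]
            else:
                others = [a for a in _AA20 if a != old]
                residues[i] = others[rng.integers(len(others))]
    if indel_rate > 0:
        keep = rng.random(len(residues)) >= indel_rate
        residues = [r for r, k in zip(residues, keep) if k]
        if not residues:
            residues = list(protein.residues[:1])
    return ProteinSeq(id=f"{protein.id}|id{target_identity:g}",
                      residues="".join(residues))


def back_translate(protein: ProteinSeq, rng_seed: int) -> str:
    """Encode a protein as DNA with uniformly chosen synonymous codons.

    A terminal TAG stop is appended, so ``translate(back_translate(p)) ==
    p + '*'``.
    """
    rng = _substream(rng_seed, "codon")
    codons = []
    for aa in protein.residues:
        if aa not in _CODONS:
            raise ValueError(f"cannot back-translate residue {aa!r}")
        options = _CODONS[aa]
        codons.append(options[rng.integers(len(options))])
    return "".join(codons) + "TAG"


def _random_background(length: int, gc_fraction: float,
                       rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - gc_fraction) / 2, gc_fraction / 2,
                  gc_fraction / 2, (1 - gc_fraction) / 2])
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length, p=p)


@dataclass(frozen=True)
class PlantSpec:
    """One ORF to plant: a seed protein degenerated to a target identity."""

    protein: ProteinSeq
    target_identity: float = 100.0
    position: int | None = None  # genomic offset of the CDS start, or auto
    strand: str | None = None  # '+'/'-', or random when None
    role: str = "decoy"  # toxin | antitoxin | decoy

    def __post_init__(self) -> None:
        if self.role not in ("toxin", "antitoxin", "decoy"):
            raise ValueError(f"unknown role {self.role!r}")
        if self.strand not in (None, "+", "-"):
            raise ValueError(f"unknown strand {self.strand!r}")


@dataclass(frozen=True)
class PlantedFeature:
    """Ground truth for one planted ORF (coordinates include the stop codon)."""

    id: str
    start: int
    end: int
    strand: str
    role: str
    protein: str
    seed_protein_id: str
    realized_identity: float


@dataclass
class GenomeManifest:
    genome_id: str
    seed: int
    status: str  # intended cohort label: pair|toxin_only|antitoxin_only|absent
    planted: list[PlantedFeature] = field(default_factory=list)
    pair_separation_bp: int | None = None


@dataclass
class CohortManifest:
    seed: int
    genomes: list[GenomeManifest] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _realized_identity(seed_protein: ProteinSeq, mutant: ProteinSeq) -> float:
    same = sum(1 for a, b in zip(seed_protein.residues, mutant.residues) if a == b)
    return round(100.0 * same / max(len(seed_protein), len(mutant)), 1)


def generate_genome(length: int, gc_fraction: float,
                    plants: list[PlantSpec],
                    spacing_bp: int = 100,
                    rng_seed: int = 0,
                    genome_id: str = "synthetic") -> tuple[GenomeRecord,
                                                           list[GeneFeature],
                                                           GenomeManifest]:
    """A random genome with planted ORFs and a ground-truth manifest.

    Toxin/antitoxin plants are placed as an operon: the antitoxin is put
    exactly ``spacing_bp`` upstream of the toxin in the toxin's transcription
    direction, both on the toxin's strand.  Other plants are placed at
    non-overlapping random (or requested) positions.  Raises ``ValueError``
    when the plants cannot fit.
    """
    if not 0 < gc_fraction < 1:
        raise ValueError("gc_fraction must be in (0, 1)")
    placement = _substream(rng_seed, f"placement:{genome_id}")
    background = _substream(rng_seed, f"background:{genome_id}")
    seq = _random_background(length, gc_fraction, background)

    # materialize each plant's DNA
    inserts: list[tuple[PlantSpec, ProteinSeq, str]] = []
    for k, spec in enumerate(plants):
        mut = mutate_protein(spec.protein, spec.target_identity,
                             rng_seed * 1000003 + k)
        dna = back_translate(mut, rng_seed * 1000003 + k)
        inserts.append((spec, mut, dna))

    toxin_idx = [i for i, (s, _, _) in enumerate(inserts) if s.role == "toxin"]
    anti_idx = [i for i, (s, _, _) in enumerate(inserts) if s.role == "antitoxin"]

    occupied: list[tuple[int, int]] = []

    def fits(start: int, end: int) -> bool:
        return 0 <= start and end <= length and all(
            end <= a or start >= b for a, b in occupied
        )

    def place(dna_len: int, requested: int | None, label: str) -> int:
        if requested is not None:
            if not fits(requested, requested + dna_len):
                raise ValueError(
                    f"plant {label!r} at {requested} (+{dna_len} bp) conflicts "
                    f"with occupied intervals {occupied} or genome bounds"
                )
            return requested
        for _ in range(200):
            start = int(placement.integers(0, max(1, length - dna_len)))
            if fits(start, start + dna_len):
                return start
        raise ValueError(f"could not place plant {label!r} ({dna_len} bp) in "
                         f"{length} bp genome; occupied: {occupied}")

    features: list[GeneFeature] = []
    planted: list[PlantedFeature] = []

    def install(idx: int, start: int, strand: str) -> None:
        spec, mut, dna = inserts[idx]
        if strand == "-":
            from .seqio import reverse_complement
            dna = reverse_complement(dna)
        end = start + len(dna)
        seq[start:end] = np.frombuffer(dna.encode(), dtype="S1")
        occupied.append((start, end))
        fid = f"{genome_id}_{spec.role}{idx}"
        features.append(GeneFeature(id=fid, start=start, end=end, strand=strand,
                                    product=f"planted {spec.role}"))
        planted.append(
            PlantedFeature(
                id=fid, start=start, end=end, strand=strand, role=spec.role,
                protein=mut.residues, seed_protein_id=spec.protein.id,
                realized_identity=_realized_identity(spec.protein, mut),
            )
        )

    pair_sep: int | None = None
    if toxin_idx and anti_idx:
        ti, ai = toxin_idx[0], anti_idx[0]
        t_spec, _, t_dna = inserts[ti]
        _, _, a_dna = inserts[ai]
        strand = t_spec.strand or ("+" if placement.random() < 0.5 else "-")
        block = len(a_dna) + spacing_bp + len(t_dna)
        if t_spec.position is not None:
            t_start = t_spec.position
            block_start = (t_start - len(a_dna) - spacing_bp
                           if strand == "+" else t_start)
            if not fits(block_start, block_start + block):
                raise ValueError("toxin-antitoxin block does not fit at the "
                                 f"requested position {t_spec.position}")
        else:
            block_start = place(block, None, "TA-pair")
            t_start = (block_start + len(a_dna) + spacing_bp
                       if strand == "+" else block_start)
        # antitoxin upstream in the toxin's transcription direction
        a_start = (block_start if strand == "+"
                   else t_start + len(t_dna) + spacing_bp)
        install(ti, t_start, strand)
        install(ai, a_start, strand)
        pair_sep = spacing_bp
        remaining = [i for i in range(len(inserts)) if i not in (ti, ai)]
    else:
        remaining = list(range(len(inserts)))

    for idx in remaining:
        spec, _, dna = inserts[idx]
        strand = spec.strand or ("+" if placement.random() < 0.5 else "-")
        start = place(len(dna), spec.position, spec.role)
        install(idx, start, strand)

    genome = GenomeRecord(id=genome_id, sequence=seq.tobytes().decode(),
                          features=sorted(features, key=lambda f: f.start))
    manifest = GenomeManifest(genome_id=genome_id, seed=rng_seed,
                              status="unlabelled", planted=planted,
                              pair_separation_bp=pair_sep)
    return genome, genome.features, manifest


def toxin_seed(seed: int = 20190204) -> ProteinSeq:
    """Synthetic stand-in for a zeta-family toxin query (197 aa).

    A deterministic random protein with the Walker-A variant ``GPNGAGKS``
    written at positions 9-16 (1-based), mirroring where the motif sits in
    zeta-family kinases.  Synthetic: not a real toxin sequence.
    """
    rng = _substream(seed, "toxin-seed")
    res = list("".join(_AA20[i] for i in rng.integers(0, 20, size=197)))
    res[8:16] = "GPNGAGKS"
    return ProteinSeq(id="synthetic_toxin_seed", residues="".join(res))


def antitoxin_seed(seed: int = 20190204) -> ProteinSeq:
    """Synthetic stand-in for the cognate antitoxin query (129 aa).

    Synthetic: not a real antitoxin sequence.
    """
    rng = _substream(seed, "antitoxin-seed")
    res = "".join(_AA20[i] for i in rng.integers(0, 20, size=129))
    return ProteinSeq(id="synthetic_antitoxin_seed", residues=res)


def generate_cohort(n_pair: int, n_toxin_only: int, n_antitoxin_only: int,
                    n_absent: int,
                    identity_range: tuple[float, float] = (70.0, 90.0),
                    spacing_range: tuple[int, int] = (50, 150),
                    rng_seed: int = 0,
                    genome_length: int = 50_000,
                    gc_fraction: float = 0.65,
                    toxin: ProteinSeq | None = None,
                    antitoxin: ProteinSeq | None = None,
                    ) -> tuple[list[GenomeRecord], CohortManifest]:
    """A cohort of genomes with known per-genome TA status.

    Identities and spacings are sampled uniformly from the given ranges;
    everything is reproducible from ``rng_seed``.  Defaults state the world
    the survey is validated in: 50 kb genomes at 65% GC (actinobacteria-like),
    plants at 70-90% identity, pair spacing 50-150 bp.
    """
    for n in (n_pair, n_toxin_only, n_antitoxin_only, n_absent):
        if n < 0:
            raise ValueError("cohort counts must be >= 0")
    toxin = toxin or toxin_seed()
    antitoxin = antitoxin or antitoxin_seed()
    sampler = _substream(rng_seed, "cohort")
    statuses = (["pair"] * n_pair + ["toxin_only"] * n_toxin_only
                + ["antitoxin_only"] * n_antitoxin_only + ["absent"] * n_absent)
    genomes: list[GenomeRecord] = []
    manifest = CohortManifest(seed=rng_seed)
    for i, status in enumerate(statuses):
        plants: list[PlantSpec] = []
        ident = float(sampler.uniform(*identity_range))
        spacing = int(sampler.integers(spacing_range[0], spacing_range[1] + 1))
        if status in ("pair", "toxin_only"):
            plants.append(PlantSpec(protein=toxin, target_identity=ident,
                                    role="toxin"))
        if status in ("pair", "antitoxin_only"):
            plants.append(PlantSpec(protein=antitoxin, target_identity=ident,
                                    role="antitoxin"))
        genome, _, gman = generate_genome(
            length=genome_length, gc_fraction=gc_fraction, plants=plants,
            spacing_bp=spacing, rng_seed=rng_seed * 10007 + i,
            genome_id=f"cohort{rng_seed}_g{i:03d}_{status}",
        )
        gman.status = status
        genomes.append(genome)
        manifest.genomes.append(gman)
    return genomes, manifest
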