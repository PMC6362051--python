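# Methods

This note records the models, conventions and deliberate choices behind
`tapairscan`, in the order the pipeline applies them.

## Coordinates and translation

Internal coordinates are 0-based half-open everywhere; GFF3 I/O converts to
and from the format's 1-based inclusive convention at the boundary. This
makes the intergenic-distance arithmetic of the pairing rule exact and
unambiguous. Genomes are treated as linear: no wrap-around ORFs.

Translation uses the bacterial/archaeal genetic code (NCBI table 11) with
no alternative-start handling — GTG/TTG are translated literally, because
all downstream consumers operate on aligned or frame-translated sequence
where start-codon identity is irrelevant. Stop codons are kept as `*` in
frame translations (the search layer decides what to do with them), and a
codon containing IUPAC ambiguity codes translates to the unique amino acid
it resolves to, else `X`. `X` participates in alignment with the score the
substitution matrix assigns to its column.

## Local alignment

The aligner is an affine-gap Smith–Waterman using the Gotoh three-state
recurrence, with BLOSUM62 (shipped as an NCBI-format text file) and gap
open 11 / extend 1 by default; a gap of length *g* costs `open + g·extend`,
i.e. the first gap position costs 12. All four scoring parameters and the
matrix are overridable.

Determinism: ties for the best-scoring cell are broken by smallest subject
index, then smallest query index; within the traceback, ties prefer the
diagonal, then gap-in-subject, then gap-in-query, and a tied gap state
closes the gap rather than extending it. Two runs on the same inputs
produce byte-identical alignments.

Percent identity uses one denominator everywhere: identical columns over
*all* alignment columns, gap columns included. Aligners differ on this
definition and published identity figures rarely state theirs, which is why
the reference-panel checks carry a ±3 percentage-point band rather than an
exact target.

Two independent implementations exist on purpose: a reference Python DP
with full traceback, and a numba-compiled score-only kernel used by the
search layer to prefilter segments. The test suite holds them equal, and
additionally checks both against an exhaustive alignment-path enumerator
(small inputs) and Biopython's `PairwiseAligner` in the same gap convention.

## E-values

Hit significance is the Karlin–Altschul expectation `E = K·m·n·exp(−λS)`
with the published gapped BLOSUM62-11-1 constants λ = 0.267, K = 0.041.
Two BLAST refinements are deliberately omitted: effective-length (edge)
corrections and compositional adjustment. Absolute E-values therefore
differ somewhat from NCBI BLAST output, but the coarse gates this pipeline
uses (1e−06 for discovery, 1e−04 for surveys) are insensitive to that
difference, and the simpler form is exactly reproducible and testable
against arbitrary-precision arithmetic.

The search inverts the formula to a minimum raw score before aligning, so
segments that cannot reach significance are skipped cheaply (a segment of
length L cannot score above L times the largest matrix entry).

## Translated search

Queries are aligned against the six frame translations of each genome,
split at `*` into stop-free segments — alignments never cross an in-frame
stop, mirroring how translated-search tools treat nonsense codons. `n` in
the E-value is the total stop-free translated residue count of every genome
in the invocation, computed before filtering, so E-values are deterministic
and order-independent. Subject spans map back to forward-strand genomic
coordinates through each frame's codon coordinate map.

Same-strand hits within 30 bp of each other (configurable) merge to one
locus carrying the union span and the best E-value; this absorbs
frameshift-split hits without bridging distinct genes. Hit spans cover the
aligned residues only, so a hit to a full-length planted ORF excludes the
3 bp stop codon of the annotated CDS.

## Operon pairing

A candidate antitoxin is accepted iff (1) it precedes the toxin in the
toxin's transcription direction and (2) the gene-boundary separation is
≤ 150 bp, inclusive — separation 150 accepted, 151 rejected. Separation is
`max(starts) − min(ends)`, which equals the intergenic gap for disjoint
genes, is negative by the overlap length for overlapping ones, and is
symmetric under coordinate mirroring. Overlapping genes are ordered by
midpoint. Rejections carry the first failing reason, checked in the order
wrong_side, strand_mismatch, too_far.

Two points the pairing rule leaves open are parameters rather than guesses:
co-orientation is required by default (type II TA pairs are co-transcribed
operons) but can be disabled, and overlapping partners are allowed by
default (TA genes frequently overlap by a few bases) but can be rejected.

## Survey and classification

Each cohort genome is searched with both queries, hits are merged, and all
toxin × antitoxin cross pairings are evaluated; the genome is `pair` if any
pairing is accepted (existential reading), else `toxin_only` /
`antitoxin_only` / `absent` by which hits passed the gates. When both
partners pass but no pairing is accepted, the status enum forces a choice:
the role of the lower-E-value hit wins (ties favour the toxin).

When a genome carries annotations, hits snap to the same-strand annotated
gene they overlap most before pairing. This matters at the 150 bp boundary:
raw hit spans exclude stop codons and may be soft-trimmed at the termini,
so raw separations can exceed the annotated intergenic distance by a few
bases. Unannotated genomes are surveyed on raw hit spans, and boundary-
exact behaviour is only guaranteed with annotations. Coverage gates use
non-strict inequalities (≥), likewise the E-value gate (≤).

## Synthetic genomes

The generator states the world the pipeline is validated in:

* background DNA is i.i.d. with a controlled GC fraction, default 0.65
  (actinobacteria-like, the GC range of mycobacteria);
* planted ORFs are back-translations (uniform synonymous codons, terminal
  TAG) of seed proteins degenerated to a target percent identity —
  substitution-only by default, so realized identity is exact to rounding;
  replacement residues are BLOSUM62-positive partners with probability 0.7
  to mimic homologous divergence;
* TA pairs are planted at an exact intergenic spacing with the antitoxin
  upstream in the toxin's transcription direction, both co-oriented;
* cohorts mix pair / toxin-only / antitoxin-only / absent genomes, default
  50 kb genomes, identities 70–90%, spacings 50–150 bp, with a JSON
  manifest recording intervals, strands, roles and realized identities;
* all randomness derives from one seed through named substreams, so
  outputs are byte-reproducible.

The default seed queries are *synthetic stand-ins*: deterministic random
proteins of the lengths typical of ζ-family toxins (197 aa, with the
Walker-A variant `GPNGAGKS` written at positions 9–16) and their antitoxins
(129 aa). They are not real toxin sequences.

What a green synthetic test establishes: that the search recovers
substitution-diverged ORFs at the stated identities, that coordinates map
back exactly, and that the pairing and classification logic is boundary-
exact. What it does not establish: behaviour under indels (an optional
indel rate exists but defaults to 0), repeat-rich or biased-composition
genomes, codon-usage realism, or agreement with any specific BLAST build's
E-values. Checks that need the real reference proteins (exact motif
positions in the real toxin, published pairwise identities) run only when
the user supplies those sequences; they are reported as failures, not
skipped, when the panel is absent.

## Numerical and degenerate-input choices

* Empty local alignment (no positive-scoring pair) is a score-0 result with
  zero-length spans; percent identity on it raises rather than returning 0.
* `min_score_for_evalue` guards the `ceil` against floating-point boundary
  effects by checking its neighbours directly.
* Identical intervals have separation −length (full overlap), not an error.
* A reference position aligned to a gap column, or outside the aligned
  span, has equivalence status `unaligned`; `similar` means a non-identical
  pairing with a strictly positive matrix score. Conservation counts
  identical residues only, with similar counts reported alongside.
* Per-genome failures during a survey are recorded as `error` records and
  excluded from the database length; the survey continues.

## Known limitations

* No heuristic seeding: every stop-free segment above the score bound is
  aligned exactly. Fine for cohorts of bacterial genomes on one CPU;
  not a metagenome-scale tool.
* No effective-length correction means E-values are conservative for short
  subjects relative to BLAST's.
* Pairwise residue-equivalence mapping can differ from what a curated
  multiple sequence alignment would give in low-identity regions; treat
  single-residue equivalences below ~20% identity as qualitative.
* The survey's `pair` call is purely geometric; it does not verify
  co-transcription or functional neutralization.
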