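# Methods

This note records the models, conventions and numerical choices behind
`hgvsmap`, and what its synthetic fixtures do and do not establish.

## Coordinate model

All public genomic coordinates are 1-based inclusive, matching HGVS and
VCF. GFF3 input is already 1-based inclusive; UCSC chain files are
0-based half-open with minus-strand query coordinates counted on the
reversed sequence, and that double convention is confined to the
liftover module — nothing else ever sees it. BED-style inputs are not
accepted. The motivation is blunt: mixed indexing conventions are the
dominant source of off-by-one errors when harmonizing variant data, so
the package exposes exactly one convention.

A transcript is modelled by its exons (ascending, non-overlapping
genomic intervals), the genomic positions of the first and last coding
base, a strand, and a MANE flag. CDS coordinates (`c.`) count coding
bases in transcript orientation: `c.1` is the first base of the start
codon, and on minus-strand transcripts `c` increases as the genomic
coordinate decreases. Codon reading order follows the coding strand, so
a minus-strand codon's genomic positions are descending. The mapping
`genomic_to_cds`/`cds_to_genomic` is an explicit bijection between the
coding genomic positions and `1..CDS_length`; it is verified
exhaustively in tests rather than sampled. Intronic and exonic-UTR
positions raise distinct typed errors; intronic `c.` offset notation
(`c.88+2T>G`) is recognized by the grammar but deliberately unsupported
in v1.

Validation is front-loaded: at construction a transcript must have
sorted non-overlapping exons, CDS bounds inside exons, and a CDS length
that is a positive multiple of 3. Translation requires a terminal stop
codon and no internal stop (the offending residue index is reported).
Genomes accept only {A,C,G,T,N}; any operation that needs a concrete
base at an `N` raises an explicit ambiguous-reference error rather than
guessing. Sequences are uppercased at load; soft-masking is discarded.

A FASTA header of the form `chr7:140752800-140755334` (the
`samtools faidx` region convention) may be loaded as a *window*: bases
are stored from the stated offset and all lookups use absolute
chromosome coordinates. This lets a snapshot carry a single gene
neighborhood at true assembly coordinates.

## Transcript selection

When a gene has several transcripts the MANE-flagged one is used. The
fallback ordering — longest CDS, then lexicographically smallest
transcript id — is this package's own deterministic convention, and the
rule actually applied is reported in every output so downstream users
can see which substrate produced a call. v1 models MANE as a single
boolean; a separate MANE Plus Clinical tier is not represented.

## Reverse translation (protein → DNA)

For a residue change the reference codon is read at the codon's genomic
locus, and every codon of the target amino acid becomes a candidate,
scored by Hamming distance (1–3). Candidates are sorted by
(n_changes, transition count descending, codon lexicographic) and the
first is selected. The minimality claim is not taken on faith: tests
compare the selected distance against a brute-force minimum over all 64
codons for every ordered amino-acid pair. The transition-first tie-break
is a documented package convention (transitions being the more frequent
mutational event); the source material for this feature specifies only
the minimal-change criterion, so any consistent tie order would be
defensible — this one is deterministic and visible in the output.
Requesting the amino acid the codon already encodes is a typed
"synonymous request" error: a zero-change self-candidate would be
meaningless as an exchange. When no single-base candidate exists the
selected exchange needs 2–3 bases; it is flagged multi-nucleotide and
all its edits are emitted (for an exon-junction codon they may be
non-adjacent genomic positions).

Edits are always expressed as plus-strand alleles; for minus-strand
transcripts the coding-strand alleles are complemented at the boundary,
and a dedicated test re-derives them through an independent
reverse-complement path.

## Consequence calling (DNA → protein)

The supplied ref allele is asserted against the loaded genome before
anything else — a mismatch is a loud reference-assertion error, because
it almost always means a stale annotation or wrong assembly. Every gene
overlapping the position is consulted through its selected transcript;
the primary call is the first whose CDS contains the position and the
rest are carried in `others`, never silently dropped. Consequences are
classified by translating the reference and mutant codons: synonymous
(rendered `p.X123=`), missense, nonsense, stop-lost. Non-coding hits
(intronic / UTR / intergenic) return a typed result rather than an
exception, mirroring how annotation tools report rather than fail.

The round-trip harness (`roundtrip_check`) feeds the selected exchange
back through the consequence caller and demands the original change
re-emerge. Multi-nucleotide selections cannot ride a single SNV back, so
they are verified at codon level instead; the diagnostic says which path
was taken.

## Liftover

A chain file is parsed into blocks of colinear segments; the cumulative
size/dt/dq arithmetic is re-verified against the header spans and any
mismatch is a hard integrity error (experience says silently tolerating
malformed chains is how coordinates go wrong). A position maps if a
segment covers it; positions inside a block but between segments are
typed `unmapped(gap)`, positions outside every block `unmapped(no-chain)`.
When several chains cover a position the highest score wins, ties going
to the lowest chain id, and the number of alternatives is reported —
the multi-mapping policy is this package's documented choice. Variant
liftover complements alleles across strand flips and re-validates the
ref allele on the target assembly; a disagreement is returned as a typed
`reference-changed` result, never as a silent variant.

## Fusion frame

Breakpoint semantics are explicit: the 5' breakpoint is the last
retained base, the 3' breakpoint the first retained base. With
L5 = coding bases of the 5' partner from `c.1` through its breakpoint
and L3_up = coding bases of the 3' partner strictly before its
breakpoint, the junction is in-frame iff `L5 ≡ L3_up (mod 3)` and both
breakpoints fall inside their partners' CDS spans; intronic breakpoints
count only completed exons (the junction is assumed exon-boundary
spliced). Junctions in UTRs return `non-coding-junction` — no frame
statement is meaningful there. These conventions are enforced rather
than merely asserted: the frame call is checked against a translation
oracle (does the 3' partner's complete downstream codon tail appear
verbatim in the translated fusion?) across hundreds of seeded events,
and `fused_protein` reports the residue of the first premature stop for
shifted frames.

## HGVS subset

Supported: substitution, deletion, insertion, delins, duplication at
`g.`/`c.`/`p.`; one- and three-letter amino acids (`Ter` accepted,
normalized to `*`); the bare `GENE:V600E` shorthand. Recognized but
typed as unsupported (never mis-parsed): intronic offsets, UTR
positions, frameshifts, repeats. Formatting canonicalizes to one-letter
codes, and parse∘format is property-tested as an identity on the
subset. Applying an edit always asserts the stated reference
allele/residues first; p-level range notation names only its boundary
residues, which are stored (`start_ref`/`end_ref`) and checked
positionally.

## Service envelope

Every request yields exactly one envelope
`{"header": {"qid", "status_code"}, "data": ...}` with only the two
status codes 200 and 400; finer error taxonomy lives in
`data.error.kind`. Batches preserve input order, pass caller qids
through verbatim (line numbers otherwise), and never abort on a bad
record. The envelope contract is published as a JSON schema generated
from the pydantic model that also validates it. The toolbox is exposed
as a library plus CLI; an HTTP layer would be a thin additional wrapper
and is intentionally out of scope.

## Synthetic fixtures — what they show and what they don't

`make_toy_reference(seed, ...)` designs proteins first (start methionine,
no internal stops by construction), reverse-translates them with random
codon choice, adds short UTRs and 1–4 exons with random introns, and
places genes on both strands of small chromosomes. Defaults (8 genes,
2 chromosomes, proteins of 12–40 residues, half the genes on the minus
strand) keep exhaustive sweeps — every coding position, every residue ×
19 substitutions — affordable while covering the structural cases that
matter: strand, exon junctions inside codons, UTR flanks, multi-exon
CDS. `make_toy_chain` builds a target assembly by applying offset /
gap / inversion edits and emits the chain, its exact inverse, and an
independently computed per-position truth table.

`synthetic_clinical_snapshot` is a synthetic stand-in for a real
GRCh38 BRAF snapshot: random sequence with one anchored fact — the
minus-strand transcript's codon 600 is GTG with its middle base at
chr7:140753336 — stored as a ~2.5 kb region window. It demonstrates the
classic V600E conversion at true assembly coordinates without any
download. Its transcript id is `SYNTH-BRAF-001` precisely so it cannot
be mistaken for a real RefSeq record. To run against real data, export
a region FASTA with `samtools faidx`, the MANE GFF3 (or the documented
TSV columns) and an HGNC custom download; the readers consume those
directly.

What passing these tests does *not* show: behavior on UTA-style gapped
transcript↔genome alignments (fixtures assume exact exon
correspondence), indel consequence calling at protein level, splice-site
effects, repeat-mediated HGVS normalization (3'-shifting), or real-data
edge cases such as selenoproteins and non-standard genetic codes. Those
are stated non-goals of this version.

## Problem sizes and tolerances

Test and acceptance sweeps use the generator defaults above (three
8-gene references for the bijection sweep, 380 ordered amino-acid pairs
× all source codons for minimality, ~2 400 residue×substitution round
trips, ~1 400 lifted positions, 200 fusion events). All acceptance
properties are exact (zero violations demanded); nothing is compared
with a numeric tolerance because every quantity in scope is discrete.
Caching of per-transcript coding-position walks is keyed by transcript
identity plus structure, so mutated copies of a transcript cannot alias
a stale cache entry.
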