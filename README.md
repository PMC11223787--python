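# hgvsmap

Convert variant descriptions between genomic, transcript and protein
coordinates — entirely offline, against plain local snapshot files.

Genetic datasets describe the same event in incompatible vocabularies: a
clinical panel reports `BRAF:V600E`, a WGS pipeline reports
`chr7:g.140753336A>T`, an older cohort uses a retired gene symbol and a
different reference assembly. Harmonizing them by hand is slow and
error-prone (is the coordinate 0- or 1-based? is the coding strand
forward or reverse?). `hgvsmap` packages those conversions as a library
and CLI for people who integrate variant data: it needs only a FASTA
genome (or a windowed region of one), a transcript annotation (GFF3 or
TSV), an HGNC-style symbol table and, for liftover, a UCSC chain file —
no databases, no network, which also suits air-gapped clinical
environments.

## What it computes

* **Protein → DNA.** For a residue change like V600E it enumerates every
  codon of the target amino acid, scores each by Hamming distance to the
  reference codon, and selects the genomic exchange with the **minimum
  number of base changes** (ties: more transitions A↔G/C↔T first, then
  codon order). All candidates are reported; edits are expressed as
  plus-strand alleles whatever the transcript strand.
* **DNA → protein.** A genomic SNV is mapped through the MANE Select
  transcript (fallback: longest CDS) to its codon, classified as
  synonymous / missense / nonsense / stop-lost, and printed as an HGVS
  `p.` string.
* **Coordinate mapping.** Exact bijection between genomic positions and
  CDS coordinates (`c.1` = first base of the start codon, counted in
  transcript orientation), plus per-exon reports.
* **Liftover.** UCSC chain files (0-based half-open, strand-flipped
  query coordinates) drive position and variant liftover behind a purely
  1-based plus-strand API; ref alleles are re-validated on the target
  assembly.
* **Fusion frame.** A junction with L5 coding bases retained from the 5'
  partner and L3 coding bases lost from the 3' partner is **in-frame iff
  L5 ≡ L3 (mod 3)**; the call is substantiated by translating the fused
  CDS.
* **HGVS grammar.** Substitution, deletion, insertion, delins and
  duplication at `g.`/`c.`/`p.` (1- and 3-letter amino acids, the bare
  `GENE:V600E` shorthand), with reference-allele assertion on every
  edit.
* **Symbols.** Approved / alias / previous gene-symbol normalization.

Every operation is also exposed through a batch service that wraps each
result in `{"header": {"qid": ..., "status_code": 200|400}, "data": ...}`
so pipeline inputs map one-to-one onto outputs.

## Worked example

The package ships a deterministic generator for toy references, and a
synthetic GRCh38-coordinate snapshot whose minus-strand BRAF-like
transcript anchors codon 600 (GTG, valine) at its true locus:

```python
from hgvsmap.fixtures import synthetic_clinical_snapshot
from hgvsmap.service import ToolboxContext, handle_request

snap = synthetic_clinical_snapshot(seed=0)
ctx = ToolboxContext(assembly=snap.assembly,
                     transcripts=snap.transcripts,
                     symbols=snap.symbols)
print(handle_request(ctx, "protein_to_dna", {"hgvs": "BRAF:V600E"}, qid=1))
```

prints (reformatted):

```json
{"header": {"qid": 1, "status_code": 200},
 "data": {"input": "BRAF:p.V600E",
          "transcript": "SYNTH-BRAF-001",
          "selection_rule": "mane",
          "possible_exchange": [
            {"codon": "GAG", "n_changes": 1,
             "edits": ["chr7:g.140753336A>T"], "is_selected": true},
            {"codon": "GAA", "n_changes": 2,
             "edits": ["chr7:g.140753335C>T", "chr7:g.140753336A>T"],
             "is_selected": false}],
          "mapped_position": "chr7:g.140753336A>T",
          "is_multi_nucleotide": false, ...}}
```

Reading: glutamate has two codons; `GAG` needs a single base change, so
the selected exchange is the middle base of the codon — coding-strand
T>A, which on the plus strand of this minus-strand gene is
`chr7:g.140753336A>T`. Running the reverse conversion on that variant
returns `BRAF:p.V600E` (missense), closing the round trip. Symbol
normalization on the same snapshot resolves the alias `HGFR` to the
approved symbol `MET`.

The same operations are available from the shell:

```
hgvsmap --genome genome.fa --transcripts transcripts.tsv \
        protein-to-dna "BRAF:V600E"
hgvsmap --symbols symbols.tsv normalize HGFR
hgvsmap --chain hg19ToHg38.over.chain liftover chr7:140453136
```

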