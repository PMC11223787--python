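"""Bidirectional variant conversion: DNA→protein consequence calling and
protein→DNA reverse translation with minimal nucleotide changes.

Reverse translation enumerates every codon of the target amino acid,
expresses the differences to the reference codon as plus-strand genomic
edits, and selects the candidate with the fewest base changes.  Among
equal-minimal candidates the tie breaks first to the one with more
transitions (A<->G, C<->T) — the more frequent mutational event — then to
codon-lexicographic order; the rule is deterministic and carried in the
output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .coordinate_map import CodonLocus, codon_locus, genomic_to_cds
from .errors import (
    CoordinateError,
    IntronicPositionError,
    ReferenceMismatchError,
    SynonymousRequestError,
    UtrPositionError,
    ValidationError,
)
from .reference_model import (
    GeneticCode,
    GenomeAssembly,
    STANDARD_CODE,
    TranscriptModel,
    get_genomic_sequence,
    get_protein_sequence,
    reverse_complement,
    select_transcript,
)

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass(frozen=True)
class GenomicVariant:
    """A single-position substitution in plus-strand genomic coordinates."""

    assembly: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValidationError("ref and alt alleles must differ")
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValidationError("GenomicVariant holds single-base alleles")

    def __str__(self) -> str:
        return f"{self.chrom}:g.{self.pos}{self.ref}>{self.alt}"


@dataclass(frozen=True)
class ProteinChange:
    gene_symbol: str
    transcript_id: str
    residue_index: int  # 1-based
    ref_aa: str
    alt_aa: str  # one-letter or '*'


@dataclass(frozen=True)
class CodonCandidate:
    """An alternative codon for the target amino acid."""

    codon: str  # coding-strand orientation
    n_changes: int  # Hamming distance to the reference codon
    edits: tuple[GenomicVariant, ...]  # plus-strand alleles
    is_selected: bool = False


@dataclass(frozen=True)
class ProteinToDnaResult:
    change: ProteinChange
    candidates: tuple[CodonCandidate, ...]  # the "possible exchange" list
    selected: CodonCandidate  # the "mapped position"
    is_mnv: bool  # selected needs >1 base change

    @property
    def selected_variant(self) -> GenomicVariant:
        """The selected edit as one variant (first edit of an MNV)."""
        return self.selected.edits[0]


@dataclass(frozen=True)
class ConsequenceCall:
    change: ProteinChange
    consequence: str  # synonymous | missense | nonsense | stop-lost
    hgvs_p: str
    selection_rule: str
    others: tuple["ConsequenceCall", ...] = ()


@dataclass(frozen=True)
class NoCodingConsequence:
    """Typed non-exceptional result: the variant hits no coding base."""

    reason: str  # intronic | utr | intergenic
    detail: str = ""


def _transition_count(ref_codon: str, codon: str) -> int:
    return sum(
        1
        for a, b in zip(ref_codon, codon)
        if a != b and (a, b) in _TRANSITIONS
    )


def enumerate_candidates(
    ref_codon: str,
    target_aa: str,
    locus: CodonLocus,
    strand: str,
    code: GeneticCode = STANDARD_CODE,
) -> list[CodonCandidate]:
    """All codons encoding ``target_aa``, as genomic edit sets.

    Sorted by (number of changes, transitions descending, codon); asking
    for the amino acid the reference codon already encodes is a typed
    error — the zero-change self-candidate is never listed.
    """
    ref_aa = code.codon_to_aa[ref_codon]
    if ref_aa == target_aa:
        raise SynonymousRequestError(
            f"codon {ref_codon} already encodes {target_aa}"
        )
    codons = code.aa_to_codons.get(target_aa)
    if not codons:
        raise ValidationError(f"no codons for amino acid {target_aa!r}")
    out = []
    for codon in codons:
        diffs = [i for i in range(3) if codon[i] != ref_codon[i]]
        edits = []
        for i in diffs:
            ref_b, alt_b = ref_codon[i], codon[i]
            if strand == "-":
                ref_b, alt_b = reverse_complement(ref_b), reverse_complement(alt_b)
            edits.append(
                GenomicVariant(
                    assembly="",
                    chrom=locus.chrom,
                    pos=locus.codon_genomic_positions[i],
                    ref=ref_b,
                    alt=alt_b,
                )
            )
        edits.sort(key=lambda v: v.pos)
        out.append(
            CodonCandidate(codon=codon, n_changes=len(diffs), edits=tuple(edits))
        )
    out.sort(
        key=lambda c: (
            c.n_changes,
            -_transition_count(ref_codon, c.codon),
            c.codon,
        )
    )
    return out


def protein_to_dna(
    change: ProteinChange,
    transcript: TranscriptModel,
    assembly: GenomeAssembly,
    code: GeneticCode = STANDARD_CODE,
) -> ProteinToDnaResult:
    """Reverse-translate an amino-acid change into genomic variants.

    The stated reference residue is asserted against the translated
    reference protein first, so stale annotations fail loudly.
    """
    protein = get_protein_sequence(transcript, assembly, code)
    r = change.residue_index
    if not (1 <= r <= len(protein) + 1):
        raise CoordinateError(
            f"residue {r} out of range 1..{len(protein)} for "
            f"{transcript.transcript_id}"
        )
    observed = protein[r - 1] if r <= len(protein) else "*"
    if observed != change.ref_aa:
        raise ReferenceMismatchError(
            f"{change.gene_symbol} residue {r}: expected {change.ref_aa!r}, "
            f"reference protein has {observed!r}",
            expected=change.ref_aa,
            observed=observed,
        )
    locus = codon_locus(transcript, assembly, r, code)
    candidates = enumerate_candidates(
        locus.ref_codon, change.alt_aa, locus, transcript.strand, code
    )
    selected = replace(candidates[0], is_selected=True)
    candidates = (selected, *candidates[1:])
    edits = tuple(replace(e, assembly=assembly.name) for e in selected.edits)
    selected = replace(selected, edits=edits)
    return ProteinToDnaResult(
        change=replace(change, transcript_id=transcript.transcript_id),
        candidates=candidates,
        selected=selected,
        is_mnv=selected.n_changes > 1,
    )


def _consequence(ref_aa: str, alt_aa: str) -> str:
    if ref_aa == alt_aa:
        return "synonymous"
    if alt_aa == "*":
        return "nonsense"
    if ref_aa == "*":
        return "stop-lost"
    return "missense"


def _format_p(gene: str, ref_aa: str, pos: int, alt_aa: str) -> str:
    if ref_aa == alt_aa:
        return f"{gene}:p.{ref_aa}{pos}="
    return f"{gene}:p.{ref_aa}{pos}{alt_aa}"


def dna_to_protein(
    variant: GenomicVariant,
    transcripts: list[TranscriptModel],
    assembly: GenomeAssembly,
    code: GeneticCode = STANDARD_CODE,
) -> ConsequenceCall | NoCodingConsequence:
    """Map a genomic SNV to its protein consequence.

    For every gene overlapping the position the selected (MANE-or-fallback)
    transcript is consulted; the primary call is the first transcript whose
    CDS contains the position, with any further coding hits reported in
    ``others``.  Non-coding positions return a typed result rather than an
    exception.
    """
    observed = get_genomic_sequence(assembly, variant.chrom, variant.pos, variant.pos)
    if observed != variant.ref:
        raise ReferenceMismatchError(
            f"{variant.chrom}:{variant.pos}: expected ref {variant.ref!r}, "
            f"assembly has {observed!r}",
            expected=variant.ref,
            observed=observed,
        )
    overlapping = {
        t.gene_symbol
        for t in transcripts
        if t.chrom == variant.chrom and t.span[0] <= variant.pos <= t.span[1]
    }
    if not overlapping:
        return NoCodingConsequence("intergenic", f"no transcript at {variant}")
    calls: list[ConsequenceCall] = []
    misses: list[str] = []
    for gene in sorted(overlapping):
        choice = select_transcript(gene, transcripts)
        t = choice.transcript
        try:
            cpos = genomic_to_cds(t, variant.pos)
        except IntronicPositionError:
            misses.append("intronic")
            continue
        except (UtrPositionError, CoordinateError):
            misses.append("utr")
            continue
        residue = (cpos.c_pos + 2) // 3
        offset_in_codon = (cpos.c_pos - 1) % 3
        locus = codon_locus(t, assembly, residue, code)
        ref_b, alt_b = variant.ref, variant.alt
        if t.strand == "-":
            ref_b = reverse_complement(ref_b)
            alt_b = reverse_complement(alt_b)
        assert locus.ref_codon[offset_in_codon] == ref_b
        mutant = (
            locus.ref_codon[:offset_in_codon]
            + alt_b
            + locus.ref_codon[offset_in_codon + 1 :]
        )
        ref_aa = code.codon_to_aa[locus.ref_codon]
        alt_aa = code.codon_to_aa[mutant]
        change = ProteinChange(
            gene_symbol=gene,
            transcript_id=t.transcript_id,
            residue_index=residue,
            ref_aa=ref_aa,
            alt_aa=alt_aa,
        )
        calls.append(
            ConsequenceCall(
                change=change,
                consequence=_consequence(ref_aa, alt_aa),
                hgvs_p=_format_p(gene, ref_aa, residue, alt_aa),
                selection_rule=choice.rule,
            )
        )
    if not calls:
        reason = "intronic" if "intronic" in misses else "utr"
        return NoCodingConsequence(reason, f"no coding transcript at {variant}")
    primary = calls[0]
    return replace(primary, others=tuple(calls[1:]))


def roundtrip_check(
    change: ProteinChange,
    transcript: TranscriptModel,
    transcripts: list[TranscriptModel],
    assembly: GenomeAssembly,
    code: GeneticCode = STANDARD_CODE,
) -> tuple[bool, str]:
    """Does protein→DNA→protein reproduce the input change?

    Single-base selections go back through the full genomic consequence
    caller; multi-base selections (no 1-change codon exists) are verified
    at codon level, since a lone SNV cannot carry them.
    """
    fwd = protein_to_dna(change, transcript, assembly, code)
    if not fwd.is_mnv:
        back = dna_to_protein(fwd.selected_variant, transcripts, assembly, code)
        if isinstance(back, NoCodingConsequence):
            return False, f"round trip lost coding context: {back.reason}"
        got = back.change
        candidates = [got] + [c.change for c in back.others]
        for cand in candidates:
            if (
                cand.gene_symbol == change.gene_symbol
                and cand.residue_index == change.residue_index
                and cand.ref_aa == change.ref_aa
                and cand.alt_aa == change.alt_aa
            ):
                return True, "ok"
        return False, f"expected {change}, got {got}"
    translated = code.codon_to_aa[fwd.selected.codon]
    if translated == change.alt_aa:
        return True, "ok (multi-nucleotide, codon-level check)"
    return False, f"MNV codon {fwd.selected.codon} translates to {translated}"
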