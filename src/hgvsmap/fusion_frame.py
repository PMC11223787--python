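"""Reading-frame analysis of gene fusion events.

Breakpoint semantics: the 5' partner's breakpoint is the genomic position
of its *last retained* base, the 3' partner's the position of its *first
retained* base.  Intronic breakpoints keep only the coding bases of
completed exons — the junction is assumed to be spliced at exon
boundaries.

With L5 = coding bases retained from the 5' partner (c.1 through its
breakpoint) and L3_up = coding bases of the 3' partner upstream of (not
retained before) its breakpoint, the junction preserves frame exactly when
L5 = L3_up (mod 3) and both sides fall inside a coding region.
"""

from __future__ import annotations

from dataclasses import dataclass

from .coordinate_map import coding_genomic_positions
from .errors import CoordinateError, FusionError
from .reference_model import (
    GeneticCode,
    GenomeAssembly,
    STANDARD_CODE,
    TranscriptModel,
    spliced_cds,
)


@dataclass(frozen=True)
class FusionEvent:
    five_prime: TranscriptModel
    five_breakpoint_g: int  # last retained base
    three_prime: TranscriptModel
    three_breakpoint_g: int  # first retained base

    def __post_init__(self) -> None:
        for t, bp, side in (
            (self.five_prime, self.five_breakpoint_g, "5'"),
            (self.three_prime, self.three_breakpoint_g, "3'"),
        ):
            lo, hi = t.span
            if not (lo <= bp <= hi):
                raise CoordinateError(
                    f"{side} breakpoint {bp} outside transcript "
                    f"{t.transcript_id} span {lo}-{hi}"
                )


@dataclass(frozen=True)
class FusionCall:
    status: str  # 'in-frame' | 'out-of-frame' | 'non-coding-junction'
    l5: int  # coding bases retained from the 5' partner
    l3_up: int  # 3'-partner coding bases upstream of its breakpoint
    phase5: int
    phase3: int


@dataclass(frozen=True)
class FusedProteinResult:
    status: str
    protein: str  # translated fusion product (up to first stop)
    truncated_at: int | None  # residue index of a premature stop, if any


def _retained_5p(transcript: TranscriptModel, bp: int) -> int:
    """Coding bases from c.1 through the breakpoint (transcript order)."""
    positions = coding_genomic_positions(transcript)
    if transcript.strand == "+":
        return sum(1 for p in positions if p <= bp)
    return sum(1 for p in positions if p >= bp)


def _upstream_3p(transcript: TranscriptModel, bp: int) -> int:
    """Coding bases strictly before the breakpoint (transcript order)."""
    positions = coding_genomic_positions(transcript)
    if transcript.strand == "+":
        return sum(1 for p in positions if p < bp)
    return sum(1 for p in positions if p > bp)


def fusion_check(event: FusionEvent) -> FusionCall:
    """Classify a fusion junction as in-frame / out-of-frame.

    A breakpoint outside its partner's CDS genomic span (5' or 3' UTR)
    yields a non-coding-junction call: no frame statement is meaningful
    there.
    """
    t5, bp5 = event.five_prime, event.five_breakpoint_g
    t3, bp3 = event.three_prime, event.three_breakpoint_g
    l5 = _retained_5p(t5, bp5)
    l3_up = _upstream_3p(t3, bp3)
    coding5 = t5.cds_start_g <= bp5 <= t5.cds_end_g and 0 < l5 < t5.cds_length
    coding3 = t3.cds_start_g <= bp3 <= t3.cds_end_g and l3_up < t3.cds_length
    phase5, phase3 = l5 % 3, l3_up % 3
    if not (coding5 and coding3):
        status = "non-coding-junction"
    elif phase5 == phase3:
        status = "in-frame"
    else:
        status = "out-of-frame"
    return FusionCall(
        status=status, l5=l5, l3_up=l3_up, phase5=phase5, phase3=phase3
    )


def fused_protein(
    event: FusionEvent,
    assembly: GenomeAssembly,
    code: GeneticCode = STANDARD_CODE,
) -> FusedProteinResult:
    """Translate the fused coding sequence to substantiate the frame call.

    The retained 5' CDS prefix is concatenated with the retained 3' CDS
    suffix and translated from the 5' start codon; translation stops at the
    first stop codon.  For an in-frame junction the product ends with the
    3' partner's own residues; a premature stop is reported by residue.
    """
    call = fusion_check(event)
    if call.status == "non-coding-junction":
        raise FusionError(
            "junction is outside the coding region of at least one partner; "
            "no fusion product is defined"
        )
    cds5 = spliced_cds(event.five_prime, assembly)
    cds3 = spliced_cds(event.three_prime, assembly)
    fused = cds5[: call.l5] + cds3[call.l3_up :]
    residues = []
    truncated_at = None
    n_full = len(fused) // 3
    for i in range(n_full):
        aa = code.codon_to_aa.get(fused[3 * i : 3 * i + 3])
        if aa is None:  # ambiguous base; cannot happen on ACGT fixtures
            break
        if aa == "*":
            if i + 1 < n_full:
                truncated_at = i + 1
            break
        residues.append(aa)
    else:
        # ran off the end without a stop (trailing partial codon dropped)
        truncated_at = None
    return FusedProteinResult(
        status=call.status, protein="".join(residues), truncated_at=truncated_at
    )
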