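"""Mapping between genomic, CDS (c.) and protein (p.) coordinates.

The CDS coordinate system counts coding bases in transcript orientation:
c.1 is the first base of the start codon, whatever its genomic position.
For minus-strand transcripts c increases as the genomic coordinate
decreases; a codon's genomic positions are therefore descending.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from .errors import CoordinateError, IntronicPositionError, UtrPositionError
from .reference_model import (
    GeneticCode,
    GenomeAssembly,
    STANDARD_CODE,
    TranscriptModel,
    get_genomic_sequence,
    reverse_complement,
)


@dataclass(frozen=True)
class CdsPosition:
    transcript_id: str
    c_pos: int  # 1-based index into the spliced CDS


@dataclass(frozen=True)
class CodonLocus:
    transcript_id: str
    chrom: str
    strand: str
    residue_index: int  # 1-based
    codon_genomic_positions: tuple[int, int, int]  # codon reading order
    ref_codon: str  # coding-strand orientation


@dataclass(frozen=True)
class ExonRecord:
    ordinal: int  # 1-based, in transcript orientation
    start_g: int
    end_g: int
    length: int
    coding_bases: int


def coding_genomic_positions(transcript: TranscriptModel) -> list[int]:
    """Genomic positions of the CDS in transcript (coding) order.

    ``result[c - 1]`` is the genomic position of c.<c>.
    """
    return list(_coding_positions_cached(_key(transcript)))


_TRANSCRIPT_REGISTRY: dict[tuple, TranscriptModel] = {}


def _key(t: TranscriptModel) -> tuple:
    k = (
        t.transcript_id,
        t.chrom,
        t.strand,
        tuple(t.exons),
        t.cds_start_g,
        t.cds_end_g,
    )
    _TRANSCRIPT_REGISTRY[k] = t
    return k


@lru_cache(maxsize=4096)
def _coding_positions_cached(key: tuple) -> tuple[int, ...]:
    t = _TRANSCRIPT_REGISTRY[key]
    positions: list[int] = []
    for s, e in t.exons:
        lo, hi = max(s, t.cds_start_g), min(e, t.cds_end_g)
        if lo <= hi:
            positions.extend(range(lo, hi + 1))
    if t.strand == "-":
        positions.reverse()
    return tuple(positions)


def genomic_to_cds(transcript: TranscriptModel, g_pos: int) -> CdsPosition:
    """Map a genomic position to its 1-based CDS coordinate.

    Intronic, UTR-exonic and out-of-transcript positions raise distinct
    typed errors so callers can report the class of miss.
    """
    span = transcript.span
    if not (span[0] <= g_pos <= span[1]):
        raise CoordinateError(
            f"{g_pos} outside transcript {transcript.transcript_id} "
            f"span {span[0]}-{span[1]}"
        )
    in_exon = any(s <= g_pos <= e for s, e in transcript.exons)
    if not in_exon:
        raise IntronicPositionError(
            f"{g_pos} is intronic in {transcript.transcript_id}"
        )
    if not (transcript.cds_start_g <= g_pos <= transcript.cds_end_g):
        raise UtrPositionError(f"{g_pos} is in the UTR of {transcript.transcript_id}")
    positions = _coding_positions_cached(_key(transcript))
    try:
        idx = positions.index(g_pos)
    except ValueError:  # exonic inside CDS genomic bounds but not coding: intron
        raise IntronicPositionError(
            f"{g_pos} is intronic in {transcript.transcript_id}"
        ) from None
    return CdsPosition(transcript.transcript_id, idx + 1)


def cds_to_genomic(transcript: TranscriptModel, c_pos: int) -> int:
    """Inverse of :func:`genomic_to_cds`."""
    positions = _coding_positions_cached(_key(transcript))
    if not (1 <= c_pos <= len(positions)):
        raise CoordinateError(
            f"c.{c_pos} out of range 1..{len(positions)} "
            f"for {transcript.transcript_id}"
        )
    return positions[c_pos - 1]


def codon_locus(
    transcript: TranscriptModel,
    assembly: GenomeAssembly,
    residue_index: int,
    code: GeneticCode = STANDARD_CODE,
) -> CodonLocus:
    """Genomic anatomy of one codon: its three genomic positions (codon
    reading order) and the reference codon on the coding strand."""
    n_residues = transcript.cds_length // 3
    if not (1 <= residue_index <= n_residues):
        raise CoordinateError(
            f"residue {residue_index} out of range 1..{n_residues} "
            f"for {transcript.transcript_id}"
        )
    c_positions = (3 * residue_index - 2, 3 * residue_index - 1, 3 * residue_index)
    g_positions = tuple(cds_to_genomic(transcript, c) for c in c_positions)
    bases = [
        get_genomic_sequence(assembly, transcript.chrom, g, g) for g in g_positions
    ]
    codon = "".join(bases)
    if transcript.strand == "-":
        codon = "".join(reverse_complement(b) for b in bases)
    return CodonLocus(
        transcript_id=transcript.transcript_id,
        chrom=transcript.chrom,
        strand=transcript.strand,
        residue_index=residue_index,
        codon_genomic_positions=g_positions,
        ref_codon=codon,
    )


def exon_info(transcript: TranscriptModel) -> list[ExonRecord]:
    """Per-exon report in transcript orientation (ordinal 1 = 5'-most exon)."""
    exons = list(transcript.exons)
    if transcript.strand == "-":
        exons.reverse()
    records = []
    for i, (s, e) in enumerate(exons, start=1):
        lo, hi = max(s, transcript.cds_start_g), min(e, transcript.cds_end_g)
        coding = hi - lo + 1 if lo <= hi else 0
        records.append(
            ExonRecord(
                ordinal=i, start_g=s, end_g=e, length=e - s + 1, coding_bases=coding
            )
        )
    return records
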