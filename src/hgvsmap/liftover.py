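"""Assembly liftover over UCSC chain files.

Chain files use 0-based half-open coordinates, and minus-strand query
coordinates count from the reversed sequence — both per UCSC convention.
That double convention stays entirely inside this module: the public API
speaks 1-based plus-strand positions only.

Here the chain's *target* (t) side is the source assembly being lifted
from and the *query* (q) side is the destination, matching how UCSC names
its ``<from>To<To>.over.chain`` files.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass

from .errors import ChainIntegrityError, ChainParseError, ReferenceMismatchError
from .reference_model import GenomeAssembly, get_genomic_sequence, reverse_complement
from .variant_convert import GenomicVariant


@dataclass(frozen=True)
class ChainSegment:
    source_start: int  # 0-based, source (t) assembly
    target_start: int  # 0-based, in q-strand orientation
    length: int


@dataclass(frozen=True)
class ChainBlock:
    chain_id: int
    score: int
    source_chrom: str
    source_size: int
    source_strand: str  # always '+'
    source_start: int
    source_end: int
    target_chrom: str
    target_size: int
    target_strand: str  # '+' or '-'
    target_start: int
    target_end: int
    segments: tuple[ChainSegment, ...]


@dataclass(frozen=True)
class ChainSet:
    blocks: tuple[ChainBlock, ...]
    source_assembly: str = ""
    target_assembly: str = ""


@dataclass(frozen=True)
class LiftedPosition:
    chrom: str
    pos: int  # 1-based plus strand
    strand: str  # strand of the aligned target block
    chain_id: int
    n_alternatives: int  # how many chains could have mapped this position


@dataclass(frozen=True)
class Unmapped:
    reason: str  # 'gap' | 'no-chain'
    detail: str = ""


@dataclass(frozen=True)
class ReferenceChanged:
    """The position lifts but the target assembly holds a different base."""

    lifted: LiftedPosition
    expected: str
    observed: str


def parse_chain(
    path: str, source_assembly: str = "", target_assembly: str = ""
) -> ChainSet:
    """Parse a UCSC chain file (plain or gzipped).

    Cumulative size/dt/dq arithmetic is re-verified against the header
    spans; a mismatch raises a chain-integrity error.
    """
    opener = gzip.open if path.endswith(".gz") else open
    blocks: list[ChainBlock] = []
    seen_ids: set[int] = set()
    with opener(path, "rt") as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        parts = line.split()
        if parts[0] != "chain" or len(parts) != 13:
            raise ChainParseError(f"{path}:{i + 1}: malformed chain header {line!r}")
        try:
            score = int(parts[1])
            t_name, t_size = parts[2], int(parts[3])
            t_strand = parts[4]
            t_start, t_end = int(parts[5]), int(parts[6])
            q_name, q_size = parts[7], int(parts[8])
            q_strand = parts[9]
            q_start, q_end = int(parts[10]), int(parts[11])
            chain_id = int(parts[12])
        except ValueError as exc:
            raise ChainParseError(f"{path}:{i + 1}: {exc}") from None
        if t_strand != "+":
            raise ChainParseError(
                f"{path}:{i + 1}: source strand must be '+', got {t_strand!r}"
            )
        if chain_id in seen_ids:
            raise ChainParseError(f"{path}:{i + 1}: duplicate chain id {chain_id}")
        seen_ids.add(chain_id)
        i += 1
        segments: list[ChainSegment] = []
        t_pos, q_pos = t_start, q_start
        while i < len(lines):
            row = lines[i].strip()
            i += 1
            if not row:
                break
            nums = row.split()
            if len(nums) not in (1, 3):
                raise ChainParseError(f"{path}:{i}: bad alignment row {row!r}")
            size = int(nums[0])
            segments.append(ChainSegment(t_pos, q_pos, size))
            if len(nums) == 3:
                t_pos += size + int(nums[1])
                q_pos += size + int(nums[2])
            else:
                t_pos += size
                q_pos += size
                break
        if t_pos != t_end or q_pos != q_end:
            raise ChainIntegrityError(
                f"{path}: chain {chain_id}: cumulative sizes reach "
                f"({t_pos},{q_pos}), header declares ({t_end},{q_end})"
            )
        if t_end > t_size or q_end > q_size:
            raise ChainIntegrityError(
                f"{path}: chain {chain_id}: span exceeds chromosome size"
            )
        blocks.append(
            ChainBlock(
                chain_id=chain_id,
                score=score,
                source_chrom=t_name,
                source_size=t_size,
                source_strand=t_strand,
                source_start=t_start,
                source_end=t_end,
                target_chrom=q_name,
                target_size=q_size,
                target_strand=q_strand,
                target_start=q_start,
                target_end=q_end,
                segments=tuple(segments),
            )
        )
    return ChainSet(
        blocks=tuple(blocks),
        source_assembly=source_assembly,
        target_assembly=target_assembly,
    )


def write_chain(chains: ChainSet, path: str) -> None:
    """Serialize back to UCSC chain format (round-trips with parse_chain)."""
    with open(path, "w") as fh:
        for b in chains.blocks:
            fh.write(
                f"chain {b.score} {b.source_chrom} {b.source_size} "
                f"{b.source_strand} {b.source_start} {b.source_end} "
                f"{b.target_chrom} {b.target_size} {b.target_strand} "
                f"{b.target_start} {b.target_end} {b.chain_id}\n"
            )
            segs = b.segments
            for j, seg in enumerate(segs):
                if j + 1 < len(segs):
                    dt = segs[j + 1].source_start - (seg.source_start + seg.length)
                    dq = segs[j + 1].target_start - (seg.target_start + seg.length)
                    fh.write(f"{seg.length} {dt} {dq}\n")
                else:
                    fh.write(f"{seg.length}\n")
            fh.write("\n")


def lift_position(
    chains: ChainSet, chrom: str, pos: int
) -> LiftedPosition | Unmapped:
    """Lift one 1-based position to the target assembly.

    When several chains cover the position the highest score wins (equal
    scores break to the lowest chain id); the number of alternatives is
    reported.  Positions inside an alignment gap or outside every chain
    return a typed unmapped result.
    """
    p0 = pos - 1
    hits: list[tuple[ChainBlock, ChainSegment]] = []
    in_gap = False
    for block in chains.blocks:
        if block.source_chrom != chrom:
            continue
        if not (block.source_start <= p0 < block.source_end):
            continue
        seg_hit = None
        for seg in block.segments:
            if seg.source_start <= p0 < seg.source_start + seg.length:
                seg_hit = seg
                break
        if seg_hit is None:
            in_gap = True
        else:
            hits.append((block, seg_hit))
    if not hits:
        if in_gap:
            return Unmapped("gap", f"{chrom}:{pos} falls in an alignment gap")
        return Unmapped("no-chain", f"{chrom}:{pos} not covered by any chain")
    hits.sort(key=lambda h: (-h[0].score, h[0].chain_id))
    block, seg = hits[0]
    q0 = seg.target_start + (p0 - seg.source_start)
    if block.target_strand == "-":
        plus0 = block.target_size - 1 - q0
    else:
        plus0 = q0
    return LiftedPosition(
        chrom=block.target_chrom,
        pos=plus0 + 1,
        strand=block.target_strand,
        chain_id=block.chain_id,
        n_alternatives=len(hits),
    )


def lift_variant(
    chains: ChainSet,
    source: GenomeAssembly,
    target: GenomeAssembly,
    variant: GenomicVariant,
) -> GenomicVariant | Unmapped | ReferenceChanged:
    """Lift a variant, complementing alleles across strand flips and
    re-validating the ref allele against the target assembly."""
    observed = get_genomic_sequence(source, variant.chrom, variant.pos, variant.pos)
    if observed != variant.ref:
        raise ReferenceMismatchError(
            f"{variant.chrom}:{variant.pos}: expected ref {variant.ref!r}, "
            f"source assembly has {observed!r}",
            expected=variant.ref,
            observed=observed,
        )
    lifted = lift_position(chains, variant.chrom, variant.pos)
    if isinstance(lifted, Unmapped):
        return lifted
    ref, alt = variant.ref, variant.alt
    if lifted.strand == "-":
        ref, alt = reverse_complement(ref), reverse_complement(alt)
    target_base = get_genomic_sequence(target, lifted.chrom, lifted.pos, lifted.pos)
    if target_base != ref:
        return ReferenceChanged(lifted=lifted, expected=ref, observed=target_base)
    return GenomicVariant(
        assembly=target.name, chrom=lifted.chrom, pos=lifted.pos, ref=ref, alt=alt
    )
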