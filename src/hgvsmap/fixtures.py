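"""Deterministic synthetic reference data for fully offline testing.

Everything here is a pure function of (seed, parameters): a toy genome
with strand-mixed multi-exon genes, UCSC chain files with a matching
truth table, and a small synthetic snapshot that pins a BRAF-like gene to
its real GRCh38 neighborhood so the classic V600E worked example runs
without any download.

The generators write the same FASTA/GFF3/TSV/chain formats the production
readers consume; production code never imports this module's oracles.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from Bio.Seq import Seq

from .errors import GenerationError
from .liftover import ChainBlock, ChainSegment, ChainSet, write_chain
from .reference_model import (
    GeneSymbolTable,
    GenomeAssembly,
    STANDARD_CODE,
    TranscriptModel,
    reverse_complement,
    write_fasta,
    write_transcripts_tsv,
)

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_SENSE_CODONS = {
    aa: codons for aa, codons in STANDARD_CODE.aa_to_codons.items() if aa != "*"
}
_STOPS = STANDARD_CODE.aa_to_codons["*"]


def _random_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


@dataclass
class ToyReference:
    assembly: GenomeAssembly
    transcripts: list[TranscriptModel]
    symbols: GeneSymbolTable
    proteins: dict[str, str]  # transcript_id -> designed protein (truth)


def _reverse_translate(rng: random.Random, protein: str) -> str:
    codons = [rng.choice(_SENSE_CODONS[aa]) for aa in protein]
    codons.append(rng.choice(_STOPS))
    return "".join(codons)


def make_toy_reference(
    seed: int,
    n_chroms: int = 2,
    n_genes: int = 8,
    minus_fraction: float = 0.5,
    exon_range: tuple[int, int] = (1, 4),
    protein_length: tuple[int, int] = (12, 40),
    outdir: str | None = None,
) -> ToyReference:
    """Generate a toy genome with annotated genes on both strands.

    Each gene gets a designed protein (no internal stops by construction),
    a CDS reverse-translated from it, short UTRs, and 1-4 exons; roughly
    ``minus_fraction`` of genes land on the minus strand.  One transcript
    per gene carries the MANE flag; some genes get a second, unflagged
    transcript with identical structure to exercise transcript selection.

    With ``outdir`` set, writes ``genome.fa``, ``transcripts.tsv``,
    ``transcripts.gff3`` and ``symbols.tsv``.
    """
    if exon_range[0] < 1 or exon_range[1] < exon_range[0]:
        raise GenerationError(f"bad exon_range {exon_range}")
    if protein_length[0] < 2:
        raise GenerationError("proteins must have at least 2 residues")
    rng = random.Random(seed)
    chrom_parts: dict[str, list[str]] = {
        f"chr{i + 1}": [_random_dna(rng, rng.randint(15, 30))]
        for i in range(n_chroms)
    }
    chrom_len: dict[str, int] = {
        c: len(parts[0]) for c, parts in chrom_parts.items()
    }
    transcripts: list[TranscriptModel] = []
    proteins: dict[str, str] = {}
    approved: set[str] = set()
    alias: dict[str, list[str]] = {}
    previous: dict[str, list[str]] = {}

    for g in range(n_genes):
        gene = f"GENE{g + 1}"
        chrom = f"chr{(g % n_chroms) + 1}"
        strand = "-" if rng.random() < minus_fraction else "+"
        plen = rng.randint(*protein_length)
        protein = "M" + "".join(
            rng.choice(_AA20) for _ in range(plen - 1)
        )
        cds = _reverse_translate(rng, protein)
        utr5 = _random_dna(rng, rng.randint(0, 8))
        utr3 = _random_dna(rng, rng.randint(0, 8))
        mrna = utr5 + cds + utr3

        n_exons = rng.randint(*exon_range)
        n_exons = min(n_exons, len(mrna))
        cuts = sorted(rng.sample(range(1, len(mrna)), n_exons - 1))
        bounds = [0, *cuts, len(mrna)]
        exon_lens = [bounds[i + 1] - bounds[i] for i in range(n_exons)]
        intron_lens = [rng.randint(10, 30) for _ in range(n_exons - 1)]

        # region string in coding orientation, then exon offsets within it
        region_parts: list[str] = []
        exon_offsets: list[tuple[int, int]] = []  # 0-based [start, end] coding
        off = 0
        for i, elen in enumerate(exon_lens):
            exon_offsets.append((off, off + elen - 1))
            region_parts.append(mrna[bounds[i] : bounds[i + 1]])
            off += elen
            if i < n_exons - 1:
                region_parts.append(_random_dna(rng, intron_lens[i]))
                off += intron_lens[i]
        region = "".join(region_parts)
        cds_off = (len(utr5), len(utr5) + len(cds) - 1)  # mrna coords
        # mrna offset -> region offset (coding orientation)
        def mrna_to_region(m: int) -> int:
            for i, elen in enumerate(exon_lens):
                if m < bounds[i + 1]:
                    return exon_offsets[i][0] + (m - bounds[i])
            raise AssertionError
        cds_region = (mrna_to_region(cds_off[0]), mrna_to_region(cds_off[1]))

        start_g = chrom_len[chrom] + 1  # 1-based genomic start of region
        if strand == "+":
            genomic_region = region
            exons = [
                (start_g + a, start_g + b) for a, b in exon_offsets
            ]
            cds_start_g = start_g + cds_region[0]
            cds_end_g = start_g + cds_region[1]
        else:
            genomic_region = reverse_complement(region)
            n = len(region)
            exons = sorted(
                (start_g + (n - 1 - b), start_g + (n - 1 - a))
                for a, b in exon_offsets
            )
            cds_start_g = start_g + (n - 1 - cds_region[1])
            cds_end_g = start_g + (n - 1 - cds_region[0])

        chrom_parts[chrom].append(genomic_region)
        chrom_parts[chrom].append(_random_dna(rng, rng.randint(20, 50)))
        chrom_len[chrom] += len(genomic_region) + len(chrom_parts[chrom][-1])

        tid = f"TX{g + 1:03d}.1"
        tx = TranscriptModel(
            transcript_id=tid,
            gene_symbol=gene,
            assembly="toy1",
            chrom=chrom,
            strand=strand,
            exons=exons,
            cds_start_g=cds_start_g,
            cds_end_g=cds_end_g,
            is_mane=True,
        )
        transcripts.append(tx)
        proteins[tid] = protein
        if rng.random() < 0.3:  # unflagged sibling to exercise selection
            sib = TranscriptModel(
                transcript_id=f"TX{g + 1:03d}.2",
                gene_symbol=gene,
                assembly="toy1",
                chrom=chrom,
                strand=strand,
                exons=exons,
                cds_start_g=cds_start_g,
                cds_end_g=cds_end_g,
                is_mane=False,
            )
            transcripts.append(sib)
            proteins[sib.transcript_id] = protein

        approved.add(gene)
        alias[f"ALS{g + 1}"] = [gene]
        previous[f"OLD{g + 1}"] = [gene]

    assembly = GenomeAssembly(
        name="toy1",
        sequences={c: "".join(parts) for c, parts in chrom_parts.items()},
    )
    symbols = GeneSymbolTable(
        approved=approved, alias_to_approved=alias, previous_to_approved=previous
    )

    # generator self-check: every designed protein must round-trip
    for tx in transcripts:
        assert tx.cds_length == 3 * (len(proteins[tx.transcript_id]) + 1)

    if outdir is not None:
        write_fasta(assembly, f"{outdir}/genome.fa")
        write_transcripts_tsv(transcripts, f"{outdir}/transcripts.tsv")
        _write_gff3(transcripts, f"{outdir}/transcripts.gff3")
        _write_symbols_tsv(symbols, f"{outdir}/symbols.tsv")
    return ToyReference(assembly, transcripts, symbols, proteins)


def _write_gff3(transcripts: list[TranscriptModel], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if transcripts:
            fh.write(f"##genome-build local {transcripts[0].assembly}\n")
        genes: dict[str, list[TranscriptModel]] = {}
        for t in transcripts:
            genes.setdefault(t.gene_symbol, []).append(t)
        for gene, txs in genes.items():
            lo = min(t.span[0] for t in txs)
            hi = max(t.span[1] for t in txs)
            t0 = txs[0]
            fh.write(
                f"{t0.chrom}\thgvsmap\tgene\t{lo}\t{hi}\t.\t{t0.strand}\t.\t"
                f"ID=gene-{gene};Name={gene}\n"
            )
            for t in txs:
                attrs = f"ID={t.transcript_id};Parent=gene-{gene};gene={gene}"
                if t.is_mane:
                    attrs += ";tag=MANE_Select"
                fh.write(
                    f"{t.chrom}\thgvsmap\tmRNA\t{t.span[0]}\t{t.span[1]}\t.\t"
                    f"{t.strand}\t.\t{attrs}\n"
                )
                for i, (s, e) in enumerate(t.exons, start=1):
                    fh.write(
                        f"{t.chrom}\thgvsmap\texon\t{s}\t{e}\t.\t{t.strand}\t.\t"
                        f"ID={t.transcript_id}.exon{i};Parent={t.transcript_id}\n"
                    )
                for i, (s, e) in enumerate(t.exons, start=1):
                    lo_c = max(s, t.cds_start_g)
                    hi_c = min(e, t.cds_end_g)
                    if lo_c <= hi_c:
                        fh.write(
                            f"{t.chrom}\thgvsmap\tCDS\t{lo_c}\t{hi_c}\t.\t"
                            f"{t.strand}\t0\tID={t.transcript_id}.cds;"
                            f"Parent={t.transcript_id}\n"
                        )


def _write_symbols_tsv(symbols: GeneSymbolTable, path: str) -> None:
    rows: dict[str, tuple[list[str], list[str]]] = {
        a: ([], []) for a in sorted(symbols.approved)
    }
    for syn, targets in symbols.alias_to_approved.items():
        for t in targets:
            rows[t][0].append(syn)
    for syn, targets in symbols.previous_to_approved.items():
        for t in targets:
            rows[t][1].append(syn)
    with open(path, "w") as fh:
        fh.write("approved_symbol\talias_symbols\tprevious_symbols\n")
        for approved, (als, prevs) in rows.items():
            fh.write(
                f"{approved}\t{'|'.join(sorted(als))}\t{'|'.join(sorted(prevs))}\n"
            )


# ---------------------------------------------------------------------------
# chain fixtures
# ---------------------------------------------------------------------------

@dataclass
class ToyChain:
    target_assembly: GenomeAssembly
    chains: ChainSet
    inverse_chains: ChainSet
    truth: dict[tuple[str, int], tuple]  # (chrom, pos) -> mapping or unmapped


def make_toy_chain(
    seed: int,
    assembly: GenomeAssembly,
    ops: list[dict],
    outdir: str | None = None,
) -> ToyChain:
    """Build a target assembly by editing the source, plus the chain pair.

    ``ops`` entries (1-based inclusive coordinates on the source):

    - ``{"kind": "offset", "chrom": c, "amount": n}`` — prepend ``n``
      novel bases to the target chromosome (uniform +n shift).
    - ``{"kind": "gap", "chrom": c, "start": s, "length": L}`` — delete
      ``L`` source bases starting at ``s`` (they become unmapped).
    - ``{"kind": "inversion", "chrom": c, "start": s, "end": e}`` —
      reverse-complement the segment in the target.

    Returns the target assembly, the source→target chains, the exact
    inverse chains, and a per-position truth table
    ``("mapped", chrom, pos, strand)`` / ``("unmapped", reason)`` used as
    an independent oracle by the tests.
    """
    rng = random.Random(seed)
    by_chrom: dict[str, list[dict]] = {}
    for op in ops:
        by_chrom.setdefault(op["chrom"], []).append(op)

    target_seqs: dict[str, str] = {}
    fwd_blocks: list[ChainBlock] = []
    inv_blocks: list[ChainBlock] = []
    truth: dict[tuple[str, int], tuple] = {}
    next_id = 1

    for chrom, src in assembly.sequences.items():
        n = len(src)
        chrom_ops = by_chrom.get(chrom, [])
        offsets = [o for o in chrom_ops if o["kind"] == "offset"]
        if len(offsets) > 1:
            raise GenerationError(f"{chrom}: at most one offset op")
        pad = offsets[0]["amount"] if offsets else 0
        region_ops = sorted(
            (o for o in chrom_ops if o["kind"] != "offset"),
            key=lambda o: o["start"],
        )
        runs: list[tuple[int, int, int, str]] = []  # (src0, tgt0, len, strand)
        gap_positions: set[int] = set()
        out = [_random_dna(rng, pad)] if pad else []
        cursor, t = 0, pad
        for op in region_ops:
            s0 = op["start"] - 1
            if op["kind"] == "gap":
                e0 = s0 + op["length"]
            elif op["kind"] == "inversion":
                e0 = op["end"]
            else:
                raise GenerationError(f"unknown op kind {op['kind']!r}")
            if s0 < cursor or e0 > n:
                raise GenerationError(
                    f"{chrom}: op at {op['start']} overlaps a previous op "
                    f"or exceeds the chromosome"
                )
            if s0 > cursor:
                runs.append((cursor, t, s0 - cursor, "+"))
                out.append(src[cursor:s0])
                t += s0 - cursor
                cursor = s0
            if op["kind"] == "gap":
                gap_positions.update(range(s0, e0))
                cursor = e0
            else:
                out.append(reverse_complement(src[s0:e0]))
                runs.append((s0, t, e0 - s0, "-"))
                t += e0 - s0
                cursor = e0
        if cursor < n:
            runs.append((cursor, t, n - cursor, "+"))
            out.append(src[cursor:])
        tgt = "".join(out)
        target_seqs[chrom] = tgt
        q_size = len(tgt)

        fwd_runs = [r for r in runs if r[3] == "+"]
        if fwd_runs:
            segs = tuple(ChainSegment(a, b, ln) for a, b, ln, _ in fwd_runs)
            fwd_blocks.append(
                ChainBlock(
                    chain_id=next_id,
                    score=sum(s.length for s in segs),
                    source_chrom=chrom,
                    source_size=n,
                    source_strand="+",
                    source_start=segs[0].source_start,
                    source_end=segs[-1].source_start + segs[-1].length,
                    target_chrom=chrom,
                    target_size=q_size,
                    target_strand="+",
                    target_start=segs[0].target_start,
                    target_end=segs[-1].target_start + segs[-1].length,
                    segments=segs,
                )
            )
            inv_segs = tuple(ChainSegment(b, a, ln) for a, b, ln, _ in fwd_runs)
            inv_blocks.append(
                ChainBlock(
                    chain_id=next_id,
                    score=sum(s.length for s in inv_segs),
                    source_chrom=chrom,
                    source_size=q_size,
                    source_strand="+",
                    source_start=inv_segs[0].source_start,
                    source_end=inv_segs[-1].source_start + inv_segs[-1].length,
                    target_chrom=chrom,
                    target_size=n,
                    target_strand="+",
                    target_start=inv_segs[0].target_start,
                    target_end=inv_segs[-1].target_start + inv_segs[-1].length,
                    segments=inv_segs,
                )
            )
            next_id += 1
        for s0, a, ln, strand in runs:
            if strand == "+":
                continue
            fwd_blocks.append(
                ChainBlock(
                    chain_id=next_id,
                    score=ln,
                    source_chrom=chrom,
                    source_size=n,
                    source_strand="+",
                    source_start=s0,
                    source_end=s0 + ln,
                    target_chrom=chrom,
                    target_size=q_size,
                    target_strand="-",
                    target_start=q_size - (a + ln),
                    target_end=q_size - a,
                    segments=(ChainSegment(s0, q_size - (a + ln), ln),),
                )
            )
            inv_blocks.append(
                ChainBlock(
                    chain_id=next_id,
                    score=ln,
                    source_chrom=chrom,
                    source_size=q_size,
                    source_strand="+",
                    source_start=a,
                    source_end=a + ln,
                    target_chrom=chrom,
                    target_size=n,
                    target_strand="-",
                    target_start=n - (s0 + ln),
                    target_end=n - s0,
                    segments=(ChainSegment(a, n - (s0 + ln), ln),),
                )
            )
            next_id += 1

        # truth table
        covered_spans = [
            (b.source_start, b.source_end)
            for b in fwd_blocks
            if b.source_chrom == chrom
        ]
        mapped: dict[int, tuple] = {}
        for s0, a, ln, strand in runs:
            for k in range(ln):
                p0 = s0 + k
                if strand == "+":
                    mapped[p0] = ("mapped", chrom, a + k + 1, "+")
                else:
                    mapped[p0] = ("mapped", chrom, a + (ln - 1 - k) + 1, "-")
        for p0 in range(n):
            if p0 in mapped:
                truth[(chrom, p0 + 1)] = mapped[p0]
            elif any(s <= p0 < e for s, e in covered_spans):
                truth[(chrom, p0 + 1)] = ("unmapped", "gap")
            else:
                truth[(chrom, p0 + 1)] = ("unmapped", "no-chain")

    src_name, tgt_name = assembly.name, f"{assembly.name}_lifted"
    target_assembly = GenomeAssembly(name=tgt_name, sequences=target_seqs)
    chains = ChainSet(tuple(fwd_blocks), src_name, tgt_name)
    inverse = ChainSet(tuple(inv_blocks), tgt_name, src_name)
    if outdir is not None:
        write_fasta(target_assembly, f"{outdir}/target.fa")
        write_chain(chains, f"{outdir}/{src_name}To{tgt_name}.chain")
        write_chain(inverse, f"{outdir}/{tgt_name}To{src_name}.chain")
    return ToyChain(target_assembly, chains, inverse, truth)


# ---------------------------------------------------------------------------
# independent translation oracle (tests only)
# ---------------------------------------------------------------------------

def oracle_translate(
    transcript: TranscriptModel, assembly: GenomeAssembly, code=None
) -> str:
    """Naive splice-and-translate via Biopython, sharing no code with the
    production path; used only as a cross-implementation check in tests."""
    seq = assembly.sequences[transcript.chrom]
    off = assembly.offset(transcript.chrom)
    parts = []
    for s, e in transcript.exons:
        lo = max(s, transcript.cds_start_g)
        hi = min(e, transcript.cds_end_g)
        if lo <= hi:
            parts.append(seq[lo - off : hi - off + 1])
    cds = "".join(parts)
    if transcript.strand == "-":
        cds = str(Seq(cds).reverse_complement())
    aa = str(Seq(cds).translate())
    if not aa.endswith("*"):
        raise ValueError(f"{transcript.transcript_id}: no terminal stop")
    return aa[:-1]


# ---------------------------------------------------------------------------
# synthetic clinical-coordinate snapshot
# ---------------------------------------------------------------------------

BRAF_V600_GENOMIC_POS = 140753336  # GRCh38 chr7, middle base of codon 600

_SNAPSHOT_CDS_END_G = BRAF_V600_GENOMIC_POS + 3 * 600 - 2  # c.1799 anchor
_SNAPSHOT_PROTEIN_LEN = 765
_SNAPSHOT_CDS_LEN = 3 * (_SNAPSHOT_PROTEIN_LEN + 1)
_SNAPSHOT_CDS_START_G = _SNAPSHOT_CDS_END_G - _SNAPSHOT_CDS_LEN + 1


@dataclass
class ClinicalSnapshot:
    assembly: GenomeAssembly
    transcripts: list[TranscriptModel]
    symbols: GeneSymbolTable


def synthetic_clinical_snapshot(seed: int = 0) -> ClinicalSnapshot:
    """A synthetic stand-in for a GRCh38 BRAF neighborhood snapshot.

    The sequence is random except for one anchored fact: the minus-strand
    BRAF-like transcript is laid out so that codon 600 is GTG (valine)
    with its middle base at chr7:140753336, the classic V600E locus.  Only
    a ~2.5 kb window around the gene is stored (region-FASTA style), so
    lookups use true GRCh38-scale coordinates without a real genome.

    The bundled symbol table carries the MET/HGFR approved/alias pair.
    """
    rng = random.Random(seed)
    protein = ["M"] + [rng.choice(_AA20) for _ in range(_SNAPSHOT_PROTEIN_LEN - 1)]
    protein[599] = "V"
    codons = [rng.choice(_SENSE_CODONS[aa]) for aa in protein]
    codons[599] = "GTG"
    codons.append(rng.choice(_STOPS))
    cds = "".join(codons)
    assert len(cds) == _SNAPSHOT_CDS_LEN

    window_start = _SNAPSHOT_CDS_START_G - 40
    window_end = _SNAPSHOT_CDS_END_G + 40
    left = _random_dna(rng, _SNAPSHOT_CDS_START_G - window_start)
    right = _random_dna(rng, window_end - _SNAPSHOT_CDS_END_G)
    window = left + reverse_complement(cds) + right

    assembly = GenomeAssembly(
        name="GRCh38",
        sequences={"chr7": window},
        offsets={"chr7": window_start},
    )
    transcript = TranscriptModel(
        transcript_id="SYNTH-BRAF-001",
        gene_symbol="BRAF",
        assembly="GRCh38",
        chrom="chr7",
        strand="-",
        exons=[(_SNAPSHOT_CDS_START_G, _SNAPSHOT_CDS_END_G)],
        cds_start_g=_SNAPSHOT_CDS_START_G,
        cds_end_g=_SNAPSHOT_CDS_END_G,
        is_mane=True,
    )
    symbols = GeneSymbolTable(
        approved={"BRAF", "MET", "EGFR"},
        alias_to_approved={"HGFR": ["MET"], "ERBB1": ["EGFR"]},
        previous_to_approved={"BRAF1": ["BRAF"]},
    )
    return ClinicalSnapshot(assembly, [transcript], symbols)
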