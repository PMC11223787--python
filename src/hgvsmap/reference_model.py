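"""Local reference snapshots: genome, transcripts, gene symbols, genetic code.

Everything operates on plain files (FASTA, GFF3, TSV) so the toolbox runs
fully offline.  All genomic coordinates in the public data model are
1-based inclusive; GFF3 is already 1-based inclusive and chain files are
converted at the liftover boundary.

A FASTA record whose header looks like ``chr7:140752800-140755334`` (the
``samtools faidx`` region convention) is treated as a *window* onto the
named chromosome when loaded with ``region_headers=True``: stored bases
start at the given 1-based position, and all lookups still use absolute
chromosome coordinates.  This lets a snapshot carry only the neighborhood
of a gene instead of a whole chromosome.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

from .errors import (
    AlphabetError,
    AmbiguousReferenceError,
    CoordinateError,
    FileLoadError,
    TranslationError,
    UnknownChromosomeError,
    UnknownGeneError,
    ValidationError,
)

DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_REGION_RE = re.compile(r"^(\S+):(\d+)-(\d+)$")


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

@dataclass
class GenomeAssembly:
    """A named set of chromosome sequences (possibly windowed).

    ``offsets[chrom]`` is the absolute 1-based position of the first stored
    base; it defaults to 1 (whole chromosome stored).
    """

    name: str
    sequences: dict[str, str]
    offsets: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, seq in self.sequences.items():
            if not seq:
                raise ValidationError(f"chromosome {chrom!r} has empty sequence")
            bad = set(seq) - DNA_ALPHABET
            if bad:
                off = next(i for i, c in enumerate(seq) if c in bad)
                raise AlphabetError(
                    f"chromosome {chrom!r}: non-IUPAC character "
                    f"{seq[off]!r} at offset {off}"
                )

    def offset(self, chrom: str) -> int:
        return self.offsets.get(chrom, 1)

    def chrom_end(self, chrom: str) -> int:
        """Absolute 1-based position of the last stored base."""
        return self.offset(chrom) + len(self.sequences[chrom]) - 1


@dataclass
class TranscriptModel:
    """Exon/CDS structure of one transcript on one assembly.

    ``exons`` are 1-based inclusive genomic intervals, ascending by start,
    non-overlapping.  ``cds_start_g``/``cds_end_g`` are the genomic
    positions of the first and last coding base in *genomic* order
    (``cds_start_g <= cds_end_g`` regardless of strand).
    """

    transcript_id: str
    gene_symbol: str
    assembly: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start_g: int
    cds_end_g: int
    is_mane: bool = False

    def __post_init__(self) -> None:
        tid = self.transcript_id
        if self.strand not in "+-":
            raise ValidationError(f"{tid}: strand must be '+' or '-'")
        if not self.exons:
            raise ValidationError(f"{tid}: transcript has no exons")
        prev_end = 0
        for start, end in self.exons:
            if start > end:
                raise ValidationError(f"{tid}: exon {start}-{end} inverted")
            if start <= prev_end:
                raise ValidationError(
                    f"{tid}: exons overlap or are unsorted at {start}-{end}"
                )
            prev_end = end
        if self.cds_start_g > self.cds_end_g:
            raise ValidationError(f"{tid}: cds_start_g > cds_end_g")
        for pos in (self.cds_start_g, self.cds_end_g):
            if not any(s <= pos <= e for s, e in self.exons):
                raise ValidationError(f"{tid}: CDS bound {pos} not inside an exon")
        if self.cds_length % 3 != 0:
            raise ValidationError(
                f"{tid}: CDS length {self.cds_length} is not a multiple of 3"
            )
        if self.cds_length <= 0:
            raise ValidationError(f"{tid}: empty CDS")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        total = 0
        for s, e in self.exons:
            lo, hi = max(s, self.cds_start_g), min(e, self.cds_end_g)
            if lo <= hi:
                total += hi - lo + 1
        return total


@dataclass
class GeneSymbolTable:
    """Approved / alias / previous gene symbols.

    Alias and previous maps hold lists because a synonym may point at more
    than one approved gene; matching is case-insensitive, output preserves
    the table's case.
    """

    approved: set[str]
    alias_to_approved: dict[str, list[str]]
    previous_to_approved: dict[str, list[str]]

    def __post_init__(self) -> None:
        self._approved_ci = {s.upper(): s for s in self.approved}
        self._alias_ci = {k.upper(): v for k, v in self.alias_to_approved.items()}
        self._previous_ci = {k.upper(): v for k, v in self.previous_to_approved.items()}

    def lookup_approved(self, symbol: str) -> str | None:
        return self._approved_ci.get(symbol.upper())

    def lookup_alias(self, symbol: str) -> list[str]:
        return self._alias_ci.get(symbol.upper(), [])

    def lookup_previous(self, symbol: str) -> list[str]:
        return self._previous_ci.get(symbol.upper(), [])


class GeneticCode:
    """The standard genetic code: 61 sense codons, 3 stops ('*')."""

    def __init__(self) -> None:
        table = CodonTable.unambiguous_dna_by_id[1]
        self.codon_to_aa: dict[str, str] = dict(table.forward_table)
        for stop in table.stop_codons:
            self.codon_to_aa[stop] = "*"
        assert len(self.codon_to_aa) == 64
        self.aa_to_codons: dict[str, list[str]] = {}
        for codon, aa in sorted(self.codon_to_aa.items()):
            self.aa_to_codons.setdefault(aa, []).append(codon)

    def translate(self, cds: str) -> str:
        """Translate a nucleotide string codon-by-codon (no stop handling)."""
        if len(cds) % 3:
            raise TranslationError(f"sequence length {len(cds)} not a multiple of 3")
        out = []
        for i in range(0, len(cds), 3):
            codon = cds[i : i + 3]
            if "N" in codon:
                raise AmbiguousReferenceError(
                    f"ambiguous base in codon {codon!r} at nt {i + 1}"
                )
            out.append(self.codon_to_aa[codon])
        return "".join(out)


STANDARD_CODE = GeneticCode()


# ---------------------------------------------------------------------------
# sequence operations
# ---------------------------------------------------------------------------

def reverse_complement(seq: str) -> str:
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise AlphabetError(f"invalid character(s) {sorted(bad)!r} in sequence")
    return seq.translate(_COMPLEMENT)[::-1]


def get_genomic_sequence(
    assembly: GenomeAssembly, chrom: str, start: int, end: int, strand: str = "+"
) -> str:
    """Plus-strand bases ``start..end`` (1-based inclusive); reverse
    complement when ``strand`` is ``'-'``."""
    if chrom not in assembly.sequences:
        raise UnknownChromosomeError(f"chromosome {chrom!r} not in {assembly.name}")
    off = assembly.offset(chrom)
    if not (off <= start <= end <= assembly.chrom_end(chrom)):
        raise CoordinateError(
            f"{chrom}:{start}-{end} outside stored range "
            f"{off}-{assembly.chrom_end(chrom)}"
        )
    sub = assembly.sequences[chrom][start - off : end - off + 1]
    return reverse_complement(sub) if strand == "-" else sub


def spliced_cds(transcript: TranscriptModel, assembly: GenomeAssembly) -> str:
    """The coding sequence in coding-strand orientation."""
    parts = []
    for s, e in transcript.exons:
        lo = max(s, transcript.cds_start_g)
        hi = min(e, transcript.cds_end_g)
        if lo <= hi:
            parts.append(get_genomic_sequence(assembly, transcript.chrom, lo, hi))
    cds = "".join(parts)
    return reverse_complement(cds) if transcript.strand == "-" else cds


def get_protein_sequence(
    transcript: TranscriptModel,
    assembly: GenomeAssembly,
    code: GeneticCode = STANDARD_CODE,
) -> str:
    """Translate the spliced CDS; the terminal stop is dropped.

    An internal stop codon raises a :class:`TranslationError` naming the
    offending residue index.
    """
    aa = code.translate(spliced_cds(transcript, assembly))
    if aa[-1] != "*":
        raise TranslationError(
            f"{transcript.transcript_id}: CDS does not end in a stop codon"
        )
    body = aa[:-1]
    if "*" in body:
        idx = body.index("*") + 1
        raise TranslationError(
            f"{transcript.transcript_id}: internal stop codon at residue {idx}"
        )
    return body


@dataclass(frozen=True)
class TranscriptChoice:
    transcript: TranscriptModel
    rule: str  # "mane" | "longest-cds" | "only"


def select_transcript(
    gene_symbol: str, transcripts: list[TranscriptModel]
) -> TranscriptChoice:
    """Pick the annotation substrate for a gene.

    The MANE-flagged transcript wins; with no flag, the longest CDS; ties
    break to the lexicographically smallest transcript id.
    """
    mine = [t for t in transcripts if t.gene_symbol.upper() == gene_symbol.upper()]
    if not mine:
        raise UnknownGeneError(f"no transcripts for gene {gene_symbol!r}")
    mane = [t for t in mine if t.is_mane]
    if mane:
        best = min(mane, key=lambda t: t.transcript_id)
        return TranscriptChoice(best, "mane")
    if len(mine) == 1:
        return TranscriptChoice(mine[0], "only")
    best = min(mine, key=lambda t: (-t.cds_length, t.transcript_id))
    return TranscriptChoice(best, "longest-cds")


# ---------------------------------------------------------------------------
# file loaders / writers
# ---------------------------------------------------------------------------

def load_fasta(path: str, region_headers: bool = False) -> GenomeAssembly:
    """Load a FASTA snapshot into memory.

    Headers must be unique; sequences are uppercased and checked against
    the {A,C,G,T,N} alphabet.  With ``region_headers=True``, headers of the
    form ``name:start-end`` become windows at the stated absolute offset.
    """
    sequences: dict[str, str] = {}
    offsets: dict[str, int] = {}
    for record in SeqIO.parse(path, "fasta"):
        name = record.id
        start = 1
        if region_headers:
            m = _REGION_RE.match(name)
            if m:
                name = m.group(1)
                start = int(m.group(2))
        if name in sequences:
            raise FileLoadError(f"duplicate FASTA header {name!r} in {path}")
        seq = str(record.seq).upper()
        bad = set(seq) - DNA_ALPHABET
        if bad:
            off = next(i for i, c in enumerate(seq) if c in bad)
            raise FileLoadError(
                f"{path}: record {name!r} has non-IUPAC character "
                f"{seq[off]!r} at offset {off}"
            )
        sequences[name] = seq
        if start != 1:
            offsets[name] = start
    if not sequences:
        raise FileLoadError(f"{path}: no FASTA records found")
    name = re.sub(r"\.(fa|fasta|fna)$", "", path.rsplit("/", 1)[-1])
    return GenomeAssembly(name=name, sequences=sequences, offsets=offsets)


def write_fasta(assembly: GenomeAssembly, path: str, width: int = 60) -> None:
    """Write all records at fixed column width (region headers preserved)."""
    with open(path, "w") as fh:
        for chrom, seq in assembly.sequences.items():
            header = chrom
            off = assembly.offset(chrom)
            if off != 1:
                header = f"{chrom}:{off}-{assembly.chrom_end(chrom)}"
            fh.write(f">{header}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


TRANSCRIPT_TSV_COLUMNS = [
    "transcript_id",
    "gene",
    "assembly",
    "chrom",
    "strand",
    "exon_starts",
    "exon_ends",
    "cds_start",
    "cds_end",
    "mane",
]


def load_transcripts(
    path: str, format: str = "tsv", assembly: str | None = None
) -> list[TranscriptModel]:
    """Load transcript annotation from a TSV snapshot or a GFF3 file.

    The TSV dialect has the columns in :data:`TRANSCRIPT_TSV_COLUMNS`
    (exon lists comma-separated, ``mane`` 0/1).  GFF3 must use
    gene/mRNA/exon/CDS features linked by ID/Parent; an mRNA carrying
    ``tag=MANE_Select`` is flagged as MANE.  CDS phase columns are ignored
    and recomputed internally.
    """
    if format == "tsv":
        return _load_transcripts_tsv(path, assembly)
    if format == "gff3":
        return _load_transcripts_gff3(path, assembly)
    raise FileLoadError(f"unknown transcript format {format!r}")


def _load_transcripts_tsv(path: str, assembly: str | None) -> list[TranscriptModel]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(TRANSCRIPT_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise FileLoadError(f"{path}: missing TSV columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        starts = [int(x) for x in str(row.exon_starts).split(",")]
        ends = [int(x) for x in str(row.exon_ends).split(",")]
        if len(starts) != len(ends):
            raise FileLoadError(
                f"{row.transcript_id}: exon_starts/exon_ends length mismatch"
            )
        out.append(
            TranscriptModel(
                transcript_id=row.transcript_id,
                gene_symbol=row.gene,
                assembly=assembly or row.assembly,
                chrom=row.chrom,
                strand=row.strand,
                exons=list(zip(starts, ends)),
                cds_start_g=int(row.cds_start),
                cds_end_g=int(row.cds_end),
                is_mane=str(row.mane) in ("1", "True", "true"),
            )
        )
    return out


def _load_transcripts_gff3(path: str, assembly: str | None) -> list[TranscriptModel]:
    import gffutils

    build = assembly
    with open(path) as fh:
        for line in fh:
            if line.startswith("##genome-build"):
                build = build or line.split()[-1]
            elif not line.startswith("#"):
                break
    db = gffutils.create_db(
        path, ":memory:", keep_order=True, merge_strategy="create_unique"
    )
    out = []
    for mrna in db.features_of_type("mRNA"):
        gene_symbol = mrna.attributes.get("gene", [None])[0]
        if gene_symbol is None:
            parents = list(db.parents(mrna, featuretype="gene"))
            if parents:
                gene_symbol = parents[0].attributes.get(
                    "Name", [parents[0].id]
                )[0]
            else:
                gene_symbol = mrna.id
        exons = sorted(
            (f.start, f.end) for f in db.children(mrna, featuretype="exon")
        )
        cds_rows = sorted(
            (f.start, f.end) for f in db.children(mrna, featuretype="CDS")
        )
        if not cds_rows:
            raise ValidationError(f"{mrna.id}: mRNA has no CDS features")
        is_mane = "MANE_Select" in mrna.attributes.get("tag", [])
        out.append(
            TranscriptModel(
                transcript_id=mrna.id,
                gene_symbol=gene_symbol,
                assembly=build or "unknown",
                chrom=mrna.seqid,
                strand=mrna.strand,
                exons=exons,
                cds_start_g=cds_rows[0][0],
                cds_end_g=cds_rows[-1][1],
                is_mane=is_mane,
            )
        )
    return out


def write_transcripts_tsv(transcripts: list[TranscriptModel], path: str) -> None:
    rows = []
    for t in transcripts:
        rows.append(
            {
                "transcript_id": t.transcript_id,
                "gene": t.gene_symbol,
                "assembly": t.assembly,
                "chrom": t.chrom,
                "strand": t.strand,
                "exon_starts": ",".join(str(s) for s, _ in t.exons),
                "exon_ends": ",".join(str(e) for _, e in t.exons),
                "cds_start": t.cds_start_g,
                "cds_end": t.cds_end_g,
                "mane": int(t.is_mane),
            }
        )
    pd.DataFrame(rows, columns=TRANSCRIPT_TSV_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def load_gene_symbols(path: str) -> GeneSymbolTable:
    """Load an HGNC-style custom-download TSV: ``approved_symbol``,
    ``alias_symbols`` and ``previous_symbols`` (pipe-separated)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    needed = {"approved_symbol", "alias_symbols", "previous_symbols"}
    if not needed <= set(df.columns):
        raise FileLoadError(f"{path}: needs columns {sorted(needed)}")
    approved: set[str] = set()
    alias: dict[str, list[str]] = {}
    previous: dict[str, list[str]] = {}
    for row in df.itertuples(index=False):
        sym = row.approved_symbol.strip()
        if not sym:
            continue
        approved.add(sym)
        for a in filter(None, (x.strip() for x in row.alias_symbols.split("|"))):
            alias.setdefault(a, [])
            if sym not in alias[a]:
                alias[a].append(sym)
        for p in filter(None, (x.strip() for x in row.previous_symbols.split("|"))):
            previous.setdefault(p, [])
            if sym not in previous[p]:
                previous[p].append(sym)
    return GeneSymbolTable(
        approved=approved, alias_to_approved=alias, previous_to_approved=previous
    )
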