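"""Batch service layer: every operation behind one JSON envelope.

Each request yields exactly one envelope::

    {"header": {"qid": <id>, "status_code": 200|400}, "data": {...}}

200 means the request was processed; any typed error becomes 400 with a
machine-readable ``data.error.kind``.  A batch never aborts on a single
bad record, and envelopes come back in input order with the caller's qids
(line numbers are assigned when absent) so inputs map one-to-one onto
outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, is_dataclass
from typing import Any, Callable

from pydantic import BaseModel, ConfigDict

from .coordinate_map import exon_info
from .errors import HgvsmapError, HgvsSyntaxError, UnknownGeneError, ValidationError
from .fusion_frame import FusionEvent, fusion_check, fused_protein
from .hgvs_grammar import (
    EditKind,
    HgvsVariant,
    UnsupportedVariant,
    apply_edit,
    format_hgvs,
    parse_hgvs,
    write_fasta_record,
)
from .liftover import ChainSet, ReferenceChanged, Unmapped, lift_position, lift_variant
from .reference_model import (
    GenomeAssembly,
    GeneSymbolTable,
    STANDARD_CODE,
    TranscriptModel,
    get_genomic_sequence,
    get_protein_sequence,
    reverse_complement,
    select_transcript,
)
from .symbols import normalize_symbol
from .variant_convert import (
    GenomicVariant,
    NoCodingConsequence,
    ProteinChange,
    dna_to_protein,
    protein_to_dna,
)


class EnvelopeHeader(BaseModel):
    model_config = ConfigDict(extra="forbid")
    qid: int | str
    status_code: int


class Envelope(BaseModel):
    """The published response contract (also serves as its JSON schema)."""

    model_config = ConfigDict(extra="forbid")
    header: EnvelopeHeader
    data: dict[str, Any]


ENVELOPE_SCHEMA: dict = Envelope.model_json_schema()


def validate_envelope(envelope: dict) -> None:
    """Raise if an envelope violates the published schema."""
    env = Envelope.model_validate(envelope)
    if env.header.status_code not in (200, 400):
        raise ValidationError(
            f"status_code must be 200 or 400, got {env.header.status_code}"
        )
    if env.header.status_code == 400 and "error" not in env.data:
        raise ValidationError("error envelopes must carry data.error")


@dataclass
class ToolboxContext:
    """Loaded snapshots shared by all endpoints."""

    assembly: GenomeAssembly | None = None
    transcripts: list[TranscriptModel] = field(default_factory=list)
    symbols: GeneSymbolTable | None = None
    chains: ChainSet | None = None
    target_assembly: GenomeAssembly | None = None


def _to_plain(obj: Any) -> Any:
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in asdict(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(x) for x in obj]
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, EditKind):
        return obj.value
    return obj


def _parse_supported(text: str) -> HgvsVariant:
    parsed = parse_hgvs(text)
    if isinstance(parsed, UnsupportedVariant):
        raise HgvsSyntaxError(
            f"{text!r}: {parsed.reason} notation is recognized but not supported"
        )
    return parsed


def _need(ctx_attr: Any, what: str) -> Any:
    if ctx_attr is None or ctx_attr == []:
        raise ValidationError(f"no {what} loaded in this context")
    return ctx_attr


def _parse_genomic_variant(ctx: ToolboxContext, payload: dict) -> GenomicVariant:
    assembly = _need(ctx.assembly, "genome")
    if "variant" in payload:
        v = _parse_supported(str(payload["variant"]))
        if v.level != "g" or v.edit_kind is not EditKind.SUBSTITUTION:
            raise ValidationError("expected a g.-level substitution")
        return GenomicVariant(
            assembly=assembly.name,
            chrom=v.reference,
            pos=v.start,
            ref=v.ref_allele,
            alt=v.alt_allele,
        )
    return GenomicVariant(
        assembly=assembly.name,
        chrom=str(payload["chrom"]),
        pos=int(payload["pos"]),
        ref=str(payload["ref"]).upper(),
        alt=str(payload["alt"]).upper(),
    )


def _ep_protein_to_dna(ctx: ToolboxContext, payload: dict) -> dict:
    assembly = _need(ctx.assembly, "genome")
    transcripts = _need(ctx.transcripts, "transcripts")
    v = _parse_supported(str(payload["hgvs"]))
    if v.level != "p" or v.edit_kind is not EditKind.SUBSTITUTION:
        raise ValidationError("protein-to-dna expects a p.-level substitution")
    gene = v.reference
    if ctx.symbols is not None:
        norm = normalize_symbol(gene, ctx.symbols)
        if norm.approved is not None:
            gene = norm.approved
    choice = select_transcript(gene, transcripts)
    change = ProteinChange(
        gene_symbol=gene,
        transcript_id=choice.transcript.transcript_id,
        residue_index=v.start,
        ref_aa=v.ref_allele,
        alt_aa=v.alt_allele,
    )
    result = protein_to_dna(change, choice.transcript, assembly)
    return {
        "input": format_hgvs(v),
        "transcript": choice.transcript.transcript_id,
        "selection_rule": choice.rule,
        "possible_exchange": [
            {
                "codon": c.codon,
                "n_changes": c.n_changes,
                "edits": [str(e) for e in c.edits],
                "is_selected": c.is_selected,
            }
            for c in result.candidates
        ],
        "mapped_position": str(result.selected_variant),
        "is_multi_nucleotide": result.is_mnv,
        "edits": _to_plain(result.selected.edits),
    }


def _ep_dna_to_protein(ctx: ToolboxContext, payload: dict) -> dict:
    assembly = _need(ctx.assembly, "genome")
    transcripts = _need(ctx.transcripts, "transcripts")
    variant = _parse_genomic_variant(ctx, payload)
    result = dna_to_protein(variant, transcripts, assembly)
    if isinstance(result, NoCodingConsequence):
        return {"input": str(variant), "coding": False, "reason": result.reason}
    return {
        "input": str(variant),
        "coding": True,
        "hgvs_p": result.hgvs_p,
        "consequence": result.consequence,
        "change": _to_plain(result.change),
        "selection_rule": result.selection_rule,
        "others": [c.hgvs_p for c in result.others],
    }


def _ep_liftover(ctx: ToolboxContext, payload: dict) -> dict:
    chains = _need(ctx.chains, "chain file")
    if "position" in payload:
        text = str(payload["position"])
        try:
            chrom, pos_s = text.rsplit(":", 1)
            pos = int(pos_s)
        except ValueError:
            raise ValidationError(f"bad position {text!r}; expected chrN:pos")
        lifted = lift_position(chains, chrom, pos)
        if isinstance(lifted, Unmapped):
            return {"mapped": False, "reason": lifted.reason}
        return {"mapped": True, **_to_plain(lifted)}
    variant = _parse_genomic_variant(ctx, payload)
    source = _need(ctx.assembly, "genome")
    target = _need(ctx.target_assembly, "target genome")
    lifted = lift_variant(chains, source, target, variant)
    if isinstance(lifted, Unmapped):
        return {"mapped": False, "reason": lifted.reason}
    if isinstance(lifted, ReferenceChanged):
        return {
            "mapped": True,
            "reference_changed": True,
            "expected": lifted.expected,
            "observed": lifted.observed,
            "position": _to_plain(lifted.lifted),
        }
    return {"mapped": True, "reference_changed": False, "variant": str(lifted)}


def _ep_normalize(ctx: ToolboxContext, payload: dict) -> dict:
    table = _need(ctx.symbols, "symbol table")
    return _to_plain(normalize_symbol(str(payload["symbol"]), table))


def _transcripts_for_gene(ctx: ToolboxContext, gene: str) -> list[TranscriptModel]:
    hits = [
        t for t in ctx.transcripts if t.gene_symbol.upper() == gene.upper()
    ]
    if not hits:
        raise UnknownGeneError(f"no transcripts for gene {gene!r}")
    return hits


def _ep_transcripts(ctx: ToolboxContext, payload: dict) -> dict:
    _need(ctx.transcripts, "transcripts")
    hits = _transcripts_for_gene(ctx, str(payload["gene"]))
    return {
        "gene": hits[0].gene_symbol,
        "transcripts": [
            {
                "transcript_id": t.transcript_id,
                "chrom": t.chrom,
                "strand": t.strand,
                "n_exons": len(t.exons),
                "cds_length": t.cds_length,
                "is_mane": t.is_mane,
            }
            for t in hits
        ],
    }


def _ep_exons(ctx: ToolboxContext, payload: dict) -> dict:
    _need(ctx.transcripts, "transcripts")
    if "transcript" in payload:
        tid = str(payload["transcript"])
        hits = [t for t in ctx.transcripts if t.transcript_id == tid]
        if not hits:
            raise UnknownGeneError(f"no transcript {tid!r}")
        t = hits[0]
    else:
        t = select_transcript(str(payload["gene"]), ctx.transcripts).transcript
    return {
        "transcript_id": t.transcript_id,
        "strand": t.strand,
        "exons": _to_plain(exon_info(t)),
    }


def _find_transcript(ctx: ToolboxContext, tid: str) -> TranscriptModel:
    hits = [t for t in ctx.transcripts if t.transcript_id == tid]
    if not hits:
        raise UnknownGeneError(f"no transcript {tid!r}")
    return hits[0]


def _ep_fusion_check(ctx: ToolboxContext, payload: dict) -> dict:
    assembly = _need(ctx.assembly, "genome")
    _need(ctx.transcripts, "transcripts")
    if "fusion" in payload:
        # "TX1:chrom:pos::TX2:chrom:pos"
        try:
            five, three = str(payload["fusion"]).split("::")
            tid5, _, pos5 = five.split(":")
            tid3, _, pos3 = three.split(":")
        except ValueError:
            raise ValidationError(
                "bad fusion string; expected TX1:chrom:pos::TX2:chrom:pos"
            )
        payload = {
            "five_transcript": tid5,
            "five_breakpoint": int(pos5),
            "three_transcript": tid3,
            "three_breakpoint": int(pos3),
        }
    event = FusionEvent(
        five_prime=_find_transcript(ctx, str(payload["five_transcript"])),
        five_breakpoint_g=int(payload["five_breakpoint"]),
        three_prime=_find_transcript(ctx, str(payload["three_transcript"])),
        three_breakpoint_g=int(payload["three_breakpoint"]),
    )
    call = fusion_check(event)
    out = _to_plain(call)
    if payload.get("translate") and call.status != "non-coding-junction":
        result = fused_protein(event, assembly)
        out["fused_protein"] = result.protein
        out["truncated_at"] = result.truncated_at
    return out


def _ep_protein_seq(ctx: ToolboxContext, payload: dict) -> dict:
    assembly = _need(ctx.assembly, "genome")
    _need(ctx.transcripts, "transcripts")
    if "transcript" in payload:
        t = _find_transcript(ctx, str(payload["transcript"]))
        rule = "explicit"
    else:
        gene = str(payload["gene"])
        if ctx.symbols is not None:
            norm = normalize_symbol(gene, ctx.symbols)
            if norm.approved is not None:
                gene = norm.approved
        choice = select_transcript(gene, ctx.transcripts)
        t, rule = choice.transcript, choice.rule
    protein = get_protein_sequence(t, assembly, STANDARD_CODE)
    out = {
        "transcript_id": t.transcript_id,
        "gene": t.gene_symbol,
        "selection_rule": rule,
        "length": len(protein),
        "sequence": protein,
    }
    if "edit" in payload:
        v = _parse_supported(str(payload["edit"]))
        if v.level != "p":
            raise ValidationError("protein edits must be p.-level")
        edited = apply_edit(protein, v)
        header = f"{t.gene_symbol}|{t.transcript_id}|{format_hgvs(v)}"
        out["edited_sequence"] = edited
        out["fasta"] = write_fasta_record(header, edited)
    return out


def _ep_genomic_seq(ctx: ToolboxContext, payload: dict) -> dict:
    assembly = _need(ctx.assembly, "genome")
    seq = get_genomic_sequence(
        assembly,
        str(payload["chrom"]),
        int(payload["start"]),
        int(payload["end"]),
        str(payload.get("strand", "+")),
    )
    return {
        "chrom": payload["chrom"],
        "start": int(payload["start"]),
        "end": int(payload["end"]),
        "strand": payload.get("strand", "+"),
        "length": len(seq),
        "sequence": seq,
    }


def _ep_revcomp(ctx: ToolboxContext, payload: dict) -> dict:
    seq = str(payload["sequence"]).upper()
    return {"sequence": seq, "reverse_complement": reverse_complement(seq)}


ENDPOINTS: dict[str, Callable[[ToolboxContext, dict], dict]] = {
    "protein_to_dna": _ep_protein_to_dna,
    "dna_to_protein": _ep_dna_to_protein,
    "liftover": _ep_liftover,
    "normalize": _ep_normalize,
    "transcripts": _ep_transcripts,
    "exons": _ep_exons,
    "fusion_check": _ep_fusion_check,
    "protein_seq": _ep_protein_seq,
    "genomic_seq": _ep_genomic_seq,
    "revcomp": _ep_revcomp,
}


def handle_request(
    ctx: ToolboxContext,
    endpoint: str,
    payload: dict,
    qid: int | str | None = None,
) -> dict:
    """Run one request and wrap the outcome in an envelope.

    Typed toolbox errors (and malformed payloads) become 400 envelopes;
    the batch caller never sees an exception from a bad record.
    """
    if qid is None:
        qid = 0
    handler = ENDPOINTS.get(endpoint)
    if handler is None:
        return _error_envelope(qid, "unknown-endpoint", f"no endpoint {endpoint!r}")
    try:
        data = handler(ctx, payload)
    except HgvsmapError as exc:
        return _error_envelope(qid, exc.kind, exc.message)
    except (KeyError, TypeError, ValueError) as exc:
        return _error_envelope(qid, "bad-payload", f"{type(exc).__name__}: {exc}")
    return {"header": {"qid": qid, "status_code": 200}, "data": data}


def _error_envelope(qid: int | str, kind: str, message: str) -> dict:
    return {
        "header": {"qid": qid, "status_code": 400},
        "data": {"error": {"kind": kind, "message": message}},
    }


def run_batch(
    ctx: ToolboxContext,
    endpoint: str,
    records: list[dict],
    qid_key: str = "qid",
) -> list[dict]:
    """One envelope per record, in input order.

    A record's ``qid`` field is passed through verbatim; records without
    one get their 1-based input line number.
    """
    out = []
    for i, record in enumerate(records, start=1):
        payload = dict(record)
        qid = payload.pop(qid_key, i)
        out.append(handle_request(ctx, endpoint, payload, qid))
    return out


def read_batch_file(path: str, fmt: str = "jsonl") -> list[dict]:
    """Read batch input as JSON-lines or TSV (header row = field names)."""
    records: list[dict] = []
    with open(path) as fh:
        if fmt == "jsonl":
            for line in fh:
                line = line.strip()
                if line:
                    records.append(json.loads(line))
        elif fmt == "tsv":
            header: list[str] | None = None
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                if header is None:
                    header = line.split("\t")
                    continue
                records.append(dict(zip(header, line.split("\t"))))
        else:
            raise ValidationError(f"unknown batch format {fmt!r}")
    return records
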