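"""A documented subset of HGVS variant nomenclature at g./c./p. level.

Supported edit kinds: substitution, deletion, insertion, deletion-insertion
(delins) and duplication.  The bare shorthand ``GENE:V600E`` (no ``p.``
prefix) is accepted and canonicalized to a p-level substitution.  Amino
acids may be written in one- or three-letter code; internally everything
is one-letter with ``*`` for the stop (``Ter`` accepted on input).

Descriptions the grammar recognizes but does not model — intronic offsets
(``c.88+2T>G``), UTR positions (``c.-5``, ``c.*12``), frameshifts
(``p.V600fs``) and repeats — parse to a typed :class:`UnsupportedVariant`
rather than being mis-parsed.  Anything else raises
:class:`~hgvsmap.errors.HgvsSyntaxError` with the failing character offset.

For p-level range notation (``p.K2_M5del``) only the boundary residues are
named in the text; they are kept in ``start_ref``/``end_ref`` and checked
against the sequence when an edit is applied.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum

from Bio.Data.IUPACData import protein_letters_1to3

from .errors import (
    CoordinateError,
    HgvsSyntaxError,
    ReferenceMismatchError,
    UnknownAminoAcidError,
    ValidationError,
)

AA1_TO_3 = {**protein_letters_1to3, "*": "Ter"}
AA3_TO_1 = {v.capitalize(): k for k, v in AA1_TO_3.items()}
AA_LETTERS = frozenset(AA1_TO_3) | {"="}  # '=' marks a synonymous alt


class EditKind(str, Enum):
    SUBSTITUTION = "substitution"
    DELETION = "deletion"
    INSERTION = "insertion"
    DELINS = "delins"
    DUPLICATION = "duplication"


@dataclass(frozen=True)
class HgvsVariant:
    """A parsed variant description in one coordinate level.

    ``ref_allele`` holds the full reference bases/residues when the text
    states them (it may legitimately be empty: canonical deletions omit
    the deleted sequence).  ``start_ref``/``end_ref`` carry the boundary
    residues of p-level range notation.
    """

    reference: str
    level: str  # 'g' | 'c' | 'p'
    edit_kind: EditKind
    start: int
    end: int
    ref_allele: str = ""
    alt_allele: str = ""
    start_ref: str = ""
    end_ref: str = ""

    def __post_init__(self) -> None:
        if self.level not in "gcp":
            raise ValidationError(f"bad level {self.level!r}")
        if self.start < 1 or self.end < self.start:
            raise ValidationError(
                f"bad position range {self.start}_{self.end}"
            )
        k = self.edit_kind
        if k is EditKind.SUBSTITUTION:
            if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
                raise ValidationError("substitution needs 1-length ref and alt")
            if self.start != self.end:
                raise ValidationError("substitution spans one position")
        elif k is EditKind.INSERTION:
            if self.end != self.start + 1:
                raise ValidationError("insertion flanks must be adjacent")
            if self.ref_allele:
                raise ValidationError("insertion has no reference allele")
            if not self.alt_allele:
                raise ValidationError("insertion needs inserted sequence")
        elif k is EditKind.DELINS and not self.alt_allele:
            raise ValidationError("delins needs inserted sequence")


@dataclass(frozen=True)
class UnsupportedVariant:
    """Recognized HGVS notation outside the supported subset."""

    text: str
    reason: str  # e.g. "intronic-offset", "frameshift", "repeat", "utr-position"


_NT = "[ACGT]"
_G_SUB = re.compile(rf"^(\d+)({_NT})>({_NT})$")
_G_DEL = re.compile(rf"^(\d+)(?:_(\d+))?del({_NT}*)$")
_G_DUP = re.compile(r"^(\d+)(?:_(\d+))?dup$")
_G_INS = re.compile(rf"^(\d+)_(\d+)ins({_NT}+)$")
_G_DELINS = re.compile(rf"^(\d+)(?:_(\d+))?delins({_NT}+)$")

_AA = r"(?:\*|Ter|[A-Z][a-z]{2}|[A-Z])"
_P_SUB = re.compile(rf"^({_AA})(\d+)({_AA}|=)$")
_P_DEL = re.compile(rf"^({_AA})(\d+)(?:_({_AA})(\d+))?del$")
_P_DUP = re.compile(rf"^({_AA})(\d+)(?:_({_AA})(\d+))?dup$")
_P_INS = re.compile(rf"^({_AA})(\d+)_({_AA})(\d+)ins((?:{_AA})+)$")
_P_DELINS = re.compile(rf"^({_AA})(\d+)(?:_({_AA})(\d+))?delins((?:{_AA})+)$")

_INTRONIC = re.compile(r"\d+[+-]\d+")
_UTR_POS = re.compile(r"^[-*]\d|_[-*]\d")
_AA3_TOKEN = re.compile(r"\*|Ter|[A-Z][a-z]{2}|[A-Z]")


def _aa1(token: str, text: str, offset: int) -> str:
    """Normalize one amino-acid token to one-letter code."""
    if token in ("*", "Ter"):
        return "*"
    if len(token) == 1:
        if token not in AA1_TO_3:
            raise UnknownAminoAcidError(f"unknown amino acid {token!r} in {text!r}")
        return token
    aa = AA3_TO_1.get(token.capitalize())
    if aa is None:
        raise UnknownAminoAcidError(f"unknown amino acid code {token!r} in {text!r}")
    return aa


def _aa_seq(tokens: str, text: str, offset: int) -> str:
    return "".join(
        _aa1(m.group(0), text, offset) for m in _AA3_TOKEN.finditer(tokens)
    )


def parse_hgvs(text: str) -> HgvsVariant | UnsupportedVariant:
    """Parse ``"<reference>:<level>.<description>"`` (or the bare
    ``GENE:V600E`` shorthand) into a normalized :class:`HgvsVariant`."""
    if ":" not in text:
        raise HgvsSyntaxError(f"missing ':' separator in {text!r}", len(text))
    reference, desc = text.split(":", 1)
    reference = reference.strip()
    desc = desc.strip()
    desc_off = text.index(":") + 1
    if not reference:
        raise HgvsSyntaxError(f"empty reference in {text!r}", 0)
    if not desc:
        raise HgvsSyntaxError(f"empty description in {text!r}", desc_off)

    if len(desc) > 2 and desc[0] in "gcp" and desc[1] == ".":
        level, body = desc[0], desc[2:]
    else:
        # bare protein shorthand: V600E / Val600Glu
        level, body = "p", desc

    if "fs" in body:
        return UnsupportedVariant(text, "frameshift")
    if "[" in body or "(" in body:
        return UnsupportedVariant(text, "repeat")
    if level in "gc":
        if _UTR_POS.search(body):
            return UnsupportedVariant(text, "utr-position")
        if _INTRONIC.search(body):
            return UnsupportedVariant(text, "intronic-offset")
        return _parse_nt(reference, level, body, text, desc_off)
    return _parse_protein(reference, body, text, desc_off)


def _parse_nt(
    reference: str, level: str, body: str, text: str, off: int
) -> HgvsVariant:
    if m := _G_SUB.match(body):
        pos = int(m.group(1))
        return HgvsVariant(
            reference, level, EditKind.SUBSTITUTION, pos, pos, m.group(2), m.group(3)
        )
    if m := _G_DELINS.match(body):
        start = int(m.group(1))
        end = int(m.group(2)) if m.group(2) else start
        return HgvsVariant(
            reference, level, EditKind.DELINS, start, end, "", m.group(3)
        )
    if m := _G_DEL.match(body):
        start = int(m.group(1))
        end = int(m.group(2)) if m.group(2) else start
        ref = m.group(3)
        if ref and len(ref) != end - start + 1:
            raise HgvsSyntaxError(
                f"deleted sequence length disagrees with range in {text!r}", off
            )
        return HgvsVariant(reference, level, EditKind.DELETION, start, end, ref, "")
    if m := _G_INS.match(body):
        start, end = int(m.group(1)), int(m.group(2))
        if end != start + 1:
            raise HgvsSyntaxError(
                f"insertion flanks must be adjacent in {text!r}", off
            )
        return HgvsVariant(
            reference, level, EditKind.INSERTION, start, end, "", m.group(3)
        )
    if m := _G_DUP.match(body):
        start = int(m.group(1))
        end = int(m.group(2)) if m.group(2) else start
        return HgvsVariant(reference, level, EditKind.DUPLICATION, start, end)
    raise HgvsSyntaxError(f"unrecognized {level}. description in {text!r}", off)


def _parse_protein(reference: str, body: str, text: str, off: int) -> HgvsVariant:
    if m := _P_SUB.match(body):
        ref = _aa1(m.group(1), text, off)
        pos = int(m.group(2))
        alt = ref if m.group(3) == "=" else _aa1(m.group(3), text, off)
        return HgvsVariant(
            reference, "p", EditKind.SUBSTITUTION, pos, pos, ref, alt
        )
    if m := _P_DELINS.match(body):
        sref, start = _aa1(m.group(1), text, off), int(m.group(2))
        if m.group(3):
            eref, end = _aa1(m.group(3), text, off), int(m.group(4))
        else:
            eref, end = sref, start
        alt = _aa_seq(m.group(5), text, off)
        full_ref = sref if start == end else ""
        return HgvsVariant(
            reference, "p", EditKind.DELINS, start, end, full_ref, alt,
            start_ref=sref, end_ref=eref,
        )
    if m := _P_DEL.match(body):
        sref, start = _aa1(m.group(1), text, off), int(m.group(2))
        if m.group(3):
            eref, end = _aa1(m.group(3), text, off), int(m.group(4))
        else:
            eref, end = sref, start
        full_ref = sref if start == end else ""
        return HgvsVariant(
            reference, "p", EditKind.DELETION, start, end, full_ref, "",
            start_ref=sref, end_ref=eref,
        )
    if m := _P_INS.match(body):
        sref, start = _aa1(m.group(1), text, off), int(m.group(2))
        eref, end = _aa1(m.group(3), text, off), int(m.group(4))
        if end != start + 1:
            raise HgvsSyntaxError(
                f"insertion flanks must be adjacent in {text!r}", off
            )
        alt = _aa_seq(m.group(5), text, off)
        return HgvsVariant(
            reference, "p", EditKind.INSERTION, start, end, "", alt,
            start_ref=sref, end_ref=eref,
        )
    if m := _P_DUP.match(body):
        sref, start = _aa1(m.group(1), text, off), int(m.group(2))
        if m.group(3):
            eref, end = _aa1(m.group(3), text, off), int(m.group(4))
        else:
            eref, end = sref, start
        full_ref = sref if start == end else ""
        return HgvsVariant(
            reference, "p", EditKind.DUPLICATION, start, end, full_ref, "",
            start_ref=sref, end_ref=eref,
        )
    raise HgvsSyntaxError(f"unrecognized p. description in {text!r}", off)


def format_hgvs(variant: HgvsVariant) -> str:
    """Canonical text for a variant (one-letter amino-acid codes)."""
    v = variant
    head = f"{v.reference}:{v.level}."
    if v.level in "gc":
        span = f"{v.start}" if v.start == v.end else f"{v.start}_{v.end}"
        if v.edit_kind is EditKind.SUBSTITUTION:
            return f"{head}{v.start}{v.ref_allele}>{v.alt_allele}"
        if v.edit_kind is EditKind.DELETION:
            return f"{head}{span}del"
        if v.edit_kind is EditKind.INSERTION:
            return f"{head}{v.start}_{v.end}ins{v.alt_allele}"
        if v.edit_kind is EditKind.DELINS:
            return f"{head}{span}delins{v.alt_allele}"
        return f"{head}{span}dup"
    sref = v.start_ref or (v.ref_allele[:1] if v.ref_allele else "")
    eref = v.end_ref or (v.ref_allele[-1:] if v.ref_allele else "")
    if v.edit_kind is EditKind.SUBSTITUTION:
        if v.ref_allele == v.alt_allele:
            return f"{head}{v.ref_allele}{v.start}="
        return f"{head}{v.ref_allele}{v.start}{v.alt_allele}"
    span = (
        f"{sref}{v.start}"
        if v.start == v.end
        else f"{sref}{v.start}_{eref}{v.end}"
    )
    if v.edit_kind is EditKind.DELETION:
        return f"{head}{span}del"
    if v.edit_kind is EditKind.INSERTION:
        return f"{head}{sref}{v.start}_{eref}{v.end}ins{v.alt_allele}"
    if v.edit_kind is EditKind.DELINS:
        return f"{head}{span}delins{v.alt_allele}"
    return f"{head}{span}dup"


def apply_edit(sequence: str, variant: HgvsVariant) -> str:
    """Apply one edit to a raw sequence string.

    The stated reference allele (or boundary residues for p-level ranges)
    is always checked against the sequence first; a mismatch raises a
    reference-assertion error instead of silently editing.
    """
    v = variant
    n = len(sequence)
    if v.edit_kind is EditKind.INSERTION:
        if not (1 <= v.start and v.end <= n):
            raise CoordinateError(
                f"insertion flanks {v.start}_{v.end} outside sequence of length {n}"
            )
    elif not (1 <= v.start and v.end <= n):
        raise CoordinateError(
            f"positions {v.start}_{v.end} outside sequence of length {n}"
        )

    observed = sequence[v.start - 1 : v.end]
    if v.edit_kind is not EditKind.INSERTION:
        if v.ref_allele and observed != v.ref_allele:
            raise ReferenceMismatchError(
                f"reference assertion failed at {v.start}: expected "
                f"{v.ref_allele!r}, observed {observed!r}",
                expected=v.ref_allele,
                observed=observed,
            )
        for pos, token in ((v.start, v.start_ref), (v.end, v.end_ref)):
            if token and sequence[pos - 1] != token:
                raise ReferenceMismatchError(
                    f"reference assertion failed at {pos}: expected "
                    f"{token!r}, observed {sequence[pos - 1]!r}",
                    expected=token,
                    observed=sequence[pos - 1],
                )
    else:
        for pos, token in ((v.start, v.start_ref), (v.end, v.end_ref)):
            if token and sequence[pos - 1] != token:
                raise ReferenceMismatchError(
                    f"insertion flank assertion failed at {pos}: expected "
                    f"{token!r}, observed {sequence[pos - 1]!r}",
                    expected=token,
                    observed=sequence[pos - 1],
                )

    if v.edit_kind is EditKind.SUBSTITUTION:
        return sequence[: v.start - 1] + v.alt_allele + sequence[v.start :]
    if v.edit_kind is EditKind.DELETION:
        return sequence[: v.start - 1] + sequence[v.end :]
    if v.edit_kind is EditKind.INSERTION:
        return sequence[: v.start] + v.alt_allele + sequence[v.start :]
    if v.edit_kind is EditKind.DELINS:
        return sequence[: v.start - 1] + v.alt_allele + sequence[v.end :]
    # duplication
    return sequence[: v.end] + sequence[v.start - 1 : v.end] + sequence[v.end :]


def write_fasta_record(header: str, sequence: str, width: int = 60) -> str:
    """One FASTA record as text, wrapped at ``width`` columns."""
    if not sequence:
        raise ValidationError("refusing to write an empty sequence")
    lines = [f">{header}"]
    for i in range(0, len(sequence), width):
        lines.append(sequence[i : i + width])
    return "\n".join(lines) + "\n"
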