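"""Gene symbol normalization against an approved/alias/previous table.

Matching is case-insensitive; output preserves the table's case.
Precedence: approved > alias > previous.  A synonym recorded for more
than one approved gene is reported as ambiguous with all candidates —
never silently resolved.
"""

from __future__ import annotations

from dataclasses import dataclass

from .reference_model import GeneSymbolTable


@dataclass(frozen=True)
class NormalizedSymbol:
    query: str
    approved: str | None  # the single approved symbol, if resolved
    status: str  # 'approved' | 'alias' | 'previous' | 'ambiguous' | 'unknown'
    candidates: tuple[str, ...] = ()


def normalize_symbol(symbol: str, table: GeneSymbolTable) -> NormalizedSymbol:
    """Resolve a gene symbol to its currently approved form."""
    query = symbol.strip()
    if not query:
        return NormalizedSymbol(query=symbol, approved=None, status="unknown")
    hit = table.lookup_approved(query)
    if hit is not None:
        return NormalizedSymbol(query, hit, "approved", (hit,))
    for status, matches in (
        ("alias", table.lookup_alias(query)),
        ("previous", table.lookup_previous(query)),
    ):
        if len(matches) == 1:
            return NormalizedSymbol(query, matches[0], status, tuple(matches))
        if len(matches) > 1:
            return NormalizedSymbol(query, None, "ambiguous", tuple(matches))
    return NormalizedSymbol(query=query, approved=None, status="unknown")
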