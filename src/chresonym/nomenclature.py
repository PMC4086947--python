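"""Scientific-name parsing and spelling-variant canonicalization.

Compound names ("Uca (Minuca) pugnax", "Gelasimus vocans var. nitidus")
are split positionally into genus / subgenus / specific / subspecific
parts; anything unclassifiable is kept as a qualifier token so the
original string can always be reassembled.  Epithet comparison is
table-driven: a :class:`VariantTable` maps misspellings, typographic
errors and gender-agreement variants onto a canonical epithet.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

__all__ = [
    "ParsedName",
    "VariantTable",
    "AmbiguousVariantError",
    "parse_compound_name",
    "canonical_epithet",
    "names_match",
]

# Tokens that mark the tail of a name as open nomenclature / annotation
# rather than a latinized epithet.  Matched case-insensitively.
_QUALIFIER_TOKENS = {
    "sp.", "sp", "spp.", "spp", "var.", "var", "cf.", "cf", "aff.", "aff",
    "unnamed", "undescribed", "nov.", "n.", "forma", "f.", "gen.", "indet.",
}

_TOKEN_RE = re.compile(r"\([^)]*\)|\S+")
_ALPHA_RE = re.compile(r"^[A-Za-z][A-Za-z\-]*$")


class AmbiguousVariantError(ValueError):
    """A variant epithet is mapped to more than one canonical epithet."""


@dataclass(frozen=True)
class ParsedName:
    """Positional decomposition of a verbatim compound name.

    Original capitalization is preserved in every part; use
    :meth:`comparison_key` for case-insensitive work.
    """

    genus: Optional[str] = None
    subgenus: Optional[str] = None
    specific: Optional[str] = None
    subspecific: Optional[str] = None
    qualifiers: tuple[str, ...] = ()

    def comparison_key(self) -> tuple:
        """Lowercased tuple of parts; capitalization variation is ignored."""
        lower = lambda s: s.lower() if s else None
        return (
            lower(self.genus),
            lower(self.subgenus),
            lower(self.specific),
            lower(self.subspecific),
            tuple(q.lower() for q in self.qualifiers),
        )

    @property
    def is_empty(self) -> bool:
        return not (
            self.genus or self.subgenus or self.specific
            or self.subspecific or self.qualifiers
        )


class VariantTable:
    """Functional mapping variant epithet -> canonical epithet.

    Lookup is case-insensitive; canonical epithets map to themselves and
    the mapping is closed (the canonical of a canonical is itself).
    Unknown epithets pass through unchanged (lowercased) -- the database
    deliberately holds misspellings that are not yet tabled.
    """

    def __init__(self, entries: Iterable[tuple[str, str]] | Mapping[str, str] = ()):
        self._map: dict[str, str] = {}
        self._class: dict[str, Optional[str]] = {}
        items = entries.items() if isinstance(entries, Mapping) else entries
        for variant, canonical in items:
            self.add(variant, canonical)

    def add(self, variant: str, canonical: str, variant_class: Optional[str] = None) -> None:
        v, c = variant.lower().strip(), canonical.lower().strip()
        if not v or not c:
            raise ValueError("variant and canonical epithets must be non-empty")
        existing = self._map.get(v)
        if existing is not None and existing != c:
            raise AmbiguousVariantError(
                f"variant {v!r} mapped to both {existing!r} and {c!r}"
            )
        self._map[v] = c
        self._class[v] = variant_class
        # closure: the canonical must resolve to itself
        prior = self._map.get(c)
        if prior is not None and prior != c:
            raise AmbiguousVariantError(
                f"canonical {c!r} of variant {v!r} itself maps to {prior!r}"
            )
        self._map.setdefault(c, c)

    def canonical(self, epithet: str) -> str:
        return self._map.get(epithet.lower(), epithet.lower())

    def variant_class(self, variant: str) -> Optional[str]:
        return self._class.get(variant.lower())

    def variants_of(self, canonical: str) -> list[str]:
        c = canonical.lower()
        return sorted(v for v, m in self._map.items() if m == c)

    def items(self) -> list[tuple[str, str, Optional[str]]]:
        return [(v, c, self._class.get(v)) for v, c in sorted(self._map.items())]

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, epithet: str) -> bool:
        return epithet.lower() in self._map


def _is_qualifier(token: str) -> bool:
    return token.lower() in _QUALIFIER_TOKENS or not _ALPHA_RE.match(token)


def parse_compound_name(verbatim: str) -> ParsedName:
    """Split a verbatim compound name into its positional parts.

    Conventions: a leading capitalized token is the genus; a
    parenthesized capitalized token immediately after it is the
    subgenus; following plain-alphabetic tokens fill specific then
    subspecific slots.  Once a qualifier token ("sp.", "var.",
    "unnamed", anything parenthesized or non-alphabetic) is seen, it
    and everything after it land in ``qualifiers``.  Never raises:
    unclassifiable input degrades to qualifiers.
    """
    if not verbatim or not verbatim.strip():
        raise ValueError("empty name string")
    tokens = _TOKEN_RE.findall(verbatim.strip())

    genus = subgenus = specific = subspecific = None
    qualifiers: list[str] = []
    i = 0

    first = tokens[0]
    if _ALPHA_RE.match(first) and first[0].isupper():
        genus = first
        i = 1
        if i < len(tokens) and tokens[i].startswith("("):
            inner = tokens[i][1:-1].strip()
            if _ALPHA_RE.match(inner) and inner[:1].isupper():
                subgenus = inner
                i += 1

    in_tail = False
    for tok in tokens[i:]:
        if in_tail or _is_qualifier(tok):
            in_tail = True
            qualifiers.append(tok)
        elif specific is None:
            specific = tok
        elif subspecific is None:
            subspecific = tok
        else:
            in_tail = True
            qualifiers.append(tok)

    parsed = ParsedName(genus, subgenus, specific, subspecific, tuple(qualifiers))
    if parsed.is_empty:
        # e.g. input was pure punctuation; keep raw tokens as qualifiers
        parsed = ParsedName(qualifiers=tuple(tokens))
    return parsed


def canonical_epithet(epithet: str, table: VariantTable) -> str:
    """Canonical (accepted-spelling) form of an epithet, lowercased.

    Idempotent; unknown epithets pass through unchanged apart from case.
    """
    if not epithet:
        raise ValueError("empty epithet")
    return table.canonical(epithet)


def names_match(a: str, b: str, table: VariantTable) -> bool:
    """True if two verbatim names refer to the same epithet modulo variants.

    Specific (and, when both carry one, subspecific) epithets are
    compared after canonicalization.  Genus differences alone never
    block a match: genus migration (Gelasimus -> Uca) is pervasive in
    the literature, so only epithet-less names fall back to genus
    comparison.
    """
    pa, pb = parse_compound_name(a), parse_compound_name(b)
    if pa.specific and pb.specific:
        if table.canonical(pa.specific) != table.canonical(pb.specific):
            return False
        if pa.subspecific and pb.subspecific:
            return table.canonical(pa.subspecific) == table.canonical(pb.subspecific)
        return True
    if pa.specific or pb.specific:
        return False
    if pa.genus and pb.genus:
        return table.canonical(pa.genus) == table.canonical(pb.genus)
    return pa.comparison_key() == pb.comparison_key()
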