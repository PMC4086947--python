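"""Domain types and dataset-level validation.

A dataset is four tables: publications, name-usage records, a
spelling-variant table and an accepted-species table.  Every usage is
one verbatim occurrence of a name in one publication together with the
context of that use (specimen, location, citation, or none) and either
an explicit currently-accepted species, a marker that the species must
be computed from the cited work, or an unknown marker.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .nomenclature import VariantTable

__all__ = [
    "NameKeyError",
    "NameKey",
    "ContextKind",
    "AcceptedMode",
    "AcceptedAssignment",
    "CitationTarget",
    "NameUsage",
    "Publication",
    "Species",
    "Dataset",
    "Issue",
    "parse_name_key",
    "validate_dataset",
]


class NameKeyError(ValueError):
    """Raised for malformed name-key strings."""


@dataclass(frozen=True)
class NameKey:
    """Integer base plus optional context index identifying a name use.

    ``base`` is a positive integer per unique name within a publication
    (0 is reserved for general citations to a publication as a whole);
    ``context`` distinguishes multiple contextual uses of one name.
    ``raw`` is the verbatim string form and round-trips losslessly.
    A lone period means the key is missing/unrecorded.
    """

    base: Optional[int]
    context: Optional[int]
    raw: str

    @property
    def is_missing(self) -> bool:
        return self.base is None

    @property
    def is_general(self) -> bool:
        return self.base == 0

    def serialize(self) -> str:
        if self.base is None:
            return "."
        if self.context is None:
            return str(self.base)
        return f"{self.base}.{self.context}"


def _parse_int_part(part: str, raw: str, minimum: int) -> int:
    if not part.isdigit():
        raise NameKeyError(f"malformed name key {raw!r}: token {part!r} is not an integer")
    if part != str(int(part)):
        raise NameKeyError(f"malformed name key {raw!r}: token {part!r} has leading zeros")
    value = int(part)
    if value < minimum:
        raise NameKeyError(f"malformed name key {raw!r}: token {part!r} below {minimum}")
    return value


def parse_name_key(raw: str) -> NameKey:
    """Parse a raw key string ("3", "3.1", "0", ".") into a :class:`NameKey`.

    Base and context are split on the dot and parsed as two integers --
    never through floating point, so "3.10" is context 10 and distinct
    from "3.1".
    """
    if not raw:
        raise NameKeyError("empty name key")
    if raw == ".":
        return NameKey(None, None, raw)
    parts = raw.split(".")
    if len(parts) == 1:
        base = _parse_int_part(parts[0], raw, 0)
        return NameKey(base, None, raw)
    if len(parts) == 2:
        base = _parse_int_part(parts[0], raw, 1)
        context = _parse_int_part(parts[1], raw, 1)
        return NameKey(base, context, raw)
    raise NameKeyError(f"malformed name key {raw!r}: too many dots")


class ContextKind(enum.Enum):
    """The four contexts in which a taxonomic name is used."""

    SPECIMEN = "specimen"
    LOCATION = "location"
    CITATION = "citation"
    NONE = "none"


class AcceptedMode(enum.Enum):
    EXPLICIT = "explicit"   # currently accepted species recorded directly
    COMPUTE = "compute"     # "=": resolve through the citation chain
    UNKNOWN = "unknown"     # indeterminate


@dataclass(frozen=True)
class AcceptedAssignment:
    mode: AcceptedMode
    species_id: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.mode is AcceptedMode.EXPLICIT) != (self.species_id is not None):
            raise ValueError("species_id must be present exactly when mode is EXPLICIT")

    @classmethod
    def explicit(cls, species_id: str) -> "AcceptedAssignment":
        return cls(AcceptedMode.EXPLICIT, species_id)

    @classmethod
    def compute(cls) -> "AcceptedAssignment":
        return cls(AcceptedMode.COMPUTE)

    @classmethod
    def unknown(cls) -> "AcceptedAssignment":
        return cls(AcceptedMode.UNKNOWN)


@dataclass(frozen=True)
class CitationTarget:
    """Pointer from a citing record to name key(s) in a cited publication.

    A base-only key cites every context of that name; base.context cites
    one context; 0 is a general citation to the publication; "." means
    the cited work has not yet been recorded.
    """

    cited_pub: str
    cited_key: NameKey


@dataclass(frozen=True)
class NameUsage:
    """One verbatim name occurrence in one publication, with context."""

    pub_key: str
    name_key: NameKey
    verbatim_name: str
    locus: str
    context: ContextKind
    accepted: AcceptedAssignment
    place: Optional[str] = None
    specimen_id: Optional[str] = None
    citation: Optional[CitationTarget] = None
    common_name: Optional[str] = None
    notes: Optional[str] = None
    # disambiguates deliberate multi-species duplicate rows
    species_tag: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.context is ContextKind.CITATION) != (self.citation is not None):
            raise ValueError(
                f"{self.pub_key}|{self.name_key.raw}: citation target present "
                f"iff context is CITATION"
            )


@dataclass(frozen=True)
class Publication:
    key: str
    year: int
    citation_text: str = ""
    recorded: bool = True


@dataclass(frozen=True)
class Species:
    species_id: str
    binomial: str
    status: str = "extant"
    etymology: Optional[str] = None


_SPECIES_STATUSES = {"extant", "extinct", "invalid", "uncertain"}


@dataclass
class Dataset:
    """In-memory view of the four flat-file tables."""

    publications: dict[str, Publication] = field(default_factory=dict)
    usages: list[NameUsage] = field(default_factory=list)
    species: dict[str, Species] = field(default_factory=dict)
    variants: VariantTable = field(default_factory=VariantTable)

    def usages_of(self, pub_key: str) -> list[NameUsage]:
        return [u for u in self.usages if u.pub_key == pub_key]

    def replace_usage(self, old: NameUsage, new: NameUsage) -> "Dataset":
        usages = [new if u is old else u for u in self.usages]
        return Dataset(dict(self.publications), usages, dict(self.species), self.variants)


@dataclass(frozen=True)
class Issue:
    """One validation finding; ``severity`` is "error" or "warning"."""

    severity: str
    code: str
    message: str
    pub_key: Optional[str] = None

    def __str__(self) -> str:  # machine-parseable single line
        return f"{self.severity}\t{self.code}\t{self.pub_key or '.'}\t{self.message}"


def _usage_label(u: NameUsage) -> str:
    return f"{u.pub_key}|{u.name_key.raw}"


def validate_dataset(dataset: Dataset) -> list[Issue]:
    """Structural validation. Reports issues; never raises.

    Errors: duplicate record keys without species-id disambiguation,
    compute markers outside citation contexts, explicit assignments to
    unknown species.  Warnings: dangling publication keys and citation
    targets matching nothing (the database is perpetually in-progress,
    so unresolved references are routine), same-year or future-dated
    citations (chronology hazards), and specimen/location records
    lacking a place.
    """
    issues: list[Issue] = []
    by_pub: dict[str, list[NameUsage]] = {}
    for u in dataset.usages:
        by_pub.setdefault(u.pub_key, []).append(u)

    for pub_key, rows in by_pub.items():
        if pub_key not in dataset.publications:
            issues.append(Issue(
                "warning", "unknown-publication",
                f"usage rows reference publication {pub_key!r} absent from the publication table",
                pub_key,
            ))
        seen: dict[tuple[str, Optional[str]], int] = {}
        for u in rows:
            if u.context is ContextKind.CITATION:
                continue  # independent citation entries may legally share a key
            key = (u.name_key.raw, u.species_tag)
            seen[key] = seen.get(key, 0) + 1
        for (raw, tag), n in seen.items():
            if n > 1:
                issues.append(Issue(
                    "error", "duplicate-key",
                    f"{pub_key}|{raw}: {n} rows share this key without distinct species-id tags",
                    pub_key,
                ))

    for u in dataset.usages:
        label = _usage_label(u)
        if u.accepted.mode is AcceptedMode.COMPUTE and u.context is not ContextKind.CITATION:
            issues.append(Issue(
                "error", "compute-on-noncitation",
                f"{label}: compute marker ('=') on a {u.context.value} record",
                u.pub_key,
            ))
        if u.accepted.mode is AcceptedMode.EXPLICIT and u.accepted.species_id not in dataset.species:
            issues.append(Issue(
                "error", "unknown-species",
                f"{label}: accepted species {u.accepted.species_id!r} not in the species table",
                u.pub_key,
            ))
        if u.context in (ContextKind.SPECIMEN, ContextKind.LOCATION) and not u.place:
            issues.append(Issue(
                "warning", "missing-place",
                f"{label}: {u.context.value} record without a geographic place",
                u.pub_key,
            ))
        if u.context is ContextKind.CITATION:
            issues.extend(_validate_citation(u, dataset, by_pub))

    for sp in dataset.species.values():
        if sp.status not in _SPECIES_STATUSES:
            issues.append(Issue(
                "warning", "unknown-status",
                f"species {sp.species_id}: unrecognized status {sp.status!r}",
            ))
    return issues


def _validate_citation(
    u: NameUsage, dataset: Dataset, by_pub: dict[str, list[NameUsage]]
) -> list[Issue]:
    issues: list[Issue] = []
    label = _usage_label(u)
    target = u.citation
    assert target is not None
    cited_pub = dataset.publications.get(target.cited_pub)
    if cited_pub is None:
        issues.append(Issue(
            "warning", "dangling-publication",
            f"{label}: cites unknown publication {target.cited_pub!r}",
            u.pub_key,
        ))
        return issues
    citing_pub = dataset.publications.get(u.pub_key)
    if citing_pub is not None and target.cited_pub != u.pub_key:
        if cited_pub.year > citing_pub.year:
            issues.append(Issue(
                "warning", "future-citation",
                f"{label}: cites {target.cited_pub} ({cited_pub.year}) "
                f"published after {citing_pub.year}",
                u.pub_key,
            ))
        elif cited_pub.year == citing_pub.year:
            issues.append(Issue(
                "warning", "same-year-citation",
                f"{label}: cites {target.cited_pub} from the same year ({cited_pub.year})",
                u.pub_key,
            ))
    key = target.cited_key
    if key.is_missing or key.is_general or not cited_pub.recorded:
        return issues
    rows = by_pub.get(target.cited_pub, [])
    if key.context is None:
        if not any(r.name_key.base == key.base for r in rows):
            issues.append(Issue(
                "warning", "empty-expansion",
                f"{label}: citation to {target.cited_pub}|{key.raw} matches no "
                f"recorded name in that publication",
                u.pub_key,
            ))
    else:
        if not any(r.name_key.raw == key.raw for r in rows):
            issues.append(Issue(
                "warning", "dangling-target",
                f"{label}: citation to {target.cited_pub}|{key.raw} matches no "
                f"recorded context in that publication",
                u.pub_key,
            ))
    return issues
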