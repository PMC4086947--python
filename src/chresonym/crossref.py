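"""Derived cross-reference structures behind the generated site.

Four collections are built from a resolved dataset: a specific-name
index (one entry per canonical epithet, variants folded in), a
binomial/compound-name index (one entry per distinct verbatim spelling,
capitalization ignored), per-publication entries with name-citation
"cited by" lists, and per-species entries whose publication lists come
from the *resolved* species — what the author actually referred to —
rather than the names they printed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .datamodel import (
    AcceptedMode,
    ContextKind,
    Dataset,
    NameUsage,
    Publication,
    Species,
)
from .nomenclature import parse_compound_name
from .resolver import UNKNOWN_SPECIES, Resolution, expand_citation_target

__all__ = [
    "UsageRow",
    "SpecificNameEntry",
    "BinomialEntry",
    "PublicationEntry",
    "SpeciesEntry",
    "CrossReference",
    "build_specific_index",
    "build_binomial_index",
    "build_publication_entries",
    "build_species_entries",
    "build_crossref",
    "summarize_dataset",
]

# Note text marking a usage as the introduction of a new name; used to
# spot homonymy (the same epithet introduced as novel more than once).
TYPE_DESCRIPTION_MARKER = "type description"


@dataclass(frozen=True)
class UsageRow:
    """One display row: a usage with its resolved species rendered."""

    pub_key: str
    year: int
    name: str
    locus: str
    context_summary: str
    accepted_display: str
    accepted_ids: tuple[str, ...]
    in_part: bool


@dataclass
class SpecificNameEntry:
    epithet: str                       # canonical, lowercased
    species_ids: list[str]             # current species this epithet has referred to
    original_spelling: Optional[str]   # as first printed
    original_source: Optional[str]     # publication key with priority
    original_year: Optional[int]
    etymology: Optional[str]
    binomials: list[str]               # all compound names built on this epithet
    variants: list[str]                # variant spellings of the epithet
    notes: list[str]                   # synonymy / homonymy remarks


@dataclass
class BinomialEntry:
    name: str                          # display form (first occurrence)
    key: str                           # lowercased grouping key
    epithet: Optional[str]             # canonical specific epithet, if any
    rows: list[UsageRow]
    species_ids: list[str]             # distinct resolved species, no unknowns


@dataclass
class PublicationEntry:
    publication: Publication
    rows: list[UsageRow]
    cited_by: list[str]                # pub keys citing its name records


@dataclass
class SpeciesEntry:
    species: Species
    synonyms: list[str]                # verbatim names applied to this species
    publications: list[tuple[str, list[str]]]  # (pub key, names used there)


@dataclass
class CrossReference:
    specific_index: list[SpecificNameEntry]
    binomial_index: list[BinomialEntry]
    publications: list[PublicationEntry]
    species: list[SpeciesEntry]
    summary: dict


def _epithets_of(name: str, dataset: Dataset) -> list[str]:
    parsed = parse_compound_name(name)
    out = []
    for part in (parsed.specific, parsed.subspecific):
        if part:
            out.append(dataset.variants.canonical(part))
    return out


def _context_summary(u: NameUsage, dataset: Dataset) -> str:
    if u.context is ContextKind.SPECIMEN:
        bits = [b for b in (u.place, u.specimen_id) if b]
        return "specimen: " + "; ".join(bits) if bits else "specimen"
    if u.context is ContextKind.LOCATION:
        return f"location: {u.place}" if u.place else "location"
    if u.context is ContextKind.CITATION:
        target = u.citation
        assert target is not None
        if target.cited_key.is_general:
            return f"citation: {target.cited_pub} (general)"
        if target.cited_key.is_missing:
            return f"citation: {target.cited_pub} (not yet recorded)"
        cited = expand_citation_target(target, dataset)
        names = sorted({r.verbatim_name for r in cited})
        suffix = f" [{'; '.join(names)}]" if names else ""
        return f"citation: {target.cited_pub}{suffix}"
    return "no context"


def _accepted_display(ids: tuple[str, ...], in_part: bool, dataset: Dataset) -> str:
    parts = []
    for sid in ids:
        if sid == UNKNOWN_SPECIES:
            parts.append("unknown")
        else:
            sp = dataset.species.get(sid)
            parts.append(sp.binomial if sp else sid)
    text = ", ".join(parts)
    if in_part:
        text += " in part"
    return text


def _usage_row(u: NameUsage, dataset: Dataset, resolved: Resolution) -> UsageRow:
    r = resolved[u]
    pub = dataset.publications.get(u.pub_key)
    return UsageRow(
        pub_key=u.pub_key,
        year=pub.year if pub else 0,
        name=u.verbatim_name,
        locus=u.locus,
        context_summary=_context_summary(u, dataset),
        accepted_display=_accepted_display(r.accepted, r.in_part, dataset),
        accepted_ids=r.accepted,
        in_part=r.in_part,
    )


def _ordered_rows(usages: list[NameUsage], dataset: Dataset,
                  resolved: Resolution) -> list[UsageRow]:
    position = {id(u): i for i, u in enumerate(dataset.usages)}

    def sort_key(u: NameUsage):
        pub = dataset.publications.get(u.pub_key)
        return (pub.year if pub else 0, u.pub_key, position.get(id(u), 0))

    return [_usage_row(u, dataset, resolved) for u in sorted(usages, key=sort_key)]


def build_specific_index(dataset: Dataset, resolved: Resolution) -> list[SpecificNameEntry]:
    """One entry per canonical specific/subspecific epithet in the data."""
    by_epithet: dict[str, list[NameUsage]] = {}
    for u in dataset.usages:
        for ep in _epithets_of(u.verbatim_name, dataset):
            by_epithet.setdefault(ep, []).append(u)

    # species whose accepted binomial carries a given canonical epithet
    accepted_epithet: dict[str, list[str]] = {}
    for sp in dataset.species.values():
        for ep in _epithets_of(sp.binomial, dataset):
            accepted_epithet.setdefault(ep, []).append(sp.species_id)

    entries = []
    for epithet in sorted(by_epithet):
        usages = by_epithet[epithet]
        species_ids = sorted({
            sid for u in usages for sid in resolved[u].accepted
            if sid != UNKNOWN_SPECIES
        })
        dated = [
            (dataset.publications[u.pub_key].year, u.pub_key, i, u)
            for i, u in enumerate(usages) if u.pub_key in dataset.publications
        ]
        first = min(dated)[3] if dated else usages[0]
        first_pub = dataset.publications.get(first.pub_key)
        parsed = parse_compound_name(first.verbatim_name)
        original = parsed.subspecific if (
            parsed.subspecific
            and dataset.variants.canonical(parsed.subspecific) == epithet
        ) else parsed.specific

        etymology = None
        for sid in accepted_epithet.get(epithet, []):
            if dataset.species[sid].etymology:
                etymology = dataset.species[sid].etymology
                break

        binomials = sorted(
            {u.verbatim_name for u in usages},
            key=lambda s: s.lower(),
        )
        variants = [v for v in dataset.variants.variants_of(epithet) if v != epithet]

        notes = []
        introductions = {
            u.pub_key for u in usages
            if u.notes and TYPE_DESCRIPTION_MARKER in u.notes.lower()
        }
        if len(introductions) > 1:
            notes.append(
                f"homonym: introduced as a new name {len(introductions)} times "
                f"({', '.join(sorted(introductions))})"
            )
        senior = {
            dataset.species[sid].binomial for sid in species_ids
            if sid in dataset.species
            and epithet not in _epithets_of(dataset.species[sid].binomial, dataset)
        }
        if senior:
            notes.append("junior synonym of " + ", ".join(sorted(senior)))

        entries.append(SpecificNameEntry(
            epithet=epithet,
            species_ids=species_ids,
            original_spelling=original,
            original_source=first_pub.key if first_pub else None,
            original_year=first_pub.year if first_pub else None,
            etymology=etymology,
            binomials=binomials,
            variants=variants,
            notes=notes,
        ))
    return entries


def build_binomial_index(dataset: Dataset, resolved: Resolution) -> list[BinomialEntry]:
    """One entry per distinct verbatim compound name, case-folded."""
    by_key: dict[str, list[NameUsage]] = {}
    for u in dataset.usages:
        by_key.setdefault(u.verbatim_name.lower(), []).append(u)

    entries = []
    for key in sorted(by_key):
        usages = by_key[key]
        rows = _ordered_rows(usages, dataset, resolved)
        species_ids = sorted({
            sid for u in usages for sid in resolved[u].accepted
            if sid != UNKNOWN_SPECIES
        })
        parsed = parse_compound_name(usages[0].verbatim_name)
        epithet = (dataset.variants.canonical(parsed.specific)
                   if parsed.specific else None)
        entries.append(BinomialEntry(
            name=rows[0].name if rows else usages[0].verbatim_name,
            key=key,
            epithet=epithet,
            rows=rows,
            species_ids=species_ids,
        ))
    return entries


def build_publication_entries(dataset: Dataset, resolved: Resolution) -> list[PublicationEntry]:
    """One entry per publication; cited_by covers name-record citations
    only — general (zero-key) citations never appear."""
    cited_by: dict[str, set[str]] = {}
    for u in dataset.usages:
        if u.citation is None or u.citation.cited_key.is_general:
            continue
        if u.citation.cited_pub != u.pub_key:
            cited_by.setdefault(u.citation.cited_pub, set()).add(u.pub_key)

    entries = []
    for key in sorted(dataset.publications):
        pub = dataset.publications[key]
        rows = _ordered_rows(dataset.usages_of(key), dataset, resolved)
        entries.append(PublicationEntry(
            publication=pub,
            rows=rows,
            cited_by=sorted(cited_by.get(key, set())),
        ))
    return entries


def build_species_entries(dataset: Dataset, resolved: Resolution) -> list[SpeciesEntry]:
    """One entry per species; publications come from resolved usages."""
    pubs_for: dict[str, dict[str, set[str]]] = {}
    names_for: dict[str, set[str]] = {}
    for u in dataset.usages:
        for sid in resolved[u].accepted:
            if sid == UNKNOWN_SPECIES:
                continue
            pubs_for.setdefault(sid, {}).setdefault(u.pub_key, set()).add(u.verbatim_name)
            names_for.setdefault(sid, set()).add(u.verbatim_name)

    entries = []
    for sid in sorted(dataset.species):
        sp = dataset.species[sid]
        accepted_lower = sp.binomial.lower()
        synonyms = sorted(
            {n for n in names_for.get(sid, set()) if n.lower() != accepted_lower},
            key=str.lower,
        )
        def pub_sort(key: str):
            pub = dataset.publications.get(key)
            return (pub.year if pub else 0, key)
        publications = [
            (key, sorted(pubs_for.get(sid, {})[key], key=str.lower))
            for key in sorted(pubs_for.get(sid, {}), key=pub_sort)
        ]
        entries.append(SpeciesEntry(species=sp, synonyms=synonyms,
                                    publications=publications))
    return entries


def summarize_dataset(dataset: Dataset, resolved: Resolution) -> dict:
    """Dataset-level counts: names, species, genera, context mix."""
    epithets = set()
    compound = set()
    genera_verbatim = set()
    genera_canonical = set()
    for u in dataset.usages:
        compound.add(u.verbatim_name.lower())
        epithets.update(_epithets_of(u.verbatim_name, dataset))
        parsed = parse_compound_name(u.verbatim_name)
        if parsed.genus:
            genera_verbatim.add(parsed.genus.lower())
            genera_canonical.add(dataset.variants.canonical(parsed.genus))
    context_counts = {k.value: 0 for k in ContextKind}
    for u in dataset.usages:
        context_counts[u.context.value] += 1
    n = len(dataset.usages)
    per_year: dict[int, int] = {}
    for pub in dataset.publications.values():
        per_year[pub.year] = per_year.get(pub.year, 0) + 1
    accepted_statuses = ("extant", "extinct")
    return {
        "n_usages": n,
        "n_publications": len(dataset.publications),
        "n_species_accepted": sum(
            1 for s in dataset.species.values() if s.status in accepted_statuses
        ),
        "n_specific_names": len(epithets),
        "n_compound_names": len(compound),
        "n_genera": len(genera_verbatim),
        "n_genera_canonical": len(genera_canonical),
        "context_counts": context_counts,
        "citation_share": (context_counts["citation"] / n) if n else 0.0,
        "n_unknown_resolutions": sum(
            1 for r in resolved.values() if UNKNOWN_SPECIES in r.accepted
        ),
        "publications_per_year": {str(y): per_year[y] for y in sorted(per_year)},
    }


def build_crossref(dataset: Dataset, resolved: Resolution) -> CrossReference:
    return CrossReference(
        specific_index=build_specific_index(dataset, resolved),
        binomial_index=build_binomial_index(dataset, resolved),
        publications=build_publication_entries(dataset, resolved),
        species=build_species_entries(dataset, resolved),
        summary=summarize_dataset(dataset, resolved),
    )
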