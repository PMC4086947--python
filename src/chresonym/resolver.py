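"""Chronological resolution of accepted species through citation chains.

Explicit assignments pass through untouched.  Citation records marked
for computation pool the already-resolved accepted species of every
cited context and decide by unanimity, plurality, a spelling-variant
match against the citing name, or first appearance — flagging "in part"
whenever the pool spans more than one known species.  Publications are
processed oldest first, so a single pass suffices: by the time a
citation is examined, everything it can cite has been resolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

from .datamodel import (
    AcceptedMode,
    CitationTarget,
    ContextKind,
    Dataset,
    NameUsage,
)
from .nomenclature import VariantTable, names_match

__all__ = [
    "UNKNOWN_SPECIES",
    "ResolvedUsage",
    "Resolution",
    "Edit",
    "ChronologyError",
    "CycleError",
    "DanglingTargetError",
    "EditError",
    "expand_citation_target",
    "resolve_citation",
    "resolve_all",
    "chronological_order",
    "apply_edits",
    "update_and_repropagate",
]

#: Sentinel species id for indeterminate resolutions.
UNKNOWN_SPECIES = "?"


class ChronologyError(RuntimeError):
    """A cited usage was not resolved before its citing record."""


class CycleError(ChronologyError):
    """Citation cycle among same-year publications."""

    def __init__(self, members: Sequence[str]):
        self.members = list(members)
        super().__init__(f"citation cycle among publications: {', '.join(self.members)}")


class DanglingTargetError(LookupError):
    """A context-specific citation target matches nothing in a recorded work."""


class EditError(ValueError):
    """An edit addressed a record that may not be edited."""


@dataclass(frozen=True)
class ResolvedUsage:
    """A usage together with its computed accepted species.

    ``accepted`` holds species ids (or the :data:`UNKNOWN_SPECIES`
    sentinel); ``provenance`` lists the cited contexts consumed during
    resolution as (cited pub, cited key, contributed species) triples.
    """

    usage: NameUsage
    accepted: tuple[str, ...]
    in_part: bool = False
    provenance: tuple[tuple[str, str, str], ...] = ()


class Resolution(Mapping):
    """Mapping from usage rows to :class:`ResolvedUsage`, in dataset order.

    Keyed by row identity so that deliberate duplicate rows stay
    distinct.  ``warnings`` collects dangling-target and unresolvable
    citations encountered during the pass.
    """

    def __init__(self) -> None:
        self._entries: dict[int, ResolvedUsage] = {}
        self._order: list[NameUsage] = []
        self.warnings: list[str] = []

    def _put(self, usage: NameUsage, resolved: ResolvedUsage) -> None:
        if id(usage) not in self._entries:
            self._order.append(usage)
        self._entries[id(usage)] = resolved

    def __getitem__(self, usage: NameUsage) -> ResolvedUsage:
        return self._entries[id(usage)]

    def get(self, usage: NameUsage, default=None):
        return self._entries.get(id(usage), default)

    def __contains__(self, usage) -> bool:
        return id(usage) in self._entries

    def __iter__(self):
        return iter(self._order)

    def __len__(self) -> int:
        return len(self._entries)

    def values(self):
        return [self._entries[id(u)] for u in self._order]

    def items(self):
        return [(u, self._entries[id(u)]) for u in self._order]


def _index_by_pub(dataset: Dataset) -> dict[str, list[NameUsage]]:
    index: dict[str, list[NameUsage]] = {}
    for u in dataset.usages:
        index.setdefault(u.pub_key, []).append(u)
    return index


def expand_citation_target(
    target: CitationTarget,
    dataset: Dataset,
    _index: Optional[dict[str, list[NameUsage]]] = None,
) -> list[NameUsage]:
    """All usage rows in the cited publication addressed by a target.

    Base-only keys expand to every context sharing that base;
    base.context keys to the single matching context (duplicate rows
    included); general (0) and missing (".") keys to nothing.
    """
    key = target.cited_key
    if key.is_missing or key.is_general:
        return []
    index = _index if _index is not None else _index_by_pub(dataset)
    rows = index.get(target.cited_pub, [])
    if key.context is None:
        return [r for r in rows if r.name_key.base == key.base]
    matches = [r for r in rows if r.name_key.raw == key.raw]
    if not matches:
        pub = dataset.publications.get(target.cited_pub)
        if pub is not None and pub.recorded and rows:
            raise DanglingTargetError(
                f"citation to {target.cited_pub}|{key.raw} matches no recorded context"
            )
    return matches


def _citation_group(usage: NameUsage, pub_rows: Iterable[NameUsage]) -> list[NameUsage]:
    """Independent citation entries sharing this usage's full name key."""
    return [
        r for r in pub_rows
        if r.context is ContextKind.CITATION
        and r.accepted.mode is AcceptedMode.COMPUTE
        and r.name_key.raw == usage.name_key.raw
    ]


def resolve_citation(
    usage: NameUsage,
    resolved: Mapping,
    dataset: Dataset,
    variants: Optional[VariantTable] = None,
    _index: Optional[dict[str, list[NameUsage]]] = None,
    _warnings: Optional[list[str]] = None,
) -> ResolvedUsage:
    """Resolve one compute-marked citation record against earlier records.

    Decision ladder over the pooled accepted species of all cited
    contexts (all citation entries sharing this usage's name key):
    unanimity; plurality; on a plurality tie, a spelling-variant match
    between the citing verbatim name and a tied species' accepted name;
    finally the first tied species in cited-context order.  Any outcome
    past unanimity is flagged "in part".  An empty or all-unknown pool
    resolves to unknown.
    """
    if usage.context is not ContextKind.CITATION or usage.accepted.mode is not AcceptedMode.COMPUTE:
        raise ValueError("resolve_citation applies only to compute-marked citation records")
    variants = variants if variants is not None else dataset.variants
    index = _index if _index is not None else _index_by_pub(dataset)
    citing_pub = dataset.publications.get(usage.pub_key)

    pool: list[str] = []          # known species, in cited-context order
    provenance: list[tuple[str, str, str]] = []
    saw_unknown = False

    for entry in _citation_group(usage, index.get(usage.pub_key, [])):
        target = entry.citation
        assert target is not None
        try:
            cited_rows = expand_citation_target(target, dataset, index)
        except DanglingTargetError as exc:
            if _warnings is not None:
                _warnings.append(f"{usage.pub_key}|{usage.name_key.raw}: {exc}")
            continue
        for row in cited_rows:
            row_resolved = resolved.get(row)
            if row_resolved is None:
                cited_pub = dataset.publications.get(target.cited_pub)
                if citing_pub is not None and cited_pub is not None \
                        and cited_pub.year > citing_pub.year:
                    # forward-dated citation: flagged by validation;
                    # contributes nothing rather than seeing the future
                    if _warnings is not None:
                        _warnings.append(
                            f"{usage.pub_key}|{usage.name_key.raw}: skipped "
                            f"forward citation to {target.cited_pub} ({cited_pub.year})"
                        )
                    continue
                raise ChronologyError(
                    f"{usage.pub_key}|{usage.name_key.raw} cites unresolved "
                    f"{row.pub_key}|{row.name_key.raw}"
                )
            for species in row_resolved.accepted:
                provenance.append((row.pub_key, row.name_key.raw, species))
                if species == UNKNOWN_SPECIES:
                    saw_unknown = True
                else:
                    pool.append(species)

    if not pool:
        return ResolvedUsage(usage, (UNKNOWN_SPECIES,), False, tuple(provenance))

    distinct: list[str] = []
    counts: dict[str, int] = {}
    for species in pool:
        if species not in counts:
            distinct.append(species)
        counts[species] = counts.get(species, 0) + 1

    if len(distinct) == 1:
        return ResolvedUsage(usage, (distinct[0],), False, tuple(provenance))

    top = max(counts.values())
    plurality = [s for s in distinct if counts[s] == top]
    if len(plurality) == 1:
        return ResolvedUsage(usage, (plurality[0],), True, tuple(provenance))

    for species in plurality:
        sp = dataset.species.get(species)
        candidate = sp.binomial if sp is not None else species
        if names_match(usage.verbatim_name, candidate, variants):
            return ResolvedUsage(usage, (species,), True, tuple(provenance))

    return ResolvedUsage(usage, (plurality[0],), True, tuple(provenance))


def chronological_order(dataset: Dataset) -> list[str]:
    """Publication keys in resolution order: by year, then by citation
    dependency inside each year group, ties broken lexicographically.

    Raises :class:`CycleError` on a citation cycle within a year group.
    """
    by_year: dict[int, list[str]] = {}
    for pub in dataset.publications.values():
        by_year.setdefault(pub.year, []).append(pub.key)
    edges: dict[str, set[str]] = {}
    for u in dataset.usages:
        if u.citation is None:
            continue
        cited = dataset.publications.get(u.citation.cited_pub)
        citing = dataset.publications.get(u.pub_key)
        if cited and citing and cited.year == citing.year and cited.key != citing.key:
            edges.setdefault(cited.key, set()).add(citing.key)

    order: list[str] = []
    for year in sorted(by_year):
        group = by_year[year]
        graph = nx.DiGraph()
        graph.add_nodes_from(group)
        for src, dsts in edges.items():
            if src in graph:
                graph.add_edges_from((src, d) for d in dsts if d in graph)
        try:
            order.extend(nx.lexicographical_topological_sort(graph))
        except nx.NetworkXUnfeasible:
            cycle = [a for a, _ in nx.find_cycle(graph)]
            raise CycleError(sorted(cycle)) from None
    return order


def resolve_all(
    dataset: Dataset,
    variants: Optional[VariantTable] = None,
    pub_order: Optional[Sequence[str]] = None,
) -> Resolution:
    """Resolve every usage in one chronological pass.

    ``pub_order`` overrides the default (year, dependency, key) order;
    it must still be a linear extension of the citation partial order
    or a :class:`ChronologyError` is raised.
    """
    variants = variants if variants is not None else dataset.variants
    index = _index_by_pub(dataset)
    order = list(pub_order) if pub_order is not None else chronological_order(dataset)
    resolution = Resolution()

    for pub_key in order:
        for usage in index.get(pub_key, []):
            if usage.accepted.mode is AcceptedMode.EXPLICIT:
                resolution._put(usage, ResolvedUsage(usage, (usage.accepted.species_id,)))
            elif usage.accepted.mode is AcceptedMode.UNKNOWN:
                resolution._put(usage, ResolvedUsage(usage, (UNKNOWN_SPECIES,)))
        for usage in index.get(pub_key, []):
            if usage.accepted.mode is AcceptedMode.COMPUTE:
                resolution._put(usage, resolve_citation(
                    usage, resolution, dataset, variants,
                    _index=index, _warnings=resolution.warnings,
                ))

    # usages of publications missing from the table (validation flags them)
    for usage in dataset.usages:
        if usage not in resolution:
            if usage.accepted.mode is AcceptedMode.EXPLICIT:
                resolution._put(usage, ResolvedUsage(usage, (usage.accepted.species_id,)))
            else:
                resolution._put(usage, ResolvedUsage(usage, (UNKNOWN_SPECIES,)))
                resolution.warnings.append(
                    f"{usage.pub_key}|{usage.name_key.raw}: publication not in "
                    f"table; resolved as unknown"
                )
    return resolution


@dataclass(frozen=True)
class Edit:
    """Retarget one explicit assignment on a non-citation base record."""

    pub_key: str
    key_raw: str
    species_id: str
    species_tag: Optional[str] = None


def apply_edits(dataset: Dataset, edits: Sequence[Edit]) -> Dataset:
    """Return a new dataset with the edits applied; the input is untouched."""
    result = dataset
    for edit in edits:
        matches = [
            u for u in result.usages
            if u.pub_key == edit.pub_key and u.name_key.raw == edit.key_raw
            and (edit.species_tag is None or u.species_tag == edit.species_tag)
        ]
        if not matches:
            raise EditError(f"no record {edit.pub_key}|{edit.key_raw}")
        if len(matches) > 1:
            raise EditError(
                f"{edit.pub_key}|{edit.key_raw} is ambiguous; supply species_tag"
            )
        target = matches[0]
        if target.context is ContextKind.CITATION:
            raise EditError(
                f"{edit.pub_key}|{edit.key_raw} is a citation record; its species "
                f"is computed, not edited"
            )
        if target.accepted.mode is not AcceptedMode.EXPLICIT:
            raise EditError(
                f"{edit.pub_key}|{edit.key_raw} has no explicit assignment to edit"
            )
        new = replace(target, accepted=replace(target.accepted, species_id=edit.species_id))
        result = result.replace_usage(target, new)
    return result


def update_and_repropagate(dataset: Dataset, edits: Sequence[Edit]) -> Resolution:
    """Re-resolve after editing base records; citations update automatically."""
    return resolve_all(apply_edits(dataset, edits))
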