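"""Flat-file readers and writers for the four dataset tables.

Canonical dialect is tab-delimited UTF-8 with a header row; a period in
any cell means "no data" (cells are never left blank).  A comma dialect
is available for interchange.  The usage-record column layout is::

    pub_key  name_key  name  locus  context  context_1  context_2  accepted  notes  common_name

``context_1``/``context_2`` depend on the context kind: place and
specimen id for specimen records, place for locations, cited
publication key and cited name key for citations.  The accepted column
holds a species id, "=" (compute from the cited work) or "?"
(indeterminate).  Deliberate multi-species duplicate rows tag the key
column as ``<key>#<species-tag>``.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Union

from .datamodel import (
    AcceptedAssignment,
    AcceptedMode,
    CitationTarget,
    ContextKind,
    Dataset,
    NameUsage,
    Publication,
    Species,
    parse_name_key,
)
from .nomenclature import AmbiguousVariantError, VariantTable

__all__ = [
    "RecordFileDialect",
    "RecordIOError",
    "TSV",
    "CSV",
    "USAGE_COLUMNS",
    "read_usages",
    "write_usages",
    "read_publications",
    "write_publications",
    "read_variants",
    "write_variants",
    "read_species",
    "write_species",
    "load_dataset",
    "write_dataset",
    "export_json",
]

MISSING = "."

USAGE_COLUMNS = (
    "pub_key", "name_key", "name", "locus", "context",
    "context_1", "context_2", "accepted", "notes", "common_name",
)
PUBLICATION_COLUMNS = ("pub_key", "year", "citation", "recorded", "notes")
VARIANT_COLUMNS = ("variant", "canonical", "class")
SPECIES_COLUMNS = ("species_id", "binomial", "status", "etymology")

_CONTEXT_TOKENS = {k.value: k for k in ContextKind}


class RecordIOError(ValueError):
    """Malformed table file; message carries the path and line number."""


@dataclass(frozen=True)
class RecordFileDialect:
    delimiter: str = "\t"
    missing_marker: str = MISSING
    encoding: str = "utf-8"


TSV = RecordFileDialect()
CSV = RecordFileDialect(delimiter=",")


def _cell(value: Optional[str], dialect: RecordFileDialect) -> str:
    return value if value not in (None, "") else dialect.missing_marker


def _opt(cell: str, dialect: RecordFileDialect) -> Optional[str]:
    return None if cell == dialect.missing_marker else cell


def _rows(path: Path, dialect: RecordFileDialect, expected: tuple[str, ...],
          min_cols: int) -> Iterable[tuple[int, list[str]]]:
    with open(path, "r", encoding=dialect.encoding, newline="") as fh:
        reader = csv.reader(fh, delimiter=dialect.delimiter)
        header = next(reader, None)
        if header is None:
            return
        if [h.strip() for h in header[:min_cols]] != list(expected[:min_cols]):
            raise RecordIOError(
                f"{path}:1: unexpected header {header!r}; expected {list(expected)}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if not (min_cols <= len(row) <= len(expected)):
                raise RecordIOError(
                    f"{path}:{lineno}: expected {min_cols}-{len(expected)} "
                    f"columns, found {len(row)}"
                )
            row = row + [MISSING] * (len(expected) - len(row))
            yield lineno, row


def _split_key_cell(cell: str) -> tuple[str, Optional[str]]:
    if "#" in cell:
        raw, tag = cell.split("#", 1)
        return raw, tag
    return cell, None


def read_usages(path: Union[str, Path], dialect: RecordFileDialect = TSV) -> list[NameUsage]:
    """Read name-usage records; verbatim names are never altered."""
    path = Path(path)
    usages: list[NameUsage] = []
    for lineno, row in _rows(path, dialect, USAGE_COLUMNS, min_cols=9):
        (pub_key, key_cell, name, locus, context_cell,
         ctx1, ctx2, accepted_cell, notes, common) = row[:10]
        raw_key, tag = _split_key_cell(key_cell)
        try:
            name_key = parse_name_key(raw_key)
        except ValueError as exc:
            raise RecordIOError(f"{path}:{lineno}: {exc}") from exc
        kind = _CONTEXT_TOKENS.get(context_cell.lower())
        if kind is None:
            raise RecordIOError(
                f"{path}:{lineno}: unknown context token {context_cell!r}"
            )
        place = specimen_id = None
        citation = None
        if kind is ContextKind.SPECIMEN:
            place, specimen_id = _opt(ctx1, dialect), _opt(ctx2, dialect)
        elif kind is ContextKind.LOCATION:
            place = _opt(ctx1, dialect)
        elif kind is ContextKind.CITATION:
            cited_pub = _opt(ctx1, dialect)
            if cited_pub is None:
                raise RecordIOError(
                    f"{path}:{lineno}: citation context without a cited publication key"
                )
            try:
                cited_key = parse_name_key(ctx2)
            except ValueError as exc:
                raise RecordIOError(f"{path}:{lineno}: {exc}") from exc
            citation = CitationTarget(cited_pub, cited_key)
        if accepted_cell == "=":
            accepted = AcceptedAssignment.compute()
        elif accepted_cell in ("?", dialect.missing_marker):
            accepted = AcceptedAssignment.unknown()
        else:
            accepted = AcceptedAssignment.explicit(accepted_cell)
        usages.append(NameUsage(
            pub_key=pub_key,
            name_key=name_key,
            verbatim_name=name,
            locus=locus,
            context=kind,
            accepted=accepted,
            place=place,
            specimen_id=specimen_id,
            citation=citation,
            notes=_opt(notes, dialect),
            common_name=_opt(common, dialect),
            species_tag=tag,
        ))
    return usages


def _accepted_cell(a: AcceptedAssignment) -> str:
    if a.mode is AcceptedMode.COMPUTE:
        return "="
    if a.mode is AcceptedMode.UNKNOWN:
        return "?"
    return a.species_id  # type: ignore[return-value]


def write_usages(usages: Iterable[NameUsage], path: Union[str, Path],
                 dialect: RecordFileDialect = TSV) -> None:
    path = Path(path)
    with open(path, "w", encoding=dialect.encoding, newline="") as fh:
        writer = csv.writer(fh, delimiter=dialect.delimiter, lineterminator="\n")
        writer.writerow(USAGE_COLUMNS)
        for u in usages:
            key_cell = u.name_key.raw
            if u.species_tag is not None:
                key_cell = f"{key_cell}#{u.species_tag}"
            if u.context is ContextKind.SPECIMEN:
                ctx1, ctx2 = u.place, u.specimen_id
            elif u.context is ContextKind.LOCATION:
                ctx1, ctx2 = u.place, None
            elif u.context is ContextKind.CITATION:
                assert u.citation is not None
                ctx1, ctx2 = u.citation.cited_pub, u.citation.cited_key.raw
            else:
                ctx1 = ctx2 = None
            writer.writerow([
                u.pub_key, key_cell, u.verbatim_name, u.locus, u.context.value,
                _cell(ctx1, dialect), _cell(ctx2, dialect),
                _accepted_cell(u.accepted),
                _cell(u.notes, dialect), _cell(u.common_name, dialect),
            ])


def read_publications(path: Union[str, Path],
                      dialect: RecordFileDialect = TSV) -> dict[str, Publication]:
    path = Path(path)
    pubs: dict[str, Publication] = {}
    for lineno, row in _rows(path, dialect, PUBLICATION_COLUMNS, min_cols=4):
        key, year_cell, citation_text, recorded_cell = row[:4]
        if not year_cell.isdigit():
            raise RecordIOError(f"{path}:{lineno}: year {year_cell!r} is not an integer")
        if key in pubs:
            raise RecordIOError(f"{path}:{lineno}: duplicate publication key {key!r}")
        recorded = recorded_cell.lower() in ("yes", "true", "1", dialect.missing_marker)
        pubs[key] = Publication(
            key=key, year=int(year_cell),
            citation_text="" if citation_text == dialect.missing_marker else citation_text,
            recorded=recorded,
        )
    return pubs


def write_publications(pubs: dict[str, Publication], path: Union[str, Path],
                       dialect: RecordFileDialect = TSV) -> None:
    with open(path, "w", encoding=dialect.encoding, newline="") as fh:
        writer = csv.writer(fh, delimiter=dialect.delimiter, lineterminator="\n")
        writer.writerow(PUBLICATION_COLUMNS[:4])
        for pub in pubs.values():
            writer.writerow([
                pub.key, pub.year, _cell(pub.citation_text, dialect),
                "yes" if pub.recorded else "no",
            ])


def read_variants(path: Union[str, Path],
                  dialect: RecordFileDialect = TSV) -> VariantTable:
    path = Path(path)
    table = VariantTable()
    for lineno, row in _rows(path, dialect, VARIANT_COLUMNS, min_cols=2):
        variant, canonical, klass = row[0], row[1], _opt(row[2], dialect)
        try:
            table.add(variant, canonical, klass)
        except AmbiguousVariantError as exc:
            raise RecordIOError(f"{path}:{lineno}: {exc}") from exc
    return table


def write_variants(table: VariantTable, path: Union[str, Path],
                   dialect: RecordFileDialect = TSV) -> None:
    with open(path, "w", encoding=dialect.encoding, newline="") as fh:
        writer = csv.writer(fh, delimiter=dialect.delimiter, lineterminator="\n")
        writer.writerow(VARIANT_COLUMNS)
        for variant, canonical, klass in table.items():
            writer.writerow([variant, canonical, _cell(klass, dialect)])


def read_species(path: Union[str, Path],
                 dialect: RecordFileDialect = TSV) -> dict[str, Species]:
    path = Path(path)
    species: dict[str, Species] = {}
    for lineno, row in _rows(path, dialect, SPECIES_COLUMNS, min_cols=3):
        sid, binomial, status, etymology = row[:4]
        if sid in species:
            raise RecordIOError(f"{path}:{lineno}: duplicate species id {sid!r}")
        species[sid] = Species(
            species_id=sid, binomial=binomial, status=status,
            etymology=_opt(etymology, dialect),
        )
    return species


def write_species(species: dict[str, Species], path: Union[str, Path],
                  dialect: RecordFileDialect = TSV) -> None:
    with open(path, "w", encoding=dialect.encoding, newline="") as fh:
        writer = csv.writer(fh, delimiter=dialect.delimiter, lineterminator="\n")
        writer.writerow(SPECIES_COLUMNS)
        for sp in species.values():
            writer.writerow([
                sp.species_id, sp.binomial, sp.status, _cell(sp.etymology, dialect),
            ])


# Conventional file names inside a dataset directory.
USAGES_FILE = "usages.tsv"
PUBLICATIONS_FILE = "publications.tsv"
VARIANTS_FILE = "variants.tsv"
SPECIES_FILE = "species.tsv"


def load_dataset(directory: Union[str, Path],
                 dialect: RecordFileDialect = TSV) -> Dataset:
    """Load the four tables from a dataset directory."""
    directory = Path(directory)
    for name in (USAGES_FILE, PUBLICATIONS_FILE, VARIANTS_FILE, SPECIES_FILE):
        if not (directory / name).exists():
            raise FileNotFoundError(directory / name)
    return Dataset(
        publications=read_publications(directory / PUBLICATIONS_FILE, dialect),
        usages=read_usages(directory / USAGES_FILE, dialect),
        species=read_species(directory / SPECIES_FILE, dialect),
        variants=read_variants(directory / VARIANTS_FILE, dialect),
    )


def write_dataset(dataset: Dataset, directory: Union[str, Path],
                  dialect: RecordFileDialect = TSV) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_usages(dataset.usages, directory / USAGES_FILE, dialect)
    write_publications(dataset.publications, directory / PUBLICATIONS_FILE, dialect)
    write_species(dataset.species, directory / SPECIES_FILE, dialect)
    write_variants(dataset.variants, directory / VARIANTS_FILE, dialect)


def export_json(dataset: Dataset, path: Union[str, Path]) -> None:
    """Single-document JSON export of all four tables."""
    def usage_dict(u: NameUsage) -> dict:
        d = {
            "pub_key": u.pub_key,
            "name_key": u.name_key.raw,
            "name": u.verbatim_name,
            "locus": u.locus,
            "context": u.context.value,
            "accepted": _accepted_cell(u.accepted),
        }
        for attr in ("place", "specimen_id", "notes", "common_name", "species_tag"):
            value = getattr(u, attr)
            if value is not None:
                d[attr] = value
        if u.citation is not None:
            d["cited_pub"] = u.citation.cited_pub
            d["cited_key"] = u.citation.cited_key.raw
        return d

    doc = {
        "publications": [
            {"pub_key": p.key, "year": p.year, "citation": p.citation_text,
             "recorded": p.recorded}
            for p in dataset.publications.values()
        ],
        "usages": [usage_dict(u) for u in dataset.usages],
        "species": [
            {"species_id": s.species_id, "binomial": s.binomial,
             "status": s.status, "etymology": s.etymology}
            for s in dataset.species.values()
        ],
        "variants": [
            {"variant": v, "canonical": c, "class": k}
            for v, c, k in dataset.variants.items()
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2, ensure_ascii=False, sort_keys=True)
        fh.write("\n")
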