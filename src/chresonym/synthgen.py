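"""Synthetic literature networks with planted ground truth.

Generates a citation network of publications over a span of years, each
holding name-usage records in the four context classes, with known
planted species per record, optional taxonomic split events (which
plant citations whose expected resolution is "in part"), and optional
spelling drift registered in the emitted variant table.  Citations
always point to strictly earlier publications, so the network is
acyclic by construction and every expected value is derivable without
running the resolver.

Also houses :func:`oracle_resolve`, a deliberately naive
iterate-to-fixed-point re-implementation of the single-level resolution
rule, used only to cross-check the chronological single-pass resolver.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from .datamodel import (
    AcceptedAssignment,
    AcceptedMode,
    CitationTarget,
    ContextKind,
    Dataset,
    NameKey,
    NameUsage,
    Publication,
    Species,
    parse_name_key,
)
from .nomenclature import VariantTable, names_match
from .resolver import UNKNOWN_SPECIES, CycleError, expand_citation_target

__all__ = ["SynthParams", "GroundTruth", "generate", "oracle_resolve"]

_SYLLABLES = [
    "pug", "nax", "vo", "cans", "bel", "la", "tor", "sig", "na", "tus",
    "mar", "io", "nis", "cra", "ssi", "pes", "dus", "su", "mi", "eri",
    "an", "nu", "li", "chlo", "ro", "phtal", "mus", "te", "tra", "gon",
]


@dataclass(frozen=True)
class SynthParams:
    """Knobs for one synthetic dataset; same params + seed => same bytes."""

    n_publications: int = 30
    year_start: int = 1850
    year_end: int = 1980
    n_species: int = 6
    citation_fraction: float = 0.7
    p_general_citation: float = 0.4
    n_splits: int = 0
    variant_rate: float = 0.0
    records_min: int = 1
    records_max: int = 4
    force_year_ties: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("citation_fraction", "p_general_citation", "variant_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.n_publications < 1:
            raise ValueError("need at least one publication")
        if self.n_species < 1:
            raise ValueError("need at least one species")
        if self.n_publications == 1 and self.citation_fraction > 0:
            raise ValueError("citations requested but only one publication")
        if self.n_splits > 0 and self.n_publications < 3:
            raise ValueError("split events need at least three publications")


@dataclass
class GroundTruth:
    """Planted truths, keyed by "pub|key" strings (JSON-friendly).

    ``species`` maps every record to its planted species;
    ``citations`` maps compute-marked citation records to their
    expected resolution and in-part flag.
    """

    species: dict[str, str] = field(default_factory=dict)
    citations: dict[str, dict] = field(default_factory=dict)

    def to_json(self, path: Union[str, Path]) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"species": self.species, "citations": self.citations},
                      fh, indent=2, sort_keys=True)
            fh.write("\n")


def _make_epithets(rng: random.Random, n: int) -> list[str]:
    epithets: list[str] = []
    seen = set()
    while len(epithets) < n:
        ep = "".join(rng.choice(_SYLLABLES) for _ in range(3))
        if ep not in seen:
            seen.add(ep)
            epithets.append(ep)
    return epithets


def _mutate(rng: random.Random, epithet: str) -> str:
    """Single-character edit; may collide with the input, caller checks."""
    i = rng.randrange(len(epithet))
    if rng.random() < 0.5 and len(epithet) > 4:
        return epithet[:i] + epithet[i + 1:]
    return epithet[:i] + rng.choice("abcdefghijklmnopqrstuvwxyz") + epithet[i + 1:]


def generate(params: SynthParams) -> tuple[Dataset, GroundTruth]:
    """Build a dataset plus its by-construction expected resolutions."""
    rng = random.Random(params.seed)

    epithets = _make_epithets(rng, params.n_species + params.n_splits)
    base_epithets = epithets[:params.n_species]
    split_epithets = epithets[params.n_species:]
    species = {
        ep: Species(species_id=ep, binomial=f"Uca {ep}") for ep in epithets
    }
    variants = VariantTable()
    for ep in epithets:
        variants.add(ep, ep)

    # years: distinct where the range allows, unless ties are forced
    span = params.year_end - params.year_start + 1
    if params.force_year_ties and params.n_publications >= 2:
        pool = [params.year_start + (i // 2) % span for i in range(params.n_publications)]
    elif span >= params.n_publications:
        pool = rng.sample(range(params.year_start, params.year_end + 1),
                          params.n_publications)
    else:
        pool = [rng.randrange(params.year_start, params.year_end + 1)
                for _ in range(params.n_publications)]
    years = sorted(pool)

    key_ids = [f"Pub{i:03d}" for i in range(params.n_publications)]
    rng.shuffle(key_ids)  # keys must not encode chronology
    pubs = [Publication(key=key_ids[i], year=years[i],
                        citation_text=f"Author {key_ids[i]} ({years[i]}) Synthetic title.")
            for i in range(params.n_publications)]

    usages: list[NameUsage] = []
    truth = GroundTruth()
    # (pub_key, base, raw keys, species set, context rows) eligible as targets
    citable: list[dict] = []

    # schedule split events on early publications (never the last one)
    split_origin_idx = {}
    if params.n_splits:
        origin_choices = list(range(max(1, params.n_publications - 2)))
        rng.shuffle(origin_choices)
        for s in range(params.n_splits):
            split_origin_idx[origin_choices[s % len(origin_choices)]] = s

    def variant_name(ep: str) -> str:
        if params.variant_rate and rng.random() < params.variant_rate:
            for _ in range(10):
                mutated = _mutate(rng, ep)
                if mutated != ep and (mutated not in variants
                                      or variants.canonical(mutated) == ep):
                    variants.add(mutated, ep, "typographic")
                    return f"Uca {mutated}"
        return f"Uca {ep}"

    pending_split_citations: list[dict] = []

    for idx, pub in enumerate(pubs):
        next_base = 1
        pub_records: list[NameUsage] = []

        def add(usage: NameUsage, planted: str) -> None:
            pub_records.append(usage)
            truth.species[f"{usage.pub_key}|{usage.name_key.raw}"] = planted

        if idx in split_origin_idx:
            s = split_origin_idx[idx]
            parent = base_epithets[s % params.n_species]
            derived = split_epithets[s]
            base = next_base
            next_base += 1
            for ctx_i, (region, planted) in enumerate(
                    [("Region A", parent), ("Region B", derived)], start=1):
                raw = f"{base}.{ctx_i}"
                add(NameUsage(
                    pub_key=pub.key,
                    name_key=parse_name_key(raw),
                    verbatim_name=f"Uca {parent}",
                    locus=f"p. {10 * ctx_i}",
                    context=ContextKind.LOCATION,
                    accepted=AcceptedAssignment.explicit(planted),
                    place=region,
                ), planted)
            citable.append({
                "pub": pub.key, "raw": str(base), "species": {parent, derived},
                "contexts": [f"{base}.1", f"{base}.2"],
                "verbatim": f"Uca {parent}", "split_parent": parent,
            })
            pending_split_citations.append({
                "pub": pub.key, "base": str(base), "parent": parent,
            })

        n_rec = rng.randint(params.records_min, params.records_max)
        for _ in range(n_rec):
            make_citation = (
                citable and idx > 0 and rng.random() < params.citation_fraction
            )
            base = next_base
            next_base += 1
            raw = str(base)
            if make_citation:
                # only cite earlier publications; prefer single-species groups
                candidates = [c for c in citable if c["pub"] != pub.key
                              and len(c["species"]) == 1]
                if not candidates:
                    make_citation = False
            if make_citation:
                target = rng.choice(candidates)
                planted = next(iter(target["species"]))
                general = rng.random() < params.p_general_citation
                cited_raw = target["raw"] if general else rng.choice(target["contexts"])
                add(NameUsage(
                    pub_key=pub.key,
                    name_key=parse_name_key(raw),
                    verbatim_name=variant_name(planted),
                    locus=f"p. {base}",
                    context=ContextKind.CITATION,
                    accepted=AcceptedAssignment.compute(),
                    citation=CitationTarget(target["pub"], parse_name_key(cited_raw)),
                ), planted)
                truth.citations[f"{pub.key}|{raw}"] = {
                    "species": planted, "in_part": False,
                }
                citable.append({
                    "pub": pub.key, "raw": raw, "species": {planted},
                    "contexts": [raw], "verbatim": f"Uca {planted}",
                })
            else:
                planted = rng.choice(base_epithets)
                kind = rng.choice(
                    [ContextKind.SPECIMEN, ContextKind.LOCATION, ContextKind.NONE]
                )
                place = f"Locality {rng.randrange(1, 20)}" \
                    if kind is not ContextKind.NONE else None
                add(NameUsage(
                    pub_key=pub.key,
                    name_key=parse_name_key(raw),
                    verbatim_name=variant_name(planted),
                    locus=f"p. {base}",
                    context=kind,
                    accepted=AcceptedAssignment.explicit(planted),
                    place=place,
                    specimen_id=(f"Lot {rng.randrange(100, 999)}"
                                 if kind is ContextKind.SPECIMEN else None),
                ), planted)
                citable.append({
                    "pub": pub.key, "raw": raw, "species": {planted},
                    "contexts": [raw], "verbatim": f"Uca {planted}",
                })

        # plant the in-part citation for any split whose origin precedes us
        if idx == params.n_publications - 1 and pending_split_citations:
            for split in pending_split_citations:
                raw = str(next_base)
                next_base += 1
                add(NameUsage(
                    pub_key=pub.key,
                    name_key=parse_name_key(raw),
                    verbatim_name=f"Uca {split['parent']}",
                    locus=f"p. {90 + next_base}",
                    context=ContextKind.CITATION,
                    accepted=AcceptedAssignment.compute(),
                    citation=CitationTarget(split["pub"], parse_name_key(split["base"])),
                ), split["parent"])
                # tie {parent, derived}; citing verbatim matches the parent
                truth.citations[f"{pub.key}|{raw}"] = {
                    "species": split["parent"], "in_part": True,
                }

        usages.extend(pub_records)

    dataset = Dataset(
        publications={p.key: p for p in pubs},
        usages=usages,
        species={s.species_id: s for s in species.values()},
        variants=variants,
    )
    return dataset, truth


def oracle_resolve(
    dataset: Dataset,
    variants: Optional[VariantTable] = None,
) -> dict[int, tuple[tuple[str, ...], bool]]:
    """Fixed-point re-resolution oracle, independent of the single-pass
    resolver's chronological machinery.

    Repeatedly re-applies the pooling/plurality rule to every
    compute-marked citation record until nothing changes.  Returns
    ``{usage list index: (accepted tuple, in_part)}`` for comparison.
    Raises :class:`CycleError` if no fixed point emerges after
    ``len(usages) + 1`` sweeps.
    """
    variants = variants if variants is not None else dataset.variants
    index: dict[str, list[NameUsage]] = {}
    for u in dataset.usages:
        index.setdefault(u.pub_key, []).append(u)

    state: dict[int, tuple[tuple[str, ...], bool]] = {}
    for i, u in enumerate(dataset.usages):
        if u.accepted.mode is AcceptedMode.EXPLICIT:
            state[i] = ((u.accepted.species_id,), False)
        else:
            state[i] = ((UNKNOWN_SPECIES,), False)

    pos = {id(u): i for i, u in enumerate(dataset.usages)}

    def one_step(i: int, u: NameUsage) -> tuple[tuple[str, ...], bool]:
        group = [
            r for r in index.get(u.pub_key, [])
            if r.context is ContextKind.CITATION
            and r.accepted.mode is AcceptedMode.COMPUTE
            and r.name_key.raw == u.name_key.raw
        ]
        pool: list[str] = []
        for entry in group:
            try:
                rows = expand_citation_target(entry.citation, dataset, index)
            except LookupError:
                continue
            for row in rows:
                accepted, _ = state[pos[id(row)]]
                pool.extend(s for s in accepted if s != UNKNOWN_SPECIES)
        if not pool:
            return ((UNKNOWN_SPECIES,), False)
        order: list[str] = []
        counts: dict[str, int] = {}
        for s in pool:
            if s not in counts:
                order.append(s)
            counts[s] = counts.get(s, 0) + 1
        if len(order) == 1:
            return ((order[0],), False)
        top = max(counts.values())
        tied = [s for s in order if counts[s] == top]
        if len(tied) == 1:
            return ((tied[0],), True)
        for s in tied:
            sp = dataset.species.get(s)
            if names_match(u.verbatim_name, sp.binomial if sp else s, variants):
                return ((s,), True)
        return ((tied[0],), True)

    compute_rows = [
        (i, u) for i, u in enumerate(dataset.usages)
        if u.accepted.mode is AcceptedMode.COMPUTE
    ]
    for _ in range(len(dataset.usages) + 1):
        changed = False
        for i, u in compute_rows:
            new = one_step(i, u)
            if new != state[i]:
                state[i] = new
                changed = True
        if not changed:
            return state
    raise CycleError([u.pub_key for _, u in compute_rows])
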