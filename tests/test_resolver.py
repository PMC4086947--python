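import dataclasses

import pytest

from chresonym.datamodel import (
    AcceptedAssignment,
    CitationTarget,
    ContextKind,
    Dataset,
    NameUsage,
    Publication,
    Species,
    parse_name_key,
)
from chresonym.nomenclature import VariantTable
from chresonym.resolver import (
    UNKNOWN_SPECIES,
    ChronologyError,
    CycleError,
    DanglingTargetError,
    Edit,
    EditError,
    apply_edits,
    chronological_order,
    expand_citation_target,
    resolve_all,
    update_and_repropagate,
)


def _pub(key, year):
    return Publication(key, year, f"{key} ({year})")


def _loc(pub, key, name, species, place="Somewhere"):
    return NameUsage(
        pub_key=pub, name_key=parse_name_key(key), verbatim_name=name,
        locus="p. 1", context=ContextKind.LOCATION,
        accepted=AcceptedAssignment.explicit(species), place=place,
    )


def _cite(pub, key, name, cited_pub, cited_key, accepted="="):
    if accepted == "=":
        assignment = AcceptedAssignment.compute()
    else:
        assignment = AcceptedAssignment.explicit(accepted)
    return NameUsage(
        pub_key=pub, name_key=parse_name_key(key), verbatim_name=name,
        locus="p. 1", context=ContextKind.CITATION, accepted=assignment,
        citation=CitationTarget(cited_pub, parse_name_key(cited_key)),
    )


def _species(*ids):
    return {s: Species(s, f"Uca {s}") for s in ids}


def _dataset(pubs, usages, species, variants=None):
    return Dataset(
        publications={p.key: p for p in pubs},
        usages=usages,
        species=species,
        variants=variants or VariantTable(),
    )


class TestExpandCitationTarget:
    def test_base_only_expands_to_all_contexts(self, macnae):
        target = CitationTarget("Macnae1966", parse_name_key("3"))
        rows = expand_citation_target(target, macnae)
        assert [r.name_key.raw for r in rows] == ["3.1", "3.2"]
        assert {r.verbatim_name for r in rows} == {"Uca bellator"}

    def test_specific_context_expands_to_one(self, macnae):
        target = CitationTarget("Macnae1966", parse_name_key("3.1"))
        rows = expand_citation_target(target, macnae)
        assert len(rows) == 1
        assert rows[0].context is ContextKind.LOCATION

    def test_zero_key_is_empty(self, macnae):
        target = CitationTarget("Macnae1966", parse_name_key("0"))
        assert expand_citation_target(target, macnae) == []

    def test_missing_key_is_empty(self, macnae):
        target = CitationTarget("Macnae1966", parse_name_key("."))
        assert expand_citation_target(target, macnae) == []

    def test_dangling_specific_target_raises(self, macnae):
        target = CitationTarget("Hess1865", parse_name_key("9.1"))
        with pytest.raises(DanglingTargetError):
            expand_citation_target(target, macnae)


class TestResolveCitation:
    def test_macnae_record_b_resolves_to_signata(self, macnae):
        resolution = resolve_all(macnae)
        record_b = next(u for u in macnae.usages if u.name_key.raw == "3.2")
        r = resolution[record_b]
        assert r.accepted == ("signata",)
        assert r.in_part is False
        assert r.provenance == (("Hess1865", "2", "signata"),)

    def test_single_context_copies_species(self):
        pubs = [_pub("A1900", 1900), _pub("B1950", 1950)]
        usages = [
            _loc("A1900", "1", "Uca x", "x"),
            _cite("B1950", "1", "Uca x", "A1900", "1"),
        ]
        res = resolve_all(_dataset(pubs, usages, _species("x")))
        assert res[usages[1]].accepted == ("x",)
        assert res[usages[1]].in_part is False

    def test_plurality_wins_with_in_part(self):
        # pool {x, x, y}: x has the plurality
        pubs = [_pub("A1900", 1900), _pub("B1950", 1950)]
        usages = [
            _loc("A1900", "1.1", "Uca x", "x"),
            _loc("A1900", "1.2", "Uca x", "x"),
            _loc("A1900", "1.3", "Uca x", "y"),
            _cite("B1950", "1", "Uca x", "A1900", "1"),
        ]
        res = resolve_all(_dataset(pubs, usages, _species("x", "y")))
        r = res[usages[3]]
        assert r.accepted == ("x",)
        assert r.in_part is True

    def test_tie_broken_by_name_match_with_variant(self):
        # pool {x, y} tied; citing name is a spelling variant of y
        pubs = [_pub("A1900", 1900), _pub("B1950", 1950)]
        usages = [
            _loc("A1900", "1.1", "Uca xerus", "xerus"),
            _loc("A1900", "1.2", "Uca yalta", "yalta"),
            _cite("B1950", "1", "Gelasimus yaltus", "A1900", "1"),
        ]
        variants = VariantTable([("yaltus", "yalta")])
        res = resolve_all(_dataset(pubs, usages, _species("xerus", "yalta"), variants))
        r = res[usages[2]]
        assert r.accepted == ("yalta",)
        assert r.in_part is True

    def test_unbroken_tie_falls_back_to_first_appearance(self):
        pubs = [_pub("A1900", 1900), _pub("B1950", 1950)]
        usages = [
            _loc("A1900", "1.1", "Uca other", "yalta"),
            _loc("A1900", "1.2", "Uca other", "xerus"),
            _cite("B1950", "1", "Uca zed", "A1900", "1"),
        ]
        res = resolve_all(_dataset(pubs, usages, _species("xerus", "yalta", "zed")))
        r = res[usages[2]]
        assert r.accepted == ("yalta",)  # first in cited-context order
        assert r.in_part is True

    def test_general_zero_citation_resolves_unknown(self):
        pubs = [_pub("A1900", 1900), _pub("B1950", 1950)]
        usages = [
            _loc("A1900", "1", "Uca x", "x"),
            _cite("B1950", "1", "Uca x", "A1900", "0"),
        ]
        res = resolve_all(_dataset(pubs, usages, _species("x")))
        r = res[usages[1]]
        assert r.accepted == (UNKNOWN_SPECIES,)
        assert r.in_part is False
        assert r.provenance == ()

    def test_all_unknown_pool_is_unknown_without_in_part(self):
        pubs = [_pub("A1900", 1900), _pub("B1950", 1950)]
        unknown_row = NameUsage(
            pub_key="A1900", name_key=parse_name_key("1"),
            verbatim_name="Uca x", locus="p. 1",
            context=ContextKind.NONE, accepted=AcceptedAssignment.unknown(),
        )
        usages = [unknown_row, _cite("B1950", "1", "Uca x", "A1900", "1")]
        res = resolve_all(_dataset(pubs, usages, _species("x")))
        r = res[usages[1]]
        assert r.accepted == (UNKNOWN_SPECIES,)
        assert r.in_part is False

    def test_unknowns_do_not_defeat_known_names(self):
        pubs = [_pub("A1900", 1900), _pub("B1950", 1950)]
        unknown_row = NameUsage(
            pub_key="A1900", name_key=parse_name_key("1.1"),
            verbatim_name="Uca x", locus="p. 1",
            context=ContextKind.NONE, accepted=AcceptedAssignment.unknown(),
        )
        usages = [
            unknown_row,
            _loc("A1900", "1.2", "Uca x", "x"),
            _cite("B1950", "1", "Uca x", "A1900", "1"),
        ]
        res = resolve_all(_dataset(pubs, usages, _species("x")))
        r = res[usages[2]]
        assert r.accepted == ("x",)
        assert r.in_part is False  # only one distinct known name in the pool

    def test_grouped_citation_entries_pool_together(self):
        # one citing name key, two independent citation entries
        pubs = [_pub("A1900", 1900), _pub("B1920", 1920), _pub("C1950", 1950)]
        usages = [
            _loc("A1900", "1", "Uca x", "x"),
            _loc("B1920", "1", "Uca x", "x"),
            _loc("B1920", "2", "Uca y", "y"),
            _cite("C1950", "1", "Uca x", "A1900", "1"),
            _cite("C1950", "1", "Uca x", "B1920", "1"),
        ]
        res = resolve_all(_dataset(pubs, usages, _species("x", "y")))
        for row in usages[3:]:
            assert res[row].accepted == ("x",)
            assert len(res[row].provenance) == 2


class TestResolveAll:
    def test_three_level_chain_single_pass(self):
        pubs = [_pub("C1930", 1930), _pub("B1940", 1940), _pub("A1950", 1950)]
        usages = [
            _loc("C1930", "1", "Uca x", "x"),
            _cite("B1940", "1", "Uca x", "C1930", "1"),
            _cite("A1950", "1", "Uca x", "B1940", "1"),
        ]
        res = resolve_all(_dataset(pubs, usages, _species("x")))
        assert res[usages[1]].accepted == ("x",)
        assert res[usages[2]].accepted == ("x",)

    def test_no_citations_is_passthrough(self, macnae):
        ds = Dataset(
            publications=dict(macnae.publications),
            usages=[u for u in macnae.usages if u.context is not ContextKind.CITATION],
            species=dict(macnae.species),
            variants=macnae.variants,
        )
        res = resolve_all(ds)
        for u in ds.usages:
            assert res[u].accepted == (u.accepted.species_id,)
            assert res[u].in_part is False

    def test_gould_style_duplicate_cited_generally(self):
        # one name recorded twice for two species; a general citation ties
        pubs = [_pub("Gould1841", 1841), _pub("Later1900", 1900)]
        dup1 = dataclasses.replace(
            _loc("Gould1841", "1", "Gelasimus vocans", "pugilator",
                 "Massachusetts"), species_tag="pugilator")
        dup2 = dataclasses.replace(
            _loc("Gould1841", "1", "Gelasimus vocans", "pugnax",
                 "Massachusetts"), species_tag="pugnax")
        citing = _cite("Later1900", "1", "Uca pugnax", "Gould1841", "1")
        ds = _dataset(pubs, [dup1, dup2, citing],
                      _species("pugilator", "pugnax"))
        res = resolve_all(ds)
        r = res[citing]
        assert r.accepted == ("pugnax",)  # step 5: citing name matches
        assert r.in_part is True

    def test_order_independence_over_linear_extensions(self):
        import itertools
        pubs = [_pub("A1900", 1900), _pub("B1920", 1920),
                _pub("C1940", 1940), _pub("D1960", 1960)]
        usages = [
            _loc("A1900", "1", "Uca x", "x"),
            _loc("B1920", "1", "Uca y", "y"),
            _cite("C1940", "1", "Uca x", "A1900", "1"),
            _cite("D1960", "1", "Uca y", "B1920", "1"),
        ]
        ds = _dataset(pubs, usages, _species("x", "y"))
        baseline = resolve_all(ds)
        # every order in which cited precedes citer
        for order in itertools.permutations(["A1900", "B1920", "C1940", "D1960"]):
            if order.index("A1900") < order.index("C1940") \
                    and order.index("B1920") < order.index("D1960"):
                res = resolve_all(ds, pub_order=list(order))
                for u in usages:
                    assert res[u].accepted == baseline[u].accepted
                    assert res[u].in_part == baseline[u].in_part

    def test_anti_anachronism_forward_citation_contributes_nothing(self):
        pubs = [_pub("A1950", 1950), _pub("B1900", 1900)]
        usages = [
            _loc("A1950", "1", "Uca x", "x"),
            _cite("B1900", "1", "Uca x", "A1950", "1"),
        ]
        res = resolve_all(_dataset(pubs, usages, _species("x")))
        assert res[usages[1]].accepted == (UNKNOWN_SPECIES,)
        assert any("forward" in w for w in res.warnings)

    def test_same_year_acyclic_citation_is_resolved(self):
        pubs = [_pub("A1950", 1950), _pub("B1950", 1950)]
        usages = [
            _loc("B1950", "1", "Uca x", "x"),
            _cite("A1950", "1", "Uca x", "B1950", "1"),
        ]
        res = resolve_all(_dataset(pubs, usages, _species("x")))
        assert res[usages[1]].accepted == ("x",)

    def test_same_year_cycle_raises(self):
        pubs = [_pub("A1950", 1950), _pub("B1950", 1950)]
        usages = [
            _cite("A1950", "1", "Uca x", "B1950", "1"),
            _cite("B1950", "1", "Uca x", "A1950", "1"),
        ]
        with pytest.raises(CycleError) as err:
            resolve_all(_dataset(pubs, usages, _species("x")))
        assert set(err.value.members) == {"A1950", "B1950"}

    def test_chronological_order_breaks_ties_lexicographically(self):
        pubs = [_pub("B1950", 1950), _pub("A1950", 1950), _pub("C1900", 1900)]
        ds = _dataset(pubs, [], {})
        assert chronological_order(ds) == ["C1900", "A1950", "B1950"]

    def test_dangling_target_logged_not_fatal(self):
        pubs = [_pub("A1900", 1900), _pub("B1950", 1950)]
        usages = [
            _loc("A1900", "1", "Uca x", "x"),
            _cite("B1950", "1", "Uca x", "A1900", "7.1"),
        ]
        res = resolve_all(_dataset(pubs, usages, _species("x")))
        assert res[usages[1]].accepted == (UNKNOWN_SPECIES,)
        assert res.warnings


class TestUpdateAndRepropagate:
    def _red_sea_dataset(self):
        pubs = [_pub("Base1880", 1880), _pub("Mid1920", 1920),
                _pub("Late1960", 1960)]
        usages = [
            _loc("Base1880", "1", "Uca annulipes", "annulipes", "Red Sea"),
            _cite("Mid1920", "1", "Uca annulipes", "Base1880", "1"),
            _cite("Late1960", "1", "Uca annulipes", "Mid1920", "1"),
        ]
        return _dataset(pubs, usages, _species("annulipes", "albimana"))

    def test_base_edit_propagates_downstream(self):
        ds = self._red_sea_dataset()
        res = update_and_repropagate(
            ds, [Edit("Base1880", "1", "albimana")])
        for u in res:
            assert res[u].accepted == ("albimana",)

    def test_empty_edit_list_is_identity(self):
        ds = self._red_sea_dataset()
        before = resolve_all(ds)
        after = update_and_repropagate(ds, [])
        for u, r in before.items():
            assert after[u].accepted == r.accepted

    def test_edit_then_revert_restores(self):
        ds = self._red_sea_dataset()
        edited = apply_edits(ds, [Edit("Base1880", "1", "albimana")])
        reverted = apply_edits(edited, [Edit("Base1880", "1", "annulipes")])
        before = {(u.pub_key, u.name_key.raw): r.accepted
                  for u, r in resolve_all(ds).items()}
        after = {(u.pub_key, u.name_key.raw): r.accepted
                 for u, r in resolve_all(reverted).items()}
        assert before == after

    def test_edit_on_citation_record_rejected(self):
        ds = self._red_sea_dataset()
        with pytest.raises(EditError):
            apply_edits(ds, [Edit("Mid1920", "1", "albimana")])

    def test_edit_on_missing_record_rejected(self):
        ds = self._red_sea_dataset()
        with pytest.raises(EditError):
            apply_edits(ds, [Edit("Nope1800", "1", "albimana")])

    def test_original_dataset_untouched(self):
        ds = self._red_sea_dataset()
        update_and_repropagate(ds, [Edit("Base1880", "1", "albimana")])
        assert ds.usages[0].accepted.species_id == "annulipes"


class TestRejectedDrillDownForContrast:
    """The recursive drill-to-basal-works algorithm, reimplemented here
    only to document why it was rejected: a long list of citations in an
    early compendium overrides the narrow species the citing author
    meant."""

    @staticmethod
    def _drill(usage, ds, seen=None):
        from chresonym.resolver import expand_citation_target
        seen = seen or set()
        if usage.accepted.species_id is not None:
            return [usage.accepted.species_id]
        if usage.citation is None or id(usage) in seen:
            return []
        seen = seen | {id(usage)}
        pool = []
        for row in expand_citation_target(usage.citation, ds):
            pool.extend(TestRejectedDrillDownForContrast._drill(row, ds, seen))
        return pool

    def test_drill_down_disagrees_with_single_pass(self):
        # compendium C lumps two species under one name; later author B
        # narrows it to one context; A cites B.
        pubs = [_pub("C1800", 1800), _pub("B1900", 1900), _pub("A1950", 1950)]
        usages = [
            _loc("C1800", "1.1", "Cancer vocans", "x"),
            _loc("C1800", "1.2", "Cancer vocans", "y"),
            _loc("C1800", "1.3", "Cancer vocans", "y"),
            _cite("B1900", "1", "Uca x", "C1800", "1.1"),
            _cite("A1950", "1", "Uca x", "B1900", "1"),
        ]
        ds = _dataset(pubs, usages, _species("x", "y"))
        res = resolve_all(ds)
        # single chronological pass keeps the narrow meaning
        assert res[usages[4]].accepted == ("x",)
        # drilling through B down into C's full lists would pull in y
        drill_pool = self._drill(usages[4], ds)
        assert drill_pool == ["x"]  # narrow here because B cited one context
        wide = _cite("A1950", "2", "Uca x", "C1800", "1")
        ds2 = _dataset(pubs, usages + [wide], _species("x", "y"))
        res2 = resolve_all(ds2)
        drill_wide = self._drill(wide, ds2)
        # drill-down sees {x, y, y}: majority y, the lumped compendium wins
        assert sorted(drill_wide) == ["x", "y", "y"]
        # the adopted algorithm still reports y only via the in-part flag
        assert res2[wide].accepted == ("y",)
        assert res2[wide].in_part is True
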