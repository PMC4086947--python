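"""Small worked-example datasets drawn from the fiddler-crab literature.

These are real historical usages (Macnae 1966, Hess 1865, Kingsley 1880,
Alcock 1900) encoded by hand; they double as documentation of the record
layout and as ground truth for tests: Macnae's *Uca bellator* appears in
two contexts, one a citation of Hess's *Gelasimus signatus* that must
resolve to *Uca signata*, and Alcock's *Gelasimus inversus* ends up
applied to two currently recognized species.
"""

from __future__ import annotations

from .datamodel import (
    AcceptedAssignment,
    CitationTarget,
    ContextKind,
    Dataset,
    NameUsage,
    Publication,
    Species,
    parse_name_key,
)
from .nomenclature import VariantTable

__all__ = ["macnae_example", "inversus_example"]


def _usage(pub, key, name, locus, context, accepted, *, place=None,
           specimen_id=None, cite=None, notes=None) -> NameUsage:
    citation = None
    if cite is not None:
        cited_pub, cited_key = cite
        citation = CitationTarget(cited_pub, parse_name_key(cited_key))
    if accepted == "=":
        assignment = AcceptedAssignment.compute()
    elif accepted == "?":
        assignment = AcceptedAssignment.unknown()
    else:
        assignment = AcceptedAssignment.explicit(accepted)
    return NameUsage(
        pub_key=pub,
        name_key=parse_name_key(key),
        verbatim_name=name,
        locus=locus,
        context=context,
        accepted=assignment,
        place=place,
        specimen_id=specimen_id,
        citation=citation,
        notes=notes,
    )


def macnae_example() -> Dataset:
    """Macnae 1966 + Hess 1865 + King & Siddall: eight usage records.

    Macnae uses *Uca bellator* in two contexts — a Queensland location
    (accepted *Uca signata*) and a citation of Hess's name #2,
    *Gelasimus signatus*, marked for computation.  King & Siddall's
    *Uca pugilator* record has no usable context.
    """
    publications = {
        "Hess1865": Publication(
            "Hess1865", 1865,
            "Hess, W. (1865) Beiträge zur Kenntniss der Decapoden-Krebse "
            "Ost-Australiens.",
        ),
        "Macnae1966": Publication(
            "Macnae1966", 1966,
            "Macnae, W. (1966) Mangroves in eastern and southern Australia.",
        ),
        "KingSiddall1969": Publication(
            "KingSiddall1969", 1969,
            "King, D.S. & Siddall, J.B. (1969) Conversion of alpha-ecdysone "
            "to beta-ecdysone by crustaceans and insects.",
        ),
    }
    species = {
        sid: Species(sid, binomial)
        for sid, binomial in [
            ("signata", "Uca signata"),
            ("dussumieri", "Uca dussumieri"),
            ("longidigitum", "Uca longidigitum"),
            ("polita", "Uca polita"),
            ("flammula", "Uca flammula"),
            ("pugilator", "Uca pugilator"),
            ("bellator", "Uca bellator"),
        ]
    }
    variants = VariantTable([
        ("signatus", "signata"),
        ("coarctatus", "coarctata"),
        ("coartatus", "coarctata"),
        ("corctata", "coarctata"),
    ])
    usages = [
        _usage("Hess1865", "2", "Gelasimus signatus", "p. 146, pl. 6 fig. 8",
               ContextKind.SPECIMEN, "signata",
               place="Sydney, Australia",
               notes="type description"),
        _usage("Macnae1966", "1", "Uca dussumieri", "p. 82",
               ContextKind.LOCATION, "dussumieri",
               place="Eastern Queensland, Australia"),
        _usage("Macnae1966", "2", "Uca longidigitum", "p. 82",
               ContextKind.LOCATION, "longidigitum",
               place="Eastern Queensland, Australia"),
        # record A: the name applied to a location
        _usage("Macnae1966", "3.1", "Uca bellator", "p. 82",
               ContextKind.LOCATION, "signata",
               place="Eastern Queensland, Australia"),
        # record B: the same name applied to Hess's name #2
        _usage("Macnae1966", "3.2", "Uca bellator", "p. 82",
               ContextKind.CITATION, "=",
               cite=("Hess1865", "2")),
        # record E: undescribed species, later named Uca polita
        _usage("Macnae1966", "4", "Uca unnamed sp. (pink claw)", "p. 83",
               ContextKind.LOCATION, "polita",
               place="Eastern Queensland, Australia"),
        # record F: undescribed species with red legs, now Uca flammula
        _usage("Macnae1966", "5", "Uca unnamed sp.", "p. 83",
               ContextKind.LOCATION, "flammula",
               place="Darwin, Australia",
               notes="red legs"),
        # record D: no usable context; authors' lab location implausible
        _usage("KingSiddall1969", "1", "Uca pugilator", "p. 37",
               ContextKind.NONE, "pugilator",
               notes="no collection locality given; lab location implausible "
                     "for this species"),
    ]
    return Dataset(publications=publications, usages=usages,
                   species=species, variants=variants)


def inversus_example() -> Dataset:
    """Alcock 1900 applies *Gelasimus inversus* both to his own material
    and to Kingsley 1880's *Gelasimus smithii* — two species today."""
    publications = {
        "Kingsley1880": Publication(
            "Kingsley1880", 1880,
            "Kingsley, J.S. (1880) Carcinological notes, No. II. Revision of "
            "the Gelasimi.",
        ),
        "Alcock1900": Publication(
            "Alcock1900", 1900,
            "Alcock, A. (1900) Materials for a carcinological fauna of India, "
            "No. 6. The Brachyura Catometopa, or Grapsoidea.",
        ),
    }
    species = {
        "inversa": Species("inversa", "Uca inversa"),
        "chlorophthalmus": Species("chlorophthalmus", "Uca chlorophthalmus"),
    }
    variants = VariantTable([
        ("inversus", "inversa"),
        ("smithii", "smithii"),
    ])
    usages = [
        _usage("Kingsley1880", "1", "Gelasimus smithii", "p. 151",
               ContextKind.SPECIMEN, "chlorophthalmus",
               place="Zanzibar"),
        _usage("Alcock1900", "1.1", "Gelasimus inversus", "p. 360",
               ContextKind.LOCATION, "inversa",
               place="Karachi"),
        _usage("Alcock1900", "1.2", "Gelasimus inversus", "p. 360",
               ContextKind.CITATION, "=",
               cite=("Kingsley1880", "1")),
    ]
    return Dataset(publications=publications, usages=usages,
                   species=species, variants=variants)
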