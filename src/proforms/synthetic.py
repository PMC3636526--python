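"""Deterministic test-data generators.

Two generators live here:

* :func:`spindle_fixture` — a self-contained reconstruction of the
  spindle-checkpoint corner of a protein-form ontology: the BUB-like
  family (BUB1, BUB1B, MAD3) with Pfam domain cross-references, the four
  multiply-phosphorylated BUB1B forms and their human/frog children, the
  mitotic checkpoint complex and the BUB1-containing complexes,
  kinetochore/centromere annotation lines (including the
  modifier-carrying lines that record how phosphorylation changes a
  form's functions), and a three-species gapped BUB1B alignment whose
  pinned columns realize the curated human/frog/mouse phosphosite
  correspondences.  The builder is fully deterministic: building twice
  yields byte-identical files.

* :func:`random_fixture` — seeded random ontologies with the same
  statistical shape (family → gene → organism gene → phospho-form DAG,
  localization annotations with modifiers, physical-interaction lines,
  kinase comments) for oracle-equivalence property tests.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .conservation import (
    Alignment,
    FormSite,
    ModForm,
    ModSite,
    write_alignment_fasta,
    write_forms_tsv,
    write_registry_tsv,
    write_sites_tsv,
)
from .graph import OntologyGraph
from .obo import ProTerm, write_obo
from .paf import NO_MODIFIER, PafRecord, write_paf

__all__ = ["SpindleFixture", "spindle_fixture", "build_spindle_fixture", "random_fixture"]

# ---------------------------------------------------------------------------
# accession book-keeping for the spindle fixture
#
# Printed accessions are used where the source figures give them; entities
# the figures name without an accession get ids in the reserved synthetic
# namespace PR:9000000xx so they cannot collide with real terms.

IDS = {
    "protein": "PR:000000001",
    "family_bub1_bub1b": "PR:000035665",
    "mad3": "PR:000035499",
    "bub1": "PR:000004854",
    "bub1b": "PR:000004855",
    "bub3": "PR:000004856",
    "bub1b_iso1": "PR:000028795",
    # organism-specific gene-level terms
    "h_bub1": "PR:000035400",
    "y_bub1": "PR:000035402",
    "sp_bub1": "PR:000035570",
    "h_bub3": "PR:000026899",
    "y_bub3": "PR:000035532",
    "sp_bub3": "PR:000035571",
    "h_bub1b": "PR:000026903",
    "f_bub1b": "PR:900000011",
    "m_bub1b": "PR:900000012",
    "h_mad1l1": "PR:000035474",
    "h_mad2l1": "PR:900000013",
    "h_cdc20": "PR:900000014",
    "h_aurkb": "PR:000035358",
    "h_plk1": "PR:000035455",
    "h_apc": "PR:000030190",
    "h_cenpe": "PR:000035367",
    "h_sgol1": "PR:000035551",
    "h_dvl2": "PR:000035487",
    "h_casc5": "PR:900000015",
    "h_ttk": "PR:900000016",
    "h_atm": "PR:900000017",
    "h_cdk1": "PR:900000018",
    "h_pp2a": "PR:900000019",
    "h_h3": "PR:900000028",
    "h_h2a": "PR:900000029",
    "h_birc5": "PR:900000037",
    "h_incenp": "PR:900000038",
    "h_cdca8": "PR:900000039",
    "h_cenpa": "PR:900000040",
    # BUB1B phosphorylated forms
    "p1": "PR:000035361",
    "p2": "PR:000035427",
    "p3": "PR:000035431",
    "p4": "PR:000035434",
    "h_p1": "PR:000035362",
    "f_p1": "PR:000035426",
    "h_p2": "PR:000035428",
    "f_p2": "PR:000035430",
    "h_p3": "PR:000035432",
    "f_p3": "PR:000035433",
    "h_p4": "PR:000035435",
    # other modification-level terms
    "h_bub1b_unphos": "PR:000035373",
    "h_bub1_unphos": "PR:900000031",
    "h_cdc20_unphos": "PR:000035369",
    "h_aurkb_unphos": "PR:000035661",
    "h_bub1_p7": "PR:000035412",
    "h_bub1_p8": "PR:000035418",
    "h_apc_p1": "PR:000030182",
    "h_cdc20_p1": "PR:900000032",
    "h_aurkb_p1": "PR:900000033",
    "h_atm_p2": "PR:900000034",
    "h_h2a_p2": "PR:900000035",
    "h_h3t3ph": "PR:900000036",
    # complexes
    "go_macromolecular": "GO:0032991",
    "go_protein_complex": "GO:0043234",
    "go_mcc": "GO:0033597",
    "h_mcc": "PR:000035511",
    "bub1_bub3": "PR:000035566",
    "h_bub1_bub3": "PR:900000041",
    "y_bub1_bub3": "PR:900000042",
    "sp_bub1_bub3": "PR:900000043",
    "bub1_bub3_mad1l1": "PR:000035567",
    "bub1_bub3_apc": "PR:000035576",
    "bub1_bub1b": "PR:000035578",
    "h_bub1_bub1b_unphos": "PR:000035579",
    "h_bub1_bub1b_p2": "PR:000035577",
    "bub1_plk1": "PR:000035580",
    "h_phosbub1_plk1": "PR:000035581",
    "h_bub1b_pp2a": "PR:900000051",
    "h_bub1b_cenpe": "PR:900000052",
    "h_bub1b_sgol1": "PR:900000053",
    "h_bub1b_casc5": "PR:900000054",
    "h_bub1b_aurkb": "PR:900000055",
}

HUMAN, FROG, MOUSE = "BUB1B_human", "BUB1B_frog", "BUB1B_mouse"

#: curated human/frog/mouse phosphosite correspondences the alignment must
#: realize (human position -> (frog, mouse); None = gap / lost in species)
CORRESPONDENCES: dict[int, tuple[int | None, int | None]] = {
    608: (593, 601),
    620: (605, 613),
    670: (649, 659),
    676: (655, 665),
    680: (659, 669),
    543: (528, 535),    # frog position aligns but the residue differs
    1043: (None, 1033),  # frog alignment gap, site lost
}

_AA = "ACDEFGHIKLMNPQRSTVWY"
_HUMAN_LEN = 1050
_PINNED = {543: "S", 608: "T", 620: "T", 670: "S", 676: "S", 680: "T",
           792: "T", 1008: "T", 1043: "S"}
_FROG_GAPS = set(range(50, 65)) | set(range(630, 636)) | set(range(1020, 1051))
_MOUSE_GAPS = set(range(30, 38)) | set(range(640, 644))
_MOUSE_INSERTIONS = (560, 900)  # extra mouse residue after these human positions


def _build_alignment() -> Alignment:
    rng = random.Random(20130426)
    human, frog, mouse = [], [], []
    for hpos in range(1, _HUMAN_LEN + 1):
        res = _PINNED.get(hpos) or rng.choice(_AA)
        human.append(res)
        frog.append("-" if hpos in _FROG_GAPS else ("A" if hpos == 543 else res))
        mouse.append("-" if hpos in _MOUSE_GAPS else res)
        if hpos in _MOUSE_INSERTIONS:
            human.append("-")
            frog.append("-")
            mouse.append(rng.choice(_AA))
    aln = Alignment(
        [(HUMAN, "".join(human)), (FROG, "".join(frog)), (MOUSE, "".join(mouse))]
    )
    # internal consistency: every curated correspondence must be realized,
    # which also guarantees per-pair monotonicity
    for hpos, (fpos, mpos) in CORRESPONDENCES.items():
        got_m = aln.map_position(HUMAN, hpos, MOUSE)
        if got_m != mpos:
            raise AssertionError(f"human {hpos} -> mouse {got_m}, expected {mpos}")
        if fpos is not None and aln.map_position(HUMAN, hpos, FROG) != fpos:
            raise AssertionError(f"human {hpos} -> frog mismatch")
    return aln


# ---------------------------------------------------------------------------
# term construction helpers


def _term(
    key: str,
    name: str,
    category: str,
    definition: str = "",
    taxon: int | None = None,
    is_a: Iterable[str] = (),
    parts: Iterable[str] = (),
    xrefs: Iterable[str] = (),
    comment: str = "",
    synonyms: Iterable[str] = (),
) -> ProTerm:
    relations: list[tuple[str, str]] = [("is_a", IDS.get(p, p)) for p in is_a]
    relations += [("has_part", IDS.get(p, p)) for p in parts]
    if taxon is not None:
        relations.append(("only_in_taxon", f"NCBITaxon:{taxon}"))
    return ProTerm(
        term_id=IDS.get(key, key),
        name=name,
        definition=definition,
        comment=comment,
        category=category,
        synonyms=list(synonyms),
        xrefs=list(xrefs),
        relations=relations,
        taxon_id=taxon,
    )


_BUB1 = "mitotic checkpoint serine/threonine-protein kinase BUB1"
_BUB1B = "mitotic checkpoint serine/threonine-protein kinase BUB1 beta"
_CDK1_KIN = 'Kinase = "CDK1"; PR:900000018.'
_PLK1_KIN = 'Kinase = "PLK1"; PR:000035455.'
_P3_COMMENT = (
    "One of the articles cited mentions BUBR1 (PR:000026903) as the kinase "
    "when bound to CENPE (PR:000035367)."
)


def _spindle_terms() -> list[ProTerm]:
    t: list[ProTerm] = []

    t.append(_term("protein", "protein", "family",
                   "A biological macromolecule translated from an mRNA."))
    t.append(_term(
        "family_bub1_bub1b", "BUB1/BUB1B family protein", "family",
        "A protein with an N-terminal MAD3/BUB1 homology (TPR) domain and a "
        "C-terminal protein kinase domain. Members of this class are related "
        "to MAD3.",
        is_a=["protein"], xrefs=["PFAM:PF08311", "PFAM:PF00069"],
    ))
    t.append(_term(
        "mad3", "mitotic spindle checkpoint protein MAD3", "gene",
        "A spindle checkpoint protein with an N-terminal MAD3/BUB1 homology "
        "(TPR) domain and no kinase domain.",
        is_a=["protein"], xrefs=["PFAM:PF08311"], synonyms=["MAD3"],
    ))
    t.append(_term("bub1", _BUB1, "gene",
                   "A BUB1/BUB1B family protein that is a bona fide protein "
                   "kinase and generates the spindle checkpoint signal at "
                   "kinetochores.",
                   is_a=["family_bub1_bub1b"], synonyms=["BUB1"]))
    t.append(_term("bub1b", _BUB1B, "gene",
                   "A BUB1/BUB1B family protein, likely a pseudokinase, that "
                   "is a component of the mitotic checkpoint complex.",
                   is_a=["family_bub1_bub1b"], synonyms=["BUB1B", "BubR1"]))
    t.append(_term("bub3", "mitotic checkpoint protein BUB3", "gene",
                   "A WD-repeat spindle checkpoint protein that binds BUB1 "
                   "and BUB1B.",
                   is_a=["protein"], synonyms=["BUB3"]))
    t.append(_term("bub1b_iso1", f"{_BUB1B} isoform 1", "sequence",
                   "A BUB1B protein with the canonical translation product "
                   "sequence.", is_a=["bub1b"], synonyms=["BUB1B iso:1"]))

    def organism_gene(key, base, short, taxon, parent="protein", definition=""):
        label = {9606: "human", 10090: "mouse", 8355: "frog",
                 4932: "budding yeast", 4896: "fission yeast"}[taxon]
        t.append(_term(key, f"{base} ({label})", "organism-gene",
                       definition or f"A {base} in {label}.",
                       taxon=taxon, is_a=[parent], synonyms=[short]))

    organism_gene("h_bub1", _BUB1, "hBUB1", 9606, "bub1")
    organism_gene("y_bub1", _BUB1, "yBUB1", 4932, "bub1")
    organism_gene("sp_bub1", _BUB1, "SpomBUB1", 4896, "bub1")
    organism_gene("h_bub3", "mitotic checkpoint protein BUB3", "hBUB3", 9606, "bub3")
    organism_gene("y_bub3", "mitotic checkpoint protein BUB3", "yBUB3", 4932, "bub3")
    organism_gene("sp_bub3", "mitotic checkpoint protein BUB3", "SpomBUB3", 4896, "bub3")
    organism_gene("h_bub1b", _BUB1B, "hBUB1B", 9606, "bub1b")
    organism_gene("f_bub1b", _BUB1B, "fBUB1B", 8355, "bub1b")
    organism_gene("m_bub1b", _BUB1B, "mBUB1B", 10090, "bub1b")
    organism_gene("h_mad1l1", "mitotic spindle assembly checkpoint protein MAD1", "hMAD1L1", 9606)
    organism_gene("h_mad2l1", "mitotic spindle assembly checkpoint protein MAD2A", "hMAD2L1", 9606)
    organism_gene("h_cdc20", "APC/C activator protein CDC20", "hCDC20", 9606)
    organism_gene("h_aurkb", "aurora kinase B", "hAURKB", 9606)
    organism_gene("h_plk1", "serine/threonine-protein kinase PLK1", "hPLK1", 9606)
    organism_gene("h_apc", "adenomatous polyposis coli protein", "hAPC", 9606)
    organism_gene("h_cenpe", "centromere-associated protein E", "hCENPE", 9606)
    organism_gene("h_sgol1", "shugoshin-like 1", "hSGOL1", 9606)
    organism_gene("h_dvl2", "segment polarity protein dishevelled homolog DVL-2", "hDVL2", 9606)
    organism_gene("h_casc5", "kinetochore scaffold protein CASC5", "hCASC5", 9606)
    organism_gene("h_ttk", "dual specificity protein kinase TTK", "hTTK", 9606)
    organism_gene("h_atm", "serine-protein kinase ATM", "hATM", 9606)
    organism_gene("h_cdk1", "cyclin-dependent kinase 1", "hCDK1", 9606)
    organism_gene("h_pp2a", "serine/threonine-protein phosphatase 2A 56 kDa "
                            "regulatory subunit alpha", "hPP2A-B56alpha", 9606)
    organism_gene("h_h3", "histone H3.1", "hH3", 9606)
    organism_gene("h_h2a", "histone H2A type 1", "hHHTA1", 9606)
    organism_gene("h_birc5", "baculoviral IAP repeat-containing protein 5", "hBIRC5", 9606)
    organism_gene("h_incenp", "inner centromere protein", "hINCENP", 9606)
    organism_gene("h_cdca8", "borealin", "hCDCA8", 9606)
    organism_gene("h_cenpa", "histone H3-like centromeric protein A", "hCENPA", 9606)

    # species-independent multiply phosphorylated BUB1B forms
    t.append(_term("p1", f"{_BUB1B} phosphorylated 1", "modification",
                   "A BUB1 beta protein that has been phosphorylated by CDK1 "
                   "on the site analogous to Thr-620 of the human protein.",
                   is_a=["bub1b"], synonyms=["BUB1B/Phos:1"]))
    t.append(_term("p2", f"{_BUB1B} phosphorylated 2", "modification",
                   "A BUB1 beta protein phosphorylated by CDK1 on the site "
                   "analogous to human Thr-620 and additionally by PLK1 on "
                   "sites analogous to human Ser-676 and Thr-680.",
                   is_a=["bub1b"], synonyms=["BUB1B/Phos:2"]))
    t.append(_term("p3", f"{_BUB1B} phosphorylated 3", "modification",
                   "A BUB1 beta protein phosphorylated on the site analogous "
                   "to Thr-608 of the human protein.",
                   is_a=["bub1b"], synonyms=["BUB1B/Phos:3"]))
    t.append(_term("p4", f"{_BUB1B} phosphorylated 4", "modification",
                   "A BUB1 beta protein phosphorylated by CDK1 on sites "
                   "analogous to Ser-543, Ser-670 and Ser-1043 of the human "
                   "protein.",
                   is_a=["bub1b"], synonyms=["BUB1B/Phos:4"]))

    def organism_mod(key, base, short, taxon, parents, comment="", definition=""):
        label = {9606: "human", 8355: "frog", 10090: "mouse"}[taxon]
        t.append(_term(key, f"{base} ({label})", "organism-modification",
                       definition or f"A {base} in {label}.",
                       taxon=taxon, is_a=parents, comment=comment,
                       synonyms=[short]))

    organism_mod("h_p1", f"{_BUB1B} phosphorylated 1", "hBUB1B/Phos:1", 9606,
                 ["p1", "h_bub1b"], _CDK1_KIN,
                 "A human BUB1 beta phosphorylated on Thr-620 by CDK1.")
    organism_mod("f_p1", f"{_BUB1B} phosphorylated 1", "fBUB1B/Phos:1", 8355,
                 ["p1", "f_bub1b"], _CDK1_KIN,
                 "A frog BUB1 beta phosphorylated on Thr-605 by CDK1.")
    organism_mod("h_p2", f"{_BUB1B} phosphorylated 2", "hBUB1B/Phos:2", 9606,
                 ["p2", "h_bub1b"], f"{_CDK1_KIN} {_PLK1_KIN}",
                 "A human BUB1 beta phosphorylated on Thr-620 by CDK1 and on "
                 "Ser-676 and Thr-680 by PLK1; observed while kinetochores "
                 "attach to the spindle and after nocodazole or taxol "
                 "treatment.")
    organism_mod("f_p2", f"{_BUB1B} phosphorylated 2", "fBUB1B/Phos:2", 8355,
                 ["p2", "f_bub1b"], f"{_CDK1_KIN} {_PLK1_KIN}",
                 "A frog BUB1 beta phosphorylated on Thr-605 by CDK1, which "
                 "stimulates further phosphorylation by PLK1.")
    organism_mod("h_p3", f"{_BUB1B} phosphorylated 3", "hBUB1B/Phos:3", 9606,
                 ["p3", "h_bub1b"], _P3_COMMENT,
                 "A human BUB1 beta phosphorylated on Thr-608.")
    organism_mod("f_p3", f"{_BUB1B} phosphorylated 3", "fBUB1B/Phos:3", 8355,
                 ["p3", "f_bub1b"], _P3_COMMENT,
                 "A frog BUB1 beta phosphorylated on Thr-593.")
    organism_mod("h_p4", f"{_BUB1B} phosphorylated 4", "hBUB1B/Phos:4", 9606,
                 ["p4", "h_bub1b"], _CDK1_KIN,
                 "A human BUB1 beta phosphorylated on the CDK1 consensus "
                 "sites Ser-543, Ser-670 and Ser-1043.")

    organism_mod("h_bub1b_unphos", f"{_BUB1B} unmodified form", "hBUB1B/PhosRes-",
                 9606, ["h_bub1b"], "",
                 "A human BUB1 beta that is unphosphorylated at all "
                 "characterized mitotic sites.")
    organism_mod("h_bub1_unphos", f"{_BUB1} unmodified form", "hBUB1/PhosRes-",
                 9606, ["h_bub1"], "",
                 "A human BUB1 that is unphosphorylated at all characterized "
                 "mitotic sites.")
    organism_mod("h_cdc20_unphos", "APC/C activator protein CDC20 unmodified form",
                 "hCDC20/PhosRes-", 9606, ["h_cdc20"], "",
                 "A human CDC20 that is unphosphorylated at all characterized "
                 "mitotic sites.")
    organism_mod("h_aurkb_unphos", "aurora kinase B unmodified form",
                 "hAURKB/PhosRes-", 9606, ["h_aurkb"], "",
                 "A human aurora kinase B that is unphosphorylated at all "
                 "characterized mitotic sites.")
    organism_mod("h_bub1_p7", f"{_BUB1} phosphorylated 7", "hBUB1/Phos:7", 9606,
                 ["h_bub1"], _CDK1_KIN,
                 "A human BUB1 phosphorylated by CDK1 on Ser-593 and Thr-609, "
                 "which is required for PLK1 binding.")
    organism_mod("h_bub1_p8", f"{_BUB1} phosphorylated 8", "hBUB1/Phos:8", 9606,
                 ["h_bub1"], f"{_CDK1_KIN} {_PLK1_KIN}",
                 "A human BUB1 phosphorylated by CDK1 and PLK1.")
    organism_mod("h_apc_p1", "adenomatous polyposis coli protein phosphorylated 1",
                 "hAPC/Phos:1", 9606, ["h_apc"],
                 'Kinase = "BUB1"; PR:000035400.',
                 "A human APC protein phosphorylated by the BUB1:BUB3 kinase.")
    organism_mod("h_cdc20_p1", "APC/C activator protein CDC20 phosphorylated 1",
                 "CDC20/Phos:1", 9606, ["h_cdc20"],
                 'Kinase = "BUB1"; PR:000035400.',
                 "A human CDC20 phosphorylated by BUB1.")
    organism_mod("h_aurkb_p1", "aurora kinase B phosphorylated 1",
                 "AURKB/Phos:1", 9606, ["h_aurkb"],
                 'Kinase = "AURKB"; PR:000035358.',
                 "A human aurora kinase B phosphorylated in its activation "
                 "loop.")
    organism_mod("h_atm_p2", "serine-protein kinase ATM phosphorylated 2",
                 "ATM/Phos:2", 9606, ["h_atm"],
                 'Kinase = "AURKB"; PR:000035358.',
                 "A human ATM phosphorylated by aurora kinase B during "
                 "mitosis.")
    organism_mod("h_h2a_p2", "histone H2A type 1 phosphorylated 2",
                 "HHTA1/Phos:2", 9606, ["h_h2a"],
                 'Kinase = "BUB1"; PR:000035400.',
                 "A human histone H2A phosphorylated on Ser-121 by BUB1.")
    organism_mod("h_h3t3ph", "histone H3.1 phosphorylated 1", "H3T3ph", 9606,
                 ["h_h3"], "",
                 "A human histone H3 phosphorylated on Thr-3.")

    # complexes
    t.append(_term("go_macromolecular", "macromolecular complex", "complex",
                   "A stable assembly of two or more macromolecules."))
    t.append(_term("go_protein_complex", "protein complex", "complex",
                   "A stable macromolecular complex composed of two or more "
                   "polypeptide subunits.", is_a=["go_macromolecular"]))
    t.append(_term("go_mcc", "mitotic checkpoint complex", "complex",
                   "A multiprotein complex that functions as a mitotic "
                   "checkpoint inhibitor of the anaphase-promoting "
                   "complex/cyclosome.", is_a=["go_protein_complex"]))
    t.append(_term("h_mcc", "mitotic checkpoint complex (human)",
                   "organism-complex",
                   "A mitotic checkpoint complex whose components are MAD2, "
                   "BubR1, BUB3 and CDC20.",
                   taxon=9606, is_a=["go_mcc"],
                   parts=["h_mad2l1", "h_bub1b", "h_bub3", "h_cdc20"],
                   xrefs=["Reactome:REACT_5836"], synonyms=["hMCC"]))
    t.append(_term("bub1_bub3", "BUB1:BUB3 complex", "complex",
                   "A protein complex of BUB1 and BUB3 that localizes to "
                   "kinetochores.",
                   is_a=["go_protein_complex"], parts=["bub1", "bub3"]))
    for key, taxon, label in (
        ("h_bub1_bub3", 9606, "human"),
        ("y_bub1_bub3", 4932, "budding yeast"),
        ("sp_bub1_bub3", 4896, "fission yeast"),
    ):
        part_prefix = {"h": "h", "y": "y", "sp": "sp"}[key.split("_", 1)[0]]
        t.append(_term(key, f"BUB1:BUB3 complex ({label})", "organism-complex",
                       f"A BUB1:BUB3 complex in {label}.",
                       taxon=taxon, is_a=["bub1_bub3"],
                       parts=[f"{part_prefix}_bub1", f"{part_prefix}_bub3"]))
    t.append(_term("bub1_bub3_mad1l1", "BUB1:BUB3:MAD1L1 complex", "complex",
                   "A complex of BUB1, BUB3 and MAD1 that forms at "
                   "kinetochores during checkpoint activation.",
                   is_a=["go_protein_complex"],
                   parts=["bub1", "bub3", "h_mad1l1"]))
    t.append(_term("bub1_bub3_apc", "BUB1:BUB3:APC complex", "complex",
                   "A complex of BUB1, BUB3 and the adenomatous polyposis "
                   "coli protein.",
                   is_a=["go_protein_complex"],
                   parts=["bub1", "bub3", "h_apc"]))
    t.append(_term("bub1_bub1b", "BUB1:BUB1B complex", "complex",
                   "A complex of BUB1 and BUB1B.",
                   is_a=["go_protein_complex"], parts=["bub1", "bub1b"]))
    t.append(_term("h_bub1_bub1b_unphos",
                   "BUB1:unmodified BUB1B complex (human)", "organism-complex",
                   "A human complex of BUB1 and the unphosphorylated form of "
                   "BUB1B.",
                   taxon=9606, is_a=["bub1_bub1b"],
                   parts=["h_bub1", "h_bub1b_unphos"]))
    t.append(_term("h_bub1_bub1b_p2",
                   "BUB1:phosphorylated BUB1B complex (human)",
                   "organism-complex",
                   "A human complex of BUB1 and BUB1B/Phos:2; formation is "
                   "enhanced by the mitotic phosphorylation of BUB1B.",
                   taxon=9606, is_a=["bub1_bub1b"],
                   parts=["h_bub1", "h_p2"]))
    t.append(_term("bub1_plk1", "BUB1:PLK1 complex", "complex",
                   "A complex of BUB1 and the polo-like kinase PLK1.",
                   is_a=["go_protein_complex"], parts=["bub1", "h_plk1"]))
    t.append(_term("h_phosbub1_plk1", "phospho-BUB1:PLK1 complex (human)",
                   "organism-complex",
                   "A human complex of PLK1 and the CDK1-phosphorylated form "
                   "of BUB1.",
                   taxon=9606, is_a=["bub1_plk1"],
                   parts=["h_bub1_p7", "h_plk1"]))
    for key, partner, partner_key, extra in (
        ("h_bub1b_pp2a", "PP2A-B56-alpha", "h_pp2a",
         "the phosphatase that reverses aurora-B phosphorylation of "
         "kinetochore substrates; binds specifically to BUB1B/Phos:2"),
        ("h_bub1b_cenpe", "CENPE", "h_cenpe",
         "binding to CENPE may stimulate BUB1B auto-phosphorylation"),
        ("h_bub1b_sgol1", "SGOL1", "h_sgol1", "links BUB1B to sister "
         "chromatid cohesion"),
        ("h_bub1b_casc5", "CASC5", "h_casc5", "docks BUB1B at the outer "
         "kinetochore"),
        ("h_bub1b_aurkb", "AURKB", "h_aurkb", "associates BUB1B with the "
         "chromosomal passenger kinase"),
    ):
        bub1b_part = "h_p2" if key == "h_bub1b_pp2a" else "h_bub1b"
        t.append(_term(key, f"BUB1B:{partner} complex (human)",
                       "organism-complex",
                       f"A human complex of BUB1B and {partner}; {extra}.",
                       taxon=9606, is_a=["go_protein_complex"],
                       parts=[bub1b_part, partner_key]))
    return t


# ---------------------------------------------------------------------------
# annotation lines

_GO_KINETOCHORE = ("GO:0000776", "kinetochore")
_GO_CENTROMERE = ("GO:0000779", "condensed chromosome, centromeric region")
_GO_BINDING = ("GO:0005515", "Protein binding")

#: (form key, modifier, relation, GO id, GO term, interactor key) — the
#: annotation lines recording how phosphorylation changes each form
_MODIFIER_LINES = [
    ("h_cdc20_p1", "decreased", "has_function", "GO:0061630", "Ubiquitin protein ligase activity", None),
    ("h_cdc20_p1", "increased", "participates_in", "GO:0031577", "Spindle checkpoint", None),
    ("h_p2", "increased", "has_function", *_GO_BINDING, "h_bub1"),
    ("h_p2", "increased", "has_function", *_GO_BINDING, "h_pp2a"),
    ("h_p2", "increased", "has_function", "GO:0004672", "Protein kinase activity", None),
    ("h_p2", "increased", "participates_in", "GO:0008608", "Attachment of spindle microtubules to kinetochores", None),
    ("h_p2", "increased", "participates_in", "GO:0051310", "Metaphase plate congression", None),
    ("h_p3", "increased", "participates_in", "GO:0051310", "Metaphase plate congression", None),
    ("h_p3", "increased", "participates_in", "GO:0007059", "Chromosome segregation", None),
    ("h_p3", "increased", "participates_in", "GO:0031577", "Spindle checkpoint", None),
    ("h_p3", "increased", "participates_in", "GO:0034501", "Protein localization to kinetochore", None),
    ("h_p3", "decreased", "participates_in", "GO:0001933", "Negative regulation of protein phosphorylation", None),
    ("h_p4", "increased", "participates_in", "GO:0008608", "Attachment of spindle microtubules to kinetochores", None),
    ("h_p4", "increased", "participates_in", "GO:1905786", "Inhibition of mitotic anaphase-promoting complex activity", None),
    ("h_p4", "increased", "participates_in", "GO:0051310", "Metaphase plate congression", None),
    ("h_aurkb_p1", "increased", "has_function", "GO:0004672", "Protein kinase activity", None),
    ("h_aurkb_p1", "increased", "participates_in", "GO:0007059", "Chromosome segregation", None),
    ("h_aurkb_p1", "increased", "participates_in", "GO:0051310", "Metaphase plate congression", None),
    ("h_aurkb_p1", "increased", "participates_in", "GO:0031577", "Spindle checkpoint", None),
    ("h_atm_p2", "increased", "has_function", "GO:0004672", "Protein kinase activity", None),
    ("h_atm_p2", "increased", "participates_in", "GO:0031577", "Spindle checkpoint", None),
    ("h_h2a_p2", "increased", "participates_in", "GO:0071459", "Protein localization to chromosome, centromeric region", None),
    ("h_h3t3ph", "increased", "has_function", *_GO_BINDING, "h_birc5"),
    ("h_h3t3ph", "increased", "participates_in", "GO:0071459", "Protein localization to chromosome, centromeric region", None),
]

_KINETOCHORE_KEYS = [
    "h_bub1", "h_bub1b", "h_bub3", "h_mad1l1", "h_mad2l1", "h_cdc20",
    "h_aurkb", "h_plk1", "h_cenpe", "h_sgol1", "h_casc5", "h_ttk",
    "h_apc", "h_dvl2", "h_pp2a", "h_atm",
    "h_p2", "h_p3", "h_p4", "h_aurkb_p1", "h_cdc20_p1", "h_atm_p2",
    "h_bub1b_unphos", "h_cdc20_unphos", "h_aurkb_unphos", "h_bub1_unphos",
]
_CENTROMERE_KEYS = [
    "h_aurkb", "h_aurkb_p1", "h_h3t3ph", "h_h2a_p2", "h_h3", "h_h2a",
    "h_cenpa", "h_birc5", "h_incenp", "h_cdca8",
]

#: unordered physical-interaction pairs (IPI evidence); the annotation is
#: written on the first member with the second as interactor
_IPI_PAIRS = [
    ("h_bub1", "h_bub1b"), ("h_bub1", "h_bub3"), ("h_bub1", "h_mad1l1"),
    ("h_bub1b", "h_bub3"), ("h_bub1b", "h_mad2l1"),
    ("h_bub3", "h_mad1l1"), ("h_bub3", "h_mad2l1"),
    ("h_mad1l1", "h_mad2l1"),
    ("h_aurkb", "h_bub1b"),
    ("h_cdc20", "h_mad2l1"), ("h_cdc20", "h_bub1b"), ("h_cdc20", "h_bub3"),
    ("h_cdc20_p1", "h_mad2l1"), ("h_cdc20_p1", "h_bub1b"),
    ("h_cdc20_unphos", "h_mad2l1"), ("h_cdc20_unphos", "h_bub1b"),
    ("h_aurkb", "h_birc5"), ("h_aurkb", "h_cdca8"), ("h_aurkb", "h_incenp"),
    ("h_aurkb_p1", "h_incenp"), ("h_aurkb_unphos", "h_incenp"),
    ("h_aurkb", "h_sgol1"), ("h_incenp", "h_sgol1"), ("h_cdca8", "h_sgol1"),
    ("h_aurkb", "h_cenpa"),
    ("h_bub1", "h_casc5"), ("h_bub1b", "h_casc5"),
    ("h_bub1b", "h_sgol1"), ("h_bub1b", "h_cenpe"),
    ("h_bub1", "h_apc"), ("h_bub1b", "h_apc"), ("h_bub3", "h_apc"),
    ("h_mad2l1", "h_apc"),
    ("h_ttk", "h_dvl2"), ("h_apc", "h_dvl2"),
    ("h_plk1", "h_bub1"), ("h_plk1", "h_bub1b"),
    ("h_plk1", "h_sgol1"), ("h_plk1", "h_dvl2"),
]

_REF = "PMID:23420618"


def _spindle_paf(terms: dict[str, ProTerm]) -> list[PafRecord]:
    def rec(key, relation, go, go_term, evidence="IDA", modifier=NO_MODIFIER,
            interactor_key=None):
        term = terms[IDS[key]]
        return PafRecord(
            pro_id=term.term_id,
            object_name=term.name,
            object_synonym=term.synonyms[0] if term.synonyms else "",
            modifier=modifier,
            relation=relation,
            ontology_id=go,
            ontology_term=go_term,
            evidence_code=evidence,
            interactor_id=IDS[interactor_key] if interactor_key else "",
            taxon_id=term.taxon_id,
            reference=_REF,
            date="2013-04-26",
        )

    paf: list[PafRecord] = []
    for key in _KINETOCHORE_KEYS:
        paf.append(rec(key, "located_in", *_GO_KINETOCHORE))
    for key in _CENTROMERE_KEYS:
        paf.append(rec(key, "located_in", *_GO_CENTROMERE))
    for a, b in _IPI_PAIRS:
        paf.append(rec(a, "has_function", *_GO_BINDING, evidence="IPI",
                       interactor_key=b))
    # the modification state of BUB1 gates its PLK1 interaction: the
    # unphosphorylated form does not bind (negating NOT modifier)
    paf.append(rec("h_bub1_unphos", "has_function", *_GO_BINDING,
                   evidence="IPI", modifier="NOT", interactor_key="h_plk1"))
    for key, modifier, relation, go, go_term, interactor in _MODIFIER_LINES:
        paf.append(rec(key, relation, go, go_term,
                       evidence="IPI" if interactor else "IMP",
                       modifier=modifier, interactor_key=interactor))
    return paf


# ---------------------------------------------------------------------------
# sites, forms, registry


def _spindle_sites() -> tuple[list[ModSite], list[ModSite]]:
    experimental = [
        ModSite(HUMAN, 543, "S", "phosphorylation", "in_vivo"),
        ModSite(HUMAN, 608, "T", "phosphorylation", "in_vivo"),
        ModSite(HUMAN, 620, "T", "phosphorylation", "in_vivo"),
        ModSite(HUMAN, 670, "S", "phosphorylation", "in_vivo"),
        ModSite(HUMAN, 676, "S", "phosphorylation", "in_vivo"),
        ModSite(HUMAN, 680, "T", "phosphorylation", "in_vivo"),
        ModSite(HUMAN, 792, "T", "phosphorylation", "in_vitro"),
        ModSite(HUMAN, 1008, "T", "phosphorylation", "in_vitro"),
        ModSite(HUMAN, 1043, "S", "phosphorylation", "in_vivo"),
        ModSite(FROG, 593, "T", "phosphorylation", "in_vivo"),
        ModSite(FROG, 605, "T", "phosphorylation", "in_vivo"),
    ]
    corroborating = [
        ModSite(MOUSE, 535, "S", "phosphorylation", "high_throughput"),
        ModSite(MOUSE, 601, "T", "phosphorylation", "high_throughput"),
        ModSite(MOUSE, 613, "T", "phosphorylation", "high_throughput"),
        ModSite(MOUSE, 1033, "S", "phosphorylation", "high_throughput"),
    ]
    return experimental, corroborating


def _site(pos: int, res: str, tier: str = "in_vivo") -> ModSite:
    return ModSite(HUMAN, pos, res, "phosphorylation", tier)


def _spindle_forms() -> list[ModForm]:
    return [
        ModForm(IDS["p1"], "BUB1B", HUMAN,
                (FormSite(_site(620, "T")),), "CDK1"),
        ModForm(IDS["p2"], "BUB1B", HUMAN,
                (FormSite(_site(620, "T")), FormSite(_site(676, "S")),
                 FormSite(_site(680, "T")),
                 FormSite(_site(792, "T", "in_vitro"), required=False),
                 FormSite(_site(1008, "T", "in_vitro"), required=False)),
                "PLK1"),
        ModForm(IDS["p3"], "BUB1B", HUMAN,
                (FormSite(_site(608, "T")),), "BUB1B (CENPE-bound)"),
        ModForm(IDS["p4"], "BUB1B", HUMAN,
                (FormSite(_site(543, "S")), FormSite(_site(670, "S")),
                 FormSite(_site(1043, "S"))),
                "CDK1"),
    ]


def _spindle_registry() -> list[tuple[str, str, str]]:
    return [
        (IDS["p1"], HUMAN, IDS["h_p1"]),
        (IDS["p1"], FROG, IDS["f_p1"]),
        (IDS["p2"], HUMAN, IDS["h_p2"]),
        (IDS["p2"], FROG, IDS["f_p2"]),
        (IDS["p3"], HUMAN, IDS["h_p3"]),
        (IDS["p3"], FROG, IDS["f_p3"]),
        (IDS["p4"], HUMAN, IDS["h_p4"]),
    ]


@dataclass
class SpindleFixture:
    """The in-memory spindle-checkpoint fixture."""

    terms: list[ProTerm]
    paf: list[PafRecord]
    alignment: Alignment
    sites_experimental: list[ModSite]
    sites_corroborating: list[ModSite]
    forms: list[ModForm]
    registry: list[tuple[str, str, str]]  # (form_id, species, curated term)
    evidence_tags: dict[tuple[str, str], tuple[str, ...]] = field(default_factory=dict)
    ids: dict[str, str] = field(default_factory=lambda: dict(IDS))

    def graph(self) -> OntologyGraph:
        return OntologyGraph(self.terms)

    def registry_pairs(self) -> set[tuple[str, str]]:
        return {(fid, sp) for fid, sp, _ in self.registry}

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "obo": outdir / "spindle.obo",
            "paf": outdir / "spindle.paf",
            "alignment": outdir / "bub1b_alignment.fasta",
            "sites": outdir / "sites.tsv",
            "forms": outdir / "forms.tsv",
            "registry": outdir / "registry.tsv",
        }
        paths["obo"].write_text(write_obo(self.terms))
        paths["paf"].write_text(write_paf(self.paf))
        write_alignment_fasta(self.alignment, paths["alignment"])
        write_sites_tsv(
            self.sites_experimental + self.sites_corroborating, paths["sites"]
        )
        write_forms_tsv(self.forms, paths["forms"])
        write_registry_tsv(self.registry, paths["registry"])
        return paths


def spindle_fixture() -> SpindleFixture:
    """Build the deterministic spindle-checkpoint fixture in memory."""
    terms = _spindle_terms()
    by_id = {t.term_id: t for t in terms}
    experimental, corroborating = _spindle_sites()
    fx = SpindleFixture(
        terms=terms,
        paf=_spindle_paf(by_id),
        alignment=_build_alignment(),
        sites_experimental=experimental,
        sites_corroborating=corroborating,
        forms=_spindle_forms(),
        registry=_spindle_registry(),
        evidence_tags={(IDS["p2"], FROG): ("analogous_kinase_demonstrated",)},
    )
    for site in fx.sites_experimental + fx.sites_corroborating:
        site.validate(fx.alignment)
    fx.graph()  # validates terms and asserts acyclicity
    return fx


def build_spindle_fixture(outdir: str | Path) -> dict[str, Path]:
    """Write the spindle fixture files; byte-identical on every call."""
    return spindle_fixture().write(outdir)


# ---------------------------------------------------------------------------
# seeded random fixtures

_TAXA = (9606, 10090, 8355, 4932, 7227, 6239, 7955, 10116)
_GO_POOL = (
    ("GO:0000776", "kinetochore"),
    ("GO:0000779", "condensed chromosome, centromeric region"),
    ("GO:0005634", "nucleus"),
    ("GO:0005737", "cytoplasm"),
    ("GO:0005819", "spindle"),
)


@dataclass
class RandomFixture:
    terms: list[ProTerm]
    paf: list[PafRecord]
    seed: int

    def graph(self) -> OntologyGraph:
        return OntologyGraph(self.terms)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {"obo": outdir / "random.obo", "paf": outdir / "random.paf"}
        paths["obo"].write_text(write_obo(self.terms))
        paths["paf"].write_text(write_paf(self.paf))
        return paths


def random_fixture(
    seed: int,
    n_genes: int = 12,
    n_species: int = 3,
    p_modified: float = 0.5,
    p_interaction: float = 0.15,
) -> RandomFixture:
    """Seeded random ontology + annotations with family/gene/form structure.

    Raises ``ValueError`` for non-positive sizes or probabilities outside
    [0, 1].  The generated is_a graph is a DAG by construction (edges
    always point from later-created to earlier-created terms).
    """
    if n_genes < 1 or n_species < 1:
        raise ValueError("n_genes and n_species must be positive")
    if not (0.0 <= p_modified <= 1.0 and 0.0 <= p_interaction <= 1.0):
        raise ValueError("probabilities must lie in [0, 1]")
    if n_species > len(_TAXA):
        raise ValueError(f"at most {len(_TAXA)} species supported")

    rng = random.Random(seed)
    counter = 0

    def acc() -> str:
        nonlocal counter
        counter += 1
        return f"PR:8{counter:08d}"

    terms: list[ProTerm] = [ProTerm("PR:000000001", "protein", category="family")]
    paf: list[PafRecord] = []
    taxa = _TAXA[:n_species]
    org_by_taxon: dict[int, list[ProTerm]] = {tx: [] for tx in taxa}

    family_id: str | None = None
    for g in range(n_genes):
        if g % 3 == 0:
            family_id = acc()
            terms.append(ProTerm(
                family_id, f"kinase family F{g // 3}", category="family",
                definition=f"A synthetic protein family F{g // 3}.",
                relations=[("is_a", "PR:000000001")],
            ))
        gene_id = acc()
        terms.append(ProTerm(
            gene_id, f"protein kinase GENE{g}", category="gene",
            definition=f"A synthetic member of family F{g // 3}.",
            synonyms=[f"G{g}"],
            relations=[("is_a", family_id)],
        ))
        for tx in taxa:
            org_id = acc()
            org = ProTerm(
                org_id, f"protein kinase GENE{g} (taxon {tx})",
                category="organism-gene",
                definition=f"A GENE{g} protein in taxon {tx}.",
                synonyms=[f"G{g}/{tx}"],
                relations=[("is_a", gene_id), ("only_in_taxon", f"NCBITaxon:{tx}")],
                taxon_id=tx,
            )
            terms.append(org)
            org_by_taxon[tx].append(org)
            go, go_name = rng.choice(_GO_POOL)
            modifier = rng.choice(
                [NO_MODIFIER, NO_MODIFIER, NO_MODIFIER, "increased", "decreased"]
            )
            paf.append(PafRecord(
                pro_id=org_id, object_name=org.name,
                object_synonym=org.synonyms[0], modifier=modifier,
                relation="located_in", ontology_id=go, ontology_term=go_name,
                evidence_code="IDA", taxon_id=tx, reference=f"PMID:{seed}",
            ))
            if rng.random() < p_modified:
                mod_id = acc()
                kinase = rng.choice(org_by_taxon[tx])
                terms.append(ProTerm(
                    mod_id,
                    f"protein kinase GENE{g} phosphorylated 1 (taxon {tx})",
                    category="organism-modification",
                    definition=f"A GENE{g} protein in taxon {tx} that has "
                               f"been phosphorylated.",
                    synonyms=[f"G{g}/{tx}/Phos:1"],
                    comment=f'Kinase = "{kinase.synonyms[0]}"; {kinase.term_id}.',
                    relations=[("is_a", org_id),
                               ("only_in_taxon", f"NCBITaxon:{tx}")],
                    taxon_id=tx,
                ))

    for tx in taxa:
        orgs = org_by_taxon[tx]
        for i in range(len(orgs)):
            for j in range(i + 1, len(orgs)):
                if rng.random() < p_interaction:
                    paf.append(PafRecord(
                        pro_id=orgs[i].term_id, object_name=orgs[i].name,
                        object_synonym=orgs[i].synonyms[0],
                        relation="has_function", ontology_id="GO:0005515",
                        ontology_term="protein binding", evidence_code="IPI",
                        interactor_id=orgs[j].term_id, taxon_id=tx,
                        reference=f"PMID:{seed}",
                    ))
    return RandomFixture(terms=terms, paf=paf, seed=seed)
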