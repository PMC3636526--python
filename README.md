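# proforms

Protein-form ontology analysis for systems biologists studying processes —
like the mitotic spindle checkpoint — where function hinges on *which form*
of a protein is present: a specific phosphorylated form, an isoform, or a
complex, rather than the gene-level protein.

The package provides, as composable library functions plus a thin CLI:

* **I/O** for protein-ontology term stanzas (an OBO 1.2 dialect with
  family/gene/sequence/modification/complex categories) and for the
  tab-delimited protein annotation file (PAF) that attaches GO/Pfam
  annotations, evidence codes, `increased`/`decreased` modifiers and
  physical-interaction partners to individual forms. Writers are
  byte-deterministic and round-trip with the parsers field-for-field.
* An **ontology graph**: a typed DAG with `is_a` (child → parent) and
  `has_part` (complex → component) edges, transitive
  ancestor/descendant queries, complex-composition closure, and
  orthology groups (organism-specific terms sharing a
  species-independent same-level parent).
* A **boolean query engine** with field-restricted clauses
  (`Name`, `Taxon ID`, `Ontology ID`, `PRO ID`, `Definition`,
  `Modifier`, `Evidence Code`, or any field), `AND`/`OR`/`NOT` with
  `NOT > AND > OR` precedence, `NULL` / `NOT NULL` tests, category
  quick links (phosphorylated forms, modified forms, complexes), and
  tab-delimited result-table export.
* A **network builder** that turns IPI (inferred from physical
  interaction) annotation lines, standardized kinase comments
  (`Kinase = "NAME"; ACCESSION`) and modification→gene hierarchy edges
  into typed edges — `interacts_with`, `inhibited_interaction`
  (IPI + negating `NOT` modifier), `phosphorylates`, `is_a_parent` —
  and writes Cytoscape-importable network/attribute tables and SIF.
* **Conservation inference**: mapping modification sites between
  species through a multiple sequence alignment (1-based residue and
  column coordinates) and classifying a modified-form hypothesis per
  target species as `curated`, `predicted`, `absent`, or
  `insufficient_evidence` from site conservation plus corroborating
  evidence (high-throughput or in vivo sites in the target, or a
  demonstrated analogous kinase event). Output includes a Jalview
  sequence-features file.
* A **synthetic-data module** that generates the packaged
  spindle-checkpoint fixture (BUB1/BUB1B/MAD3 family, four BUB1B
  phospho-forms across human/frog/mouse, the mitotic checkpoint
  complex, BUB1-containing complexes, kinetochore/centromere
  annotations, and a three-species BUB1B alignment realizing the
  curated site correspondences) and seeded random fixtures for
  property tests.

## The inference rule at the core

For a modified form *F* defined on a reference sequence with required
sites *S* = {s₁…sₖ} (sites confirmed in vivo in the reference species),
and a target species *t* in the alignment *A*:

* map each sᵢ through its alignment column; sᵢ is **conserved** iff the
  column is not a gap in *t* and the target residue matches (optionally
  treating Ser/Thr as equivalent);
* status(F, t) = `curated` if (F, t) is in the curated registry;
  `absent` if some required sᵢ is not conserved; `predicted` if all
  required sites are conserved **and** at least one corroborating item
  exists (`target_htp_site`, `target_in_vivo_site`, or
  `analogous_kinase_demonstrated`); otherwise `insufficient_evidence`.

Position mapping through a shared alignment is strictly monotone per
sequence pair and self-inverse on non-gap columns; adding required
sites can only move a call toward `absent`.

## Worked example

```bash
proforms fixtures spindle --out demo
proforms search --obo demo/spindle.obo --paf demo/spindle.paf \
    --query 'Ontology ID PFAM:PF08311' --columns id,name,xrefs
```

```
id      name    xrefs
PR:000035499    mitotic spindle checkpoint protein MAD3    PFAM:PF08311
PR:000035665    BUB1/BUB1B family protein    PFAM:PF08311|PFAM:PF00069
```

A search for the shared N-terminal TPR domain (Pfam PF08311) returns
exactly two classes: the MAD3 gene-level term (TPR domain only) and the
BUB1/BUB1B family term, which additionally carries the C-terminal
protein kinase domain (PF00069) — the domain architecture that
separates the kinase-bearing BUB-like proteins from MAD3.

```bash
proforms conserve --aln demo/bub1b_alignment.fasta --sites demo/sites.tsv \
    --forms demo/forms.tsv --registry demo/registry.tsv \
    --target BUB1B_mouse --out calls.tsv
```

```
PR:000035361    predicted
PR:000035427    predicted
PR:000035431    predicted
PR:000035434    predicted
```

All four multiply-phosphorylated BUB1B forms characterized in human
come out `predicted` in mouse: every required site is conserved and
each form is corroborated by a high-throughput mouse phosphosite at a
mapped position. Running the same command with `--target BUB1B_frog`
classifies the fourth form (`PR:000035434`) `absent` — only one of its
three required sites survives in the frog sequence.

The kinetochore/centromere interaction network is built with:

```bash
proforms network --obo demo/spindle.obo --paf demo/spindle.paf \
    --query 'Taxon ID 9606 AND Ontology ID GO:0000776 OR Taxon ID 9606 AND Ontology ID GO:0000779' \
    --edges edges.tsv --attrs attrs.tsv
# -> 35 nodes, 62 edges
```

`edges.tsv` (`source  interaction  target  evidence  reference`) and
`attrs.tsv` (`id  name  category  label  definition`) import directly
into Cytoscape via "Import → Network from table" and
"Import → Attribute from table".

## PAF column layout

Fixed 12-column tab-delimited lines:
`PRO_ID, Object_name, Object_synonym, Modifier, Relation, Ontology_ID,
Ontology_term, Evidence_code, Interactor_ID, Taxon_ID, Reference, Date`.
The modifier vocabulary is `increased`, `decreased`, `altered`, `NOT`
(negated/blocked), with an empty field meaning no modifier; IPI lines
must carry an interactor accession.

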