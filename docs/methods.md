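# Methods

## Scope and data model

The package models a protein-form ontology: terms at five hierarchy
levels (family, gene, sequence, modification, complex), each either
species-independent or organism-specific (the organism-specific
categories carry an `organism-` prefix and require an NCBI taxon).
Terms are connected by `is_a` (subclass, child → parent), `has_part`
(complex → component), `derives_from` (cleavage products; modeled but
not exercised by the packaged fixture) and `only_in_taxon` (metadata —
never traversed as hierarchy). Annotations live outside the ontology
file in a tab-delimited annotation file (PAF) whose lines attach GO or
Pfam terms to individual forms with an evidence code, an optional
`increased`/`decreased`/`altered`/`NOT` modifier, and — for physical
interactions (evidence code IPI) — a partner accession.

## File dialects

**OBO.** The parser accepts the OBO 1.2 subset `format-version`,
`[Term]`, `id`, `name`, `def`, `comment`, `synonym`, `xref`, `is_a`,
`relationship`, `is_obsolete`. Unknown tag lines are kept verbatim and
re-emitted so that parse ∘ write is the identity on any term set the
writer accepts; the writer is byte-deterministic (LF endings, fixed
field order). Term categories are serialized as a leading
`Category=<name>.` marker in the comment, the convention used by
protein-ontology curators. Synonym scopes are normalized to `EXACT` on
write; definition cross-reference lists are not preserved. When a term
carries no explicit category it is inferred: GO accessions are treated
as species-independent complexes (the ontology reuses GO complex
terms); other accessions are gene-level, organism-specific iff a taxon
is present.

**PAF.** The annotation dialect is a frozen 12-column layout (see
README). The source material never states a column order, so one had
to be declared; reproducibility requires freezing it. An empty
modifier field means "no modifier" (`none` internally); unknown
evidence codes and IPI lines without interactors are retained with a
warning and a flag rather than dropped, so files can be inspected
after a partial failure.

**Kinase comments.** Kinase provenance appears in free-text comments
in the standardized form `Kinase = "NAME"; ACCESSION`. The strict
parser matches only that pattern and is total (arbitrary text yields an
empty list). A lenient mode additionally captures narrative phrasings
of the form `NAME (ACCESSION) as the kinase …`, keeping the trailing
clause as a qualifier; it is off by default because narrative mentions
can be speculative.

## Graph semantics

The graph keeps every term as a node (obsolete terms are retained but
contribute no edges) and adds one typed edge per relation line, so
edge counts always equal relation-line counts in the source file.
Relation targets absent from the file become stub nodes flagged
external rather than being dropped — complex terms routinely point at
GO parents that live in another ontology. `is_a` acyclicity is
asserted on every build and a violation names the cycle. Ancestors /
descendants are transitive closures over a caller-chosen set of edge
kinds; complex composition is the `has_part` closure. Orthology groups
collect organism-specific terms under a shared species-independent
parent *of the same level* (an organism-gene term grouped under a
family-level parent would otherwise pull in every protein of the
family).

## Query semantics

Free-text fields (`Name` — name plus synonyms, `Definition`, any
field) match by case-insensitive substring; identifier fields
(`Taxon ID`, `Ontology ID`, `PRO ID`, `Modifier`, `Evidence Code`)
match exactly, tolerant of a database prefix on either side (`PF08311`
matches the cross-reference `PFAM:PF08311`). Any-field search covers
id, name, synonyms, definition and cross-references — not comments,
which hold curator notes rather than searchable content. A term
matches an annotation-backed clause when *any* of its annotation lines
matches; `Modifier NOT NULL` therefore means "at least one annotation
line carries a modifier". Results are sets of term accessions
("N results" counts terms, never annotation lines), sorted by
accession wherever an order is emitted; `NOT` complements within the
non-obsolete universe. The phosphorylated-forms quick link keeps
modification-level terms whose name/synonyms/definition mention
phosphorylation in non-negated form (the match is rejected when the
mention is letter-prefixed, as in *un*phosphorylated or
*de*phosphorylated), which cleanly separates phosphorylated forms from
the `PhosRes-` unmodified-form terms.

## Network derivation

Interaction edges are undirected in meaning: each unordered IPI pair
is recorded once (smaller accession first) regardless of which side
carried the annotation, and re-extraction is idempotent. An IPI line
with the negating `NOT` modifier becomes an `inhibited_interaction`
edge — the encoding chosen here for "the unmodified form fails to
bind". Interactions annotated on modified forms stay on the form and
are not lifted to the gene level; that specificity (e.g. a phosphatase
binding only the phosphorylated kinase form) is the point of
form-level annotation. Kinase edges point kinase → phosphorylated-form
term. Hierarchy edges are emitted only from modification-level terms
to their direct gene-level parents, matching how such networks display
"which gene does this form belong to". Unresolvable interactor
accessions are reported in a skipped-lines list.

## Conservation inference

Coordinates are 1-based for both residues and alignment columns, gap
character `-`, no half-open intervals. Mapping a site goes through its
alignment column; the result is a position in the target or a gap
verdict. Residue equivalence defaults to *identical* — every curated
correspondence in the packaged data is T↔T or S↔S, and accepting S↔T
by default would over-predict; `st_equivalent` is available as an
option. The classification rule (curated / absent / predicted /
insufficient_evidence) is described in the README; corroboration is
restricted to a fixed three-tag vocabulary (`target_htp_site`,
`target_in_vivo_site`, `analogous_kinase_demonstrated`) so calls are
auditable. Forms that share sites (the multiply-phosphorylated forms
are nested) are classified independently; no subsumption logic is
applied. The Jalview sequence-features writer emits experimental sites
and predicted sites as two feature classes and re-validates every
position against the ungapped sequences.

## The spindle-checkpoint fixture

The synthetic-data module reconstructs the spindle-checkpoint corner
of the ontology from curated facts: the BUB1/BUB1B family (Pfam
PF08311 + PF00069) and MAD3 (PF08311 only); the four
species-independent multiply-phosphorylated BUB1B forms with their
human and frog children and standardized kinase comments (CDK1, PLK1);
the human mitotic checkpoint complex with its four components (MAD2,
BUB1B, BUB3, CDC20); eleven BUB1-containing complexes (five
species-independent, three organism-specific BUB1:BUB3 complexes, the
two modification-state-specific human BUB1:BUB1B complexes and the
phospho-BUB1:PLK1 complex) plus five BUB1B-only complexes;
kinetochore/centromere localization lines for the human forms; the
physical-interaction lines among the core checkpoint proteins (all
pairs except BUB1B–MAD1 and BUB1–MAD2) and their kinetochore
neighbours; the modifier lines recording how phosphorylation changes
each of the eight phosphorylated kinetochore/centromere forms; and a
three-species BUB1B alignment.

Entities the curated record names without an accession use a reserved
synthetic namespace (`PR:9000000xx`) so fixture ids cannot collide
with real ontology terms.

The alignment is synthetic: filler residues are drawn from a
fixed-seed generator and shared across the three rows (a deliberately
high-identity alignment), with the curated sites pinned at their
stated positions and gap blocks placed so that every curated
human/frog/mouse correspondence is realized
(620↔605↔613, 676↔655↔665, 680↔659↔669, 608↔593↔601, 543↔·↔535,
670↔649↔659, 1043↔·↔1033). The human-543 column aligns to a frog
position whose residue deliberately differs (site lost by
substitution) while human-1043 falls in a frog gap (site lost by
deletion), exercising both failure modes. Because all rows share a
column system, per-pair correspondences are monotone by construction;
the builder re-checks every correspondence at build time and fails
loudly on drift. What the fixture does *not* emulate: real BUB1B
sequence content, realistic inter-species divergence, release-level
term counts, or annotation completeness — passing tests show the
machinery reproduces the curated case study, not that it would score
well against a full ontology release.

The random generator (`random_fixture`) mirrors the fixture's
statistical shape — families of three genes, organism terms across up
to eight taxa, phospho-forms with probability `p_modified` (default
0.5, roughly the fraction of checkpoint proteins with curated
phospho-forms), same-taxon IPI pairs with probability `p_interaction`
(default 0.15, a typical density for curated interaction sets) — and
is used by the oracle-equivalence property tests. Identical seeds give
byte-identical files; its `is_a` edges always point from
later-created to earlier-created terms, so it generates DAGs by
construction.

## Verification strategy

Every non-trivial operation is checked against an independent oracle:
transitive closures against brute-force expansion on random DAGs, the
query engine against a naive per-term filter over 1000 seeded random
queries, parsers against line-scan counts and (for the OBO dialect)
against an independent OBO reader, coordinate mapping against
hand-countable toy alignments plus monotonicity/inverse properties on
random alignments, and inference against its anti-monotonicity
property. Writers are asserted byte-stable. The acceptance script
recomputes the complex-conservation counts end-to-end — generate,
write, re-parse, query, traverse — rather than reading any cached
value.

## Known limitations

* The OBO subset is deliberately small: no OWL, no OBO 1.4 grammar,
  no GAF/GPAD.
* Query parsing reserves the field keywords; a bare search for a word
  that is also a field name must be quoted.
* `derives_from` relations and the `disease_forms` quick link are
  modeled but unexercised by the packaged fixture.
* Conservation calls consider sequence conservation and the fixed
  corroboration vocabulary only — no kinase-motif scoring, no
  structural context.
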