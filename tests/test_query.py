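"""Boolean field-restricted search: grammar, semantics, exports."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from proforms.obo import ProTerm
from proforms.paf import NO_MODIFIER
from proforms.query import (
    And,
    Clause,
    FIELDS,
    Not,
    Or,
    QueryError,
    QuerySyntaxError,
    evaluate,
    export_table,
    parse_query,
    print_query,
    quicklink_filter,
)
from proforms.synthetic import IDS, random_fixture


# ---------------------------------------------------------------------------
# independent oracle: evaluate one clause against one term by direct scan


def clause_matches_oracle(clause, term, paf_lines):
    if clause.field == "Name":
        hay = [term.name] + term.synonyms
    elif clause.field == "Definition":
        hay = [term.definition]
    elif clause.field == "AnyField":
        hay = [term.term_id, term.name, *term.synonyms, term.definition,
               *term.xrefs]
    elif clause.field == "PROID":
        hay = [term.term_id]
    elif clause.field == "TaxonID":
        hay = ([str(term.taxon_id)] if term.taxon_id else []) + [
            str(r.taxon_id) for r in paf_lines if r.taxon_id
        ]
    elif clause.field == "OntologyID":
        hay = [r.ontology_id for r in paf_lines if r.ontology_id] + term.xrefs
    elif clause.field == "Modifier":
        hay = [r.modifier for r in paf_lines if r.modifier != NO_MODIFIER]
    elif clause.field == "EvidenceCode":
        hay = [r.evidence_code for r in paf_lines if r.evidence_code]
    if clause.test == "not_null":
        return bool(hay)
    if clause.test == "is_null":
        return not hay
    if clause.test == "contains":
        return any(clause.value.lower() in h.lower() for h in hay)
    q = clause.value.lower()
    return any(
        q == h.lower()
        or q == h.lower().split(":", 1)[-1]
        or q.split(":", 1)[-1] == h.lower()
        for h in hay
    )


def evaluate_oracle(expr, terms, paf):
    by_id = {}
    for r in paf:
        by_id.setdefault(r.pro_id, []).append(r)
    universe = {t.term_id for t in terms if not t.is_obsolete}

    def matches(e, t):
        if isinstance(e, Clause):
            return clause_matches_oracle(e, t, by_id.get(t.term_id, []))
        if isinstance(e, Not):
            return not matches(e.expr, t)
        if isinstance(e, And):
            return matches(e.left, t) and matches(e.right, t)
        return matches(e.left, t) or matches(e.right, t)

    return {t.term_id for t in terms
            if t.term_id in universe and matches(expr, t)}


def random_expr(rng, values, depth=0):
    if depth >= 3 or rng.random() < 0.45:
        field = rng.choice(list(FIELDS))
        test = rng.choice(["value", "value", "value", "is_null", "not_null"])
        if test == "value":
            t = "contains" if field in ("AnyField", "Name", "Definition") else "equals"
            return Clause(field, t, rng.choice(values))
        return Clause(field, test)
    kind = rng.choice([And, Or, Not])
    if kind is Not:
        return Not(random_expr(rng, values, depth + 1))
    return kind(random_expr(rng, values, depth + 1),
                random_expr(rng, values, depth + 1))


# ---------------------------------------------------------------------------


class TestGrammar:
    def test_precedence_or_of_two_ands(self):
        expr = parse_query(
            "Taxon ID 9606 AND Ontology ID GO:0000776 OR "
            "Taxon ID 9606 AND Ontology ID GO:0000779"
        )
        assert isinstance(expr, Or)
        assert isinstance(expr.left, And) and isinstance(expr.right, And)
        assert expr.left.right == Clause("OntologyID", "equals", "GO:0000776")

    def test_null_and_not_null_clauses(self):
        assert parse_query("Modifier NULL") == Clause("Modifier", "is_null")
        assert parse_query("Modifier NOT NULL") == Clause("Modifier", "not_null")

    def test_not_binds_tighter_than_and(self):
        expr = parse_query("NOT Name bub1 AND Taxon ID 9606")
        assert isinstance(expr, And) and isinstance(expr.left, Not)

    def test_parentheses_override(self):
        expr = parse_query("Name a AND (Name b OR Name c)")
        assert isinstance(expr, And) and isinstance(expr.right, Or)

    def test_bare_value_searches_any_field(self):
        assert parse_query("bub1") == Clause("AnyField", "contains", "bub1")

    def test_quoted_phrase(self):
        assert parse_query('Name "bub1 beta"') == Clause("Name", "contains",
                                                         "bub1 beta")

    @pytest.mark.parametrize("bad", ["", "Name", "AND foo", "(Name a", "Name a )"])
    def test_syntax_errors_carry_position(self, bad):
        with pytest.raises(QuerySyntaxError):
            parse_query(bad)

    @settings(max_examples=200, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_print_parse_round_trip(self, seed):
        rng = random.Random(seed)
        expr = random_expr(rng, ["bub1", "9606", "GO:0000776", "kinase",
                                 "bub1 beta", "IPI", "increased"])
        assert parse_query(print_query(expr)) == expr


class TestEvaluate:
    def test_pfam_domain_search_returns_family_and_mad3(self, fx):
        ids = evaluate("Ontology ID PFAM:PF08311", fx.terms, fx.paf)
        assert ids == {IDS["family_bub1_bub1b"], IDS["mad3"]}

    def test_taxon_search_is_exact(self, fx):
        ids = evaluate("Taxon ID 9606", fx.terms, fx.paf)
        assert IDS["h_bub1"] in ids
        assert IDS["y_bub1"] not in ids
        assert IDS["bub1"] not in ids

    def test_contradiction_is_empty(self, fx):
        assert evaluate("Name bub1 AND NOT Name bub1", fx.terms, fx.paf) == set()

    def test_de_morgan_consistency(self, fx):
        a, b = 'Name "bub1 beta"', "Taxon ID 9606"
        lhs = evaluate(f"NOT ({a} OR {b})", fx.terms, fx.paf)
        rhs = evaluate(f"NOT {a} AND NOT {b}", fx.terms, fx.paf)
        assert lhs == rhs

    def test_and_clause_never_enlarges(self, fx):
        base = evaluate('Name "bub1 beta"', fx.terms, fx.paf)
        narrowed = evaluate('Name "bub1 beta" AND Taxon ID 9606',
                            fx.terms, fx.paf)
        assert narrowed <= base

    def test_obsolete_terms_excluded_by_default(self):
        terms = [ProTerm("PR:1", name="zombie protein", is_obsolete=True)]
        assert evaluate("Name zombie", terms, []) == set()
        assert evaluate("Name zombie", terms, [], include_obsolete=True) == {"PR:1"}

    def test_unknown_field_rejected(self):
        with pytest.raises(QueryError):
            Clause("Shoesize", "equals", "42")

    @pytest.mark.parametrize("seed", [11, 12])
    def test_matches_naive_filter_oracle(self, seed):
        fixture = random_fixture(seed, n_genes=8, n_species=2)
        rng = random.Random(seed)
        values = ["GENE3", "9606", "GO:0000776", "increased", "IPI", "G2",
                  "phospho", "kinase"]
        for _ in range(150):
            expr = random_expr(rng, values)
            assert evaluate(expr, fixture.terms, fixture.paf) == \
                evaluate_oracle(expr, fixture.terms, fixture.paf)


class TestQuickLinks:
    def test_phospho_form_search_returns_eleven(self, fx, graph):
        ids = evaluate('Name "bub1 beta"', fx.terms, fx.paf)
        forms = quicklink_filter(ids, "phosphorylated_forms", graph)
        assert len(forms) == 11
        si = {f for f in forms if not graph.terms[f].organism_specific}
        assert si == {IDS["p1"], IDS["p2"], IDS["p3"], IDS["p4"]}

    def test_unphosphorylated_form_not_a_phospho_form(self, fx, graph):
        ids = {IDS["h_bub1b_unphos"], IDS["h_p2"]}
        assert quicklink_filter(ids, "phosphorylated_forms", graph) == {IDS["h_p2"]}

    def test_complexes_filter_is_subset_with_complex_category(self, fx, graph):
        ids = evaluate("bub1", fx.terms, fx.paf)
        cx = quicklink_filter(ids, "complexes", graph)
        assert cx <= ids
        assert all(graph.terms[c].level == "complex" for c in cx)

    def test_empty_input_empty_output(self, graph):
        assert quicklink_filter(set(), "complexes", graph) == set()

    def test_unknown_kind_rejected(self, graph):
        with pytest.raises(QueryError):
            quicklink_filter(set(), "phosphoforms", graph)


class TestExportTable:
    def test_two_term_result_with_domain_columns(self, fx):
        ids = evaluate("Ontology ID PFAM:PF08311", fx.terms, fx.paf)
        table = export_table(ids, ["id", "name", "xrefs", "definition"], fx.terms)
        assert len(table) == 2
        assert list(table["id"]) == sorted(ids)
        row = table[table["id"] == IDS["family_bub1_bub1b"]].iloc[0]
        assert "PFAM:PF08311" in row["xrefs"] and "PFAM:PF00069" in row["xrefs"]

    def test_empty_ids_header_only(self, fx):
        table = export_table(set(), ["id", "name"], fx.terms)
        tsv = table.to_csv(sep="\t", index=False)
        assert tsv == "id\tname\n"

    def test_tsv_reread_preserves_id_set(self, fx, tmp_path):
        import pandas as pd

        ids = evaluate('Name "bub1 beta"', fx.terms, fx.paf)
        table = export_table(ids, ["id", "name", "category"], fx.terms)
        p = tmp_path / "t.tsv"
        p.write_text(table.to_csv(sep="\t", index=False, lineterminator="\n"))
        assert set(pd.read_csv(p, sep="\t")["id"]) == ids

    def test_unknown_column_rejected(self, fx):
        with pytest.raises(QueryError):
            export_table(set(), ["id", "shoesize"], fx.terms)
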