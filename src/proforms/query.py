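"""Boolean field-restricted search over terms and their annotations.

The grammar mirrors an ontology website search box::

    query   := or
    or      := and ( OR and )*
    and     := not ( AND not )*
    not     := NOT not | atom
    atom    := '(' or ')' | clause
    clause  := [field] ( 'NULL' | 'NOT NULL' | value )

Fields are ``Any Field``, ``Name``, ``Definition``, ``Taxon ID``,
``Ontology ID``, ``PRO ID``, ``Modifier`` and ``Evidence Code``; a bare
value searches Any Field.  Values with spaces are double-quoted.
``AND`` binds tighter than ``OR`` and ``NOT`` tighter than both.

Matching semantics: free-text fields (Name, Definition, Any Field) are
case-insensitive substring matches; identifier fields (Taxon ID,
Ontology ID, PRO ID, Modifier, Evidence Code) are exact
(case-insensitive) matches.  Annotation-backed fields match a term when
*any* of its annotation lines matches.  ``Modifier NOT NULL`` selects
terms with at least one annotation line whose modifier is not ``none``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .graph import OntologyGraph
from .obo import ProTerm
from .paf import NO_MODIFIER, PafRecord

__all__ = [
    "Clause",
    "And",
    "Or",
    "Not",
    "QuerySyntaxError",
    "QueryError",
    "parse_query",
    "print_query",
    "evaluate",
    "quicklink_filter",
    "export_table",
    "FIELDS",
    "QUICKLINKS",
]

# canonical field key -> surface name in the grammar
FIELDS: dict[str, str] = {
    "AnyField": "Any Field",
    "Name": "Name",
    "Definition": "Definition",
    "TaxonID": "Taxon ID",
    "OntologyID": "Ontology ID",
    "PROID": "PRO ID",
    "Modifier": "Modifier",
    "EvidenceCode": "Evidence Code",
}
_SURFACE = {v.lower(): k for k, v in FIELDS.items()}

_TEXT_FIELDS = {"AnyField", "Name", "Definition"}

QUICKLINKS = ("phosphorylated_forms", "complexes", "modified_forms", "disease_forms")


class QuerySyntaxError(ValueError):
    """Query text does not match the grammar; message carries the position."""


class QueryError(ValueError):
    """Semantic error (unknown field, unknown quick link, ...)."""


# ---------------------------------------------------------------------------
# AST


@dataclass(frozen=True)
class Clause:
    field: str
    test: str  # contains | equals | is_null | not_null
    value: str | None = None

    def __post_init__(self):
        if self.field not in FIELDS:
            raise QueryError(f"unknown field {self.field!r}")
        if self.test in ("is_null", "not_null"):
            if self.value is not None:
                raise QueryError(f"{self.test} clause carries no value")
        elif self.value is None:
            raise QueryError(f"{self.test} clause requires a value")


@dataclass(frozen=True)
class Not:
    expr: "Expr"


@dataclass(frozen=True)
class And:
    left: "Expr"
    right: "Expr"


@dataclass(frozen=True)
class Or:
    left: "Expr"
    right: "Expr"


Expr = Clause | Not | And | Or


# ---------------------------------------------------------------------------
# parser

_TOKEN_RE = re.compile(r'\s*(\(|\)|"(?:[^"\\]|\\.)*"|[^\s()]+)')


def _tokenize(text: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m:
            break
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    if text[pos:].strip():
        raise QuerySyntaxError(f"cannot tokenize at position {pos}")
    return tokens


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self, ahead: int = 0) -> str | None:
        j = self.i + ahead
        return self.tokens[j][0] if j < len(self.tokens) else None

    def next(self) -> str:
        if self.i >= len(self.tokens):
            raise QuerySyntaxError(f"unexpected end of query at position {len(self.text)}")
        tok, _ = self.tokens[self.i]
        self.i += 1
        return tok

    def error(self, msg: str) -> QuerySyntaxError:
        pos = self.tokens[self.i][1] if self.i < len(self.tokens) else len(self.text)
        return QuerySyntaxError(f"{msg} at position {pos}")

    # grammar -------------------------------------------------------------
    def parse(self) -> Expr:
        if not self.tokens:
            raise QuerySyntaxError("empty query")
        expr = self.parse_or()
        if self.i < len(self.tokens):
            raise self.error(f"unexpected token {self.peek()!r}")
        return expr

    def parse_or(self) -> Expr:
        left = self.parse_and()
        while self.peek() == "OR":
            self.next()
            left = Or(left, self.parse_and())
        return left

    def parse_and(self) -> Expr:
        left = self.parse_not()
        while self.peek() == "AND":
            self.next()
            left = And(left, self.parse_not())
        return left

    def parse_not(self) -> Expr:
        if self.peek() == "NOT" and self.peek(1) != "NULL":
            self.next()
            return Not(self.parse_not())
        return self.parse_atom()

    def parse_atom(self) -> Expr:
        if self.peek() == "(":
            self.next()
            expr = self.parse_or()
            if self.peek() != ")":
                raise self.error("expected ')'")
            self.next()
            return expr
        return self.parse_clause()

    def _match_field(self) -> str | None:
        one = self.peek()
        if one is None:
            return None
        two = f"{one} {self.peek(1)}".lower() if self.peek(1) else None
        if two in _SURFACE:
            self.next()
            self.next()
            return _SURFACE[two]
        if one.lower() in _SURFACE:
            self.next()
            return _SURFACE[one.lower()]
        return None

    def parse_clause(self) -> Clause:
        field = self._match_field() or "AnyField"
        tok = self.peek()
        if tok is None:
            raise self.error("expected a search value")
        if tok == "NULL":
            self.next()
            return Clause(field, "is_null")
        if tok == "NOT" and self.peek(1) == "NULL":
            self.next()
            self.next()
            return Clause(field, "not_null")
        value = self.next()
        if value in (")", "(", "AND", "OR"):
            raise self.error(f"expected a search value, got {value!r}")
        if value.startswith('"') and value.endswith('"') and len(value) >= 2:
            value = value[1:-1].replace('\\"', '"').replace("\\\\", "\\")
        test = "contains" if field in _TEXT_FIELDS else "equals"
        return Clause(field, test, value)


def parse_query(text: str) -> Expr:
    """Parse query text into an AST; raises :class:`QuerySyntaxError`."""
    return _Parser(text).parse()


def _print_value(value: str) -> str:
    if value == "" or re.search(r"[\s()\"]", value) or value in ("AND", "OR", "NOT", "NULL"):
        return '"' + value.replace("\\", "\\\\").replace('"', '\\"') + '"'
    return value


def print_query(expr: Expr) -> str:
    """Canonical text form; ``parse_query(print_query(e))`` is identity."""
    if isinstance(expr, Clause):
        surface = FIELDS[expr.field]
        if expr.test == "is_null":
            return f"{surface} NULL"
        if expr.test == "not_null":
            return f"{surface} NOT NULL"
        return f"{surface} {_print_value(expr.value)}"
    if isinstance(expr, Not):
        inner = print_query(expr.expr)
        if isinstance(expr.expr, (And, Or)):
            inner = f"({inner})"
        return f"NOT {inner}"
    if isinstance(expr, And):
        left = print_query(expr.left)
        if isinstance(expr.left, Or):
            left = f"({left})"
        right = print_query(expr.right)
        if isinstance(expr.right, (And, Or)):  # parser is left-associative
            right = f"({right})"
        return f"{left} AND {right}"
    if isinstance(expr, Or):
        right = print_query(expr.right)
        if isinstance(expr.right, Or):
            right = f"({right})"
        return f"{print_query(expr.left)} OR {right}"
    raise TypeError(f"not a query expression: {expr!r}")


# ---------------------------------------------------------------------------
# evaluation


def _norm_acc(s: str) -> str:
    return s.strip().lower()


def _acc_matches(query: str, candidate: str) -> bool:
    """Exact accession match, tolerant of a database prefix on either side."""
    q, c = _norm_acc(query), _norm_acc(candidate)
    if q == c:
        return True
    c_local = c.split(":", 1)[-1]
    q_local = q.split(":", 1)[-1]
    return q == c_local or q_local == c


class _TermView:
    """Pre-joined view of one term and its annotation lines."""

    __slots__ = ("term", "paf")

    def __init__(self, term: ProTerm, paf: list[PafRecord]):
        self.term = term
        self.paf = paf

    def field_values(self, field: str) -> list[str]:
        t = self.term
        if field == "Name":
            return [t.name, *t.synonyms]
        if field == "Definition":
            return [t.definition]
        if field == "AnyField":
            return [t.term_id, t.name, *t.synonyms, t.definition, *t.xrefs]
        if field == "PROID":
            return [t.term_id]
        if field == "TaxonID":
            vals = [str(t.taxon_id)] if t.taxon_id is not None else []
            vals += [str(r.taxon_id) for r in self.paf if r.taxon_id is not None]
            return vals
        if field == "OntologyID":
            return [r.ontology_id for r in self.paf if r.ontology_id] + list(t.xrefs)
        if field == "Modifier":
            return [r.modifier for r in self.paf if r.modifier != NO_MODIFIER]
        if field == "EvidenceCode":
            return [r.evidence_code for r in self.paf if r.evidence_code]
        raise QueryError(f"unknown field {field!r}")

    def matches(self, clause: Clause) -> bool:
        values = self.field_values(clause.field)
        if clause.test == "not_null":
            return bool(values)
        if clause.test == "is_null":
            return not values
        if clause.test == "contains":
            needle = clause.value.lower()
            return any(needle in v.lower() for v in values)
        return any(_acc_matches(clause.value, v) for v in values)


def _views(
    terms: Iterable[ProTerm], paf: Iterable[PafRecord]
) -> dict[str, _TermView]:
    by_id: dict[str, list[PafRecord]] = {}
    for r in paf:
        by_id.setdefault(r.pro_id, []).append(r)
    return {t.term_id: _TermView(t, by_id.get(t.term_id, [])) for t in terms}


def evaluate(
    expr: Expr | str,
    terms: Iterable[ProTerm],
    paf: Iterable[PafRecord] = (),
    include_obsolete: bool = False,
) -> set[str]:
    """Evaluate a query over terms + annotations; returns matching term ids.

    Set semantics: the result is a set of term accessions; NOT is the
    complement within the evaluated universe (non-obsolete terms unless
    ``include_obsolete``).
    """
    if isinstance(expr, str):
        expr = parse_query(expr)
    views = _views(terms, paf)
    if not include_obsolete:
        views = {k: v for k, v in views.items() if not v.term.is_obsolete}
    universe = set(views)

    def ev(e: Expr) -> set[str]:
        if isinstance(e, Clause):
            return {tid for tid, v in views.items() if v.matches(e)}
        if isinstance(e, Not):
            return universe - ev(e.expr)
        if isinstance(e, And):
            return ev(e.left) & ev(e.right)
        if isinstance(e, Or):
            return ev(e.left) | ev(e.right)
        raise TypeError(f"not a query expression: {e!r}")

    return ev(expr)


# ---------------------------------------------------------------------------
# quick links

# a "phospho" mention not preceded by a letter; rejects unphosphorylated,
# dephosphorylated and similar negated compounds
_PHOS_RE = re.compile(r"(?<![a-z])phospho", re.IGNORECASE)


def _is_phospho_form(term: ProTerm) -> bool:
    text = " ".join([term.name, *term.synonyms, term.definition])
    return bool(_PHOS_RE.search(text))


def quicklink_filter(
    ids: Iterable[str],
    kind: str,
    graph: OntologyGraph,
) -> set[str]:
    """Restrict a result set to a category shortcut.

    ``complexes`` keeps complex-level terms; ``modified_forms`` keeps
    modification-level terms; ``phosphorylated_forms`` additionally
    requires a (non-negated) phosphorylation mention in the name,
    synonyms or definition; ``disease_forms`` keeps terms flagged as
    disease-related in their text.
    """
    if kind not in QUICKLINKS:
        raise QueryError(f"unknown quick link {kind!r}")
    out: set[str] = set()
    for tid in ids:
        term = graph.terms.get(tid)
        if term is None:
            continue
        level = (graph.category(tid) or "").removeprefix("organism-")
        if kind == "complexes":
            ok = level == "complex"
        elif kind == "modified_forms":
            ok = level == "modification"
        elif kind == "phosphorylated_forms":
            ok = level == "modification" and _is_phospho_form(term)
        else:  # disease_forms
            text = " ".join([term.name, *term.synonyms, term.definition])
            ok = "disease" in text.lower()
        if ok:
            out.add(tid)
    return out


# ---------------------------------------------------------------------------
# result tables

_COLUMN_GETTERS = {
    "id": lambda t: t.term_id,
    "name": lambda t: t.name,
    "category": lambda t: t.category or "",
    "definition": lambda t: t.definition,
    "comment": lambda t: t.comment,
    "synonyms": lambda t: "|".join(t.synonyms),
    "xrefs": lambda t: "|".join(t.xrefs),
    "taxon_id": lambda t: "" if t.taxon_id is None else str(t.taxon_id),
}


def export_table(
    ids: Iterable[str],
    columns: Sequence[str],
    terms: Mapping[str, ProTerm] | Iterable[ProTerm],
) -> pd.DataFrame:
    """Result table with the selected columns, rows sorted by accession.

    ``DataFrame.to_csv(sep="\\t", index=False)`` yields the downloadable
    tab-delimited form.
    """
    for c in columns:
        if c not in _COLUMN_GETTERS:
            raise QueryError(f"unknown column {c!r}")
    if not isinstance(terms, Mapping):
        terms = {t.term_id: t for t in terms}
    rows = []
    for tid in sorted(set(ids)):
        t = terms[tid]
        rows.append({c: _COLUMN_GETTERS[c](t) for c in columns})
    return pd.DataFrame(rows, columns=list(columns))
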