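"""Reading and writing of protein-ontology term stanzas (OBO dialect).

The dialect is the subset of OBO 1.2 used by protein-form ontologies:
``format-version``, ``[Term]`` stanzas with ``id``, ``name``, ``def``,
``comment``, ``synonym``, ``xref``, ``is_a``, ``relationship`` and
``is_obsolete`` lines.  Unknown tag lines are preserved verbatim so that
``parse_obo(write_obo(terms))`` reproduces every term field-for-field.

Term categories (family / gene / sequence / modification / complex, each
optionally organism-specific) follow the curators' convention of a
``Category=<name>.`` marker at the start of the free-text comment.

Kinase provenance is carried in the comment in the standardized form
``Kinase = "NAME"; ACCESSION`` and extracted by :func:`parse_kinase_comment`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

__all__ = [
    "ProTerm",
    "KinaseStatement",
    "OboParseError",
    "TermValidationError",
    "parse_obo",
    "write_obo",
    "parse_kinase_comment",
    "is_accession",
]

#: categories at each level of the hierarchy; organism-specific variants
#: carry an ``organism-`` prefix (e.g. ``organism-modification``).
LEVELS = ("family", "gene", "sequence", "modification", "complex")
CATEGORIES = LEVELS + tuple("organism-" + lv for lv in LEVELS)

_ACCESSION_RE = re.compile(r"^[A-Za-z][A-Za-z0-9_]*:[A-Za-z0-9._\-]+$")

_KNOWN_TAGS = (
    "id",
    "name",
    "def",
    "comment",
    "synonym",
    "xref",
    "is_a",
    "relationship",
    "is_obsolete",
)


class OboParseError(ValueError):
    """Malformed stanza; the message names the offending line number."""


class TermValidationError(ValueError):
    """A term violates the dialect invariants."""


def is_accession(s: str) -> bool:
    """True for a well-formed ``PREFIX:LOCAL`` ontology accession."""
    return bool(_ACCESSION_RE.match(s))


@dataclass
class ProTerm:
    """One ontology term.

    ``relations`` holds ``(kind, target)`` pairs for is_a, has_part,
    derives_from and only_in_taxon; ``taxon_id`` mirrors the
    only_in_taxon relation for organism-specific terms.
    """

    term_id: str
    name: str = ""
    definition: str = ""
    comment: str = ""
    category: str | None = None
    synonyms: list[str] = field(default_factory=list)
    xrefs: list[str] = field(default_factory=list)
    relations: list[tuple[str, str]] = field(default_factory=list)
    taxon_id: int | None = None
    is_obsolete: bool = False
    extra_tags: list[tuple[str, str]] = field(default_factory=list)

    # -- category helpers -------------------------------------------------
    @property
    def level(self) -> str | None:
        """Hierarchy level with the organism- prefix stripped."""
        if self.category is None:
            return None
        return self.category.removeprefix("organism-")

    @property
    def organism_specific(self) -> bool:
        return self.category is not None and self.category.startswith("organism-")

    def parents(self, kind: str = "is_a") -> list[str]:
        return [t for k, t in self.relations if k == kind]

    def validate(self) -> None:
        if not self.term_id:
            raise TermValidationError("term has empty id")
        if not is_accession(self.term_id):
            raise TermValidationError(f"malformed term id {self.term_id!r}")
        if self.category is not None and self.category not in CATEGORIES:
            raise TermValidationError(
                f"{self.term_id}: unknown category {self.category!r}"
            )
        for kind, target in self.relations:
            if not is_accession(target):
                raise TermValidationError(
                    f"{self.term_id}: malformed relation target {target!r}"
                )
        if self.organism_specific and self.taxon_id is None:
            raise TermValidationError(
                f"{self.term_id}: organism-specific category requires a taxon"
            )
        if self.is_obsolete and self.relations:
            raise TermValidationError(
                f"{self.term_id}: obsolete terms carry no relations"
            )


@dataclass(frozen=True)
class KinaseStatement:
    """A parsed kinase assertion from a term comment."""

    kinase_name: str
    kinase_id: str
    substrate_form_id: str | None = None
    qualifier: str | None = None


# ---------------------------------------------------------------------------
# parsing

_CATEGORY_RE = re.compile(r"^Category=([A-Za-z-]+)\.\s*")
_QUOTED_RE = re.compile(r'^"((?:[^"\\]|\\.)*)"')


def _unescape(s: str) -> str:
    return s.replace('\\"', '"').replace("\\\\", "\\")


def _take_quoted(text: str, lineno: int) -> tuple[str, str]:
    m = _QUOTED_RE.match(text)
    if not m:
        raise OboParseError(f"line {lineno}: expected quoted string in {text!r}")
    return _unescape(m.group(1)), text[m.end():]


def parse_obo(stream: str | Iterable[str]) -> list[ProTerm]:
    """Parse OBO text into a list of :class:`ProTerm`, order preserved.

    Header lines before the first stanza are ignored; non-``[Term]``
    stanzas are skipped.  Raises :class:`OboParseError` for a stanza
    without an ``id`` line or a duplicated id.
    """
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = [ln.rstrip("\r\n") for ln in stream]

    terms: list[ProTerm] = []
    seen: dict[str, int] = {}
    cur: ProTerm | None = None
    cur_start = 0
    in_term = False

    def flush() -> None:
        nonlocal cur
        if in_term:
            if cur is None or not cur.term_id:
                raise OboParseError(f"line {cur_start}: [Term] stanza missing id")
            if cur.term_id in seen:
                raise OboParseError(
                    f"line {cur_start}: duplicate term id {cur.term_id}"
                )
            seen[cur.term_id] = cur_start
            terms.append(cur)
        cur = None

    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip()
        if not line or line.startswith("!"):
            continue
        if line.startswith("["):
            flush()
            in_term = line == "[Term]"
            cur = ProTerm(term_id="") if in_term else None
            cur_start = lineno
            continue
        if not in_term or cur is None:
            continue
        if ":" not in line:
            raise OboParseError(f"line {lineno}: expected 'tag: value', got {line!r}")
        tag, _, value = line.partition(":")
        tag = tag.strip()
        value = value.strip()
        _parse_tag(cur, tag, value, lineno)
    flush()
    return terms


def _parse_tag(term: ProTerm, tag: str, value: str, lineno: int) -> None:
    if tag == "id":
        term.term_id = value
    elif tag == "name":
        term.name = value
    elif tag == "def":
        text, _rest = _take_quoted(value, lineno)
        term.definition = text
    elif tag == "comment":
        m = _CATEGORY_RE.match(value)
        if m:
            term.category = m.group(1)
            value = value[m.end():]
        term.comment = value
    elif tag == "synonym":
        text, _rest = _take_quoted(value, lineno)
        term.synonyms.append(text)
    elif tag == "xref":
        term.xrefs.append(value)
    elif tag == "is_a":
        target = value.split("!", 1)[0].strip()
        term.relations.append(("is_a", target))
    elif tag == "relationship":
        body = value.split("!", 1)[0].strip()
        parts = body.split()
        if len(parts) != 2:
            raise OboParseError(f"line {lineno}: malformed relationship {value!r}")
        kind, target = parts
        term.relations.append((kind, target))
        if kind == "only_in_taxon" and target.startswith("NCBITaxon:"):
            try:
                term.taxon_id = int(target.split(":", 1)[1])
            except ValueError:
                raise OboParseError(f"line {lineno}: bad taxon in {value!r}") from None
    elif tag == "is_obsolete":
        term.is_obsolete = value.lower() == "true"
    else:
        term.extra_tags.append((tag, value))


# ---------------------------------------------------------------------------
# writing


def _escape(s: str) -> str:
    return s.replace("\\", "\\\\").replace('"', '\\"')


def _term_lines(t: ProTerm) -> Iterator[str]:
    yield "[Term]"
    yield f"id: {t.term_id}"
    if t.name:
        yield f"name: {t.name}"
    if t.definition:
        yield f'def: "{_escape(t.definition)}" []'
    if t.category is not None or t.comment:
        prefix = f"Category={t.category}. " if t.category is not None else ""
        yield f"comment: {prefix}{t.comment}".rstrip()
    for syn in t.synonyms:
        yield f'synonym: "{_escape(syn)}" EXACT []'
    for x in t.xrefs:
        yield f"xref: {x}"
    for kind, target in t.relations:
        if kind == "is_a":
            yield f"is_a: {target}"
        else:
            yield f"relationship: {kind} {target}"
    if t.is_obsolete:
        yield "is_obsolete: true"
    for tag, value in t.extra_tags:
        yield f"{tag}: {value}"


def write_obo(terms: Iterable[ProTerm]) -> str:
    """Serialize terms byte-deterministically (LF endings, fixed header)."""
    out = ["format-version: 1.2", ""]
    for t in terms:
        t.validate()
        out.extend(_term_lines(t))
        out.append("")
    return "\n".join(out)


# ---------------------------------------------------------------------------
# kinase comments

# the accession may be followed by sentence punctuation: forbid a final dot
_ACC_PAT = r"[A-Za-z]+:[A-Za-z0-9._\-]*[A-Za-z0-9]"
_KINASE_STRICT = re.compile(r'Kinase\s*=\s*"([^"]+)"\s*;\s*(' + _ACC_PAT + ")")
_KINASE_LENIENT = re.compile(
    r"(\S+)\s+\((" + _ACC_PAT + r")\)\s+as\s+the\s+kinase(?:\s+([^.]*))?"
)


def parse_kinase_comment(
    comment: str,
    substrate_form_id: str | None = None,
    lenient: bool = False,
) -> list[KinaseStatement]:
    """Extract kinase statements from free-text comments.

    The strict pattern is the curators' standardized ``Kinase = "NAME";
    ACCESSION``.  With ``lenient=True``, narrative phrasings of the form
    ``NAME (ACCESSION) as the kinase ...`` are captured too, with the
    trailing clause kept as a qualifier.  Total on any input: unmatched
    text yields an empty list, never an error.
    """
    if not comment:
        return []
    stmts = [
        KinaseStatement(name.strip(), acc, substrate_form_id)
        for name, acc in _KINASE_STRICT.findall(comment)
    ]
    if lenient:
        for m in _KINASE_LENIENT.finditer(comment):
            qual = m.group(3)
            stmts.append(
                KinaseStatement(
                    m.group(1),
                    m.group(2),
                    substrate_form_id,
                    qual.strip() if qual else None,
                )
            )
    return stmts
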