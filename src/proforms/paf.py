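"""Reading and writing of the tab-delimited protein annotation file (PAF).

The dialect is a fixed 12-column layout, one annotation per line:

==  ==============  ========================================================
 1  PRO_ID          term accession the annotation is attached to
 2  Object_name     free-text label of the annotated form
 3  Object_synonym  short label (may be empty)
 4  Modifier        increased / decreased / altered / NOT; empty means none
 5  Relation        controlled relation (located_in, participates_in, ...)
 6  Ontology_ID     GO / Pfam accession the annotation points to
 7  Ontology_term   free-text name of that accession
 8  Evidence_code   GO evidence code (IPI, IDA, ISS, ...)
 9  Interactor_ID   binding partner accession; required iff evidence is IPI
10  Taxon_ID        numeric NCBI taxon
11  Reference       PMID or source identifier
12  Date            ISO date of the annotation (may be empty)
==  ==============  ========================================================

An optional header line repeating the column names is recognised and
skipped on read and always emitted on write.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable

from .obo import is_accession

__all__ = [
    "PafRecord",
    "PafParseError",
    "parse_paf",
    "write_paf",
    "COLUMNS",
    "MODIFIERS",
    "EVIDENCE_CODES",
    "NO_MODIFIER",
]

COLUMNS = (
    "PRO_ID",
    "Object_name",
    "Object_synonym",
    "Modifier",
    "Relation",
    "Ontology_ID",
    "Ontology_term",
    "Evidence_code",
    "Interactor_ID",
    "Taxon_ID",
    "Reference",
    "Date",
)

NO_MODIFIER = "none"
MODIFIERS = ("increased", "decreased", "altered", "NOT", NO_MODIFIER)

#: closed set of GO evidence codes accepted without a warning
EVIDENCE_CODES = frozenset(
    {
        "EXP", "IDA", "IPI", "IMP", "IGI", "IEP",
        "HTP", "HDA", "HMP", "HGI", "HEP",
        "ISS", "ISO", "ISA", "ISM", "IBA",
        "TAS", "NAS", "IC", "ND", "IEA",
    }
)


class PafParseError(ValueError):
    """Malformed annotation line; the message names the line number."""


@dataclass
class PafRecord:
    """One annotation line of the PAF."""

    pro_id: str
    object_name: str = ""
    object_synonym: str = ""
    modifier: str = NO_MODIFIER
    relation: str = ""
    ontology_id: str = ""
    ontology_term: str = ""
    evidence_code: str = ""
    interactor_id: str = ""
    taxon_id: int | None = None
    reference: str = ""
    date: str = ""
    flags: tuple[str, ...] = field(default_factory=tuple, compare=False)

    def validate(self) -> None:
        if not is_accession(self.pro_id):
            raise PafParseError(f"malformed PRO id {self.pro_id!r}")
        if self.modifier not in MODIFIERS:
            raise PafParseError(f"{self.pro_id}: unknown modifier {self.modifier!r}")
        if self.evidence_code and self.evidence_code not in EVIDENCE_CODES:
            raise PafParseError(
                f"{self.pro_id}: unknown evidence code {self.evidence_code!r}"
            )
        if self.evidence_code == "IPI" and not self.interactor_id:
            raise PafParseError(
                f"{self.pro_id}: IPI annotation requires an interactor id"
            )


def parse_paf(stream: str | Iterable[str]) -> list[PafRecord]:
    """Parse tab-delimited annotation text into :class:`PafRecord` objects.

    The empty modifier field maps to ``"none"``.  A wrong column count is
    an error naming the line; an unknown evidence code or an IPI line
    without an interactor triggers a warning and the record is retained
    with the problem recorded in ``flags``.
    """
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = [ln.rstrip("\r\n") for ln in stream]

    records: list[PafRecord] = []
    for lineno, line in enumerate(lines, start=1):
        if not line or line.startswith("!"):
            continue
        cols = line.split("\t")
        if cols[0] == COLUMNS[0]:
            continue  # header
        if len(cols) != len(COLUMNS):
            raise PafParseError(
                f"line {lineno}: expected {len(COLUMNS)} columns, got {len(cols)}"
            )
        flags: list[str] = []
        evidence = cols[7].strip()
        if evidence and evidence not in EVIDENCE_CODES:
            warnings.warn(
                f"line {lineno}: unknown evidence code {evidence!r}", stacklevel=2
            )
            flags.append("unknown_evidence_code")
        if evidence == "IPI" and not cols[8].strip():
            warnings.warn(
                f"line {lineno}: IPI annotation without interactor", stacklevel=2
            )
            flags.append("ipi_without_interactor")
        taxon = cols[9].strip()
        records.append(
            PafRecord(
                pro_id=cols[0].strip(),
                object_name=cols[1].strip(),
                object_synonym=cols[2].strip(),
                modifier=cols[3].strip() or NO_MODIFIER,
                relation=cols[4].strip(),
                ontology_id=cols[5].strip(),
                ontology_term=cols[6].strip(),
                evidence_code=evidence,
                interactor_id=cols[8].strip(),
                taxon_id=int(taxon) if taxon else None,
                reference=cols[10].strip(),
                date=cols[11].strip(),
                flags=tuple(flags),
            )
        )
    return records


def write_paf(records: Iterable[PafRecord]) -> str:
    """Serialize records byte-deterministically; ``none`` modifier → empty."""
    buf = io.StringIO()
    buf.write("\t".join(COLUMNS) + "\n")
    for r in records:
        r.validate()
        row = (
            r.pro_id,
            r.object_name,
            r.object_synonym,
            "" if r.modifier == NO_MODIFIER else r.modifier,
            r.relation,
            r.ontology_id,
            r.ontology_term,
            r.evidence_code,
            r.interactor_id,
            "" if r.taxon_id is None else str(r.taxon_id),
            r.reference,
            r.date,
        )
        buf.write("\t".join(row) + "\n")
    return buf.getvalue()
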