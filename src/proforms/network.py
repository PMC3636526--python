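"""Typed interaction networks derived from terms + annotations.

Edges come from four sources:

* ``interacts_with`` — annotation lines with the IPI evidence code
  (inferred from physical interaction), symmetrized and deduplicated;
* ``inhibited_interaction`` — IPI lines carrying the negating ``NOT``
  modifier (a modification state that blocks the binding);
* ``phosphorylates`` — standardized kinase statements parsed out of the
  comments of modification-level terms, kinase → phosphorylated form;
* ``is_a_parent`` — hierarchy edges from a modification-level term to
  its gene-level parent(s).

The result can be bundled into two deterministic tab-delimited tables
(network + node attributes) in the layout Cytoscape imports via
"Import → Network from table" / "Import → Attribute from table".
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .graph import OntologyGraph
from .obo import ProTerm, is_accession, parse_kinase_comment
from .paf import PafRecord

__all__ = [
    "NetEdge",
    "NetworkBundle",
    "EdgeExtraction",
    "extract_edges",
    "build_bundle",
    "write_cytoscape",
    "read_cytoscape",
    "bundle_to_sif",
    "EDGE_KINDS",
]

EDGE_KINDS = ("interacts_with", "inhibited_interaction", "phosphorylates", "is_a_parent")

EDGE_COLUMNS = ("source", "interaction", "target", "evidence", "reference")
ATTR_COLUMNS = ("id", "name", "category", "label", "definition")


@dataclass(frozen=True, order=True)
class NetEdge:
    source: str
    kind: str
    target: str
    evidence_code: str = ""
    reference: str = ""


@dataclass(frozen=True)
class EdgeExtraction:
    edges: tuple[NetEdge, ...]
    skipped: tuple[str, ...]  # human-readable notes on unusable lines


class NetworkError(ValueError):
    pass


def extract_edges(
    ids: Iterable[str],
    terms: Mapping[str, ProTerm] | Iterable[ProTerm],
    paf: Iterable[PafRecord],
    graph: OntologyGraph,
    include_is_a: bool = True,
    lenient_kinase: bool = False,
) -> EdgeExtraction:
    """Derive typed edges for the selected terms.

    Interaction edges are undirected in meaning: each unordered pair is
    recorded once with the lexicographically smaller accession as the
    source.  Kinase edges point kinase → phosphorylated-form term.
    IPI lines whose interactor accession is malformed or unknown are
    reported in ``skipped``, never silently dropped.
    """
    if not isinstance(terms, Mapping):
        terms = {t.term_id: t for t in terms}
    idset = set(ids)
    edges: set[NetEdge] = set()
    skipped: list[str] = []

    for r in sorted(
        (r for r in paf if r.evidence_code == "IPI" and r.pro_id in idset),
        key=lambda r: (r.pro_id, r.interactor_id, r.reference),
    ):
        if not r.interactor_id or not is_accession(r.interactor_id):
            skipped.append(f"{r.pro_id}: unusable interactor {r.interactor_id!r}")
            continue
        if r.interactor_id not in terms:
            skipped.append(f"{r.pro_id}: unknown interactor {r.interactor_id}")
            continue
        kind = "inhibited_interaction" if r.modifier == "NOT" else "interacts_with"
        a, b = sorted((r.pro_id, r.interactor_id))
        if a == b:
            skipped.append(f"{r.pro_id}: self-interaction line skipped")
            continue
        candidate = NetEdge(a, kind, b, "IPI", r.reference)
        # first line (in sorted order) wins for the provenance fields
        if not any(e.source == a and e.target == b and e.kind == kind for e in edges):
            edges.add(candidate)

    for tid in sorted(idset):
        term = terms.get(tid)
        if term is None:
            continue
        level = (graph.category(tid) or "").removeprefix("organism-")
        if level != "modification":
            continue
        for stmt in parse_kinase_comment(term.comment, tid, lenient=lenient_kinase):
            if stmt.kinase_id in terms:
                edges.add(NetEdge(stmt.kinase_id, "phosphorylates", tid))
            else:
                skipped.append(f"{tid}: unknown kinase {stmt.kinase_id}")
        if include_is_a:
            for parent in term.parents("is_a"):
                if parent in graph.terms and (
                    graph.category(parent) or ""
                ).removeprefix("organism-") == "gene":
                    edges.add(NetEdge(tid, "is_a_parent", parent))

    return EdgeExtraction(tuple(sorted(edges)), tuple(skipped))


@dataclass(frozen=True, eq=False)
class NetworkBundle:
    """Edge table + node attribute table, both deterministic."""

    nodes: pd.DataFrame  # columns ATTR_COLUMNS
    edges: pd.DataFrame  # columns EDGE_COLUMNS

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, NetworkBundle)
            and self.nodes.equals(other.nodes)
            and self.edges.equals(other.edges)
        )


def _label(term: ProTerm) -> str:
    """Short display label: the first synonym when present, else the name."""
    return term.synonyms[0] if term.synonyms else term.name


def build_bundle(
    edges: Iterable[NetEdge],
    terms: Mapping[str, ProTerm] | Iterable[ProTerm],
    extra_ids: Iterable[str] = (),
) -> NetworkBundle:
    """Assemble the two tables; every edge endpoint must be a known term."""
    if not isinstance(terms, Mapping):
        terms = {t.term_id: t for t in terms}
    edges = sorted(set(edges))
    node_ids = set(extra_ids)
    for e in edges:
        node_ids.update((e.source, e.target))
    for tid in sorted(node_ids):
        if tid not in terms:
            raise NetworkError(f"edge references unknown term {tid}")
    nodes = pd.DataFrame(
        [
            {
                "id": tid,
                "name": terms[tid].name,
                "category": terms[tid].category or "",
                "label": _label(terms[tid]),
                "definition": terms[tid].definition,
            }
            for tid in sorted(node_ids)
        ],
        columns=list(ATTR_COLUMNS),
    )
    edge_df = pd.DataFrame(
        [
            {
                "source": e.source,
                "interaction": e.kind,
                "target": e.target,
                "evidence": e.evidence_code,
                "reference": e.reference,
            }
            for e in edges
        ],
        columns=list(EDGE_COLUMNS),
    )
    return NetworkBundle(nodes=nodes, edges=edge_df)


def write_cytoscape(
    bundle: NetworkBundle, edge_path: str | Path, attr_path: str | Path
) -> None:
    """Write the importable network and attribute files (LF, byte-stable)."""
    Path(edge_path).write_text(
        bundle.edges.to_csv(sep="\t", index=False, lineterminator="\n")
    )
    Path(attr_path).write_text(
        bundle.nodes.to_csv(sep="\t", index=False, lineterminator="\n")
    )


def read_cytoscape(edge_path: str | Path, attr_path: str | Path) -> NetworkBundle:
    edges = pd.read_csv(edge_path, sep="\t", dtype=str, keep_default_na=False)
    nodes = pd.read_csv(attr_path, sep="\t", dtype=str, keep_default_na=False)
    return NetworkBundle(nodes=nodes, edges=edges)


def bundle_to_sif(bundle: NetworkBundle) -> str:
    """SIF export; the edge kind string is the interaction label."""
    return "".join(
        f"{row.source}\t{row.interaction}\t{row.target}\n"
        for row in bundle.edges.itertuples()
    )
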