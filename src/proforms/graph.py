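"""Typed DAG over ontology terms: hierarchy and composition queries.

The graph keeps one node per term and one directed edge per relation
line.  ``is_a`` edges run child → parent and must be acyclic;
``has_part`` edges run whole → part.  Relation targets that are not in
the parsed file (e.g. parent complex terms reused from another
ontology) become stub nodes flagged *external* rather than being
dropped, so edge counts always match the source file.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import networkx as nx

from .obo import ProTerm

__all__ = ["OntologyGraph", "GraphError"]

#: relation kinds traversed as hierarchy; only_in_taxon is metadata
TRAVERSABLE = ("is_a", "has_part", "derives_from")


class GraphError(ValueError):
    pass


class OntologyGraph:
    """A typed DAG built from parsed terms.

    Attributes
    ----------
    terms : dict mapping term_id -> ProTerm (stubs included)
    external_ids : set of stub ids created for dangling relation targets
    """

    def __init__(self, terms: Iterable[ProTerm]):
        self.terms: dict[str, ProTerm] = {}
        self.external_ids: set[str] = set()
        self._g = nx.MultiDiGraph()

        for t in list(terms):
            t.validate()
            if t.term_id in self.terms:
                raise GraphError(f"duplicate term id {t.term_id}")
            self.terms[t.term_id] = t
            self._g.add_node(t.term_id)

        for t in list(self.terms.values()):
            if t.is_obsolete:
                continue
            for kind, target in t.relations:
                if kind == "only_in_taxon":
                    continue
                if target not in self.terms:
                    if target not in self.external_ids:
                        self.external_ids.add(target)
                        stub = ProTerm(term_id=target, name=target)
                        self.terms[target] = stub
                        self._g.add_node(target, external=True)
                self._g.add_edge(t.term_id, target, key=kind)

        self._assert_acyclic()

    # -- construction helpers ---------------------------------------------
    @classmethod
    def from_terms(cls, terms: Iterable[ProTerm]) -> "OntologyGraph":
        return cls(terms)

    def _assert_acyclic(self) -> None:
        sub = self._edge_subgraph({"is_a"})
        try:
            cycle = nx.find_cycle(sub)
        except nx.NetworkXNoCycle:
            return
        path = " -> ".join(e[0] for e in cycle) + " -> " + cycle[-1][1]
        raise GraphError(f"is_a cycle: {path}")

    def _edge_subgraph(self, kinds: set[str]) -> nx.MultiDiGraph:
        keep = [(u, v, k) for u, v, k in self._g.edges(keys=True) if k in kinds]
        sub = nx.MultiDiGraph()
        sub.add_nodes_from(self._g.nodes)
        sub.add_edges_from((u, v, k) for u, v, k in keep)
        return sub

    # -- basic accessors ---------------------------------------------------
    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def edges(self, kinds: Iterable[str] | None = None) -> list[tuple[str, str, str]]:
        """(source, kind, target) triples, optionally restricted by kind."""
        wanted = set(kinds) if kinds is not None else None
        return sorted(
            (u, k, v)
            for u, v, k in self._g.edges(keys=True)
            if wanted is None or k in wanted
        )

    def category(self, term_id: str) -> str | None:
        """Explicit category, else inferred from namespace and taxon.

        Inference: a GO accession is a species-independent complex (the
        ontology reuses GO complex terms); any other accession is
        gene-level, organism-specific when it carries a taxon.
        """
        t = self.terms[term_id]
        if t.category is not None:
            return t.category
        if term_id.startswith("GO:"):
            return "complex"
        return "organism-gene" if t.taxon_id is not None else "gene"

    def _require(self, term_id: str) -> ProTerm:
        if term_id not in self.terms:
            raise GraphError(f"unknown term id {term_id}")
        return self.terms[term_id]

    # -- traversal ----------------------------------------------------------
    def ancestors(
        self, term_id: str, relation_kinds: Iterable[str] = ("is_a",)
    ) -> set[str]:
        """Transitive closure along the given relation kinds, excluding self."""
        self._require(term_id)
        sub = self._edge_subgraph(set(relation_kinds))
        return set(nx.descendants(sub, term_id))

    def descendants(
        self, term_id: str, relation_kinds: Iterable[str] = ("is_a",)
    ) -> set[str]:
        """Inverse of :meth:`ancestors`: everything reaching term_id."""
        self._require(term_id)
        sub = self._edge_subgraph(set(relation_kinds))
        return set(nx.ancestors(sub, term_id))

    def children(self, term_id: str, kind: str = "is_a") -> set[str]:
        self._require(term_id)
        return {
            u for u, v, k in self._g.in_edges(term_id, keys=True) if k == kind
        }

    def complex_components(self, term_id: str, transitive: bool = False) -> set[str]:
        """Direct (or transitive) has_part targets of a complex term."""
        t = self._require(term_id)
        if (t.level or self.category(term_id).removeprefix("organism-")) != "complex":
            raise GraphError(f"{term_id} is not a complex-category term")
        if transitive:
            return self.ancestors(term_id, relation_kinds=("has_part",))
        return {v for _, v, k in self._g.out_edges(term_id, keys=True) if k == "has_part"}

    def orthology_group(self, term_id: str) -> set[str]:
        """Organism-specific terms grouped under the same species-independent
        parent as ``term_id`` (itself included)."""
        t = self._require(term_id)
        if not t.organism_specific:
            raise GraphError(f"{term_id} is not organism-specific")
        si_parents = [
            p
            for p in t.parents("is_a")
            if p in self.terms
            and not self.terms[p].organism_specific
            and self.terms[p].level == t.level
        ]
        if not si_parents:
            warnings.warn(
                f"{term_id} has no species-independent {t.level}-level parent",
                stacklevel=2,
            )
            return set()
        group: set[str] = set()
        for p in si_parents:
            for c in self.children(p, "is_a"):
                if self.terms[c].organism_specific and self.terms[c].level == t.level:
                    group.add(c)
        group.add(term_id)
        return group

    # -- export --------------------------------------------------------------
    def to_sif(self, kinds: Iterable[str] | None = None) -> str:
        """Simple-interaction-format text, one relation per line."""
        return "".join(f"{u}\t{k}\t{v}\n" for u, k, v in self.edges(kinds))

    def to_networkx(self) -> nx.MultiDiGraph:
        g = self._g.copy()
        for tid, t in self.terms.items():
            g.nodes[tid]["name"] = t.name
            g.nodes[tid]["category"] = self.category(tid) or ""
            g.nodes[tid]["taxon"] = str(t.taxon_id or "")
        return g

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)


def build_graph(terms: Iterable[ProTerm]) -> OntologyGraph:
    """Functional alias for :class:`OntologyGraph`."""
    return OntologyGraph(terms)
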