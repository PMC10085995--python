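"""Ontology graph model and the neighbor relation used by sphere expansion.

Terms live in namespaces (for the real Gene Ontology: biological_process,
cellular_component, molecular_function) and are connected by directed
child -> parent ``is_a`` edges forming a DAG.  Sphere expansion treats two
terms as *adjacent* when they are at distance 1 in this DAG in either
direction (direct parent or direct child); namespaces are hard boundaries.
Other relation types (part_of, regulates, ...) are ignored.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import networkx as nx
import obonet


class OntologyGraph:
    """A validated is_a DAG of ontology terms.

    Wraps a :class:`networkx.DiGraph` whose edges point child -> parent and
    whose nodes carry ``name`` and ``namespace`` attributes.
    """

    def __init__(self, graph: nx.DiGraph):
        self._g = graph
        self._validate()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_terms(
        cls,
        terms: Mapping[str, tuple[str, str]],
        edges: Iterable[tuple[str, str]],
    ) -> "OntologyGraph":
        """Build from {term_id: (name, namespace)} and child->parent edges."""
        g = nx.DiGraph()
        for tid, (name, namespace) in terms.items():
            g.add_node(tid, name=name, namespace=namespace)
        for child, parent in edges:
            g.add_edge(child, parent)
        return cls(g)

    def _validate(self) -> None:
        missing = sorted(
            t for t, d in self._g.nodes(data=True) if "namespace" not in d
        )
        if missing:
            raise ValueError(
                f"is_a references terms never defined in the file: {missing}"
            )
        for child, parent in self._g.edges():
            cns = self._g.nodes[child]["namespace"]
            pns = self._g.nodes[parent]["namespace"]
            if cns != pns:
                raise ValueError(
                    f"is_a edge {child} -> {parent} crosses namespaces "
                    f"({cns!r} -> {pns!r})"
                )
        if not nx.is_directed_acyclic_graph(self._g):
            cycle = nx.find_cycle(self._g)
            raise ValueError(f"ontology contains a cycle: {cycle}")

    # -- queries ----------------------------------------------------------

    @property
    def terms(self) -> list[str]:
        return sorted(self._g.nodes)

    @property
    def graph(self) -> nx.DiGraph:
        return self._g

    def __contains__(self, term: str) -> bool:
        return term in self._g

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    def __eq__(self, other) -> bool:
        if not isinstance(other, OntologyGraph):
            return NotImplemented
        return (
            dict(self._g.nodes(data=True)) == dict(other._g.nodes(data=True))
            and set(self._g.edges()) == set(other._g.edges())
        )

    def _check(self, term: str) -> None:
        if term not in self._g:
            raise KeyError(f"unknown term {term!r}")

    def name(self, term: str) -> str:
        self._check(term)
        return self._g.nodes[term].get("name", term)

    def namespace(self, term: str) -> str:
        self._check(term)
        return self._g.nodes[term]["namespace"]

    def parents(self, term: str) -> set[str]:
        """Direct is_a parents."""
        self._check(term)
        return set(self._g.successors(term))

    def children(self, term: str) -> set[str]:
        """Direct is_a children."""
        self._check(term)
        return set(self._g.predecessors(term))

    def neighbors(self, term: str) -> set[str]:
        """Distance-1 terms in either direction; never contains `term`."""
        self._check(term)
        return set(self._g.successors(term)) | set(self._g.predecessors(term))

    def roots(self) -> list[str]:
        """Terms with no parent, sorted."""
        return sorted(t for t in self._g.nodes if self._g.out_degree(t) == 0)

    def namespaces(self) -> list[str]:
        return sorted({d["namespace"] for _, d in self._g.nodes(data=True)})

    def terms_in_namespace(self, namespace: str) -> list[str]:
        return sorted(
            t for t, d in self._g.nodes(data=True) if d["namespace"] == namespace
        )

    # -- serialization ----------------------------------------------------

    def write_obo(self, path: str | os.PathLike) -> None:
        """Write as an OBO 1.2 flat file (terms sorted by id, deterministic)."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("format-version: 1.2\n")
            fh.write("ontology: enrichsphere-synthetic\n")
            for tid in sorted(self._g.nodes):
                d = self._g.nodes[tid]
                fh.write("\n[Term]\n")
                fh.write(f"id: {tid}\n")
                fh.write(f"name: {d.get('name', tid)}\n")
                fh.write(f"namespace: {d['namespace']}\n")
                for parent in sorted(self._g.successors(tid)):
                    fh.write(f"is_a: {parent} ! {self._g.nodes[parent].get('name', parent)}\n")


def parse_obo(path: str | os.PathLike) -> OntologyGraph:
    """Parse an OBO 1.2 file into a validated is_a DAG.

    Obsolete terms are dropped; only is_a edges are retained.  Raises on
    cycles and on is_a targets that are never defined.
    """
    multi = obonet.read_obo(path, ignore_obsolete=True)
    g = nx.DiGraph()
    for tid, data in multi.nodes(data=True):
        attrs = {}
        if "name" in data:
            attrs["name"] = data["name"]
        if "namespace" in data:
            attrs["namespace"] = data["namespace"]
        g.add_node(tid, **attrs)
    for child, parent, key in multi.edges(keys=True):
        if key == "is_a":
            g.add_edge(child, parent)
    return OntologyGraph(g)


def neighbors(graph: OntologyGraph, term: str) -> set[str]:
    """Union of direct parents and direct children of `term`."""
    return graph.neighbors(term)


def validate_ontology(
    graph: OntologyGraph, feature_ids: Iterable[str] | None = None
) -> dict:
    """Diagnostics: term counts per namespace, roots, max depth, missing terms.

    `feature_ids` (e.g. the rows of an abundance table) are checked for
    presence in the graph; absentees are listed, not raised.
    """
    per_ns: dict[str, int] = {}
    for _, d in graph.graph.nodes(data=True):
        per_ns[d["namespace"]] = per_ns.get(d["namespace"], 0) + 1
    max_depth = 0
    if graph.graph.number_of_nodes():
        max_depth = int(nx.dag_longest_path_length(graph.graph))
    missing = []
    if feature_ids is not None:
        missing = sorted(set(feature_ids) - set(graph.graph.nodes))
    return {
        "n_terms": graph.graph.number_of_nodes(),
        "n_edges": graph.graph.number_of_edges(),
        "terms_per_namespace": dict(sorted(per_ns.items())),
        "roots": graph.roots(),
        "max_depth": max_depth,
        "missing_from_graph": missing,
    }
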