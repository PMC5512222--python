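"""Domain co-occurrence and adjacency networks over architecture tables.

Two graphs over domain types are built from the same table:

* the **co-occurrence network** (undirected): an edge joins two distinct
  domains whenever both occur anywhere in the same protein, adjacent or not;
  each protein contributes at most 1 to an edge's occurrence count however
  many copies it carries;
* the **adjacency network** (directed): an edge joins consecutive domain
  hits only, oriented from the N-side domain to its C-terminal partner.

Tandem repeats of one domain contribute no edge; the graphs have no
self-loops.  Edge occurrence classes follow the published display rule:
counts up to 15 are gray, 16-90 cadet blue, 91 and above maroon (the count
15 left open by the "<15 / 16-90" wording is resolved into the gray class so
that the classes are exhaustive and contiguous).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from ._errors import UsageError, ValidationError
from .architectures import ArchitectureTable

EDGE_CLASS_THRESHOLDS = (15, 90)  # gray <= t0 < cadetblue <= t1 < maroon
NODE_GRAY_MAX_DEGREE = 2


@dataclass
class DomainNetwork:
    """Weighted domain graph; a thin wrapper over a networkx (Di)Graph.

    Node attribute ``protein_count`` is the number of distinct proteins
    containing the domain; edge attribute ``occurrence_count`` is the number
    of contributing proteins (co-occurrence) or adjacent-pair instances
    (adjacency).
    """

    graph: nx.Graph | nx.DiGraph
    directed: bool

    def __post_init__(self):
        if self.directed != self.graph.is_directed():
            raise ValidationError("directed flag does not match graph type")
        if any(u == v for u, v in self.graph.edges):
            raise ValidationError("self-loops are not allowed in domain networks")

    def undirected_view(self) -> nx.Graph:
        return self.graph.to_undirected(as_view=False) if self.directed else self.graph

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def occurrence_count(self, u: str, v: str) -> int:
        return self.graph.edges[u, v]["occurrence_count"]


def _add_protein_counts(g, table: ArchitectureTable) -> None:
    for p in table:
        for d in sorted(set(p.domain_ids)):  # sorted: node order is reproducible
            if not g.has_node(d):
                g.add_node(d, protein_count=0)
            g.nodes[d]["protein_count"] += 1


def build_cooccurrence_network(table: ArchitectureTable) -> DomainNetwork:
    """Undirected per-protein-deduplicated co-occurrence graph."""
    g = nx.Graph()
    _add_protein_counts(g, table)
    for p in table:
        present = sorted(set(p.domain_ids))
        for i, a in enumerate(present):
            for b in present[i + 1 :]:
                if g.has_edge(a, b):
                    g.edges[a, b]["occurrence_count"] += 1
                else:
                    g.add_edge(a, b, occurrence_count=1)
    return DomainNetwork(g, directed=False)


def build_adjacency_network(table: ArchitectureTable) -> DomainNetwork:
    """Directed consecutive-pair graph, arrows pointing C-terminal."""
    g = nx.DiGraph()
    _add_protein_counts(g, table)
    for p in table:
        ids = p.domain_ids
        for a, b in zip(ids, ids[1:]):
            if a == b:
                continue  # tandem repeat: no self-loop
            if g.has_edge(a, b):
                g.edges[a, b]["occurrence_count"] += 1
            else:
                g.add_edge(a, b, occurrence_count=1)
    return DomainNetwork(g, directed=g.is_directed())


def classify_edges_and_nodes(
    net: DomainNetwork, thresholds: tuple[int, int] = EDGE_CLASS_THRESHOLDS
) -> DomainNetwork:
    """Annotate edge_class (gray/cadetblue/maroon) and node_class in place."""
    lo, hi = thresholds
    if not (0 < lo < hi):
        raise UsageError(f"bad edge thresholds {thresholds}")
    for u, v, data in net.graph.edges(data=True):
        c = data["occurrence_count"]
        data["edge_class"] = "gray" if c <= lo else ("cadetblue" if c <= hi else "maroon")
    deg = net.undirected_view().degree() if net.directed else net.graph.degree()
    deg = dict(deg)
    for n, data in net.graph.nodes(data=True):
        data["node_class"] = "gray" if deg[n] <= NODE_GRAY_MAX_DEGREE else "scaled"
    return net


# ---------------------------------------------------------------------------
# export / import

def write_graphml(net: DomainNetwork, path) -> None:
    nx.write_graphml(net.graph, str(path))


def write_edgelist_tsv(net: DomainNetwork, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("source\ttarget\tcount\tclass\n")
        if net.directed:
            edges = sorted(net.graph.edges(data=True))
        else:  # canonical lexicographic pair for undirected edges
            edges = sorted(
                (*sorted((u, v)), d) for u, v, d in net.graph.edges(data=True)
            )
        for u, v, data in edges:
            fh.write(
                f"{u}\t{v}\t{data['occurrence_count']}\t{data.get('edge_class', '')}\n"
            )


def read_edgelist_tsv(path, directed: bool) -> DomainNetwork:
    g = nx.DiGraph() if directed else nx.Graph()
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["source", "target", "count"]:
            raise ValidationError(f"bad edge list header: {header}")
        for ln in fh:
            parts = ln.rstrip("\n").split("\t")
            u, v, count = parts[0], parts[1], int(parts[2])
            g.add_edge(u, v, occurrence_count=count)
            if len(parts) > 3 and parts[3]:
                g.edges[u, v]["edge_class"] = parts[3]
    return DomainNetwork(g, directed=directed)
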