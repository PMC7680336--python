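"""Tree-induced graph sets: MRCA graphs, validation, and the hierarchy bijection.

Each rate of a tree yields a graph on the taxa whose edges join pairs with
that MRCA rate; the non-isolated part is complete multipartite with parts
equal to the child clusters.  The collection of all such graphs tiles the
complete graph and is in bijection with hierarchies, and each basis rate
matrix is the negative Laplacian of its graph.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .treecore import Hierarchy, RootedTree, TreeError
from .mrca_basis import mrca_classes

__all__ = [
    "LabeledGraph",
    "TigsSet",
    "TigsValidation",
    "mrca_graph",
    "tigs_of_tree",
    "validate_tigs",
    "hierarchy_to_tigs",
    "tigs_to_hierarchy",
    "adjacency",
    "degree_matrix",
    "laplacian",
]


@dataclass(frozen=True)
class LabeledGraph:
    """Simple undirected graph on the taxon set, optionally tagged with a rate."""

    vertices: frozenset[str]
    edges: frozenset[frozenset[str]]
    rate: Optional[str] = None

    def __post_init__(self) -> None:
        for e in self.edges:
            if len(e) != 2:
                raise ValueError(f"edge {set(e)} is not a pair of distinct vertices")
            if not e <= self.vertices:
                raise ValueError(f"edge {set(e)} leaves the vertex set")

    def support(self) -> frozenset[str]:
        """Vertices of non-zero degree."""
        return frozenset(v for e in self.edges for v in e)

    def isolated(self) -> frozenset[str]:
        return self.vertices - self.support()

    def to_nx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.vertices)
        g.add_edges_from(tuple(e) for e in self.edges)
        return g

    def parts(self) -> tuple[frozenset[str], ...]:
        """Parts of the complete multipartite component (complement cliques).

        Computed as connected components of the complement graph induced on
        the support; meaningful when the component really is complete
        multipartite (checked by :func:`validate_tigs`).
        """
        sup = self.support()
        comp = nx.complement(self.to_nx().subgraph(sup))
        return tuple(sorted((frozenset(c) for c in nx.connected_components(comp)),
                            key=lambda c: sorted(c)))

    def edge_list_tsv(self) -> str:
        lines = ["\t".join(sorted(e)) for e in sorted(self.edges, key=lambda e: sorted(e))]
        return "\n".join(lines) + ("\n" if lines else "")


@dataclass(frozen=True)
class TigsSet:
    """A collection of graphs on a common taxon set."""

    graphs: tuple[LabeledGraph, ...]

    def __post_init__(self) -> None:
        if not self.graphs:
            raise ValueError("empty graph collection")
        vs = {g.vertices for g in self.graphs}
        if len(vs) != 1:
            raise ValueError("graphs must share a vertex set")

    @property
    def vertices(self) -> frozenset[str]:
        return self.graphs[0].vertices

    def manifest(self) -> dict:
        return {
            "vertices": sorted(self.vertices),
            "graphs": [
                {
                    "rate": g.rate,
                    "edges": sorted(sorted(e) for e in g.edges),
                    "isolated": sorted(g.isolated()),
                }
                for g in self.graphs
            ],
        }

    @classmethod
    def from_manifest(cls, obj: dict) -> "TigsSet":
        vertices = frozenset(obj["vertices"])
        graphs = tuple(
            LabeledGraph(
                vertices=vertices,
                edges=frozenset(frozenset(e) for e in g["edges"]),
                rate=g.get("rate"),
            )
            for g in obj["graphs"]
        )
        return cls(graphs)


@dataclass(frozen=True)
class TigsValidation:
    ok: bool
    violation: Optional[str] = None


def mrca_graph(tree: RootedTree, rate: str) -> LabeledGraph:
    """Graph on the taxa with an edge (x, y) iff their MRCA carries ``rate``."""
    cls = mrca_classes(tree).get(rate)
    if cls is None:
        raise TreeError(f"unknown rate {rate!r}")
    return LabeledGraph(
        vertices=frozenset(tree.taxa),
        edges=frozenset(frozenset(p) for p in cls.pairs),
        rate=rate,
    )


def tigs_of_tree(tree: RootedTree) -> TigsSet:
    """The set of MRCA graphs of a tree, one per non-leaf vertex."""
    classes = mrca_classes(tree)
    vertices = frozenset(tree.taxa)
    graphs = tuple(
        LabeledGraph(
            vertices=vertices,
            edges=frozenset(frozenset(p) for p in cls.pairs),
            rate=rate,
        )
        for rate, cls in classes.items()
    )
    return TigsSet(graphs)


def _is_complete_multipartite(g: LabeledGraph) -> bool:
    """Support induces a complete multipartite graph (>= 2 parts, connected)."""
    sup = g.support()
    if not sup:
        return False
    sub = g.to_nx().subgraph(sup)
    comp = nx.complement(sub)
    parts = list(nx.connected_components(comp))
    # complement must be a disjoint union of cliques
    for p in parts:
        k = len(p)
        if comp.subgraph(p).number_of_edges() != k * (k - 1) // 2:
            return False
    # and every cross-part pair must be an edge of g
    for a, b in itertools.combinations(parts, 2):
        for x in a:
            for y in b:
                if not sub.has_edge(x, y):
                    return False
    return len(parts) >= 2


def validate_tigs(graphs: TigsSet | Sequence[LabeledGraph]) -> TigsValidation:
    """Check the four defining conditions of a tree-induced graph set.

    On failure names the first violated condition: edge-disjointness,
    completeness of the edge union, complete-multipartite structure of
    each component, uniqueness of the no-isolated-vertex graph, or the
    recursive part-support condition.
    """
    gs = tuple(graphs.graphs if isinstance(graphs, TigsSet) else graphs)
    if not gs:
        return TigsValidation(False, "empty collection")
    X = gs[0].vertices
    if any(g.vertices != X for g in gs):
        return TigsValidation(False, "graphs do not share a vertex set")

    all_edges: list[frozenset[str]] = []
    for g in gs:
        all_edges.extend(g.edges)
    if len(all_edges) != len(set(all_edges)):
        return TigsValidation(False, "edge sets are not pairwise disjoint")
    complete = {frozenset(p) for p in itertools.combinations(sorted(X), 2)}
    if set(all_edges) != complete:
        return TigsValidation(False, "edge union is not the complete graph")

    for g in gs:
        if not _is_complete_multipartite(g):
            return TigsValidation(
                False, "a component is not a complete k-partite graph"
            )

    full = [g for g in gs if not g.isolated()]
    if len(full) != 1:
        return TigsValidation(
            False, "there must be exactly one graph with no isolated vertices"
        )

    supports = {}
    for g in gs:
        supports.setdefault(g.support(), []).append(g)
    for g in gs:
        for p in g.parts():
            if len(p) <= 1:
                continue
            if len(supports.get(p, [])) != 1:
                return TigsValidation(
                    False,
                    f"part {sorted(p)} is not the support of exactly one graph",
                )
    return TigsValidation(True, None)


def hierarchy_to_tigs(h: Hierarchy) -> TigsSet:
    """Map a hierarchy to its tree-induced graph set.

    For each non-singleton cluster A with inclusion-maximal proper
    subclusters A_1..A_k, take the complement (within A) of the disjoint
    complete graphs on the A_i — i.e. the complete multipartite graph with
    parts A_i — with the rest of the taxa isolated.
    """
    X = h.taxa
    graphs = []
    for a in sorted((c for c in h.clusters if len(c) > 1), key=lambda c: (-len(c), sorted(c))):
        proper = [b for b in h.clusters if b < a]
        maximal = [b for b in proper if not any(b < c for c in proper)]
        edges = set()
        for b1, b2 in itertools.combinations(maximal, 2):
            for x in b1:
                for y in b2:
                    edges.add(frozenset({x, y}))
        graphs.append(LabeledGraph(vertices=frozenset(X), edges=frozenset(edges)))
    return TigsSet(tuple(graphs))


def tigs_to_hierarchy(g: TigsSet) -> Hierarchy:
    """Recover the hierarchy from a tree-induced graph set.

    Clusters are the full taxon set, all singletons, and every part of
    every graph's multipartite component.
    """
    check = validate_tigs(g)
    if not check.ok:
        raise TreeError(f"not a tree-induced graph set: {check.violation}")
    X = g.vertices
    clusters = {frozenset(X)} | {frozenset({t}) for t in X}
    for graph in g.graphs:
        clusters.update(graph.parts())
    return Hierarchy(taxa=frozenset(X), clusters=frozenset(clusters))


def adjacency(g: LabeledGraph, taxa: Sequence[str]) -> np.ndarray:
    idx = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)
    a = np.zeros((n, n), dtype=np.int64)
    for e in g.edges:
        x, y = tuple(e)
        a[idx[x], idx[y]] = 1
        a[idx[y], idx[x]] = 1
    return a


def degree_matrix(g: LabeledGraph, taxa: Sequence[str]) -> np.ndarray:
    a = adjacency(g, taxa)
    return np.diag(a.sum(axis=1))


def laplacian(g: LabeledGraph, taxa: Optional[Sequence[str]] = None) -> np.ndarray:
    """Laplacian D - A in the given (or sorted) taxon order."""
    order = tuple(taxa) if taxa is not None else tuple(sorted(g.vertices))
    a = adjacency(g, order)
    return np.diag(a.sum(axis=1)) - a
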