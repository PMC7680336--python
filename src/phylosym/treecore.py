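"""Rooted-tree data model, Newick I/O, clusters/hierarchies and MRCA queries.

Trees are rooted, possibly non-binary, with leaves bijectively labelled by
taxa and every non-leaf vertex (root included) carrying a symbolic rate
label.  This module is the substrate for the matrix-algebra construction:
the canonical taxon order fixed here determines row/column order of every
matrix built downstream.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterator, Mapping, Optional, Sequence

import dendropy

__all__ = [
    "TreeError",
    "RootedTree",
    "Hierarchy",
    "VertexRelation",
    "parse_newick",
    "clusters",
    "tree_from_hierarchy",
]


class TreeError(ValueError):
    """Raised for malformed trees, hierarchies, or invalid queries."""


@dataclass(frozen=True)
class VertexRelation:
    """Relation between two tree vertices.

    ``relation`` is one of ``"equal"``, ``"ancestor"`` (first argument is a
    strict ancestor of the second), ``"descendant"``, or ``"incomparable"``;
    ``siblings`` is True iff the two vertices share a parent.
    """

    relation: str
    siblings: bool


class RootedTree:
    """A rooted tree with rate labels on non-leaf vertices.

    Vertices are opaque integer ids.  Invariants enforced at construction:

    * connected and acyclic, every non-root vertex has exactly one parent;
    * every non-leaf vertex, the root included, has at least two children;
    * leaf labels form a bijection onto the taxon set;
    * rate labels are assigned to exactly the non-leaf vertices.

    Duplicate rate labels are rejected unless ``allow_duplicate_rates`` is
    set (rate-equality constraints are handled explicitly by the
    :mod:`phylosym.constraints` module, not by duplicated labels).
    """

    def __init__(
        self,
        root: int,
        children: Mapping[int, Sequence[int]],
        leaf_label: Mapping[int, str],
        rate: Mapping[int, str],
        *,
        sort_taxa: bool = False,
        allow_duplicate_rates: bool = False,
    ):
        self.root = root
        self.children = {v: tuple(cs) for v, cs in children.items()}
        self.leaf_label = dict(leaf_label)
        self.rate = dict(rate)
        self.parent: dict[int, int] = {}
        for v, cs in self.children.items():
            for c in cs:
                if c in self.parent:
                    raise TreeError(f"vertex {c} has more than one parent")
                self.parent[c] = v
        self._validate()
        order = [self.leaf_label[v] for v in self._preorder_leaves()]
        if sort_taxa:
            order = sorted(order)
        self.taxa: tuple[str, ...] = tuple(order)
        self._leaf_of_taxon = {t: v for v, t in self.leaf_label.items()}
        self._vertex_of_rate = {r: v for v, r in self.rate.items()}
        self._cluster_cache: dict[int, frozenset[str]] = {}

    # -- construction checks -------------------------------------------------

    def _validate(self) -> None:
        if self.root in self.parent:
            raise TreeError("root has a parent")
        seen: set[int] = set()
        stack = [self.root]
        while stack:
            v = stack.pop()
            if v in seen:
                raise TreeError("cycle detected")
            seen.add(v)
            stack.extend(self.children.get(v, ()))
        all_vertices = set(self.children) | set(self.parent) | {self.root}
        if seen != all_vertices:
            raise TreeError("tree is not connected")
        for v in all_vertices:
            cs = self.children.get(v, ())
            if len(cs) == 1:
                raise TreeError(f"vertex {v} has exactly one child")
            if cs:
                if v not in self.rate:
                    raise TreeError(f"non-leaf vertex {v} has no rate label")
                if v in self.leaf_label:
                    raise TreeError(f"non-leaf vertex {v} carries a taxon label")
            else:
                if v not in self.leaf_label:
                    raise TreeError(f"leaf vertex {v} has no taxon label")
                if v in self.rate:
                    raise TreeError(f"leaf vertex {v} carries a rate label")
        if len(self.children.get(self.root, ())) < 2:
            raise TreeError("root must have at least two children")
        labels = list(self.leaf_label.values())
        if len(set(labels)) != len(labels):
            raise TreeError("duplicate leaf labels")

    def check_unique_rates(self) -> None:
        rates = list(self.rate.values())
        if len(set(rates)) != len(rates):
            dupes = sorted({r for r in rates if rates.count(r) > 1})
            raise TreeError(
                f"duplicate rate labels {dupes}; supply an explicit "
                "rate-equality specification instead"
            )

    # -- traversal -----------------------------------------------------------

    def _preorder_leaves(self) -> Iterator[int]:
        for v in self.preorder():
            if self.is_leaf(v):
                yield v

    def preorder(self, start: Optional[int] = None) -> Iterator[int]:
        stack = [self.root if start is None else start]
        while stack:
            v = stack.pop()
            yield v
            stack.extend(reversed(self.children.get(v, ())))

    @property
    def vertices(self) -> tuple[int, ...]:
        return tuple(self.preorder())

    @property
    def internal_vertices(self) -> tuple[int, ...]:
        """All non-leaf vertices (root included), in preorder."""
        return tuple(v for v in self.preorder() if not self.is_leaf(v))

    @property
    def rates(self) -> tuple[str, ...]:
        """Rate labels of non-leaf vertices in preorder."""
        return tuple(self.rate[v] for v in self.internal_vertices)

    def is_leaf(self, v: int) -> bool:
        return not self.children.get(v, ())

    def leaf_of(self, taxon: str) -> int:
        try:
            return self._leaf_of_taxon[taxon]
        except KeyError:
            raise TreeError(f"unknown taxon {taxon!r}") from None

    def vertex_of_rate(self, rate: str) -> int:
        try:
            return self._vertex_of_rate[rate]
        except KeyError:
            raise TreeError(f"unknown rate {rate!r}") from None

    def n_taxa(self) -> int:
        return len(self.taxa)

    # -- clusters and mrca ---------------------------------------------------

    def cluster(self, v: int) -> frozenset[str]:
        """Set of taxa labelling the leaf descendants of ``v``."""
        if v not in self._cluster_cache:
            if self.is_leaf(v):
                self._cluster_cache[v] = frozenset({self.leaf_label[v]})
            else:
                acc: set[str] = set()
                for c in self.children[v]:
                    acc |= self.cluster(c)
                self._cluster_cache[v] = frozenset(acc)
        return self._cluster_cache[v]

    def mrca(self, x: str, y: str) -> int:
        """Most recent common ancestor of taxa ``x`` and ``y``.

        A vertex is an ancestor of itself, so ``mrca(x, x)`` is the leaf
        labelled ``x``.
        """
        u = self.leaf_of(x)
        if x == y:
            return u
        v = self.leaf_of(y)
        ancestors = set()
        w: Optional[int] = u
        while w is not None:
            ancestors.add(w)
            w = self.parent.get(w)
        w = v
        while w not in ancestors:
            w = self.parent[w]
        return w

    def is_strict_ancestor(self, u: int, v: int) -> bool:
        w = self.parent.get(v)
        while w is not None:
            if w == u:
                return True
            w = self.parent.get(w)
        return False

    def vertex_relation(self, u: int, v: int) -> VertexRelation:
        for w in (u, v):
            if w not in self.children and w not in self.parent and w != self.root:
                raise TreeError(f"unknown vertex {w}")
        sib = u != v and self.parent.get(u) is not None and self.parent.get(u) == self.parent.get(v)
        if u == v:
            rel = "equal"
        elif self.is_strict_ancestor(u, v):
            rel = "ancestor"
        elif self.is_strict_ancestor(v, u):
            rel = "descendant"
        else:
            rel = "incomparable"
        return VertexRelation(rel, sib)

    def leaf_count(self, u: int) -> int:
        """Number of leaves in the subtree rooted at ``u``."""
        return len(self.cluster(u))

    def child_toward(self, u: int, v: int) -> int:
        """The unique child of ``u`` on the path down to ``v``."""
        if not self.is_strict_ancestor(u, v):
            raise TreeError(f"vertex {v} is not a strict descendant of {u}")
        w = v
        while self.parent[w] != u:
            w = self.parent[w]
        return w

    # -- output --------------------------------------------------------------

    def to_newick(self) -> str:
        def render(v: int) -> str:
            if self.is_leaf(v):
                return self.leaf_label[v]
            inner = ",".join(render(c) for c in self.children[v])
            return f"({inner}){self.rate[v]}"

        return render(self.root) + ";"

    def __repr__(self) -> str:
        return f"RootedTree({self.to_newick()!r})"


@dataclass(frozen=True)
class Hierarchy:
    """A laminar family over a taxon set: the cluster set of a rooted tree.

    Contains the full taxon set and every singleton; any two members are
    disjoint or nested.
    """

    taxa: frozenset[str]
    clusters: frozenset[frozenset[str]]

    def __post_init__(self) -> None:
        if self.taxa not in self.clusters:
            raise TreeError("hierarchy must contain the full taxon set")
        for t in self.taxa:
            if frozenset({t}) not in self.clusters:
                raise TreeError(f"hierarchy must contain singleton {{{t}}}")
        for c in self.clusters:
            if not c or not c <= self.taxa:
                raise TreeError("cluster outside the taxon set or empty")
        for a, b in itertools.combinations(self.clusters, 2):
            if a & b and not (a <= b or b <= a):
                raise TreeError(f"clusters {set(a)} and {set(b)} overlap without nesting")

    def to_json_obj(self) -> list[list[str]]:
        return sorted(
            (sorted(c) for c in self.clusters), key=lambda c: (len(c), c)
        )

    @classmethod
    def from_json_obj(cls, obj: Sequence[Sequence[str]]) -> "Hierarchy":
        clusters = frozenset(frozenset(c) for c in obj)
        taxa = frozenset().union(*clusters) if clusters else frozenset()
        return cls(taxa, clusters)


def parse_newick(
    text: str,
    *,
    sort_taxa: bool = False,
    allow_duplicate_rates: bool = False,
) -> RootedTree:
    """Parse a Newick string into a :class:`RootedTree`.

    Internal-vertex labels are rate names; unlabeled internal vertices are
    assigned fresh names ``r1, r2, ...`` in preorder.  Branch lengths are
    accepted but ignored with a warning (rates live on vertices, not
    edges).  Duplicate internal labels are rejected unless
    ``allow_duplicate_rates`` is given (explicit constraint specifications
    are the supported route to rate equality).
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except dendropy.utility.error.DataParseError as exc:
        raise TreeError(f"Newick parse failure: {exc}") from None

    if any(nd.edge.length is not None for nd in dtree.preorder_node_iter()):
        warnings.warn(
            "branch lengths present in Newick input are ignored: rates are "
            "vertex labels in this model",
            stacklevel=2,
        )

    ids: dict[int, int] = {}
    children: dict[int, list[int]] = {}
    leaf_label: dict[int, str] = {}
    rate: dict[int, str] = {}
    for i, nd in enumerate(dtree.preorder_node_iter()):
        ids[id(nd)] = i
    for nd in dtree.preorder_node_iter():
        i = ids[id(nd)]
        kids = nd.child_nodes()
        children[i] = [ids[id(c)] for c in kids]
        if kids:
            if nd.label is not None:
                rate[i] = str(nd.label)
        else:
            label = nd.taxon.label if nd.taxon is not None else nd.label
            if label is None:
                raise TreeError("leaf without a label")
            leaf_label[i] = str(label)

    used = set(rate.values())
    counter = itertools.count(1)
    for i in sorted(children):
        if children[i] and i not in rate:
            name = next(f"r{k}" for k in counter if f"r{k}" not in used)
            rate[i] = name
            used.add(name)

    tree = RootedTree(
        root=0,
        children=children,
        leaf_label=leaf_label,
        rate=rate,
        sort_taxa=sort_taxa,
        allow_duplicate_rates=allow_duplicate_rates,
    )
    if not allow_duplicate_rates:
        tree.check_unique_rates()
    return tree


def clusters(tree: RootedTree) -> Hierarchy:
    """Cluster set of ``tree``: one cluster per vertex, forming a hierarchy."""
    return Hierarchy(
        taxa=frozenset(tree.taxa),
        clusters=frozenset(tree.cluster(v) for v in tree.preorder()),
    )


def tree_from_hierarchy(
    h: Hierarchy, *, taxon_order: Optional[Sequence[str]] = None
) -> RootedTree:
    """Reconstruct the rooted tree whose cluster set is ``h``.

    Inverse of :func:`clusters` up to vertex relabelling; rate labels on
    the reconstructed internal vertices are fresh ``r1, r2, ...`` names.
    ``taxon_order`` fixes the canonical leaf order (default lexicographic).
    """
    order = list(taxon_order) if taxon_order is not None else sorted(h.taxa)
    if set(order) != set(h.taxa):
        raise TreeError("taxon_order does not match the hierarchy's taxa")
    pos = {t: i for i, t in enumerate(order)}

    # parent of each cluster = inclusion-minimal strict superset
    clist = sorted(h.clusters, key=len, reverse=True)
    ids = {c: i for i, c in enumerate(clist)}
    children: dict[int, list[int]] = {i: [] for i in ids.values()}
    for c in clist:
        if c == h.taxa:
            continue
        supersets = [d for d in h.clusters if c < d]
        parent = min(supersets, key=len)
        children[ids[parent]].append(ids[c])
    for i in children:
        children[i].sort(key=lambda j: min(pos[t] for t in clist[j]))

    leaf_label: dict[int, str] = {}
    rate: dict[int, str] = {}
    counter = itertools.count(1)
    for c in clist:
        i = ids[c]
        if children[i]:
            rate[i] = f"r{next(counter)}"
        elif len(c) == 1:
            leaf_label[i] = next(iter(c))
        else:
            raise TreeError(f"cluster {set(c)} has no proper subclusters but is not a singleton")
    return RootedTree(
        root=ids[h.taxa],
        children=children,
        leaf_label=leaf_label,
        rate=rate,
    )
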