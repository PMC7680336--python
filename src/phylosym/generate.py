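"""Seeded random rooted trees for property tests and simulations."""

from __future__ import annotations

import random
from dataclasses import dataclass

from .treecore import RootedTree

__all__ = ["GeneratorConfig", "random_tree"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Reproducibility contract: same config, same tree.

    ``max_children`` > 2 allows polytomies via random contraction of
    internal edges after the binary attachment phase.
    """

    leaf_count: int
    seed: int
    max_children: int = 2

    def __post_init__(self) -> None:
        if self.leaf_count < 2:
            raise ValueError("need at least two leaves")
        if self.max_children < 2:
            raise ValueError("max_children must be at least 2")


def random_tree(cfg: GeneratorConfig) -> RootedTree:
    """Random rooted tree by sequential leaf attachment, then edge contraction.

    Each new leaf subdivides a uniformly chosen edge (a pseudo-edge above
    the root included, which pushes down a new root); when
    ``max_children`` exceeds 2, internal edges are contracted with
    probability 1/2 wherever the resulting vertex stays within the child
    bound.  Leaves are labelled t1..tn in attachment order and internal
    vertices get unique rates r1, r2, ... in preorder.
    """
    rng = random.Random(cfg.seed)
    nxt = iter(range(10**6))
    root = next(nxt)
    children: dict[int, list[int]] = {root: []}
    leaves: dict[int, str] = {}
    for k in (1, 2):
        leaf = next(nxt)
        children[root].append(leaf)
        children[leaf] = []
        leaves[leaf] = f"t{k}"

    parent = {c: p for p, cs in children.items() for c in cs}
    for k in range(3, cfg.leaf_count + 1):
        edges: list[tuple[int | None, int]] = [(None, root)]
        edges += [(p, c) for p, cs in children.items() for c in cs]
        up, down = edges[rng.randrange(len(edges))]
        mid = next(nxt)
        leaf = next(nxt)
        children[mid] = [down, leaf]
        children[leaf] = []
        leaves[leaf] = f"t{k}"
        parent[down] = mid
        parent[leaf] = mid
        if up is None:
            root = mid
        else:
            children[up][children[up].index(down)] = mid
            parent[mid] = up

    if cfg.max_children > 2:
        internal_edges = [
            (p, c) for p, cs in children.items() for c in cs if children.get(c)
        ]
        rng.shuffle(internal_edges)
        for p, c in internal_edges:
            if c not in children or p not in children:
                continue
            merged = len(children[p]) - 1 + len(children[c])
            if merged > cfg.max_children or rng.random() < 0.5:
                continue
            i = children[p].index(c)
            grand = children.pop(c)
            children[p][i : i + 1] = grand
            for g in grand:
                parent[g] = p

    rate = {}
    counter = 1
    order = [root]
    seq = []
    while order:
        v = order.pop()
        seq.append(v)
        order.extend(reversed(children.get(v, [])))
    for v in seq:
        if children.get(v):
            rate[v] = f"r{counter}"
            counter += 1
    return RootedTree(root=root, children=children, leaf_label=leaves, rate=rate)
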