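"""Built-in example trees and the symbolic model rendering.

``fig1`` is the five-taxon tree whose four basis matrices are the standard
worked example; ``k2p`` is the DNA tree whose sibling merge produces the
Kimura two-parameter model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .treecore import RootedTree, parse_newick
from .constraints import RateClasses

__all__ = ["Fixture", "FIXTURES", "get_fixture", "fixture_tree", "export_symbolic"]


@dataclass(frozen=True)
class Fixture:
    name: str
    newick: str
    merges: tuple[tuple[str, ...], ...] = ()


FIXTURES: dict[str, Fixture] = {
    "fig1": Fixture("fig1", "((1,2)beta,(3,(4,5)delta)gamma)alpha;"),
    "k2p": Fixture("k2p", "((A,G)b,(C,T)c)a;", merges=(("b", "c"),)),
}


def get_fixture(name: str, *, sort_taxa: bool = False) -> tuple[RootedTree, RateClasses]:
    fx = FIXTURES[name]
    tree = parse_newick(fx.newick, sort_taxa=sort_taxa)
    return tree, RateClasses.for_tree(tree, fx.merges)


def fixture_tree(name: str, *, sort_taxa: bool = False) -> RootedTree:
    return get_fixture(name, sort_taxa=sort_taxa)[0]


def export_symbolic(tree: RootedTree, classes: Optional[RateClasses] = None) -> str:
    """Render the generic algebra element as a symbolic n x n pattern.

    Off-diagonal cell (x, y) shows the equality-class label of the MRCA
    rate of x and y; the diagonal is ``*``, defined to give zero row sum.
    """
    if classes is None:
        classes = RateClasses.for_tree(tree)
    classes.validate_for(tree)
    label_of = {r: classes.label(c) for c in classes.classes for r in c}
    taxa = tree.taxa
    grid = [[""] + list(taxa)]
    for x in taxa:
        row = [x]
        for y in taxa:
            if x == y:
                row.append("*")
            else:
                row.append(label_of[tree.rate[tree.mrca(x, y)]])
        grid.append(row)
    widths = [max(len(r[c]) for r in grid) for c in range(len(grid[0]))]
    return "\n".join(
        "  ".join(cell.rjust(w) for cell, w in zip(row, widths)) for row in grid
    ) + "\n"
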