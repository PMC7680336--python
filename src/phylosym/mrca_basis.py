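"""MRCA partition classes and the basis rate matrices they induce.

Every non-leaf vertex of a rooted tree contributes one symmetric,
zero-row-sum integer matrix: off-diagonal entry (x, y) is 1 exactly when
the most recent common ancestor of taxa x and y is that vertex.  All
arithmetic here is exact integer arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .treecore import RootedTree, TreeError

__all__ = [
    "MrcaClass",
    "BasisMatrix",
    "mrca_classes",
    "basis_matrix",
    "basis",
    "j_matrix",
    "j_subtree",
    "matrix_to_tsv",
    "matrix_from_tsv",
]


@dataclass(frozen=True)
class MrcaClass:
    """Ordered taxon pairs whose MRCA carries a given rate; symmetric."""

    rate: str
    pairs: frozenset[tuple[str, str]]


@dataclass(frozen=True)
class BasisMatrix:
    """Integer basis matrix for one rate, rows/columns in canonical taxon order."""

    rate: str
    taxa: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")

    def to_tsv(self) -> str:
        return matrix_to_tsv(self.matrix, self.taxa)

    def to_json_obj(self) -> dict:
        return {
            "taxa": list(self.taxa),
            "rate": self.rate,
            "rows": self.matrix.tolist(),
        }

    @classmethod
    def from_json_obj(cls, obj: dict) -> "BasisMatrix":
        return cls(
            rate=obj["rate"],
            taxa=tuple(obj["taxa"]),
            matrix=np.array(obj["rows"], dtype=np.int64),
        )


def mrca_classes(tree: RootedTree) -> dict[str, MrcaClass]:
    """MRCA partition classes, one per non-leaf rate, in preorder.

    Together with the diagonal pairs these partition X x X: the class of a
    rate consists of all ordered pairs of taxa drawn from distinct child
    subtrees of its vertex.
    """
    out: dict[str, MrcaClass] = {}
    for u in tree.internal_vertices:
        rate = tree.rate[u]
        pairs: set[tuple[str, str]] = set()
        kids = tree.children[u]
        for i in range(len(kids)):
            for j in range(i + 1, len(kids)):
                for x in tree.cluster(kids[i]):
                    for y in tree.cluster(kids[j]):
                        pairs.add((x, y))
                        pairs.add((y, x))
        out[rate] = MrcaClass(rate=rate, pairs=frozenset(pairs))
    return out


def _fill_class(tree: RootedTree, u: int, m: np.ndarray) -> None:
    idx = {t: i for i, t in enumerate(tree.taxa)}
    kids = tree.children[u]
    clusters = [sorted(idx[t] for t in tree.cluster(c)) for c in kids]
    for a in range(len(kids)):
        for b in range(a + 1, len(kids)):
            for i in clusters[a]:
                for j in clusters[b]:
                    m[i, j] = 1
                    m[j, i] = 1


def basis_matrix(tree: RootedTree, rate: str) -> BasisMatrix:
    """Basis matrix of one rate: 1 on its MRCA class, diagonal giving zero row sums."""
    u = tree.vertex_of_rate(rate)
    n = tree.n_taxa()
    m = np.zeros((n, n), dtype=np.int64)
    _fill_class(tree, u, m)
    np.fill_diagonal(m, -m.sum(axis=1))
    return BasisMatrix(rate=rate, taxa=tree.taxa, matrix=m)


def basis(tree: RootedTree) -> dict[str, BasisMatrix]:
    """Ordered map rate -> basis matrix, one per non-leaf vertex (preorder).

    The matrices have pairwise disjoint off-diagonal supports whose union
    is every off-diagonal cell, hence are linearly independent.
    """
    tree.check_unique_rates()
    return {tree.rate[u]: basis_matrix(tree, tree.rate[u]) for u in tree.internal_vertices}


def j_matrix(n: int) -> np.ndarray:
    """The full-basis sum: 1 off the diagonal, 1-n on it."""
    if n < 2:
        raise ValueError("need at least two taxa")
    return np.ones((n, n), dtype=np.int64) - n * np.eye(n, dtype=np.int64)


def j_subtree(tree: RootedTree, u: int) -> np.ndarray:
    """Sum of the basis matrices over all non-leaf vertices in the subtree at ``u``.

    Closed form: 1 at off-diagonal (i, j) with both taxa leaf descendants
    of ``u``, -(m-1) at diagonal entries of descendants (m the number of
    leaf descendants of ``u``), 0 elsewhere.
    """
    if tree.is_leaf(u):
        raise TreeError("j_subtree is defined for non-leaf vertices only")
    idx = {t: i for i, t in enumerate(tree.taxa)}
    desc = sorted(idx[t] for t in tree.cluster(u))
    m = len(desc)
    out = np.zeros((tree.n_taxa(), tree.n_taxa()), dtype=np.int64)
    for i in desc:
        for j in desc:
            out[i, j] = 1
        out[i, i] = -(m - 1)
    return out


def matrix_to_tsv(matrix: np.ndarray, taxa: tuple[str, ...]) -> str:
    lines = ["\t".join(["", *taxa])]
    for t, row in zip(taxa, matrix):
        lines.append("\t".join([t, *(str(x) for x in row)]))
    return "\n".join(lines) + "\n"


def matrix_from_tsv(text: str) -> tuple[np.ndarray, tuple[str, ...]]:
    rows = [line.split("\t") for line in text.splitlines() if line.strip()]
    taxa = tuple(rows[0][1:])
    m = np.array([[int(x) for x in r[1:]] for r in rows[1:]], dtype=np.int64)
    return m, taxa
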