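"""Exact products in the MRCA basis: closed forms, span tests and closure.

Products of basis matrices collapse to short linear combinations: the
product for comparable vertices is a scalar multiple of the lower matrix,
incomparable vertices annihilate each other, and squares expand over the
rates of the subtree.  Everything here is exact (integers / rationals);
floating point appears only in the matrix-exponential convenience check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import sympy

from .treecore import RootedTree
from .mrca_basis import BasisMatrix, basis

__all__ = [
    "CoefficientVector",
    "StructureTensor",
    "ClosureReport",
    "SpanResult",
    "TransitionMatrix",
    "square_entrywise",
    "square_coeffs_closed_form",
    "product_coeffs",
    "structure_constants",
    "span_coeffs",
    "closure_check",
    "instantiate",
    "is_proper_rate_matrix",
    "transition_matrix",
]

@dataclass(frozen=True)
class CoefficientVector:
    """Finitely-supported map rate-label -> rational coefficient.

    Absent keys mean zero; zero coefficients are never stored.
    """

    coeffs: Mapping[str, Fraction] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned = {k: Fraction(v) for k, v in self.coeffs.items() if v != 0}
        object.__setattr__(self, "coeffs", cleaned)

    def __getitem__(self, key: str) -> Fraction:
        return self.coeffs.get(key, Fraction(0))

    def __eq__(self, other: object) -> bool:
        if isinstance(other, CoefficientVector):
            return dict(self.coeffs) == dict(other.coeffs)
        if isinstance(other, dict):
            return dict(self.coeffs) == {k: Fraction(v) for k, v in other.items() if v != 0}
        return NotImplemented

    def to_matrix(self, basis_mats: Mapping[str, BasisMatrix]) -> np.ndarray:
        n = next(iter(basis_mats.values())).matrix.shape[0] if basis_mats else 0
        out = np.zeros((n, n), dtype=object)
        for rate, c in self.coeffs.items():
            out = out + c * basis_mats[rate].matrix.astype(object)
        return out

    def to_json_obj(self) -> dict[str, str]:
        return {k: str(v) for k, v in sorted(self.coeffs.items())}


@dataclass(frozen=True)
class StructureTensor:
    """All pairwise products expanded in the basis; symmetric in the pair."""

    entries: Mapping[tuple[str, str], CoefficientVector]

    def __getitem__(self, pair: tuple[str, str]) -> CoefficientVector:
        a, b = pair
        if (a, b) in self.entries:
            return self.entries[(a, b)]
        return self.entries[(b, a)]

    def to_json_obj(self) -> list[dict]:
        return [
            {"pair": list(p), "coeffs": cv.to_json_obj()}
            for p, cv in sorted(self.entries.items())
        ]


@dataclass(frozen=True)
class SpanResult:
    """Outcome of an exact span-membership test."""

    in_span: bool
    coeffs: CoefficientVector
    residual: np.ndarray


@dataclass(frozen=True)
class ClosureReport:
    """Verdict of the multiplication-closure decision with optional witness."""

    closed: bool
    witness: Optional[tuple[str, str, np.ndarray]] = None

    def __post_init__(self) -> None:
        if self.closed != (self.witness is None):
            raise ValueError("closed verdict inconsistent with witness")

    def to_json_obj(self) -> dict:
        obj: dict = {"closed": self.closed}
        if self.witness is not None:
            a, b, res = self.witness
            obj["witness"] = {
                "pair": [a, b],
                "residual": [[str(x) for x in row] for row in res],
            }
        return obj


@dataclass(frozen=True)
class TransitionMatrix:
    matrix: np.ndarray
    invertible: bool
    det: Union[Fraction, float]


def square_entrywise(tree: RootedTree, rate: str) -> np.ndarray:
    """Square of a basis matrix from its closed entrywise form.

    With d_i the off-diagonal row count (vertex degree in the rate's MRCA
    graph) and parts the child clusters of the rate's vertex: diagonal
    d_i(d_i + 1); cross-part entries -(subtree leaf count); same-part
    off-diagonal entries d_i; zero outside the subtree.
    """
    u = tree.vertex_of_rate(rate)
    n = tree.n_taxa()
    idx = {t: i for i, t in enumerate(tree.taxa)}
    parts = [frozenset(idx[t] for t in tree.cluster(c)) for c in tree.children[u]]
    size = tree.leaf_count(u)
    d = {}
    for p in parts:
        for i in p:
            d[i] = size - len(p)
    out = np.zeros((n, n), dtype=np.int64)
    for a, pa in enumerate(parts):
        for pb in parts[a + 1 :]:
            for i in pa:
                for j in pb:
                    out[i, j] = -size
                    out[j, i] = -size
        for i in pa:
            for j in pa:
                out[i, j] = d[i] if i != j else d[i] * (d[i] + 1)
    return out


def square_coeffs_closed_form(tree: RootedTree, rate: str) -> CoefficientVector:
    """Basis expansion of a square without matrix arithmetic.

    Q^2 for the rate at vertex u expands as -|T_u| Q_u plus, for each child
    v, (|T_u| - |T_v|) times the sum of the basis matrices in the subtree
    at v (leaf children contribute nothing).  Validated against the
    entrywise form by the test suite.
    """
    u = tree.vertex_of_rate(rate)
    size = tree.leaf_count(u)
    coeffs: dict[str, Fraction] = {rate: Fraction(-size)}
    for v in tree.children[u]:
        if tree.is_leaf(v):
            continue
        w = Fraction(size - tree.leaf_count(v))
        for x in tree.preorder(v):
            if not tree.is_leaf(x):
                coeffs[tree.rate[x]] = coeffs.get(tree.rate[x], Fraction(0)) + w
    return CoefficientVector(coeffs)


def product_coeffs(tree: RootedTree, rate_a: str, rate_b: str) -> CoefficientVector:
    """Expansion of the product of two basis matrices in the basis.

    Incomparable vertices give the zero matrix; for v a descendant of u the
    product is (|T^u_v| - |T^u|) times the matrix of v; equal rates reduce
    to the square expansion.
    """
    tree.check_unique_rates()
    u = tree.vertex_of_rate(rate_a)
    v = tree.vertex_of_rate(rate_b)
    if u == v:
        cv = square_coeffs_closed_form(tree, rate_a)
        # cross-validate against exact extraction from the entrywise square
        sq = square_entrywise(tree, rate_a)
        extracted = span_coeffs(sq, basis(tree))
        if not extracted.in_span or extracted.coeffs != cv:
            raise AssertionError(
                f"square expansion mismatch for rate {rate_a!r}"
            )  # pragma: no cover - internal consistency guard
        return cv
    rel = tree.vertex_relation(u, v).relation
    if rel == "incomparable":
        return CoefficientVector({})
    if rel == "descendant":  # u below v: swap so u is the ancestor
        u, v, rate_a, rate_b = v, u, rate_b, rate_a
    toward = tree.child_toward(u, v)
    coeff = Fraction(tree.leaf_count(toward) - tree.leaf_count(u))
    return CoefficientVector({rate_b: coeff})


def structure_constants(tree: RootedTree) -> StructureTensor:
    """Expansion of every unordered pairwise product, squares included."""
    rates = tree.rates
    entries: dict[tuple[str, str], CoefficientVector] = {}
    for i, a in enumerate(rates):
        for b in rates[i:]:
            entries[(a, b)] = product_coeffs(tree, a, b)
    return StructureTensor(entries)


def _named_matrices(
    basis_set: Union[Mapping[str, BasisMatrix], Iterable[BasisMatrix], Mapping[str, np.ndarray]],
) -> list[tuple[str, np.ndarray]]:
    if isinstance(basis_set, Mapping):
        out = []
        for k, v in basis_set.items():
            out.append((k, v.matrix if isinstance(v, BasisMatrix) else np.asarray(v)))
        return out
    return [(bm.rate, bm.matrix) for bm in basis_set]


def span_coeffs(
    m: np.ndarray,
    basis_set: Union[Mapping[str, BasisMatrix], Iterable[BasisMatrix]],
) -> SpanResult:
    """Exact membership of ``m`` in the span of matrices with disjoint supports.

    The coefficient of each basis element is read off any of its
    off-diagonal support cells; membership holds iff the implied
    combination reproduces ``m`` exactly, diagonal included.
    """
    named = _named_matrices(basis_set)
    work = np.asarray(m, dtype=object)
    coeffs: dict[str, Fraction] = {}
    for rate, bm in named:
        off = bm.copy()
        np.fill_diagonal(off, 0)
        support = np.argwhere(off != 0)
        if support.size == 0:
            raise ValueError(f"basis element {rate!r} has empty off-diagonal support")
        i, j = support[0]
        c = Fraction(work[i, j]) / Fraction(int(bm[i, j]))
        if c:
            coeffs[rate] = c
            work = work - c * bm.astype(object)
    residual = work
    in_span = bool(np.all(residual == 0))
    return SpanResult(in_span=in_span, coeffs=CoefficientVector(coeffs), residual=residual)


def _check_basis_shape(named: Sequence[tuple[str, np.ndarray]]) -> None:
    seen = None
    for rate, m in named:
        if m.shape[0] != m.shape[1]:
            raise ValueError("basis matrices must be square")
        if not np.array_equal(m, m.T):
            raise ValueError(f"basis element {rate!r} is not symmetric")
        if np.any(m.sum(axis=1) != 0):
            raise ValueError(f"basis element {rate!r} has non-zero row sums")
        off = m.copy()
        np.fill_diagonal(off, 0)
        sup = off != 0
        if seen is None:
            seen = sup
        else:
            if np.any(seen & sup):
                raise ValueError("off-diagonal supports are not pairwise disjoint")
            seen = seen | sup


def closure_check(
    basis_set: Union[Mapping[str, BasisMatrix], Iterable[BasisMatrix], Mapping[str, np.ndarray]],
) -> ClosureReport:
    """Decide closure under multiplication of a disjoint-support basis.

    Every unordered pairwise product (squares included) must lie in the
    exact span; since the inputs are symmetric with symmetric span this
    also settles the ordered products.  The witness is the first failing
    pair with the residual left after support extraction.
    """
    named = _named_matrices(basis_set)
    _check_basis_shape(named)
    as_map = {rate: m for rate, m in named}
    for i, (ra, ma) in enumerate(named):
        for rb, mb in named[i:]:
            prod = ma.astype(object) @ mb.astype(object)
            res = span_coeffs(prod, as_map)
            if not res.in_span:
                return ClosureReport(closed=False, witness=(ra, rb, res.residual))
    return ClosureReport(closed=True)


def instantiate(
    basis_set: Union[Mapping[str, BasisMatrix], Mapping[str, np.ndarray]],
    values: Mapping[str, Union[int, float, Fraction]],
) -> np.ndarray:
    """Numeric rate matrix: the value-weighted sum of the basis matrices.

    Exact (Fraction entries) when every value is an int or Fraction,
    float otherwise.  Off-diagonal rates are not forced non-negative; see
    :func:`is_proper_rate_matrix`.
    """
    named = _named_matrices(basis_set)
    missing = [r for r, _ in named if r not in values]
    if missing:
        raise ValueError(f"missing rate values for {missing}")
    exact = all(isinstance(values[r], (int, Fraction)) for r, _ in named)
    n = named[0][1].shape[0]
    if exact:
        out = np.zeros((n, n), dtype=object)
        for r, m in named:
            out = out + Fraction(values[r]) * m.astype(object)
    else:
        out = np.zeros((n, n), dtype=float)
        for r, m in named:
            out = out + float(values[r]) * m.astype(float)
    return out


def is_proper_rate_matrix(q: np.ndarray) -> bool:
    """True iff every off-diagonal entry is non-negative."""
    off = np.asarray(q).copy()
    np.fill_diagonal(off, np.zeros(off.shape[0], dtype=off.dtype))
    return bool(np.all(off >= 0))


def transition_matrix(q: np.ndarray) -> TransitionMatrix:
    """I + Q with an invertibility verdict (exact when entries are rational)."""
    n = q.shape[0]
    exact = all(isinstance(x, (int, np.integer, Fraction)) for x in np.asarray(q).flat)
    if exact:
        m = np.eye(n, dtype=object) + np.asarray(q, dtype=object)
        sm = sympy.Matrix(n, n, lambda i, j: sympy.Rational(Fraction(m[i, j])))
        det_exact = sm.det()
        det: Union[Fraction, float] = Fraction(int(det_exact.p), int(det_exact.q))
        return TransitionMatrix(matrix=m, invertible=det != 0, det=det)
    m = np.eye(n) + np.asarray(q, dtype=float)
    det_f = float(np.linalg.det(m))
    return TransitionMatrix(matrix=m, invertible=abs(det_f) > 1e-12, det=det_f)
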