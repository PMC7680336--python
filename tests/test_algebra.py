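import itertools
from fractions import Fraction

import numpy as np
import pytest
from scipy.linalg import expm

from phylosym.algebra import (
    CoefficientVector,
    closure_check,
    instantiate,
    is_proper_rate_matrix,
    product_coeffs,
    span_coeffs,
    square_coeffs_closed_form,
    square_entrywise,
    structure_constants,
    transition_matrix,
)
from phylosym.mrca_basis import basis, j_matrix
from phylosym.treecore import TreeError, parse_newick

from conftest import FIG1_MATRICES, tree_sweep


class TestSquareEntrywise:
    def test_fig1_gamma_against_brute_force(self, fig1):
        # oracle: square the printed matrix directly
        expected = FIG1_MATRICES["gamma"] @ FIG1_MATRICES["gamma"]
        assert np.array_equal(square_entrywise(fig1, "gamma"), expected)
        block = square_entrywise(fig1, "gamma")[2:, 2:]
        assert np.array_equal(block, np.array([[6, -3, -3], [-3, 2, 1], [-3, 1, 2]]))

    def test_fig1_delta(self, fig1):
        expected = FIG1_MATRICES["delta"] @ FIG1_MATRICES["delta"]
        got = square_entrywise(fig1, "delta")
        assert np.array_equal(got, expected)
        assert got[3, 3] == got[4, 4] == 2 and got[3, 4] == got[4, 3] == -2

    def test_two_leaf_star(self):
        t = parse_newick("(a,b)r;")
        assert np.array_equal(square_entrywise(t, "r"), np.array([[2, -2], [-2, 2]]))

    def test_matches_brute_force_everywhere(self):
        for t in tree_sweep(40):
            b = basis(t)
            for rate in t.rates:
                m = b[rate].matrix
                assert np.array_equal(square_entrywise(t, rate), m @ m)


class TestProductCoeffs:
    def test_fig1_alpha_gamma(self, fig1):
        cv = product_coeffs(fig1, "alpha", "gamma")
        assert cv == {"gamma": -2}

    def test_fig1_incomparable_pair_vanishes(self, fig1):
        assert product_coeffs(fig1, "beta", "delta") == {}
        prod = FIG1_MATRICES["beta"] @ FIG1_MATRICES["delta"]
        assert np.all(prod == 0)

    def test_fig1_gamma_square(self, fig1):
        assert product_coeffs(fig1, "gamma", "gamma") == {"gamma": -3, "delta": 1}

    def test_symmetric_in_arguments(self, fig1):
        for a, b in itertools.combinations(fig1.rates, 2):
            assert product_coeffs(fig1, a, b) == product_coeffs(fig1, b, a)

    def test_unknown_rate(self, fig1):
        with pytest.raises(TreeError):
            product_coeffs(fig1, "alpha", "zeta")

    def test_duplicate_rates_rejected(self):
        t = parse_newick("((a,b)x,(c,d)x)r;", allow_duplicate_rates=True)
        with pytest.raises(TreeError):
            product_coeffs(t, "r", "x")

    def test_oracle_equivalence_on_random_trees(self):
        # every closed-form expansion must reconstruct the brute-force
        # integer matrix product exactly
        for t in tree_sweep(40):
            b = basis(t)
            for ra, rb in itertools.combinations_with_replacement(t.rates, 2):
                cv = product_coeffs(t, ra, rb)
                reconstructed = cv.to_matrix(b)
                brute = b[ra].matrix.astype(object) @ b[rb].matrix.astype(object)
                assert np.all(reconstructed == brute), (ra, rb, t.to_newick())

    def test_square_closed_form_matches_entrywise(self):
        for t in tree_sweep(30):
            b = basis(t)
            for rate in t.rates:
                cv = square_coeffs_closed_form(t, rate)
                assert np.all(cv.to_matrix(b) == square_entrywise(t, rate))


class TestStructureConstants:
    def test_fig1_pair_count(self, fig1):
        tensor = structure_constants(fig1)
        assert len(tensor.entries) == 10  # 4 squares + 6 mixed pairs

    def test_cherry(self):
        t = parse_newick("(a,b)r;")
        tensor = structure_constants(t)
        assert tensor[("r", "r")] == {"r": -2}

    def test_incomparable_entries_empty(self):
        for t in tree_sweep(10):
            tensor = structure_constants(t)
            for ra, rb in itertools.combinations(t.rates, 2):
                u, v = t.vertex_of_rate(ra), t.vertex_of_rate(rb)
                if t.vertex_relation(u, v).relation == "incomparable":
                    assert tensor[(ra, rb)] == {}

    def test_symmetric_lookup(self, fig1):
        tensor = structure_constants(fig1)
        assert tensor[("gamma", "alpha")] == tensor[("alpha", "gamma")]

    def test_commutativity_brute_force(self):
        for t in tree_sweep(20):
            b = basis(t)
            for ra, rb in itertools.combinations(t.rates, 2):
                ma, mb = b[ra].matrix, b[rb].matrix
                assert np.array_equal(ma @ mb, mb @ ma)


class TestSpanCoeffs:
    def test_j_against_fig1_basis(self, fig1):
        res = span_coeffs(j_matrix(5), basis(fig1))
        assert res.in_span
        assert res.coeffs == {"alpha": 1, "beta": 1, "gamma": 1, "delta": 1}

    def test_zero_matrix(self, fig1):
        res = span_coeffs(np.zeros((5, 5), dtype=int), basis(fig1))
        assert res.in_span and res.coeffs == {}

    def test_gamma_square(self, fig1):
        res = span_coeffs(square_entrywise(fig1, "gamma"), basis(fig1))
        assert res.in_span
        assert res.coeffs == {"gamma": -3, "delta": 1}

    def test_not_in_span(self, fig1):
        m = np.zeros((5, 5), dtype=int)
        m[0, 0] = 1
        res = span_coeffs(m, basis(fig1))
        assert not res.in_span
        assert np.any(res.residual != 0)

    def test_rational_coefficients(self, fig1):
        b = basis(fig1)
        m = Fraction(1, 3) * b["beta"].matrix.astype(object)
        res = span_coeffs(m, b)
        assert res.in_span and res.coeffs == {"beta": Fraction(1, 3)}


class TestClosureCheck:
    def test_fig1_closed(self, fig1):
        assert closure_check(basis(fig1)).closed

    def test_merged_unequal_siblings_not_closed(self, fig1):
        b = basis(fig1)
        merged = {
            "alpha": b["alpha"].matrix,
            "beta=gamma": b["beta"].matrix + b["gamma"].matrix,
            "delta": b["delta"].matrix,
        }
        report = closure_check(merged)
        assert not report.closed
        assert report.witness is not None

    def test_single_j_closed(self):
        # star tree: J^2 = -n J
        for n in (3, 5):
            report = closure_check({"j": j_matrix(n)})
            assert report.closed
            assert np.array_equal(j_matrix(n) @ j_matrix(n), -n * j_matrix(n))

    def test_malformed_basis_rejected(self):
        with pytest.raises(ValueError):
            closure_check({"bad": np.array([[0, 1], [0, 0]])})
        with pytest.raises(ValueError):
            closure_check({"bad": np.array([[1, 1], [1, 1]])})
        b = np.array([[-1, 1], [1, -1]])
        with pytest.raises(ValueError):
            closure_check({"a": b, "b": b})

    def test_closure_on_random_unique_rate_trees(self):
        for t in tree_sweep(30):
            assert closure_check(basis(t)).closed


class TestInstantiate:
    def test_zero_values(self, fig1):
        b = basis(fig1)
        q = instantiate(b, {r: 0 for r in b})
        assert np.all(q == 0)
        tm = transition_matrix(q)
        assert tm.invertible and tm.det == 1
        assert np.all(tm.matrix == np.eye(5, dtype=object))

    def test_all_ones_gives_j(self, fig1):
        b = basis(fig1)
        q = instantiate(b, {r: 1 for r in b})
        assert np.all(q == j_matrix(5))
        tm = transition_matrix(q)
        # det(I + J) for n=5: eigenvalues 1 (once) and -4 (four times)
        assert tm.det == 256
        assert tm.invertible

    def test_missing_value(self, fig1):
        with pytest.raises(ValueError):
            instantiate(basis(fig1), {"alpha": 1})

    def test_proper_rate_matrix_flag(self, fig1):
        b = basis(fig1)
        assert is_proper_rate_matrix(instantiate(b, {r: 1 for r in b}))
        assert not is_proper_rate_matrix(
            instantiate(b, {"alpha": -1, "beta": 1, "gamma": 1, "delta": 1})
        )

    def test_float_values(self, fig1):
        b = basis(fig1)
        q = instantiate(b, {"alpha": 0.5, "beta": 1, "gamma": 1, "delta": 1})
        tm = transition_matrix(q)
        assert tm.matrix.dtype == float
        assert tm.invertible


class TestExponentialProperty:
    def test_expm_minus_identity_stays_in_span(self):
        # closure implies exp(tQ) - I lies in the (real) span of the basis
        rng = np.random.default_rng(42)
        for t in tree_sweep(10, leaf_range=(3, 8)):
            b = basis(t)
            vals = {r: Fraction(int(rng.integers(1, 8)), int(rng.integers(1, 5))) for r in b}
            q = np.asarray(instantiate(b, vals), dtype=float)
            flat_basis = np.stack([bm.matrix.astype(float).ravel() for bm in b.values()], axis=1)
            for scale in (0.1, 1.0):
                p = expm(scale * q) - np.eye(t.n_taxa())
                _, residual, *_ = np.linalg.lstsq(flat_basis, p.ravel(), rcond=None)
                misfit = (
                    np.sqrt(residual[0])
                    if residual.size
                    else np.linalg.norm(flat_basis @ np.linalg.lstsq(flat_basis, p.ravel(), rcond=None)[0] - p.ravel())
                )
                assert misfit < 1e-8


class TestCoefficientVector:
    def test_zero_coefficients_dropped(self):
        cv = CoefficientVector({"a": Fraction(0), "b": Fraction(2)})
        assert "a" not in cv.coeffs
        assert cv["a"] == 0 and cv["b"] == 2

    def test_json(self):
        cv = CoefficientVector({"b": Fraction(-1, 3)})
        assert cv.to_json_obj() == {"b": "-1/3"}
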