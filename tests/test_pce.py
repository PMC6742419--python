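"""Sparse-PCE machinery against independent oracles: Gauss-quadrature
orthonormality, normal-equation OLS, explicit leave-one-out refits, and
enumeration of truncation sets."""

import math

import numpy as np
import pytest

from nspce import pce
from nspce.pce import (
    ExperimentalDesign,
    MultiIndexSet,
    basis_adaptive_fit,
    eval_basis,
    hybrid_lar_fit,
    hyperbolic_truncation,
    loo_error,
    ols_fit,
    sequential_ed_fit,
)
from nspce.space import Marginal, ParameterSpace, uniform_box


# ---------------------------------------------------------------- truncation

@pytest.mark.parametrize("M,p", [(1, 4), (2, 3), (3, 4), (4, 3), (6, 2)])
def test_total_degree_cardinality_closed_form(M, p):
    got = len(hyperbolic_truncation(M, p, 1.0))
    assert got == math.comb(M + p, p)


def test_hyperbolic_q_half_excludes_interactions():
    idx = set(hyperbolic_truncation(2, 3, 0.5))
    # (1,1) has ||.||_0.5 = (1+1)^2 = 4 > 3
    assert idx == {(0, 0), (1, 0), (0, 1), (2, 0), (0, 2), (3, 0), (0, 3)}


@pytest.mark.parametrize("q", [0.4, 0.6, 0.75])
def test_q1_set_is_superset_of_smaller_q(q):
    full = set(hyperbolic_truncation(3, 4, 1.0))
    sub = set(hyperbolic_truncation(3, 4, q))
    assert sub <= full
    assert (0, 0, 0) in sub


def test_multi_index_invariants():
    idx = hyperbolic_truncation(2, 3, 0.75)
    assert len(set(idx)) == len(idx)
    degrees = [sum(a) for a in idx]
    assert degrees == sorted(degrees)  # graded ordering
    with pytest.raises(ValueError):
        MultiIndexSet(((0, 0), (0, 0)))


# ---------------------------------------------------------------- basis

def _gauss_gram(space, idx, nodes=40):
    """Quadrature oracle for the basis Gram matrix."""
    z, w = np.polynomial.legendre.leggauss(nodes)
    fams = [m.family for m in space.marginals]
    if fams[0] == "gaussian":
        z, w = np.polynomial.hermite_e.hermegauss(nodes)
        w = w / np.sqrt(2 * np.pi)
    else:
        w = w / 2.0
    M = space.dimension
    grids = np.meshgrid(*([z] * M), indexing="ij")
    Z = np.column_stack([g.ravel() for g in grids])
    W = np.ones(Z.shape[0])
    for j in range(M):
        W = W * w[np.searchsorted(z, Z[:, j])]
    A = eval_basis(space, idx, Z, standardized=True)
    return (A * W[:, None]).T @ A


@pytest.mark.parametrize("family", ["uniform", "gaussian"])
def test_basis_orthonormality_to_degree_10(family):
    if family == "uniform":
        space = uniform_box([(0.0, 3.0)])
    else:
        space = ParameterSpace((Marginal("gaussian", 1.0, 2.0),))
    idx = hyperbolic_truncation(1, 10, 1.0)
    G = _gauss_gram(space, idx)
    np.testing.assert_allclose(G, np.eye(len(idx)), atol=1e-10)


def test_bivariate_gram_identity():
    space = uniform_box([(0, 1), (-2, 5)])
    idx = hyperbolic_truncation(2, 5, 1.0)
    G = _gauss_gram(space, idx, nodes=20)
    np.testing.assert_allclose(G, np.eye(len(idx)), atol=1e-10)


def test_zero_index_column_is_ones(rng):
    space = uniform_box([(0, 1), (0, 1)])
    idx = hyperbolic_truncation(2, 3, 1.0)
    A = eval_basis(space, idx, space.sample(9, rng))
    np.testing.assert_array_equal(A[:, 0], np.ones(9))


def test_degree_one_legendre_value():
    space = uniform_box([(-1.0, 1.0)])
    idx = MultiIndexSet(((0,), (1,)))
    A = eval_basis(space, idx, np.array([[1.0]]))
    assert A[0, 1] == pytest.approx(np.sqrt(3.0))


# ---------------------------------------------------------------- OLS / LOO

def test_ols_constant_basis_returns_mean():
    A = np.ones((3, 1))
    coef = ols_fit(A, np.array([1.0, 2.0, 3.0]))
    assert coef[0] == pytest.approx(2.0)


def test_ols_matches_normal_equations(rng):
    for _ in range(5):
        A = rng.normal(size=(20, 5))
        y = rng.normal(size=20)
        coef = ols_fit(A, y)
        oracle = np.linalg.solve(A.T @ A, A.T @ y)
        np.testing.assert_allclose(coef, oracle, atol=1e-10)


def test_ols_rank_deficiency_raises():
    A = np.ones((4, 2))
    with pytest.raises(np.linalg.LinAlgError):
        ols_fit(A, np.arange(4.0))


def test_exactly_representable_function_has_tiny_loo(rng):
    space = uniform_box([(0, 1)])
    idx = hyperbolic_truncation(1, 2, 1.0)
    X = space.sample(10, rng)
    A = eval_basis(space, idx, X)
    y = A @ np.array([1.0, 0.5, -0.25])
    coef = ols_fit(A, y)
    assert loo_error(A, y, coef) < 1e-12


def test_analytic_loo_equals_explicit_refits(rng):
    space = uniform_box([(0, 1), (0, 1)])
    idx = hyperbolic_truncation(2, 2, 1.0)
    X = space.sample(30, rng)
    A = eval_basis(space, idx, X)
    y = np.sin(3 * X[:, 0]) + X[:, 1] ** 2 + 0.1 * rng.normal(size=30)
    coef = ols_fit(A, y)
    eps = loo_error(A, y, coef)
    press = []
    for i in range(30):
        mask = np.ones(30, dtype=bool)
        mask[i] = False
        ci = ols_fit(A[mask], y[mask])
        press.append((y[i] - A[i] @ ci) ** 2)
    oracle = np.mean(press) / np.var(y)
    assert eps == pytest.approx(oracle, rel=1e-8)


def test_loo_is_scale_invariant(rng):
    space = uniform_box([(0, 1)])
    idx = hyperbolic_truncation(1, 2, 1.0)
    X = space.sample(15, rng)
    A = eval_basis(space, idx, X)
    y = np.exp(X[:, 0]) + 0.05 * rng.normal(size=15)
    e1 = loo_error(A, y, ols_fit(A, y))
    e2 = loo_error(A, 10 * y, ols_fit(A, 10 * y))
    assert e1 == pytest.approx(e2, rel=1e-10)


# ---------------------------------------------------------------- hybrid LAR

def test_hybrid_lar_recovers_sparse_truth(rng):
    space = uniform_box([(0, 1), (0, 1)])
    cand = hyperbolic_truncation(2, 4, 1.0)
    X = space.sample(40, rng)
    A = eval_basis(space, cand, X)
    pos = list(cand).index((1, 0))
    y = 2.0 * A[:, pos]
    fit = hybrid_lar_fit(space, cand, ExperimentalDesign(X, y))
    noncst = [a for a in fit.indices if sum(a) > 0]
    assert noncst == [(1, 0)]
    k = list(fit.indices).index((1, 0))
    assert fit.coefficients[k] == pytest.approx(2.0, abs=1e-8)


def test_hybrid_lar_ignores_irrelevant_dimensions(rng):
    M = 6
    space = uniform_box([(0, 1)] * M)
    cand = hyperbolic_truncation(M, 3, 0.75)
    X = space.sample(60, rng)
    z = space.standardize(X)
    y = 1.5 * z[:, 0] + 0.7 * z[:, 0] ** 2
    fit = hybrid_lar_fit(space, cand, ExperimentalDesign(X, y))
    for alpha in fit.indices:
        assert all(alpha[i] == 0 for i in range(1, M)), alpha


def test_hybrid_lar_underdetermined_beats_truncated_ols(rng):
    # N < P candidates: the regularized path still fits a sparse truth well
    space = uniform_box([(0, 1)] * 6)
    cand = hyperbolic_truncation(6, 2, 1.0)  # P = 28
    X = space.sample(20, rng)
    z = space.standardize(X)
    y = 2.0 * z[:, 2]
    fit = hybrid_lar_fit(space, cand, ExperimentalDesign(X, y))
    Xv = space.sample(1000, rng)
    zv = space.standardize(Xv)
    rmse = np.sqrt(np.mean((fit(Xv) - 2.0 * zv[:, 2]) ** 2))
    assert rmse < 1e-6


def test_hybrid_lar_constant_response(rng):
    space = uniform_box([(0, 1)])
    cand = hyperbolic_truncation(1, 3, 1.0)
    X = space.sample(10, rng)
    fit = hybrid_lar_fit(space, cand, ExperimentalDesign(X, np.full(10, 3.0)))
    assert fit.loo_error == 0.0
    assert fit.moments() == (pytest.approx(3.0), pytest.approx(0.0))


def test_hybrid_lar_matches_ols_when_overdetermined(rng):
    space = uniform_box([(0, 1)])
    cand = hyperbolic_truncation(1, 3, 1.0)
    X = space.sample(80, rng)
    A = eval_basis(space, cand, X)
    truth = np.array([0.5, 1.0, -0.7, 0.2])
    y = A @ truth
    fit = hybrid_lar_fit(space, cand, ExperimentalDesign(X, y))
    dense = dict(zip(fit.indices, fit.coefficients))
    for alpha, c in zip(cand, ols_fit(A, y)):
        assert dense.get(alpha, 0.0) == pytest.approx(c, abs=1e-6)


# ---------------------------------------------------------------- adaptivity

def test_basis_adaptive_finds_quadratic_degree(rng):
    space = uniform_box([(0, 1)])
    X = space.sample(30, rng)
    z = space.standardize(X)
    y = 1 + z[:, 0] + 0.5 * z[:, 0] ** 2
    fit = basis_adaptive_fit(space, ExperimentalDesign(X, y), p_range=range(1, 6))
    assert max(sum(a) for a in fit.indices) == 2
    assert fit.loo_error < 1e-10


def test_basis_adaptive_is_argmin_over_sweep(rng):
    space = uniform_box([(0, 1), (0, 1)])
    X = space.sample(35, rng)
    y = np.sin(4 * X[:, 0]) * np.exp(X[:, 1]) + 0.01 * rng.normal(size=35)
    ed = ExperimentalDesign(X, y)
    best = basis_adaptive_fit(space, ed, p_range=range(1, 6), early_stop=10)
    for p in range(1, 6):
        forced = hybrid_lar_fit(space, hyperbolic_truncation(2, p, 0.75), ed)
        assert best.loo_error <= forced.loo_error + 1e-15


def test_best_loo_nonincreasing_with_degree_budget(rng):
    space = uniform_box([(-1.0, 1.0)])
    X = space.sample(120, rng)
    y = np.sin(5 * X[:, 0])
    ed = ExperimentalDesign(X, y)
    best_so_far = np.inf
    errors = []
    for pmax in range(3, 16, 3):
        fit = basis_adaptive_fit(space, ed, p_range=range(1, pmax + 1), early_stop=100)
        best_so_far = min(best_so_far, fit.loo_error)
        errors.append(best_so_far)
    assert all(e2 <= e1 + 1e-15 for e1, e2 in zip(errors, errors[1:]))
    assert errors[-1] < 1e-8


# ---------------------------------------------------------------- sequential ED

def test_sequential_ed_converges_without_enrichment_on_linear_truth():
    space = uniform_box([(0, 1), (0, 1)])
    calls = []

    def fn(x):
        calls.append(1)
        return 2.0 + 3.0 * x[0] - x[1]

    fit, ed, converged = sequential_ed_fit(fn, space, 1e-6, 10, 5, 50, seed=0)
    assert converged
    assert ed.n == 10
    assert len(calls) == 10


def test_sequential_ed_saturates_on_discontinuous_truth():
    # the motivating failure mode: a step response defeats global PCE
    space = uniform_box([(1.0, 4.0)])

    def fn(x):
        return max(1.0 - 0.5 * x[0], 0.0)

    fit, ed, converged = sequential_ed_fit(fn, space, 1e-8, 10, 10, 60, seed=1,
                                           p_range=range(1, 12))
    assert not converged
    assert fit.loo_error >= 1e-8
    assert 10 <= ed.n <= 60


def test_sequential_ed_skips_failing_samples():
    space = uniform_box([(0.0, 1.0)])
    n_fail = [0]

    def fn(x):
        if n_fail[0] == 0:
            n_fail[0] += 1
            raise RuntimeError("one-off failure")
        return x[0]

    fit, ed, converged = sequential_ed_fit(fn, space, 1e-6, 10, 5, 30, seed=2)
    assert converged
    assert ed.n == 9  # one sample skipped


# ---------------------------------------------------------------- moments

def test_moments_from_orthonormal_coefficients():
    space = uniform_box([(0, 1), (0, 1)])
    idx = MultiIndexSet(((0, 0), (1, 0), (0, 1)))
    fit = pce.SparsePCE(space, idx, np.array([1.0, 2.0, 3.0]), 0.0)
    mean, var = fit.moments()
    assert mean == pytest.approx(1.0)
    assert var == pytest.approx(13.0)


def test_surrogate_mc_moments_match_analytic(rng):
    space = uniform_box([(0, 2)])
    idx = MultiIndexSet(((0,), (1,), (2,)))
    fit = pce.SparsePCE(space, idx, np.array([0.5, 1.5, -0.4]), 0.0)
    mean, var = fit.moments()
    y = fit(space.sample(100000, rng))
    assert abs(y.mean() - mean) < 3 * y.std() / np.sqrt(y.size)
    assert abs(y.var() - var) / var < 0.05


def test_loo_tracks_validation_error_within_sanity_band(rng):
    # for smooth targets the analytic LOO estimate should sit within a
    # factor of 5 of the true relative validation MSE
    space = uniform_box([(0, 1), (0, 1)])
    X = space.sample(60, rng)
    y = np.exp(0.8 * X[:, 0]) * np.sin(2 * X[:, 1]) + 0.02 * rng.normal(size=60)
    fit = basis_adaptive_fit(space, ExperimentalDesign(X, y), p_range=range(1, 7))
    Xv = space.sample(10000, rng)
    yv = np.exp(0.8 * Xv[:, 0]) * np.sin(2 * Xv[:, 1]) + 0.02 * rng.normal(size=10000)
    rel_mse = np.mean((fit(Xv) - yv) ** 2) / np.var(yv)
    assert rel_mse / 5 <= fit.loo_error <= rel_mse * 5
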