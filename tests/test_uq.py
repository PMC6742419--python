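"""Forward/inverse UQ: Sobol identities and cross-checks, likelihood
against a direct normal-pdf product, systematic-resampling properties,
SMC conjugate recovery, and MAP/Laplace on closed-form posteriors."""

import collections

import numpy as np
import pytest
from scipy import stats

from nspce.pce import MultiIndexSet, SparsePCE
from nspce.space import Marginal, ParameterSpace, uniform_box
from nspce.uq import (
    Dataset,
    NoiseModel,
    ParticleEnsemble,
    effective_sample_size,
    laplace_posterior,
    log_likelihood,
    map_estimate,
    neg_log_posterior,
    propagate,
    smc_run,
    sobol_from_pce,
    sobol_mc_on_surrogate,
    systematic_resample,
)


class _FixedNoise(NoiseModel):
    """Constant-sigma noise for conjugate checks."""

    def sd(self, v):
        return np.ones_like(np.asarray(v, dtype=float)) * self.sd_floor


# ---------------------------------------------------------------- Sobol

def _pce2(coeff_map):
    sp = uniform_box([(0, 1), (0, 1)])
    idx = MultiIndexSet(tuple(coeff_map))
    return SparsePCE(sp, idx, np.array(list(coeff_map.values()), dtype=float), 0.0)


def test_first_order_indices_without_interactions():
    pce = _pce2({(0, 0): 1.0, (1, 0): 2.0, (0, 1): 3.0})
    np.testing.assert_allclose(sobol_from_pce(pce, "first"), [4 / 13, 9 / 13])
    np.testing.assert_allclose(sobol_from_pce(pce, "total"), [4 / 13, 9 / 13])


def test_interaction_term_raises_total_above_first():
    pce = _pce2({(0, 0): 1.0, (1, 0): 2.0, (0, 1): 3.0, (1, 1): 1.0})
    np.testing.assert_allclose(sobol_from_pce(pce, "first"), [4 / 14, 9 / 14])
    np.testing.assert_allclose(sobol_from_pce(pce, "total"), [5 / 14, 10 / 14])


def test_partial_variances_sum_to_total():
    pce = _pce2({(0, 0): 0.3, (1, 0): 1.0, (0, 1): -2.0, (2, 0): 0.5, (1, 1): 0.25})
    _, var = pce.moments()
    S1 = sobol_from_pce(pce, "first")
    inter = 0.25**2 / var
    assert S1.sum() + inter == pytest.approx(1.0)
    T = sobol_from_pce(pce, "total")
    assert np.all(S1 <= T + 1e-15) and np.all(T <= 1 + 1e-15)


def test_zero_variance_pce_has_no_indices():
    sp = uniform_box([(0, 1)])
    pce = SparsePCE(sp, MultiIndexSet(((0,),)), np.array([2.0]), 0.0)
    with pytest.raises(ValueError):
        sobol_from_pce(pce)


def test_saltelli_additive_function():
    sp = uniform_box([(0, 1), (0, 1)])

    def f(X):
        return X[:, 0] + 2.0 * X[:, 1]

    S, se = sobol_mc_on_surrogate(f, sp, n=20000, seed=0)
    np.testing.assert_allclose(S, [1 / 5, 4 / 5], atol=3 * se.max() + 0.01)


def test_saltelli_agrees_with_coefficient_indices():
    pce = _pce2({(0, 0): 1.0, (1, 0): 2.0, (0, 1): 3.0, (1, 1): 1.0})
    S, se = sobol_mc_on_surrogate(pce, pce.space, n=40000, seed=1)
    exact = sobol_from_pce(pce, "first")
    assert np.all(np.abs(S - exact) < 3 * se + 1e-3)
    T, seT = sobol_mc_on_surrogate(pce, pce.space, n=40000, seed=1, order="total")
    exactT = sobol_from_pce(pce, "total")
    assert np.all(np.abs(T - exactT) < 3 * seT + 1e-3)


def test_unused_parameter_has_null_index():
    sp = uniform_box([(0, 1), (0, 1)])
    S, se = sobol_mc_on_surrogate(lambda X: np.sin(X[:, 0]), sp, n=20000, seed=2)
    assert abs(S[1]) < 3 * se[1] + 1e-3


# ---------------------------------------------------------------- likelihood

def test_loglik_closed_form_single_observation():
    ll = log_likelihood(np.array([10.0]), np.array([10.0]), NoiseModel(0.05))
    assert float(ll) == pytest.approx(-0.5 * np.log(2 * np.pi * 0.25))


def test_loglik_residual_equal_to_sigma():
    noise = NoiseModel(0.05)
    v = 10.0
    sigma = 0.5
    ll = log_likelihood(np.array([v + sigma]), np.array([v]), noise)
    assert float(ll) == pytest.approx(-0.5 * np.log(2 * np.pi * sigma**2) - 0.5)


def test_loglik_matches_pdf_product_oracle(rng):
    noise = NoiseModel(0.05, sd_floor=1e-6)
    for _ in range(10):
        v = rng.uniform(0.1, 10.0, size=6)
        d = v + rng.normal(0, 0.05 * v)
        ours = float(log_likelihood(d, v, noise))
        oracle = float(np.sum(stats.norm.logpdf(d, loc=v, scale=noise.sd(v))))
        assert ours == pytest.approx(oracle, abs=1e-12)


def test_nonfinite_prediction_gives_minus_infinity():
    ll = log_likelihood(np.array([1.0]), np.array([[np.nan]]), NoiseModel(0.05))
    assert ll[0] == -np.inf


def test_sd_floor_applies_at_zero_signal():
    noise = NoiseModel(0.05, sd_floor=1e-8)
    assert noise.sd(0.0) == 1e-8


# ---------------------------------------------------------------- resampling

def test_systematic_resample_hand_case():
    idx = systematic_resample(np.array([0.2, 0.8]), 0.5, n_out=5)
    counts = collections.Counter(idx.tolist())
    assert counts == {0: 1, 1: 4}


def test_uniform_weights_resample_to_identity():
    n = 17
    idx = systematic_resample(np.full(n, 1 / n), 0.3)
    np.testing.assert_array_equal(np.sort(idx), np.arange(n))


def test_systematic_resample_unbiased(rng):
    w = np.array([0.1, 0.25, 0.05, 0.6])
    n_draws = 10000
    counts = np.zeros(4)
    for _ in range(n_draws):
        idx = systematic_resample(w, rng.uniform())
        for i in idx:
            counts[i] += 1
    freq = counts / (n_draws * w.size)
    se = np.sqrt(w * (1 - w) / (n_draws * w.size))
    assert np.all(np.abs(freq - w) < 3 * se + 1e-3)


# ---------------------------------------------------------------- SMC

def test_flat_likelihood_leaves_prior_unchanged():
    prior = uniform_box([(0.0, 1.0)])
    surr = {("y", 0.0): lambda X: np.zeros(np.atleast_2d(X).shape[0])}
    ds = Dataset([("y", 0.0, 0.0)])
    hist = smc_run(prior, surr, ds, _FixedNoise(1.0, 1.0), n_particles=20000, seed=3)
    ks = stats.kstest(hist[-1].particles[:, 0], "uniform")
    assert ks.pvalue > 0.01


def test_conjugate_gaussian_recovery():
    prior = ParameterSpace((Marginal("gaussian", 0.0, 1.0),))
    surr = {("y", 0.0): lambda X: np.atleast_2d(X)[:, 0]}
    ds = Dataset([("y", 0.0, 1.0)])
    hist = smc_run(prior, surr, ds, _FixedNoise(1.0, 1.0), n_particles=50000, seed=4)
    post = hist[-1]
    se_mean = np.sqrt(0.5 / post.n)
    assert abs(post.mean()[0] - 0.5) < 3 * se_mean
    assert abs(post.var()[0] - 0.5) < 3 * np.sqrt(2) * 0.5 / np.sqrt(post.n)


def test_stages_grouped_by_time_and_ess_recorded():
    prior = uniform_box([(0.0, 1.0)])
    surr = {("y", t): (lambda X: np.atleast_2d(X)[:, 0]) for t in (0.0, 1.0, 2.0)}
    ds = Dataset([("y", t, 0.5) for t in (0.0, 1.0, 2.0)])
    hist = smc_run(prior, surr, ds, NoiseModel(0.5), n_particles=2000, seed=5)
    assert len(hist) == 3
    for ens in hist:
        assert 1.0 <= ens.ess() <= ens.n
        assert ens.weights.sum() == pytest.approx(1.0, abs=1e-12)


def test_all_zero_weights_is_reported_with_stage():
    prior = uniform_box([(0.0, 1.0)])
    surr = {("y", 0.0): lambda X: np.full(np.atleast_2d(X).shape[0], np.nan)}
    ds = Dataset([("y", 0.0, 1.0)])
    with pytest.raises(RuntimeError, match="stage 1"):
        smc_run(prior, surr, ds, NoiseModel(0.05), n_particles=100, seed=6)


# ---------------------------------------------------------------- propagate

def test_propagate_constant_surrogate_degenerate_histogram():
    sp = uniform_box([(0, 1)])
    samples, hists = propagate([lambda X: np.full(np.atleast_2d(X).shape[0], 2.0)],
                               sp, n=500, seed=0)
    edges, counts = hists[0]
    assert counts.sum() == 500 and len(counts) == 1


def test_propagate_mean_matches_pce_moments(rng):
    sp = uniform_box([(0, 2)])
    pce = SparsePCE(sp, MultiIndexSet(((0,), (1,))), np.array([1.0, 0.5]), 0.0)
    samples, _ = propagate([pce], sp, n=100000, seed=1)
    mean, var = pce.moments()
    assert abs(samples.mean() - mean) < 3 * np.sqrt(var / samples.size)


# ---------------------------------------------------------------- MAP/Laplace

def _ridge_problem():
    # linear model v = a + b t, fixed sigma = 1, gaussian priors
    prior = ParameterSpace((Marginal("gaussian", 0.0, 2.0), Marginal("gaussian", 1.0, 3.0)))
    times = [0.0, 1.0, 2.0, 3.0]
    d = np.array([1.0, 1.6, 1.9, 2.6])
    ds = Dataset([("q", t, di) for t, di in zip(times, d)])

    def predict(X, obs):
        X = np.atleast_2d(X)
        return np.column_stack([X[:, 0] + X[:, 1] * t for (_q, t, _d) in obs])

    # analytic ridge solution of the gaussian posterior
    A = np.array([[1.0, t] for t in times])
    P0 = np.diag([1 / 2.0**2, 1 / 3.0**2])
    H = A.T @ A + P0
    rhs = A.T @ d + P0 @ np.array([0.0, 1.0])
    xstar = np.linalg.solve(H, rhs)
    cov = np.linalg.inv(H)
    return prior, ds, predict, xstar, cov


def test_map_matches_analytic_ridge_solution():
    prior, ds, predict, xstar, _cov = _ridge_problem()
    res = map_estimate(ds, predict, _FixedNoise(1.0, 1.0), prior)
    np.testing.assert_allclose(res.map_point, xstar, atol=1e-6)


def test_neg_log_posterior_infinite_outside_uniform_support():
    prior = uniform_box([(0.0, 1.0)])
    ds = Dataset([("q", 0.0, 0.5)])
    val = neg_log_posterior(np.array([2.0]), ds,
                            lambda X, obs: np.atleast_2d(X)[:, :1], NoiseModel(0.05), prior)
    assert val == np.inf


def test_laplace_recovers_gaussian_covariance():
    prior, ds, predict, xstar, cov = _ridge_problem()
    noise = _FixedNoise(1.0, 1.0)
    res = map_estimate(ds, predict, noise, prior)
    obj = lambda x: neg_log_posterior(x, ds, predict, noise, prior)  # noqa: E731
    post = laplace_posterior(res, obj, steps=1e-4 * prior.sd)
    np.testing.assert_allclose(post.covariance, cov, rtol=1e-4, atol=1e-8)
    assert np.all(np.linalg.eigvalsh(post.covariance) > 0)


def test_insensitive_parameter_keeps_prior_sd():
    # data only constrain x1; x2's Laplace sd must stay near its prior sd
    prior = ParameterSpace((Marginal("gaussian", 0.0, 1.0), Marginal("gaussian", 0.0, 0.5)))
    ds = Dataset([("q", float(t), 0.2) for t in range(5)])

    def predict(X, obs):
        X = np.atleast_2d(X)
        return np.column_stack([X[:, 0] for _ in obs])

    noise = _FixedNoise(1.0, 0.3)
    res = map_estimate(ds, predict, noise, prior)
    obj = lambda x: neg_log_posterior(x, ds, predict, noise, prior)  # noqa: E731
    post = laplace_posterior(res, obj, steps=1e-4 * prior.sd)
    assert abs(post.sd()[1] - 0.5) / 0.5 < 0.2


def test_laplace_rejects_saddle_point():
    res_like = type("R", (), {"map_point": np.zeros(2), "objective_value": 0.0, "converged": True})()
    obj = lambda x: x[0] ** 2 - x[1] ** 2  # noqa: E731
    from nspce.uq import GaussianPosterior

    res = GaussianPosterior(np.zeros(2), None, 0.0)
    with pytest.raises(ValueError, match="negative eigenvalue"):
        laplace_posterior(res, obj, steps=np.array([1e-3, 1e-3]))


# ---------------------------------------------------------------- ensembles

def test_particle_ensemble_validation():
    with pytest.raises(ValueError):
        ParticleEnsemble(np.zeros((3, 1)), np.array([0.5, 0.5, 0.5]))
    ens = ParticleEnsemble(np.arange(4.0)[:, None], np.full(4, 0.25))
    assert effective_sample_size(ens.weights) == pytest.approx(4.0)
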