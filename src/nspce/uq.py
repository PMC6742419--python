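"""Forward and inverse uncertainty quantification on (ns)PCE surrogates.

Forward tasks: Sobol sensitivity indices (analytically from PCE
coefficients where the surrogate is a single expansion, or by Saltelli
pick-freeze Monte Carlo for piecewise surrogates) and distribution
propagation.  Inverse tasks: Gaussian likelihood with state-proportional
noise, sequential Monte Carlo (SMC) posterior sampling with systematic
resampling, MAP estimation by non-smooth-tolerant local search, and the
Laplace (Gaussian) posterior approximation from a finite-difference
Hessian at the MAP point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .pce import SparsePCE
from .space import ParameterSpace

logger = logging.getLogger(__name__)

__all__ = [
    "NoiseModel",
    "Dataset",
    "ParticleEnsemble",
    "GaussianPosterior",
    "sobol_from_pce",
    "sobol_mc_on_surrogate",
    "propagate",
    "log_likelihood",
    "systematic_resample",
    "smc_run",
    "neg_log_posterior",
    "map_estimate",
    "laplace_posterior",
    "effective_sample_size",
]


@dataclass(frozen=True)
class NoiseModel:
    """State-proportional Gaussian noise: sigma = relative_sd * |v|.

    ``sd_floor`` keeps sigma strictly positive at zero concentrations,
    where the proportional rule alone would be ill-posed.
    """

    relative_sd: float = 0.05
    sd_floor: float = 1e-8

    def __post_init__(self) -> None:
        if not self.relative_sd >= 0:
            raise ValueError("relative_sd must be nonnegative")
        if not self.sd_floor > 0:
            raise ValueError("sd_floor must be positive")

    def sd(self, v):
        return np.maximum(self.relative_sd * np.abs(v), self.sd_floor)


@dataclass
class Dataset:
    """Long-form observations: (quantity label, time, measured value)."""

    observations: list[tuple[str, float, float]]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.observations)

    def stages(self, by: str = "time") -> list[list[tuple[str, float, float]]]:
        """Group observations into SMC stages (default: one per time point,
        in increasing time order; ``by="observation"`` gives one each)."""
        if by == "observation":
            return [[o] for o in sorted(self.observations, key=lambda o: o[1])]
        times = sorted({o[1] for o in self.observations})
        return [[o for o in self.observations if o[1] == t] for t in times]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.observations, columns=["quantity", "time", "value"])

    @classmethod
    def from_frame(cls, df) -> "Dataset":
        obs = [(str(q), float(t), float(v)) for q, t, v in df[["quantity", "time", "value"]].itertuples(index=False)]
        return cls(obs)


@dataclass
class ParticleEnsemble:
    """Weighted SMC particles targeting a (partial) posterior."""

    particles: np.ndarray
    weights: np.ndarray
    stage: int = 0

    def __post_init__(self) -> None:
        self.particles = np.atleast_2d(np.asarray(self.particles, dtype=float))
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if self.particles.shape[0] != self.weights.size:
            raise ValueError("particles / weights size mismatch")
        if self.particles.shape[0] < 2:
            raise ValueError("need at least 2 particles")
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be nonnegative and normalized")

    @property
    def n(self) -> int:
        return self.particles.shape[0]

    def ess(self) -> float:
        return effective_sample_size(self.weights)

    def mean(self) -> np.ndarray:
        return self.weights @ self.particles

    def var(self) -> np.ndarray:
        mu = self.mean()
        return self.weights @ (self.particles - mu) ** 2

    def quantiles(self, qs) -> np.ndarray:
        out = []
        for j in range(self.particles.shape[1]):
            order = np.argsort(self.particles[:, j])
            cw = np.cumsum(self.weights[order])
            out.append(np.interp(qs, cw, self.particles[order, j]))
        return np.array(out)


@dataclass
class GaussianPosterior:
    """MAP point with Laplace covariance (and the objective at the MAP)."""

    map_point: np.ndarray
    covariance: np.ndarray | None
    objective_value: float
    converged: bool = True

    def sd(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))


def effective_sample_size(weights: np.ndarray) -> float:
    w = np.asarray(weights, dtype=float)
    return float(1.0 / np.sum(w * w))


# --------------------------------------------------------------------------
# Sobol sensitivity
# --------------------------------------------------------------------------

def sobol_from_pce(pce: SparsePCE, order: str = "first") -> np.ndarray:
    """Sobol indices computed analytically from PCE coefficients.

    First-order ``S_i`` sums squared coefficients of terms involving only
    parameter ``i``; total ``T_i`` sums those of every term involving
    parameter ``i``; both are normalized by the total variance.
    """
    _, var = pce.moments()
    if var <= 0:
        raise ValueError("zero-variance PCE has no Sobol indices")
    M = pce.space.dimension
    S = np.zeros(M)
    for alpha, a in zip(pce.indices, pce.coefficients):
        nz = [i for i, v in enumerate(alpha) if v > 0]
        if not nz:
            continue
        if order == "first":
            if len(nz) == 1:
                S[nz[0]] += a * a
        elif order == "total":
            for i in nz:
                S[i] += a * a
        else:
            raise ValueError("order must be 'first' or 'total'")
    return S / var


def sobol_mc_on_surrogate(surrogate, space: ParameterSpace, n: int = 20000,
                          seed=None, order: str = "first") -> tuple[np.ndarray, np.ndarray]:
    """Saltelli pick-freeze Monte Carlo Sobol estimator on any evaluatable.

    Works for piecewise (nsPCE) surrogates where the coefficient formulas
    only apply within elements.  Returns (indices, standard errors).
    """
    if n < 1000:
        raise ValueError("need n >= 1000 for a stable pick-freeze estimate")
    rng = np.random.default_rng(seed)
    M = space.dimension
    A = space.sample(n, rng)
    B = space.sample(n, rng)
    yA = np.asarray(surrogate(A), dtype=float)
    yB = np.asarray(surrogate(B), dtype=float)
    f0 = 0.5 * (yA.mean() + yB.mean())
    var = 0.5 * (yA.var() + yB.var())
    if var <= 0:
        raise ValueError("zero-variance surrogate")
    S = np.empty(M)
    se = np.empty(M)
    for i in range(M):
        ABi = A.copy()
        ABi[:, i] = B[:, i]
        yABi = np.asarray(surrogate(ABi), dtype=float)
        if order == "first":
            # Sobol-Saltelli first-order: E_i = yB (yABi - yA)
            prod = yB * (yABi - yA)
        elif order == "total":
            prod = 0.5 * (yA - yABi) ** 2
        else:
            raise ValueError("order must be 'first' or 'total'")
        S[i] = prod.mean() / var
        se[i] = prod.std(ddof=1) / np.sqrt(n) / var
    return S, se


# --------------------------------------------------------------------------
# Forward propagation
# --------------------------------------------------------------------------

def propagate(surrogates, source, n: int = 10000, seed=None, bins: int = 50):
    """Evaluate surrogates on prior draws or posterior particles.

    ``source`` is a :class:`ParameterSpace` (prior draws) or a
    :class:`ParticleEnsemble` (importance-resampled posterior draws).
    Returns ``(samples matrix, list of (bin_edges, counts))``.
    """
    rng = np.random.default_rng(seed)
    if isinstance(source, ParticleEnsemble):
        idx = systematic_resample(source.weights, rng.uniform())
        X = source.particles[idx]
        if X.shape[0] > n:
            X = X[rng.choice(X.shape[0], n, replace=False)]
    else:
        X = source.sample(n, rng)
    cols = [np.asarray(sur(X), dtype=float) for sur in surrogates]
    samples = np.column_stack(cols)
    hists = []
    for c in cols:
        if np.ptp(c) <= 1e-300:
            edges = np.array([c[0] - 0.5, c[0] + 0.5])
            hists.append((edges, np.array([c.size])))
        else:
            counts, edges = np.histogram(c, bins=bins)
            hists.append((edges, counts))
    return samples, hists


# --------------------------------------------------------------------------
# Likelihood / SMC
# --------------------------------------------------------------------------

def log_likelihood(observed: np.ndarray, predicted: np.ndarray, noise: NoiseModel) -> np.ndarray:
    """Gaussian log likelihood with model-state-proportional noise.

    ``sigma_i = max(relative_sd * |prediction_i|, sd_floor)`` — the noise
    scale follows the model prediction, so the normalization term varies
    with the parameters and is always kept.  Accepts a matrix of
    predictions (rows = parameter vectors) and returns one value per row.
    """
    d = np.asarray(observed, dtype=float).ravel()
    v = np.atleast_2d(np.asarray(predicted, dtype=float))
    squeeze = np.asarray(predicted).ndim == 1
    if v.shape[1] != d.size:
        raise ValueError("predictions not aligned to observations")
    sigma = noise.sd(v)
    with np.errstate(invalid="ignore"):
        ll = -0.5 * np.log(2.0 * np.pi * sigma**2) - (d - v) ** 2 / (2.0 * sigma**2)
    out = ll.sum(axis=1)
    bad = ~np.isfinite(v).all(axis=1)
    if np.any(bad):
        logger.warning("non-finite predictions for %d parameter vectors", int(bad.sum()))
        out[bad] = -np.inf
    return out[0] if squeeze else out


def systematic_resample(weights: np.ndarray, u: float, n_out: int | None = None) -> np.ndarray:
    """Systematic resampling: positions (i + u)/N against the cumulative
    weights; order-preserving, one uniform draw.  ``n_out`` defaults to
    the number of weights."""
    w = np.asarray(weights, dtype=float)
    if not 0.0 <= u < 1.0:
        raise ValueError("u must be in [0, 1)")
    n = n_out if n_out is not None else w.size
    positions = (np.arange(n) + u) / n
    return np.searchsorted(np.cumsum(w), positions).clip(max=w.size - 1)


class SurrogatePredictor:
    """Maps a dataset's (quantity, time) keys to surrogate evaluations."""

    def __init__(self, surrogates: dict):
        self.surrogates = dict(surrogates)

    def __call__(self, X: np.ndarray, observations) -> np.ndarray:
        X = np.atleast_2d(X)
        cols = []
        for (q, t, _d) in observations:
            key = (q, t)
            if key not in self.surrogates:
                raise KeyError(f"no surrogate for quantity {q!r} at time {t}")
            cols.append(np.asarray(self.surrogates[key](X), dtype=float))
        return np.column_stack(cols)


def smc_run(
    prior: ParameterSpace,
    surrogates: dict,
    dataset: Dataset,
    noise: NoiseModel,
    n_particles: int = 10000,
    seed=None,
    stage_by: str = "time",
    resample_every_stage: bool = True,
    ess_threshold: float | None = None,
) -> list[ParticleEnsemble]:
    """Sequential Monte Carlo targeting the Bayesian posterior.

    Initializes equal-weight prior particles, then per data stage:
    reweight by the stage likelihood (evaluated through the surrogates),
    normalize, and systematically resample back to equal weights.  The
    printed algorithm resamples unconditionally each stage; set
    ``resample_every_stage=False`` with an ``ess_threshold`` for
    ESS-triggered resampling instead.  Returns one ensemble per stage.
    """
    rng = np.random.default_rng(seed)
    predictor = surrogates if isinstance(surrogates, SurrogatePredictor) else SurrogatePredictor(surrogates)
    X = prior.sample(n_particles, rng)
    logw = np.zeros(n_particles)
    history: list[ParticleEnsemble] = []
    for k, stage in enumerate(dataset.stages(by=stage_by), start=1):
        d = np.array([o[2] for o in stage])
        V = predictor(X, stage)
        ll = log_likelihood(d, V, noise)
        logw = logw + ll
        if not np.any(np.isfinite(logw)):
            raise RuntimeError(
                f"all particle weights vanished at stage {k}; max stage log-likelihood {ll.max():.3g}"
            )
        w = np.exp(logw - logw.max())
        w /= w.sum()
        ens = ParticleEnsemble(X.copy(), w, stage=k)
        history.append(ens)
        do_resample = resample_every_stage or (
            ess_threshold is not None and ens.ess() < ess_threshold * n_particles
        )
        if do_resample:
            idx = systematic_resample(w, rng.uniform())
            X = X[idx]
            logw = np.zeros(n_particles)
    return history


# --------------------------------------------------------------------------
# MAP + Laplace
# --------------------------------------------------------------------------

def _log_prior(x: np.ndarray, prior: ParameterSpace) -> float:
    lp = 0.0
    for xi, m in zip(x, prior.marginals):
        if m.family == "uniform":
            if not (m.a <= xi <= m.b):
                return -np.inf
        else:
            lp += -0.5 * ((xi - m.a) / m.b) ** 2 - 0.5 * np.log(2 * np.pi * m.b**2)
    return lp


def neg_log_posterior(x, dataset: Dataset, predict_fn, noise: NoiseModel, prior: ParameterSpace) -> float:
    """Negative log posterior (all Gaussian normalization terms kept,
    since sigma depends on the parameters).  ``predict_fn(x, observations)``
    returns the prediction row aligned to the dataset."""
    x = np.asarray(x, dtype=float).ravel()
    lp = _log_prior(x, prior)
    if not np.isfinite(lp):
        return np.inf
    d = np.array([o[2] for o in dataset.observations])
    v = predict_fn(x[None, :], dataset.observations)[0]
    ll = float(log_likelihood(d, v, noise))
    return -(ll + lp)


def map_estimate(
    dataset: Dataset,
    predict_fn,
    noise: NoiseModel,
    prior: ParameterSpace,
    support: ParameterSpace | None = None,
    x0: np.ndarray | None = None,
    maxiter: int = 2000,
) -> GaussianPosterior:
    """MAP point by a derivative-free local search from the prior mean.

    Iterates are clipped to the surrogate support; a Gaussian prior acts
    as the ridge regularizer.  Uses Nelder-Mead, which tolerates the
    non-smoothness of piecewise surrogates.
    """
    support = support or prior
    lo = support.lower
    hi = support.upper

    def clip(x):
        return np.clip(x, lo, hi)

    def obj(x):
        return neg_log_posterior(clip(x), dataset, predict_fn, noise, prior)

    x0 = np.asarray(x0 if x0 is not None else prior.mean, dtype=float)
    res = minimize(obj, x0, method="Nelder-Mead",
                   options={"maxiter": maxiter, "xatol": 1e-8, "fatol": 1e-10, "adaptive": True})
    xmap = clip(res.x)
    return GaussianPosterior(xmap, None, float(res.fun), converged=bool(res.success))


def laplace_posterior(
    map_result: GaussianPosterior,
    objective,
    steps: np.ndarray,
) -> GaussianPosterior:
    """Laplace approximation: covariance = inverse finite-difference
    Hessian of the negative log posterior at the MAP point.

    ``steps`` are per-dimension central-difference steps (recommended:
    1e-4 times the prior sd).  Symmetrizes the Hessian; clearly negative
    eigenvalues mean the point is not a local minimum and raise.
    """
    x = np.asarray(map_result.map_point, dtype=float)
    M = x.size
    h = np.asarray(steps, dtype=float).ravel()
    f0 = objective(x)
    H = np.empty((M, M))
    for i in range(M):
        ei = np.zeros(M)
        ei[i] = h[i]
        fpp = objective(x + ei)
        fmm = objective(x - ei)
        H[i, i] = (fpp - 2 * f0 + fmm) / h[i] ** 2
        for j in range(i + 1, M):
            ej = np.zeros(M)
            ej[j] = h[j]
            fp_p = objective(x + ei + ej)
            fp_m = objective(x + ei - ej)
            fm_p = objective(x - ei + ej)
            fm_m = objective(x - ei - ej)
            H[i, j] = H[j, i] = (fp_p - fp_m - fm_p + fm_m) / (4 * h[i] * h[j])
    H = 0.5 * (H + H.T)
    evals, evecs = np.linalg.eigh(H)
    tr = float(np.sum(np.abs(evals)))
    if np.any(evals < -1e-8 * max(tr, 1.0)):
        raise ValueError("Hessian has a significantly negative eigenvalue; MAP is not a local minimum")
    evals = np.clip(evals, 1e-300, None)
    cov = (evecs / evals) @ evecs.T
    cov = 0.5 * (cov + cov.T)
    return GaussianPosterior(x, cov, map_result.objective_value, map_result.converged)
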