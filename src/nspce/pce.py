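"""Sparse polynomial chaos expansions.

Implements orthonormal tensor-product bases (normalized Legendre for
uniform marginals, normalized probabilists' Hermite for Gaussian
marginals), hyperbolic truncation of the multi-index set, ordinary least
squares and hybrid least-angle-regression (LAR) fitting with the analytic
leave-one-out (LOO) cross-validation error, basis-adaptive model
selection, and the sequential experimental-design (ED) enrichment loop.

A fitted surrogate is a :class:`SparsePCE`: an active multi-index set
``A``, coefficients ``a`` in the orthonormal convention (so the mean is
the constant coefficient and the variance is the sum of squared
non-constant coefficients), and the relative LOO error ``eps_LOO``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import lars_path

from .space import ParameterSpace

logger = logging.getLogger(__name__)

__all__ = [
    "MultiIndexSet",
    "ExperimentalDesign",
    "SparsePCE",
    "hyperbolic_truncation",
    "eval_basis",
    "ols_fit",
    "loo_error",
    "hybrid_lar_fit",
    "basis_adaptive_fit",
    "sequential_ed_fit",
    "evaluate_pce",
    "pce_moments",
]

#: slack in the hyperbolic-norm test, avoids float exclusion of boundary indices
NUM_TOL = 1e-10


class RankDeficiencyError(np.linalg.LinAlgError):
    """OLS design matrix is rank deficient; use the sparse (LAR) fit instead."""


@dataclass(frozen=True)
class MultiIndexSet:
    """Ordered set of multi-indices (graded-lexicographic, zero index first)."""

    indices: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        idx = tuple(tuple(int(v) for v in a) for a in self.indices)
        if len(idx) == 0:
            raise ValueError("multi-index set may not be empty")
        if len(set(idx)) != len(idx):
            raise ValueError("duplicate multi-indices")
        object.__setattr__(self, "indices", idx)

    @property
    def dimension(self) -> int:
        return len(self.indices[0])

    @property
    def cardinality(self) -> int:
        return len(self.indices)

    def __len__(self) -> int:
        return len(self.indices)

    def __iter__(self):
        return iter(self.indices)

    def __getitem__(self, i):
        return self.indices[i]

    def subset(self, positions) -> "MultiIndexSet":
        return MultiIndexSet(tuple(self.indices[i] for i in positions))

    def as_array(self) -> np.ndarray:
        return np.array(self.indices, dtype=int)


def _graded_lex_key(alpha: tuple[int, ...]):
    return (sum(alpha), alpha)


def hyperbolic_truncation(M: int, p: int, q: float = 1.0) -> MultiIndexSet:
    """Multi-index set ``{alpha : ||alpha||_q <= p}`` with ``0 < q <= 1``.

    ``q = 1`` is total-degree truncation with cardinality
    ``(M+p)! / (M! p!)``; smaller ``q`` prunes high-order interactions.
    """
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    if p < 0:
        raise ValueError("p must be >= 0")

    out = []
    # ||alpha||_q >= ||alpha||_1 for q <= 1, so total degree <= p suffices
    for total in range(p + 1):
        for alpha in _compositions(total, M):
            if q == 1.0:
                out.append(alpha)
            else:
                norm = float(np.sum(np.array(alpha, dtype=float) ** q)) ** (1.0 / q)
                if norm <= p + NUM_TOL:
                    out.append(alpha)
    out.sort(key=_graded_lex_key)
    return MultiIndexSet(tuple(out))


def _compositions(total: int, M: int):
    """All M-tuples of nonnegative integers summing to ``total``."""
    if M == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in _compositions(total - first, M - 1):
            yield (first,) + rest


def _legendre_orthonormal(z: np.ndarray, pmax: int) -> np.ndarray:
    """Orthonormal Legendre values, shape (len(z), pmax+1).

    Orthonormal w.r.t. the uniform density on [-1, 1]; degree-n norm factor
    is sqrt(2n+1).
    """
    z = np.asarray(z, dtype=float)
    out = np.empty((z.size, pmax + 1))
    out[:, 0] = 1.0
    if pmax >= 1:
        out[:, 1] = z
    for n in range(1, pmax):
        out[:, n + 1] = ((2 * n + 1) * z * out[:, n] - n * out[:, n - 1]) / (n + 1)
    out *= np.sqrt(2 * np.arange(pmax + 1) + 1.0)
    return out


def _hermite_orthonormal(z: np.ndarray, pmax: int) -> np.ndarray:
    """Orthonormal probabilists' Hermite values He_n / sqrt(n!)."""
    z = np.asarray(z, dtype=float)
    he = np.empty((z.size, pmax + 1))
    he[:, 0] = 1.0
    if pmax >= 1:
        he[:, 1] = z
    for n in range(1, pmax):
        he[:, n + 1] = z * he[:, n] - n * he[:, n - 1]
    fact = np.cumprod(np.concatenate(([1.0], np.arange(1, pmax + 1, dtype=float)))) if pmax else np.array([1.0])
    return he / np.sqrt(fact)


def eval_basis(space: ParameterSpace, indices: MultiIndexSet, x: np.ndarray, *, standardized: bool = False) -> np.ndarray:
    """Model matrix of orthonormal tensor-product polynomials at samples ``x``.

    Returns the ``N x P`` matrix with one column per multi-index; the
    column of the zero index is identically 1.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    z = x if standardized else space.standardize(x, check=False)
    M = space.dimension
    if indices.dimension != M:
        raise ValueError("multi-index dimension does not match space")
    pmax = int(indices.as_array().max(initial=0))
    uni = []
    for j, m in enumerate(space.marginals):
        fn = _legendre_orthonormal if m.family == "uniform" else _hermite_orthonormal
        uni.append(fn(z[:, j], pmax))
    A = np.ones((z.shape[0], len(indices)))
    for k, alpha in enumerate(indices):
        for j in range(M):
            if alpha[j]:
                A[:, k] *= uni[j][:, alpha[j]]
    return A


@dataclass
class ExperimentalDesign:
    """Parameter samples, model responses and optional singularity times."""

    X: np.ndarray
    Y: np.ndarray | None = None
    T_singularity: np.ndarray | None = None
    seed: int | None = None
    trajectories: list = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.Y is not None:
            self.Y = np.asarray(self.Y, dtype=float).ravel()
            if self.Y.size != self.X.shape[0]:
                raise ValueError("X and Y row counts disagree")
        if self.T_singularity is not None:
            self.T_singularity = np.asarray(self.T_singularity, dtype=float).ravel()
            if self.T_singularity.size != self.X.shape[0]:
                raise ValueError("X and T_singularity row counts disagree")

    @property
    def n(self) -> int:
        return self.X.shape[0]


@dataclass
class SparsePCE:
    """A fitted sparse PCE: active indices, coefficients, and eps_LOO."""

    space: ParameterSpace
    indices: MultiIndexSet
    coefficients: np.ndarray
    loo_error: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float).ravel()
        if self.coefficients.size != len(self.indices):
            raise ValueError("coefficient count must equal index count")
        if not self.loo_error >= 0:
            raise ValueError("eps_LOO must be nonnegative")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        A = eval_basis(self.space, self.indices, x)
        return A @ self.coefficients

    def moments(self) -> tuple[float, float]:
        """(mean, variance) from orthonormality: mean is the constant
        coefficient, variance the sum of squared non-constant ones."""
        mean = 0.0
        var = 0.0
        for alpha, a in zip(self.indices, self.coefficients):
            if all(v == 0 for v in alpha):
                mean = float(a)
            else:
                var += float(a) ** 2
        return mean, var

    def to_dict(self) -> dict:
        return {
            "schema": "nspce.SparsePCE/1",
            "space": self.space.to_dict(),
            "indices": [list(a) for a in self.indices],
            "coefficients": list(map(float, self.coefficients)),
            "loo_error": float(self.loo_error),
            "meta": {k: v for k, v in self.meta.items() if _jsonable(v)},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SparsePCE":
        return cls(
            space=ParameterSpace.from_dict(d["space"]),
            indices=MultiIndexSet(tuple(tuple(a) for a in d["indices"])),
            coefficients=np.array(d["coefficients"], dtype=float),
            loo_error=float(d["loo_error"]),
            meta=dict(d.get("meta", {})),
        )


def _jsonable(v) -> bool:
    return isinstance(v, (int, float, str, bool, type(None), list, tuple))


def evaluate_pce(pce: SparsePCE, x: np.ndarray) -> np.ndarray:
    return pce(x)


def pce_moments(pce: SparsePCE) -> tuple[float, float]:
    return pce.moments()


def ols_fit(model_matrix: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Ordinary least squares via QR; errors out on rank deficiency."""
    A = np.asarray(model_matrix, dtype=float)
    Y = np.asarray(Y, dtype=float).ravel()
    N, P = A.shape
    if N < P:
        raise RankDeficiencyError(f"N={N} < P={P}; use the sparse (LAR) fit")
    coef, _, rank, _ = np.linalg.lstsq(A, Y, rcond=None)
    if rank < P:
        raise RankDeficiencyError(f"model matrix rank {rank} < P={P}; use the sparse (LAR) fit")
    return coef


def _hat_diagonal(A: np.ndarray) -> np.ndarray:
    Q, _ = np.linalg.qr(A)
    return np.sum(Q * Q, axis=1)


def loo_error(model_matrix: np.ndarray, Y: np.ndarray, coefficients: np.ndarray) -> float:
    """Analytic relative leave-one-out error via the hat-matrix diagonal.

    ``eps_LOO = mean(((y_i - yhat_i) / (1 - h_i))^2) / Var{Y}``; returns 0
    for degenerate zero-variance responses fitted exactly.
    """
    A = np.asarray(model_matrix, dtype=float)
    Y = np.asarray(Y, dtype=float).ravel()
    resid = Y - A @ np.asarray(coefficients, dtype=float)
    h = _hat_diagonal(A)
    if np.any(h >= 1.0 - 1e-10):
        raise ValueError("hat diagonal reaches 1 (interpolating point); add samples")
    varY = float(np.var(Y))
    press = float(np.mean((resid / (1.0 - h)) ** 2))
    if varY <= 0.0:
        if press <= 1e-28:
            return 0.0
        raise ValueError("zero response variance with nonzero residuals")
    return press / varY


def _corrected_loo(A: np.ndarray, Y: np.ndarray, coef: np.ndarray) -> float:
    """LOO with the variance-inflation correction used to rank LAR prefixes.

    T(P, N) = (1 - P/N)^-1 (1 + tr((A^T A)^-1)) penalizes designs where P
    approaches N; uncorrected eps_LOO is what gets reported to users.
    """
    N, P = A.shape
    eps = loo_error(A, Y, coef)
    if N <= P:
        return np.inf
    G = A.T @ A
    try:
        tr = float(np.trace(np.linalg.inv(G)))
    except np.linalg.LinAlgError:
        return np.inf
    T = (1.0 + tr) / (1.0 - P / N)
    return eps * max(T, 1.0)


def _constant_pce(space: ParameterSpace, value: float, meta: dict) -> SparsePCE:
    zero = MultiIndexSet((tuple([0] * space.dimension),))
    return SparsePCE(space, zero, np.array([value]), 0.0, meta)


#: responses with variance below var_floor get a constant surrogate
VAR_FLOOR_REL = 1e-12


def hybrid_lar_fit(
    space: ParameterSpace,
    candidate_indices: MultiIndexSet,
    ed: ExperimentalDesign,
    *,
    meta: dict | None = None,
) -> SparsePCE:
    """Hybrid least-angle regression: one LAR path over the candidate
    basis, OLS refit of every path prefix, ranked by corrected eps_LOO.

    The constant term is always included; the best prefix (minimal
    corrected LOO) is returned with its plain eps_LOO stored.
    """
    if ed.Y is None:
        raise ValueError("experimental design has no responses")
    X, Y = ed.X, ed.Y
    N = X.shape[0]
    if N < 3:
        raise ValueError("need at least 3 design points")
    meta = dict(meta or {})
    meta.setdefault("N", N)

    varY = float(np.var(Y))
    if varY <= VAR_FLOOR_REL * (1.0 + float(np.mean(Y)) ** 2):
        return _constant_pce(space, float(np.mean(Y)), {**meta, "constant": True})

    A_full = eval_basis(space, candidate_indices, X)
    const_pos = next(i for i, a in enumerate(candidate_indices) if sum(a) == 0)
    noncst = [i for i in range(len(candidate_indices)) if i != const_pos]

    # LAR runs on centered/scaled columns; refits use the raw orthonormal ones
    Ac = A_full[:, noncst] - A_full[:, noncst].mean(axis=0)
    scale = np.sqrt(np.sum(Ac * Ac, axis=0))
    keep = scale > 1e-13
    Ac = Ac[:, keep] / np.where(keep, scale, 1.0)[keep]
    cols = [noncst[i] for i in np.nonzero(keep)[0]]
    Yc = Y - Y.mean()

    order: list[int] = []
    if Ac.shape[1] > 0:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, _, coefs = lars_path(Ac, Yc, method="lar", max_iter=min(N - 2, Ac.shape[1]))
        entered = set()
        for step in range(coefs.shape[1]):
            for j in np.nonzero(coefs[:, step])[0]:
                if j not in entered:
                    entered.add(j)
                    order.append(cols[j])

    best = None
    # k = 0 is the constant-only model
    for k in range(0, len(order) + 1):
        sel = [const_pos] + order[:k]
        if N <= len(sel):
            break
        A_sel = A_full[:, sel]
        try:
            coef = ols_fit(A_sel, Y)
            score = _corrected_loo(A_sel, Y, coef)
        except (RankDeficiencyError, ValueError):
            continue
        if best is None or score < best[0]:
            eps = loo_error(A_sel, Y, coef)
            best = (score, sel, coef, eps)

    if best is None:
        return _constant_pce(space, float(np.mean(Y)), {**meta, "constant": True})

    _, sel, coef, eps = best
    return SparsePCE(space, candidate_indices.subset(sel), coef, eps, meta)


def basis_adaptive_fit(
    space: ParameterSpace,
    ed: ExperimentalDesign,
    p_range=range(1, 11),
    q_list=(0.75,),
    early_stop: int = 2,
) -> SparsePCE:
    """Sweep maximum degree ``p`` (and ``q``), keep the fit with minimal
    eps_LOO, stopping after ``early_stop`` consecutive non-improving
    degrees."""
    p_range = list(p_range)
    if not p_range:
        raise ValueError("p_range may not be empty")
    best: SparsePCE | None = None
    stall = 0
    for p in p_range:
        improved = False
        for q in q_list:
            cand = hyperbolic_truncation(space.dimension, p, q)
            pce = hybrid_lar_fit(space, cand, ed, meta={"p": p, "q": q})
            if best is None or pce.loo_error < best.loo_error:
                best = pce
                improved = True
        stall = 0 if improved else stall + 1
        if best is not None and best.meta.get("constant"):
            break
        if stall >= early_stop:
            break
    assert best is not None
    return best


def sequential_ed_fit(
    model_fn,
    space: ParameterSpace,
    eps_target: float = 1e-3,
    n_init: int = 20,
    n_add: int = 10,
    n_max: int = 200,
    seed: int | np.random.Generator | None = None,
    p_range=range(1, 11),
    q_list=(0.75,),
    early_stop: int = 2,
    collect=None,
) -> tuple[SparsePCE, ExperimentalDesign, bool]:
    """Sequential experimental-design loop.

    1. initialize the ED with ``n_init`` Monte Carlo samples;
    2. fit a basis-adaptive sparse PCE and compute eps_LOO;
    3. stop if ``eps_LOO < eps_target``, else add ``n_add`` fresh samples
       and repeat (until ``n_max`` model evaluations).

    ``model_fn(x) -> float`` is called per sample; failing samples are
    skipped with a warning (more than 20% failures is an error).
    ``collect(x, result)`` optionally captures side products (e.g. full
    trajectories).  Returns ``(pce, ed, converged)``.
    """
    if n_init < 3:
        raise ValueError("n_init must be >= 3")
    if n_max < n_init:
        raise ValueError("n_max must be >= n_init")
    rng = np.random.default_rng(seed)

    X_rows, Y_vals = [], []
    n_fail = 0

    def _extend(n):
        nonlocal n_fail
        for x in space.sample(n, rng):
            try:
                y = model_fn(x)
            except Exception as exc:  # noqa: BLE001 - sample-level robustness
                n_fail += 1
                logger.warning("model evaluation failed at %s: %s", x, exc)
                if n_fail > 0.2 * max(len(X_rows) + n_fail, n_init):
                    raise RuntimeError("more than 20% of model evaluations failed") from exc
                continue
            if collect is not None:
                collect(x, y)
            X_rows.append(x)
            Y_vals.append(float(y) if np.isscalar(y) or np.ndim(y) == 0 else float(np.asarray(y).ravel()[0]))

    _extend(n_init)
    while True:
        ed = ExperimentalDesign(np.array(X_rows), np.array(Y_vals))
        pce = basis_adaptive_fit(space, ed, p_range=p_range, q_list=q_list, early_stop=early_stop)
        if pce.loo_error < eps_target:
            return pce, ed, True
        room = n_max - len(X_rows)
        if room <= 0:
            return pce, ed, False
        _extend(min(n_add, room))
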