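"""Parameter spaces with independent uniform or Gaussian marginals.

The random input vector ``X ~ f_X`` of a surrogate model is described by a
:class:`ParameterSpace`: a list of independent one-dimensional marginals,
each either uniform on an interval or Gaussian.  All polynomial-chaos
machinery works in *standardized* coordinates — uniform marginals map
affinely to ``[-1, 1]`` and Gaussian marginals to the standard normal —
so the space also carries the forward/inverse affine transforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Marginal", "ParameterSpace", "uniform_box", "sample_space"]

_FAMILIES = ("uniform", "gaussian")


@dataclass(frozen=True)
class Marginal:
    """One independent marginal distribution.

    For ``family="uniform"`` the parameters are the interval bounds
    ``(a, b)`` with ``a < b``; for ``family="gaussian"`` they are the
    mean and standard deviation ``(mu, sd)`` with ``sd > 0``.
    """

    family: str
    a: float
    b: float

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown marginal family {self.family!r}")
        if self.family == "uniform" and not self.a < self.b:
            raise ValueError(f"uniform bounds must satisfy a < b, got ({self.a}, {self.b})")
        if self.family == "gaussian" and not self.b > 0:
            raise ValueError(f"gaussian sd must be positive, got {self.b}")

    @property
    def mean(self) -> float:
        return 0.5 * (self.a + self.b) if self.family == "uniform" else self.a

    @property
    def sd(self) -> float:
        if self.family == "uniform":
            return (self.b - self.a) / np.sqrt(12.0)
        return self.b

    @property
    def support(self) -> tuple[float, float]:
        if self.family == "uniform":
            return (self.a, self.b)
        return (-np.inf, np.inf)


@dataclass(frozen=True)
class ParameterSpace:
    """Independent product of marginals; the support is denoted ``S``."""

    marginals: tuple[Marginal, ...]
    names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        marginals = tuple(self.marginals)
        object.__setattr__(self, "marginals", marginals)
        if len(marginals) < 1:
            raise ValueError("parameter space needs at least one marginal")
        names = tuple(self.names) if self.names else tuple(f"x{i + 1}" for i in range(len(marginals)))
        if len(names) != len(marginals):
            raise ValueError("names length must match marginal count")
        object.__setattr__(self, "names", names)

    @property
    def dimension(self) -> int:
        return len(self.marginals)

    @property
    def lower(self) -> np.ndarray:
        return np.array([m.support[0] for m in self.marginals])

    @property
    def upper(self) -> np.ndarray:
        return np.array([m.support[1] for m in self.marginals])

    @property
    def mean(self) -> np.ndarray:
        return np.array([m.mean for m in self.marginals])

    @property
    def sd(self) -> np.ndarray:
        return np.array([m.sd for m in self.marginals])

    def contains(self, x: np.ndarray, atol: float = 1e-12) -> np.ndarray:
        """Elementwise support membership for sample rows ``x``."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        lo, hi = self.lower, self.upper
        span = np.where(np.isfinite(hi - lo), hi - lo, 1.0)
        return np.all((x >= lo - atol * (1 + span)) & (x <= hi + atol * (1 + span)), axis=1)

    def sample(self, n: int, rng: np.random.Generator | int | None = None) -> np.ndarray:
        """Draw ``n`` i.i.d. samples from ``f_X`` (rows are samples)."""
        if n < 1:
            raise ValueError("need n >= 1 samples")
        rng = np.random.default_rng(rng)
        cols = []
        for m in self.marginals:
            if m.family == "uniform":
                cols.append(rng.uniform(m.a, m.b, size=n))
            else:
                cols.append(rng.normal(m.a, m.b, size=n))
        return np.column_stack(cols)

    def standardize(self, x: np.ndarray, check: bool = True) -> np.ndarray:
        """Map samples to standardized coordinates ``Z``.

        Uniform marginals map to ``[-1, 1]``, Gaussian marginals to the
        standard normal.  Inverse of :meth:`unstandardize`.
        """
        x = np.asarray(x, dtype=float)
        squeeze = x.ndim == 1
        x2 = np.atleast_2d(x)
        if x2.shape[1] != self.dimension:
            raise ValueError(f"expected {self.dimension} columns, got {x2.shape[1]}")
        if check and not np.all(self.contains(x2)):
            raise ValueError("sample outside the parameter-space support")
        z = np.empty_like(x2)
        for j, m in enumerate(self.marginals):
            if m.family == "uniform":
                z[:, j] = 2.0 * (x2[:, j] - m.a) / (m.b - m.a) - 1.0
            else:
                z[:, j] = (x2[:, j] - m.a) / m.b
        return z[0] if squeeze else z

    def unstandardize(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        squeeze = z.ndim == 1
        z2 = np.atleast_2d(z)
        x = np.empty_like(z2)
        for j, m in enumerate(self.marginals):
            if m.family == "uniform":
                x[:, j] = m.a + 0.5 * (z2[:, j] + 1.0) * (m.b - m.a)
            else:
                x[:, j] = m.a + m.b * z2[:, j]
        return x[0] if squeeze else x

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "marginals": [{"family": m.family, "a": m.a, "b": m.b} for m in self.marginals],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSpace":
        margs = tuple(Marginal(m["family"], float(m["a"]), float(m["b"])) for m in d["marginals"])
        return cls(margs, tuple(d.get("names") or ()))


def uniform_box(bounds, names=None) -> ParameterSpace:
    """Convenience constructor for an axis-aligned uniform box."""
    margs = tuple(Marginal("uniform", float(a), float(b)) for a, b in bounds)
    return ParameterSpace(margs, tuple(names) if names else ())


def sample_space(space: ParameterSpace, n: int, seed=None) -> np.ndarray:
    """Functional alias for :meth:`ParameterSpace.sample`."""
    return space.sample(n, seed)
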