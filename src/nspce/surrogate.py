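"""The non-smooth PCE (nsPCE) surrogate method.

DFBA responses lose differentiability in the parameters at the singularity
time ``t_s(x)`` — the instant the active set of the embedded LP switches
(a substrate runs out, the penalty turns on).  A single global polynomial
expansion converges very slowly across that manifold.  The nsPCE method:

1. fits a sparse PCE surrogate of the singularity time itself, which *is*
   a smooth function of the parameters;
2. for a response at time ``t``, partitions the support into the element
   where the singularity has not yet occurred, ``S1 = {x : t_s(x) > t}``,
   and its complement ``S2 = {x : t_s(x) <= t}``;
3. fits separate sparse PCEs on hyper-rectangular outer bounds of each
   element (using only samples whose membership test passes), reusing the
   trajectories stored while fitting the boundary to initialize both local
   experimental designs;
4. evaluates the piecewise surrogate by routing each point through the
   *fitted* boundary — fit and evaluation use the same routing, so the
   piecewise model is self-consistent even where the boundary model errs.

When ``t`` lies outside the support of ``t_s(X)``, one element is empty
and the method degenerates to a single global PCE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .dfba import DFBAModel, integrate_dfba, interpolate_quantity, singularity_times
from .pce import ExperimentalDesign, SparsePCE, basis_adaptive_fit, sequential_ed_fit
from .space import Marginal, ParameterSpace

logger = logging.getLogger(__name__)

__all__ = [
    "SingularitySurrogate",
    "CallableBoundary",
    "Element",
    "NsPCESurrogate",
    "fit_singularity_surrogate",
    "partition_design",
    "outer_bound_element",
    "train_nspce",
    "evaluate_nspce",
    "select_boundary",
]

#: local responses with variance below var_floor*(1+mean^2) get constant fits
VAR_FLOOR = 1e-12
#: bounding boxes are expanded by this fraction of each side before clipping to S
BOX_MARGIN = 0.01
#: rejection-sampling oversampling cap for small-probability elements
MAX_OVERSAMPLE = 100


@dataclass
class SingularitySurrogate:
    """Sparse PCE of a singularity time, with its MC-estimated range."""

    pce: SparsePCE
    support_range: tuple[float, float]
    label: str

    def __post_init__(self) -> None:
        if self.support_range[0] > self.support_range[1]:
            raise ValueError("support_range min must be <= max")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.pce(x)

    def to_dict(self) -> dict:
        return {"schema": "nspce.SingularitySurrogate/1", "pce": self.pce.to_dict(),
                "support_range": list(self.support_range), "label": self.label}

    @classmethod
    def from_dict(cls, d: dict) -> "SingularitySurrogate":
        return cls(SparsePCE.from_dict(d["pce"]), tuple(d["support_range"]), d["label"])


@dataclass
class CallableBoundary:
    """Adapter for an analytically known singularity time ``t_s(x)``.

    Duck-type compatible with :class:`SingularitySurrogate` wherever only
    evaluation and the support range are needed (training, routing);
    unlike a fitted boundary it cannot be serialized."""

    fn: object
    support_range: tuple[float, float]
    label: str = "analytic"

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x2 = np.atleast_2d(np.asarray(x, dtype=float))
        return np.asarray(self.fn(x2), dtype=float).ravel()


@dataclass
class Element:
    """One side of the partition at response time ``t``.

    ``side=1`` is where the singularity has not occurred (``t_s(x) > t``);
    ``side=2`` where it has (``t_s(x) <= t``; ties go to side 2, matching
    the closed half-space in the set definition)."""

    side: int
    t: float
    boundary: SingularitySurrogate | None
    bounding_box: np.ndarray | None  # (M, 2) or None when element is empty
    empty: bool = False

    def membership(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if self.empty:
            return np.zeros(x.shape[0], dtype=bool)
        if self.boundary is None:  # degenerate single-element surrogate
            return np.ones(x.shape[0], dtype=bool)
        ts = self.boundary(x)
        return ts > self.t if self.side == 1 else ts <= self.t


def _box_space(space: ParameterSpace, box: np.ndarray) -> ParameterSpace:
    """Local independent space on a hyper-rectangle: uniform marginals are
    restricted to the box interval; Gaussian marginals are kept as-is
    (regression absorbs the conditional-density mismatch)."""
    margs = []
    for j, m in enumerate(space.marginals):
        if m.family == "uniform":
            a, b = float(box[j, 0]), float(box[j, 1])
            if not b > a:
                mid = 0.5 * (a + b)
                w = max(1e-12, 1e-9 * (abs(mid) + 1))
                a, b = mid - w, mid + w
            margs.append(Marginal("uniform", a, b))
        else:
            margs.append(m)
    return ParameterSpace(tuple(margs), space.names)


@dataclass
class NsPCESurrogate:
    """Piecewise PCE surrogate of a response at a fixed time ``t``."""

    t: float
    response: str
    boundary: SingularitySurrogate | None
    elements: tuple[Element, Element] | tuple[Element]
    local_pces: tuple
    probabilities: tuple[float, ...]
    meta: dict = field(default_factory=dict)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return evaluate_nspce(self, x)

    @property
    def space(self) -> ParameterSpace:
        if self.boundary is not None and hasattr(self.boundary, "pce"):
            return self.boundary.pce.space
        for pce in self.local_pces:
            if pce is not None:
                return pce.space
        raise ValueError("surrogate has no fitted element")

    def to_dict(self) -> dict:
        return {
            "schema": "nspce.NsPCESurrogate/1",
            "t": self.t,
            "response": self.response,
            "boundary": self.boundary.to_dict() if self.boundary else None,
            "elements": [
                {"side": e.side, "t": e.t, "empty": e.empty,
                 "bounding_box": None if e.bounding_box is None else e.bounding_box.tolist()}
                for e in self.elements
            ],
            "local_pces": [p.to_dict() if p is not None else None for p in self.local_pces],
            "probabilities": list(self.probabilities),
            "meta": {k: v for k, v in self.meta.items()
                     if isinstance(v, (int, float, str, bool, type(None), list))},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NsPCESurrogate":
        boundary = SingularitySurrogate.from_dict(d["boundary"]) if d["boundary"] else None
        elements = tuple(
            Element(e["side"], e["t"], boundary,
                    None if e["bounding_box"] is None else np.array(e["bounding_box"]),
                    e["empty"])
            for e in d["elements"]
        )
        pces = tuple(SparsePCE.from_dict(p) if p is not None else None for p in d["local_pces"])
        return cls(d["t"], d["response"], boundary, elements, pces, tuple(d["probabilities"]),
                   dict(d.get("meta", {})))


def fit_singularity_surrogate(
    model: DFBAModel,
    space: ParameterSpace,
    label: str,
    eps_target: float = 1e-4,
    t_span=None,
    seed=None,
    n_init: int = 20,
    n_add: int = 10,
    n_max: int = 200,
    p_range=range(1, 11),
    q_list=(0.75,),
    n_range_mc: int = 100000,
    integrate_kwargs: dict | None = None,
) -> tuple[SingularitySurrogate, ExperimentalDesign]:
    """Fit a sparse PCE of the labeled singularity time.

    Runs the sequential-ED loop with the full DFBA simulation as the model
    function; the complete trajectories are cached on the returned design
    for reuse when initializing response surrogates.  The surrogate's
    support range is estimated from ``n_range_mc`` surrogate evaluations.
    """
    ikw = dict(integrate_kwargs or {})
    span = t_span if t_span is not None else model.default_t_span
    cache: list = []
    missing: list = []

    def model_fn(x):
        traj = integrate_dfba(model, x, span, **ikw)
        ts = singularity_times(traj, [label])[label]
        if ts is None:
            missing.append(x)
            raise ValueError(f"event {label!r} did not occur within the simulation span")
        cache.append((x, traj))
        return ts

    try:
        pce, ed, converged = sequential_ed_fit(
            model_fn, space, eps_target, n_init, n_add, n_max, seed,
            p_range=p_range, q_list=q_list,
        )
    except RuntimeError as exc:
        if missing:
            raise ValueError(
                f"singularity {label!r} missing for {len(missing)} samples "
                f"(e.g. {np.array2string(np.asarray(missing[0]), precision=4)}); "
                "the boundary model is undefined there"
            ) from exc
        raise
    if missing:
        raise ValueError(f"singularity {label!r} missing for {len(missing)} sampled parameters")

    ed.trajectories = [traj for (_x, traj) in cache[: ed.n]]
    ed.T_singularity = ed.Y.copy()
    rng = np.random.default_rng(seed)
    ts_mc = pce(space.sample(n_range_mc, rng))
    surr = SingularitySurrogate(pce, (float(ts_mc.min()), float(ts_mc.max())), label)
    surr.pce.meta["converged"] = bool(converged)
    return surr, ed


def select_boundary(boundaries, t: float) -> SingularitySurrogate | None:
    """Pick the singularity whose MC support range contains ``t``.

    Multiple sequential singularities are handled as long as their ranges
    do not overlap; overlapping ranges would require more than two
    elements and are rejected."""
    for i, a in enumerate(boundaries):
        for b in boundaries[i + 1:]:
            lo = max(a.support_range[0], b.support_range[0])
            hi = min(a.support_range[1], b.support_range[1])
            if lo < hi:
                raise NotImplementedError(
                    f"singularity supports of {a.label!r} and {b.label!r} overlap on "
                    f"[{lo:.4g}, {hi:.4g}]; multi-element refinement beyond two elements "
                    "is not supported"
                )
    for b in boundaries:
        if b.support_range[0] <= t <= b.support_range[1]:
            return b
    return None


def partition_design(ed: ExperimentalDesign, boundary: SingularitySurrogate, t: float):
    """Split an ED by the fitted boundary: sample i joins element 1 iff
    ``t_s_hat(x_i) > t``, else element 2 (ties to element 2)."""
    ts = boundary(ed.X)
    in1 = ts > t
    def take(mask):
        sub = ExperimentalDesign(ed.X[mask], None if ed.Y is None else ed.Y[mask],
                                 None if ed.T_singularity is None else ed.T_singularity[mask],
                                 ed.seed)
        if ed.trajectories:
            sub.trajectories = [tr for tr, m in zip(ed.trajectories, mask) if m]
        return sub
    return take(in1), take(~in1)


def outer_bound_element(
    samples: np.ndarray,
    side: int,
    boundary: SingularitySurrogate,
    t: float,
    space: ParameterSpace,
    n_scan: int = 10000,
    seed: int = 0,
) -> np.ndarray | None:
    """Hyper-rectangular outer bound of an element.

    Per-dimension min/max over the element's own samples and an MC scan of
    the membership test, expanded by 1% of each side and clipped to the
    support.  Returns ``None`` (empty-element marker) when nothing lands
    inside."""
    element = Element(side, t, boundary, None)
    pts = [np.atleast_2d(samples)[element.membership(samples)]] if samples is not None and len(samples) else []
    scan = space.sample(n_scan, np.random.default_rng(seed))
    pts.append(scan[element.membership(scan)])
    allpts = np.vstack([p for p in pts if p.size]) if any(p.size for p in pts) else np.empty((0, space.dimension))
    if allpts.shape[0] == 0:
        return None
    lo = allpts.min(axis=0)
    hi = allpts.max(axis=0)
    width = hi - lo
    lo = lo - BOX_MARGIN * width
    hi = hi + BOX_MARGIN * width
    slo, shi = space.lower, space.upper
    return np.column_stack([np.maximum(lo, slo), np.minimum(hi, shi)])


def _fit_local(space, box, Xs, Ys, p_range, q_list):
    local_space = _box_space(space, box)
    ed = ExperimentalDesign(Xs, Ys)
    return basis_adaptive_fit(local_space, ed, p_range=p_range, q_list=q_list)


def train_nspce(
    model: DFBAModel,
    space: ParameterSpace,
    response: str,
    t: float,
    boundary: SingularitySurrogate | None,
    cached_ed: ExperimentalDesign | None = None,
    eps_target: float = 1e-3,
    n_add: int = 10,
    n_max: int = 500,
    seed=None,
    p_range=range(1, 11),
    q_list=(0.75,),
    t_span=None,
    n_prob_mc: int = 100000,
    integrate_kwargs: dict | None = None,
) -> NsPCESurrogate:
    """Train a two-element nsPCE surrogate of ``response`` at time ``t``.

    The cached boundary-fitting trajectories are interpolated at ``t`` to
    initialize both local EDs for free; each unconverged element is then
    enriched with fresh full-model simulations, drawn from the global
    space and routed by the membership test, until its eps_LOO meets the
    target or the total simulation budget ``n_max`` is reached.
    """
    rng = np.random.default_rng(seed)
    ikw = dict(integrate_kwargs or {})
    span = t_span if t_span is not None else model.default_t_span
    qfun = response  # state id (callables allowed through interpolate_quantity)

    if cached_ed is None or not cached_ed.trajectories:
        raise ValueError("train_nspce needs the boundary's cached experimental design")

    X0 = cached_ed.X
    Y0 = np.array([float(interpolate_quantity(tr, t, qfun)) for tr in cached_ed.trajectories])
    n_sims = 0  # enrichment simulations beyond the reused cache

    # degenerate: t outside the boundary's singular range -> one global PCE
    if boundary is None or not (boundary.support_range[0] <= t <= boundary.support_range[1]):
        side_all = 1 if boundary is None or t < boundary.support_range[0] else 2
        pce, n_sims = _enrich_global(model, space, qfun, t, span, X0, Y0, eps_target,
                                     n_add, n_max, rng, p_range, q_list, ikw)
        el = Element(side_all, t, None, np.column_stack([space.lower, space.upper]))
        empty = Element(3 - side_all, t, None, None, empty=True)
        elements = (el, empty) if side_all == 1 else (empty, el)
        pces = (pce, None) if side_all == 1 else (None, pce)
        probs = (1.0, 0.0) if side_all == 1 else (0.0, 1.0)
        return NsPCESurrogate(t, str(response), boundary, elements, pces, probs,
                              meta={"n_simulations": n_sims, "degenerate": True})

    # probabilities Pr(X in S_k) by MC on the boundary surrogate
    Xp = space.sample(n_prob_mc, rng)
    frac1 = float(np.mean(boundary(Xp) > t))
    probs = (frac1, 1.0 - frac1)

    elements = []
    pces = []
    for side in (1, 2):
        el_probe = Element(side, t, boundary, None)
        mask = el_probe.membership(X0)
        box = outer_bound_element(X0[mask] if mask.any() else None, side, boundary, t, space,
                                  seed=int(rng.integers(2**31 - 1)))
        if box is None:
            if probs[side - 1] > 1e-3:
                raise RuntimeError(
                    f"element {side} is empty although its MC probability is {probs[side-1]:.3g}; "
                    "boundary and routing are inconsistent"
                )
            elements.append(Element(side, t, boundary, None, empty=True))
            pces.append(None)
            continue

        Xs = X0[mask]
        Ys = Y0[mask]
        pce = None
        while True:
            if Xs.shape[0] >= 3:
                pce = _fit_local(space, box, Xs, Ys, p_range, q_list)
                if pce.loo_error < eps_target:
                    break
            if n_sims >= n_max:
                break
            Xnew, Ynew, used = _enrich_element(model, el_probe, space, qfun, t, span,
                                               min(n_add, n_max - n_sims), rng, ikw)
            n_sims += used
            if Xnew.size:
                Xs = np.vstack([Xs, Xnew])
                Ys = np.concatenate([Ys, Ynew])
        if pce is None:
            raise RuntimeError(f"element {side}: not enough samples to fit a local surrogate")
        elements.append(Element(side, t, boundary, box))
        pces.append(pce)

    return NsPCESurrogate(t, str(response), boundary, tuple(elements), tuple(pces), probs,
                          meta={"n_simulations": n_sims})


def _enrich_element(model, element, space, qfun, t, span, n_want, rng, ikw):
    """Draw from S, keep points routed into the element, simulate them.

    Enrichment simulations only need the state up to the response time, so
    the integration span is truncated at ``t`` (exact, not an
    approximation: the response at ``t`` is independent of later dynamics).
    """
    span = (span[0], min(span[1], t))
    Xn, Yn = [], []
    used = 0
    attempts = 0
    while len(Xn) < n_want and attempts < MAX_OVERSAMPLE:
        batch = space.sample(max(n_want * 2, 8), rng)
        keep = batch[element.membership(batch)]
        attempts += 1
        for x in keep[: n_want - len(Xn)]:
            traj = integrate_dfba(model, x, span, **ikw)
            Xn.append(x)
            Yn.append(float(interpolate_quantity(traj, t, qfun)))
            used += 1
    if attempts >= MAX_OVERSAMPLE and not Xn:
        raise RuntimeError(
            f"element {element.side} rejection sampling exceeded {MAX_OVERSAMPLE}x oversampling; "
            "its probability is too small to enrich"
        )
    return np.array(Xn).reshape(-1, space.dimension), np.array(Yn), used


def _enrich_global(model, space, qfun, t, span, X0, Y0, eps_target, n_add, n_max, rng, p_range, q_list, ikw):
    span = (span[0], min(span[1], t))
    Xs, Ys = X0.copy(), Y0.copy()
    n_sims = 0
    while True:
        pce = basis_adaptive_fit(space, ExperimentalDesign(Xs, Ys), p_range=p_range, q_list=q_list)
        if pce.loo_error < eps_target or n_sims >= n_max:
            return pce, n_sims
        for x in space.sample(min(n_add, n_max - n_sims), rng):
            traj = integrate_dfba(model, x, span, **ikw)
            Xs = np.vstack([Xs, x])
            Ys = np.append(Ys, float(interpolate_quantity(traj, t, qfun)))
            n_sims += 1


def evaluate_nspce(surrogate: NsPCESurrogate, x: np.ndarray) -> np.ndarray:
    """Evaluate the piecewise surrogate; each point is routed through the
    boundary membership test to its element's local PCE.  Output order
    matches input order."""
    x2 = np.atleast_2d(np.asarray(x, dtype=float))
    out = np.empty(x2.shape[0])
    assigned = np.zeros(x2.shape[0], dtype=bool)
    for el, pce in zip(surrogate.elements, surrogate.local_pces):
        if el.empty:
            continue
        mask = el.membership(x2) & ~assigned
        if not mask.any():
            continue
        if pce is None:
            raise RuntimeError(f"element {el.side} has members but no local surrogate")
        if el.bounding_box is not None:
            inside = np.all((x2[mask] >= el.bounding_box[:, 0]) & (x2[mask] <= el.bounding_box[:, 1]), axis=1)
            if not inside.all():
                logger.warning("%d points outside element %d bounding box; extrapolating",
                               int((~inside).sum()), el.side)
        out[mask] = pce(x2[mask])
        assigned |= mask
    if not assigned.all():
        raise RuntimeError("some points were not routed to any element")
    return out[0] if np.asarray(x).ndim == 1 else out
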