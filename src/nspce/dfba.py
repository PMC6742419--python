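"""Dynamic flux balance analysis: stiff ODEs with an embedded lexicographic LP.

A DFBA model couples extracellular mass balances ``ds/dt = f(t, s, v(s))``
to a flux balance LP ``max h(v)`` subject to ``A v = 0`` and state-dependent
flux bounds.  Degeneracy of the LP solution is resolved by lexicographic
optimization: an ordered hierarchy of objectives, each re-optimized with all
previous optima fixed, yields a unique flux vector.

Integration proceeds piecewise: within each smooth segment an error-controlled
stiff integrator is used, with the LP solved at every right-hand-side
evaluation.  Events are recorded whenever

* a watched extracellular species crosses its depletion threshold (localized
  with the integrator's continuous event root finding),
* the active-set signature of the LP solution changes (localized by bisection
  on the dense segment solution), or
* the LP becomes infeasible.

If the level-1 LP is infeasible and the model declares a penalty state, the
LP is re-solved in a relaxed form whose minimal l1 bound violation ``gamma``
drives the penalty dynamics ``alpha' = gamma``; otherwise integration stops
at the infeasibility time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import linprog

logger = logging.getLogger(__name__)

__all__ = [
    "MetabolicNetwork",
    "ObjectiveHierarchy",
    "DFBAModel",
    "FluxSolution",
    "Trajectory",
    "Event",
    "solve_fba",
    "bounds_from_state",
    "integrate_dfba",
    "singularity_times",
    "interpolate_quantity",
]

ACT_TOL = 1e-7  #: bound counted as active within this tolerance
EVENT_TOL = 1e-6  #: signature-change localization tolerance (hr)
DEPLETION_TOL = 1e-6  #: default "consumed" threshold in model units
_BIG = 1e6  # box for otherwise-free fluxes in the relaxed (penalty) LP
_FALLBACK_LOG = None  # diagnostic hook


class UnboundedFBAError(RuntimeError):
    """The LP is unbounded at some hierarchy level."""


class IntegrationError(RuntimeError):
    def __init__(self, msg: str, last_time: float | None = None):
        super().__init__(msg)
        self.last_time = last_time


class _InfeasibleLP(Exception):
    def __init__(self, t: float):
        self.t = t


@dataclass(frozen=True)
class MetabolicNetwork:
    """Stoichiometric matrix, default flux bounds and bookkeeping labels."""

    stoichiometry: np.ndarray  # metabolites x reactions
    flux_lower: np.ndarray
    flux_upper: np.ndarray
    reaction_ids: tuple[str, ...]
    metabolite_ids: tuple[str, ...] = ()
    exchange_map: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        S = np.atleast_2d(np.asarray(self.stoichiometry, dtype=float))
        object.__setattr__(self, "stoichiometry", S)
        lb = np.asarray(self.flux_lower, dtype=float).ravel()
        ub = np.asarray(self.flux_upper, dtype=float).ravel()
        object.__setattr__(self, "flux_lower", lb)
        object.__setattr__(self, "flux_upper", ub)
        n = S.shape[1]
        if lb.size != n or ub.size != n or len(self.reaction_ids) != n:
            raise ValueError("bound vectors / reaction ids inconsistent with stoichiometry")
        if self.metabolite_ids and len(self.metabolite_ids) != S.shape[0]:
            raise ValueError("metabolite ids inconsistent with stoichiometry")
        if np.any(lb > ub):
            raise ValueError("flux_lower > flux_upper")
        for name, j in self.exchange_map.items():
            if not 0 <= j < n:
                raise ValueError(f"exchange {name!r} maps to invalid reaction index {j}")

    @property
    def n_reactions(self) -> int:
        return self.stoichiometry.shape[1]


@dataclass(frozen=True)
class ObjectiveHierarchy:
    """Ordered (weights, sense) pairs; the first entry is the cellular
    objective, later entries resolve LP degeneracy."""

    levels: tuple[tuple[np.ndarray, str], ...]

    def __post_init__(self) -> None:
        if not self.levels:
            raise ValueError("objective hierarchy may not be empty")
        lv = []
        for w, sense in self.levels:
            if sense not in ("max", "min"):
                raise ValueError("sense must be 'max' or 'min'")
            lv.append((np.asarray(w, dtype=float).ravel(), sense))
        object.__setattr__(self, "levels", tuple(lv))

    @classmethod
    def from_reactions(cls, network: MetabolicNetwork, spec: list[tuple[str, str]]) -> "ObjectiveHierarchy":
        """Build from (reaction_id, sense) pairs."""
        levels = []
        for rid, sense in spec:
            w = np.zeros(network.n_reactions)
            w[network.reaction_ids.index(rid)] = 1.0
            levels.append((w, sense))
        return cls(tuple(levels))

    def __len__(self) -> int:
        return len(self.levels)


@dataclass
class FluxSolution:
    fluxes: np.ndarray
    objective_values: tuple[float, ...]
    active_set_signature: tuple
    feasible: bool
    penalty: float = 0.0


def _signature(fluxes: np.ndarray, lb: np.ndarray, ub: np.ndarray, penalized: bool) -> tuple:
    # collapsed bound intervals are canonicalized as 'F' (fixed) so the
    # signature does not flap between L- and U-tight as an interval closes
    with np.errstate(invalid="ignore"):
        collapsed = np.isfinite(ub - lb) & ((ub - lb) <= ACT_TOL * (1.0 + np.abs(ub)))
        tight_lo = np.isfinite(lb) & (np.abs(fluxes - lb) <= ACT_TOL * (1.0 + np.abs(lb))) & ~collapsed
        tight_up = np.isfinite(ub) & (np.abs(fluxes - ub) <= ACT_TOL * (1.0 + np.abs(ub))) & ~collapsed
    sig = [("F", int(j)) for j in np.nonzero(collapsed)[0]]
    sig += [("L", int(j)) for j in np.nonzero(tight_lo)[0]]
    sig += [("U", int(j)) for j in np.nonzero(tight_up)[0]]
    if penalized:
        sig.append(("PEN", -1))
    return tuple(sorted(sig))


def solve_fba(
    network: MetabolicNetwork,
    objectives: ObjectiveHierarchy,
    flux_lower: np.ndarray | None = None,
    flux_upper: np.ndarray | None = None,
    *,
    relaxed: bool = False,
) -> FluxSolution:
    """Lexicographic FBA solve at fixed (state-folded) flux bounds.

    Level 1 is solved first; each subsequent level re-optimizes with all
    previous objective values fixed (within a relative tolerance).  An
    infeasible level-1 LP returns ``feasible=False`` rather than raising,
    because the integrator uses that signal; with ``relaxed=True`` the
    bounds get l1 slack variables whose minimal total violation is the
    penalty value ``gamma`` (the DFBAlab-style feasibility objective).
    """
    lb = network.flux_lower if flux_lower is None else np.asarray(flux_lower, dtype=float)
    ub = network.flux_upper if flux_upper is None else np.asarray(flux_upper, dtype=float)
    S = network.stoichiometry
    m, n = S.shape

    if not relaxed:
        sol = _lex_solve(S, lb, ub, objectives.levels)
        if sol is None:
            return FluxSolution(np.full(n, np.nan), (), (), feasible=False)
        fluxes, vals = sol
        return FluxSolution(fluxes, tuple(vals), _signature(fluxes, lb, ub, False), True)

    # Relaxed solve: minimize total l1 bound violation first.  Demand-type
    # constraints (finite positive lower bounds, e.g. ATP maintenance) are
    # relaxed first — irreversibility (lb = 0) and kinetic uptake caps are
    # structural and stay hard; only if that is still infeasible does every
    # finite bound get a slack.
    slack_lo = np.nonzero(np.isfinite(lb) & (lb > 0))[0]
    sol = _relaxed_solve(S, lb, ub, objectives, slack_lo, np.array([], dtype=int))
    if sol is None:
        slack_lo = np.nonzero(np.isfinite(lb))[0]
        slack_up = np.nonzero(np.isfinite(ub))[0]
        sol = _relaxed_solve(S, lb, ub, objectives, slack_lo, slack_up)
    if sol is None:  # pragma: no cover - full relaxation is always feasible
        return FluxSolution(np.full(n, np.nan), (), (), feasible=False)
    return sol


def _relaxed_solve(S, lb, ub, objectives, slack_lo, slack_up) -> FluxSolution | None:
    """l1 bound-violation relaxation with slack on the listed bound rows."""
    m, nv = S.shape
    ns = slack_lo.size + slack_up.size
    A_eq = np.hstack([S, np.zeros((m, ns))]) if m else None
    b_eq = np.zeros(m) if m else None
    A_lo = np.zeros((slack_lo.size, nv + ns))  # -v_j - s_k <= -lb_j
    for k, j in enumerate(slack_lo):
        A_lo[k, j] = -1.0
        A_lo[k, nv + k] = -1.0
    A_up = np.zeros((slack_up.size, nv + ns))  # v_j - s_k <= ub_j
    for k, j in enumerate(slack_up):
        A_up[k, j] = 1.0
        A_up[k, nv + slack_lo.size + k] = -1.0
    # bounds with a slack row become free in the box; others stay hard
    vlo = np.where(np.isin(np.arange(nv), slack_lo), -_BIG, np.maximum(lb, -_BIG))
    vhi = np.where(np.isin(np.arange(nv), slack_up), _BIG, np.minimum(ub, _BIG))
    bounds = list(zip(vlo, vhi)) + [(0, None)] * ns

    c_pen = np.concatenate([np.zeros(nv), np.ones(ns)])
    levels = [(c_pen, "min")] + [(np.concatenate([w, np.zeros(ns)]), s) for w, s in objectives.levels]
    sol = _lex_solve(None, None, None, levels, A_eq=A_eq, b_eq=b_eq,
                     A_ub=[A_lo, A_up] if ns else None,
                     b_ub=[-lb[slack_lo], ub[slack_up]] if ns else None,
                     var_bounds=bounds)
    if sol is None:
        return None
    xfull, vals = sol
    fluxes = xfull[:nv]
    gamma = max(float(vals[0]), 0.0)
    return FluxSolution(fluxes, tuple(vals[1:]), _signature(fluxes, lb, ub, gamma > ACT_TOL), True, penalty=gamma)


def _linprog(c, A_ub, b_ub, A_eq, b_eq, bounds):
    """linprog with a presolve-off retry: HiGHS presolve can misreport
    infeasibility when kinetic bounds shrink below its tolerances."""
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    if res.status == 2:
        res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds,
                      method="highs", options={"presolve": False})
    return res


def _lex_solve(S, lb, ub, levels, *, A_eq=None, b_eq=None, A_ub=None, b_ub=None, var_bounds=None):
    """Shared lexicographic loop; returns (x, per-level values) or None."""
    if var_bounds is None:
        var_bounds = list(zip(lb, ub))
        if S is not None and S.shape[0]:
            A_eq, b_eq = S, np.zeros(S.shape[0])
    rows = list(A_ub) if A_ub is not None else []
    rhs = list(b_ub) if b_ub is not None else []
    eq_rows: list[np.ndarray] = []
    eq_rhs: list[float] = []
    vals: list[float] = []
    x = None
    for k, (w, sense) in enumerate(levels):
        c = -w if sense == "max" else w
        Aub = np.vstack([np.atleast_2d(r) for r in rows]) if rows else None
        bub = np.concatenate([np.atleast_1d(r) for r in rhs]) if rows else None
        Aeq_k = A_eq
        beq_k = b_eq
        if eq_rows:
            extra = np.vstack(eq_rows)
            Aeq_k = extra if A_eq is None else np.vstack([A_eq, extra])
            beq_k = np.asarray(eq_rhs) if b_eq is None else np.concatenate([b_eq, eq_rhs])
        res = _linprog(c, Aub, bub, Aeq_k, beq_k, var_bounds)
        if res.status == 2 and k > 0 and eq_rows:
            # exact fixing of prior optima can be numerically infeasible;
            # retry with fix_tol inequality relaxations, escalating the
            # tolerance if accumulated solver error demands it
            senses_prior = [s for _w, s in levels[:k]]
            for tol_scale in (1e-7, 1e-5):
                rows_try = list(rows)
                rhs_try = list(rhs)
                for wr, vr, sr in zip(eq_rows, eq_rhs, senses_prior):
                    fix_tol = tol_scale * (1.0 + abs(vr))
                    if sr == "max":
                        rows_try.append(-wr)
                        rhs_try.append(-(vr - fix_tol))
                    else:
                        rows_try.append(wr)
                        rhs_try.append(vr + fix_tol)
                Aub = np.vstack([np.atleast_2d(r) for r in rows_try])
                bub = np.concatenate([np.atleast_1d(r) for r in rhs_try])
                res = _linprog(c, Aub, bub, A_eq, b_eq, var_bounds)
                if res.status != 2:
                    rows, rhs = rows_try, rhs_try
                    eq_rows, eq_rhs = [], []
                    break
        if res.status == 2:
            # either level 1 is infeasible, or the state sits so close to
            # the feasibility boundary that the solver's verdict flips
            # between hierarchy levels; both mean "infeasible" upstream
            return None
        if res.status == 3:
            raise UnboundedFBAError(f"LP unbounded at objective level {k + 1}")
        if res.status != 0:
            raise RuntimeError(f"LP solver failure at level {k + 1}: {res.message}")
        val = float(w @ res.x)
        vals.append(val)
        x = res.x
        eq_rows.append(w)
        eq_rhs.append(val)
    return x, vals


@dataclass
class DFBAModel:
    """A DFBA model: network + objective hierarchy + extracellular dynamics.

    ``initial_state(params)`` and ``uptake_kinetics(state, params)`` map the
    uncertain parameter vector into initial conditions and state-dependent
    exchange-flux bounds; ``extracellular_rhs(t, state, fluxes, params)``
    is the mass-balance right-hand side.  ``uptake_kinetics`` returns a dict
    ``{reaction_index: (lb, ub)}`` of bound overrides.
    """

    network: MetabolicNetwork
    objectives: ObjectiveHierarchy
    state_ids: tuple[str, ...]
    initial_state: Callable[[np.ndarray], np.ndarray]
    extracellular_rhs: Callable[[float, np.ndarray, np.ndarray, np.ndarray], np.ndarray]
    uptake_kinetics: Callable[[np.ndarray, np.ndarray], dict] | None = None
    param_names: tuple[str, ...] = ()
    penalty_index: int | None = None
    depletion_watch: dict[str, float] = field(default_factory=dict)
    closed_form: dict = field(default_factory=dict)
    default_t_span: tuple[float, float] = (0.0, 1.0)
    #: optional params -> MetabolicNetwork map for uncertain stoichiometry
    network_builder: Callable[[np.ndarray], MetabolicNetwork] | None = None

    def bind_network(self, params: np.ndarray) -> MetabolicNetwork:
        return self.network_builder(params) if self.network_builder is not None else self.network

    def __post_init__(self) -> None:
        s0 = np.asarray(self.initial_state(self.nominal_params()), dtype=float)
        if s0.size != len(self.state_ids):
            raise ValueError("initial_state length must equal state_ids length")
        if self.penalty_index is not None and abs(s0[self.penalty_index]) > 0:
            raise ValueError("penalty state must start at 0")

    def nominal_params(self) -> np.ndarray:
        return np.asarray(self.closed_form.get("nominal_params", np.zeros(max(len(self.param_names), 1))), dtype=float)


def bounds_from_state(model: DFBAModel, state: np.ndarray, params: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-reaction bounds at the given extracellular state.

    Evaluates the model's uptake kinetics (Michaelis-Menten / inhibition
    forms, clamped at zero where applicable) and overlays them on the
    network's default bounds; non-exchange bounds are unchanged.
    """
    state = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(state)):
        raise ValueError("state must be finite")
    net = model.bind_network(params)
    lb = net.flux_lower.copy()
    ub = net.flux_upper.copy()
    if model.uptake_kinetics is not None:
        for j, (lo, hi) in model.uptake_kinetics(state, params).items():
            lb[j], ub[j] = lo, hi
    if np.any(lb > ub + 1e-12):
        raise ValueError("kinetic bounds produced flux_lower > flux_upper")
    return lb, np.maximum(ub, lb)


@dataclass
class Event:
    time: float
    label: str
    signature_before: tuple
    signature_after: tuple


@dataclass
class Trajectory:
    """Event-annotated DFBA solution with a dense interpolant.

    States are held constant after the final feasible time (the biomass-
    constant assumption after full substrate depletion).
    """

    times: np.ndarray
    states: np.ndarray
    events: list[Event]
    state_ids: tuple[str, ...]
    pieces: list  # (t0, t1, OdeSolution)
    t_span: tuple[float, float]
    terminal_state: np.ndarray

    def interpolate(self, t) -> np.ndarray:
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.empty((t_arr.size, len(self.state_ids)))
        starts = np.array([p[0] for p in self.pieces])
        last_t1 = self.pieces[-1][1]
        for i, ti in enumerate(t_arr):
            if ti >= last_t1:
                out[i] = self.terminal_state
                continue
            if ti < self.t_span[0]:
                raise ValueError(f"time {ti} before trajectory start")
            k = int(np.searchsorted(starts, ti, side="right")) - 1
            k = max(k, 0)
            out[i] = self.pieces[k][2](ti)
        return out[0] if np.isscalar(t) or np.ndim(t) == 0 else out

    def quantity(self, t, quantity):
        s = self.interpolate(t)
        if callable(quantity):
            return quantity(s.T) if np.ndim(s) > 1 else quantity(s)
        try:
            j = self.state_ids.index(quantity)
        except ValueError as exc:
            raise KeyError(f"unknown quantity {quantity!r}") from exc
        return s[..., j]


def singularity_times(traj: Trajectory, labels) -> dict:
    """First occurrence time of each labeled event; ``None`` if absent."""
    out = {}
    for lab in labels:
        t = None
        for ev in traj.events:
            if ev.label == lab:
                t = ev.time
                break
        out[lab] = t
    return out


def interpolate_quantity(traj: Trajectory, t, quantity):
    """Dense-interpolant evaluation; terminal value beyond the final time."""
    return traj.quantity(t, quantity)


def integrate_dfba(
    model: DFBAModel,
    params: np.ndarray,
    t_span: tuple[float, float] | None = None,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
    event_tol: float = EVENT_TOL,
    max_events: int = 50,
) -> Trajectory:
    """Integrate a DFBA model, recording active-set and depletion events."""
    from scipy.integrate import solve_ivp

    params = np.asarray(params, dtype=float).ravel()
    t0, tf = t_span if t_span is not None else model.default_t_span
    s = np.asarray(model.initial_state(params), dtype=float).copy()
    nstate = s.size
    pen = model.penalty_index
    has_penalty = pen is not None
    watch = {model.state_ids.index(k): v for k, v in model.depletion_watch.items()}

    net = model.bind_network(params)
    S = net.stoichiometry
    nrx = net.n_reactions
    current_sig: list[tuple | None] = [None]  # segment's active set for the fast path

    memo: list = [None]  # (lb, ub, FluxSolution) of the last full solve

    def flux_full(t, state):
        lb, ub = bounds_from_state(model, state, params)
        if memo[0] is not None:
            lb0, ub0, sol0 = memo[0]
            scale = 1.0 + np.abs(lb0) + np.abs(ub0)
            with np.errstate(invalid="ignore"):
                same = np.all(np.abs(lb - lb0) <= 1e-12 * scale) and np.all(
                    (np.abs(ub - ub0) <= 1e-12 * scale) | (np.isinf(ub) & np.isinf(ub0))
                )
            if same:
                return sol0
        # once the penalty is active the plain LP stays infeasible for the
        # rest of the batch; skip straight to the relaxed solve then
        pen_mode = current_sig[0] is not None and any(c[0] == "PEN" for c in current_sig[0])
        sol = None
        if not pen_mode:
            sol = solve_fba(net, model.objectives, lb, ub)
        if sol is None or not sol.feasible:
            if has_penalty:
                sol = solve_fba(net, model.objectives, lb, ub, relaxed=True)
            else:
                raise _InfeasibleLP(float(t))
        memo[0] = (lb, ub, sol)
        return sol

    def flux_at(t, state):
        # Within a smooth segment the LP's active set is fixed, so the flux
        # solution follows from the tight-constraint linear system at the
        # current bounds — orders of magnitude cheaper than the LP.  The
        # result is accepted only if it is square/consistent and feasible;
        # any failure (or penalty mode) falls back to the full solve.
        sig = current_sig[0]
        if sig:
            penalized = any(c[0] == "PEN" for c in sig)
            lb, ub = bounds_from_state(model, state, params)
            tight = [c for c in sig if c[0] != "PEN"]
            bnd = np.zeros((len(tight), nrx))
            bval = np.empty(len(tight))
            ok = True
            for k, (kind, j) in enumerate(tight):
                bnd[k, j] = 1.0
                if kind == "L":
                    bval[k] = lb[j]
                elif kind == "U":
                    bval[k] = ub[j]
                else:  # 'F': collapsed interval
                    bval[k] = 0.5 * (lb[j] + ub[j])
                if not np.isfinite(bval[k]):
                    ok = False
                    break
            if ok:
                A = np.vstack([S, bnd]) if S.shape[0] else bnd
                b = np.concatenate([np.zeros(S.shape[0]), bval])
                v, _res, rank, _sv = np.linalg.lstsq(A, b, rcond=None)
                tol_lo = 10 * ACT_TOL * (1 + np.abs(lb))
                tol_up = 10 * ACT_TOL * (1 + np.abs(ub))
                if penalized:
                    # demand (lb > 0) bounds carry the l1 slack in penalty
                    # mode; every other bound must still hold
                    lo_ok = np.all((v >= lb - tol_lo) | (lb > 0))
                else:
                    lo_ok = np.all(v >= lb - tol_lo)
                if (
                    rank == nrx
                    and np.max(np.abs(A @ v - b)) < 1e-7 * (1 + np.max(np.abs(b)))
                    and lo_ok
                    and np.all(v <= ub + tol_up)
                ):
                    gamma = float(np.sum(np.maximum(lb - v, 0.0)[np.isfinite(lb) & (lb > 0)])) if penalized else 0.0
                    # recompute the signature from the solution: for pure
                    # bound motion an optimal basis stays optimal while
                    # primal feasible, so this is the true active set
                    return FluxSolution(v, (), _signature(v, lb, ub, penalized and gamma > ACT_TOL),
                                        True, penalty=gamma)
        return flux_full(t, state)

    def rhs(t, state):
        fs = flux_at(t, state)
        ds = np.asarray(model.extracellular_rhs(t, state, fs.fluxes, params), dtype=float)
        if has_penalty:
            ds[pen] = fs.penalty
        if not np.all(np.isfinite(ds)):
            raise IntegrationError(f"non-finite right-hand side at t={t}", last_time=t)
        return ds

    def sig_at(t, state):
        return flux_at(t, state).active_set_signature

    pieces, events, depleted = [], [], set()
    t = float(t0)
    sig = None
    try:
        sig = sig_at(t, s)
    except _InfeasibleLP:
        raise IntegrationError("LP infeasible at the initial state", last_time=t)

    while t < tf - 1e-12 and len(events) < max_events:
        ev_funcs = []
        ev_idx = []
        for j, thr in watch.items():
            if j in depleted:
                continue

            def make(jj, th):
                f = lambda tt, ss: ss[jj] - th  # noqa: E731
                f.terminal = True
                f.direction = -1.0
                return f

            ev_funcs.append(make(j, thr))
            ev_idx.append(j)

        seg_end = tf
        current_sig[0] = sig
        try:
            sol = solve_ivp(rhs, (t, seg_end), s, method=method, rtol=rtol, atol=atol,
                            dense_output=True, events=ev_funcs)
            fail_t = None
        except _InfeasibleLP as exc:
            # retry on a shrunken window ending just before the infeasibility
            fail_t = exc.t
            ok = None
            hi = fail_t
            for _ in range(60):
                target = max(t + 1e-12, hi - max(event_tol, 1e-9 * (1 + abs(hi))))
                if target <= t:
                    break
                try:
                    ok = solve_ivp(rhs, (t, target), s, method=method, rtol=rtol, atol=atol,
                                   dense_output=True, events=ev_funcs)
                    break
                except _InfeasibleLP as exc2:
                    hi = exc2.t
            if ok is None:
                raise IntegrationError("LP infeasible immediately; cannot advance", last_time=t)
            sol = ok

        if sol.status == -1:
            raise IntegrationError(f"integration failure: {sol.message}", last_time=float(sol.t[-1]))

        # localize any active-set signature change among accepted nodes;
        # once the penalty is active further active-set shuffling inside the
        # relaxed LP is not a modeled singularity, so it is not tracked
        pen_active = any(c[0] == "PEN" for c in sig)
        nodes = sol.t
        sig_nodes = [sig]
        change_at = None
        if not pen_active:
            for i in range(1, len(nodes)):
                si = sig_at(nodes[i], sol.sol(nodes[i]))
                sig_nodes.append(si)
                if si != sig_nodes[i - 1]:
                    change_at = (nodes[i - 1], nodes[i], si)
                    break

        ev_time = None
        ev_label = None
        ev_state_idx = None
        if sol.status == 1:  # depletion event terminated the segment
            which = [k for k, te in enumerate(sol.t_events) if te.size]
            k = min(which, key=lambda kk: sol.t_events[kk][0])
            ev_time = float(sol.t_events[k][0])
            ev_state_idx = ev_idx[k]
            ev_label = f"depletion:{model.state_ids[ev_state_idx]}"

        if change_at is not None and (ev_time is None or change_at[1] < ev_time):
            lo, hi, sig_hi = change_at
            # bisection on the discrete signature to event_tol
            while hi - lo > event_tol:
                mid = 0.5 * (lo + hi)
                try:
                    smid = sig_at(mid, sol.sol(mid))
                except _InfeasibleLP:
                    smid = ("INFEASIBLE",)
                if smid == sig:
                    lo = mid
                else:
                    hi = mid
                    sig_hi = smid
            ev_time = float(hi)
            pen_on = any(c[0] == "PEN" for c in sig_hi) and not any(c[0] == "PEN" for c in sig)
            ev_label = "penalty_on" if pen_on else "active_set_change"
            ev_state_idx = None
        elif ev_time is not None:
            pass
        else:
            ev_time = float(sol.t[-1])

        t1 = ev_time
        if t1 > t + 1e-13:
            pieces.append((t, t1, sol.sol))
        s_new = np.asarray(sol.sol(t1), dtype=float).copy()

        if ev_label is not None:
            if ev_state_idx is not None:
                s_new[ev_state_idx] = watch[ev_state_idx]  # clamp exactly at threshold
                depleted.add(ev_state_idx)
            try:
                new_sig = sig_at(t1, s_new)
            except _InfeasibleLP:
                events.append(Event(t1, ev_label, sig, ("INFEASIBLE",)))
                events.append(Event(t1, "infeasible", sig, ("INFEASIBLE",)))
                t, s = t1, s_new
                break
            events.append(Event(t1, ev_label, sig, new_sig))
            sig = new_sig
            t, s = t1, s_new
            if fail_t is not None and ev_label != "penalty_on":
                # the shrink-retry ended because of infeasibility ahead
                try:
                    sig_at(t + event_tol, s)
                except _InfeasibleLP:
                    events.append(Event(t, "infeasible", sig, ("INFEASIBLE",)))
                    break
            continue

        t, s = t1, s_new
        if fail_t is not None:
            events.append(Event(t, "infeasible", sig, ("INFEASIBLE",)))
            break

    if not pieces:
        # degenerate zero-length trajectory: constant piece
        const = _ConstInterp(s)
        pieces = [(t0, max(t, t0 + 1e-12), const)]

    traj = _assemble(pieces, events, model.state_ids, (t0, tf))
    return traj


class _ConstInterp:
    def __init__(self, s):
        self.s = np.asarray(s, dtype=float)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        if t.ndim == 0:
            return self.s.copy()
        return np.tile(self.s[:, None], (1, t.size))


def _assemble(pieces, events, state_ids, t_span) -> Trajectory:
    times = []
    for (p0, p1, interp) in pieces:
        seg = np.asarray(getattr(interp, "ts", np.linspace(p0, p1, 5)), dtype=float)
        seg = seg[(seg >= p0 - 1e-15) & (seg <= p1 + 1e-15)]
        times.extend([p0, *seg.tolist(), p1])
    times = np.unique(np.asarray(times, dtype=float))
    last_t1 = pieces[-1][1]
    terminal = np.asarray(pieces[-1][2](last_t1), dtype=float)
    traj = Trajectory(
        times=times,
        states=np.empty((0, len(state_ids))),
        events=sorted(events, key=lambda e: e.time),
        state_ids=tuple(state_ids),
        pieces=pieces,
        t_span=t_span,
        terminal_state=terminal,
    )
    traj.states = traj.interpolate(times)
    return traj
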