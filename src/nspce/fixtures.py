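"""Built-in desk-scale DFBA models and a synthetic-data generator.

Three model families are bundled so every other module is testable without
external downloads:

* :func:`make_toy_model` — a scalar non-smooth ODE with an embedded
  one-reaction LP.  The state decays at rate ``x`` while positive and then
  sticks at zero, so the closed form ``y(t, x) = max(y0 - t x, 0)`` and the
  singularity time ``t_s(x) = y0 / x`` are known exactly and serve as
  oracles.
* :func:`make_synthetic_network` — an 8-reaction, 20-parameter synthetic
  metabolic network consuming carbon C, nitrogen N and oxygen O to produce
  biomass X, lipids L, ethanol E, an oxidation product COX and maintenance
  ATP, with a penalty state ``alpha`` that grows once the embedded LP turns
  infeasible.  Stoichiometric values, objective hierarchy and parameter
  bounds are package defaults chosen so that the network reproduces four
  qualitative behaviors of living cultures: ethanol is only produced in the
  absence of O; lipids only accumulate in the absence of N; a minimum ATP
  maintenance demand is always met while feasible; and aerobic oxidation of
  C yields more ATP per carbon than fermentation.
* :func:`make_ecoli_model` — the extracellular structure of aerobic batch
  growth on a glucose/xylose mixture (biomass/glucose/xylose mass balances
  with Michaelis-Menten uptake and glucose inhibition of xylose uptake),
  coupled either to a user-supplied constraint-based network exposing
  glucose/xylose/oxygen exchange hooks or to a small synthetic stand-in
  network bundled here.
"""

from __future__ import annotations

import numpy as np

from .dfba import DFBAModel, MetabolicNetwork, ObjectiveHierarchy, integrate_dfba, interpolate_quantity
from .space import Marginal, ParameterSpace, uniform_box
from .uq import Dataset, NoiseModel

__all__ = [
    "make_toy_model",
    "make_synthetic_network",
    "make_ecoli_model",
    "standin_ecoli_network",
    "generate_dataset",
    "SYNTHETIC_PARAM_NAMES",
    "ECOLI_PARAM_NAMES",
    "ECOLI_NOMINALS",
    "ECOLI_MEASUREMENT_TIMES",
]


# --------------------------------------------------------------------------
# Toy non-smooth model
# --------------------------------------------------------------------------

def make_toy_model(y0: float = 1.0, x_bounds: tuple[float, float] = (1.0, 4.0)) -> tuple[DFBAModel, ParameterSpace]:
    """Scalar non-smooth decay model with closed-form solution.

    dy/dt = -x while y > 0 and 0 afterwards, rendered as a genuine DFBA
    model: a single consumption reaction v with upper bound x while the
    resource y is present, cellular objective "maximize v", dy/dt = -v.
    """
    if y0 <= 0:
        raise ValueError("y0 must be positive")
    network = MetabolicNetwork(
        stoichiometry=np.zeros((0, 1)),
        flux_lower=np.array([0.0]),
        flux_upper=np.array([np.inf]),
        reaction_ids=("consume",),
        metabolite_ids=(),
        exchange_map={"y": 0},
    )
    objectives = ObjectiveHierarchy(((np.array([1.0]), "max"),))

    def kinetics(state, params):
        x = float(params[0])
        if x < 0:
            raise ValueError("decay rate parameter must be nonnegative")
        ub = x if state[0] > 0.0 else 0.0
        return {0: (0.0, ub)}

    model = DFBAModel(
        network=network,
        objectives=objectives,
        state_ids=("y",),
        initial_state=lambda params: np.array([y0]),
        extracellular_rhs=lambda t, s, v, params: np.array([-v[0]]),
        uptake_kinetics=kinetics,
        param_names=("x",),
        depletion_watch={"y": 0.0},
        closed_form={
            "solution": lambda t, x: np.maximum(y0 - np.asarray(t) * np.asarray(x), 0.0),
            "singularity_time": lambda x: y0 / np.asarray(x),
            "nominal_params": np.array([0.5 * (x_bounds[0] + x_bounds[1])]),
        },
        default_t_span=(0.0, 1.0),
    )
    space = uniform_box([x_bounds], names=("x",))
    return model, space


# --------------------------------------------------------------------------
# Synthetic metabolic network (20 uncertain parameters)
# --------------------------------------------------------------------------

SYNTHETIC_PARAM_NAMES = (
    "vmax_C", "K_C", "K_iE",
    "vmax_N", "K_N",
    "vmax_O", "K_O",
    "X0", "C0", "N0", "O0",
    "S_ATP_OX", "S_ATP_Ferm", "S_OX_OX", "S_OX_Ferm",
    "S_ATP_L", "S_C_X", "S_N_X", "S_ATP_X",
    "m_ATP",
)

#: package-default nominal values (documented defaults, see module docstring)
SYNTHETIC_NOMINALS = dict(
    vmax_C=1.0, K_C=0.05, K_iE=5.0,
    vmax_N=0.2, K_N=0.02,
    vmax_O=0.6, K_O=0.03,
    X0=0.1, C0=40.0, N0=1.5, O0=6.0,
    S_ATP_OX=2.0, S_ATP_Ferm=2.0, S_OX_OX=1.0, S_OX_Ferm=1.0,
    S_ATP_L=1.0, S_C_X=2.0, S_N_X=0.5, S_ATP_X=3.0,
    m_ATP=0.03,
)

_SYN_STATES = ("X", "C", "N", "O", "L", "E", "COX", "alpha")
_SYN_RXNS = ("vC", "vN", "vO", "vOX", "vFerm", "vL", "vX", "vATP")


def synthetic_prior_space(rel_width: float = 0.10) -> ParameterSpace:
    """20-D uniform box, +/- ``rel_width`` around the nominal values."""
    bounds = []
    for name in SYNTHETIC_PARAM_NAMES:
        v = SYNTHETIC_NOMINALS[name]
        bounds.append((v * (1 - rel_width), v * (1 + rel_width)))
    return uniform_box(bounds, names=SYNTHETIC_PARAM_NAMES)


def _syn_p(params):
    return dict(zip(SYNTHETIC_PARAM_NAMES, np.asarray(params, dtype=float)))


def _syn_network(params) -> MetabolicNetwork:
    p = _syn_p(params)
    # intracellular steady-state metabolites: C, N, O, ATP
    # reactions: vC, vN, vO, vOX, vFerm, vL, vX, vATP
    S = np.array([
        # vC   vN   vO   vOX            vFerm  vL             vX               vATP
        [1.0, 0.0, 0.0, -1.0,          -4.0,  -4.0,          -p["S_C_X"],      0.0],   # C
        [0.0, 1.0, 0.0,  0.0,           0.0,   0.0,          -p["S_N_X"],      0.0],   # N
        [0.0, 0.0, 1.0, -1.0,           0.0,   0.0,           0.0,             0.0],   # O
        [0.0, 0.0, 0.0,  p["S_ATP_OX"], p["S_ATP_Ferm"], -p["S_ATP_L"], -p["S_ATP_X"], -1.0],  # ATP
    ])
    lb = np.zeros(8)
    ub = np.full(8, np.inf)
    lb[7] = p["m_ATP"]  # minimum ATP maintenance requirement
    return MetabolicNetwork(
        stoichiometry=S,
        flux_lower=lb,
        flux_upper=ub,
        reaction_ids=_SYN_RXNS,
        metabolite_ids=("C", "N", "O", "ATP"),
        exchange_map={"C": 0, "N": 1, "O": 2},
    )


def make_synthetic_network(params: np.ndarray | str = "prior") -> tuple[DFBAModel, ParameterSpace]:
    """Assemble the synthetic-network DFBA model and its 20-D prior box.

    The objective hierarchy (maximize growth; then maximize lipid
    production; then minimize C, N and O uptake) spans the LP degeneracy so
    all exchange fluxes are unique.  The penalty state ``alpha`` integrates
    the minimal l1 bound violation once maintenance can no longer be met.
    """
    space = synthetic_prior_space()
    nominal = np.array([SYNTHETIC_NOMINALS[n] for n in SYNTHETIC_PARAM_NAMES])
    pvec = nominal if isinstance(params, str) else np.asarray(params, dtype=float)
    if not isinstance(params, str) and not bool(space.contains(pvec)[0]):
        raise ValueError("parameter vector outside the prior bounds")

    network = _syn_network(nominal)  # placeholder; rebuilt per params below

    hierarchy = [("vX", "max"), ("vL", "max"), ("vC", "min"), ("vN", "min"), ("vO", "min")]
    objectives = ObjectiveHierarchy.from_reactions(network, hierarchy)

    def initial_state(par):
        p = _syn_p(par)
        return np.array([p["X0"], p["C0"], p["N0"], p["O0"], 0.0, 0.0, 0.0, 0.0])

    def kinetics(state, par):
        p = _syn_p(par)
        for k in ("K_C", "K_N", "K_O", "K_iE"):
            if p[k] < 0:
                raise ValueError(f"negative saturation constant {k}")
        X, C, N, O, L, E = state[0], state[1], state[2], state[3], state[4], state[5]
        vC = max(0.0, p["vmax_C"] * C / (p["K_C"] + C) / (1.0 + E / p["K_iE"]))
        vN = max(0.0, p["vmax_N"] * N / (p["K_N"] + N))
        vO = max(0.0, p["vmax_O"] * O / (p["K_O"] + O))
        return {0: (0.0, vC), 1: (0.0, vN), 2: (0.0, vO)}

    def rhs(t, s, v, par):
        p = _syn_p(par)
        X = s[0]
        return np.array([
            v[6] * X,                                  # biomass
            -v[0] * X,                                 # C
            -v[1] * X,                                 # N
            -v[2] * X,                                 # O
            v[5] * X,                                  # L
            v[4] * X,                                  # E (1 per vFerm)
            (p["S_OX_OX"] * v[3] + p["S_OX_Ferm"] * v[4]) * X,  # COX
            0.0,                                       # alpha, set by integrator
        ])

    model = DFBAModel(
        network=network,
        objectives=objectives,
        state_ids=_SYN_STATES,
        initial_state=initial_state,
        extracellular_rhs=rhs,
        uptake_kinetics=kinetics,
        param_names=SYNTHETIC_PARAM_NAMES,
        penalty_index=_SYN_STATES.index("alpha"),
        depletion_watch={"C": 1e-6, "N": 1e-6, "O": 1e-6},
        closed_form={"nominal_params": pvec},
        default_t_span=(0.0, 40.0),
        network_builder=_syn_network,
    )
    return model, space


# --------------------------------------------------------------------------
# E. coli batch fermentation (extracellular structure)
# --------------------------------------------------------------------------

ECOLI_PARAM_NAMES = ("u_g_max", "K_g", "u_z_max", "K_z", "K_ig", "u_o")

#: nominal literature-style values (mmol/gDW/h and g/L); the lumped u_o
#: replaces u_o,max * o / (K_o + o) at the fixed oxygen level
ECOLI_NOMINALS = dict(u_g_max=10.5, K_g=0.0027, u_z_max=6.0, K_z=0.0165, K_ig=0.005, u_o=15.0)

ECOLI_MEASUREMENT_TIMES = (5.5, 6.0, 6.5, 7.0, 7.25, 8.0, 8.25, 8.5)

_MW_GLC = 0.18016  # g/mmol
_MW_XYL = 0.15013

ECOLI_INITIAL = dict(b=0.03, g=15.5, z=8.0)  # g/L
ECOLI_OXYGEN = 0.24  # mmol/L, held constant


def standin_ecoli_network() -> MetabolicNetwork:
    """Small synthetic stand-in for a genome-scale network.

    Exposes the three exchange hooks (v_g_ext, v_z_ext, v_o_ext) plus
    growth and overflow reactions; yields are chosen to give plausible
    diauxic time scales, not to represent iJR904.
    """
    # metabolites: G, Z, O2 (intracellular); reactions:
    # 0 v_g_ext: -> G, 1 v_z_ext: -> Z, 2 v_o_ext: -> O2,
    # 3 grow_g: G + 2 O2 -> biomass, 4 grow_z: Z + 2 O2 -> biomass,
    # 5 waste_g: G ->, 6 waste_z: Z ->, 7 waste_o: O2 ->
    S = np.array([
        [1.0, 0.0, 0.0, -1.0, 0.0, -1.0, 0.0, 0.0],   # G
        [0.0, 1.0, 0.0, 0.0, -1.0, 0.0, -1.0, 0.0],   # Z
        [0.0, 0.0, 1.0, -2.0, -2.0, 0.0, 0.0, -1.0],  # O2
    ])
    return MetabolicNetwork(
        stoichiometry=S,
        flux_lower=np.zeros(8),
        flux_upper=np.full(8, np.inf),
        reaction_ids=("v_g_ext", "v_z_ext", "v_o_ext", "grow_g", "grow_z", "waste_g", "waste_z", "waste_o"),
        metabolite_ids=("G", "Z", "O2"),
        exchange_map={"glucose": 0, "xylose": 1, "oxygen": 2},
    )


#: biomass yields of the stand-in network (g biomass per mmol substrate)
_STANDIN_YIELDS = (0.09, 0.05)


def make_ecoli_model(network_source: MetabolicNetwork | None = None,
                     growth_weights: np.ndarray | None = None) -> tuple[DFBAModel, ParameterSpace]:
    """Couple the batch glucose/xylose extracellular model to a network.

    ``network_source`` must expose exchange hooks named glucose/xylose/
    oxygen in its ``exchange_map``; the bundled synthetic stand-in is used
    when none is supplied.  The uptake rates computed from the Michaelis-
    Menten kinetics are imposed on the exchange fluxes as equality bounds,
    and the first objective level maximizes growth.  The prior is the 6-D
    uniform box of +/-10% around the nominal kinetic parameters.
    """
    net = network_source if network_source is not None else standin_ecoli_network()
    for hook in ("glucose", "xylose", "oxygen"):
        if hook not in net.exchange_map:
            raise ValueError(
                f"network is missing exchange hook {hook!r}; expected exchange_map "
                "entries for glucose, xylose and oxygen"
            )
    jg, jz, jo = (net.exchange_map[h] for h in ("glucose", "xylose", "oxygen"))

    if growth_weights is None:
        w = np.zeros(net.n_reactions)
        ids = net.reaction_ids
        if "grow_g" in ids and "grow_z" in ids:
            w[ids.index("grow_g")] = _STANDIN_YIELDS[0]
            w[ids.index("grow_z")] = _STANDIN_YIELDS[1]
        else:
            raise ValueError("growth_weights must be supplied for external networks")
    else:
        w = np.asarray(growth_weights, dtype=float)
    objectives = ObjectiveHierarchy((
        (w, "max"),
        # degeneracy resolution: prefer glucose-derived growth, then less waste
        (_unit(net.n_reactions, net.reaction_ids, "grow_g"), "max") if "grow_g" in net.reaction_ids else (w, "max"),
    ))

    def kinetics(state, par):
        ug_max, Kg, uz_max, Kz, Kig, uo = np.asarray(par, dtype=float)
        for k, v in (("K_g", Kg), ("K_z", Kz), ("K_ig", Kig)):
            if v < 0:
                raise ValueError(f"negative saturation constant {k}")
        g = max(state[1], 0.0)
        z = max(state[2], 0.0)
        ug = ug_max * g / (Kg + g)
        uz = uz_max * z / (Kz + z) / (1.0 + g / Kig)
        return {jg: (ug, ug), jz: (uz, uz), jo: (uo, uo)}

    def rhs(t, s, v, par):
        mu = float(w @ v)
        b = s[0]
        return np.array([mu * b, -_MW_GLC * v[jg] * b, -_MW_XYL * v[jz] * b])

    model = DFBAModel(
        network=net,
        objectives=objectives,
        state_ids=("b", "g", "z"),
        initial_state=lambda par: np.array([ECOLI_INITIAL["b"], ECOLI_INITIAL["g"], ECOLI_INITIAL["z"]]),
        extracellular_rhs=rhs,
        uptake_kinetics=kinetics,
        param_names=ECOLI_PARAM_NAMES,
        depletion_watch={"g": 1e-6, "z": 1e-6},
        closed_form={"nominal_params": np.array([ECOLI_NOMINALS[n] for n in ECOLI_PARAM_NAMES])},
        default_t_span=(0.0, 8.5),
    )
    bounds = [(v * 0.9, v * 1.1) for v in (ECOLI_NOMINALS[n] for n in ECOLI_PARAM_NAMES)]
    space = uniform_box(bounds, names=ECOLI_PARAM_NAMES)
    return model, space


def _unit(n, ids, rid):
    w = np.zeros(n)
    w[ids.index(rid)] = 1.0
    return w


# --------------------------------------------------------------------------
# Synthetic measurement generation
# --------------------------------------------------------------------------

def generate_dataset(
    model: DFBAModel,
    true_params: np.ndarray,
    times,
    quantities,
    noise: NoiseModel,
    seed: int | np.random.Generator | None = None,
    trajectory=None,
    **integrate_kwargs,
) -> Dataset:
    """Simulate at ``true_params`` and add state-proportional Gaussian noise.

    Each observation of quantity ``v`` at time ``t_i`` is
    ``d = v(t_i) + eps`` with ``eps ~ N(0, sigma^2)`` and
    ``sigma = max(relative_sd * |v(t_i)|, sd_floor)``.
    """
    rng = np.random.default_rng(seed)
    if trajectory is None:
        tf = max(times)
        t_span = (model.default_t_span[0], max(model.default_t_span[1], tf))
        trajectory = integrate_dfba(model, true_params, t_span, **integrate_kwargs)
    obs = []
    for q in quantities:
        for t in times:
            v = float(interpolate_quantity(trajectory, float(t), q))
            sigma = noise.sd(v)
            d = v + (rng.normal(0.0, sigma) if noise.relative_sd > 0 else 0.0)
            obs.append((q, float(t), d))
    return Dataset(observations=obs, provenance={"true_params": np.asarray(true_params, dtype=float).tolist(),
                                                 "relative_sd": noise.relative_sd})
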