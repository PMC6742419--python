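# nspce — non-smooth polynomial chaos surrogates for dynamic FBA

Dynamic flux balance analysis (DFBA) models couple extracellular mass
balances to an embedded flux balance linear program:

    ds/dt = f(t, s, v(s)),    v(s) ∈ argmax_v h(v)  s.t.  A v = 0,  v_LB(s) ≤ v ≤ v_UB(s).

They are expensive to simulate and, worse for uncertainty quantification,
*non-smooth* in their parameters: whenever a substrate runs out the LP's
active set switches, and the state trajectory loses differentiability at a
parameter-dependent **singularity time** `t_s(x)`.  Standard polynomial
chaos expansions (PCE) converge very slowly across such kinks.

This package implements the **non-smooth PCE (nsPCE)** surrogate method for
DFBA models, aimed at systems/computational biologists who need forward or
Bayesian UQ on models that are too slow for direct Monte Carlo.  The key
idea: the singularity time itself *is* a smooth function of the parameters,
so

1. fit a sparse PCE `t̂_s(x)` of the singularity time from full DFBA
   simulations;
2. for a response at time `t`, split the parameter support into
   `S1 = {x : t̂_s(x) > t}` and `S2 = {x : t̂_s(x) ≤ t}`;
3. fit separate sparse PCEs on hyper-rectangular outer bounds of each
   element, reusing the boundary-fitting trajectories to seed both local
   designs;
4. evaluate piecewise, routing each point through the same fitted boundary.

Sparse fitting uses hybrid least-angle regression with hyperbolic
truncation `{α : ‖α‖_q ≤ p}`, basis-adaptive degree selection by the
analytic leave-one-out error `ε_LOO`, and sequential experimental-design
enrichment to a target error.  On top of the surrogates the package
provides Sobol sensitivity indices (analytic from coefficients, or
Saltelli Monte Carlo for piecewise surrogates), forward propagation,
sequential Monte Carlo (SMC) posterior sampling with systematic
resampling, MAP estimation, and Laplace posterior approximation.

The DFBA simulator itself is included: lexicographic LP resolution (HiGHS)
for unique fluxes, error-controlled stiff integration with event
detection, depletion-event localization, and DFBAlab-style l1 penalty
dynamics once the LP turns infeasible.  Three model families are bundled:
a scalar non-smooth fixture with closed-form solution, a 20-parameter
synthetic metabolic network with a penalty state, and a glucose/xylose
batch fermentation structure that couples to any user-supplied
constraint-based network (SBML via cobrapy, or plain TSV).

## Worked example

```python
import numpy as np
from nspce.fixtures import make_toy_model
from nspce.surrogate import fit_singularity_surrogate, train_nspce, evaluate_nspce

# scalar non-smooth DFBA fixture: dy/dt = -x while y > 0, x ~ U[1, 4]
model, space = make_toy_model(y0=1.0)

# 1. surrogate of the singularity (depletion) time t_s = y0/x
boundary, design = fit_singularity_surrogate(
    model, space, "depletion:y", eps_target=1e-8, seed=11,
    n_init=20, n_add=10, n_max=120, p_range=range(1, 13))
print(f"boundary eps_LOO = {boundary.pce.loo_error:.2e} from N = {design.n} simulations")
print(f"singularity-time range over the prior: "
      f"[{boundary.support_range[0]:.3f}, {boundary.support_range[1]:.3f}] hr")

# 2. two-element surrogate of y at t = 0.5 (inside the singular range)
surrogate = train_nspce(model, space, "y", 0.5, boundary, cached_ed=design,
                        eps_target=1e-8, n_add=10, n_max=40, seed=5,
                        p_range=range(1, 5))
print(f"element probabilities: {surrogate.probabilities[0]:.3f} / "
      f"{surrogate.probabilities[1]:.3f}")

# 3. validation against the closed form y = max(1 - 0.5 x, 0)
Xv = space.sample(10000, 99)
exact = np.maximum(1.0 - 0.5 * Xv[:, 0], 0.0)
rmse = np.sqrt(np.mean((evaluate_nspce(surrogate, Xv) - exact) ** 2))
print(f"validation RMSE vs closed form: {rmse:.2e}")
```

Output:

```
boundary eps_LOO = 9.10e-10 from N = 30 simulations
singularity-time range over the prior: [0.250, 1.000] hr
element probabilities: 0.332 / 0.668
validation RMSE vs closed form: 7.30e-17
```

The boundary model needed 30 simulations to push its leave-one-out error
below 1e-8; its estimated range [0.25, 1.0] hr says the response is
non-smooth for any `t` in that window.  At `t = 0.5` about a third of the
prior mass has not yet hit the singularity (element 1).  Because the
response is piecewise linear and the boundary is accurate, the two-element
surrogate reproduces the closed form to rounding error — a single global
sparse PCE on the same simulation budget is stuck around 1e-2 RMSE.

A command-line pipeline wraps the same steps for batch use:

```bash
nspce simulate config.yaml          # trajectory + events CSV
nspce fit-boundary config.yaml      # singularity-time surrogate
nspce train-surrogates config.yaml  # nsPCE per (quantity, time) + manifest
nspce sobol / propagate / smc / map config.yaml
```

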