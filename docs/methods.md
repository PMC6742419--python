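# Methods

## The problem

Dynamic flux balance analysis (DFBA) couples the extracellular mass
balances of a microbial culture,

    ds/dt = f(t, s(t), v(s(t))),    s(0) = s0,

to an embedded flux balance linear program (LP) that allocates the
intracellular fluxes `v` at every instant:

    v(s) ∈ argmax_v h(v)   s.t.   A v = 0,   v_LB(s) ≤ v ≤ v_UB(s).

The flux bounds follow the extracellular state through uptake kinetics
(Michaelis–Menten saturation, product inhibition), so the LP's active set
switches as substrates run out.  At each such switch — the *singularity
time* `t_s(x)` — the state trajectory loses differentiability with
respect to the model parameters `x`.  Polynomial chaos expansions (PCE),
which approximate a random response `Y = M(X)` in polynomials orthonormal
to the parameter distribution, converge very slowly across such kinks.

## The nsPCE surrogate

The non-smooth PCE method exploits the observation that while the
*response* is non-smooth in `x`, the *singularity time itself* is smooth.
The procedure, per response quantity and time `t`:

1. **Boundary model.** Fit a sparse PCE `t̂_s(x)` of the singularity time
   from full DFBA simulations; estimate its range over the support by
   Monte Carlo on the surrogate.
2. **Partition.** If `t` lies inside that range, split the support into
   `S1 = {x : t̂_s(x) > t}` (singularity not yet occurred) and its
   complement `S2` (ties to `S2`).  Outside the range, one element is
   empty and the method reduces to a single global sparse PCE.
3. **Local fits.** Outer-bound each element with a hyper-rectangle
   (per-dimension extent of element samples and a 10⁴-point Monte Carlo
   scan of the membership test, padded by 1% per side and clipped to the
   support).  Fit an independent sparse PCE on each box using only
   samples whose membership test passes.  The trajectories stored while
   fitting the boundary are interpolated at `t` to initialize both local
   designs at zero extra simulation cost.
4. **Sequential enrichment.** While a local leave-one-out error exceeds
   the target, draw fresh parameters from the full support, route them by
   the membership test, simulate, and refit, up to a simulation budget.
5. **Evaluation.** Route each query point with the same fitted boundary
   and evaluate the corresponding local expansion.  Because fitting and
   evaluation use the *same* routing, the piecewise model is
   self-consistent even where `t̂_s` misclassifies; misclassification is
   tolerated, not corrected.

Multiple sequential singularities are supported when their Monte Carlo
ranges do not overlap (the boundary whose range contains `t` is used);
overlapping ranges would require more than two elements and raise a
`NotImplementedError`.

### Sparse regression machinery

* **Bases.** Orthonormal tensor products: normalized Legendre for uniform
  marginals (affinely mapped to `[-1, 1]`), normalized probabilists'
  Hermite for Gaussian marginals.  Local element bases are built on the
  bounding box treated as an independent uniform box (Gaussian marginals
  are kept unrestricted); the conditional-density mismatch is absorbed by
  regression rather than projection, which is what hyper-rectangular
  outer-bounding implies.
* **Truncation.** Hyperbolic index sets `{α : ‖α‖_q ≤ p}`, `0 < q ≤ 1`,
  with a `1e-10` slack so boundary indices are not lost to rounding;
  `q = 1` is total-degree truncation with `(M+p)!/(M!p!)` terms.
* **Hybrid least-angle regression.** One LAR pass over centered/scaled
  candidate columns provides the entry order; every path prefix is refit
  by ordinary least squares on the raw orthonormal columns and scored by
  the *corrected* leave-one-out error
  `ε·(1 − P/N)⁻¹(1 + tr((ΨᵀΨ)⁻¹))`, which penalizes prefixes approaching
  interpolation.  The plain relative LOO error (computed analytically
  from the hat-matrix diagonal) is what gets reported and compared to the
  target.  The constant term is always included.
* **Basis adaptivity.** The maximum degree sweeps a range (and optionally
  several `q` values); the sweep stops after 2 consecutive non-improving
  degrees and returns the minimum-LOO fit.
* **Sequential experimental design.** Initialize with `N_init` Monte Carlo
  samples, fit, stop when `ε_LOO` beats the target, otherwise add `N_add`
  fresh samples until `N_max`.  Failing simulations are skipped with a
  warning; more than 20% failures abort.
* **Degenerate responses.** Responses whose sample variance falls below
  `1e-12·(1 + mean²)` get a constant surrogate with `ε_LOO = 0` (e.g. a
  depleted substrate after its own singularity).

## The DFBA simulator

* **Lexicographic LP.** scipy's HiGHS interface solves each objective
  level; prior optima are fixed as equality constraints, falling back to
  inequality fixings with escalating tolerance (`1e-7`, `1e-5` relative)
  when exact fixing is numerically infeasible.  A level reported
  infeasible after fixing is treated as overall infeasibility: it occurs
  only when the state sits on the feasibility boundary, which is exactly
  the penalty-activation condition.  HiGHS presolve occasionally
  misreports infeasibility when kinetic bounds shrink below its
  tolerances, so every infeasible verdict is retried with presolve off.
* **Active-set signature.** The sorted set of bound constraints tight
  within `1e-7` (relative) at the lexicographic optimum; bound intervals
  collapsed to a width below that tolerance are canonicalized as "fixed"
  so the signature does not flap as an interval closes.
* **Events.** Depletion of watched species is localized by the ODE
  solver's continuous event root-finding (high precision, needed to meet
  the `1e-8` closed-form agreement on the scalar fixture); pure
  active-set changes, which have no continuous event function, are
  localized by bisection on the dense segment solution to `1e-6` hr.
  Integration restarts at each event; the depleted species is clamped to
  its threshold.
* **Fast path.** Within a smooth segment the active set is fixed, and for
  pure bound motion an optimal LP basis stays optimal while it remains
  primal feasible.  The flux solution therefore follows from the
  tight-constraint linear system at the current bounds, checked for
  squareness, consistency and feasibility at every right-hand-side
  evaluation; any failure falls back to the full LP.  This reduces the
  per-simulation cost by roughly an order of magnitude without changing
  the computed trajectories beyond solver tolerances.
* **Penalty mode.** When the LP turns infeasible and the model declares a
  penalty state `α`, the LP is re-solved with l1 slacks and `α' = γ`, the
  minimal total violation.  Slack is granted first to demand-type
  constraints only (finite *positive* lower bounds such as ATP
  maintenance); irreversibility (`lb = 0`) and kinetic uptake caps are
  structural and stay hard.  Only if that restricted relaxation is still
  infeasible does every finite bound receive a slack.  This choice keeps
  post-penalty trajectories physical (no reverse flux through
  irreversible reactions, no uptake of absent substrates) and preserves
  the monotonicity of products after the batch ends.  Active-set changes
  *inside* the relaxed LP after penalty activation are not modeled
  singularities and are not tracked as events.
* **Integrator.** `solve_ivp` (LSODA by default) with `rtol 1e-8`,
  `atol 1e-10` defaults.  The desk-scale studies of the synthetic network
  use `rtol 1e-4`, `atol 1e-6`, which reproduce the tight-tolerance
  responses to ~2·10⁻⁴ relative — two orders below the surrogate error
  targets — at less than half the cost.
* **Terminal behavior.** States are held constant after the final
  feasible time (cells cannot be predicted past full substrate depletion,
  so biomass and products are frozen); response interpolation past the
  span returns the terminal state.

## Built-in models

* **Scalar non-smooth fixture.** `dy/dt = −x` while `y > 0`, then 0,
  rendered as a genuine one-reaction DFBA model.  Closed forms
  `y(t,x) = max(y0 − tx, 0)` and `t_s = y0/x` are attached as oracles.
  Default prior: `x ~ U[1, 4]`, `y0 = 1`.
* **Synthetic metabolic network.** Eight unidirectional reactions (C, N,
  O uptake; aerobic oxidation; fermentation; lipid synthesis; growth; ATP
  maintenance) over four balanced intracellular metabolites, eight
  extracellular states `(X, C, N, O, L, E, COX, α)` and twenty uncertain
  parameters (7 kinetic, 4 initial conditions, 9 stoichiometric/demand)
  with ±10% uniform priors around package-default nominal values.  The
  nominals were chosen once so the culture reproduces four qualitative
  behaviors of living systems — ethanol only without oxygen, lipid
  accumulation only without nitrogen, a hard ATP maintenance demand, and
  a higher aerobic than fermentative ATP yield per carbon — and so the
  depletion order is N (~12.5 hr), O (~15.7 hr), C/penalty (~23 hr)
  within the 40 hr batch for every draw from the prior.  The objective
  hierarchy (max growth; max lipids; min C, N, O uptake) spans the LP
  degeneracy, making all exchange fluxes unique.
* **Glucose/xylose batch model.** Biomass/glucose/xylose mass balances
  with Michaelis–Menten uptake, glucose inhibition of xylose uptake, and
  a lumped oxygen uptake parameter `u_o` (oxygen is held constant, so its
  maximum rate and saturation constant are not separately identifiable).
  Nominal kinetic values follow the published batch-fermentation
  parameter set this configuration is standard for; the genome-scale
  network is deliberately not bundled — the loader couples the
  extracellular structure to any user-supplied constraint-based model
  exposing glucose/xylose/oxygen exchange hooks, and a small synthetic
  stand-in network with plausible diauxic yields is provided for tests.
  Initial conditions 0.03 / 15.5 / 8 g/L, oxygen 0.24 mmol/L, batch span
  8.5 hr, measurements of (b, g, z) at
  {5.5, 6.0, 6.5, 7.0, 7.25, 8.0, 8.25, 8.5} hr.
* **Synthetic data.** Observations are the simulated truth plus
  independent zero-mean Gaussian noise with state-proportional standard
  deviation `σ = relative_sd·|v(t_i)|` (default 5%), floored at `1e-8`
  model units so σ never vanishes at zero concentrations — the
  proportional rule alone is ill-posed there.  The likelihood uses the
  *model-predicted* magnitude in σ, so the Gaussian normalization term
  varies with the parameters and is always kept.

## Inference machinery

* **SMC.** Equal-weight prior particles; per measurement stage (default:
  one stage per time point), weights are multiplied by the stage
  likelihood evaluated through the surrogates, normalized in log space,
  and systematically resampled back to equal weights.  Resampling is
  unconditional, matching the algorithm as printed; an ESS-threshold
  option exists but is off by default.  ESS is recorded per stage.
* **MAP.** Negative log posterior minimized by adaptive Nelder–Mead from
  the prior mean (tolerant of the piecewise surrogate's kinks), iterates
  clipped to the surrogate support.  Uniform priors contribute a constant
  inside the support and +∞ outside; Gaussian priors a quadratic.
* **Laplace.** Covariance is the inverse of the central-difference
  Hessian at the MAP (per-dimension steps `1e-4`·prior sd), symmetrized;
  eigenvalues below `−1e-8`·trace raise (not a minimum), small negatives
  are clipped.
* **Sobol.** For a single expansion, indices come analytically from the
  coefficients (first-order: terms involving only `i`; total: terms
  involving `i`).  For piecewise surrogates those formulas only hold per
  element, so global indices use the Saltelli pick-freeze Monte Carlo
  estimator with reported standard errors.

## What the generator does and does not emulate

The synthetic datasets reproduce the additive, state-proportional,
independent Gaussian noise structure of batch concentration measurements
and the sparse time grids typical of such experiments.  They do not
emulate sensor bias, autocorrelated noise, missing values, or model
misspecification — the data-generating model is the same DFBA model being
calibrated.  Passing inference tests therefore demonstrates correctness
of the algorithms (posterior recovery, coverage, sensitivity rankings)
under a well-specified model, not robustness to the structural errors
real data carry.

## Desk-scale study sizes

The bundled studies are sized to run on a single CPU in minutes; these
are the package's own scaled-down choices:

* scalar fixture: boundary from ≤120 simulations (`ε_target 1e-8`);
  nsPCE-vs-global comparison at 20 total simulations; SMC coverage from
  100 repeated datasets at 4000 particles.
* synthetic network: boundary from ≤100 simulations (`ε_target 1e-3`,
  degrees 1–3, `q = 0.75`), seven response surrogates at one interior
  time point with ≤30 enrichment simulations each, 25 validation
  simulations; response times outside the singular range reuse the
  boundary design at zero extra cost.  At this budget the boundary and
  element-1 fits converge near their targets while the post-singularity
  element, whose responses are end-of-batch totals over 20 parameters,
  remains a factor of 10–100 above target; the nsPCE-vs-global ordering
  is preserved throughout.

## Known limitations

* Two elements only; overlapping singularity ranges are detected and
  rejected rather than refined further.
* Enrichment simulations are not shared across response quantities (the
  boundary design is shared; a cross-response working design would reduce
  cost further).
* Local bases ignore the exact conditional density on non-rectangular
  elements; regression absorbs the mismatch, but moment formulas for
  local expansions refer to the box density, which is why global moments
  and Sobol indices of piecewise surrogates are computed by Monte Carlo.
* The lexicographic hierarchy must be supplied by the user for external
  genome-scale models; no canonical hierarchy is bundled.
* Nelder–Mead MAP search is local; multistart is available but off by
  default.
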