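# Methods

## Model

Free thyroxine (FT4, pmol/l) under a constant daily anti-thyroid-drug dose
`d` (mg) is modelled by the Bernoulli ODE

    dy/dt = A * B(d) * y - C * y^2,    B(d) = ic50 / (ic50 + d).

The synthesis term is proportional to the current FT4 level (thyroid output
tracks the TSH-receptor drive, which itself depends on FT4), scaled down by
the Hill-type inhibition factor `B(d)`; decay is second order, reflecting
thyroxine's induction of its own catabolism (its half-life shortens in
hyperthyroidism and lengthens in hypothyroidism). The closed-form solution
in reciprocal form,

    1/y(t,d) = C*(ic50+d)/(A*ic50) + C1 * exp(-A*ic50*t/(ic50+d)),

is positive and strictly decreasing toward the steady state
`A*ic50/(C*(ic50+d))` exactly when `C1 < 0` and
`C*exp(A*B*t) + A*B*C1 > 0` at every point of interest.

**Overflow policy.** The direct exponential form of the solution produces
exponents of several hundred for routine clinical intervals (e.g. a
203-day follow-up gives ≈708, past the IEEE-double limit of ~709). Every
evaluation therefore routes through the reciprocal identity above, which is
algebraically identical but only ever exponentiates non-positive arguments.
The positivity conditions are likewise checked in log form. The direct form
is retained solely as a cross-check at safe exponents.

**Dose-change convention.** Predictions at visit `i` plug the cumulative
time `t_i` and the *latest* prescribed dose `d_{i-1}` into the single-dose
closed form. Trajectories are not integrated piecewise across dose changes;
this plug-in convention is what the estimator fits and what the what-if
solvers invert, so all components are mutually consistent. It is a modelling
simplification, kept deliberately.

**Units** are fixed: days, mg/day, pmol/l. Report tables round FT4 and dose
to one decimal and times to whole days; solvers never round internally.

## Estimation

Per patient, parameters minimize the mean squared deviation between
predicted and measured FT4 over follow-up visits (`i = 2..m`; visit 1
anchors the initial condition and is excluded from the objective):

    minimize (1/(m-1)) * sum_{i>=2} (f(t_i, d_{i-1}) - y_i)^2
    s.t.     A - y1*(C + A*C1) = 0            (initial condition)
             positivity at every (t_i, d_{i-1})
             A > 0, C > 0, C1 < 0, 0 < ic50 <= 150 mg.

Design choices, made once:

- **Exact elimination of C1.** The equality constraint is solved in closed
  form, `C1 = 1/y1 - C/A`, removing one decision variable rather than
  imposing the equality numerically. A useful consequence (provable in two
  lines from the reciprocal form): with `C1` so pinned and negative,
  `1/y(t,d) >= C/A + C1 = 1/y1 > 0` everywhere, so every per-visit
  positivity inequality holds automatically. The inequalities are still
  re-checked post hoc on every returned fit at tolerance 1e-6.
- **Log-space optimization.** The free variables are
  `(log A, log C, log ic50)`, making positivity structural and turning the
  `ic50` cap and the `C1 < 0` condition
  (`log C - log A >= log(1/y1 + eps)`) into box/linear constraints. The
  strictness margin is `eps = 1e-8` (configurable); the published
  formulation states strict inequalities without margins.
- **Solver.** scipy's SLSQP with 2-point finite-difference gradients
  (objective and constraints are smooth in log space; analytic gradients
  were not needed for 3 variables). Convergence = solver success AND finite
  objective AND post-hoc feasibility.
- **Multistart.** 16 random starts (A log-uniform on [1e-3, 1e2], C
  log-uniform on [1e-4, 10], ic50 uniform on (1, 150]; draws with pinned
  `C1 >= 0` are resampled) plus two data-driven heuristic starts placing
  the untreated steady state `A/C` just below the smallest observed FT4, in
  a slow (`A = 0.05`/day) and a fast (`A = 4`/day) equilibration regime.
  All randomness flows from one seed; fits are bit-reproducible.
- **Acceptance statistic.** "Average predicted FT4 within tolerance" is
  implemented as *mean absolute deviation* over follow-up visits <= 4.5
  pmol/l, boundary inclusive; `max_abs` and `rmse` are available as
  configurable alternatives since the phrase admits several readings.
- **Identifiability.** With fewer than two distinct nonzero doses only the
  lumped quantity `A*ic50/(ic50+d)` is constrained per dose level, so `A`
  and `ic50` are reported with a warning flag (as are fits with fewer
  residuals than free parameters). The objective surface generally has
  local optima; distinct parameter vectors can yield near-identical
  trajectories, so *predictions*, not parameter values, are the unit of
  validation throughout.

Non-convergence is an outcome, not an exception: the result carries
`converged=False` and counts against (never out of) a cohort denominator.

## What-if solvers

The fitted formula ties `(t, d, y)` together through `F(t,d,y) = y - y(t,d) = 0`.

- Unknown `y`: direct evaluation.
- Unknown `d`: a 129-point sign-change scan over `[0, dose_cap]` (default
  cap 60 mg/day, a prescribing ceiling, configurable) followed by Brent
  refinement to |Δd| <= 1e-3 mg. Monotonicity of `y` in `d` at fixed `t` is
  *not* assumed; if several roots exist the smallest dose is returned, the
  lowest effective dose being the titration goal. Targets outside the
  achievable FT4 range come back `infeasible` with that range attached.
- Unknown `t`: closed-form inversion of the reciprocal identity,
  `t = -(ic50+d)/(A*ic50) * ln[(1/y - C*(ic50+d)/(A*ic50))/C1]`, feasible
  exactly when the log argument is in (0, 1]; cross-validated against
  bisection in the tests to 1e-4 days. Times beyond the horizon (default
  730 days) are reported `at_bound` with the unconstrained value.

A second-order Taylor shortcut of the reciprocal (for by-hand estimation)
is provided; once `A*B*t` grows past ~1 its quadratic truncation can turn
non-positive, which is flagged as divergence rather than raised.

## Cohort evaluation protocol

Each patient's series is truncated to the first `x` visits — `exact_first_x`
drops patients with fewer than `x` visits; `at_most_first_x` keeps everyone
at `min(m, x)` — then fitted and tested against the tolerance. The accuracy
rate is `accepted / entered`, kept as an exact ratio (reported to one
decimal as a percentage). Two-visit patients under `at_most` schemes are
fitted anyway, flagged under-determined, and stay in the denominator;
non-convergent fits count as not accepted.

## Virtual patients

The generator emulates a titration clinic so the full pipeline is testable
without patient data: initial FT4 uniform on 20–90 pmol/l, 2–10 reviews at
28–180-day intervals, a step-down dosing rule (30 mg/day if the initial FT4
exceeds 40 pmol/l else 15, halved once the model-predicted next FT4 falls
below 20), and additive Gaussian observation noise (default sd 1 pmol/l,
roughly an assay-scale error; floored at 0.5 pmol/l). Ground truths sample
the synthesis rate log-uniformly over 0.05–5/day and ic50 uniformly over
20–120 mg — spanning the slow and fast equilibration regimes seen in fitted
patients — and place the untreated steady state `A/C` at 30–90% of the
initial FT4, with `C1` pinned by the initial-condition identity, so every
draw is valid by construction. Schedule/dose and noise streams are seeded
separately: changing only the noise seed changes measurements, never visits
or doses.

What the generator does **not** emulate: TSH feedback and hysteresis,
assay-specific error structure, missed visits, dose nonadherence, or any
drift in a patient's kinetics over time. Passing recovery tests therefore
demonstrates correctness of the estimation machinery on model-true data,
not clinical validity on real cohorts.

Problem sizes used in the validation suite: 20-patient cohorts with 4–8
visits for recovery and accuracy checks (noise sd 0 and 2.25 pmol/l, i.e.
half the acceptance tolerance), 10^4 random parameter/point draws for the
monotonicity and asymptote properties, and 40–200 draws where each check
needs an ODE integration or root solve.

## Numerical notes and limitations

- Strict monotonicity and round-trip identities are verified while the
  exponential tail is still resolvable in double precision (`A*B*t` up to
  ~15); past that the trajectory sits on its asymptote to machine accuracy
  and time is no longer identifiable from FT4 — the solvers then report
  infeasibility honestly rather than returning a pseudo-inverse.
- Individually rounded published constants need not satisfy the initial
  condition their unrounded originals met (a three-decimal parameter set
  can miss `A - y1(C + A C1) = 0` by ~0.03); reconstructing parameters from
  the printed *products* `A*ic50` and `A*ic50*C1` is the faithful route and
  is what `ModelParams.from_products` implements.
- The model is strictly one patient at a time: no population priors, no
  mixed effects, no uncertainty intervals on parameters.
- FT4 is the only state: TSH normalization, relapse prediction and
  block-and-replace regimens are out of scope.
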