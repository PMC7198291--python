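# Methods

## The kinetic model

`ridkin` models whole-body retinol kinetics as a linear compartmental
system.  An oral input (labeled dose at t = 0; unlabeled dietary intake at
a constant rate) is absorbed with efficiency `absorption_efficiency`,
transits an absorption/chylomicron-processing delay (component 3), clears
through a chylomicron compartment (4, rate `l_5_4`), and enters plasma
retinol (5).  Plasma exchanges with a large slow storage pool (6, in
`l_6_5`, out `l_5_6`) and a small fast pool (7, `l_7_5`/`l_5_7`), and
loses retinol irreversibly through a catabolic component fed from plasma
(`l_8_5`) and through the large store's output (`l_0_6`).  All transfers
are first order (fractional transfer coefficients, /d), so tracer
trajectories are expressed per unit dose and are invariant to dose size.
Total body stores are TBS = M(6) + M(7).

Assumptions inherited from the isotope-dilution framework: tracee masses
are at steady state for the study duration (stores change little over
28–42 d); the tracer is kinetically identical to the tracee; absorption
efficiency applies equally to dose and diet.

### Delay implementation

A pure transit delay is approximated by an Erlang chain of n = 25
identical first-order stages (stage rate n/τ), which keeps the whole
system a plain linear ODE.  The chain's transit-time dispersion is
τ/√n = 0.2 τ; in the single-pathway test the resulting plasma curve
matches an exact time shift to within ~0.5% at late times (amplitude
error ≈ exp(λ²τ²/2n) for a terminal slope λ).  Delays below 1e-6 d
(~0.1 s) are treated as zero rather than building an extremely stiff
chain.

### Solvers

The default integrator is LSODA with rtol 1e-8 / atol 1e-10 (the system
is stiff: stage rates ~100/d against store turnover ~0.004/d).  Because
the system is linear and time-invariant, an exact discrete propagator
(`method="expm"`: matrix exponentials cached per unique grid spacing) is
also provided and is used inside the fitting loop for speed; the two
paths agree to ~1e-7 and the test suite checks the integrator against an
independently assembled matrix-exponential oracle.  Default output grid
0–42 d at 0.05 d.  Steady-state masses are solved in closed form from the
node balances; a dense linear-solve oracle verifies them to 1e-10.

## RID coefficients

From a model solution, Fa(t) = F(6)+F(7), S(t) = plasma SA over store SA,
and the composite coefficient FaS(t) = [F(5)/M(5)]·[M(6)+M(7)], computed
independently of Fa and S; FaS ≡ Fa·S is verified pointwise as an
algebraic identity.  (Only this form is dimensionally consistent with
TBS = FaS/SA_p and recovers M(6)+M(7) exactly when a subject is predicted
with their own coefficients.)  Coefficient curves are interpolated at
arbitrary sampling times with monotone cubic (PCHIP) interpolation; the
curves are smooth and the grid dense, and monotone interpolation avoids
overshoot near the early FaS peak.  Predictions before day 4 are computed
but warned about — mixing of dose with stores is incomplete early and the
boundary is population dependent.

The equilibrium ratio S_eq = R(5,6)/[R(5,4)+R(5,6)] is exact in the limit
where plasma and the fast pool are small relative to the large store;
otherwise the simulated plateau (the slowest eigenmode's SA ratio)
deviates by roughly (m7/m6)(1−S_eq) plus terms of order λ·m/R.  The
reference parameter set keeps this deviation below 1e-3 (see below).

Zero-intake behaviour: tracer dynamics never depend on intake, so the
S → 1 plateau when subjects consume no vitamin A is a *tracee* effect —
stores wash out through the same kinetics as the tracer, and both relax
onto the slowest eigenmode, making all specific activities equal.
`washout_sa` therefore evolves tracee masses from their pre-dose steady
state instead of freezing them; with any constant positive intake the
masses are constant and the two formulations coincide.

## The reference parameter set

No printed rate constants exist for this model class, so the package
ships an illustrative set constructed from a target steady-state
geometry: plasma 1.25 µmol, large store 1750 µmol, fast store 3 µmol;
intake 2.27 µmol/d with absorption 0.8; store recycling R(5,6) set to
4× the absorbed dietary inflow (S_eq = 0.8 exactly); disposal split 66%
store-side / 34% plasma-side; 1 µmol/d plasma–fast-store exchange; 0.25 d
absorption delay.  This reproduces the qualitative features expected for
children with high vitamin A intakes — steep early plasma SA decline with
a bend after a few days, plasma/store SA crossover near day 12, flat Fa
near 0.73–0.74, S ≈ 3.0/1.7/0.91/0.81 at days 4/7/14/21 — while keeping
the simulated S plateau within ~6e-4 of the closed form.  It is a design
choice, not a fit to any cohort.

## Composite ("super-person") estimation

`SuperPersonModel` pools all subjects' plasma SA observations and fits
one parameter set by weighted nonlinear least squares
(`scipy.optimize.least_squares`, trust-region reflective), with:

* **log-parameter search space** — rates are positive and span orders of
  magnitude;
* **relative (constant-CV) weights** `1/max(SA_obs, 1e-12)²` — plasma SA
  spans ~3 decades over a month, and measurement error is close to
  multiplicative;
* **multi-start** (default 5 seeded starts, lognormal perturbations of
  SD 0.3 in log space around the initial values; best final objective
  wins, ties by first found);
* **fractional standard deviations (FCV)** per free parameter from the
  Jacobian at the optimum (SD of the log-parameter).

An optional `pre_average="geometric"` mode collapses the pooled data to
geometric-mean SA per scheduled time before fitting; the default fits the
pooled observations directly.

**Fixed parameters.** `absorption_efficiency` must come from outside
information — it rescales the whole curve and is not identifiable from
plasma SA.  `delay_time` is fixed because post-day-1 sparse samples do
not inform it.  `l_0_6` is fixed for a structural reason: Laplace-domain
analysis of the plasma transfer function (plus the steady-state intake
constraint) shows that with both loss routes free there is a
one-parameter family of models with identical plasma output along which
TBS varies — the split between plasma-side and store-side irreversible
loss is unidentifiable from a plasma tracer curve alone.  Fixing the
store-side fractional rate restores identifiability, and fitted stores
are insensitive to misspecifying it (relative TBS error ≈
Δl_0_6/l_5_6, a ~6× damping at the reference values).  The remaining six
rates are free by default.

## Synthetic populations and the study engine

`generate_subjects` draws each listed parameter independently lognormal
with **median** at the reference value and σ = √ln(1+CV²), so the
empirical CV matches the request.  Defaults: CV 0.3 on `l_5_6`, `l_6_5`,
`l_8_5` and `dietary_intake` (the drivers of store size and turnover),
CV 0.1 on the other rates.  Absorption efficiency, delay and dose are
common to all subjects: absorption is treated as known outside
information, and a lognormal spread on a fraction near 1 would escape
(0, 1].  Measurement noise in `observe` is multiplicative lognormal with
mean 1 (E[SA] unbiased; E[log SA] = log truth − σ²/2), independent
streams per subject.

`run_superstudy` samples every subject at a common day (default 4) plus
one other day from the schedule {0.25, 0.5, 1, 2, 4, 7, 10, 14, 21, 28}
(balanced seeded assignment: each eligible day used ⌊n/9⌋ or ⌈n/9⌉
times), pools the observations, fits the composite model, and predicts
each subject as FaS_pop(common)/SA_i(common).  The known intake given to
the fit defaults to the sample mean of the subjects' intakes — the
design requires an intake estimate and a field study obtains one by
dietary assessment.  Scores: group-mean percent error, fraction of
subjects within 25%, Spearman rank correlation, and the across-subject
CV% of individual FaS at every schedule time (ddof = 1).

### What the synthetic validation does and does not show

The generator emulates between-subject lognormal kinetic heterogeneity
and multiplicative assay noise.  It does **not** emulate parameter
correlations within subjects (draws are independent), intake reporting
error, non-steady stores, assay outliers, or absorption variability —
so passing tests demonstrate the internal consistency and statistical
behaviour of the workflow under the stated conditions, not field
performance.

Two structural findings from this validation are worth knowing when
interpreting results.  First, the precision of the population store
estimate is limited by the late samples: store turnover (~250 d) is far
slower than the 28-d window, so the fitted TBS rides on the late-time SA
level, which only ~2 subjects per late day inform; per-replicate group
errors are heavy-tailed as a result.  Second, individual predictions at
the default common day 4 are limited by the across-subject dispersion of
FaS(4) itself (CV ≈ 25–38% under the default heterogeneity): even
predicting with the best possible population coefficient leaves a
substantial fraction of subjects outside ±25%.  The package's timing
scan makes the remedy quantitative — the FaS CV drops to ~7% near days
14–21, where individual recovery and rank preservation are far better —
which is exactly the "sample where the FaS CV is lowest" criterion the
scan implements.

## Problem sizes and numerical defaults

Default suite and acceptance runs use: simulation grids of ≤ ~850 points
(0.05 d spacing), 10 study replicates of 20 subjects (chosen as a
realistically small field cohort), 5 optimizer starts, and Monte-Carlo
checks of 10⁴–5·10⁴ draws.  Steady-state balance is asserted at 1e-10,
tracer conservation at 1e-8, solver cross-validation at 1e-6, plateau
convergence at 1e-3.  Seeds control every stochastic component
(population draw, design assignment, noise streams, optimizer starts);
reruns with the same seed are bit-reproducible.

## Known limitations

* The Erlang delay is an approximation; applications needing exact
  transit delays at sub-0.1-d resolution should raise the stage count.
* Compartment 7 has no irreversible output and the model has no
  retinyl-ester/chylomicron sub-model of the absorption phase; absorption
  efficiency must be supplied, not estimated.
* Per-individual fitting of two-sample subjects is deliberately absent —
  the sparse design only supports a composite fit.
* Store-side vs plasma-side disposal cannot be separated from plasma
  data; results condition on the fixed `l_0_6`.
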