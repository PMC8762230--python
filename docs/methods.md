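# Methods

## Structural model and assumptions

The parent drug follows one-compartment disposition with first-order oral
absorption and two parallel elimination pathways: a linear clearance `CL1`
(lumping renal and any non-N-oxide hepatic elimination — the data cannot
separate them) and a capacity-limited pathway `Vmax/(C1+Km)` that produces
the N-oxide metabolite.  The metabolite has its own one-compartment
disposition (`V2`, `CL2`) and inhibits the pathway that produces it through
a saturable concentration-dependent factor `1 − Imax·C2/(IC50+C2)`.
Time-dependent (enzyme-turnover) auto-inhibition is deliberately not
modelled: trough-only data carry no information about within-day onset
kinetics, so the inhibition is driven by the metabolite concentration
alone.  Intravenous dosing and peripheral distribution compartments are out
of scope.

The amount-conversion factor `kn` in the metabolite inflow defaults to 1:
both analytes are tracked in milligrams of drug equivalents, so every
milligram cleared through the saturable pathway enters the metabolite
compartment and the system obeys an exact mass balance (a test asserts it
to 1e-6 after 14 days of dosing).  Users who prefer true metabolite mass
can set `kn` to the VNO/VCZ molar-mass ratio; nothing else changes.

Five quantities are conventionally fixed rather than estimated, because a
trough-only design cannot identify them: `F = 0.895`, `ka = 1.1 /h`
(absorption), and `Km = 1.15 mg/L`, `Imax = 0.75`, `IC50 = 14.6 mg/L`
(saturation/inhibition constants, which need concentration ranges the data
do not cover).

### Reference parameter set

`voripk.reference` carries the final estimates of a published 78-patient
adult TDM cohort (oral 200 mg q12h): `V1 207.29 L`, `CL1 1.91 L/h`,
`V2 10.01 L`, `Vmax 18.80 mg/h`, `CL2 4.65 L/h`, CYP2C19 effects
`theta_IM −0.31`, `theta_PM −0.61` on `Vmax`, diagonal between-subject
variability printed as 240.77 / 6.02 / 25.57 / 21.13 % on
`V1/CL1/CL2/Vmax`, and proportional residual error 46.97 % (parent) and
27.93 % (metabolite).

### The omega-percent convention

Fit reports print between-subject variability as a percentage without
defining the transform to the log-scale standard deviation ω.  Two readings
are supported:

* `cv_percent` (default): the percent is the coefficient of variation of
  the lognormal distribution, `ω = sqrt(ln(1+CV²))` exactly.  240.77 % maps
  to ω = 1.374.
* `sd_times_100`: the percent is 100·ω directly (240.77 % → ω = 2.408).

The readings coincide for small variability and diverge strongly for the
volume term.  `cv_percent` is the default because a CV%-style report is the
standard convention and because, with residual error included, it
reproduces the published 200 mg twice-daily simulation anchors within a few
percent on the medians.  This is the dominant sensitivity of every
simulation output, so `pta_convention_report` always prints the anchor rows
under both readings, and each result records the convention used.

## Numerics

The hot loop of both estimation and simulation is a multi-dose solve of the
five-state system (two amounts, the gut depot, and two running AUC
integrals).  The default integrator is an in-package Dormand–Prince RK5(4)
with proportional step control, compiled with numba.  Two choices matter:

* The gut amount decays as a pure exponential between dose events, so it is
  propagated analytically at every stage instead of being error-controlled
  by the embedded pair.  Naive error control on that component pins the
  step size to the absorption time constant long after the amount has
  stopped mattering (we measured ~50 steps per dosing interval; the hybrid
  scheme needs ~6), without any accuracy cost — agreement with a
  tight-tolerance LSODA reference stays at ~1e-8 and with the closed-form
  one-compartment (Bateman) superposition at ~5e-8 in the linear limit.
* Dose events restart the integrator exactly (no smoothing); observations
  at a dose time are pre-dose by convention.  The adaptive step is carried
  across segment boundaries (clipping a step to a segment end does not
  shrink the controller state).

Default tolerances are rtol 1e-8 / atol 1e-10 for simulation and
rtol 1e-6 / atol 1e-9 inside estimation.  Negative states are never
clipped: a state below −1e-9 aborts the solve with an explicit error, as
does step underflow or an exhausted step budget (the budget exists so that
pathological parameter corners probed by optimizer line searches fail fast
instead of grinding).  `scipy.integrate.solve_ivp` (LSODA) is available as
`backend="lsoda"` and serves as the independent cross-check in the tests.

## Estimation

Per subject, minus twice the conditional log likelihood

    g(eta) = sum_j [ ln(2π v_j) + (y_j − f_j(eta))²/v_j ] + etaᵀΩ⁻¹eta

is minimized over the random effects by a damped Newton search with
finite-difference sensitivities `G = df/deta` (step 1e-4, sensitivities
reused across iterations until the step size exceeds 0.05), backtracking
line search, and tolerance 1e-6 on the step.  The residual variance `v`
uses the current eta (the interaction variant — necessary with
proportional error).  The subject's marginal contribution is the Laplace
value at the mode with a Gauss–Newton Hessian:

    OFV_i = g(eta_hat) + ln det Ω + ln det( Σ_j G_j G_jᵀ / v_j + Ω⁻¹ )

All constants are kept, so `AIC = OFV + 2p` and `BIC = OFV + p·ln(n)` hold
exactly as printed by standard tools; only OFV differences matter for
selection decisions.  For models linear in eta with Gaussian error this
expression is the exact marginal likelihood, which is the test oracle.

The outer optimization follows a Lindstrom–Bates-style alternation: anchor
the conditional modes, recentre the means (typical values and categorical
covariate thetas absorb the average mode of their eta — the update that
actually moves covariate coefficients, since in the conditional objective
they trade off against the modes almost exactly), then take a bounded
L-BFGS-B pass on a frozen-mode surrogate whose gradient needs almost no
extra ODE solves: a log-scale typical value acts multiplicatively exactly
like its eta, so the cached eta-sensitivity column doubles as the
outer-parameter sensitivity.  Steps are accepted only when the full
conditional-mode OFV confirms them.  Positives are log-transformed;
variability terms packed at exactly zero stay pinned (structural zeros).

Identifiability: trough-only designs with fixed `F`/`ka` leave `V1` weakly
identified; the fitter reports an information-matrix condition number and a
warning note rather than failing.  Observations below the 0.0005 mg/L
assay quantification limit are excluded from fitting with a logged count
and kept in files.  Subjects whose un-genotyped phenotype cannot be mapped
are imputed to the reference (NM) category.

Covariate screening uses the power form `θ·(cov/median)^θcov` for
continuous covariates and `θ·exp(θcov)` for categorical ones; forward
inclusion needs ΔOFV > 3.84 per added theta, backward retention needs
ΔOFV ≥ 6.63 per theta.  The collinearity screen is rank-based (Spearman) by
default because the laboratory covariates are heavily right-skewed.

## Qualification

* Bootstrap: subjects resampled with replacement at the cohort size, model
  refit per resample; median, 2.5/97.5 percentiles and
  `bias% = (bootstrap median − original)/original × 100` per parameter;
  non-converged resamples are counted and excluded, with a warning above a
  20 % failure rate.  Resample indices are logged for reproducibility.
* VPC: replicate cohorts simulated under the observed design (variability
  and residual error included); observed 2.5/50/97.5 percentiles compared
  with the simulation bands of those percentiles in quantile bins of time
  after the last dose (8 by default — the study's sampling is
  trough-clustered, so fixed-width bins would be mostly empty); undersized
  bins are merged with neighbours and counted.  Prediction correction is
  not applied by default.
* A brute-force Monte Carlo marginal likelihood (`mc_marginal_ofv`,
  random effects drawn from their prior) is available as an independent
  check of the Laplace approximation on small problems; a test holds the
  two within 2 % on a nonlinear cohort.  The bootstrap can optionally be
  stratified by phenotype (`stratify_by="PHENOTYPE"`); plain resampling is
  the default.
* CWRES from the first-order linearization at the conditional mode:
  residual against `f(eta_hat) − G·eta_hat`, whitened by the symmetric
  inverse square root of `G Ω Gᵀ + diag(v)`.  With no random effects and
  additive error this reduces to `(obs − pred)/σ` exactly.  Known
  limitation: at the reference model's very large volume variability the
  linearization is visibly biased (mean CWRES ≈ −0.4 on a well-specified
  cohort), so the calibration test runs at moderate variability where the
  diagnostic is accurate.

## Dose-optimization simulation

For each phenotype × regimen cell (doses 125–400 mg, q12h or q8h), virtual
subjects are drawn from the population model and dosed to day 14; the
pre-dose trough at day 14 is the steady-state trough `Cssmin`.  Steady
state is verified per subject (successive troughs within 0.5 %);
non-converged subjects — a substantial fraction under the large volume
variability, since a small clearance/volume ratio means slow accumulation —
are counted and reported, and can optionally be re-simulated once at twice
the horizon (`extend_nonconverged=True`).  Extension is off by default so
that every subject contributes the same day-14 estimand.

The reported trough is an observation-level value: the proportional
residual error is applied on top of the individual prediction, matching how
simulation tables are generated by standard pharmacometric software (and
the only way a nonzero fraction of subjects can exceed the 5.5 mg/L
toxicity cut-off at these parameter values).  Residual-free troughs are
available with `include_residual=False`; exposure metrics
(`Cmin`/`Cmax`/`AUC24` over 144–168 h and the metabolic ratio
`AUC_VNO/AUC_VCZ`) are always residual-free, the standard convention for
derived exposure.  PTA is the percentage of troughs at or above each
cut-off (1, 2 and 5.5 mg/L), with its binomial Monte Carlo standard error
(~1.5 points at n = 1000) reported per cell.

## What the synthetic cohorts emulate — and what they do not

`synthetic_data.generate_cohort` reproduces the study design: 78 subjects
(27 NM / 32 IM / 16 PM / 3 un-genotyped, simulated as NM but labelled
unknown), oral 200 mg q12h without loading, trough-only sampling with a
log-uniform first draw in 23–4,223 h after the first dose, up to eight
samples per subject with a geometric count distribution calibrated to the
study's ~2.7 samples/subject (≈427 dual-analyte observations, one
metabolite sample dropped at random), and covariates drawn from the study's
marginal summaries — truncated normals with the location solved so the
truncated mean matches the reported mean, and lognormals matched to the
reported median and mean.  Body surface area is computed from height and
weight by the Mosteller formula, so the weight–BSA collinearity that the
screen must flag is real.  Everything else is generated independently:
no covariate–parameter correlations, no dropout, no mid-therapy dose
adjustments, no comedication effects, no inter-occasion variability.
Passing tests therefore show that the algorithms recover what this
generator encodes, not that the model is correct for any particular real
population.

`generate_rich_cohort` is the identifiability-friendly design used by the
recovery suite: dense sampling across the first-dose day plus a
steady-state interval (day 8), which makes absorption-phase and volume
parameters estimable.  Recovery tests initialize fits at the generating
values — the standard simulation-study convention for separating estimator
bias from global-search performance — and the test suite separately checks
that a fit from neutral initial values reaches at least the
generating-value likelihood.  Problem sizes in the suite (24–100 subjects,
10 replicates, reduced bootstrap/VPC counts) were chosen to keep the full
run in the minutes range while leaving every statistical check
well-powered; module defaults (1,000 bootstrap resamples, 1,000 VPC and
PTA subjects) match routine practice.

## Known limitations

* The published simulation procedure is not fully specified; with the
  default configuration the package reproduces the 200 mg bid anchor
  medians within ~7 % and the target-attainment percentages within ~2–5
  points, with the NM attainment fraction at 2 mg/L the least well
  reproduced (~24 % vs ~30 %).
* FOCE equivalence with proprietary implementations is claimed only at the
  level of the stated approximation (conditional modes, Gauss–Newton
  curvature, interaction); internals differ.
* Standard errors come from a finite-difference Hessian of the frozen-mode
  objective — adequate for flagging weak identifiability, not a substitute
  for a bootstrap.
* The estimator assumes diagonal Ω and one residual term per analyte;
  inter-occasion variability and off-diagonal correlations are out of
  scope.
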