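# voripk

Joint population pharmacokinetics of voriconazole (VCZ) and its major
metabolite voriconazole N-oxide (VNO) in adults on oral therapy, for
pharmacometricians and clinical-pharmacology researchers who want a fully
scriptable, testable counterpart to a commercial NLME workflow: forward
simulation, FOCE-style mixed-effects estimation with CYP2C19 covariate
modelling, bootstrap/VPC qualification, and Monte Carlo dose-optimization.

## The model

VCZ is absorbed first-order from the gut (rate constant *k*<sub>a</sub>,
bioavailability *F*) into a one-compartment central space (*V*<sub>1</sub>)
and eliminated by two parallel pathways: a linear clearance
*CL*<sub>1</sub> and a saturable (Michaelis–Menten) clearance that converts
parent to N-oxide and is inhibited by the circulating metabolite
(auto-inhibition).  VNO occupies its own compartment (*V*<sub>2</sub>,
clearance *CL*<sub>2</sub>):

    dA_gut/dt = -ka · A_gut
    dA1/dt    =  F · ka · A_gut − (CL1/V1)·A1 − (CL_nl/V1)·A1
    dA2/dt    =  (CL_nl/V1)·A1 · kn − (CL2/V2)·A2
    CL_nl     =  Vmax/(C1 + Km) · (1 − Imax·C2/(IC50 + C2))

with *C*<sub>1</sub> = *A*<sub>1</sub>/*V*<sub>1</sub>,
*C*<sub>2</sub> = *A*<sub>2</sub>/*V*<sub>2</sub>.  Between-subject
variability is lognormal, *P*<sub>i</sub> = θ·exp(η<sub>i</sub>) with
η ~ N(0, ω²) on *V*<sub>1</sub>, *CL*<sub>1</sub>, *CL*<sub>2</sub> and
*V*<sub>max</sub>; residual error is proportional per analyte.  The CYP2C19
phenotype acts on the saturable pathway,
*V*<sub>max</sub> = 18.80·exp(θ<sub>CYP2C19</sub>), with intermediate and
poor metabolizers at θ = −0.31 and −0.61 (26.7% and 45.7% lower
*V*<sub>max</sub> than normal metabolizers).  The packaged reference
estimates come from a therapeutic-drug-monitoring cohort of 78
immunocompromised adults on 200 mg twice daily (`voripk.reference`).

Estimation maximizes the FOCE/Laplace approximation of the marginal
likelihood (conditional modes of η per subject, Gauss–Newton curvature,
interaction with the proportional error), reports OFV/AIC/BIC and empirical
Bayes estimates, screens covariates by forward selection (ΔOFV > 3.84) and
backward elimination (ΔOFV ≥ 6.63) with a rank-correlation collinearity
screen, and is qualified by subject-resampling bootstrap, visual predictive
checks and conditional weighted residuals.

## Worked example

```python
import voripk as v

fixed = v.reference_fixed_effects()
omega = v.reference_omega()          # CV-percent reading of the omegas
sigma = v.reference_sigma()

# probability of attaining a 2 mg/L steady-state trough on 200 mg bid
rows = v.pta_table(fixed, omega,
                   regimens={ph: [(200, 12)] for ph in ("NM", "IM", "PM")},
                   n_subjects=1000, seed=1, sigma_vcz=sigma["VCZ"])
for r in rows:
    print(f"{r.phenotype} {r.label}: median trough "
          f"{r.median_cssmin:.2f} mg/L, PTA(>=2) {r.pta[2.0]:.1f}%, "
          f"failing the target {v.failure_fraction(r, 2.0):.1f}%")
```

prints (seed 1):

```
NM 200 mg, bid: median trough 1.23 mg/L, PTA(>=2) 25.1%, failing the target 74.9%
IM 200 mg, bid: median trough 1.94 mg/L, PTA(>=2) 48.7%, failing the target 51.3%
PM 200 mg, bid: median trough 2.56 mg/L, PTA(>=2) 64.0%, failing the target 36.0%
```

i.e. the standard maintenance dose leaves the median normal and
intermediate metabolizer below the 2 mg/L therapeutic floor, while poor
metabolizers centre inside the 2–5.5 mg/L window — the rationale for
phenotype-guided dosing.  A full end-to-end run (synthesize a cohort, fit
it, bootstrap, VPC, PTA grid) is available from the command line:

```bash
voripk synth --seed 7 --out cohort.csv
voripk fit cohort.csv --seed 7 --out fit.txt
voripk pta --n 1000 --seed 1 --out pta.csv
```

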