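"""Study emulator: cohorts with the trial's design and statistical structure.

The default design mirrors the therapeutic-drug-monitoring study the reference
parameter set comes from: 78 adults on oral 200 mg twice daily without a
loading dose, trough-only sampling (pre-dose draws, first sample between 23
and 4,223 h after the first dose, at most eight per subject, about 427
dual-analyte observations in total), CYP2C19 phenotypes 27 NM / 32 IM / 16 PM
with 3 un-genotyped, and demographic/laboratory covariates drawn to match the
study's marginal summaries.

Covariates are generated independently of each other and of the PK parameters
except body surface area, which is computed from height and weight by the
Mosteller formula (so the weight-BSA collinearity the covariate screen must
flag is real).  Laboratory covariates are causally inert: the final model has
no lab effects, and keeping the columns preserves the negative-screening test
surface.  Un-genotyped subjects are simulated with NM kinetics but labelled
``unknown``, exercising the estimation-side imputation policy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .io import EventDataset, flag_blq
from .model_core import FixedEffects, Regimen, mosteller_bsa, solve_profile
from .popsim import OmegaSpec, SigmaSpec, apply_residual, sample_individual

#: Table of covariate marginals: (mean, sd, median, low, high, distribution)
COVARIATE_SUMMARIES: dict[str, tuple] = {
    "AGE": (37.5, 14.7, 36.5, 14.0, 70.0, "normal"),
    "WT": (63.2, 12.3, 64.0, 44.0, 111.0, "normal"),
    "HT": (167.6, 6.0, 170.0, 151.0, 190.0, "normal"),
    "BUN": (7.71, 5.90, 5.92, 1.36, 35.21, "lognormal"),
    "UA": (273.2, 128.2, 267.1, 1.7, 677.6, "lognormal"),
    "SCR": (84.0, 63.7, 72.4, 30.4, 667.7, "lognormal"),
    "TBIL": (11.3, 7.8, 9.7, 2.9, 60.1, "lognormal"),
    "DBIL": (6.1, 6.2, 4.6, 0.9, 50.6, "lognormal"),
    "IBIL": (5.4, 2.9, 4.8, 0.8, 25.9, "lognormal"),
    "TBA": (10.6, 11.6, 7.0, 1.0, 86.1, "lognormal"),
    "ALT": (27.8, 33.5, 17.0, 3.0, 256.0, "lognormal"),
    "AST": (25.7, 29.8, 18.0, 3.0, 261.0, "lognormal"),
    "ALP": (134.4, 120.3, 100.0, 30.0, 898.0, "lognormal"),
    "GGT": (122.4, 182.1, 65.0, 10.0, 1445.0, "lognormal"),
    "TP": (60.6, 9.5, 61.5, 30.1, 84.7, "normal"),
    "ALB": (39.1, 6.4, 39.5, 20.0, 51.8, "normal"),
    "GLB": (21.6, 5.1, 21.2, 7.9, 39.1, "normal"),
}


@dataclass(frozen=True)
class CohortDesign:
    """Design of the emulated study."""

    n_subjects: int = 78
    phenotype_counts: dict = field(default_factory=lambda: {
        "NM": 27, "IM": 32, "PM": 16, "unknown": 3})
    dose: float = 200.0
    interval: float = 12.0
    sampling: str = "trough_only"
    max_samples: int = 8
    #: geometric decay of the per-subject sample-count distribution on 1..max;
    #: 0.68 gives a mean near the study's 214/78 ~ 2.7 samples per subject
    samples_decay: float = 0.68
    first_sample_window: tuple[float, float] = (23.0, 4223.0)
    #: troughs are drawn this long (h) before a dose, uniform over the range
    trough_offset_range: tuple[float, float] = (0.0, 0.5)
    male_fraction: float = 57.0 / 78.0
    ppi_fraction: float = 51.0 / 78.0
    glucocorticoid_fraction: float = 33.0 / 78.0

    def __post_init__(self) -> None:
        if sum(self.phenotype_counts.values()) != self.n_subjects:
            raise ValueError("phenotype counts must sum to n_subjects")
        if self.sampling not in ("trough_only", "rich"):
            raise ValueError(f"unknown sampling scheme {self.sampling!r}")
        lo, hi = self.first_sample_window
        if lo < self.interval:
            raise ValueError("first-sample window opens before the second dose")


@lru_cache(maxsize=None)
def _truncnorm_loc(mean: float, sd: float, lo: float, hi: float) -> float:
    """Location whose [lo, hi]-truncated normal has the requested mean
    (plain truncation of N(mean, sd) would bias the mean inward)."""
    from scipy import optimize, stats

    def gap(mu):
        a, b = (lo - mu) / sd, (hi - mu) / sd
        return stats.truncnorm.mean(a, b, loc=mu, scale=sd) - mean

    return optimize.brentq(gap, mean - 3 * sd, mean + 3 * sd)


def _draw_covariate(name: str, rng: np.random.Generator) -> float:
    mean, sd, median, lo, hi, dist = COVARIATE_SUMMARIES[name]
    for _ in range(100):
        if dist == "normal":
            x = rng.normal(_truncnorm_loc(mean, sd, lo, hi), sd)
        else:
            # lognormal matched to median and mean: median = exp(mu),
            # mean/median = exp(sigma^2/2)
            sigma = math.sqrt(max(2.0 * math.log(mean / median), 1e-4))
            x = rng.lognormal(math.log(median), sigma)
        if lo <= x <= hi:
            return x
    return float(np.clip(x, lo, hi))


def _draw_sample_count(design: CohortDesign, rng: np.random.Generator) -> int:
    k = np.arange(1, design.max_samples + 1)
    p = design.samples_decay ** k
    return int(rng.choice(k, p=p / p.sum()))


def _trough_times(design: CohortDesign, rng: np.random.Generator) -> np.ndarray:
    """Pre-dose sampling instants for one subject (h after first dose)."""
    lo, hi = design.first_sample_window
    tau = design.interval
    first = math.exp(rng.uniform(math.log(lo), math.log(hi)))
    k = max(2, int(math.ceil(first / tau)))  # index of the dose sampled before
    n = _draw_sample_count(design, rng)
    ks = [k]
    for _ in range(n - 1):
        ks.append(ks[-1] + int(rng.integers(2, 21)))  # 1-10 days later
    d_lo, d_hi = design.trough_offset_range
    offsets = rng.uniform(d_lo, d_hi, size=n)
    return np.array([kk * tau - off for kk, off in zip(ks, offsets)])


def _covariate_row(design: CohortDesign, rng: np.random.Generator) -> dict:
    row = {"SEX": "M" if rng.random() < design.male_fraction else "F"}
    for name in COVARIATE_SUMMARIES:
        row[name] = round(_draw_covariate(name, rng), 2)
    row["BSA"] = round(mosteller_bsa(row["HT"], row["WT"]), 3)
    row["PPI"] = int(rng.random() < design.ppi_fraction)
    row["GC"] = int(rng.random() < design.glucocorticoid_fraction)
    return row


def generate_cohort(design: CohortDesign, fixed: FixedEffects,
                    omega: OmegaSpec, sigma: dict[str, SigmaSpec],
                    seed: int, **solver_opts):
    """Forward-simulate a cohort under the study design.

    Returns ``(EventDataset, truth)`` where ``truth`` carries the generating
    parameters and each subject's realized individual parameters for recovery
    scoring.  One metabolite observation is dropped at random, reproducing the
    study's 214 + 213 pattern of one missing metabolite sample.
    """
    rng = np.random.default_rng(seed)
    phenotypes = [ph for ph, n in design.phenotype_counts.items() for _ in range(n)]
    rng.shuffle(phenotypes)

    rows = []
    truth_rows = []
    for sid, label in enumerate(phenotypes, start=1):
        kinetic_ph = "NM" if label == "unknown" else label
        params = sample_individual(fixed, omega, kinetic_ph, rng)
        obs_times = np.sort(_trough_times(design, rng))
        n_doses = int(math.ceil(obs_times[-1] / design.interval))
        regimen = Regimen.repeated(design.dose, design.interval, n_doses)
        profile = solve_profile(regimen, params, obs_times, **solver_opts)
        cov = _covariate_row(design, rng)
        cov["PHENOTYPE"] = label
        truth_rows.append({"ID": sid, "PHENOTYPE": label,
                           "V1": params.V1, "CL1": params.CL1,
                           "CL2": params.CL2, "Vmax": params.Vmax})
        for t_dose, amt in zip(regimen.times, regimen.amounts):
            rows.append({"ID": sid, "TIME": t_dose, "EVID": 1, "AMT": amt,
                         "DV": np.nan, "DVID": np.nan, **cov})
        dv1 = apply_residual(profile.C1, sigma["VCZ"], rng)
        dv2 = apply_residual(profile.C2, sigma["VNO"], rng)
        for t, v1, v2 in zip(obs_times, dv1, dv2):
            rows.append({"ID": sid, "TIME": t, "EVID": 0, "AMT": np.nan,
                         "DV": v1, "DVID": 1, **cov})
            rows.append({"ID": sid, "TIME": t, "EVID": 0, "AMT": np.nan,
                         "DV": v2, "DVID": 2, **cov})

    df = pd.DataFrame(rows).sort_values(["ID", "TIME", "EVID"],
                                        ascending=[True, True, False],
                                        kind="stable").reset_index(drop=True)
    # drop one metabolite observation at random (the study's 214+213 pattern)
    vno_idx = df.index[(df.EVID == 0) & (df.DVID == 2)]
    if len(vno_idx):
        df = df.drop(rng.choice(vno_idx)).reset_index(drop=True)
    df = flag_blq(df)
    truth = {"fixed": fixed, "omega": omega, "sigma": sigma, "seed": seed,
             "individual": pd.DataFrame(truth_rows).set_index("ID")}
    return EventDataset(df), truth


#: sampling template for the identifiability-friendly design: hours after the
#: morning dose, applied on day 1 and within a steady-state interval
RICH_DAY1_OFFSETS = (0.5, 1.0, 2.0, 4.0, 8.0, 11.9)
RICH_SS_OFFSETS = (0.25, 0.5, 1.0, 2.0, 4.0, 6.0, 9.0, 11.9)


def generate_rich_cohort(n: int, fixed: FixedEffects, omega: OmegaSpec,
                         sigma: dict[str, SigmaSpec], seed: int,
                         samples_per_interval: int = 8,
                         dose: float = 200.0, interval: float = 12.0,
                         ss_day: int = 8, **solver_opts):
    """Dense-sampling cohort for parameter-recovery studies.

    Each subject is dosed q12h for ``ss_day`` days and sampled across the
    first-dose day plus a steady-state dosing interval; phenotypes are
    assigned in the study's NM/IM/PM proportions (un-genotyped excluded).
    """
    if n < 20:
        raise ValueError("rich designs need n >= 20 for stable recovery")
    rng = np.random.default_rng(seed)
    props = np.array([27.0, 32.0, 16.0])
    counts = np.floor(props / props.sum() * n).astype(int)
    counts[0] += n - counts.sum()
    phenotypes = [ph for ph, c in zip(("NM", "IM", "PM"), counts)
                  for _ in range(c)]
    rng.shuffle(phenotypes)

    ss_start = (ss_day - 1) * 24.0
    obs_times = np.sort(np.concatenate([
        np.array(RICH_DAY1_OFFSETS),
        ss_start + np.array(RICH_SS_OFFSETS[:samples_per_interval]),
    ]))
    n_doses = int(ss_day * 24 / interval)
    regimen = Regimen.repeated(dose, interval, n_doses)

    rows = []
    truth_rows = []
    for sid, ph in enumerate(phenotypes, start=1):
        params = sample_individual(fixed, omega, ph, rng)
        profile = solve_profile(regimen, params, obs_times, **solver_opts)
        truth_rows.append({"ID": sid, "PHENOTYPE": ph, "V1": params.V1,
                           "CL1": params.CL1, "CL2": params.CL2,
                           "Vmax": params.Vmax})
        cov = {"PHENOTYPE": ph, "WT": round(_draw_covariate("WT", rng), 1)}
        for t_dose, amt in zip(regimen.times, regimen.amounts):
            rows.append({"ID": sid, "TIME": t_dose, "EVID": 1, "AMT": amt,
                         "DV": np.nan, "DVID": np.nan, **cov})
        dv1 = apply_residual(profile.C1, sigma["VCZ"], rng)
        dv2 = apply_residual(profile.C2, sigma["VNO"], rng)
        for t, v1, v2 in zip(obs_times, dv1, dv2):
            rows.append({"ID": sid, "TIME": t, "EVID": 0, "AMT": np.nan,
                         "DV": v1, "DVID": 1, **cov})
            rows.append({"ID": sid, "TIME": t, "EVID": 0, "AMT": np.nan,
                         "DV": v2, "DVID": 2, **cov})
    df = pd.DataFrame(rows).sort_values(["ID", "TIME", "EVID"],
                                        ascending=[True, True, False],
                                        kind="stable").reset_index(drop=True)
    df = flag_blq(df)
    truth = {"fixed": fixed, "omega": omega, "sigma": sigma, "seed": seed,
             "individual": pd.DataFrame(truth_rows).set_index("ID")}
    return EventDataset(df), truth
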