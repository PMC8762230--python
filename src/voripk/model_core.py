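"""Structural parent-metabolite model for voriconazole (VCZ) and its N-oxide (VNO).

One-compartment oral absorption of the parent with mixed linear and saturable
(Michaelis-Menten) elimination; the saturable pathway feeds a one-compartment
metabolite whose circulating concentration inhibits that same pathway
(auto-inhibition).  State vector, in amounts:

    A_gut  VCZ at the absorption site (mg)
    A1     VCZ in the central compartment (mg)
    A2     VNO in the metabolite compartment (mg)
    cumAUC1, cumAUC2  running time integrals of C1 = A1/V1, C2 = A2/V2 (mg*h/L)

    dA_gut/dt = -ka * A_gut
    dA1/dt    =  F * ka * A_gut - (CL1/V1) * A1 - (CL_nl/V1) * A1
    dA2/dt    =  (CL_nl/V1) * A1 * kn - (CL2/V2) * A2
    CL_nl     =  Vmax/(C1 + Km) * (1 - Imax * C2/(IC50 + C2))

Oral doses are instantaneous additions to A_gut.  The default integrator is an
in-package adaptive Dormand-Prince RK5(4) compiled with numba (the per-subject
multi-dose solve is the hot loop of both estimation and Monte Carlo dosing
simulation); ``scipy.integrate.solve_ivp`` is available as a cross-check
backend.  The system is non-stiff at clinically relevant parameter values
(time constants of ~1 h for absorption and tens of hours for elimination).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(fn):
            return fn

        return wrap


# --- defaults shared package-wide ------------------------------------------

#: default integrator tolerances (relative, absolute)
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10
#: states more negative than this abort the solve (clipping is forbidden)
NEGATIVE_STATE_TOL = -1e-9
#: assay lower limit of quantification, mg/L (0.5 ng/ml)
LLOQ_MG_L = 0.5e-3

PHENOTYPES = ("NM", "IM", "PM")


class SolverError(RuntimeError):
    """Raised when the ODE solve fails (step underflow or negative state)."""


# --- domain types -----------------------------------------------------------


@dataclass(frozen=True)
class FixedEffects:
    """Population (typical) parameters of the joint VCZ/VNO model.

    ``theta_NM``/``theta_IM``/``theta_PM`` are log-scale CYP2C19 phenotype
    effects on ``Vmax`` (the reference NM effect is 0 by construction).
    ``kn`` is the parent-to-metabolite amount-conversion factor; the default 1
    tracks both analytes in mg of drug equivalents (every mg cleared through
    the saturable pathway enters the metabolite compartment), and it may be
    set to the VNO/VCZ molar-mass ratio instead.
    """

    F: float
    ka: float
    V1: float
    CL1: float
    V2: float
    Vmax: float
    Km: float
    CL2: float
    Imax: float
    IC50: float
    theta_NM: float = 0.0
    theta_IM: float = 0.0
    theta_PM: float = 0.0
    kn: float = 1.0
    fixed_mask: tuple[str, ...] = ("F", "ka", "Km", "Imax", "IC50", "theta_NM")

    def __post_init__(self) -> None:
        for name in ("ka", "V1", "CL1", "V2", "Vmax", "Km", "CL2", "IC50", "kn"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if not 0 < self.F <= 1:
            raise ValueError(f"F must lie in (0, 1], got {self.F}")
        if not 0 <= self.Imax <= 1:
            raise ValueError(f"Imax must lie in [0, 1], got {self.Imax}")
        if self.theta_NM != 0.0:
            raise ValueError("theta_NM is the reference category and must be 0")

    def theta_for(self, phenotype: str) -> float:
        try:
            return {"NM": self.theta_NM, "IM": self.theta_IM, "PM": self.theta_PM}[phenotype]
        except KeyError:
            raise ValueError(f"unknown CYP2C19 phenotype {phenotype!r}") from None

    def with_updates(self, **kwargs) -> "FixedEffects":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class IndividualParams:
    """Realized per-subject parameters after covariate effects and eta draws."""

    V1: float
    CL1: float
    CL2: float
    Vmax: float
    F: float
    ka: float
    V2: float
    Km: float
    Imax: float
    IC50: float
    kn: float = 1.0

    def __post_init__(self) -> None:
        for name in ("V1", "CL1", "CL2", "ka", "V2", "Km", "IC50", "kn"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.Vmax < 0:  # Vmax == 0 is the pure-linear limit
            raise ValueError(f"Vmax must be nonnegative, got {self.Vmax}")

    def as_array(self) -> np.ndarray:
        """Parameter vector in the layout the compiled integrator expects."""
        return np.array(
            [self.F, self.ka, self.V1, self.CL1, self.V2, self.Vmax,
             self.Km, self.CL2, self.Imax, self.IC50, self.kn],
            dtype=np.float64,
        )

    @staticmethod
    def typical(f: FixedEffects, phenotype: str = "NM") -> "IndividualParams":
        """Individual parameters of the typical subject (all eta = 0)."""
        return IndividualParams(
            V1=f.V1, CL1=f.CL1, CL2=f.CL2,
            Vmax=typical_vmax(f.Vmax, phenotype, f),
            F=f.F, ka=f.ka, V2=f.V2, Km=f.Km, Imax=f.Imax, IC50=f.IC50, kn=f.kn,
        )


@dataclass(frozen=True)
class DoseEvent:
    time: float
    amount: float
    route: str = "oral"

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("dose time must be nonnegative")
        if self.amount <= 0:
            raise ValueError("dose amount must be positive")
        if self.route != "oral":
            raise ValueError("only oral dosing is supported")


@dataclass(frozen=True)
class Regimen:
    """An ordered sequence of oral dose events (times in hours from first dose)."""

    doses: tuple[DoseEvent, ...]

    def __post_init__(self) -> None:
        times = [d.time for d in self.doses]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("dose times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([d.time for d in self.doses], dtype=np.float64)

    @property
    def amounts(self) -> np.ndarray:
        return np.array([d.amount for d in self.doses], dtype=np.float64)

    @property
    def end(self) -> float:
        return self.doses[-1].time if self.doses else 0.0

    @staticmethod
    def repeated(amount: float, interval: float, n_doses: int, start: float = 0.0,
                 loading: Sequence[DoseEvent] | None = None) -> "Regimen":
        events = list(loading) if loading else []
        t0 = events[-1].time + interval if events else start
        events += [DoseEvent(t0 + k * interval, amount) for k in range(n_doses)]
        return Regimen(tuple(events))

    @staticmethod
    def bid(amount: float, days: float, loading_amount: float | None = None,
            n_loading: int = 0) -> "Regimen":
        """Twice-daily (q12h) maintenance dosing, with optional q12h loading doses."""
        return Regimen._schedule(amount, 12.0, days, loading_amount, n_loading)

    @staticmethod
    def tid(amount: float, days: float) -> "Regimen":
        """Three-times-daily (q8h) maintenance dosing."""
        return Regimen._schedule(amount, 8.0, days, None, 0)

    @staticmethod
    def _schedule(amount, interval, days, loading_amount, n_loading) -> "Regimen":
        loading = [DoseEvent(k * interval, loading_amount) for k in range(n_loading)] \
            if loading_amount else []
        n_total = int(round(days * 24.0 / interval))
        n_maint = n_total - len(loading)
        if n_maint <= 0:
            raise ValueError("regimen duration too short for the loading phase")
        return Regimen.repeated(amount, interval, n_maint, loading=loading)


@dataclass
class SystemState:
    A_gut: float = 0.0
    A1: float = 0.0
    A2: float = 0.0
    cumAUC1: float = 0.0
    cumAUC2: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.A_gut, self.A1, self.A2, self.cumAUC1, self.cumAUC2])


@dataclass(frozen=True)
class Profile:
    """Solution of the joint model at requested observation times."""

    times: np.ndarray
    C1: np.ndarray
    C2: np.ndarray
    cumAUC1: np.ndarray
    cumAUC2: np.ndarray
    states: np.ndarray = field(repr=False, default=None)


# --- elementary operations --------------------------------------------------


def nonlinear_clearance(C1: float, C2: float, p: IndividualParams) -> float:
    """Concentration-dependent clearance of the saturable VCZ -> VNO pathway (L/h).

    ``Vmax/(C1+Km)`` saturates with parent concentration; the factor
    ``1 - Imax*C2/(IC50+C2)`` is the metabolite auto-inhibition.  Strictly
    decreasing in both concentrations.
    """
    if C1 < 0 or C2 < 0:
        raise ValueError("concentrations must be nonnegative")
    inhibition = 1.0 - p.Imax * C2 / (p.IC50 + C2)
    return p.Vmax / (C1 + p.Km) * inhibition


def typical_vmax(base_vmax: float, phenotype: str, f: FixedEffects) -> float:
    """Typical Vmax for a CYP2C19 phenotype: ``base * exp(theta_phenotype)``."""
    return base_vmax * math.exp(f.theta_for(phenotype))


def ode_rhs(state: SystemState | np.ndarray, p: IndividualParams) -> np.ndarray:
    """Right-hand side of the structural ODE system (pure function)."""
    y = state.as_array() if isinstance(state, SystemState) else np.asarray(state, float)
    out = np.empty(5)
    _rhs(y, p.as_array(), out)
    return out


def mosteller_bsa(height_cm: float, weight_kg: float) -> float:
    """Mosteller body surface area, ``sqrt(height*weight/3600)`` (m^2)."""
    if height_cm <= 0 or weight_kg <= 0:
        raise ValueError("height and weight must be positive")
    return math.sqrt(height_cm * weight_kg / 3600.0)


# --- compiled integrator ----------------------------------------------------

# parameter layout: [F, ka, V1, CL1, V2, Vmax, Km, CL2, Imax, IC50, kn]


@njit(cache=False, fastmath=True)
def _rhs(y, p, out):
    C1 = y[1] / p[2]
    C2 = y[2] / p[4]
    clnl = p[5] / (C1 + p[6]) * (1.0 - p[8] * C2 / (p[9] + C2))
    out[0] = -p[1] * y[0]
    out[1] = p[0] * p[1] * y[0] - (p[3] / p[2]) * y[1] - (clnl / p[2]) * y[1]
    out[2] = (clnl / p[2]) * y[1] * p[10] - (p[7] / p[4]) * y[2]
    out[3] = C1
    out[4] = C2


@njit(cache=False, fastmath=True)
def _step_dp45(y, t, h, p, t_ref, gut_ref, k1, ynew, yerr, work):
    """Dormand-Prince 5(4) step on states 1..4; k1 holds f(t, y) on entry (FSAL).

    The gut amount (state 0) decays as a pure exponential between dose
    events, so it is propagated analytically at every stage instead of being
    error-controlled by the RK pair -- it would otherwise pin the step size
    to its own fast time constant long after the amount stopped mattering.
    ``gut_ref`` is the amount at ``t_ref`` (the last dose event).
    """
    ka = p[1]
    k2 = work[0]
    k3 = work[1]
    k4 = work[2]
    k5 = work[3]
    k6 = work[4]
    k7 = work[5]
    ytmp = work[6]
    ytmp[0] = gut_ref * math.exp(-ka * (t + 0.2 * h - t_ref))
    for i in range(1, 5):
        ytmp[i] = y[i] + h * (1.0 / 5.0) * k1[i]
    _rhs(ytmp, p, k2)
    ytmp[0] = gut_ref * math.exp(-ka * (t + 0.3 * h - t_ref))
    for i in range(1, 5):
        ytmp[i] = y[i] + h * (3.0 / 40.0 * k1[i] + 9.0 / 40.0 * k2[i])
    _rhs(ytmp, p, k3)
    ytmp[0] = gut_ref * math.exp(-ka * (t + 0.8 * h - t_ref))
    for i in range(1, 5):
        ytmp[i] = y[i] + h * (44.0 / 45.0 * k1[i] - 56.0 / 15.0 * k2[i] + 32.0 / 9.0 * k3[i])
    _rhs(ytmp, p, k4)
    ytmp[0] = gut_ref * math.exp(-ka * (t + (8.0 / 9.0) * h - t_ref))
    for i in range(1, 5):
        ytmp[i] = y[i] + h * (19372.0 / 6561.0 * k1[i] - 25360.0 / 2187.0 * k2[i]
                              + 64448.0 / 6561.0 * k3[i] - 212.0 / 729.0 * k4[i])
    _rhs(ytmp, p, k5)
    ytmp[0] = gut_ref * math.exp(-ka * (t + h - t_ref))
    for i in range(1, 5):
        ytmp[i] = y[i] + h * (9017.0 / 3168.0 * k1[i] - 355.0 / 33.0 * k2[i]
                              + 46732.0 / 5247.0 * k3[i] + 49.0 / 176.0 * k4[i]
                              - 5103.0 / 18656.0 * k5[i])
    _rhs(ytmp, p, k6)
    ynew[0] = ytmp[0]  # analytic gut amount at t + h
    for i in range(1, 5):
        ynew[i] = y[i] + h * (35.0 / 384.0 * k1[i] + 500.0 / 1113.0 * k3[i]
                              + 125.0 / 192.0 * k4[i] - 2187.0 / 6784.0 * k5[i]
                              + 11.0 / 84.0 * k6[i])
    _rhs(ynew, p, k7)
    yerr[0] = 0.0
    for i in range(1, 5):
        yerr[i] = h * (71.0 / 57600.0 * k1[i] - 71.0 / 16695.0 * k3[i]
                       + 71.0 / 1920.0 * k4[i] - 17253.0 / 339200.0 * k5[i]
                       + 22.0 / 525.0 * k6[i] - 1.0 / 40.0 * k7[i])


@njit(cache=False)
def _integrate_to(y, t0, t1, p, rtol, atol, k1, max_steps, h0):
    """Advance y in place from t0 to t1; returns (status, steps, h).

    k1 must hold f(t0, y) on entry and holds f(t1, y) on exit (FSAL reuse);
    h0 seeds the step-size controller (carried across segments by the
    caller).  Error codes: 1 = step underflow, 2 = negative state beyond
    tolerance, 3 = step budget exhausted (a guard against pathological
    parameter corners during estimation line searches).
    """
    span = t1 - t0
    steps = 0
    if span <= 0.0:
        return 0, steps, h0
    t = t0
    h = h0
    t_ref = t0
    gut_ref = y[0]
    ynew = np.empty(5)
    yerr = np.empty(5)
    work = np.empty((7, 5))
    hmin = max(span, 1.0) * 1e-14
    while t < t1:
        steps += 1
        if steps > max_steps:
            return 3, steps, h
        hs = h  # actual step, clipped to the segment end; clipping must not
        clipped = False  # shrink the controller state carried in h
        if hs > t1 - t:
            hs = t1 - t
            clipped = True
        _step_dp45(y, t, hs, p, t_ref, gut_ref, k1, ynew, yerr, work)
        errnorm = 0.0
        for i in range(5):
            sc = atol + rtol * max(abs(y[i]), abs(ynew[i]))
            e = yerr[i] / sc
            errnorm += e * e
        errnorm = math.sqrt(errnorm / 5.0)
        if errnorm <= 1.0:
            t += hs
            for i in range(5):
                y[i] = ynew[i]
                k1[i] = work[5][i]  # k7 = f(t+h, ynew)
            for i in range(3):  # amounts only; AUC states are monotone
                if y[i] < -1e-9:
                    return 2, steps, h
            if clipped:
                continue  # keep the controller's h for the next segment
        fac = 0.9 * errnorm ** -0.2 if errnorm > 0.0 else 5.0
        if fac > 5.0:
            fac = 5.0
        if fac < 0.2:
            fac = 0.2
        h = hs * fac
        if h < hmin:
            return 1, steps, h
    return 0, steps, h


@njit(cache=False)
def _simulate(dose_times, dose_amts, obs_times, p, rtol, atol, y0,
              max_steps=200000):
    """Multi-dose profile: states at each obs time (pre-dose convention).

    Observations that coincide with a dose time are evaluated before the dose
    is added.  Returns (states[n_obs, 5], status).
    """
    n_obs = obs_times.shape[0]
    out = np.zeros((n_obs, 5))
    status = 0
    y = y0.copy()
    k1 = np.empty(5)
    _rhs(y, p, k1)
    t = 0.0
    i_d = 0
    i_o = 0
    h = 1.0
    n_d = dose_times.shape[0]
    while i_o < n_obs or i_d < n_d:
        t_next_d = dose_times[i_d] if i_d < n_d else 1e300
        t_next_o = obs_times[i_o] if i_o < n_obs else 1e300
        t_next = min(t_next_d, t_next_o)
        status, used, h = _integrate_to(y, t, t_next, p, rtol, atol, k1,
                                        max_steps, h)
        max_steps -= used
        if status != 0:
            return out, status
        t = t_next
        # observations first (pre-dose trough convention)
        while i_o < n_obs and obs_times[i_o] == t_next:
            for j in range(5):
                out[i_o, j] = y[j]
            i_o += 1
        while i_d < n_d and dose_times[i_d] == t_next:
            y[0] += dose_amts[i_d]
            _rhs(y, p, k1)
            h = min(h, 1.0)
            i_d += 1
    return out, status


def _simulate_scipy(dose_times, dose_amts, obs_times, p, rtol, atol, y0):
    """Reference backend: LSODA restarts at every dose event."""
    from scipy.integrate import solve_ivp

    def rhs(t, y):
        out = np.empty(5)
        _rhs(y, p, out)
        return out

    nodes = np.unique(np.concatenate([dose_times, obs_times]))
    y = np.asarray(y0, float).copy()
    out = np.zeros((len(obs_times), 5))
    t = 0.0
    obs_idx = {}
    for i, to in enumerate(obs_times):
        obs_idx.setdefault(to, []).append(i)
    for tn in nodes:
        if tn > t:
            sol = solve_ivp(rhs, (t, tn), y, method="LSODA", rtol=rtol, atol=atol)
            if not sol.success:
                raise SolverError(f"LSODA failed at t={t}..{tn}: {sol.message}")
            y = sol.y[:, -1]
            t = tn
        for i in obs_idx.get(tn, []):
            out[i] = y
        for j in np.flatnonzero(dose_times == tn):
            y[0] += dose_amts[j]
    if np.any(y[:3] < NEGATIVE_STATE_TOL):
        raise SolverError(f"negative state beyond tolerance: {y[:3]}")
    return out


def solve_profile(regimen: Regimen, p: IndividualParams,
                  obs_times: Iterable[float],
                  rtol: float = DEFAULT_RTOL, atol: float = DEFAULT_ATOL,
                  backend: str = "dp45",
                  y0: np.ndarray | None = None) -> Profile:
    """Integrate the joint model across dose events and evaluate at obs_times.

    Dose events are instantaneous additions to the gut compartment; the solver
    restarts at each event (no smoothing).  Observations coinciding with a
    dose time are pre-dose.  Raises :class:`SolverError` on failure - never a
    silent NaN.
    """
    obs = np.asarray(list(obs_times), dtype=np.float64)
    if obs.size and (np.any(np.diff(obs) < 0) or obs[0] < 0):
        raise ValueError("obs_times must be nondecreasing and nonnegative")
    if rtol <= 0 or atol <= 0:
        raise ValueError("tolerances must be positive")
    y0 = np.zeros(5) if y0 is None else np.asarray(y0, float)
    parr = p.as_array()
    if backend == "dp45":
        states, status = _simulate(regimen.times, regimen.amounts, obs, parr,
                                   rtol, atol, y0)
        if status == 1:
            raise SolverError("step size underflow (possible stiffness); "
                              "try backend='lsoda' or looser tolerances")
        if status == 2:
            raise SolverError("state went negative beyond -1e-9; "
                              "integration aborted (clipping is forbidden)")
    elif backend == "lsoda":
        states = _simulate_scipy(regimen.times, regimen.amounts, obs, parr,
                                 rtol, atol, y0)
    else:
        raise ValueError(f"unknown backend {backend!r}")
    return Profile(times=obs, C1=states[:, 1] / p.V1, C2=states[:, 2] / p.V2,
                   cumAUC1=states[:, 3], cumAUC2=states[:, 4], states=states)


# --- closed-form oracle for the linear limit --------------------------------


def bateman_oracle(dose: float, t_since_dose: float, F: float, ka: float,
                   CL: float, V: float) -> float:
    """One-compartment oral concentration for a single dose (mg/L).

    ``C(t) = F*D*ka / (V*(ka-k)) * (exp(-k t) - exp(-ka t))`` with ``k = CL/V``;
    the ``ka == k`` case uses the analytic limit ``F*D*ka*t/V * exp(-ka t)``.
    Used as the exact reference for the model's linear limit (Vmax -> 0).
    """
    if t_since_dose < 0:
        return 0.0
    k = CL / V
    if math.isclose(ka, k, rel_tol=1e-12):
        return F * dose * ka * t_since_dose / V * math.exp(-ka * t_since_dose)
    return (F * dose * ka / (V * (ka - k))
            * (math.exp(-k * t_since_dose) - math.exp(-ka * t_since_dose)))


def bateman_superposition(regimen: Regimen, t: float, F: float, ka: float,
                          CL: float, V: float) -> float:
    """Multi-dose concentration by superposition of Bateman terms."""
    return sum(bateman_oracle(d.amount, t - d.time, F, ka, CL, V)
               for d in regimen.doses if d.time < t or math.isclose(d.time, t))
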