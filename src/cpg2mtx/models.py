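"""Structural PK/PD models for glucarpidase (CPG2) rescue of high-dose methotrexate.

Two coupled systems are implemented:

* CPG2 follows one-compartment intravenous-infusion kinetics with first-order
  elimination; its concentration-time course has a closed form.
* Methotrexate (MTX) follows two-compartment kinetics in which renal excretion
  is first order (micro-constant ``Kr``) and enzymatic decomposition by
  circulating CPG2 is a Michaelis-Menten process whose maximum rate is
  proportional to the plasma CPG2 concentration::

      dXc/dt = -(Kr + Knr + K12) Xc + K21 Xp - alpha [CPG2] [Xc] / (Km + [Xc])
      dXp/dt =  K12 Xc - K21 Xp

  with ``[Xc] = Xc / Vc`` the central MTX concentration.

Unit conventions (fixed throughout the package): MTX amounts in umol and
concentrations in umol/L (``Km`` is given in umol/L); CPG2 doses in enzyme
units (U) converted to mass via a potency constant, and CPG2 concentrations
in mg/L.  The conversion constant ``alpha`` therefore carries units of
(umol/h) per (mg/L); its published magnitude is kept as a model-unit
constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import warnings

import numpy as np
from scipy.integrate import odeint, ODEintWarning
from scipy.linalg import expm

__all__ = [
    "MTX_MOLAR_MASS", "DEFAULT_CPG2_UNITS_PER_MG",
    "cv_to_omega2", "omega2_to_cv", "bsa_dubois", "bsa_mosteller",
    "Covariates", "Cpg2PopParams", "MtxPopParams",
    "Cpg2IndivParams", "MtxIndivParams", "DoseEvent", "MtxState",
    "CPG2_FINAL_PHASE1", "CPG2_FINAL_PHASE2", "MTX_FINAL",
    "cpg2_individual", "mtx_individual", "cpg2_conc", "mtx_rhs",
    "solve_mtx", "solve_mtx_linear", "MtxProfile", "mtx_state_from_conc",
]

#: molar mass of methotrexate, g/mol (for ng/ml <-> umol/L conversion)
MTX_MOLAR_MASS = 454.44

#: CPG2 potency used only by the simulator to turn a dose in enzyme units (U)
#: into mass (mg).  The potency of the clinical product is not part of the
#: model; estimation from concentration data never uses this constant.
DEFAULT_CPG2_UNITS_PER_MG = 1000.0


def cv_to_omega2(cv: float) -> float:
    """Log-scale variance omega^2 for a lognormal parameter with coefficient
    of variation ``cv`` (fractional), via CV = sqrt(exp(omega^2) - 1)."""
    return math.log1p(cv * cv)


def omega2_to_cv(omega2: float) -> float:
    return math.sqrt(math.expm1(omega2))


def bsa_dubois(height: float, weight: float) -> float:
    """DuBois-DuBois body surface area (m^2) from height (cm), weight (kg)."""
    if height <= 0 or weight <= 0:
        raise ValueError("height and weight must be strictly positive")
    return 0.007184 * height ** 0.725 * weight ** 0.425


def bsa_mosteller(height: float, weight: float) -> float:
    """Mosteller body surface area (m^2) from height (cm), weight (kg)."""
    if height <= 0 or weight <= 0:
        raise ValueError("height and weight must be strictly positive")
    return math.sqrt(height * weight / 3600.0)


@dataclass(frozen=True)
class Covariates:
    """Subject covariates. BSA (m^2) is derived by DuBois when not supplied."""

    body_weight: float          # kg
    height: float               # cm
    bsa: float | None = None    # m^2
    age: float | None = None    # years
    serum_creatinine: float | None = None   # mg/dl
    creatinine_clearance: float | None = None  # ml/min

    def __post_init__(self) -> None:
        if self.bsa is None:
            object.__setattr__(self, "bsa", bsa_dubois(self.height, self.body_weight))
        for name in ("body_weight", "height", "bsa", "age",
                     "serum_creatinine", "creatinine_clearance"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"covariate {name} must be strictly positive, got {v!r}")


@dataclass(frozen=True)
class Cpg2PopParams:
    """Population parameters of the CPG2 one-compartment model.

    CL = tv_cl * BSA**theta_cl * exp(eta_cl), V analogous; additive residual
    error (mg/L) on concentrations.
    """

    tv_cl: float            # L/h
    theta_cl: float         # allometric exponent on BSA
    tv_v: float             # L
    theta_v: float
    omega2_cl: float = 0.0  # log-scale IIV variances
    omega2_v: float = 0.0
    sigma_add: float = 0.0  # mg/L

    def __post_init__(self) -> None:
        if self.tv_cl <= 0 or self.tv_v <= 0:
            raise ValueError("typical values must be strictly positive")
        if min(self.omega2_cl, self.omega2_v) < 0 or self.sigma_add < 0:
            raise ValueError("variances must be non-negative")


@dataclass(frozen=True)
class MtxPopParams:
    """Population parameters of the MTX two-compartment model with
    catalyst-driven Michaelis-Menten decomposition.

    Final covariate structure: CLr = tv_clr * BW/Scr/60, Vc = tv_vc * BW/BSA,
    Vp = tv_vp * BW/60, alpha = tv_alpha; each times exp(eta).  ``q_fixed``
    and ``km_fixed`` are constants and are never estimated.
    """

    tv_clr: float            # L/h
    tv_vc: float             # L
    tv_vp: float             # L
    tv_alpha: float          # (umol/h) per (mg/L)
    q_fixed: float = 0.0778  # L/h, inter-compartment clearance
    km_fixed: float = 86.0   # umol/L, Michaelis-Menten constant
    omega2_clr: float = 0.0
    omega2_vc: float = 0.0
    omega2_vp: float = 0.0
    omega2_alpha: float = 0.0
    sigma_prop: float = 0.0  # fractional

    def __post_init__(self) -> None:
        if min(self.tv_clr, self.tv_vc, self.tv_vp, self.tv_alpha,
               self.q_fixed, self.km_fixed) <= 0:
            raise ValueError("typical values and fixed constants must be positive")
        if min(self.omega2_clr, self.omega2_vc, self.omega2_vp,
               self.omega2_alpha, self.sigma_prop) < 0:
            raise ValueError("variances must be non-negative")


# Published final models (typical values, allometric exponents, IIV as CV,
# residual SDs), usable directly for simulation and as fitting truth.
CPG2_FINAL_PHASE1 = Cpg2PopParams(
    tv_cl=0.0590, theta_cl=3.227, tv_v=0.957, theta_v=2.251,
    omega2_cl=cv_to_omega2(0.032), omega2_v=cv_to_omega2(0.064),
    sigma_add=0.170,
)
CPG2_FINAL_PHASE2 = Cpg2PopParams(
    tv_cl=0.238, theta_cl=1.440, tv_v=1.200, theta_v=1.561,
    omega2_cl=cv_to_omega2(0.174), omega2_v=cv_to_omega2(0.221),
    sigma_add=0.100,
)
MTX_FINAL = MtxPopParams(
    tv_clr=3.248, tv_vc=0.386, tv_vp=3.052, tv_alpha=6.545e5,
    omega2_clr=cv_to_omega2(0.335), omega2_vc=cv_to_omega2(0.291),
    omega2_vp=cv_to_omega2(0.906), omega2_alpha=cv_to_omega2(0.798),
    sigma_prop=1.414,
)


@dataclass(frozen=True)
class Cpg2IndivParams:
    cl: float                # L/h
    v: float                 # L
    eta_cl: float = 0.0
    eta_v: float = 0.0

    @property
    def ke(self) -> float:
        """First-order elimination rate constant, 1/h."""
        return self.cl / self.v


@dataclass(frozen=True)
class MtxIndivParams:
    clr: float               # renal clearance, L/h
    vc: float                # central volume, L
    vp: float                # peripheral volume, L
    alpha: float             # conversion constant
    q: float = 0.0778        # L/h
    km: float = 86.0         # umol/L
    knr_de: float = 0.0      # optional first-order non-renal constant, 1/h
    etas: tuple = (0.0, 0.0, 0.0, 0.0)

    @property
    def kr(self) -> float:
        return self.clr / self.vc

    @property
    def k12(self) -> float:
        return self.q / self.vc

    @property
    def k21(self) -> float:
        return self.q / self.vp


@dataclass(frozen=True)
class DoseEvent:
    """A dosing event.  ``infusion_duration == 0`` denotes a bolus.

    CPG2 amounts are in enzyme units (U); MTX amounts in umol.  MTX doses may
    target the central or (for compartment-state initialisation) peripheral
    compartment.
    """

    time: float
    amount: float
    infusion_duration: float = 0.0
    analyte: str = "CPG2"            # {"CPG2", "MTX"}
    compartment: str = "central"     # MTX only: {"central", "peripheral"}

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ValueError("dose amount must be non-negative")
        if self.infusion_duration < 0:
            raise ValueError("infusion duration must be non-negative")
        if self.analyte not in ("CPG2", "MTX"):
            raise ValueError(f"unknown analyte {self.analyte!r}")
        if self.compartment not in ("central", "peripheral"):
            raise ValueError(f"unknown compartment {self.compartment!r}")


@dataclass(frozen=True)
class MtxState:
    """Amounts (umol) in the MTX system plus cumulative elimination tallies."""

    xc: float = 0.0
    xp: float = 0.0
    cum_renal: float = 0.0
    cum_degraded: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.xc, self.xp, self.cum_renal, self.cum_degraded])


def cpg2_individual(pop: Cpg2PopParams, cov: Covariates,
                    eta: Sequence[float] = (0.0, 0.0)) -> Cpg2IndivParams:
    """Individual CPG2 parameters: CL = tv * BSA**theta * exp(eta)."""
    eta_cl, eta_v = float(eta[0]), float(eta[1])
    cl = pop.tv_cl * cov.bsa ** pop.theta_cl * math.exp(eta_cl)
    v = pop.tv_v * cov.bsa ** pop.theta_v * math.exp(eta_v)
    return Cpg2IndivParams(cl=cl, v=v, eta_cl=eta_cl, eta_v=eta_v)


def mtx_individual(pop: MtxPopParams, cov: Covariates,
                   eta: Sequence[float] = (0.0, 0.0, 0.0, 0.0),
                   knr_de: float = 0.0) -> MtxIndivParams:
    """Individual MTX parameters under the final covariate model.

    CLr = tv_clr * BW/Scr/60, Vc = tv_vc * BW/BSA, Vp = tv_vp * BW/60 (body
    weight standardised at 60 kg), alpha = tv_alpha, each times exp(eta).
    """
    if cov.serum_creatinine is None or cov.serum_creatinine <= 0:
        raise ValueError("serum creatinine must be available and positive")
    e = [float(x) for x in eta]
    clr = pop.tv_clr * cov.body_weight / cov.serum_creatinine / 60.0 * math.exp(e[0])
    vc = pop.tv_vc * cov.body_weight / cov.bsa * math.exp(e[1])
    vp = pop.tv_vp * cov.body_weight / 60.0 * math.exp(e[2])
    alpha = pop.tv_alpha * math.exp(e[3])
    return MtxIndivParams(clr=clr, vc=vc, vp=vp, alpha=alpha,
                          q=pop.q_fixed, km=pop.km_fixed, knr_de=knr_de,
                          etas=tuple(e))


# ---------------------------------------------------------------------------
# CPG2 closed-form kinetics
# ---------------------------------------------------------------------------

def _one_cpt_infusion(tau: np.ndarray, rate: float, v: float, ke: float,
                      dur: float) -> np.ndarray:
    """Concentration from one zero-order infusion started ``tau`` hours ago."""
    te = np.clip(tau, 0.0, dur)   # exposure time within the infusion
    if ke == 0.0:
        c_end = rate * te / v
        decay = np.ones_like(te)
    else:
        c_end = rate / (v * ke) * (-np.expm1(-ke * te))
        decay = np.exp(-ke * np.maximum(tau - te, 0.0))
    return np.where(tau > 0.0, c_end * decay, 0.0)


def cpg2_conc(t, doses: Iterable[DoseEvent], p: Cpg2IndivParams,
              units_per_mg: float = DEFAULT_CPG2_UNITS_PER_MG):
    """Plasma CPG2 concentration (mg/L) at time(s) ``t`` by superposition of
    one-compartment infusion solutions.  Scalar in, scalar out."""
    scalar = np.isscalar(t)
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    cpg2_doses = [d for d in doses if d.analyte == "CPG2"]
    t_min = min([0.0] + [d.time for d in cpg2_doses])
    if np.any(t_arr < t_min):
        raise ValueError("time before the start of the dosing history")
    ke = p.ke
    conc = np.zeros_like(t_arr)
    for d in cpg2_doses:
        mass = d.amount / units_per_mg  # U -> mg
        tau = t_arr - d.time
        if d.infusion_duration > 0:
            conc += _one_cpt_infusion(tau, mass / d.infusion_duration, p.v, ke,
                                      d.infusion_duration)
        else:
            conc += np.where(tau > 0, mass / p.v * np.exp(-ke * np.maximum(tau, 0.0)), 0.0)
    return float(conc[0]) if scalar else conc


# ---------------------------------------------------------------------------
# MTX two-compartment system with catalyst-driven Michaelis-Menten term
# ---------------------------------------------------------------------------

def mtx_rhs(state, t: float, p: MtxIndivParams, cpg2_conc_val: float) -> np.ndarray:
    """Right-hand side of the MTX system (no dosing input).

    State is [xc, xp, cum_renal, cum_degraded] in umol.  The decomposition
    rate alpha*[CPG2]*[Xc]/(Km+[Xc]) is an amount flux (umol/h) routed to
    ``cum_degraded``; the optional first-order non-renal constant ``knr_de``
    (zero in the final model) is also routed there.
    """
    xc, xp = float(state[0]), float(state[1])
    cc = xc / p.vc if xc > 0 else 0.0
    mm = p.alpha * cpg2_conc_val * cc / (p.km + cc) if cc > 0 else 0.0
    kr, k12, k21, knr = p.kr, p.k12, p.k21, p.knr_de
    dxc = -(kr + knr + k12) * xc + k21 * xp - mm
    dxp = k12 * xc - k21 * xp
    return np.array([dxc, dxp, kr * xc, mm + knr * xc])


@dataclass
class MtxProfile:
    """Simulated MTX profile: concentrations (umol/L) and state trajectories."""

    times: np.ndarray
    conc: np.ndarray          # central concentration xc/vc, umol/L
    xc: np.ndarray
    xp: np.ndarray
    cum_renal: np.ndarray
    cum_degraded: np.ndarray
    input_amount: np.ndarray  # MTX amount delivered by each output time
    initial_amount: float = 0.0

    def mass_balance_residual(self) -> np.ndarray:
        """(xc+xp+cum_renal+cum_degraded) - (delivered + initial), umol."""
        total = self.xc + self.xp + self.cum_renal + self.cum_degraded
        return total - self.input_amount - self.initial_amount

    def at(self, t: float) -> float:
        """Linear interpolation of the concentration profile."""
        return float(np.interp(t, self.times, self.conc))


def mtx_state_from_conc(c0: float, p: MtxIndivParams) -> MtxState:
    """Initialise the compartment amounts from an observed pre-dose MTX
    concentration (umol/L), assuming distribution quasi-steady state:
    xc = C0*Vc and xp = xc*K12/K21 (equal concentrations in both
    compartments).  Intended for estimation when the dosing history before
    the observation is unknown."""
    if c0 < 0:
        raise ValueError("concentration must be non-negative")
    xc = c0 * p.vc
    return MtxState(xc=xc, xp=xc * p.k12 / p.k21)


def _parse_mtx_doses(doses):
    boluses, infusions = [], []
    for d in doses:
        if d.analyte != "MTX":
            continue
        ci = 0 if d.compartment == "central" else 1
        if d.infusion_duration > 0:
            infusions.append((d.time, d.time + d.infusion_duration,
                              d.amount / d.infusion_duration, ci))
        else:
            boluses.append((d.time, d.amount, ci))
    return boluses, infusions


def _delivered(t: np.ndarray, boluses, infusions) -> np.ndarray:
    """MTX amount delivered strictly before/at each time (bolus at exactly t
    is excluded: doses take effect for times after the event)."""
    out = np.zeros_like(t, dtype=float)
    for (tb, amt, _c) in boluses:
        out += np.where(t > tb, amt, 0.0)
    for (t0, t1, rate, _c) in infusions:
        out += rate * np.clip(t - t0, 0.0, t1 - t0)
    return out


def _linear_matrix(p: MtxIndivParams) -> np.ndarray:
    kr, k12, k21, knr = p.kr, p.k12, p.k21, p.knr_de
    return np.array([
        [-(kr + knr + k12), k21, 0.0, 0.0],
        [k12, -k21, 0.0, 0.0],
        [kr, 0.0, 0.0, 0.0],
        [knr, 0.0, 0.0, 0.0],
    ])


def _expm_step(A: np.ndarray, y: np.ndarray, b: np.ndarray, dt: float) -> np.ndarray:
    """Advance y' = A y + b exactly by ``dt`` (augmented matrix exponential)."""
    M = np.zeros((5, 5))
    M[:4, :4] = A
    M[:4, 4] = b
    z = np.append(y, 1.0)
    return (expm(M * dt) @ z)[:4]


def _segment_breaks(t_start, t_end, boluses, infusions, cpg2_times):
    pts = {t_start, t_end}
    for (tb, _a, _c) in boluses:
        pts.add(tb)
    for (t0, t1, _r, _c) in infusions:
        pts.update((t0, t1))
    pts.update(cpg2_times)
    return sorted(p for p in pts if t_start <= p <= t_end)


def solve_mtx(doses: Sequence[DoseEvent], p_mtx: MtxIndivParams,
              p_cpg2: Cpg2IndivParams | None, times,
              initial: MtxState | None = None,
              units_per_mg: float = DEFAULT_CPG2_UNITS_PER_MG,
              rtol: float = 1e-8, atol: float = 1e-10,
              max_steps: int = 100000) -> MtxProfile:
    """Integrate the MTX system over ``times`` with CPG2 as a forcing function.

    Integration is restarted at every dose-event boundary.  Segments that end
    before the first CPG2 dose are linear constant-coefficient and advanced
    by matrix exponential; the remainder uses the adaptive stiff-capable
    LSODA integrator with an analytic Jacobian.  Output at a bolus instant is
    the pre-dose (left-limit) state.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0 or np.any(np.diff(times) < 0):
        raise ValueError("times must be a non-decreasing 1-D grid")
    boluses, infusions = _parse_mtx_doses(doses)
    cpg2_doses = [d for d in doses if d.analyte == "CPG2"]
    if cpg2_doses and p_cpg2 is None:
        raise ValueError("CPG2 doses present but no CPG2 parameters supplied")

    all_times = ([d.time for d in doses] or [times[0]])
    t_start = min(times[0], min(all_times))
    t_end = times[-1]
    first_cpg2 = min((d.time for d in cpg2_doses), default=math.inf)
    cpg2_breaks = []
    for d in cpg2_doses:
        cpg2_breaks.append(d.time)
        if d.infusion_duration > 0:
            cpg2_breaks.append(d.time + d.infusion_duration)
    breaks = _segment_breaks(t_start, t_end, boluses, infusions, cpg2_breaks)

    y = (initial.as_array() if initial is not None else np.zeros(4)).astype(float)
    initial_amount = float(y[0] + y[1] + y[2] + y[3])

    vc, km, alpha = p_mtx.vc, p_mtx.km, p_mtx.alpha
    kr, k12, k21, knr = p_mtx.kr, p_mtx.k12, p_mtx.k21, p_mtx.knr_de

    # scalar CPG2 forcing on the ODE hot path (same closed form as cpg2_conc,
    # without array plumbing)
    if cpg2_doses:
        ke_c, v_c = p_cpg2.ke, p_cpg2.v
        _forcing = [(d.time, d.infusion_duration, d.amount / units_per_mg)
                    for d in cpg2_doses]

        def cpg2_at(t: float) -> float:
            c = 0.0
            for (t0, dur, mass) in _forcing:
                tau = t - t0
                if tau <= 0.0:
                    continue
                if dur > 0.0:
                    te = tau if tau < dur else dur
                    if ke_c == 0.0:
                        c_end, decay = mass / dur * te / v_c, 1.0
                    else:
                        c_end = mass / dur / (v_c * ke_c) * -math.expm1(-ke_c * te)
                        decay = math.exp(-ke_c * (tau - te)) if tau > te else 1.0
                    c += c_end * decay
                else:
                    c += mass / v_c * math.exp(-ke_c * tau)
            return c
    else:
        def cpg2_at(t: float) -> float:
            return 0.0

    out = np.empty((times.size, 4))
    idx = 0
    # outputs at/before the integration start see the initial state
    while idx < times.size and times[idx] <= t_start:
        out[idx] = y
        idx += 1

    A_lin = _linear_matrix(p_mtx)

    for a, b in zip(breaks[:-1], breaks[1:]):
        # boluses at the segment start take effect now (after any output at a)
        for (tb, amt, ci) in boluses:
            if tb == a:
                y = y.copy()
                y[ci] += amt
        rc = sum(r for (t0, t1, r, ci) in infusions if t0 <= a < t1 and ci == 0)
        rp = sum(r for (t0, t1, r, ci) in infusions if t0 <= a < t1 and ci == 1)
        j = idx
        while j < times.size and times[j] <= b:
            j += 1
        interior = times[idx:j]
        if b <= first_cpg2:
            # CPG2 absent: constant-coefficient linear system, exact step
            bvec = np.array([rc, rp, 0.0, 0.0])
            t_cur = a
            for k, tq in enumerate(interior):
                if tq > t_cur:
                    y = _expm_step(A_lin, y, bvec, tq - t_cur)
                    t_cur = tq
                out[idx + k] = y
            if b > t_cur:
                y = _expm_step(A_lin, y, bvec, b - t_cur)
        else:
            def rhs(t, s):
                xc, xp = s[0], s[1]
                cc = xc / vc if xc > 0 else 0.0
                mm = alpha * cpg2_at(t) * cc / (km + cc) if cc > 0 else 0.0
                return (
                    -(kr + knr + k12) * xc + k21 * xp - mm + rc,
                    k12 * xc - k21 * xp + rp,
                    kr * xc,
                    mm + knr * xc,
                )

            def jac(t, s):
                xc = s[0]
                cc = xc / vc if xc > 0 else 0.0
                dmm = alpha * cpg2_at(t) * km / (km + cc) ** 2 / vc
                return np.array([
                    [-(kr + knr + k12) - dmm, k21, 0.0, 0.0],
                    [k12, -k21, 0.0, 0.0],
                    [kr, 0.0, 0.0, 0.0],
                    [dmm + knr, 0.0, 0.0, 0.0],
                ])

            tseg = np.concatenate(([a], interior, [b]))
            tseg = np.unique(tseg)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ODEintWarning)
                sol, info = odeint(rhs, y, tseg, Dfun=jac, tfirst=True,
                                   rtol=rtol, atol=atol, mxstep=max_steps,
                                   full_output=True)
            if info["message"] != "Integration successful.":
                raise RuntimeError(
                    f"MTX ODE integration failed near t={info['tcur'][-1]:.4g} h: "
                    f"{info['message']}")
            for k, tq in enumerate(interior):
                out[idx + k] = sol[np.searchsorted(tseg, tq)]
            y = sol[-1]
        idx = j

    while idx < times.size:   # times beyond the last break (== t_end): constant
        out[idx] = y
        idx += 1

    delivered = _delivered(times, boluses, infusions)
    return MtxProfile(times=times, conc=out[:, 0] / vc, xc=out[:, 0],
                      xp=out[:, 1], cum_renal=out[:, 2], cum_degraded=out[:, 3],
                      input_amount=delivered, initial_amount=initial_amount)


def solve_mtx_linear(doses: Sequence[DoseEvent], p_mtx: MtxIndivParams, times,
                     initial: MtxState | None = None) -> MtxProfile:
    """Exact linear (catalyst-free) two-compartment solution via eigenvalue /
    matrix-exponential stepping.  Serves as the closed-form counterpart of
    :func:`solve_mtx` when alpha plays no role, and as the scaling model for
    back-computing infusion amounts from a target concentration."""
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0 or np.any(np.diff(times) < 0):
        raise ValueError("times must be a non-decreasing 1-D grid")
    boluses, infusions = _parse_mtx_doses(doses)
    all_times = ([d.time for d in doses if d.analyte == "MTX"] or [times[0]])
    t_start = min(times[0], min(all_times))
    t_end = times[-1]
    breaks = _segment_breaks(t_start, t_end, boluses, infusions, [])

    y = (initial.as_array() if initial is not None else np.zeros(4)).astype(float)
    initial_amount = float(y.sum())
    A = _linear_matrix(p_mtx)

    out = np.empty((times.size, 4))
    idx = 0
    while idx < times.size and times[idx] <= t_start:
        out[idx] = y
        idx += 1
    for a, b in zip(breaks[:-1], breaks[1:]):
        for (tb, amt, ci) in boluses:
            if tb == a:
                y = y.copy()
                y[ci] += amt
        rc = sum(r for (t0, t1, r, ci) in infusions if t0 <= a < t1 and ci == 0)
        rp = sum(r for (t0, t1, r, ci) in infusions if t0 <= a < t1 and ci == 1)
        bvec = np.array([rc, rp, 0.0, 0.0])
        j = idx
        while j < times.size and times[j] <= b:
            j += 1
        t_cur = a
        for k, tq in enumerate(times[idx:j]):
            if tq > t_cur:
                y = _expm_step(A, y, bvec, tq - t_cur)
                t_cur = tq
            out[idx + k] = y
        if b > t_cur:
            y = _expm_step(A, y, bvec, b - t_cur)
        idx = j
    while idx < times.size:
        out[idx] = y
        idx += 1

    delivered = _delivered(times, boluses, infusions)
    return MtxProfile(times=times, conc=out[:, 0] / p_mtx.vc, xc=out[:, 0],
                      xp=out[:, 1], cum_renal=out[:, 2], cum_degraded=out[:, 3],
                      input_amount=delivered, initial_amount=initial_amount)
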