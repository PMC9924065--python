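"""Synthetic phase-1 and phase-2 cohorts.

The generator emulates the two study designs end to end so that every
downstream stage (estimation, diagnostics, limited-sampling forecasting)
runs without external data:

* Phase 1: 16 healthy adult volunteers in two CPG2 dose arms (20 and
  50 U/kg), a second dose at 48 h, and a dense CPG2 sampling schedule.
* Phase 2: patients with delayed MTX excretion after high-dose MTX, selected
  by the concentration/time eligibility table, dosed 50 U/kg CPG2 with a
  second dose when the plasma MTX concentration rebounds above 1 umol/L at
  the >=46 h check; CPG2 and MTX are sampled on their respective schedules
  with two window-sampled draws.

Assay censoring applies the published quantification limits; values below
the LLOQ are flagged (and dropped by estimation under the M1 convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .models import (
    MTX_MOLAR_MASS, DEFAULT_CPG2_UNITS_PER_MG,
    Covariates, Cpg2PopParams, MtxPopParams, DoseEvent,
    CPG2_FINAL_PHASE1, CPG2_FINAL_PHASE2, MTX_FINAL,
    cpg2_individual, mtx_individual, cpg2_conc, solve_mtx, solve_mtx_linear,
)
from .records import Observation, SubjectRecord, EligibilityState

__all__ = [
    "StudyDesign", "eligible_for_cpg2", "acute_renal_failure",
    "generate_cohort", "apply_residual_error", "censor_assay",
    "MTX_LLOQ_UMOL_L", "CPG2_LLOQ_MG_L",
]

#: assay lower limits of quantification
MTX_LLOQ_NG_ML = 0.5
MTX_ULOQ_NG_ML = 400.0
MTX_LLOQ_UMOL_L = MTX_LLOQ_NG_ML / MTX_MOLAR_MASS     # ~0.0011 umol/L
CPG2_LLOQ_MG_L = 1e-3                                 # 1 ng/ml
CPG2_ULOQ_MG_L = 640.0                                # 640 ug/ml

#: upper limit of the serum-creatinine reference range used by the acute
#: renal failure criterion, mg/dl
SCR_ULN_MG_DL = 1.2

# Phase-1 CPG2 schedule (h): first dose at 0 (pre, 5 min, 15 min, 2, 8, 12,
# 24, 48 h) and second dose at 48 h (+5 min, +8, +12, +24, +48 h).
PHASE1_FIRST_TIMES = (0.0, 5 / 60, 15 / 60, 2.0, 8.0, 12.0, 24.0, 48.0)
PHASE1_SECOND_OFFSETS = (5 / 60, 8.0, 12.0, 24.0, 48.0)

# Phase-2 schedules: fixed nominal times plus window draws.
PHASE2_CPG2_SCHEDULE = (("pre", 0.0), ("20min", 1 / 3), ("2h", 2.0),
                        ("5-8h", (5.0, 8.0)), ("12-20h", (12.0, 20.0)),
                        ("24h", 24.0), ("48h", 48.0))
PHASE2_MTX_SCHEDULE = (("pre", 0.0), ("20min", 1 / 3), ("2h", 2.0),
                       ("5-8h", (5.0, 8.0)), ("24h", 24.0), ("48h", 48.0))
PHASE2_MTX_SECOND_DOSE_TIMES = (("72h", 72.0), ("96h", 96.0))

# Table of selection rules: (threshold umol/L, hours, needs ARF, dose window g/m2)
_ELIGIBILITY_RULES = (
    (50.0, 22.0, False, None, ">=50 umol/L (22 h)"),
    (5.0, 40.0, False, None, ">=5 umol/L (40 h)"),
    (2.0, 46.0, False, None, ">=2 umol/L (46 h)"),
    (1.0, 40.0, True, None, ">=1 umol/L (40 h + ARF)"),
    (0.4, 46.0, True, None, ">=0.4 umol/L (46 h + ARF)"),
    (0.3, 70.0, False, (3.5, math.inf), ">=0.3 umol/L (70 h and >3.5 g/m2)"),
    (0.1, 70.0, False, (1.0, 3.5), ">=0.1 umol/L (70 h and 1-3.5 g/m2)"),
)


@dataclass(frozen=True)
class StudyDesign:
    """Study design: phase, cohort size, CPG2 dosing and sampling rules."""

    phase: int
    n_subjects: int
    cpg2_dose_u_per_kg: float = 50.0
    dose_groups: tuple = (20.0, 50.0)     # phase 1 only
    missing_prob: float = 0.0             # per-sample missingness

    def __post_init__(self) -> None:
        if self.phase not in (1, 2):
            raise ValueError("phase must be 1 or 2")
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if not 0.0 <= self.missing_prob < 1.0:
            raise ValueError("missing_prob must lie in [0, 1)")

    @classmethod
    def phase1(cls, n_subjects: int = 16, missing_prob: float = 0.0) -> "StudyDesign":
        return cls(phase=1, n_subjects=n_subjects, missing_prob=missing_prob)

    @classmethod
    def phase2(cls, n_subjects: int = 15, missing_prob: float = 0.0) -> "StudyDesign":
        return cls(phase=2, n_subjects=n_subjects, missing_prob=missing_prob)


def eligible_for_cpg2(state: EligibilityState):
    """First matching selection rule, or (False, None).

    Thresholds are >= on concentration, at or after the stated hour; the two
    70-h rules additionally condition on the HD-MTX dose intensity.
    """
    for (thr, hours, needs_arf, dose_win, label) in _ELIGIBILITY_RULES:
        if state.mtx_conc < thr or state.hours_post_mtx < hours:
            continue
        if needs_arf and not state.acute_renal_failure:
            continue
        if dose_win is not None:
            if state.mtx_dose_g_per_m2 is None:
                continue
            lo, hi = dose_win
            if not (lo <= state.mtx_dose_g_per_m2 <= hi):
                continue
        return True, label
    return False, None


def acute_renal_failure(scr_now: float | None = None,
                        scr_baseline: float | None = None,
                        scr_series=None,
                        ccr_or_gfr: float | None = None,
                        scr_uln: float = SCR_ULN_MG_DL) -> bool:
    """Acute renal failure per the selection-table footnote.

    Criterion (1): >=12 h after MTX, serum creatinine above the reference
    upper limit, or creatinine clearance / GFR below 70 ml/min.
    Criterion (2): serum creatinine at least doubled from baseline, or >=1.5x
    baseline for two consecutive, increasing measurements.
    """
    if scr_now is None and scr_baseline is None and scr_series is None \
            and ccr_or_gfr is None:
        raise ValueError("at least one criterion input must be provided")
    if ccr_or_gfr is not None and ccr_or_gfr < 70.0:
        return True
    if scr_now is not None and scr_now > scr_uln:
        return True
    if scr_now is not None and scr_baseline is not None \
            and scr_now >= 2.0 * scr_baseline:
        return True
    if scr_series is not None and scr_baseline is not None:
        s = list(scr_series)
        if len(s) >= 2 and s[-1] > s[-2] and all(v >= 1.5 * scr_baseline for v in s[-2:]):
            return True
    return False


def apply_residual_error(pred: float, analyte: str, sigma: float, rng):
    """Apply the residual error model: additive (mg/L) for CPG2, proportional
    for MTX.  Negative draws are floored at 0; the flag reports flooring."""
    eps = rng.normal(0.0, sigma) if sigma > 0 else 0.0
    if analyte == "CPG2":
        value = pred + eps
    elif analyte == "MTX":
        value = pred * (1.0 + eps)
    else:
        raise ValueError(f"unknown analyte {analyte!r}")
    if value < 0:
        return 0.0, True
    return value, False


def censor_assay(value: float, analyte: str):
    """Flag values below the assay LLOQ.  Values above the ULOQ are assumed
    diluted into range by the laboratory and are not right-censored."""
    if analyte == "MTX":
        return value, value < MTX_LLOQ_UMOL_L
    if analyte == "CPG2":
        return value, value < CPG2_LLOQ_MG_L
    raise ValueError(f"unknown analyte {analyte!r}")


def _phase1_covariates(rng) -> Covariates:
    # healthy adult male volunteers; printed demographic ranges
    return Covariates(
        height=rng.uniform(162.6, 184.8),
        body_weight=rng.uniform(54.3, 66.9),
        age=rng.uniform(20.0, 40.0),
        serum_creatinine=rng.uniform(0.6, 1.1),
    )


def _log_uniform(rng, lo: float, hi: float) -> float:
    return float(math.exp(rng.uniform(math.log(lo), math.log(hi))))


def _phase2_covariates(rng) -> Covariates:
    # weight log-uniform on the printed range; height tied to weight through
    # a weight-dependent BMI so that children stay child-sized
    w = _log_uniform(rng, 10.7, 78.1)
    bmi = 14.0 + 11.0 * (w - 10.7) / (78.1 - 10.7) + rng.normal(0.0, 1.0)
    h = min(max(100.0 * math.sqrt(w / max(bmi, 10.0)), 78.5), 177.5)
    return Covariates(
        height=h,
        body_weight=w,
        age=_log_uniform(rng, 1.0, 75.0),
        serum_creatinine=_log_uniform(rng, 0.23, 3.47),
    )


def _sample_obs(rng, analyte, schedule, truth_fn, sigma, missing_prob):
    obs = []
    for label, t in schedule:
        if missing_prob > 0 and rng.uniform() < missing_prob:
            continue
        pred = truth_fn(t)
        value, _floored = apply_residual_error(pred, analyte, sigma, rng)
        value, blq = censor_assay(value, analyte)
        obs.append(Observation(time=t, analyte=analyte, value=value,
                               below_lloq=blq, nominal=label))
    return obs


def _draw_windows(rng, schedule):
    """Realise window slots as actual sampled times; returns [(label, time)]."""
    out = []
    for label, t in schedule:
        if isinstance(t, tuple):
            out.append((label, float(rng.uniform(*t))))
        else:
            out.append((label, float(t)))
    return out


def _phase1_subject(i, arm_dose, pop, rng, units_per_mg, missing_prob):
    cov = _phase1_covariates(rng)
    eta = (rng.normal(0.0, math.sqrt(pop.omega2_cl)),
           rng.normal(0.0, math.sqrt(pop.omega2_v)))
    indiv = cpg2_individual(pop, cov, eta)
    amount = arm_dose * cov.body_weight
    doses = [DoseEvent(time=0.0, amount=amount, infusion_duration=5 / 60,
                       analyte="CPG2"),
             DoseEvent(time=48.0, amount=amount, infusion_duration=5 / 60,
                       analyte="CPG2")]
    times = list(PHASE1_FIRST_TIMES) + [48.0 + dt for dt in PHASE1_SECOND_OFFSETS]
    labels = ["pre", "5min", "15min", "2h", "8h", "12h", "24h", "48h",
              "48h+5min", "56h", "60h", "72h", "96h"]
    schedule = list(zip(labels, times))
    obs = _sample_obs(rng, "CPG2", schedule,
                      lambda t: cpg2_conc(t, doses, indiv, units_per_mg),
                      pop.sigma_add, missing_prob)
    return SubjectRecord(
        id=f"P1-{i:03d}", covariates=cov, doses=doses, observations=obs,
        cpg2_indiv=indiv,
        truth={"eta_cpg2": eta, "arm_dose_u_per_kg": arm_dose},
    )


def _phase2_eligibility(rng, c0, scr, mtx_dose_g_per_m2):
    """Choose hours-post-MTX (and the ARF flag) so the drawn baseline
    concentration satisfies a selection rule by construction."""
    uplift = _log_uniform(rng, 1.0, 3.0)     # Scr rise over baseline
    arf = acute_renal_failure(scr_now=scr, scr_baseline=scr / uplift)
    if c0 >= 50.0:
        hours = rng.uniform(22.0, 40.0)
    elif c0 >= 5.0:
        hours = rng.uniform(40.0, 46.0)
    elif c0 >= 2.0:
        hours = rng.uniform(46.0, 70.0)
    else:
        # below 2 umol/L only the ARF rule applies at the drawn range (>=1.02)
        arf = True
        hours = rng.uniform(40.0, 46.0)
    return EligibilityState(mtx_conc=c0, hours_post_mtx=hours,
                            acute_renal_failure=arf,
                            mtx_dose_g_per_m2=mtx_dose_g_per_m2), arf


def _phase2_subject(i, design, pop_cpg2, pop_mtx, rng, units_per_mg):
    cov = _phase2_covariates(rng)
    eta_c = (rng.normal(0.0, math.sqrt(pop_cpg2.omega2_cl)),
             rng.normal(0.0, math.sqrt(pop_cpg2.omega2_v)))
    eta_m = tuple(rng.normal(0.0, math.sqrt(w)) for w in
                  (pop_mtx.omega2_clr, pop_mtx.omega2_vc,
                   pop_mtx.omega2_vp, pop_mtx.omega2_alpha))
    p_cpg2 = cpg2_individual(pop_cpg2, cov, eta_c)
    p_mtx = mtx_individual(pop_mtx, cov, eta_m)

    # delayed-excretion phenotype: target pre-CPG2 MTX concentration
    c0 = _log_uniform(rng, 1.02, 692.32)
    dose_gm2_drawn = _log_uniform(rng, 2.9, 14.3)
    state, _arf = _phase2_eligibility(rng, c0, cov.serum_creatinine, dose_gm2_drawn)
    ok, rule = eligible_for_cpg2(state)
    assert ok, "generated phase-2 subject must satisfy a selection rule"

    # HD-MTX infusion (6 h) ending hours_post_mtx - 6 before CPG2; the linear
    # pre-CPG2 response is proportional to dose, so scale a unit infusion to
    # hit the target baseline concentration at t = 0.
    t_mtx = -state.hours_post_mtx
    unit_dose = DoseEvent(time=t_mtx, amount=1.0, infusion_duration=6.0,
                          analyte="MTX")
    c_unit = solve_mtx_linear([unit_dose], p_mtx, np.array([0.0])).conc[-1]
    amount_umol = c0 / c_unit
    dose_g = amount_umol * MTX_MOLAR_MASS * 1e-6
    state = EligibilityState(mtx_conc=c0, hours_post_mtx=state.hours_post_mtx,
                             acute_renal_failure=state.acute_renal_failure,
                             mtx_dose_g_per_m2=dose_g / cov.bsa)

    cpg2_amount = design.cpg2_dose_u_per_kg * cov.body_weight
    doses = [
        DoseEvent(time=t_mtx, amount=amount_umol, infusion_duration=6.0,
                  analyte="MTX"),
        DoseEvent(time=0.0, amount=cpg2_amount, infusion_duration=5 / 60,
                  analyte="CPG2"),
    ]

    cpg2_sched = _draw_windows(rng, PHASE2_CPG2_SCHEDULE)
    mtx_sched = _draw_windows(rng, PHASE2_MTX_SCHEDULE)
    # the 5-8 h draw is a single blood sample shared by the two assays
    shared = dict(cpg2_sched)["5-8h"]
    mtx_sched = [(lab, shared if lab == "5-8h" else t) for lab, t in mtx_sched]

    # second CPG2 dose when the (true) MTX concentration exceeds 1 umol/L at
    # the >=46 h check; administered at 48 h, extending the MTX schedule
    grid = np.unique(np.array([t for _l, t in mtx_sched] + [46.0, 48.0]))
    prof = solve_mtx(doses, p_mtx, p_cpg2, grid, units_per_mg=units_per_mg)
    second_dose = prof.at(46.0) > 1.0
    if second_dose:
        doses.append(DoseEvent(time=48.0, amount=cpg2_amount,
                               infusion_duration=5 / 60, analyte="CPG2"))
        mtx_sched = mtx_sched + list(PHASE2_MTX_SECOND_DOSE_TIMES)
        grid = np.unique(np.array([t for _l, t in mtx_sched] + [46.0, 48.0]))
        prof = solve_mtx(doses, p_mtx, p_cpg2, grid, units_per_mg=units_per_mg)

    def mtx_true(t: float) -> float:
        return prof.at(t)

    obs = _sample_obs(rng, "CPG2", cpg2_sched,
                      lambda t: cpg2_conc(t, doses, p_cpg2, units_per_mg),
                      pop_cpg2.sigma_add, design.missing_prob)
    obs += _sample_obs(rng, "MTX", mtx_sched, mtx_true,
                       pop_mtx.sigma_prop, design.missing_prob)
    obs.sort(key=lambda o: o.time)

    true_48 = prof.at(48.0)
    return SubjectRecord(
        id=f"P2-{i:03d}", covariates=cov, doses=doses, observations=obs,
        cpg2_indiv=p_cpg2,
        truth={"eta_cpg2": eta_c, "eta_mtx": eta_m, "c0": c0,
               "eligibility": state, "rule": rule, "second_dose": second_dose,
               "true_mtx_48h": true_48, "mtx_indiv": p_mtx},
    )


def generate_cohort(design: StudyDesign,
                    pop_cpg2: Cpg2PopParams | None = None,
                    pop_mtx: MtxPopParams | None = None,
                    seed: int | np.random.Generator = 0,
                    units_per_mg: float = DEFAULT_CPG2_UNITS_PER_MG):
    """Generate a reproducible synthetic cohort for the given design.

    Phase 1 uses the phase-1 CPG2 final model by default; phase 2 uses the
    phase-2 CPG2 final model together with the coupled MTX final model.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    records = []
    if design.phase == 1:
        pop = pop_cpg2 or CPG2_FINAL_PHASE1
        n_arms = len(design.dose_groups)
        for i in range(design.n_subjects):
            arm_dose = design.dose_groups[i % n_arms]
            records.append(_phase1_subject(i, arm_dose, pop, rng,
                                           units_per_mg, design.missing_prob))
    else:
        pop_c = pop_cpg2 or CPG2_FINAL_PHASE2
        pop_m = pop_mtx or MTX_FINAL
        for i in range(design.n_subjects):
            records.append(_phase2_subject(i, design, pop_c, pop_m, rng,
                                           units_per_mg))
    return records
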