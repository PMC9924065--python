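"""Longitudinal subject records: covariates, dosing history, observations."""

from __future__ import annotations

from dataclasses import dataclass, field

from .models import Covariates, DoseEvent, Cpg2IndivParams


@dataclass(frozen=True)
class Observation:
    """A single concentration measurement.

    ``value`` is in mg/L for CPG2 and umol/L for MTX.  ``nominal`` is the
    protocol label of the draw (e.g. 'pre', '20min', '5-8h') used to map
    window-sampled points back to their scheduled slot.
    """

    time: float
    analyte: str                 # {"CPG2", "MTX"}
    value: float
    below_lloq: bool = False
    nominal: str | None = None

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("observed concentrations must be non-negative")
        if self.analyte not in ("CPG2", "MTX"):
            raise ValueError(f"unknown analyte {self.analyte!r}")


@dataclass
class SubjectRecord:
    """One subject: covariates, dose events and observations (both analytes).

    ``cpg2_indiv`` optionally carries individual CPG2 parameters (truth from
    the simulator, or empirical-Bayes estimates attached by the estimation
    pipeline) used as the catalyst forcing in the coupled MTX model.
    ``truth`` holds simulator-only ground truth and is never serialised.
    """

    id: str
    covariates: Covariates
    doses: list[DoseEvent] = field(default_factory=list)
    observations: list[Observation] = field(default_factory=list)
    cpg2_indiv: Cpg2IndivParams | None = None
    truth: dict | None = None

    def obs(self, analyte: str, include_blq: bool = False) -> list[Observation]:
        return [o for o in self.observations
                if o.analyte == analyte and (include_blq or not o.below_lloq)]


@dataclass(frozen=True)
class EligibilityState:
    """Clinical state at the CPG2 treatment decision."""

    mtx_conc: float              # umol/L
    hours_post_mtx: float        # h since start of the HD-MTX infusion
    acute_renal_failure: bool = False
    mtx_dose_g_per_m2: float | None = None

    def __post_init__(self) -> None:
        if self.mtx_conc < 0 or self.hours_post_mtx < 0:
            raise ValueError("concentration and elapsed time must be non-negative")
        if self.mtx_dose_g_per_m2 is not None and self.mtx_dose_g_per_m2 < 0:
            raise ValueError("dose intensity must be non-negative")
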