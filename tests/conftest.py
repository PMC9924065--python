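import pytest

from cpg2mtx import (
    CPG2_FINAL_PHASE1, CPG2_FINAL_PHASE2, MTX_FINAL,
    Cpg2PopParams, MtxPopParams, StudyDesign, generate_cohort,
)


@pytest.fixture(scope="session")
def phase1_cohort():
    """Standard phase-1 design (16 healthy volunteers, two dose arms)."""
    return generate_cohort(StudyDesign.phase1(), seed=101)


@pytest.fixture(scope="session")
def phase2_cohort():
    """Small phase-2-like patient cohort under the published final models."""
    return generate_cohort(StudyDesign.phase2(n_subjects=8), seed=202)


@pytest.fixture(scope="session")
def phase2_noise_free_cohort():
    """Phase-2-like cohort with all variability switched off: observations
    equal the typical-value model predictions exactly."""
    pop_c = Cpg2PopParams(tv_cl=0.238, theta_cl=1.440, tv_v=1.200,
                          theta_v=1.561, omega2_cl=0.0, omega2_v=0.0,
                          sigma_add=0.0)
    pop_m = MtxPopParams(tv_clr=3.248, tv_vc=0.386, tv_vp=3.052,
                         tv_alpha=6.545e5, omega2_clr=0.0, omega2_vc=0.0,
                         omega2_vp=0.0, omega2_alpha=0.0, sigma_prop=0.0)
    return generate_cohort(StudyDesign.phase2(n_subjects=4), pop_cpg2=pop_c,
                           pop_mtx=pop_m, seed=303)
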