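"""Estimation-engine tests: Laplace/FOCE objective vs quadrature oracle,
population fitting, empirical-Bayes estimation, covariate selection."""

import math

import numpy as np
import pytest

from cpg2mtx import Covariates, Cpg2PopParams, StudyDesign, generate_cohort
from cpg2mtx.estimate import (
    Cpg2PopModel, fit_population, lrt_threshold, map_estimate, neg2ll,
    screen_covariates, stepwise_select,
)
from cpg2mtx.records import Observation, SubjectRecord


class TestLrtThreshold:
    def test_published_inclusion_threshold(self):
        assert lrt_threshold(1, 0.001) == pytest.approx(10.828, abs=5e-4)

    def test_conventional_threshold(self):
        assert lrt_threshold(1, 0.05) == pytest.approx(3.841, abs=5e-4)

    def test_monotone_in_p(self):
        ps = [0.2, 0.1, 0.05, 0.01, 0.001]
        vals = [lrt_threshold(1, p) for p in ps]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("df,p", [(0, 0.05), (1, 0.0), (1, 1.0), (1, -1)])
    def test_invalid_inputs(self, df, p):
        with pytest.raises(ValueError):
            lrt_threshold(df, p)


class Toy1EtaModel:
    """Monoexponential bolus model with one random effect on clearance and
    additive error — small enough for exact marginal likelihood by
    Gauss-Hermite quadrature."""

    analyte = "CPG2"
    error = "additive"
    eta_names = ("cl",)
    smooth_objective = True

    def __init__(self, dose=100.0, v=10.0):
        self.dose = dose
        self.v = v

    def param_names(self):
        return ["tv_cl", "omega2_cl", "sigma_add"]

    def observations(self, rec):
        obs = rec.obs("CPG2")
        return (np.array([o.time for o in obs]),
                np.array([o.value for o in obs]))

    def predict(self, rec, params, eta, times=None):
        if times is None:
            times = self.observations(rec)[0]
        cl = params["tv_cl"] * math.exp(eta[0])
        return self.dose / self.v * np.exp(-cl / self.v
                                           * np.asarray(times, float))

    def omega2(self, params):
        return np.array([params["omega2_cl"]])

    def sigma(self, params):
        return params["sigma_add"]

    def indiv(self, params, cov, eta):
        return {"cl": params["tv_cl"] * math.exp(eta[0])}


def _toy_subject(sid, model, params, eta, rng, times=(1.0, 2.0, 4.0, 8.0)):
    cov = Covariates(body_weight=60, height=170)
    f = model.dose / model.v * np.exp(-params["tv_cl"] * math.exp(eta[0])
                                      / model.v * np.asarray(times))
    y = f + rng.normal(0, params["sigma_add"], size=len(times))
    obs = [Observation(time=t, analyte="CPG2", value=max(v, 0.0))
           for t, v in zip(times, y)]
    return SubjectRecord(id=sid, covariates=cov, observations=obs)


def _gauss_hermite_neg2ll(model, dataset, params, n_nodes=60):
    """Independent oracle: marginal -2LL by adaptive Gauss-Hermite
    quadrature over the single random effect.  The nodes are centred and
    scaled at the mode/curvature of the integrand found by a 1-D golden
    search (independent of the package's inner Newton solver)."""
    from scipy.optimize import minimize_scalar

    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    omega2 = params["omega2_cl"]
    sigma = params["sigma_add"]
    total = 0.0
    for rec in dataset:
        times, y = model.observations(rec)

        def log_g(eta):
            f = model.predict(rec, params, [eta], times)
            r = y - f
            return (-0.5 * float(np.sum(r * r)) / sigma ** 2
                    - times.size * math.log(math.sqrt(2 * math.pi) * sigma)
                    - 0.5 * eta * eta / omega2
                    - 0.5 * math.log(2 * math.pi * omega2))

        res = minimize_scalar(lambda e: -log_g(e), bounds=(-8.0, 8.0),
                              method="bounded",
                              options={"xatol": 1e-10})
        mode = res.x
        d = 1e-4
        curv = -(log_g(mode + d) - 2 * log_g(mode) + log_g(mode - d)) / d ** 2
        scale = math.sqrt(2.0 / curv)
        # log of integral exp(log_g) via adaptive GH with log-sum-exp
        terms = [math.log(w) + x * x + log_g(mode + scale * x)
                 for x, w in zip(nodes, weights)]
        m = max(terms)
        log_int = math.log(scale) + m + math.log(
            sum(math.exp(t - m) for t in terms))
        total += -2.0 * log_int
    return total


class TestObjectiveOracle:
    def test_matches_gauss_hermite(self):
        """Laplace/FOCE approximation vs exact quadrature across a grid of
        population parameters, within 0.1 OFV units."""
        model = Toy1EtaModel()
        rng = np.random.default_rng(8)
        truth = {"tv_cl": 1.0, "omega2_cl": 0.1, "sigma_add": 0.2}
        dataset = [_toy_subject(f"T{i}", model, truth,
                                [rng.normal(0, math.sqrt(0.1))], rng)
                   for i in range(2)]
        for tv in (0.8, 1.0, 1.25):
            for om2 in (0.04, 0.1, 0.25):
                for sg in (0.15, 0.3):
                    params = {"tv_cl": tv, "omega2_cl": om2, "sigma_add": sg}
                    approx, _ = neg2ll(params, dataset, model)
                    exact = _gauss_hermite_neg2ll(model, dataset, params)
                    assert approx == pytest.approx(exact, abs=0.1), \
                        f"mismatch at {params}"

    def test_shrinks_to_els_deviance_as_omega_vanishes(self):
        model = Toy1EtaModel()
        rng = np.random.default_rng(9)
        params = {"tv_cl": 1.0, "omega2_cl": 1e-12, "sigma_add": 0.2}
        dataset = [_toy_subject("T0", model, params, [0.15], rng)]
        times, y = model.observations(dataset[0])
        f = model.predict(dataset[0], params, [0.0], times)
        els = float(np.sum((y - f) ** 2 / 0.2 ** 2
                           + np.log(2 * np.pi * 0.2 ** 2)))
        val, _ = neg2ll(params, dataset, model)
        assert val == pytest.approx(els, abs=1e-3)

    def test_additive_over_subjects_and_label_invariant(self):
        model = Toy1EtaModel()
        rng = np.random.default_rng(10)
        params = {"tv_cl": 1.0, "omega2_cl": 0.1, "sigma_add": 0.2}
        rec = _toy_subject("A", model, params, [0.2], rng)
        twin = SubjectRecord(id="B", covariates=rec.covariates,
                             observations=rec.observations)
        v1, _ = neg2ll(params, [rec], model)
        v2, _ = neg2ll(params, [rec, twin], model)
        assert v2 == pytest.approx(2 * v1, rel=1e-9)
        relabeled = SubjectRecord(id="Z9", covariates=rec.covariates,
                                  observations=rec.observations)
        v3, _ = neg2ll(params, [relabeled], model)
        assert v3 == pytest.approx(v1, rel=1e-12)


def _noise_free_phase2_cpg2(n, seed):
    pop = Cpg2PopParams(tv_cl=0.238, theta_cl=1.440, tv_v=1.200,
                        theta_v=1.561)
    return generate_cohort(StudyDesign.phase2(n_subjects=n), pop_cpg2=pop,
                           seed=seed), pop


class TestFitPopulation:
    def test_noise_free_recovery_within_one_percent(self):
        cohort, pop = _noise_free_phase2_cpg2(10, seed=21)
        model = Cpg2PopModel()
        init = model.init_from(pop)
        init.update(tv_cl=pop.tv_cl * 1.25, tv_v=pop.tv_v * 0.8,
                    theta_cl_bsa=1.0, theta_v_bsa=1.0,
                    omega2_cl=1e-6, omega2_v=1e-6, sigma_add=1e-3)
        fit = fit_population(cohort, model, init,
                             fix=("omega2_cl", "omega2_v", "sigma_add"),
                             compute_se=False)
        assert fit.converged
        assert fit.params["tv_cl"] == pytest.approx(0.238, rel=0.01)
        assert fit.params["tv_v"] == pytest.approx(1.200, rel=0.01)
        assert fit.params["theta_cl_bsa"] == pytest.approx(1.440, abs=0.05)

    def test_refit_from_own_optimum_does_not_increase_ofv(self):
        cohort, pop = _noise_free_phase2_cpg2(6, seed=22)
        model = Cpg2PopModel()
        init = dict(model.init_from(pop), omega2_cl=1e-6, omega2_v=1e-6,
                    sigma_add=1e-3)
        fix = ("omega2_cl", "omega2_v", "sigma_add")
        fit1 = fit_population(cohort, model, init, fix=fix, compute_se=False)
        fit2 = fit_population(cohort, model, fit1.params, fix=fix,
                              compute_se=False)
        assert fit2.ofv <= fit1.ofv + 1e-6

    def test_standard_errors_reported_positive(self):
        cohort = generate_cohort(StudyDesign.phase2(n_subjects=12), seed=23)
        model = Cpg2PopModel()
        from cpg2mtx import CPG2_FINAL_PHASE2
        fit = fit_population(cohort, model, model.init_from(CPG2_FINAL_PHASE2))
        assert fit.se is not None
        assert fit.se["tv_cl"] > 0 and np.isfinite(fit.se["tv_cl"])

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            fit_population([], Cpg2PopModel(), {})

    def test_incomplete_init_rejected(self):
        cohort, _pop = _noise_free_phase2_cpg2(2, seed=24)
        with pytest.raises(ValueError, match="missing"):
            fit_population(cohort, Cpg2PopModel(), {"tv_cl": 0.2})


class TestMapEstimate:
    def test_no_observations_returns_prior_mode(self):
        model = Toy1EtaModel()
        cov = Covariates(body_weight=60, height=170)
        rec = SubjectRecord(id="E", covariates=cov, observations=[])
        res = map_estimate(rec, model,
                           {"tv_cl": 1.0, "omega2_cl": 0.1, "sigma_add": 0.2})
        assert res.at_prior_mode and res.n_obs == 0
        assert np.all(res.eta == 0.0)

    def test_recovers_true_eta_as_noise_vanishes(self):
        model = Toy1EtaModel()
        cov = Covariates(body_weight=60, height=170)
        eta_star = 0.4
        params = {"tv_cl": 1.0, "omega2_cl": 0.25, "sigma_add": 1e-5}
        times = np.array([1.0, 2.0, 4.0, 8.0])
        f = model.dose / model.v * np.exp(-math.exp(eta_star) / model.v * times)
        rec = SubjectRecord(id="S", covariates=cov, observations=[
            Observation(time=t, analyte="CPG2", value=v)
            for t, v in zip(times, f)])
        res = map_estimate(rec, model, params)
        assert res.eta[0] == pytest.approx(eta_star, abs=1e-3)

    def test_invariant_to_observation_order(self, phase2_cohort):
        from cpg2mtx import CPG2_FINAL_PHASE2
        model = Cpg2PopModel()
        params = model.init_from(CPG2_FINAL_PHASE2)
        rec = phase2_cohort[0]
        times, values = model.observations(rec)
        fwd = map_estimate(rec, model, params, observations=(times, values))
        rev = map_estimate(rec, model, params,
                           observations=(times[::-1], values[::-1]))
        np.testing.assert_allclose(fwd.eta, rev.eta, atol=1e-6)


def _covariate_cohort(n, seed, theta_cl=1.440, theta_v=1.561):
    pop = Cpg2PopParams(tv_cl=0.238, theta_cl=theta_cl, tv_v=1.200,
                        theta_v=theta_v,
                        omega2_cl=0.03, omega2_v=0.05, sigma_add=0.1)
    return generate_cohort(StudyDesign.phase2(n_subjects=n), pop_cpg2=pop,
                           seed=seed), pop


class TestCovariateSelection:
    def test_true_covariate_ranks_first(self):
        cohort, _ = _covariate_cohort(16, seed=31)
        base = Cpg2PopModel(cov_cl=(), cov_v=())
        init = {"tv_cl": 0.2, "tv_v": 1.0, "omega2_cl": 0.05,
                "omega2_v": 0.05, "sigma_add": 0.1}
        rows = screen_covariates(cohort, base, init, ["bsa", "age"])
        assert rows[0].covariate == "bsa"
        assert rows[0].delta_ofv > lrt_threshold(1, 0.001)
        bsa_best = max(r.delta_ofv for r in rows if r.covariate == "bsa")
        age_best = max(r.delta_ofv for r in rows if r.covariate == "age")
        assert bsa_best > age_best

    def test_null_covariate_calibration(self):
        """With no covariate effect in truth, the OFV drop for a spurious
        candidate should stay below the 5% threshold in most replicates."""
        base = Cpg2PopModel(cov_cl=(), cov_v=())
        init = {"tv_cl": 0.238, "tv_v": 1.2, "omega2_cl": 0.03,
                "omega2_v": 0.05, "sigma_add": 0.1}
        below = 0
        n_rep = 5
        for rep in range(n_rep):
            cohort, _ = _covariate_cohort(10, seed=400 + rep,
                                          theta_cl=0.0, theta_v=0.0)
            rows = screen_covariates(cohort, base, init, ["age"],
                                     targets=("cl",))
            if rows[0].delta_ofv < lrt_threshold(1, 0.05):
                below += 1
        assert below >= n_rep - 1

    def test_empty_candidates(self):
        cohort, _ = _covariate_cohort(4, seed=33)
        base = Cpg2PopModel(cov_cl=(), cov_v=())
        init = {"tv_cl": 0.238, "tv_v": 1.2, "omega2_cl": 0.03,
                "omega2_v": 0.05, "sigma_add": 0.1}
        assert screen_covariates(cohort, base, init, []) == []

    def test_stepwise_recovers_bsa_on_cl_and_v(self):
        cohort, _ = _covariate_cohort(20, seed=34)
        base = Cpg2PopModel(cov_cl=(), cov_v=())
        init = {"tv_cl": 0.2, "tv_v": 1.0, "omega2_cl": 0.05,
                "omega2_v": 0.05, "sigma_add": 0.1}
        model, fit, history = stepwise_select(cohort, base, init, ["bsa"])
        assert model.cov_cl == ("bsa",) and model.cov_v == ("bsa",)

    def test_stepwise_null_keeps_base(self):
        cohort, _ = _covariate_cohort(10, seed=35, theta_cl=0.0, theta_v=0.0)
        base = Cpg2PopModel(cov_cl=(), cov_v=())
        init = {"tv_cl": 0.238, "tv_v": 1.2, "omega2_cl": 0.03,
                "omega2_v": 0.05, "sigma_add": 0.1}
        model, fit, history = stepwise_select(cohort, base, init, ["age"])
        assert model.cov_cl == () and model.cov_v == ()
        assert len(history) == 1

    def test_candidate_already_in_base_is_noop(self):
        cohort, _ = _covariate_cohort(6, seed=36)
        base = Cpg2PopModel()          # BSA already on CL and V
        init = dict(base.init_from(Cpg2PopParams(
            tv_cl=0.238, theta_cl=1.44, tv_v=1.2, theta_v=1.561,
            omega2_cl=0.03, omega2_v=0.05, sigma_add=0.1)))
        model, fit, history = stepwise_select(cohort, base, init, ["bsa"])
        assert model.cov_cl == ("bsa",) and model.cov_v == ("bsa",)
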