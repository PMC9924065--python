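"""Population estimation for the CPG2 and coupled CPG2-MTX models.

The marginal likelihood of the nonlinear mixed-effects model is approximated
in the FOCE/Laplace family: for each subject the conditional mode of the
random effects eta is found by damped Gauss-Newton on the penalised deviance

    h(eta) = 1/2 sum_j [ r_j^2 / g_j^2 + log(2 pi g_j^2) ] + 1/2 eta' O^-1 eta

(r = residual, g = error-model SD, O = diagonal IIV covariance), and the
subject's -2 log-likelihood contribution is the Laplace expression at the
mode with a Gauss-Newton Hessian,

    -2 ll_i = dev(eta^) + eta^' O^-1 eta^ + log det(O H),   H = O^-1 + J' W J.

The outer problem minimises the summed objective function value (OFV) over
the fixed effects, IIV variances and residual variance on log-transformed
positive parameters: bounded quasi-Newton for closed-form models, and a
derivative-free quadratic trust-region search for ODE-based models whose
objective carries adaptive-integration noise.  Standard errors come from a
central-difference Hessian of the approximate -2LL.

Also provided: empirical-Bayes (MAP / post hoc) individual estimation,
likelihood-ratio thresholds, one-at-a-time covariate screening and
forward-backward stepwise selection for the CPG2 power-covariate model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.stats import chi2

from .models import (
    DEFAULT_CPG2_UNITS_PER_MG,
    Cpg2PopParams, MtxPopParams, Cpg2IndivParams, MtxIndivParams,
    mtx_individual, cpg2_conc, solve_mtx,
)
from .records import SubjectRecord

__all__ = [
    "FitResult", "CovariateScreenRow", "Cpg2PopModel", "MtxPopModel",
    "neg2ll", "fit_population", "map_estimate", "MapResult",
    "lrt_threshold", "screen_covariates", "stepwise_select",
    "attach_cpg2_ebes",
]

_LOG2PI = math.log(2.0 * math.pi)
#: floor (in prediction units) inside the proportional-error SD so that a
#: transiently zero prediction cannot produce an infinite weight
_PROP_FLOOR = 1e-6
#: floor on IIV variances when inverting the diagonal Omega
_OMEGA_FLOOR = 1e-10


def lrt_threshold(df: int, p: float) -> float:
    """Critical OFV drop for a likelihood-ratio test: chi-square upper
    quantile with ``df`` degrees of freedom at level ``p``."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie strictly between 0 and 1")
    return float(chi2.ppf(1.0 - p, df))


# ---------------------------------------------------------------------------
# Population models
# ---------------------------------------------------------------------------

class Cpg2PopModel:
    """CPG2 one-compartment population model with power covariates.

    ``cov_cl`` / ``cov_v`` are tuples of covariate attribute names entering
    CL and V as ``tv * prod(cov**theta) * exp(eta)``.  Residual error is
    additive (mg/L).
    """

    analyte = "CPG2"
    error = "additive"
    eta_names = ("cl", "v")
    smooth_objective = True     # closed-form predictions
    laplace_hessian = "exact"

    def __init__(self, cov_cl: Sequence[str] = ("bsa",),
                 cov_v: Sequence[str] = ("bsa",),
                 units_per_mg: float = DEFAULT_CPG2_UNITS_PER_MG):
        self.cov_cl = tuple(cov_cl)
        self.cov_v = tuple(cov_v)
        self.units_per_mg = units_per_mg

    def with_terms(self, cov_cl=None, cov_v=None) -> "Cpg2PopModel":
        return Cpg2PopModel(
            cov_cl=self.cov_cl if cov_cl is None else cov_cl,
            cov_v=self.cov_v if cov_v is None else cov_v,
            units_per_mg=self.units_per_mg)

    def param_names(self) -> list[str]:
        names = ["tv_cl"] + [f"theta_cl_{c}" for c in self.cov_cl]
        names += ["tv_v"] + [f"theta_v_{c}" for c in self.cov_v]
        names += ["omega2_cl", "omega2_v", "sigma_add"]
        return names

    def init_from(self, pop: Cpg2PopParams) -> dict:
        """Initial parameter dict from a :class:`Cpg2PopParams` (exponents
        are mapped onto the model's BSA terms when present, else 0)."""
        params = {"tv_cl": pop.tv_cl, "tv_v": pop.tv_v,
                  "omega2_cl": pop.omega2_cl, "omega2_v": pop.omega2_v,
                  "sigma_add": pop.sigma_add}
        for c in self.cov_cl:
            params[f"theta_cl_{c}"] = pop.theta_cl if c == "bsa" else 0.0
        for c in self.cov_v:
            params[f"theta_v_{c}"] = pop.theta_v if c == "bsa" else 0.0
        return params

    def indiv(self, params: dict, cov, eta) -> Cpg2IndivParams:
        cl = params["tv_cl"] * math.exp(eta[0])
        for c in self.cov_cl:
            cl *= getattr(cov, c) ** params[f"theta_cl_{c}"]
        v = params["tv_v"] * math.exp(eta[1])
        for c in self.cov_v:
            v *= getattr(cov, c) ** params[f"theta_v_{c}"]
        return Cpg2IndivParams(cl=cl, v=v, eta_cl=eta[0], eta_v=eta[1])

    def observations(self, rec: SubjectRecord):
        obs = rec.obs("CPG2")
        return (np.array([o.time for o in obs]),
                np.array([o.value for o in obs]))

    def predict(self, rec: SubjectRecord, params: dict, eta,
                times=None) -> np.ndarray:
        if times is None:
            times = self.observations(rec)[0]
        p = self.indiv(params, rec.covariates, eta)
        return np.atleast_1d(cpg2_conc(np.asarray(times, dtype=float),
                                       rec.doses, p, self.units_per_mg))

    def omega2(self, params: dict) -> np.ndarray:
        return np.array([params["omega2_cl"], params["omega2_v"]])

    def sigma(self, params: dict) -> float:
        return params["sigma_add"]


class MtxPopModel:
    """Coupled MTX two-compartment population model.

    The catalyst (CPG2) forcing uses each subject's individual CPG2
    parameters (``rec.cpg2_indiv`` — simulator truth or empirical-Bayes
    estimates attached by :func:`attach_cpg2_ebes`).  Covariate modes:
    ``'final'`` (BW/Scr/60 on CLr, BW/BSA on Vc, BW/60 on Vp) or ``'none'``.
    Residual error is proportional.
    """

    analyte = "MTX"
    error = "proportional"
    eta_names = ("clr", "vc", "vp", "alpha")
    smooth_objective = False    # adaptive ODE solves leave truncation noise
    inner_max_iter = 8          # warm-started modes converge in a few steps
    inner_j_refresh = 2         # chord Gauss-Newton on the costly Jacobian
    laplace_hessian = "gn"      # Gauss-Newton (FOCE-I) form: 1 solve vs 13

    def __init__(self, q_fixed: float = 0.0778, km_fixed: float = 86.0,
                 covariates: str = "final", knr_de: float = 0.0,
                 units_per_mg: float = DEFAULT_CPG2_UNITS_PER_MG,
                 rtol: float = 1e-6, atol: float = 1e-6,
                 max_steps: int = 8000):
        if covariates not in ("final", "none"):
            raise ValueError("covariates must be 'final' or 'none'")
        self.q_fixed = q_fixed
        self.km_fixed = km_fixed
        self.covariates = covariates
        self.knr_de = knr_de
        self.units_per_mg = units_per_mg
        self.rtol = rtol
        self.atol = atol
        self.max_steps = max_steps

    def param_names(self) -> list[str]:
        return ["tv_clr", "tv_vc", "tv_vp", "tv_alpha",
                "omega2_clr", "omega2_vc", "omega2_vp", "omega2_alpha",
                "sigma_prop"]

    def init_from(self, pop: MtxPopParams) -> dict:
        return {"tv_clr": pop.tv_clr, "tv_vc": pop.tv_vc, "tv_vp": pop.tv_vp,
                "tv_alpha": pop.tv_alpha, "omega2_clr": pop.omega2_clr,
                "omega2_vc": pop.omega2_vc, "omega2_vp": pop.omega2_vp,
                "omega2_alpha": pop.omega2_alpha, "sigma_prop": pop.sigma_prop}

    def indiv(self, params: dict, cov, eta) -> MtxIndivParams:
        pop = MtxPopParams(
            tv_clr=params["tv_clr"], tv_vc=params["tv_vc"],
            tv_vp=params["tv_vp"], tv_alpha=params["tv_alpha"],
            q_fixed=self.q_fixed, km_fixed=self.km_fixed)
        if self.covariates == "final":
            return mtx_individual(pop, cov, eta, knr_de=self.knr_de)
        e = [float(x) for x in eta]
        return MtxIndivParams(
            clr=pop.tv_clr * math.exp(e[0]), vc=pop.tv_vc * math.exp(e[1]),
            vp=pop.tv_vp * math.exp(e[2]), alpha=pop.tv_alpha * math.exp(e[3]),
            q=self.q_fixed, km=self.km_fixed, knr_de=self.knr_de,
            etas=tuple(e))

    def observations(self, rec: SubjectRecord):
        obs = rec.obs("MTX")
        return (np.array([o.time for o in obs]),
                np.array([o.value for o in obs]))

    def predict(self, rec: SubjectRecord, params: dict, eta,
                times=None) -> np.ndarray:
        if times is None:
            times = self.observations(rec)[0]
        times = np.asarray(times, dtype=float)
        if times.size == 0:
            return np.zeros(0)
        p = self.indiv(params, rec.covariates, eta)
        order = np.argsort(times, kind="stable")
        prof = solve_mtx(rec.doses, p, rec.cpg2_indiv, times[order],
                         units_per_mg=self.units_per_mg,
                         rtol=self.rtol, atol=self.atol,
                         max_steps=self.max_steps)
        out = np.empty_like(prof.conc)
        out[order] = prof.conc
        return out

    def omega2(self, params: dict) -> np.ndarray:
        return np.array([params["omega2_clr"], params["omega2_vc"],
                         params["omega2_vp"], params["omega2_alpha"]])

    def sigma(self, params: dict) -> float:
        return params["sigma_prop"]


def attach_cpg2_ebes(dataset: Sequence[SubjectRecord], cpg2_model: Cpg2PopModel,
                     cpg2_params: dict) -> None:
    """Attach empirical-Bayes CPG2 individual parameters to each record for
    use as the catalyst forcing in the coupled MTX model (sequential
    two-stage coupling)."""
    for rec in dataset:
        res = map_estimate(rec, cpg2_model, cpg2_params)
        rec.cpg2_indiv = res.indiv


# ---------------------------------------------------------------------------
# FOCE/Laplace engine
# ---------------------------------------------------------------------------

def _error_var(model, f: np.ndarray, sigma: float) -> np.ndarray:
    if model.error == "additive":
        return np.full_like(f, sigma * sigma)
    return sigma * sigma * (f * f + _PROP_FLOOR * _PROP_FLOOR)


def _deviance(model, y: np.ndarray, f: np.ndarray, sigma: float) -> float:
    g2 = _error_var(model, f, sigma)
    r = y - f
    return float(np.sum(r * r / g2 + np.log(2.0 * math.pi * g2)))


def _jacobian(model, rec, params, eta, times, f0, step: float = 1e-4):
    """Forward-difference Jacobian of the prediction wrt eta."""
    k = len(eta)
    J = np.empty((f0.size, k))
    for i in range(k):
        e = np.array(eta, dtype=float)
        e[i] += step
        J[:, i] = (model.predict(rec, params, e, times) - f0) / step
    return J


def _h_value(model, rec, params, eta, times, y, sigma, omega_inv):
    try:
        f = model.predict(rec, params, eta, times)
    except (OverflowError, FloatingPointError, RuntimeError):
        return math.inf, None
    if not np.all(np.isfinite(f)):
        return math.inf, None
    dev = _deviance(model, y, f, sigma)
    return 0.5 * (dev + float(eta @ (omega_inv * eta))), f


def _inner_mode(model, rec, params, times, y, sigma, omega_inv,
                eta0=None, max_iter: int = 50, tol: float = 1e-6):
    """Conditional mode of eta by damped Gauss-Newton with line search.

    Returns (eta_hat, f_hat, J_hat, H_gn, converged).
    """
    k = len(model.eta_names)
    eta = np.zeros(k) if eta0 is None else np.array(eta0, dtype=float)
    h, f = _h_value(model, rec, params, eta, times, y, sigma, omega_inv)
    if np.any(eta):
        # a stale warm start can sit in the wrong basin; never start worse
        # than the prior mode
        h0, f0 = _h_value(model, rec, params, np.zeros(k), times, y, sigma,
                          omega_inv)
        if f is None or (f0 is not None and h0 < h):
            eta, h, f = np.zeros(k), h0, f0
    if f is None:
        raise RuntimeError("model prediction failed at the prior mode")
    converged = False
    J = np.zeros((y.size, k))
    j_refresh = getattr(model, "inner_j_refresh", 1)
    for it in range(max_iter):
        if it % j_refresh == 0:
            # chord Gauss-Newton: models with expensive predictions reuse
            # the Jacobian for a few steps
            J = _jacobian(model, rec, params, eta, times, f)
        g2 = _error_var(model, f, sigma)
        r = y - f
        if model.error == "additive":
            ddev_df = -2.0 * r / g2
        else:
            s2 = sigma * sigma
            ddev_df = -2.0 * r / g2 + (2.0 * s2 * f / g2) * (1.0 - r * r / g2)
        grad = 0.5 * (J.T @ ddev_df) + omega_inv * eta
        H = np.diag(omega_inv) + J.T @ (J / g2[:, None])
        gnorm = float(np.max(np.abs(grad)))
        if gnorm < tol * (1.0 + abs(h)):
            converged = True
            break
        try:
            step = -np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = -grad
        # trust cap on the log-scale random effects
        smax = float(np.max(np.abs(step)))
        if smax > 3.0:
            step *= 3.0 / smax
        lam, ok = 1.0, False
        for _ls in range(12):
            h_new, f_new = _h_value(model, rec, params, eta + lam * step,
                                    times, y, sigma, omega_inv)
            if h_new < h - 1e-4 * lam * float(grad @ step) or h_new < h:
                eta = eta + lam * step
                h, f = h_new, f_new
                ok = True
                break
            lam *= 0.5
        if not ok:
            converged = True  # no further descent possible
            break
        if float(np.max(np.abs(lam * step))) < 1e-10:
            converged = True
            break
    # refresh linearisation at the mode
    J = _jacobian(model, rec, params, eta, times, f)
    g2 = _error_var(model, f, sigma)
    H = np.diag(omega_inv) + J.T @ (J / g2[:, None])
    return eta, f, J, H, converged


def _exact_h_hessian(model, rec, params, eta, times, y, sigma, omega_inv,
                     step: float = 1e-3):
    """Central-difference Hessian of the penalised deviance h at the mode
    (full Laplace; more accurate than the Gauss-Newton form for strongly
    nonlinear predictions)."""
    k = eta.size

    def h(e):
        return _h_value(model, rec, params, e, times, y, sigma, omega_inv)[0]

    h0 = h(eta)
    H = np.empty((k, k))
    for i in range(k):
        ei = np.zeros(k); ei[i] = step
        H[i, i] = (h(eta + ei) - 2.0 * h0 + h(eta - ei)) / step ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k); ej[j] = step
            H[i, j] = H[j, i] = (h(eta + ei + ej) - h(eta + ei - ej)
                                 - h(eta - ei + ej) + h(eta - ei - ej)) \
                / (4.0 * step ** 2)
    return H


def _subject_neg2ll(model, rec, params, omega2, sigma, eta0=None,
                    times=None, y=None):
    """Laplace -2LL contribution of one subject (and the mode)."""
    if times is None or y is None:
        times, y = model.observations(rec)
    k = len(model.eta_names)
    if y.size == 0:
        return 0.0, np.zeros(k), True
    om = np.maximum(omega2, _OMEGA_FLOOR)
    omega_inv = 1.0 / om
    eta, f, J, H, conv = _inner_mode(model, rec, params, times, y, sigma,
                                     omega_inv, eta0=eta0,
                                     max_iter=getattr(model, "inner_max_iter", 50))
    if getattr(model, "laplace_hessian", "exact") == "exact":
        He = _exact_h_hessian(model, rec, params, eta, times, y, sigma,
                              omega_inv)
        # fall back to the Gauss-Newton form if differencing is indefinite
        if np.all(np.isfinite(He)) and np.all(np.linalg.eigvalsh(He) > 0):
            H = He
    dev = _deviance(model, y, f, sigma)
    # log det(Omega H) = log det(I + Omega J'WJ), zero when data carry no
    # information about eta
    sign, logdet = np.linalg.slogdet(np.diag(om) @ H)
    if sign <= 0:
        logdet = 0.0
    val = dev + float(eta @ (omega_inv * eta)) + logdet
    return val, eta, conv


def neg2ll(params: dict, dataset: Sequence[SubjectRecord], model,
           etas: dict | None = None, on_inner_failure: str = "keep"):
    """Approximate population -2 log-likelihood (OFV), additive over subjects.

    ``etas`` (id -> eta array) serves as warm start and is updated in place.
    ``on_inner_failure``: 'keep' uses the best iterate, 'skip' drops the
    subject, 'raise' errors.
    """
    omega2 = model.omega2(params)
    sigma = model.sigma(params)
    if sigma <= 0:
        raise ValueError("residual SD must be positive for estimation")
    total = 0.0
    store = etas if etas is not None else {}
    for rec in dataset:
        val, eta, conv = _subject_neg2ll(model, rec, params, omega2, sigma,
                                         eta0=store.get(rec.id))
        if not conv:
            if on_inner_failure == "raise":
                raise RuntimeError(f"inner optimisation failed for {rec.id}")
            if on_inner_failure == "skip":
                continue
        store[rec.id] = eta
        total += val
    return total, store


# ---------------------------------------------------------------------------
# Outer optimisation
# ---------------------------------------------------------------------------

def _transform_kind(name: str) -> str:
    return "lin" if name.startswith("theta_") else "log"


def _to_x(params: dict, free: list[str]) -> np.ndarray:
    out = []
    for n in free:
        v = params[n]
        if _transform_kind(n) == "log":
            out.append(math.log(max(v, 1e-12)))
        else:
            out.append(v)
    return np.array(out)


def _from_x(x: np.ndarray, free: list[str], base: dict) -> dict:
    params = dict(base)
    for n, v in zip(free, x):
        params[n] = math.exp(v) if _transform_kind(n) == "log" else float(v)
    return params


def _quad_features(z: np.ndarray) -> np.ndarray:
    """Feature vector [1, z, z_i z_j (i<=j)] of a full quadratic model."""
    n = z.size
    feats = [1.0] + list(z)
    for i in range(n):
        for j in range(i, n):
            feats.append(z[i] * z[j])
    return np.array(feats)


def _minimize_quadratic_tr(obj, x0: np.ndarray, bounds,
                           radius: float = 0.25, n_rounds: int = 3,
                           shrink: float = 0.4):
    """Derivative-free trust-region minimisation via local quadratic
    response-surface fits.

    Designed for objectives that are smooth apart from small evaluation
    noise (adaptive-ODE marginal likelihoods): each round evaluates a
    center/axial/pairwise stencil of scale ``radius``, fits a full quadratic
    by least squares, and steps to its constrained minimiser; the radius
    shrinks each round.  Cost is ~(n^2/2 + 2n + 2) evaluations per round.
    """
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    x = np.clip(np.asarray(x0, dtype=float), lo, hi)
    n = x.size
    f_best = obj(x)
    r = radius
    for _round in range(n_rounds):
        pts, vals = [np.zeros(n)], [f_best]
        for i in range(n):
            for s in (+1.0, -1.0):
                z = np.zeros(n)
                z[i] = s * r
                pts.append(z)
                vals.append(obj(np.clip(x + z, lo, hi)))
        for i in range(n):
            for j in range(i + 1, n):
                for s in (+1.0, -1.0):
                    z = np.zeros(n)
                    z[i] = s * r / math.sqrt(2.0)
                    z[j] = r / math.sqrt(2.0)
                    pts.append(z)
                    vals.append(obj(np.clip(x + z, lo, hi)))
        vals = np.asarray(vals)
        ok = vals < 1e6          # drop failed evaluations
        X = np.array([_quad_features(z) for z, k in zip(pts, ok) if k])
        beta, *_ = np.linalg.lstsq(X, vals[ok], rcond=None)
        g = beta[1:n + 1]
        H = np.zeros((n, n))
        idx = n + 1
        for i in range(n):
            for j in range(i, n):
                if i == j:
                    H[i, i] = 2.0 * beta[idx]
                else:
                    H[i, j] = H[j, i] = beta[idx]
                idx += 1
        # minimiser of the model, regularised to be a descent step
        try:
            w, V = np.linalg.eigh(H)
            w = np.maximum(w, 1e-6)
            step = -V @ ((V.T @ g) / w)
        except np.linalg.LinAlgError:
            step = -g
        smax = float(np.max(np.abs(step)))
        if smax > r:
            step *= r / smax
        # accept the best of: model step, best stencil point
        cand = np.clip(x + step, lo, hi)
        f_cand = obj(cand)
        i_best = int(np.argmin(vals))
        if vals[i_best] < min(f_cand, f_best):
            x = np.clip(x + pts[i_best], lo, hi)
            f_best = float(vals[i_best])
        elif f_cand < f_best:
            x, f_best = cand, f_cand
        r *= shrink
    return optimize.OptimizeResult(x=x, fun=f_best, success=True,
                                   message="quadratic trust-region search "
                                           "completed")


@dataclass
class FitResult:
    """Population fit: estimates, OFV, standard errors, empirical-Bayes etas."""

    params: dict
    ofv: float
    se: dict | None
    etas: dict
    converged: bool
    n_obs: int
    n_subjects: int
    fixed: tuple = ()
    message: str = ""
    model: object = None

    @property
    def aic(self) -> float:
        n_free = len([n for n in self.params if n not in self.fixed])
        return self.ofv + 2.0 * n_free

    def param_table(self):
        import pandas as pd
        rows = []
        for n, v in self.params.items():
            rows.append({"parameter": n, "estimate": v,
                         "se": (self.se or {}).get(n, np.nan),
                         "fixed": n in self.fixed})
        return pd.DataFrame(rows)


def _central_hessian(fun, x0: np.ndarray, step: float = 1e-3) -> np.ndarray:
    n = x0.size
    H = np.empty((n, n))
    f0 = fun(x0)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = step
            ej = np.zeros(n); ej[j] = step
            if i == j:
                H[i, i] = (fun(x0 + ei) - 2.0 * f0 + fun(x0 - ei)) / step ** 2
            else:
                fpp = fun(x0 + ei + ej)
                fpm = fun(x0 + ei - ej)
                fmp = fun(x0 - ei + ej)
                fmm = fun(x0 - ei - ej)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * step ** 2)
    return H


def fit_population(dataset: Sequence[SubjectRecord], model, init: dict,
                   fix: Sequence[str] = (), compute_se: bool = True,
                   maxiter: int = 300, on_inner_failure: str = "keep",
                   method: str = "auto") -> FitResult:
    """Maximum (approximate) likelihood population fit.

    ``init`` maps parameter names to starting values; names in ``fix`` (e.g.
    variances held at known values — Q and Km are structural constants on the
    model itself and never enter the parameter vector) are not estimated.

    ``method``: 'lbfgsb' (bounded quasi-Newton with numeric gradients, good
    when predictions are closed-form and the objective is smooth to machine
    precision) or 'powell' (derivative-free direction-set search, robust to
    the small objective noise left by adaptive ODE integration); 'auto'
    picks by the model's declared objective smoothness.
    """
    if not dataset:
        raise ValueError("dataset is empty")
    names = model.param_names()
    missing = [n for n in names if n not in init]
    if missing:
        raise ValueError(f"init missing parameters: {missing}")
    unknown = [n for n in fix if n not in names]
    if unknown:
        raise ValueError(f"unknown fixed parameters: {unknown}")
    free = [n for n in names if n not in fix]
    if not free:
        raise ValueError("no free parameters")
    n_obs = sum(model.observations(r)[0].size for r in dataset)

    etas: dict = {}
    penalty = 1e12

    def obj(x: np.ndarray) -> float:
        params = _from_x(x, free, init)
        try:
            val, _ = neg2ll(params, dataset, model, etas=etas,
                            on_inner_failure=on_inner_failure)
        except (RuntimeError, FloatingPointError, np.linalg.LinAlgError,
                OverflowError, ValueError):
            return penalty
        if not np.isfinite(val):
            return penalty
        return val

    x0 = _to_x(init, free)
    bounds = [(-30.0, 30.0) if _transform_kind(n) == "log" else (-60.0, 60.0)
              for n in free]
    if method == "auto":
        method = ("lbfgsb" if getattr(model, "smooth_objective", True)
                  else "rsm")
    if method == "lbfgsb":
        res = optimize.minimize(obj, x0, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": maxiter, "ftol": 1e-9,
                                         "gtol": 1e-6})
    elif method == "lbfgsb-wide":
        # wide central-difference gradient: the 2% step keeps finite-
        # difference noise from ODE truncation error well below the OFV
        # change it measures, at the cost of O(eps^2) gradient bias
        eps = 0.02

        def grad(x):
            g = np.empty_like(x)
            for i in range(x.size):
                e = np.zeros_like(x)
                e[i] = eps
                g[i] = (obj(x + e) - obj(x - e)) / (2.0 * eps)
            return g

        res = optimize.minimize(obj, x0, jac=grad, method="L-BFGS-B",
                                bounds=bounds,
                                options={"maxiter": maxiter, "ftol": 1e-8,
                                         "gtol": 0.5})
    elif method == "rsm":
        res = _minimize_quadratic_tr(obj, x0, bounds)
    elif method == "powell":
        res = optimize.minimize(obj, x0, method="Powell", bounds=bounds,
                                options={"maxiter": maxiter, "xtol": 1e-4,
                                         "ftol": 1e-6})
    else:
        raise ValueError(f"unknown method {method!r}")
    params = _from_x(res.x, free, init)
    ofv, etas = neg2ll(params, dataset, model, etas=etas,
                       on_inner_failure=on_inner_failure)

    se = None
    if compute_se:
        try:
            H = _central_hessian(obj, res.x)
            cov = 2.0 * np.linalg.inv(H)
            d = np.diag(cov)
            se = {}
            for i, n in enumerate(free):
                if d[i] <= 0 or not np.isfinite(d[i]):
                    se[n] = np.nan
                elif _transform_kind(n) == "log":
                    se[n] = params[n] * math.sqrt(d[i])   # delta method
                else:
                    se[n] = math.sqrt(d[i])
        except np.linalg.LinAlgError:
            se = None

    converged = bool(res.success) and np.isfinite(ofv)
    return FitResult(params=params, ofv=float(ofv), se=se, etas=etas,
                     converged=converged, n_obs=n_obs, n_subjects=len(dataset),
                     fixed=tuple(fix), message=str(res.message), model=model)


# ---------------------------------------------------------------------------
# Empirical-Bayes (MAP / post hoc) estimation
# ---------------------------------------------------------------------------

@dataclass
class MapResult:
    eta: np.ndarray
    indiv: object
    n_obs: int
    at_prior_mode: bool     # True when no data informed the estimate
    objective: float


def map_estimate(rec: SubjectRecord, model, params: dict,
                 observations=None) -> MapResult:
    """Per-subject posterior-mode (empirical-Bayes) estimate with the
    population parameters fixed.

    ``observations`` optionally restricts the data to ``(times, values)``
    (e.g. a limited-sampling subset).  With no observations the prior mode
    eta = 0 (covariate-model typical values) is returned, flagged.
    """
    if observations is None:
        times, y = model.observations(rec)
    else:
        times = np.asarray(observations[0], dtype=float)
        y = np.asarray(observations[1], dtype=float)
    k = len(model.eta_names)
    omega2 = np.maximum(model.omega2(params), _OMEGA_FLOOR)
    if times.size == 0:
        eta = np.zeros(k)
        return MapResult(eta=eta, indiv=model.indiv(params, rec.covariates, eta),
                         n_obs=0, at_prior_mode=True, objective=0.0)
    sigma = model.sigma(params)
    omega_inv = 1.0 / omega2
    eta, f, _J, _H, _conv = _inner_mode(model, rec, params, times, y, sigma,
                                        omega_inv)
    h = 0.5 * (_deviance(model, y, f, sigma) + float(eta @ (omega_inv * eta)))
    return MapResult(eta=eta, indiv=model.indiv(params, rec.covariates, eta),
                     n_obs=int(times.size), at_prior_mode=False, objective=h)


# ---------------------------------------------------------------------------
# Covariate screening and stepwise selection (CPG2 power-covariate model)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CovariateScreenRow:
    label: str
    target: str            # 'cl' or 'v'
    covariate: str
    delta_ofv: float
    df: int
    p_value: float
    converged: bool


def _fit_or_none(dataset, model, init, fix, maxiter):
    try:
        return fit_population(dataset, model, init, fix=fix,
                              compute_se=False, maxiter=maxiter)
    except (RuntimeError, ValueError, np.linalg.LinAlgError):
        return None


def _fit_candidate(dataset, model, init, new_terms, fix, maxiter):
    """Fit a candidate covariate model from multiple starts and keep the
    best.  A single start is prone to the local optimum in which inflated
    IIV absorbs the covariate signal, so besides exponent starts of 0 (no
    effect) and 1 (proportional) a third start also deflates the IIV
    variances the new covariate is expected to explain."""
    starts = [dict(init), dict(init)]
    starts[1].update({n: 1.0 for n in new_terms})
    shrunk = {k: (min(v, 0.05) if k.startswith("omega2_") else v)
              for k, v in starts[1].items()}
    starts.append(shrunk)
    for s in starts[:1]:
        s.update({n: 0.0 for n in new_terms})
    best = None
    for ini in starts:
        fit = _fit_or_none(dataset, model, ini, fix, maxiter)
        if fit is not None and (best is None or fit.ofv < best.ofv):
            best = fit
    return best


def screen_covariates(dataset: Sequence[SubjectRecord], base_model: Cpg2PopModel,
                      init: dict, candidates: Sequence[str],
                      targets: Sequence[str] = ("cl", "v"),
                      fix: Sequence[str] = (), maxiter: int = 200):
    """One-at-a-time covariate screening against a base model.

    Each candidate enters as a single power term on CL or on V; rows report
    the OFV drop and the chi-square(1) p-value, sorted by drop (failed fits
    flagged not-converged with NaN statistics)."""
    base_fit = fit_population(dataset, base_model, init, fix=fix,
                              compute_se=False, maxiter=maxiter)
    rows = []
    for cov in candidates:
        for target in targets:
            if target == "cl":
                if cov in base_model.cov_cl:
                    continue
                m = base_model.with_terms(cov_cl=base_model.cov_cl + (cov,))
            else:
                if cov in base_model.cov_v:
                    continue
                m = base_model.with_terms(cov_v=base_model.cov_v + (cov,))
            cand_init = {n: init[n] for n in init if n in m.param_names()}
            new_terms = [n for n in m.param_names() if n not in cand_init]
            fit = _fit_candidate(dataset, m, cand_init, new_terms, fix,
                                 maxiter)
            label = f"{'CL' if target == 'cl' else 'V'} ~ {cov}"
            if fit is None or not np.isfinite(fit.ofv):
                rows.append(CovariateScreenRow(label, target, cov,
                                               math.nan, 1, math.nan, False))
                continue
            delta = base_fit.ofv - fit.ofv
            p = float(chi2.sf(max(delta, 0.0), 1))
            rows.append(CovariateScreenRow(label, target, cov, float(delta),
                                           1, p, fit.converged))
    rows.sort(key=lambda r: (-r.delta_ofv if np.isfinite(r.delta_ofv)
                             else math.inf))
    return rows


def stepwise_select(dataset: Sequence[SubjectRecord], base_model: Cpg2PopModel,
                    init: dict, candidates: Sequence[str],
                    targets: Sequence[str] = ("cl", "v"), p: float = 0.001,
                    fix: Sequence[str] = (), max_steps: int = 10,
                    maxiter: int = 200):
    """Forward-backward stepwise covariate selection.

    Forward steps add the largest-OFV-drop term exceeding the chi-square(1)
    threshold (AIC breaks equal-drop ties); backward steps remove terms whose
    deletion costs less than the threshold.  Returns (model, fit, history).
    """
    threshold = lrt_threshold(1, p)
    model = base_model
    cur_init = dict(init)

    def _fit(m, ini):
        full = {n: ini.get(n, 0.0) for n in m.param_names()}
        return fit_population(dataset, m, full, fix=fix, compute_se=False,
                              maxiter=maxiter)

    fit = _fit(model, cur_init)
    history = [("base", model.cov_cl, model.cov_v, fit.ofv)]

    for _ in range(max_steps):
        # forward
        best = None
        for cov in candidates:
            for target in targets:
                terms = model.cov_cl if target == "cl" else model.cov_v
                if cov in terms:
                    continue
                m = (model.with_terms(cov_cl=model.cov_cl + (cov,))
                     if target == "cl"
                     else model.with_terms(cov_v=model.cov_v + (cov,)))
                known = {**cur_init, **fit.params}
                cand_init = {n: known[n] for n in m.param_names() if n in known}
                new_terms = [n for n in m.param_names() if n not in known]
                f = _fit_candidate(dataset, m, cand_init, new_terms, fix,
                                   maxiter)
                if f is None:
                    continue
                delta = fit.ofv - f.ofv
                if delta > threshold:
                    key = (round(delta, 6), -f.aic)
                    if best is None or key > best[0]:
                        best = (key, m, f, target, cov)
        if best is None:
            break
        _, model, fit, target, cov = best
        cur_init = dict(fit.params)
        history.append((f"+{'CL' if target == 'cl' else 'V'}~{cov}",
                        model.cov_cl, model.cov_v, fit.ofv))

        # backward: drop any term no longer significant
        changed = True
        while changed:
            changed = False
            for target in targets:
                terms = model.cov_cl if target == "cl" else model.cov_v
                for cov in terms:
                    reduced = tuple(c for c in terms if c != cov)
                    m = (model.with_terms(cov_cl=reduced) if target == "cl"
                         else model.with_terms(cov_v=reduced))
                    f = _fit_or_none(dataset, m,
                                     {n: fit.params.get(n, 0.0)
                                      for n in m.param_names()}, fix, maxiter)
                    if f is None:
                        continue
                    if f.ofv - fit.ofv < threshold:
                        model, fit = m, f
                        cur_init = dict(fit.params)
                        history.append(
                            (f"-{'CL' if target == 'cl' else 'V'}~{cov}",
                             model.cov_cl, model.cov_v, fit.ofv))
                        changed = True
                        break
                if changed:
                    break
    return model, fit, history
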