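"""Model diagnostics: goodness-of-fit tables, nonparametric bootstrap, and
visual predictive checks.

CWRES here is the FOCE conditional weighted residual: the model is
linearised about each subject's empirical-Bayes mode eta^,

    y ~ N( f(eta^) - J eta^,  J Omega J' + diag(g^2) ),

and the residual vector is whitened by the Cholesky factor of that
covariance.  |CWRES| > 5 flags gross misfit.
"""

from __future__ import annotations

import copy
import math
import zlib
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .estimate import (map_estimate, fit_population, _jacobian,
                       _error_var, _OMEGA_FLOOR)
from .records import SubjectRecord

__all__ = ["gof_table", "bootstrap", "BootstrapResult", "vpc", "VpcResult"]


def gof_table(dataset: Sequence[SubjectRecord], model, params: dict,
              etas: dict | None = None) -> pd.DataFrame:
    """Per-observation goodness-of-fit table.

    Columns: subject id, time, observed DV, PRED (population prediction at
    eta = 0), IPRED (individual prediction at the empirical-Bayes mode) and
    CWRES.  Rows are the non-censored observations of the model's analyte.
    """
    omega2 = np.maximum(model.omega2(params), _OMEGA_FLOOR)
    sigma = model.sigma(params)
    k = len(model.eta_names)
    rows = []
    for rec in dataset:
        times, y = model.observations(rec)
        if times.size == 0:
            continue
        if etas is not None and rec.id in etas:
            eta = np.asarray(etas[rec.id], dtype=float)
        else:
            eta = map_estimate(rec, model, params).eta
        pred = model.predict(rec, params, np.zeros(k), times)
        ipred = model.predict(rec, params, eta, times)
        J = _jacobian(model, rec, params, eta, times, ipred)
        g2 = _error_var(model, ipred, sigma)
        cov = J @ np.diag(omega2) @ J.T + np.diag(g2)
        mean = ipred - J @ eta
        L = np.linalg.cholesky(cov)
        cwres = np.linalg.solve(L, y - mean)
        for j in range(times.size):
            rows.append({"id": rec.id, "time": times[j], "observed": y[j],
                         "pred": pred[j], "ipred": ipred[j],
                         "cwres": cwres[j]})
    return pd.DataFrame(rows)


@dataclass
class BootstrapResult:
    """Nonparametric bootstrap summary: per-parameter medians and percentile
    confidence intervals over converged replicates."""

    summary: pd.DataFrame       # index: parameter; columns: median, ci_lo, ci_hi
    estimates: pd.DataFrame     # one row per converged replicate
    n_boot: int
    n_converged: int

    @property
    def convergence_fraction(self) -> float:
        return self.n_converged / self.n_boot if self.n_boot else math.nan


def bootstrap(dataset: Sequence[SubjectRecord], model, init: dict,
              n_boot: int = 1000, seed: int = 0, fix: Sequence[str] = (),
              maxiter: int = 200,
              sampler: Callable | None = None) -> BootstrapResult:
    """Bootstrap by resampling subjects with replacement and refitting.

    ``sampler(rng, n) -> indices`` overrides the resampling rule (e.g. an
    identity permutation for checking that a degenerate bootstrap reproduces
    the original fit).  Replicates that fail to converge are excluded and
    counted.  Replicate seeds derive from the master seed.
    """
    rng = np.random.default_rng(seed)
    n = len(dataset)
    if n == 0:
        raise ValueError("dataset is empty")
    records = list(dataset)
    draws = []
    for b in range(n_boot):
        idx = (sampler(rng, n) if sampler is not None
               else rng.integers(0, n, size=n))
        resampled = []
        for j, i in enumerate(idx):
            r = copy.copy(records[i])
            r.id = f"{records[i].id}~b{b}.{j}"
            resampled.append(r)
        try:
            fit = fit_population(resampled, model, init, fix=fix,
                                 compute_se=False, maxiter=maxiter)
        except (RuntimeError, ValueError, np.linalg.LinAlgError):
            continue
        if fit.converged and np.isfinite(fit.ofv):
            draws.append(fit.params)
    est = pd.DataFrame(draws)
    if len(est):
        summary = pd.DataFrame({
            "median": est.median(),
            "ci_lo": est.quantile(0.025),
            "ci_hi": est.quantile(0.975),
        })
    else:
        summary = pd.DataFrame(columns=["median", "ci_lo", "ci_hi"])
    return BootstrapResult(summary=summary, estimates=est, n_boot=n_boot,
                           n_converged=len(est))


@dataclass
class VpcResult:
    """Visual predictive check: observed percentiles per time bin with
    simulation-based confidence envelopes."""

    table: pd.DataFrame
    n_sim: int
    percentiles: tuple = (5.0, 50.0, 95.0)

    def plot(self, ax=None):
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        if ax is None:
            _fig, ax = plt.subplots()
        t = self.table
        for q, color in zip(self.percentiles, ("tab:blue", "tab:red", "tab:blue")):
            ax.plot(t["bin_mid"], t[f"obs_p{q:g}"], "o-", color=color,
                    label=f"observed {q:g}%")
            ax.fill_between(t["bin_mid"], t[f"sim_p{q:g}_lo"],
                            t[f"sim_p{q:g}_hi"], alpha=0.25, color=color)
        ax.set_xlabel("time (h)")
        ax.set_ylabel("concentration")
        ax.legend(fontsize="small")
        return ax


def vpc(dataset: Sequence[SubjectRecord], model, params: dict,
        n_sim: int = 1000, seed: int = 0, bins=None,
        percentiles=(5.0, 50.0, 95.0)) -> VpcResult:
    """Visual predictive check.

    Observations are binned by nominal schedule label when available (the
    paper's schedules are fixed apart from window draws), otherwise by the
    supplied bin edges.  For each of ``n_sim`` replicates the original design
    (covariates, doses, observation times) is re-simulated with fresh random
    effects and residual errors, and the requested percentiles are computed
    per bin; the envelopes are the 2.5/97.5 percentiles of each statistic
    across replicates.  Empty bins are dropped.
    """
    omega2 = np.maximum(model.omega2(params), _OMEGA_FLOOR)
    sigma = model.sigma(params)
    k = len(model.eta_names)

    per_subject = []
    obs_time, obs_val, obs_bin = [], [], []
    for rec in dataset:
        obs = rec.obs(model.analyte)
        if not obs:
            continue
        times = np.array([o.time for o in obs])
        per_subject.append((rec, times))
        for o in obs:
            obs_time.append(o.time)
            obs_val.append(o.value)
            obs_bin.append(o.nominal)
    obs_time = np.array(obs_time)
    obs_val = np.array(obs_val)
    if obs_time.size == 0:
        raise ValueError("no observations for this analyte")

    if bins is not None or any(b is None for b in obs_bin):
        if bins is None:
            bins = np.quantile(obs_time, np.linspace(0, 1, 7))
        edges = np.asarray(bins, dtype=float)
        which = np.clip(np.searchsorted(edges, obs_time, side="right") - 1,
                        0, edges.size - 2)
        obs_bin = [f"bin{i}" for i in which]
    labels = sorted(set(obs_bin), key=lambda l: float(np.median(
        obs_time[[i for i, b in enumerate(obs_bin) if b == l]])))
    bin_of = {l: i for i, l in enumerate(labels)}
    bin_idx = np.array([bin_of[b] for b in obs_bin])

    def percentile_by_bin(values):
        out = np.full((len(labels), len(percentiles)), np.nan)
        for i in range(len(labels)):
            sel = values[bin_idx == i]
            if sel.size:
                out[i] = np.percentile(sel, percentiles)
        return out

    obs_stats = percentile_by_bin(obs_val)

    sim_stats = np.empty((n_sim, len(labels), len(percentiles)))
    for s in range(n_sim):
        sim_vals = np.empty(obs_time.size)
        pos = 0
        for rec, times in per_subject:
            # per-subject stream keyed by id: invariant to subject ordering
            rng = np.random.default_rng(
                (seed, s, zlib.crc32(rec.id.encode())))
            eta = rng.normal(0.0, np.sqrt(omega2), size=k)
            f = model.predict(rec, params, eta, times)
            eps = rng.normal(0.0, sigma, size=f.size)
            if model.error == "additive":
                v = f + eps
            else:
                v = f * (1.0 + eps)
            sim_vals[pos:pos + f.size] = np.maximum(v, 0.0)
            pos += f.size
        sim_stats[s] = percentile_by_bin(sim_vals)

    rows = []
    for i, lab in enumerate(labels):
        sel = bin_idx == i
        if not np.any(sel):
            continue
        row = {"bin": lab, "bin_mid": float(np.median(obs_time[sel])),
               "n_obs": int(np.sum(sel))}
        for j, q in enumerate(percentiles):
            row[f"obs_p{q:g}"] = obs_stats[i, j]
            row[f"sim_p{q:g}_lo"] = float(np.nanpercentile(sim_stats[:, i, j], 2.5))
            row[f"sim_p{q:g}_med"] = float(np.nanpercentile(sim_stats[:, i, j], 50.0))
            row[f"sim_p{q:g}_hi"] = float(np.nanpercentile(sim_stats[:, i, j], 97.5))
        rows.append(row)
    return VpcResult(table=pd.DataFrame(rows), n_sim=n_sim,
                     percentiles=tuple(percentiles))
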