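"""Model validation: conditional weighted residuals, shrinkage,
nonparametric bootstrap, and the prediction- and variability-corrected
visual predictive check (pvcVPC).

The bootstrap resamples whole subjects with replacement and refits each
replicate (warm-started at the original estimates); replicate medians and
percentile confidence intervals are compared against the point estimates.
The pvcVPC simulates the fitted model at the observed design, corrects
observations and simulations within time-after-last-dose bins for both the
local population prediction and the local predicted variability, and
compares observed percentiles with their simulated confidence bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import Cohort
from .estimation import FitResult, FOCEProblem, foce_fit
from .pk_core import PopulationModel

__all__ = [
    "BootstrapResult",
    "VPCResult",
    "cwres",
    "shrinkage",
    "bootstrap",
    "pvc_vpc",
]


@dataclass
class BootstrapResult:
    n_replicates: int
    n_failed: int
    summary: pd.DataFrame  # index = parameter; median, ci_lo, ci_hi, bias %
    estimates: pd.DataFrame  # replicate x parameter


@dataclass
class VPCResult:
    bin_edges: np.ndarray       # TAD bin edges (h)
    bin_mid: np.ndarray
    observed: np.ndarray        # (3, n_bins): corrected 5th/50th/95th
    sim_lo: np.ndarray          # (3, n_bins): lower 90% CI of each percentile
    sim_hi: np.ndarray
    n_obs_per_bin: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.bin_mid)

    def median_covered(self) -> np.ndarray:
        """Per bin: does the observed median fall inside its simulated 90% CI?"""
        return (self.observed[1] >= self.sim_lo[1]) & (self.observed[1] <= self.sim_hi[1])


def _fit_params_log(fit: FitResult) -> np.ndarray:
    return np.log(np.asarray(list(fit.theta.values()), float))


def cwres(fit: FitResult, cohort: Cohort) -> np.ndarray:
    """FOCE-linearised conditional weighted residuals, one per observation.

    Whitens the linearised residual with the Cholesky factor of
    ``V_i = diag(sigma^2 f^2) + omega^2 g g'`` evaluated at the conditional
    mode, so under the model CWRES are approximately iid standard normal.
    """
    if not fit.converged:
        raise ValueError("cwres requires a converged fit")
    problem = FOCEProblem(cohort, fit.effects)
    p_log = _fit_params_log(fit)
    _, eta, f_hat = problem.ofv_components(p_log)
    vals = np.asarray(list(fit.theta.values()), float)
    n_eff = len(fit.effects)
    omega, sigma = vals[2 + n_eff], vals[3 + n_eff]

    delta = 1e-4
    cl_typ = problem._cl_typ(vals[0], vals[1:1 + n_eff])
    g = (problem.predict(cl_typ * np.exp(eta + delta), vals[1 + n_eff])
         - problem.predict(cl_typ * np.exp(eta - delta), vals[1 + n_eff])) / (2 * delta)
    r = problem.y - f_hat + g * eta[problem.obs_subj]

    out = np.empty_like(problem.y)
    for i in range(problem.n_subj):
        m = problem.obs_subj == i
        gi = g[m]
        Vi = np.diag(sigma**2 * f_hat[m] ** 2) + omega**2 * np.outer(gi, gi)
        try:
            L = np.linalg.cholesky(Vi)
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"singular covariance for subject index {i}") from exc
        out[m] = np.linalg.solve(L, r[m])
    return out


def shrinkage(fit: FitResult) -> dict:
    """Eta- and epsilon-shrinkage (%) of a fit: ``100*(1 - SD(eta)/omega)``
    and ``100*(1 - SD(IWRES))``."""
    vals = list(fit.theta.values())
    omega = vals[2 + len(fit.effects)]
    if omega <= 0:
        raise ValueError("omega must be positive for shrinkage")
    sd_eta = float(np.std(fit.etas, ddof=1)) if len(fit.etas) > 1 else 0.0
    return {"eta": 100.0 * (1.0 - sd_eta / omega), "eps": fit.eps_shrinkage}


def bootstrap(
    cohort: Cohort,
    init: PopulationModel,
    n_replicates: int = 1000,
    seed: int = 0,
    effects=None,
) -> BootstrapResult:
    """Nonparametric bootstrap with the individual as the sampling unit.

    Each replicate draws subjects with replacement to the original cohort
    size and refits, warm-started at the original estimates; replicates
    that fail to converge are excluded and counted.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    original = foce_fit(cohort, init, effects=effects)
    warm = original.model if original.model is not None else init
    names = list(original.theta)

    rows, n_failed = [], 0
    n = len(cohort.patients)
    for _ in range(n_replicates):
        idx = rng.integers(0, n, size=n)
        resampled = []
        for new_id, i in enumerate(idx):
            p = cohort.patients[i]
            q = type(p)(**{**p.__dict__, "id": new_id + 1})
            resampled.append(q)
        try:
            f = foce_fit(Cohort(resampled), warm, effects=effects)
            if not f.converged:
                n_failed += 1
                continue
            rows.append([f.theta[k] for k in names])
        except Exception:
            n_failed += 1
    est = pd.DataFrame(rows, columns=names)
    summary = pd.DataFrame({
        "median": est.median(),
        "ci_lo": est.quantile(0.025),
        "ci_hi": est.quantile(0.975),
        "point": [original.theta[k] for k in names],
    })
    summary["bias_percent"] = 100.0 * (summary["median"] - summary["point"]) / summary["point"]
    return BootstrapResult(n_replicates=n_replicates, n_failed=n_failed,
                           summary=summary, estimates=est)


def _tad(problem: FOCEProblem) -> np.ndarray:
    """Time after the most recent dose for every observation."""
    tad = np.full(problem.n_obs, np.inf)
    np.minimum.at(tad, problem.pair_obs, problem.pair_trel)
    return tad


def _quantile_bins(tad: np.ndarray, n_bins: int) -> np.ndarray:
    edges = np.quantile(tad, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)  # merge empty/duplicate bins
    if edges.size == 1:       # all observations at one design point
        return np.array([edges[0] - 1e-9, edges[0] + 1e-9])
    edges[0], edges[-1] = edges[0] - 1e-9, edges[-1] + 1e-9
    return edges


def pvc_vpc(
    fit: FitResult,
    cohort: Cohort,
    n_sim: int = 1000,
    bins: int = 6,
    seed: int = 0,
) -> VPCResult:
    """Prediction- and variability-corrected VPC on time after last dose.

    Observations and simulations are corrected within each TAD bin by the
    bin-median population prediction (prediction correction) and each
    observation's simulated SD is rescaled to the bin-median SD
    (variability correction) before computing the 5th/50th/95th
    percentiles; the simulated 90% confidence band of each percentile is
    taken across replicates.
    """
    if not fit.converged:
        raise ValueError("pvc_vpc requires a converged fit")
    rng = np.random.default_rng(seed)
    problem = FOCEProblem(cohort, fit.effects)
    vals = np.asarray(list(fit.theta.values()), float)
    n_eff = len(fit.effects)
    volume, omega, sigma = vals[1 + n_eff], vals[2 + n_eff], vals[3 + n_eff]
    cl_typ = problem._cl_typ(vals[0], vals[1:1 + n_eff])

    pred = np.maximum(problem.predict(cl_typ, volume), 1e-10)  # eta = 0

    # simulate the design n_sim times
    sims = np.empty((n_sim, problem.n_obs))
    for s in range(n_sim):
        eta = rng.normal(0.0, omega, size=problem.n_subj)
        f = problem.predict(cl_typ * np.exp(eta), volume)
        sims[s] = f * (1.0 + rng.normal(0.0, sigma, size=problem.n_obs))
    sims = np.maximum(sims, 0.0)

    tad = _tad(problem)
    edges = _quantile_bins(tad, bins)
    bin_idx = np.clip(np.searchsorted(edges, tad, side="right") - 1,
                      0, len(edges) - 2)
    n_bins = len(edges) - 1

    y = problem.y.copy()
    pc_obs = np.empty_like(y)
    pc_sims = np.empty_like(sims)
    sd_obs_scale = np.empty_like(y)
    for b in range(n_bins):
        m = bin_idx == b
        pred_bin = np.median(pred[m])
        ratio = pred_bin / pred[m]
        pc_obs[m] = y[m] * ratio
        pc_sims[:, m] = sims[:, m] * ratio
        # variability correction: rescale each design point's deviation
        # around the bin prediction to the bin-median simulated SD
        sd_ij = np.maximum(pc_sims[:, m].std(axis=0), 1e-12)
        sd_bin = np.median(sd_ij)
        scale = sd_bin / sd_ij
        pc_obs[m] = pred_bin + (pc_obs[m] - pred_bin) * scale
        pc_sims[:, m] = pred_bin + (pc_sims[:, m] - pred_bin) * scale

    q = (5, 50, 95)
    observed = np.empty((3, n_bins))
    sim_lo = np.empty((3, n_bins))
    sim_hi = np.empty((3, n_bins))
    n_per_bin = np.empty(n_bins, dtype=int)
    mids = np.empty(n_bins)
    for b in range(n_bins):
        m = bin_idx == b
        n_per_bin[b] = int(m.sum())
        mids[b] = float(np.median(tad[m]))
        observed[:, b] = np.percentile(pc_obs[m], q)
        sim_pct = np.percentile(pc_sims[:, m], q, axis=1)  # (3, n_sim)
        sim_lo[:, b] = np.percentile(sim_pct, 5, axis=1)
        sim_hi[:, b] = np.percentile(sim_pct, 95, axis=1)

    return VPCResult(bin_edges=edges, bin_mid=mids, observed=observed,
                     sim_lo=sim_lo, sim_hi=sim_hi, n_obs_per_bin=n_per_bin)
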