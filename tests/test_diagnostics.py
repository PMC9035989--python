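"""Residual diagnostics, shrinkage, bootstrap and pvcVPC behaviour."""

import numpy as np
import pytest
from scipy.stats import kstest

import lznpk as L
from lznpk.diagnostics import bootstrap, cwres, pvc_vpc, shrinkage
from lznpk.estimation import FitResult


class TestCWRES:
    def test_null_distribution(self, fitted):
        cohort, fit = fitted
        r = cwres(fit, cohort)
        assert np.all(np.isfinite(r))
        assert -0.2 < r.mean() < 0.2
        assert np.mean(np.abs(r) < 2.0) >= 0.90

    def test_exact_prediction_gives_zero(self, default_model):
        # one subject observed exactly at the typical prediction
        doses = [L.DoseEvent(time=12.0 * j, amount=600.0) for j in range(10)]
        p_typ = L.individual_params(default_model, 65.0, 0.0)
        t = 119.5
        c = float(L.concentration(t, doses, p_typ))
        pat = L.PatientRecord(id=1, crcl=65.0, doses=doses,
                              observations=[L.Observation(time=t,
                                                          concentration=c)])
        # evaluate residuals at the generating parameters (no refit)
        fit = FitResult(
            model=default_model,
            theta={"theta_cl_intercept": 3.66, "theta_crcl_on_cl": 2.18,
                   "volume": 54.0, "omega_cl": 0.3519, "sigma_prop": 0.1905},
            rse={}, ofv=0.0, aic=0.0, bic=0.0, etas=np.zeros(1),
            eta_shrinkage=0.0, eps_shrinkage=0.0, converged=True,
            effects=(L.CovariateEffect("CL", "CRCL", 65.0),), n_obs=1)
        # the conditional mode carries an O(sigma^2) interaction shift, so
        # the residual is zero only to that order
        r = cwres(fit, L.Cohort([pat]))
        assert abs(r[0]) < 5e-3

    def test_misspecified_volume_inflates_residuals(self, fitted):
        cohort, fit = fitted
        r_null = cwres(fit, cohort)
        bad = dict(fit.theta)
        bad["volume"] = bad["volume"] * 3.0
        fit_bad = FitResult(
            model=fit.model, theta=bad, rse={}, ofv=0.0, aic=0.0, bic=0.0,
            etas=fit.etas, eta_shrinkage=0.0, eps_shrinkage=0.0,
            converged=True, effects=fit.effects, n_obs=fit.n_obs)
        r_bad = cwres(fit_bad, cohort)
        assert np.std(r_bad) > np.std(r_null)
        assert kstest(r_bad, "norm").pvalue < 0.05


class TestShrinkage:
    def _fit_with(self, etas, omega, eps_shr=0.0):
        return FitResult(
            model=None, theta={"theta_cl_intercept": 3.66, "volume": 54.0,
                               "omega_cl": omega, "sigma_prop": 0.19},
            rse={}, ofv=0.0, aic=0.0, bic=0.0, etas=np.asarray(etas),
            eta_shrinkage=0.0, eps_shrinkage=eps_shr, converged=True,
            effects=(), n_obs=len(etas))

    def test_all_zero_etas_full_shrinkage(self):
        s = shrinkage(self._fit_with(np.zeros(20), 0.4))
        assert s["eta"] == pytest.approx(100.0)

    def test_arithmetic(self):
        rng = np.random.default_rng(0)
        etas = rng.normal(0, 1, 400)
        etas = etas / np.std(etas, ddof=1) * 0.2
        s = shrinkage(self._fit_with(etas, 0.4))
        assert s["eta"] == pytest.approx(50.0, abs=1e-6)

    def test_zero_omega_rejected(self):
        with pytest.raises(ValueError):
            shrinkage(self._fit_with(np.zeros(5), 0.0))

    def test_rich_design_low_shrinkage(self, default_model):
        # 8 observations per subject: individual data dominate the prior
        rng = np.random.default_rng(12)
        patients = []
        for i in range(40):
            crcl = rng.uniform(30.0, 120.0)
            eta = rng.normal(0.0, default_model.omega_cl)
            p = L.individual_params(default_model, crcl, eta)
            doses = [L.DoseEvent(time=12.0 * j, amount=600.0)
                     for j in range(12)]
            times = np.sort(rng.uniform(73.0, 143.0, 8))
            f = np.atleast_1d(L.concentration(times, doses, p))
            y = f * (1.0 + rng.normal(0.0, default_model.sigma_prop, 8))
            obs = [L.Observation(time=float(t), concentration=float(max(c, 1e-3)))
                   for t, c in zip(times, y)]
            patients.append(L.PatientRecord(id=i + 1, crcl=crcl, doses=doses,
                                            observations=obs))
        fit = L.foce_fit(L.Cohort(patients), default_model)
        assert shrinkage(fit)["eta"] < 10.0


class TestBootstrap:
    def test_single_replicate_structure(self, synthetic_cohort,
                                        default_model):
        cohort = synthetic_cohort.fit_subset()
        bs = bootstrap(cohort, default_model, n_replicates=1, seed=1)
        assert bs.n_replicates == 1
        assert len(bs.estimates) + bs.n_failed == 1
        s = bs.summary
        assert (s["ci_lo"] <= s["median"] + 1e-12).all()
        assert (s["median"] <= s["ci_hi"] + 1e-12).all()

    def test_bias_small_at_moderate_replicates(self, synthetic_cohort,
                                               default_model):
        cohort = synthetic_cohort.fit_subset()
        bs = bootstrap(cohort, default_model, n_replicates=50, seed=2)
        assert (bs.summary["bias_percent"].abs() < 15.0).all()
        inside = ((bs.summary["point"] >= bs.summary["ci_lo"])
                  & (bs.summary["point"] <= bs.summary["ci_hi"]))
        assert inside.all()


class TestVPC:
    def test_null_model_coverage(self, fitted):
        cohort, fit = fitted
        vpc = pvc_vpc(fit, cohort, n_sim=400, bins=6, seed=3)
        assert np.mean(vpc.median_covered()) >= 0.8

    def test_percentile_bands_ordered(self, fitted):
        cohort, fit = fitted
        vpc = pvc_vpc(fit, cohort, n_sim=200, bins=5, seed=4)
        assert vpc.observed.shape[0] == 3
        assert np.all(vpc.observed[0] <= vpc.observed[1] + 1e-12)
        assert np.all(vpc.observed[1] <= vpc.observed[2] + 1e-12)
        assert np.all(vpc.sim_lo <= vpc.sim_hi + 1e-12)

    def test_invariant_to_subject_relabeling(self, fitted):
        cohort, fit = fitted
        relabeled = L.Cohort([
            type(p)(**{**p.__dict__, "id": 1000 - p.id})
            for p in cohort.patients
        ])
        v1 = pvc_vpc(fit, cohort, n_sim=150, bins=4, seed=5)
        v2 = pvc_vpc(fit, relabeled, n_sim=150, bins=4, seed=5)
        assert np.allclose(v1.observed, v2.observed)
        assert np.allclose(v1.sim_lo, v2.sim_lo)

    def test_prediction_correction_identity_when_pred_constant(self):
        # single design point replicated: PRED equal within the bin, so the
        # correction must leave observations unchanged up to the
        # variability rescaling (which is also the identity here)
        m = L.PopulationModel()
        rng = np.random.default_rng(6)
        patients = []
        for i in range(30):
            doses = [L.DoseEvent(time=12.0 * j, amount=600.0)
                     for j in range(10)]
            eta = rng.normal(0.0, m.omega_cl)
            p = L.individual_params(m, 65.0, eta)
            c = float(L.concentration(119.5, doses, p))
            c *= 1.0 + rng.normal(0.0, m.sigma_prop)
            patients.append(L.PatientRecord(
                id=i + 1, crcl=65.0, doses=doses,
                observations=[L.Observation(time=119.5,
                                            concentration=max(c, 1e-3))]))
        cohort = L.Cohort(patients)
        fit = L.foce_fit(cohort, m)
        vpc = pvc_vpc(fit, cohort, n_sim=400, bins=1, seed=7)
        y = np.array([p.observations[0].concentration for p in patients])
        # prediction correction is exactly the identity; the variability
        # rescaling adds only Monte Carlo jitter in the per-point SDs
        assert vpc.observed[1, 0] == pytest.approx(np.median(y), rel=0.05)
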