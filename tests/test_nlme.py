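"""Laplace NLME engine: oracle equivalence, model comparison, diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import rabepkpd as r
from rabepkpd.diagnostics import bootstrap, gof_diagnostics, vpc
from rabepkpd.nlme import (
    FitResult,
    LaplaceFitter,
    PKModelSpec,
    PKStructuralModel,
    compare_models,
    fit_population,
)


# ---------------------------------------------------------------------------
# Toy models (the oracle side never touches the fitter internals)
# ---------------------------------------------------------------------------

class ToyLinear:
    """y_ij = theta0 + eta_i + eps; marginal is closed-form Gaussian."""

    error_model = "normal"
    eta_names = ("mu",)

    def __init__(self, y):
        self.dv = np.asarray(y, float)
        self.mask = np.ones_like(self.dv, dtype=bool)

    def mean(self, theta, eta, idx=None):
        S, B, _ = eta.shape
        n = self.dv.shape[1]
        return np.broadcast_to((theta[0] + eta[:, :, 0])[:, :, None], (S, B, n)).copy()

    def initial_eta(self, theta):
        return np.zeros((self.dv.shape[0], 1))


class ToyExponential:
    """y_ij = theta0 * exp(eta_i) + eps; nonlinear in eta."""

    error_model = "normal"
    eta_names = ("scale",)

    def __init__(self, y):
        self.dv = np.asarray(y, float)
        self.mask = np.ones_like(self.dv, dtype=bool)

    def mean(self, theta, eta, idx=None):
        S, B, _ = eta.shape
        n = self.dv.shape[1]
        return np.broadcast_to(
            (theta[0] * np.exp(eta[:, :, 0]))[:, :, None], (S, B, n)
        ).copy()

    def initial_eta(self, theta):
        return np.zeros((self.dv.shape[0], 1))


def _closed_form_linear_ofv(y, theta, omega2, sigma):
    n = y.shape[1]
    cov = sigma**2 * np.eye(n) + omega2 * np.ones((n, n))
    return -2.0 * sum(
        stats.multivariate_normal.logpdf(row, mean=np.full(n, theta), cov=cov)
        for row in y
    )


def _adaptive_gh_ofv(y, theta, omega2, sigma, n_nodes=64):
    """Adaptive Gauss-Hermite marginal OFV for the exponential toy model."""
    from scipy.optimize import minimize_scalar

    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    total = 0.0
    for row in y:
        def neg_log_joint(e):
            pred = theta * math.exp(e)
            return (
                np.sum((row - pred) ** 2) / (2 * sigma**2)
                + len(row) * math.log(sigma * math.sqrt(2 * math.pi))
                + e**2 / (2 * omega2)
                + 0.5 * math.log(2 * math.pi * omega2)
            )
        res = minimize_scalar(neg_log_joint, bounds=(-8.0, 8.0), method="bounded",
                              options={"xatol": 1e-10})
        mode = res.x
        h = 1e-4
        curv = (neg_log_joint(mode + h) - 2 * res.fun + neg_log_joint(mode - h)) / h**2
        sd = 1.0 / math.sqrt(max(curv, 1e-12))
        etas = mode + math.sqrt(2.0) * sd * nodes
        logf = -np.array([neg_log_joint(e) for e in etas])
        logw = logf + nodes**2 + np.log(weights) + 0.5 * math.log(2.0) + math.log(sd)
        m = logw.max()
        total += -2.0 * (m + math.log(np.exp(logw - m).sum()))
    return total


class TestOFVOracles:
    def test_linear_gaussian_closed_form(self):
        rng = np.random.default_rng(0)
        y = 2.0 + rng.normal(0, 0.7, 12)[:, None] + rng.normal(0, 0.3, (12, 4))
        fitter = LaplaceFitter(ToyLinear(y))
        lap = fitter.ofv(np.array([2.0]), np.array([0.5]), 0.3)
        oracle = _closed_form_linear_ofv(y, 2.0, 0.5, 0.3)
        assert lap == pytest.approx(oracle, abs=1e-6)

    def test_nonlinear_toy_against_gauss_hermite(self):
        rng = np.random.default_rng(1)
        y = 3.0 * np.exp(rng.normal(0, 0.5, 10))[:, None] + rng.normal(0, 0.4, (10, 5))
        fitter = LaplaceFitter(ToyExponential(y))
        lap = fitter.ofv(np.array([3.0]), np.array([0.25]), 0.4)
        oracle = _adaptive_gh_ofv(y, 3.0, 0.25, 0.4)
        assert lap == pytest.approx(oracle, abs=0.1)

    def test_no_random_effects_reduces_to_direct_likelihood(self, pop):
        """With all IIV removed the OFV is the plain log-normal likelihood
        of the observations, including the log-transform Jacobian."""
        quiet = pop.with_updates(omega2={})
        cspec = r.CohortSpec(n_male=6, n_female=5, seed=77)
        trial = r.simulate_trial(r.generate_cohort(cspec), quiet, cspec, seed=78)
        spec = PKModelSpec(covariate_terms=(("Tlag", "gender"), ("Ka3", "bsa")),
                           eta_names=())
        model = PKStructuralModel(spec, trial.subjects())
        model.lloq = trial.lloq
        fitter = LaplaceFitter(model)
        theta = spec.theta_from_population(quiet)
        got = fitter.ofv(theta, np.array([]), quiet.sigma)
        # direct computation
        pop = quiet
        study_trial = trial
        direct = 0.0
        for rec in study_trial.subjects():
            ind = r.individual_parameters(pop, rec.covariates)
            pred = r.solve_profile(ind, r.DoseEvent(rec.dose_amount, rec.dose_time),
                                   rec.times).conc
            for dv, f in zip(rec.dv, pred):
                if dv > study_trial.lloq:
                    z = math.log(dv) - math.log(max(f, 1e-12))
                    direct += (
                        z**2 / pop.sigma**2
                        + math.log(2 * math.pi)
                        + 2 * math.log(pop.sigma)
                        + 2 * math.log(dv)
                    )
        assert got == pytest.approx(direct, rel=1e-6)

    def test_subject_order_invariance(self, pop, study_trial):
        spec = PKModelSpec(covariate_terms=(("Tlag", "gender"), ("Ka3", "bsa")))
        theta = spec.theta_from_population(pop)
        omega2 = np.array([pop.omega2[n] for n in spec.eta_names])

        def ofv_of(df):
            ds = r.TrialDataset(df, lloq=study_trial.lloq)
            model = PKStructuralModel(spec, ds.subjects())
            model.lloq = ds.lloq
            return LaplaceFitter(model).ofv(theta, omega2, pop.sigma)

        df = study_trial.df
        relabeled = df.copy()
        relabeled["ID"] = df.ID.max() + 1 - df.ID  # reverse the subject order
        assert ofv_of(df) == pytest.approx(ofv_of(relabeled), rel=1e-9)


def _stub_fit(ofv_value, n_params=10):
    spec = PKModelSpec()
    return FitResult(
        spec=spec, theta={}, omega2={}, sigma=0.3, ofv=ofv_value,
        n_params=n_params, converged=True, aic=ofv_value + 2 * n_params,
    )


class TestCompareModels:
    def test_forward_only_significance(self):
        """A 3.95-unit OFV drop for one extra parameter passes forward
        selection (3.84) but not backward elimination (6.63)."""
        res = compare_models(_stub_fit(1112.35), _stub_fit(1108.40), df_diff=1)
        assert res.delta_ofv == pytest.approx(-3.95)
        assert res.passes_forward and not res.passes_backward

    def test_no_change_not_significant(self):
        res = compare_models(_stub_fit(1000.0), _stub_fit(1000.0), df_diff=1)
        assert not res.passes_forward and not res.passes_backward

    def test_large_drop_passes_both(self):
        res = compare_models(_stub_fit(954.38), _stub_fit(921.86), df_diff=1)
        assert res.delta_ofv == pytest.approx(-32.52)
        assert res.passes_forward and res.passes_backward

    def test_critical_values_match_chi_square(self):
        res = compare_models(_stub_fit(10.0), _stub_fit(0.0), df_diff=1)
        assert res.chi2_forward == pytest.approx(3.841, abs=0.001)
        assert res.chi2_backward == pytest.approx(6.635, abs=0.001)

    def test_nonpositive_df_rejected(self):
        with pytest.raises(ValueError):
            compare_models(_stub_fit(1.0), _stub_fit(0.0), df_diff=0)


@pytest.fixture(scope="module")
def small_fitted(pop):
    """A small simulated trial fitted with the final covariate model."""
    spec = r.CohortSpec(n_male=16, n_female=14, seed=55)
    cohort = r.generate_cohort(spec, np.random.default_rng(55))
    ds = r.simulate_trial(cohort, pop, spec, seed=56)
    mspec = PKModelSpec(covariate_terms=(("Tlag", "gender"), ("Ka3", "bsa")))
    fit = fit_population(ds, mspec, initial=pop, seed=0, maxiter=60, restarts=0)
    return ds, fit


class TestBootstrap:
    def test_resampling_preserves_gender_split(self, study_trial):
        rng = np.random.default_rng(4)
        for _ in range(5):
            rep = study_trial.resample_subjects(rng, stratify_on="SEX")
            per = rep.df.groupby("ID").first()
            assert (per.SEX == 0).sum() == 24
            assert (per.SEX == 1).sum() == 21

    def test_same_seed_reproduces_table(self, small_fitted):
        ds, fit = small_fitted
        a = bootstrap(ds, fit, n_replicates=3, seed=9, maxiter=25)
        b = bootstrap(ds, fit, n_replicates=3, seed=9, maxiter=25)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_ci_brackets_and_failure_count(self, small_fitted):
        ds, fit = small_fitted
        res = bootstrap(ds, fit, n_replicates=4, seed=10, maxiter=25)
        assert res.n_failed <= 1
        assert res.reliable
        tab = res.table
        assert (tab.ci95_lo <= tab.ci95_hi).all()


class TestVPC:
    def test_zero_variance_bands_collapse(self, pop):
        """In a homogeneous stratum with no IIV and vanishing residual
        noise the three simulated percentile bands coincide."""
        cspec = r.CohortSpec(n_male=12, n_female=0, bsa_cv=0.0, seed=88)
        trial = r.simulate_trial(r.generate_cohort(cspec), pop, cspec, seed=89)
        spec = PKModelSpec(covariate_terms=(("Tlag", "gender"), ("Ka3", "bsa")))
        fit = FitResult(
            spec=spec,
            theta=dict(zip(spec.theta_names, spec.theta_from_population(pop))),
            omega2={n: 1e-12 for n in spec.eta_names},
            sigma=1e-6, ofv=0.0, n_params=15, converged=True, aic=0.0,
        )
        res = vpc(trial, fit, n_simulations=100, seed=0)
        spread = (res.bands.sim_p95 - res.bands.sim_p5).abs()
        scale = res.bands.sim_p50.abs().max()
        assert (spread <= 1e-4 * scale + 1e-9).all()

    def test_gender_stratification_reports_both(self, pop, study_trial, small_fitted):
        _, fit = small_fitted
        res = vpc(study_trial, fit, n_simulations=100, seed=1, stratify_gender=True)
        assert set(res.stratified) == {"male", "female"}
        assert 0.0 <= res.coverage <= 1.0

    def test_too_few_simulations_rejected(self, study_trial, small_fitted):
        _, fit = small_fitted
        with pytest.raises(ValueError):
            vpc(study_trial, fit, n_simulations=50)


class TestGOF:
    def _fit_at_truth(self, pop):
        spec = PKModelSpec(covariate_terms=(("Tlag", "gender"), ("Ka3", "bsa")))
        return FitResult(
            spec=spec,
            theta=dict(zip(spec.theta_names, spec.theta_from_population(pop))),
            omega2={n: pop.omega2[n] for n in spec.eta_names},
            sigma=pop.sigma, ofv=0.0, n_params=17, converged=True, aic=0.0,
        )

    def test_cwres_calibrated_for_correct_model(self, pop, study_trial):
        table = gof_diagnostics(study_trial, self._fit_at_truth(pop))
        assert abs(table.CWRES.mean()) < 0.15
        assert 0.8 <= table.CWRES.std() <= 1.2
        assert (table.CWRES.abs() <= 4.0).all()
        assert {"PRED", "IPRED", "CWRES", "qq_theoretical"} <= set(table.columns)

    def test_doubled_sigma_halves_cwres_spread(self, pop, study_trial):
        import dataclasses
        fit = self._fit_at_truth(pop)
        inflated = dataclasses.replace(fit, sigma=2 * pop.sigma)
        table = gof_diagnostics(study_trial, inflated)
        assert table.CWRES.std() == pytest.approx(0.5, abs=0.2)
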