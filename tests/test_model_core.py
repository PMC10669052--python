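"""Structural PK model: covariate/eta combination, solvers, error model, variants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rabepkpd as r
from rabepkpd.model import chain_conc
from rabepkpd.params import CovariateConfig


class TestIndividualParameters:
    def test_male_reference_covariates(self, pop):
        cov = r.SubjectCovariates(gender="male", bsa=1.87)
        ind = r.individual_parameters(pop, cov)
        assert ind.Tlag == pytest.approx(1.56)
        assert ind.Ka3 == pytest.approx(3.34 * np.exp(-1.11 * 0.14), rel=1e-6)

    def test_female_covariate_shifts(self, pop):
        cov = r.SubjectCovariates(gender="female", bsa=1.58)
        ind = r.individual_parameters(pop, cov)
        assert ind.Tlag == pytest.approx(1.56 * np.exp(0.73), rel=1e-6)
        assert ind.Ka3 == pytest.approx(3.34 * np.exp(1.11 * 0.15), rel=1e-6)

    def test_clearance_untouched_by_covariates(self, pop):
        for gender, bsa in (("male", 1.87), ("female", 1.58)):
            ind = r.individual_parameters(
                pop, r.SubjectCovariates(gender=gender, bsa=bsa), {"CLc": 0.0}
            )
            assert ind.CLc == 25.65

    def test_additive_form(self, pop):
        cov = r.SubjectCovariates(gender="female", bsa=1.73)
        ind = r.individual_parameters(
            pop, cov, config=CovariateConfig(form="additive")
        )
        assert ind.Tlag == pytest.approx(1.56 + 0.73)

    def test_rejects_unknown_eta_and_bad_bsa(self, pop):
        with pytest.raises(ValueError, match="eta"):
            r.individual_parameters(
                pop, r.SubjectCovariates(gender="male", bsa=1.8), {"Vp": 0.1}
            )
        with pytest.raises(ValueError, match="bsa"):
            r.SubjectCovariates(gender="male", bsa=-1.0)

    @given(eta=st.floats(-2, 2), bsa=st.floats(1.3, 2.3))
    @settings(max_examples=30, deadline=None)
    def test_outputs_always_positive(self, pop, eta, bsa):
        ind = r.individual_parameters(
            pop, r.SubjectCovariates(gender="female", bsa=bsa),
            {"Ka3": eta, "Tlag": -eta},
        )
        assert min(ind.as_array()) > 0


class TestSolveProfile:
    def test_zero_before_lag(self, typical_male, dose_10mg):
        t = np.array([0.0, 0.5, 1.0, 1.5, 1.56])
        prof = r.solve_profile(typical_male, dose_10mg, t)
        assert np.all(prof.conc == 0.0)

    def test_auc_identity(self, typical_male, dose_10mg):
        """AUC to infinity equals dose / clearance for a linear system."""
        t = np.linspace(0, 200, 20001)
        prof = r.solve_profile(typical_male, dose_10mg, t)
        expected = 1.0e7 / (25.65 * 1000.0)  # = 389.9 ng*h/mL
        assert prof.auc() == pytest.approx(expected, rel=1e-3)

    def test_terminal_slope_matches_two_compartment_beta(self, typical_male, dose_10mg):
        t = np.linspace(12, 48, 361)
        prof = r.solve_profile(typical_male, dose_10mg, t)
        slope = -np.polyfit(t, np.log(prof.conc), 1)[0]
        k10 = 25.65 / 10.31
        k12 = 5.45 / 10.31
        k21 = 5.45 / 11.46
        s = k10 + k12 + k21
        beta = 0.5 * (s - np.sqrt(s * s - 4 * k10 * k21))
        assert slope == pytest.approx(beta, rel=1e-3)
        assert slope == pytest.approx(0.380, abs=0.002)

    def test_analytic_matches_ode(self, typical_male, dose_10mg):
        t = np.linspace(0, 24, 97)
        pa = r.solve_profile(typical_male, dose_10mg, t).conc
        po = r.solve_profile(typical_male, dose_10mg, t, method="ode").conc
        scale = np.maximum(po, po.max() * 1e-9)
        assert np.max(np.abs(pa - po) / scale + (pa == po) * 0) < 1e-6 or \
            np.allclose(pa, po, rtol=1e-6, atol=po.max() * 1e-9)

    def test_degenerate_rates_fall_back_gracefully(self, dose_10mg):
        ind = r.IndividualParameters(Vc=10.0, CLc=20.0, Vp=10.0, CLp=5.0,
                                     Ka1=2.0, Ka2=2.0, Ka3=2.0, Tlag=1.0)
        t = np.linspace(0, 12, 49)
        pa = r.solve_profile(ind, dose_10mg, t).conc
        po = r.solve_profile(ind, dose_10mg, t, method="ode").conc
        assert np.allclose(pa, po, rtol=1e-6, atol=po.max() * 1e-9)

    def test_mass_balance(self, typical_male, dose_10mg):
        states = r.solve_states(typical_male, dose_10mg, np.array([0.5, 2.0, 5.0, 12.0, 48.0]))
        total = sum(states.values())
        assert np.allclose(total, 1.0e7, rtol=1e-8)

    def test_time_shift_equivariance(self, typical_male, dose_10mg):
        """Increasing Tlag by delta shifts the profile exactly by delta."""
        import dataclasses
        delta = 0.75
        t = np.arange(0.0, 12.0, 0.25)
        base = r.solve_profile(typical_male, dose_10mg, t).conc
        shifted_ind = dataclasses.replace(typical_male, Tlag=typical_male.Tlag + delta)
        shifted = r.solve_profile(shifted_ind, dose_10mg, t + delta).conc
        assert np.allclose(shifted, base, rtol=1e-9, atol=1e-12)

    def test_auc_strictly_decreases_with_clearance(self, typical_male, dose_10mg):
        import dataclasses
        t = np.linspace(0, 120, 4801)
        aucs = []
        for scale in (0.5, 1.0, 2.0, 4.0):
            ind = dataclasses.replace(typical_male, CLc=typical_male.CLc * scale)
            aucs.append(r.solve_profile(ind, dose_10mg, t).auc())
        assert all(a > b for a, b in zip(aucs, aucs[1:]))

    def test_negative_times_rejected(self, typical_male, dose_10mg):
        with pytest.raises(ValueError):
            r.solve_profile(typical_male, dose_10mg, np.array([-1.0, 1.0]))


class TestResidualError:
    def test_small_sigma_is_identity_in_the_limit(self, typical_male, dose_10mg):
        t = np.linspace(0, 12, 25)
        prof = r.solve_profile(typical_male, dose_10mg, t)
        obs = r.apply_residual_error(prof, 1e-12, rng_seed=1)
        assert np.allclose(obs, prof.conc, rtol=1e-9)

    def test_zero_prediction_stays_zero(self, typical_male, dose_10mg):
        prof = r.solve_profile(typical_male, dose_10mg, np.array([0.5, 1.0, 3.0]))
        for seed in (1, 2, 3):
            obs = r.apply_residual_error(prof, 0.37, rng_seed=seed)
            assert obs[0] == 0.0 and obs[1] == 0.0

    def test_seed_reproducibility(self, typical_male, dose_10mg):
        prof = r.solve_profile(typical_male, dose_10mg, np.linspace(0, 12, 25))
        a = r.apply_residual_error(prof, 0.37, rng_seed=42)
        b = r.apply_residual_error(prof, 0.37, rng_seed=42)
        assert np.array_equal(a, b)

    def test_log_scale_sd_matches_sigma(self, typical_male, dose_10mg):
        """Monte-Carlo: sample SD of log observations equals sigma (0.37)."""
        prof = r.solve_profile(typical_male, dose_10mg, np.array([4.0]))
        rng = np.random.default_rng(7)
        obs = np.array([r.apply_residual_error(prof, 0.37, rng)[0] for _ in range(10000)])
        assert np.std(np.log(obs)) == pytest.approx(0.37, abs=0.01)


class TestStructuralVariants:
    DISP = {"Vc": 10.31, "CLc": 25.65, "Vp": 11.46, "CLp": 5.45}

    def test_three_depot_variant_equals_main_solver(self, typical_male, dose_10mg):
        t = np.linspace(0, 12, 49)
        params = {**self.DISP, "k": 3, "Ka1": typical_male.Ka1,
                  "Ka2": typical_male.Ka2, "Ka3": typical_male.Ka3,
                  "Tlag": typical_male.Tlag,
                  "Vc": typical_male.Vc, "CLc": typical_male.CLc,
                  "Vp": typical_male.Vp, "CLp": typical_male.CLp}
        v = r.structural_variant_solve("sequential_k_depots", params, dose_10mg, t)
        ref = r.solve_profile(typical_male, dose_10mg, t)
        assert np.allclose(v.conc, ref.conc, rtol=1e-9)

    def test_chain_collapses_to_first_order_for_fast_extra_depots(self, dose_10mg):
        """With Ka2, Ka3 -> very large the 3-depot chain reduces to a single
        first-order absorption step."""
        t = np.arange(1.2, 12.0, 0.2)
        fo = r.structural_variant_solve(
            "first_order_lag", {**self.DISP, "Ka": 1.5, "Tlag": 1.0}, dose_10mg, t
        )
        chain = r.structural_variant_solve(
            "sequential_k_depots",
            {**self.DISP, "k": 3, "Ka1": 1.5, "Ka2": 1e6, "Ka3": 1e6, "Tlag": 1.0},
            dose_10mg, t,
        )
        mask = t > 1.1
        assert np.allclose(chain.conc[mask], fo.conc[mask], rtol=1e-3)

    def test_weibull_shape_one_is_first_order(self, dose_10mg):
        t = np.linspace(0, 12, 49)
        wb = r.structural_variant_solve(
            "weibull", {**self.DISP, "shape": 1.0, "scale": 0.5}, dose_10mg, t
        )
        fo = r.structural_variant_solve(
            "first_order", {**self.DISP, "Ka": 2.0}, dose_10mg, t
        )
        assert np.allclose(wb.conc, fo.conc, rtol=1e-4, atol=fo.conc.max() * 1e-6)

    def test_mtt_variant_conserves_auc(self, dose_10mg):
        t = np.linspace(0, 300, 3001)
        prof = r.structural_variant_solve(
            "mtt", {**self.DISP, "n_transit": 3, "mtt": 2.0, "Tlag": 0.0},
            dose_10mg, t,
        )
        assert prof.auc() == pytest.approx(1e7 / 25650.0, rel=2e-3)

    @pytest.mark.parametrize("k", [1, 4, 5])
    def test_chain_length_outside_two_to_three_rejected(self, dose_10mg, k):
        params = {**self.DISP, "k": k, "Tlag": 0.5,
                  **{f"Ka{i+1}": 2.0 for i in range(max(k, 3))}}
        with pytest.raises(ValueError, match="chain length"):
            r.structural_variant_solve("sequential_k_depots", params, dose_10mg, [1.0])

    def test_split_fraction_must_be_in_unit_interval(self, dose_10mg):
        params = {**self.DISP, "Ka_a": 1.0, "Ka_b": 3.0, "frac": 1.2, "Tlag": 0.0}
        with pytest.raises(ValueError, match="fraction"):
            r.structural_variant_solve("nonsequential_two_depot", params, dose_10mg, [1.0])


@given(
    tlag=st.floats(0.1, 4.0),
    ka=st.floats(0.5, 6.0),
    t=st.floats(0.0, 24.0),
)
@settings(max_examples=40, deadline=None)
def test_chain_conc_nonnegative_and_zero_before_lag(tlag, ka, t):
    conc = chain_conc(
        np.array([ka, 2.0, 3.0]), 2.0, 0.5, 0.45, 10.0, 1e7,
        np.array([[t - tlag]]),
    )[0, 0]
    assert conc >= 0.0
    if t <= tlag:
        assert conc == 0.0
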