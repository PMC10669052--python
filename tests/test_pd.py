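"""Sigmoid-Emax gastric pH model: point values, inversion, metrics, fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rabepkpd as r
from rabepkpd.model import ConcentrationProfile
from rabepkpd.pd import EffectProfile, SigmoidEmaxParams, effect_metrics, fit_pd


class TestEffectFunction:
    def test_baseline_at_zero_concentration(self, pd_params):
        assert r.effect_at_concentration(0.0, pd_params) == pytest.approx(2.50)

    def test_half_max_at_ec50(self, pd_params):
        expected = 2.50 + 4.72 / 2
        assert r.effect_at_concentration(51.58, pd_params) == pytest.approx(expected)

    def test_ph4_concentration(self, pd_params):
        assert r.effect_at_concentration(44.32, pd_params) == pytest.approx(4.00, abs=0.01)

    def test_negative_concentration_rejected(self, pd_params):
        with pytest.raises(ValueError):
            r.effect_at_concentration(-1.0, pd_params)

    def test_strictly_increasing_and_bounded(self, pd_params):
        c = np.linspace(0, 5000, 2000)
        e = r.effect_at_concentration(c, pd_params)
        assert np.all(np.diff(e) > 0)
        assert e[0] >= pd_params.E0 and e[-1] < pd_params.E0 + pd_params.Emax


class TestInvertEffect:
    def test_half_max_inverts_to_ec50(self, pd_params):
        assert r.invert_effect(2.50 + 4.72 / 2, pd_params) == pytest.approx(51.58, rel=1e-9)

    def test_ph4_inverts_to_about_44(self, pd_params):
        c = r.invert_effect(4.0, pd_params)
        # brute-force bisection oracle
        lo, hi = 1e-6, 1e6
        for _ in range(200):
            mid = np.sqrt(lo * hi)
            if r.effect_at_concentration(mid, pd_params) < 4.0:
                lo = mid
            else:
                hi = mid
        assert c == pytest.approx(lo, rel=1e-6)
        assert c == pytest.approx(44.3, abs=0.1)

    def test_baseline_unreachable(self, pd_params):
        with pytest.raises(ValueError, match="unreachable"):
            r.invert_effect(2.50, pd_params)
        with pytest.raises(ValueError, match="unreachable"):
            r.invert_effect(2.50 + 4.72, pd_params)

    @given(frac=st.floats(0.02, 0.98))
    @settings(max_examples=40, deadline=None)
    def test_mutual_inverse(self, pd_params, frac):
        target = pd_params.E0 + frac * pd_params.Emax
        c = r.invert_effect(target, pd_params)
        assert r.effect_at_concentration(c, pd_params) == pytest.approx(target, abs=1e-6)


class TestEffectProfileAndMetrics:
    def test_zero_concentration_gives_baseline(self, pd_params):
        prof = ConcentrationProfile(times=np.linspace(0, 10, 11), conc=np.zeros(11))
        eff = r.effect_profile(prof, pd_params)
        assert np.allclose(eff.pH, 2.50)

    def test_scaling_concentration_raises_ph_pointwise(self, pd_params, typical_male, dose_10mg):
        t = np.linspace(0, 10, 201)
        prof = r.solve_profile(typical_male, dose_10mg, t)
        e1 = r.effect_profile(prof, pd_params).pH
        e10 = r.effect_profile(
            ConcentrationProfile(times=t, conc=prof.conc * 10), pd_params
        ).pH
        assert np.all(e10 >= e1)

    def test_typical_male_peak_in_therapeutic_range(self, pd_params, typical_male, dose_10mg):
        t = np.arange(0, 10.001, 0.01)
        eff = r.effect_profile(r.solve_profile(typical_male, dose_10mg, t), pd_params)
        m = r.effect_metrics(eff)
        assert 4.0 < m.max_effect < 2.50 + 4.72

    def test_baseline_profile_metrics(self, pd_params):
        t = np.linspace(0, 10, 1001)
        m = effect_metrics(EffectProfile(times=t, pH=np.full_like(t, 2.50)))
        assert m.auec == pytest.approx(25.0)
        assert m.duration == 0.0
        assert m.onset is None

    def test_triangle_crossing_geometry(self):
        # rises through 4 at t=2, falls back through 4 at t=5
        t = np.array([0.0, 2.0, 3.5, 5.0, 10.0])
        ph = np.array([2.0, 4.0, 6.0, 4.0, 1.0])
        eps = 1e-9
        ph[1] += eps  # crossing at the sample
        m = effect_metrics(EffectProfile(times=t, pH=ph))
        assert m.onset == pytest.approx(2.0, abs=1e-6)
        assert m.offset == pytest.approx(5.0, abs=1e-6)
        assert m.duration == pytest.approx(3.0, abs=1e-6)

    def test_grid_refinement_stability(self, pd_params, typical_male, dose_10mg):
        coarse = np.arange(0, 10.001, 0.01)
        fine = np.arange(0, 10.0001, 0.001)
        mc = r.effect_metrics(r.effect_profile(r.solve_profile(typical_male, dose_10mg, coarse), pd_params))
        mf = r.effect_metrics(r.effect_profile(r.solve_profile(typical_male, dose_10mg, fine), pd_params))
        assert mc.onset == pytest.approx(mf.onset, abs=0.01)
        assert mc.duration == pytest.approx(mf.duration, abs=0.01)

    def test_auec_at_least_baseline_area(self, pd_params, typical_male, dose_10mg):
        t = np.arange(0, 10.001, 0.01)
        eff = r.effect_profile(r.solve_profile(typical_male, dose_10mg, t), pd_params)
        assert r.effect_metrics(eff).auec >= 2.50 * 10.0

    def test_window_not_covered_rejected(self, pd_params):
        prof = EffectProfile(times=np.linspace(0, 5, 6), pH=np.full(6, 3.0))
        with pytest.raises(ValueError, match="window"):
            effect_metrics(prof, window=(0.0, 10.0))


def _pd_dataset(pd_params, n, noise_sd, rng):
    conc = np.concatenate([[0.0], np.geomspace(5, 400, n - 1)])
    ph = np.asarray(r.effect_at_concentration(conc, pd_params))
    return conc, ph + rng.normal(0, noise_sd, size=n)


class TestFitPD:
    def test_noise_free_self_consistency(self, pd_params):
        conc = np.geomspace(1, 500, 30)
        ph = r.effect_at_concentration(conc, pd_params)
        report = fit_pd(np.column_stack([conc, ph]))
        assert report.best == "sigmoid_emax_baseline"
        best = report.best_params
        assert best.E0 == pytest.approx(2.50, rel=1e-3)
        assert best.EC50 == pytest.approx(51.58, rel=1e-3)
        assert best.gamma == pytest.approx(5.04, rel=1e-3)

    def test_noisy_data_selects_sigmoid_and_recovers_baseline(self, pd_params):
        rng = np.random.default_rng(5)
        conc, ph = _pd_dataset(pd_params, 50, 0.8, rng)
        report = fit_pd(np.column_stack([conc, np.maximum(ph, 0.5)]))
        assert report.best == "sigmoid_emax_baseline"
        assert report.best_params.E0 == pytest.approx(2.50, abs=0.3)
        assert report.candidates[report.best].r > 0.5

    def test_free_gamma_beats_fixed_gamma_on_steep_data(self, pd_params):
        rng = np.random.default_rng(11)
        conc, ph = _pd_dataset(pd_params, 60, 0.3, rng)
        report = fit_pd(np.column_stack([conc, np.maximum(ph, 0.5)]),
                        candidates=("emax_baseline", "sigmoid_emax_baseline"))
        aic_fixed = report.candidates["emax_baseline"].aic
        aic_free = report.candidates["sigmoid_emax_baseline"].aic
        assert aic_free < aic_fixed

    def test_report_carries_uncertainty_fields(self, pd_params):
        rng = np.random.default_rng(3)
        conc, ph = _pd_dataset(pd_params, 40, 0.4, rng)
        report = fit_pd(np.column_stack([conc, np.maximum(ph, 0.5)]))
        best = report.candidates[report.best]
        assert set(best.se) == {"E0", "Emax", "EC50", "gamma"}
        assert all(v > 0 for v in best.se.values())
        lo, hi = best.ci95["EC50"]
        assert lo < best.params["EC50"] < hi

    def test_too_few_points_rejected(self, pd_params):
        with pytest.raises(ValueError, match="at least 8"):
            fit_pd(np.column_stack([np.arange(5.0), np.arange(5.0)]))

    def test_ec50_median_bias_small(self, pd_params):
        """Parameter recovery across replicate noisy datasets: median |bias|
        of EC50 below 10%."""
        rng = np.random.default_rng(17)
        biases = []
        for _ in range(40):
            conc, ph = _pd_dataset(pd_params, 50, 0.8, rng)
            try:
                rep = fit_pd(np.column_stack([conc, np.maximum(ph, 0.5)]),
                             candidates=("sigmoid_emax_baseline",))
            except RuntimeError:
                continue
            biases.append(abs(rep.best_params.EC50 - 51.58) / 51.58)
        assert np.median(biases) < 0.10
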