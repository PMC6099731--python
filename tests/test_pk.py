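"""One-compartment oral (Bateman) model: evaluation, peak, AUC, fitting."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from micropkpd import (
    CompartmentParams,
    ConcentrationTimeProfile,
    auc_analytic,
    auc_trapezoid,
    concentration_at,
    fit_pk,
    tmax_cmax,
)

rates = st.floats(min_value=0.05, max_value=5.0)


def make_profile(params, t, conc=None, dose_mg=None):
    conc = concentration_at(params, t) if conc is None else conc
    return ConcentrationTimeProfile(t, conc, dose=dose_mg or params.dose / 1e6)


class TestEvaluation:
    def test_zero_at_dose_time(self):
        p = CompartmentParams(1000.0, 10.0, 1.0, 0.5)
        assert concentration_at(p, 0.0) == 0.0

    def test_decays_to_zero(self):
        p = CompartmentParams(1000.0, 10.0, 1.0, 0.5)
        assert concentration_at(p, 200.0) == pytest.approx(0.0, abs=1e-12)

    def test_negative_time_rejected(self):
        p = CompartmentParams(1000.0, 10.0, 1.0, 0.5)
        with pytest.raises(ValueError, match="nonnegative"):
            concentration_at(p, -0.5)

    def test_nonpositive_parameters_rejected(self):
        with pytest.raises(ValueError):
            CompartmentParams(1000.0, 10.0, -1.0, 0.5)

    @given(k01=rates, k10=rates)
    def test_curve_nonnegative_and_unimodal(self, k01, k10):
        p = CompartmentParams(1000.0, 10.0, k01, k10)
        t = np.linspace(0, 24, 2000)
        c = concentration_at(p, t)
        assert np.all(c >= -1e-12)
        dc = np.diff(c)
        sign_changes = np.sum(np.diff(np.sign(dc[np.abs(dc) > 1e-12])) != 0)
        assert sign_changes <= 1  # rises then falls

    def test_degenerate_equal_rates_continuous(self):
        """The limit form agrees with nearly-equal distinct rates."""
        t = np.linspace(0.1, 12, 50)
        exact_limit = concentration_at(CompartmentParams(1000.0, 10.0, 0.5, 0.5), t)
        nearly = concentration_at(CompartmentParams(1000.0, 10.0, 0.5 * (1 + 1e-7), 0.5), t)
        assert np.allclose(exact_limit, nearly, rtol=1e-6)


class TestPeak:
    def test_closed_form_peak(self):
        p = CompartmentParams(1000.0, 10.0, 1.0, 0.5)
        t_peak, c_peak = tmax_cmax(p)
        assert t_peak == pytest.approx(np.log(2) / 0.5, rel=1e-12)  # 1.386 h
        grid = np.arange(0, 24, 1e-3)
        c = concentration_at(p, grid)
        assert abs(grid[np.argmax(c)] - t_peak) <= 1e-3
        assert c_peak == pytest.approx(c.max(), rel=1e-6)

    def test_degenerate_peak_is_reciprocal_rate(self):
        t_peak, _ = tmax_cmax(CompartmentParams(1000.0, 10.0, 0.5, 0.5))
        assert t_peak == pytest.approx(2.0, rel=1e-9)

    @given(k01=rates, k10=rates)
    def test_formula_matches_grid_argmax(self, k01, k10):
        p = CompartmentParams(1000.0, 10.0, k01, k10)
        t_peak, _ = tmax_cmax(p)
        grid = np.arange(0.0, 24.0, 1e-3)
        assert abs(grid[np.argmax(concentration_at(p, grid))] - t_peak) <= 1e-3 + 1e-9


class TestAUC:
    def test_k01_free_closed_form(self):
        for k01 in (0.2, 1.0, 4.0):
            p = CompartmentParams(1000.0, 10.0, k01, 0.5)
            assert auc_analytic(p) == pytest.approx(200.0, rel=1e-12)

    def test_dose_linearity(self):
        p1 = CompartmentParams(1000.0, 10.0, 1.0, 0.5)
        p2 = CompartmentParams(2000.0, 10.0, 1.0, 0.5)
        assert auc_analytic(p2) == pytest.approx(2 * auc_analytic(p1), rel=1e-12)

    @given(k01=rates, k10=rates)
    def test_quadrature_consistency(self, k01, k10):
        """Dense trapezoid integration reproduces D/(V*k10) within 0.5%."""
        p = CompartmentParams(1000.0, 10.0, k01, k10)
        t_end = 20.0 / min(k01, k10)
        t = np.linspace(0.0, t_end, 40001)
        num = auc_trapezoid(times=t, concentrations=concentration_at(p, t))
        assert num == pytest.approx(auc_analytic(p), rel=5e-3)


class TestFlipFlop:
    def test_twin_curve_pointwise_identical(self):
        p = CompartmentParams(6e7, 63930.7, 0.6931, 0.3466)
        q = p.flipped()
        t = np.linspace(0, 12, 200)
        np.testing.assert_allclose(
            concentration_at(p, t), concentration_at(q, t), rtol=1e-12
        )
        assert q.k01 == p.k10 and q.k10 == p.k01

    def test_objective_identical_across_branches(self):
        rng = np.random.default_rng(5)
        p = CompartmentParams(6e7, 63930.7, 0.6931, 0.3466)
        t = np.arange(0.0, 9.0)
        obs = np.maximum(concentration_at(p, t) * (1 + rng.normal(0, 0.1, t.size)), 0)
        sse = lambda pars: float(np.sum((concentration_at(pars, t) - obs) ** 2))
        assert abs(sse(p) - sse(p.flipped())) < 1e-10

    def test_fitter_reports_requested_branch(self):
        p = CompartmentParams(6e7, 63930.7, 0.6931, 0.3466)
        t = np.arange(0.0, 9.0)
        prof = make_profile(p, t, dose_mg=60.0)
        fast = fit_pk(prof, branch="k01>k10").params
        slow = fit_pk(prof, branch="k10>k01").params
        assert fast.k01 > fast.k10
        assert slow.k10 > slow.k01
        tt = np.linspace(0, 8, 50)
        np.testing.assert_allclose(
            concentration_at(fast, tt), concentration_at(slow, tt), rtol=1e-6
        )


class TestFit:
    def test_noise_free_self_consistency(self):
        truth = CompartmentParams(6e7, 63930.7, 0.9, 0.3)
        t = np.arange(0.0, 9.0)
        fit = fit_pk(make_profile(truth, t, dose_mg=60.0))
        assert fit.params.volume == pytest.approx(truth.volume, rel=1e-4)
        assert fit.params.k01 == pytest.approx(truth.k01, rel=1e-4)
        assert fit.params.k10 == pytest.approx(truth.k10, rel=1e-4)
        assert fit.residual_ss == pytest.approx(0.0, abs=1e-8)
        assert fit.success

    def test_refit_of_flipped_truth_gives_identical_curve(self):
        truth = CompartmentParams(6e7, 63930.7, 0.9, 0.3)
        t = np.arange(0.0, 9.0)
        fit_a = fit_pk(make_profile(truth, t, dose_mg=60.0))
        fit_b = fit_pk(make_profile(truth.flipped(), t, dose_mg=60.0))
        tt = np.linspace(0, 8, 100)
        np.testing.assert_allclose(fit_a.predict(tt), fit_b.predict(tt), rtol=1e-6)
        assert abs(fit_a.residual_ss - fit_b.residual_ss) < 1e-10

    def test_preconditions(self):
        t = np.arange(0.0, 3.0)
        with pytest.raises(ValueError, match=">=4 time points"):
            fit_pk(ConcentrationTimeProfile(t, [0, 5, 3], dose=30.0))
        t = np.arange(0.0, 5.0)
        with pytest.raises(ValueError, match="all-zero"):
            fit_pk(ConcentrationTimeProfile(t, np.zeros(5), dose=30.0))
        with pytest.raises(ValueError, match="post-peak"):
            fit_pk(ConcentrationTimeProfile(t, [0, 1, 2, 3, 4.0], dose=30.0))
        with pytest.raises(ValueError, match="dose"):
            fit_pk(ConcentrationTimeProfile(t, [0, 5, 3, 2, 1.0]))

    def test_weighted_fit_runs(self):
        truth = CompartmentParams(6e7, 63930.7, 0.9, 0.3)
        t = np.arange(0.0, 9.0)
        for w in ("1/y", "1/y2"):
            fit = fit_pk(make_profile(truth, t, dose_mg=60.0), weighting=w)
            assert fit.params.k10 == pytest.approx(truth.k10, rel=1e-3)
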