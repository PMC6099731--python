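"""Non-compartmental analysis: AUC, terminal slope, derived parameters."""

import numpy as np
import pytest

from micropkpd import (
    CompartmentParams,
    ConcentrationTimeProfile,
    apparent_clearance,
    apparent_volume,
    auc_analytic,
    auc_trapezoid,
    concentration_at,
    mean_profile,
    nca_analyze,
    terminal_slope,
)

LN2 = np.log(2.0)


def profile(times, concs, dose=None, **kw):
    return ConcentrationTimeProfile(np.asarray(times, float), np.asarray(concs, float), dose=dose, **kw)


class TestAUC:
    def test_hand_computed_trapezoids(self):
        assert auc_trapezoid(profile([0, 1, 2], [0, 100, 50])) == pytest.approx(125.0)

    def test_constant_profile(self):
        p = profile(np.linspace(0, 8, 17), np.full(17, 42.0))
        assert auc_trapezoid(p) == pytest.approx(8 * 42.0)

    def test_dense_bateman_converges_to_analytic(self):
        params = CompartmentParams(dose=1000.0, volume=10.0, k01=1.0, k10=0.5)
        t = np.arange(0.0, 48.0, 0.01)
        p = profile(t, concentration_at(params, t))
        assert auc_trapezoid(p) == pytest.approx(auc_analytic(params), rel=5e-3)

    def test_additivity_is_exact(self):
        t = np.array([0.0, 0.5, 1.0, 2.0, 4.0, 8.0])
        c = np.array([0.0, 80.0, 100.0, 60.0, 20.0, 5.0])
        k = 3
        left = auc_trapezoid(times=t[: k + 1], concentrations=c[: k + 1])
        right = auc_trapezoid(times=t[k:], concentrations=c[k:])
        assert left + right == auc_trapezoid(times=t, concentrations=c)

    def test_linlog_exact_on_mono_exponential_decline(self):
        lam = 0.953
        t = np.array([1.0, 2.0, 4.0, 8.0])
        c = 100 * np.exp(-lam * t)
        exact = (c[0] - c[-1]) / lam
        assert auc_trapezoid(times=t, concentrations=c, method="linlog") == pytest.approx(exact, rel=1e-12)

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="two time points"):
            auc_trapezoid(profile([1.0], [5.0]))


class TestTerminalSlope:
    def test_exact_halving_per_hour(self):
        term = terminal_slope(profile([2.0, 3.0], [50.0, 25.0]), n_terminal=2)
        assert term.lambda_z == pytest.approx(LN2, rel=1e-12)
        assert term.t_half == pytest.approx(1.0, rel=1e-12)

    def test_mono_exponential_recovers_half_life(self):
        lam = 0.953  # gives t_half 0.727 h, the mid-dose scale
        t = np.array([4.0, 5.0, 6.0])
        term = terminal_slope(profile(t, 100 * np.exp(-lam * t)))
        assert term.lambda_z == pytest.approx(lam, rel=1e-10)
        assert term.t_half == pytest.approx(0.7273, abs=5e-4)

    def test_rising_terminal_points_flagged(self):
        with pytest.raises(ValueError, match="do not decline"):
            terminal_slope(profile([0, 1, 2, 3], [1.0, 2.0, 3.0, 4.0]))

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError, match="nonpositive"):
            terminal_slope(profile([0, 1, 2, 3], [10.0, 5.0, 2.0, 0.0]))


class TestUnitConversions:
    """dose mg/kg over AUC ng*h/mL must come out in L/h/kg (and V/F in L/kg)."""

    def test_apparent_clearance(self):
        # 30 mg/kg = 3e7 ng/kg; / (283.434 ng*h/mL) = 105845 mL/h/kg
        assert apparent_clearance(30.0, 283.434) == pytest.approx(105.845, abs=1e-3)

    def test_apparent_volume(self):
        assert apparent_volume(40.529, 0.726) == pytest.approx(42.45, abs=0.01)

    def test_positivity_required(self):
        with pytest.raises(ValueError):
            apparent_clearance(0.0, 100.0)
        with pytest.raises(ValueError):
            apparent_volume(10.0, -1.0)


class TestNCAAnalyze:
    def test_noise_free_bateman_recovery(self):
        """Dense noise-free sampling recovers peak, half-life and clearance."""
        params = CompartmentParams.from_mg_per_kg(60.0, 63930.7, 0.9, 0.3)
        t = np.arange(0.0, 24.0 + 1e-9, 0.05)
        p = profile(t, concentration_at(params, t), dose=60.0)
        res = nca_analyze(p, auc_basis="0-inf")
        t_peak = np.log(params.k01 / params.k10) / (params.k01 - params.k10)
        assert abs(res.tmax - t_peak) <= 0.05  # within one sampling interval
        assert res.t_half == pytest.approx(LN2 / min(params.k01, params.k10), rel=0.02)
        assert res.cl_f == pytest.approx(params.cl / 1000.0, rel=0.02)  # mL -> L
        assert res.auc_0_inf >= res.auc_0_t

    def test_cmax_tie_breaks_to_earliest_time(self):
        p = profile([0, 1, 2, 3, 4], [0, 50, 50, 20, 10], dose=30.0)
        res = nca_analyze(p)
        assert res.tmax == 1.0 and res.cmax == 50.0

    def test_zero_last_concentration_skips_extrapolation(self):
        """A terminal zero (below-LOQ) sample removes the Clast/lambda_z tail."""
        zero_tail = profile([0, 1, 2, 3, 4, 5], [0, 100, 50, 25, 12.5, 0.0], dose=30.0)
        res = nca_analyze(zero_tail)
        assert res.auc_0_inf == res.auc_0_t
        # the same profile with a positive last point does extrapolate
        pos_tail = profile([0, 1, 2, 3, 4], [0, 100, 50, 25, 12.5], dose=30.0)
        assert nca_analyze(pos_tail).auc_0_inf > nca_analyze(pos_tail).auc_0_t

    def test_vd_modes_differ_as_documented(self):
        """The literal dose/Cmax volume is far larger than the AUC-based one."""
        params = CompartmentParams.from_mg_per_kg(30.0, 120502.0, LN2, LN2 / 2)
        t = np.arange(0.0, 9.0)
        p = profile(t, concentration_at(params, t), dose=30.0)
        v_auc = nca_analyze(p, vd_mode="auc").v_f
        v_cmax = nca_analyze(p, vd_mode="cmax").v_f
        assert v_cmax == pytest.approx(30.0 * 1e3 / p.concentrations.max(), rel=1e-12)
        assert v_cmax > 1.5 * v_auc

    def test_dose_required(self):
        p = profile([0, 1, 2, 3], [0, 10, 5, 2.5])
        with pytest.raises(ValueError, match="dose"):
            nca_analyze(p)


def test_mean_of_individuals_close_to_parameters_of_mean():
    """CL/F from the mean profile vs the mean of per-subject CL/F: <1% apart
    at the 10% proportional noise level the recovery benchmarks use."""
    rng = np.random.default_rng(42)
    params = CompartmentParams.from_mg_per_kg(60.0, 63930.7, 2 * LN2 / 2, LN2 / 2)
    t = np.arange(0.0, 9.0)
    clean = concentration_at(params, t)
    profiles = [
        profile(t, np.maximum(clean * (1 + rng.normal(0, 0.1, t.size)), 0),
                dose=60.0, group="medium", subject=f"s{i}")
        for i in range(6)
    ]
    cl_each = [nca_analyze(p).cl_f for p in profiles]
    cl_mean_profile = nca_analyze(mean_profile(profiles)).cl_f
    assert np.mean(cl_each) == pytest.approx(cl_mean_profile, rel=0.01)
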