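"""Synthetic study generator: determinism, calibration, structure."""

import numpy as np
import pytest

from micropkpd import (
    StudyDesign,
    concentration_at,
    default_pd_population,
    default_pk_population,
    generate_pd_profiles,
    generate_pk_profiles,
    generate_recovery_experiment,
    generate_stability_series,
    relative_loss,
    relative_recovery,
    tmax_cmax,
)
from micropkpd.synthetic import GroupSpec, LOQ_DRUG_NG_ML


class TestPKGeneration:
    def test_same_seed_reproduces_exactly(self):
        d = StudyDesign(seed=17)
        p1, t1 = generate_pk_profiles(d)
        p2, t2 = generate_pk_profiles(d)
        assert len(p1) == len(p2) == 18  # three dosed groups of six
        for a, b in zip(p1, p2):
            np.testing.assert_array_equal(a.concentrations, b.concentrations)
        assert t1.pk == t2.pk

    def test_zero_variability_reproduces_population_curve(self):
        profiles, truth = generate_pk_profiles(
            StudyDesign(seed=0), iiv_cv=0.0, noise_cv=0.0
        )
        for p in profiles:
            pop = default_pk_population(p.dose)
            np.testing.assert_allclose(
                p.concentrations, concentration_at(pop, p.times), rtol=1e-12
            )

    def test_population_defaults_hit_design_peak(self):
        """Mean curves peak at 2 h with the calibrated group Cmax."""
        for dose, cmax in [(30.0, 124.479), (60.0, 469.258), (120.0, 805.906)]:
            t_peak, c_peak = tmax_cmax(default_pk_population(dose))
            assert t_peak == pytest.approx(2.0, rel=1e-12)
            assert c_peak == pytest.approx(cmax, rel=1e-9)

    def test_unknown_dose_rejected(self):
        with pytest.raises(ValueError, match="no default population"):
            default_pk_population(45.0)

    def test_loq_flag_counted(self):
        profiles, _ = generate_pk_profiles(StudyDesign(seed=1), iiv_cv=0.0, noise_cv=0.0)
        low = [p for p in profiles if p.group == "low"][0]
        assert low.meta["n_below_loq"] == int(np.sum(low.concentrations < LOQ_DRUG_NG_ML))

    def test_truncation_counted(self):
        _, truth = generate_pk_profiles(StudyDesign(seed=2), noise_cv=0.9)
        assert truth.n_truncated > 0


class TestPDGeneration:
    @pytest.fixture()
    def study(self):
        design = StudyDesign(seed=4)
        pk_profiles, pk_truth = generate_pk_profiles(design, iiv_cv=0.0, noise_cv=0.0)
        pd_profiles, pd_truth = generate_pd_profiles(
            design, pk_truth=pk_truth, iiv_cv=0.0, noise_cv=0.0
        )
        return design, pd_profiles, pd_truth

    def test_model_group_holds_elevated_flat_baseline(self, study):
        _, profiles, _ = study
        model = [p for p in profiles if p.group == "model"]
        blank = [p for p in profiles if p.group == "blank"]
        for p in model:
            assert np.ptp(p.concentrations) == 0.0  # unchanged over 8 h
        for b, m in zip(blank, model):
            assert np.all(b.concentrations < m.concentrations)

    def test_dosed_group_dips_and_recovers_after_peak(self, study):
        design, profiles, _ = study
        med = [p for p in profiles if p.group == "medium"][0]
        i_nadir = int(np.argmin(med.concentrations))
        assert med.times[i_nadir] > 2.0  # nadir lags the 2 h drug peak
        assert med.concentrations[0] == pytest.approx(
            default_pd_population(60.0).baseline, rel=1e-9
        )

    def test_missing_pk_truth_rejected(self):
        design = StudyDesign(seed=5)
        _, pk_truth = generate_pk_profiles(design)
        pk_truth.pk.pop(("medium", "medium-01"))
        with pytest.raises(ValueError, match="missing subject"):
            generate_pd_profiles(design, pk_truth=pk_truth)

    def test_dosed_groups_require_pk_truth(self):
        with pytest.raises(ValueError, match="pk_truth"):
            generate_pd_profiles(StudyDesign(seed=5), pk_truth=None)


class TestRecoveryGeneration:
    def test_noise_free_values_exact_by_construction(self):
        ms = generate_recovery_experiment({1.0: 0.4805}, noise_cv=0.0)
        gains = [m for m in ms if m.method == "gain"]
        losses = [m for m in ms if m.method == "loss"]
        assert len(gains) == len(losses) == 4  # bench replicate count
        for g, l in zip(gains, losses):
            assert relative_recovery(g) == pytest.approx(48.05, rel=1e-12)
            assert relative_loss(l) == pytest.approx(48.05, rel=1e-12)

    def test_determinism_and_noise(self):
        a = generate_recovery_experiment(seed=9)
        b = generate_recovery_experiment(seed=9)
        assert [m.c_dialysate for m in a] == [m.c_dialysate for m in b]

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError, match="transfer fractions"):
            generate_recovery_experiment({1.0: 1.2})
        with pytest.raises(ValueError, match="bath_concentration"):
            generate_recovery_experiment({1.0: 0.5}, bath_concentration=0.0)


class TestStabilitySeries:
    def test_length_and_determinism(self):
        s1 = generate_stability_series(seed=3)
        s2 = generate_stability_series(seed=3)
        np.testing.assert_array_equal(s1, s2)
        assert s1.size == 8

    def test_noise_free_series_constant(self):
        s = generate_stability_series(noise_cv=0.0)
        np.testing.assert_allclose(s, 29.07, rtol=1e-12)


class TestDesign:
    def test_defaults(self):
        d = StudyDesign()
        assert [g.label for g in d.groups] == ["blank", "model", "low", "medium", "high"]
        assert all(g.n == 6 for g in d.groups)
        assert list(d.times) == [0, 1, 2, 3, 4, 5, 6, 7, 8]
        assert [g.dose for g in d.dosed_groups] == [30.0, 60.0, 120.0]

    def test_validation(self):
        with pytest.raises(ValueError, match="increasing"):
            StudyDesign(times=(0.0, 2.0, 1.0))
        with pytest.raises(ValueError, match="group size"):
            GroupSpec("x", 30.0, 0)
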