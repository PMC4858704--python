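"""Generators: determinism, noiseless model-exactness, scenario structure."""

import numpy as np
import pytest

from conftest import make_spec
from silkcoat import oxygen, postharvest, water_vapour
from silkcoat.io_core import ValidationError
from silkcoat.synthetic import (
    BETA_PCT_BY_ANNEALING_H,
    DEFAULT_GEOMETRY,
    TABLE2_WVP,
    default_amide3_bands,
    default_headspace_schedule,
    gen_amide3_spectrum,
    gen_cup_series,
    gen_dehydration_series,
    gen_headspace_series,
    gen_oxygen_experiment,
    gen_puncture_curve,
    gen_stopper_experiment,
    table1_scenarios,
)


class TestOxygenGenerator:
    def test_equilibrium_start_stays_constant(self, condition):
        spec = make_spec(condition, D=0.0, D_B=0.0, noiseless=True)
        series = gen_oxygen_experiment(spec, DEFAULT_GEOMETRY, c_R0=8.0)
        np.testing.assert_allclose(series.c_R, 8.0)

    def test_known_point_on_closed_form(self, condition):
        # alpha = 0.01/min via membrane alone: c_R(100) = 8(1-e^-1) = 5.0570
        geo = DEFAULT_GEOMETRY
        D = 0.01 / geo.k_M / 60.0  # cm^2/s giving alpha = 0.01 min^-1
        spec = make_spec(condition, D=D, D_B=0.0, noiseless=True)
        series = gen_oxygen_experiment(spec, geo, schedule=np.array([0.0, 100.0]))
        assert series.c_R[-1] == pytest.approx(5.0570, abs=5e-4)

    def test_seed_reproducibility(self, condition):
        spec = make_spec(condition, seed=9)
        a = gen_oxygen_experiment(spec)
        b = gen_oxygen_experiment(spec)
        np.testing.assert_array_equal(a.c_R, b.c_R)

    def test_stopper_excludes_membrane(self, condition):
        spec = make_spec(condition, D=1e-5, D_B=0.0, noiseless=True)
        series = gen_stopper_experiment(spec)
        np.testing.assert_allclose(series.c_R, 0.0)  # no leak, no membrane

    def test_stopper_log_linear_rate(self, condition):
        spec = make_spec(condition, D=1e-5, D_B=0.2, noiseless=True)
        series = gen_stopper_experiment(spec)
        fit = oxygen.fit_diffusion_factor(series)
        assert fit.alpha_per_min == pytest.approx(0.002, rel=1e-9)  # D_B/V_R

    def test_negative_noise_rejected(self, condition):
        with pytest.raises(ValidationError):
            make_spec(condition, oxygen_noise_sd=-0.1)

    def test_noiseless_recovery_is_exact(self, condition, geometry):
        """Noiseless generator output satisfies the estimator's model: truth
        is recovered to better than 1e-6 relative."""
        spec = make_spec(condition, D=1e-6, D_B=0.02, noiseless=True)
        reps = [gen_oxygen_experiment(spec, geometry, seed_offset=i) for i in range(3)]
        stop = gen_stopper_experiment(spec, geometry)
        res = oxygen.analyze_film(reps, stop, geometry)
        assert res.D_eM_cm2_per_s == pytest.approx(1e-6, rel=1e-6)


class TestCupGenerator:
    def test_zero_wvtr_constant_weight(self):
        cup = gen_cup_series(0.0, noise_sd_g=0.0)
        assert np.ptp(cup.weight_g) == 0.0

    def test_generated_slope_matches_wvtr(self):
        cup = gen_cup_series(1.804e-3, noise_sd_g=0.0)
        wvtr, r2, _, _ = water_vapour.fit_wvtr(cup)
        assert wvtr == pytest.approx(1.804e-3, rel=1e-9)
        assert r2 == pytest.approx(1.0)

    def test_seed_reproducibility(self):
        a = gen_cup_series(1e-3, seed=4, noise_sd_g=1e-3)
        b = gen_cup_series(1e-3, seed=4, noise_sd_g=1e-3)
        np.testing.assert_array_equal(a.weight_g, b.weight_g)


class TestSpectrumGenerator:
    def test_single_beta_band_is_all_beta(self):
        centers, sigmas, areas, is_beta = default_amide3_bands(1.0)
        areas = np.where(is_beta, areas, 0.0)
        areas[np.argmax(is_beta)] = 1.0
        frac = areas[is_beta].sum() / areas.sum()
        assert frac == 1.0

    def test_equal_bands_fraction(self):
        centers = np.linspace(1212.0, 1338.0, 12)
        in_window = (centers >= 1216.0) & (centers <= 1250.0)
        areas = np.ones(12)
        assert areas[in_window].sum() / areas.sum() == pytest.approx(in_window.sum() / 12.0)

    def test_band_validation(self):
        with pytest.raises(ValidationError):
            gen_amide3_spectrum(np.full(12, 1100.0), np.full(12, 5.0), np.ones(12))
        with pytest.raises(ValidationError):
            centers, sigmas, _ = np.linspace(1212, 1338, 12), np.full(12, 5.0), None
            gen_amide3_spectrum(centers, sigmas, -np.ones(12))

    def test_seed_reproducibility(self):
        centers, sigmas, areas, _ = default_amide3_bands(0.4)
        a = gen_amide3_spectrum(centers, sigmas, areas, seed=8)
        b = gen_amide3_spectrum(centers, sigmas, areas, seed=8)
        np.testing.assert_array_equal(a.absorbance, b.absorbance)


class TestDehydrationGenerator:
    def test_zero_rate_constant_weight(self):
        ts = gen_dehydration_series(20.0, 0.0, noise_sd_g=0.0)
        np.testing.assert_allclose(ts.y, 20.0)

    def test_asymptotic_loss(self):
        # k large: w(14 d) -> w_eq = 5 g, loss fraction -> 0.75
        ts = gen_dehydration_series(20.0, 5.0, w_eq_fraction=0.25, noise_sd_g=0.0)
        assert ts.y[-1] == pytest.approx(5.0, rel=1e-6)
        ws = postharvest.WeightSeries(ts.t, ts.y)
        assert postharvest.weight_loss_fraction(ws, 14.0) == pytest.approx(0.75, rel=1e-6)

    def test_seed_reproducibility(self):
        a = gen_dehydration_series(20.0, 0.1, seed=3)
        b = gen_dehydration_series(20.0, 0.1, seed=3)
        np.testing.assert_array_equal(a.y, b.y)


class TestHeadspaceGenerator:
    def test_zero_rate_flat(self):
        jar = gen_headspace_series(0.0, noise_sd_pct=0.0, co2_0_pct=0.0)
        np.testing.assert_allclose(jar.co2_pct, 0.0)

    def test_known_accumulation(self):
        # 18 ml/kg/h, 0.1 kg, 900 ml: dCO2(6 h) = 100*18*0.1*6/900 = 1.2 %
        jar = gen_headspace_series(
            18.0, 0.1, 900.0, schedule_h=np.array([0.0, 6.0]), noise_sd_pct=0.0, co2_0_pct=0.0
        )
        assert jar.co2_pct[-1] == pytest.approx(1.2)

    def test_default_schedule_matches_protocol(self):
        """Brute-force enumeration of the sampling protocol: 30-min steps to
        5 h, 90-min steps to the 12th hour, 180-min steps for 24 h more."""
        expected = [0.0]
        t = 0.0
        for step, end in ((0.5, 5.0), (1.5, 12.0), (3.0, None)):
            stop = end if end is not None else t + 24.0
            while t < stop - 1e-9:
                t += step
                expected.append(t)
        sched = default_headspace_schedule()
        np.testing.assert_allclose(sched, expected)
        assert len(sched) - 1 == 23  # samples after t=0


class TestPunctureGenerator:
    def test_stated_peak_inside_window(self):
        curve = gen_puncture_curve(4.2, 6.0, 8.0, noise_sd_n=0.0)
        assert postharvest.max_penetration_force(curve) == pytest.approx(4.2, rel=1e-6)

    def test_peak_beyond_window(self):
        curve = gen_puncture_curve(4.2, 12.0, 8.0, noise_sd_n=0.0)
        assert postharvest.max_penetration_force(curve) < 4.2

    def test_seed_reproducibility(self):
        a = gen_puncture_curve(3.0, seed=6)
        b = gen_puncture_curve(3.0, seed=6)
        np.testing.assert_array_equal(a.force_n, b.force_n)


class TestTable1Scenarios:
    def test_annealing_to_beta_map(self):
        specs = table1_scenarios()
        mapping = {s.condition.annealing_hours: s.condition.beta_sheet_pct for s in specs}
        assert mapping == BETA_PCT_BY_ANNEALING_H

    def test_diffusivity_span_is_two_orders(self):
        specs = table1_scenarios()
        d = [s.true_D_eM_cm2_s for s in specs]
        assert d[-1] / d[0] == pytest.approx(0.01, rel=1e-9)
        assert all(a > b for a, b in zip(d, d[1:]))

    def test_wvtr_strictly_decreasing_and_anchored(self):
        specs = table1_scenarios()
        w = [s.true_wvtr_g_m2_s for s in specs]
        assert all(a > b for a, b in zip(w, w[1:]))
        # annealed films carry the measured permeabilities
        for s in specs[1:]:
            wvp = s.true_wvtr_g_m2_s * 75e-6 / (2645.0 * 0.75)
            assert wvp == pytest.approx(TABLE2_WVP[s.condition.beta_sheet_pct], rel=1e-9)

    def test_fold_ratio_configurable(self):
        specs = table1_scenarios(d_em_ratio=0.02)  # the 50-fold reading
        d = [s.true_D_eM_cm2_s for s in specs]
        assert d[-1] / d[0] == pytest.approx(0.02, rel=1e-9)
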