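"""Respiration, dehydration, firmness metrics and group statistics."""

import numpy as np
import pandas as pd
import pytest

from silkcoat.io_core import ValidationError
from silkcoat.postharvest import (
    HeadspaceSeries,
    PunctureCurve,
    WeightSeries,
    firmness_summary,
    group_compare,
    max_penetration_force,
    respiration_rate,
    weight_loss_fraction,
)


class TestRespiration:
    def test_no_co2_rise_means_zero_rate(self):
        hs = HeadspaceSeries(np.array([0.0, 6.0]), np.array([0.5, 0.5]), 0.1, 900.0)
        assert respiration_rate(hs) == 0.0

    def test_hand_checked_instance(self):
        # dCO2 1.2 % over 6 h, 0.1 kg fruit, 900 ml headspace -> 18 ml/kg/h
        hs = HeadspaceSeries(np.array([0.0, 6.0]), np.array([0.0, 1.2]), 0.1, 900.0)
        assert respiration_rate(hs) == pytest.approx(18.0)

    @pytest.mark.parametrize("f", [0.5, 2.0, 3.0])
    def test_scaling_laws(self, f):
        """Rate is linear in headspace volume, inverse in mass and time span."""
        t, c = np.array([0.0, 6.0]), np.array([0.0, 1.2])
        base = respiration_rate(HeadspaceSeries(t, c, 0.1, 900.0))
        assert respiration_rate(HeadspaceSeries(t, c, 0.1, f * 900.0)) == pytest.approx(f * base)
        assert respiration_rate(HeadspaceSeries(t, c, f * 0.1, 900.0)) == pytest.approx(base / f)
        assert respiration_rate(
            HeadspaceSeries(f * t + np.array([0.0, 0.0]), c, 0.1, 900.0)
        ) == pytest.approx(base / f)

    def test_window_selection_and_slope_method(self):
        from silkcoat.synthetic import gen_headspace_series

        jar = gen_headspace_series(18.0, noise_sd_pct=0.02, seed=2)
        assert respiration_rate(jar, window=(0.0, 12.0)) == pytest.approx(18.0, rel=0.05)
        assert respiration_rate(jar, method="slope") == pytest.approx(18.0, rel=0.02)

    def test_degenerate_window(self):
        hs = HeadspaceSeries(np.array([0.0, 1.0, 6.0]), np.array([0.0, 0.2, 1.2]), 0.1, 900.0)
        with pytest.raises(ValidationError):
            respiration_rate(hs, window=(2.0, 3.0))


class TestWeightLoss:
    SERIES = WeightSeries(
        np.array([0.0, 1.0, 3.0, 5.0, 7.0, 14.0]),
        np.array([20.0, 18.0, 15.0, 12.0, 9.0, 6.0]),
    )

    def test_day_zero_is_zero(self):
        assert weight_loss_fraction(self.SERIES, 0.0) == 0.0

    def test_seventy_percent_loss_at_day_14(self):
        # w0 = 20 g, w(14) = 6 g -> 70 % of the original weight lost
        assert weight_loss_fraction(self.SERIES, 14.0) == pytest.approx(0.70)

    def test_interpolation_between_days(self):
        assert weight_loss_fraction(self.SERIES, 2.0) == pytest.approx(1.0 - 16.5 / 20.0)

    def test_constant_weight_gives_zero_everywhere(self):
        ws = WeightSeries(np.array([0.0, 7.0, 14.0]), np.full(3, 20.0))
        for day in (0.0, 3.5, 14.0):
            assert weight_loss_fraction(ws, day) == 0.0

    def test_out_of_range_day(self):
        with pytest.raises(ValidationError):
            weight_loss_fraction(self.SERIES, 21.0)

    def test_monotone_for_nonincreasing_weights(self):
        days = np.linspace(0.0, 14.0, 29)
        losses = [weight_loss_fraction(self.SERIES, d) for d in days]
        assert all(0.0 <= x <= 1.0 for x in losses)
        assert all(b >= a for a, b in zip(losses, losses[1:]))


class TestFirmness:
    @staticmethod
    def _unimodal(peak, depth, length=8.0):
        x = np.arange(0.0, length + 0.05, 0.1)
        rel = x / depth
        return PunctureCurve(x, peak * (rel * np.exp(1 - rel)) ** 2)

    def test_peak_inside_window(self):
        assert max_penetration_force(self._unimodal(4.2, 6.0)) == pytest.approx(4.2, rel=1e-3)

    def test_peak_beyond_window_truncated(self):
        curve = self._unimodal(4.2, 12.0)  # still rising at 8 mm
        assert max_penetration_force(curve) < 4.2

    def test_monotone_curve_takes_end_value(self):
        x = np.arange(0.0, 8.1, 0.1)
        curve = PunctureCurve(x, 3.0 * x / 8.0)
        assert max_penetration_force(curve) == pytest.approx(3.0, rel=1e-2)

    def test_truncated_curve_warns(self):
        x = np.arange(0.0, 5.0, 0.1)
        with pytest.warns(UserWarning, match="truncated"):
            max_penetration_force(PunctureCurve(x, np.ones_like(x)))

    def test_replicate_aggregation(self):
        curves = [self._unimodal(4.0, 6.0), self._unimodal(5.0, 6.0)]
        mean, sd, maxima = firmness_summary(curves)
        assert mean == pytest.approx(4.5, rel=1e-3)
        assert maxima == pytest.approx([4.0, 5.0], rel=1e-3)


class TestGroupCompare:
    def test_identical_groups_not_flagged(self):
        data = {"a": [1.0, 1.1, 0.9, 1.0], "b": [1.0, 1.1, 0.9, 1.0], "c": [1.0, 1.1, 0.9, 1.0]}
        res = group_compare(data)
        assert res["anova"]["F"].iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert not res["tukey"]["reject"].any()

    def test_large_effect_flagged(self):
        rng = np.random.default_rng(0)
        data = {
            "a": 0.0 + 0.1 * rng.standard_normal(5),
            "b": 10.0 + 0.1 * rng.standard_normal(5),
        }
        res = group_compare(data)
        assert res["anova"]["p"].iloc[0] < 1e-6
        assert res["tukey"]["reject"].all()

    def test_two_way_design(self):
        rng = np.random.default_rng(1)
        rows = []
        for beta in (23, 58):
            for day in (3, 7):
                for _ in range(4):
                    rows.append(
                        {"factor_a": beta, "factor_b": day, "value": beta * 0.1 + rng.normal(0, 0.5)}
                    )
        res = group_compare(pd.DataFrame(rows), design="two-way")
        assert set(res["anova"]["factor"]) == {"factor_a", "factor_b"}
        assert res["anova"].set_index("factor").loc["factor_a", "p"] < 0.01

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValidationError):
            group_compare({"a": [1.0, 2.0], "b": [3.0]})

    def test_agrees_with_permutation_oracle(self):
        """Accept/reject at alpha = 0.05 matches a permutation test of the
        F statistic on the vast majority of random small designs."""
        rng = np.random.default_rng(123)
        agree = 0
        n_designs = 60
        for _ in range(n_designs):
            k = rng.integers(2, 4)
            n = rng.integers(4, 7)
            effect = rng.uniform(0.0, 2.0)
            groups = {
                f"g{j}": (j * effect + rng.standard_normal(n)).tolist() for j in range(k)
            }
            res = group_compare(groups)
            p_f = res["anova"]["p"].iloc[0]
            # permutation oracle on the same F statistic
            values = np.concatenate([np.asarray(v) for v in groups.values()])
            labels = np.concatenate([[j] * len(v) for j, v in enumerate(groups.values())])
            from scipy.stats import f_oneway

            f_obs = f_oneway(*[values[labels == j] for j in range(k)]).statistic
            perm_ge = 0
            n_perm = 800
            for _ in range(n_perm):
                perm = rng.permutation(labels)
                f_p = f_oneway(*[values[perm == j] for j in range(k)]).statistic
                perm_ge += f_p >= f_obs
            p_perm = (perm_ge + 1) / (n_perm + 1)
            agree += (p_f < 0.05) == (p_perm < 0.05)
        assert agree / n_designs >= 0.9
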