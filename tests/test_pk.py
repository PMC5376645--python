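"""Unit conversion, half-life fitting and standard-curve operations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ocuquant.pk import (
    FourPLCurve,
    FourParamLogistic,
    LlodSpec,
    amount_from_concentration,
    amount_from_mass,
    compute_llod,
    convert_terminal_table,
    dose_from_mass,
    fit_4pl,
    fit_monoexponential,
    fold_difference,
    interpolate_concentration,
    mass_from_amount,
    percent_injected,
    round_sig,
)


class TestUnitConversions:
    def test_terminal_mass_conversions(self):
        # 51 µg/eye of a 59 kDa protein, and 32 ng/eye of a 49 kDa Fab
        assert amount_from_mass(51_000, 59) == pytest.approx(864.4, abs=0.05)
        assert round_sig(amount_from_mass(51_000, 59), 2) == 860
        assert amount_from_mass(32, 49) == pytest.approx(0.653, abs=5e-4)
        assert amount_from_mass(0, 59) == 0.0

    def test_concentration_conversion(self):
        assert amount_from_concentration(100, 1.25, 59) == pytest.approx(
            100 * 1.25 / 59
        )
        assert amount_from_concentration(0, 1.25, 59) == 0.0

    @settings(derandomize=True, max_examples=100)
    @given(pmol=st.floats(1e-6, 1e6), mw=st.floats(1.0, 500.0))
    def test_mass_amount_round_trip(self, pmol, mw):
        assert amount_from_mass(mass_from_amount(pmol, mw), mw) == pytest.approx(
            pmol, rel=1e-12
        )

    def test_dose_conversions(self):
        assert dose_from_mass(500, 49) == pytest.approx(10_204, abs=0.1)
        assert round_sig(dose_from_mass(500, 49) / 1000, 1) == 10  # ~10 nmol
        assert dose_from_mass(6.2, 59) == pytest.approx(105.1, abs=0.05)
        assert dose_from_mass(0, 59) == 0.0

    def test_percent_injected(self):
        assert percent_injected(2.1, 105) == pytest.approx(2.0)
        assert round_sig(percent_injected(0.38, 105), 1) == pytest.approx(0.4)
        assert percent_injected(5.0, 5.0) == 100.0
        with pytest.raises(ValueError):
            percent_injected(1.0, 0.0)

    def test_invalid_molecular_weight(self):
        with pytest.raises(ValueError):
            amount_from_mass(10, 0)

    def test_fold_difference(self):
        # surfaced as-is: the day-21 ratio of the two terminal levels
        assert fold_difference(9.8, 0.1) == pytest.approx(98.0)
        assert fold_difference(5, 5) == 1.0
        assert fold_difference(0, 5) == 0.0
        with pytest.raises(ValueError):
            fold_difference(1, 0)


class TestDecayFit:
    def test_exact_on_noiseless_exponential(self):
        days = np.array([0.0, 5.0, 10.0])
        fit = fit_monoexponential(np.column_stack([days, 100 * np.exp(-0.1 * days)]))
        assert fit.k == pytest.approx(0.1, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.A0 == pytest.approx(100.0, rel=1e-12)

    def test_terminal_series_half_life_matches_hand_ols(self):
        # hand log-linear OLS oracle on the printed terminal series:
        # slope = -0.113833, t1/2 = 6.089 d, r^2 = 0.9185
        series = pd.DataFrame(
            {"day": [21, 24, 26, 30, 31], "amount_pmol": [9.8, 5.6, 3.9, 3.1, 3.0]}
        )
        fit = fit_monoexponential(series)
        assert fit.k == pytest.approx(0.11383282094284486, abs=1e-12)
        assert fit.t_half == pytest.approx(6.089168087189656, abs=1e-9)
        assert fit.r_squared == pytest.approx(0.9185464731186239, abs=1e-9)
        assert fit.t_half_ci[0] < 6.089 < fit.t_half_ci[1]

    def test_two_point_closed_form(self):
        fit = fit_monoexponential(np.array([[21.0, 9.8], [31.0, 3.0]]))
        assert fit.t_half == pytest.approx(10 * np.log(2) / np.log(9.8 / 3.0), rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_rate_recovery_under_noise(self):
        # cv = 0.2 over 8 sampling days: median |relative error| in k < 15%
        from ocuquant.synthetic import PkSeriesConfig, generate_pk_series

        errors = []
        for seed in range(200):
            table = generate_pk_series(
                PkSeriesConfig(
                    A0=100.0,
                    k=0.1137,
                    sample_days=tuple(np.linspace(1, 29, 8)),
                    cv=0.2,
                    seed=seed,
                )
            )
            fit = fit_monoexponential(table)
            errors.append(abs(fit.k - 0.1137) / 0.1137)
        assert np.median(errors) < 0.15

    @pytest.mark.parametrize(
        "data", [np.array([[1.0, 10.0], [1.0, 5.0]]), np.array([[1.0, 0.0], [2.0, 5.0]])]
    )
    def test_invalid_series_rejected(self, data):
        with pytest.raises(ValueError):
            fit_monoexponential(data)


def _twofold_standards(curve: FourPLCurve, start=200.0, n=12):
    conc = start / 2.0 ** np.arange(n)
    return conc, curve.response(conc)


class TestFourPL:
    TRUE = FourPLCurve(bottom=0.05, top=2.0, log_ec50=1.0, hill_slope=1.0)

    def test_recovers_generating_parameters(self):
        conc, resp = _twofold_standards(self.TRUE)
        est = fit_4pl(np.column_stack([conc, resp]))
        assert est.bottom == pytest.approx(self.TRUE.bottom, abs=1e-6)
        assert est.top == pytest.approx(self.TRUE.top, abs=1e-6)
        assert est.log_ec50 == pytest.approx(self.TRUE.log_ec50, abs=1e-6)
        assert est.hill_slope == pytest.approx(self.TRUE.hill_slope, abs=1e-6)

    def test_midpoint_property(self):
        y = self.TRUE.response(10.0**self.TRUE.log_ec50)
        assert y == pytest.approx((self.TRUE.top + self.TRUE.bottom) / 2, rel=1e-12)

    def test_hill_sign_flip_mirrors_curve(self):
        flipped = FourPLCurve(0.05, 2.0, 1.0, -1.0)
        dx = 0.7
        left = self.TRUE.response(10 ** (1.0 - dx))
        right = flipped.response(10 ** (1.0 + dx))
        assert left == pytest.approx(right, rel=1e-12)

    def test_forward_inverse_round_trip(self):
        rng = np.random.default_rng(5)
        for conc in rng.uniform(0.1, 190.0, size=20):
            y = self.TRUE.response(conc)
            assert self.TRUE.inverse(float(y)) == pytest.approx(conc, rel=1e-9)

    def test_dilution_factor_scales_result(self):
        y = float(self.TRUE.response(8.0))
        c1 = interpolate_concentration(y, self.TRUE, 1.0)
        c2 = interpolate_concentration(y, self.TRUE, 2.0)
        assert c2 == pytest.approx(2 * c1, rel=1e-12)

    def test_response_outside_range_rejected(self):
        with pytest.raises(ValueError, match="outside quantifiable range"):
            self.TRUE.inverse(2.5)
        with pytest.raises(ValueError, match="outside quantifiable range"):
            self.TRUE.inverse(0.05)

    def test_degenerate_standards_rejected(self):
        conc = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        with pytest.raises(ValueError):
            FourParamLogistic().fit(conc, np.ones(5))


class TestLlod:
    CURVE = FourPLCurve(bottom=0.05, top=2.0, log_ec50=1.0, hill_slope=1.0)

    def test_zero_sd_gives_blank_response(self):
        res = compute_llod(LlodSpec(blank_mean=0.06, sd_response=0.0), self.CURVE)
        assert res.llod_response == 0.06

    def test_plug_in_through_inverse(self):
        spec = LlodSpec(blank_mean=0.06, sd_response=0.01, multiplier=3)
        res = compute_llod(spec, self.CURVE)
        assert res.llod_response == pytest.approx(0.09)
        assert res.llod_concentration == pytest.approx(self.CURVE.inverse(0.09))

    def test_monotone_in_multiplier(self):
        concs = [
            compute_llod(LlodSpec(0.06, 0.01, m), self.CURVE).llod_concentration
            for m in (1, 3, 5)
        ]
        assert concs[0] < concs[1] < concs[2]

    def test_below_curve_flagged(self):
        res = compute_llod(LlodSpec(blank_mean=0.01, sd_response=0.0), self.CURVE)
        assert res.extrapolated and np.isnan(res.llod_concentration)


class TestTerminalTable:
    def test_mixed_unit_conversion(self):
        df = pd.DataFrame(
            {
                "eye_id": ["e1", "e2"],
                "drug": ["LAVA1", "ranibizumab"],
                "value": [100.0, 32.0],
                "value_unit": ["ng_per_ml", "ng_per_eye"],
                "dose_value": [105.0, np.nan],
                "dose_unit": ["pmol", "pmol"],
            }
        )
        out = convert_terminal_table(df)
        assert out.loc[0, "amount_pmol"] == pytest.approx(100 * 1.25 / 59)
        assert out.loc[1, "amount_pmol"] == pytest.approx(32 / 49)
        assert out.loc[0, "percent_injected"] == pytest.approx(
            100 * (100 * 1.25 / 59) / 105
        )
        assert np.isnan(out.loc[1, "percent_injected"])

    def test_unknown_drug_rejected(self):
        df = pd.DataFrame(
            {"drug": ["mystery"], "value": [1.0], "value_unit": ["ng_per_eye"]}
        )
        with pytest.raises(KeyError):
            convert_terminal_table(df)
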