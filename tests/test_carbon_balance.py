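"""Unit tests for the stoichiometric carbon-balance operations."""

import math

import pytest

from fermbalance import (
    CarbonBalanceWarning,
    CarbonTable,
    ProductProfile,
    SubstrateSpec,
    ValidationError,
    available_carbon,
    carbon_conversion,
    co2_from_ethanol,
    ethanol_productivity,
    ethanol_yield_pct,
    fold_change,
    glucose_equivalent,
    summarize,
    total_products,
)

M2N_T1_30C = ProductProfile(
    {
        "glucose": 0.09,
        "glycerol": 3.73,
        "acetic_acid": 0.00,
        "ethanol": 98.13,
        "maltose": 0.96,
        "co2": 93.87,
    },
    time_h=192.0,
    strain_label="M2n T1",
)

ER_T12_30C = ProductProfile(
    {
        "glucose": 0.22,
        "glycerol": 3.18,
        "acetic_acid": 0.64,
        "ethanol": 89.35,
        "maltose": 1.95,
        "co2": 85.46,
    },
    time_h=192.0,
    strain_label="ER T12",
)


class TestCarbonTable:
    def test_default_entries(self):
        table = CarbonTable.default()
        assert dict(table.entries) == {
            "maltose": (12, 342.0),
            "glucose": (6, 180.0),
            "glycerol": (3, 92.0),
            "acetic_acid": (2, 60.0),
            "ethanol": (2, 46.0),
            "co2": (1, 44.0),
        }

    @pytest.mark.parametrize(
        "entries",
        [{"x": (0, 180.0)}, {"x": (6, 0.0)}, {"x": (6, -1.0)}],
    )
    def test_invalid_constants_rejected(self, entries):
        with pytest.raises(ValidationError):
            CarbonTable(entries)


class TestGlucoseEquivalent:
    @pytest.mark.parametrize(
        "dry, added, expected",
        [
            (183.3, 5.0, 208.5),  # reference loading, reported to 1 dp
            (100.0, 0.0, 111.0),
            (183.3, 0.0, 203.5),
        ],
    )
    def test_examples(self, dry, added, expected):
        spec = SubstrateSpec(starch_as_is=dry + 20, starch_dry=dry, added_glucose=added)
        assert round(glucose_equivalent(spec), 1) == expected

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(starch_as_is=200.0, starch_dry=0.0),
            dict(starch_as_is=100.0, starch_dry=150.0),
            dict(starch_as_is=200.0, starch_dry=183.3, added_glucose=-1.0),
            dict(starch_as_is=200.0, starch_dry=183.3, hydrolysis_factor=0.9),
        ],
    )
    def test_invalid_substrate_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            SubstrateSpec(**kwargs)


class TestAvailableCarbon:
    @pytest.mark.parametrize(
        "ge, expected", [(208.5, 6.95), (180.0, 6.0), (203.5, 6.78)]
    )
    def test_examples(self, ge, expected):
        assert round(available_carbon(ge), 2) == expected

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            available_carbon(0.0)


class TestCo2FromEthanol:
    @pytest.mark.parametrize(
        "ethanol, expected", [(98.13, 93.87), (0.0, 0.0), (46.0, 44.0)]
    )
    def test_examples(self, ethanol, expected):
        assert co2_from_ethanol(ethanol) == pytest.approx(expected, abs=0.01)

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            co2_from_ethanol(-1.0)


class TestCarbonConversion:
    def test_industrial_strains(self, substrate):
        assert round(carbon_conversion(M2N_T1_30C, substrate)) == 94
        assert round(carbon_conversion(ER_T12_30C, substrate)) == 87

    def test_all_zero_profile(self, substrate):
        profile = ProductProfile({a: 0.0 for a in M2N_T1_30C.concentrations})
        assert carbon_conversion(profile, substrate) == 0.0

    def test_theoretical_full_conversion_is_exactly_100(self, substrate):
        ge = glucose_equivalent(substrate)
        profile = ProductProfile({"ethanol": ge * 92 / 180, "co2": ge * 88 / 180})
        assert carbon_conversion(profile, substrate) == pytest.approx(100.0, rel=1e-12)

    def test_co2_inferred_when_absent(self, substrate):
        conc = {k: v for k, v in M2N_T1_30C.concentrations.items() if k != "co2"}
        inferred = carbon_conversion(ProductProfile(conc), substrate)
        measured = carbon_conversion(M2N_T1_30C, substrate)
        assert inferred == pytest.approx(measured, abs=0.01)

    def test_unknown_analyte_rejected(self, substrate):
        with pytest.raises(ValidationError):
            carbon_conversion(ProductProfile({"lactate": 1.0}), substrate)

    def test_inconsistent_profile_flagged_not_clipped(self, substrate):
        ge = glucose_equivalent(substrate)
        profile = ProductProfile({"ethanol": ge * 92 / 180 * 1.1, "co2": ge * 88 / 180 * 1.1})
        with pytest.warns(CarbonBalanceWarning):
            pct = carbon_conversion(profile, substrate)
        assert pct > 105.0


class TestEthanolYield:
    @pytest.mark.parametrize(
        "ethanol, expected", [(62.20, 60), (98.13, 94), (0.0, 0)]
    )
    def test_examples(self, ethanol, expected):
        assert round(ethanol_yield_pct(ethanol, 208.5)) == expected

    def test_stoichiometric_factor_does_not_reproduce_tables(self):
        # printed yield is 94; 0.511 g/g gives 92, evidence for the 0.50 default
        assert round(ethanol_yield_pct(98.13, 208.5, theoretical_factor=0.511)) == 92

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            ethanol_yield_pct(10.0, 0.0)
        with pytest.raises(ValidationError):
            ethanol_yield_pct(-1.0, 208.5)


class TestProductivityTotalsFold:
    @pytest.mark.parametrize(
        "ethanol, hours, expected", [(62.20, 192, 0.32), (98.13, 192, 0.51), (0, 192, 0.0)]
    )
    def test_productivity(self, ethanol, hours, expected):
        assert round(ethanol_productivity(ethanol, hours), 2) == expected

    def test_productivity_requires_positive_time(self):
        with pytest.raises(ValidationError):
            ethanol_productivity(10.0, 0.0)

    def test_total_products_printed_column(self):
        profile = ProductProfile(
            {
                "glucose": 46.30,
                "glycerol": 6.64,
                "maltose": 1.03,
                "acetic_acid": 1.66,
                "ethanol": 62.20,
                "co2": 59.50,
            }
        )
        assert round(total_products(profile), 2) == 177.33

    def test_total_infers_co2(self):
        profile = ProductProfile({"ethanol": 46.0})
        assert round(total_products(profile), 2) == 90.00

    @pytest.mark.parametrize(
        "num, den, expected", [(51.71, 33.14, 1.6), (15.30, 3.99, 3.8), (7.7, 7.7, 1.0)]
    )
    def test_fold_change(self, num, den, expected):
        assert round(fold_change(num, den), 1) == expected

    def test_fold_change_rejects_zero_denominator(self):
        with pytest.raises(ValidationError):
            fold_change(1.0, 0.0)


class TestSummarize:
    def test_single_point_matches_printed_row(self, substrate):
        [summary] = summarize([M2N_T1_30C], substrate)
        row = summary.as_report_row()
        assert row["carbon_conversion_pct"] == 94
        assert row["ethanol_yield_pct"] == 94
        assert row["ethanol_productivity"] == 0.51
        assert row["glucose_equivalent"] == 208.5

    def test_empty_timecourse(self, substrate):
        assert summarize([], substrate) == []

    def test_productivity_halves_with_doubled_elapsed_time(self, substrate):
        conc = dict(M2N_T1_30C.concentrations)
        early = ProductProfile(conc, time_h=96.0)
        late = ProductProfile(conc, time_h=192.0)
        s96, s192 = summarize([early, late], substrate)
        assert s96.carbon_conversion_pct == s192.carbon_conversion_pct
        assert s192.productivity == pytest.approx(s96.productivity / 2)

    def test_nonincreasing_times_rejected(self, substrate):
        points = [
            ProductProfile(dict(M2N_T1_30C.concentrations), time_h=t)
            for t in (96.0, 96.0)
        ]
        with pytest.raises(ValidationError):
            summarize(points, substrate)


def test_negative_concentration_rejected():
    with pytest.raises(ValidationError):
        ProductProfile({"ethanol": -0.1})


def test_nan_concentration_rejected():
    with pytest.raises(ValidationError):
        ProductProfile({"ethanol": math.nan})
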