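"""Per-colony carbon arithmetic and compartment aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gorgonian_carbon.allometry import (
    FactorUnits,
    LinearDensityFactor,
    PowerLawModel,
    SizeClassTable,
)
from gorgonian_carbon.budget import (
    aggregate_budget,
    budget_from_totals,
    closure_check,
    colony_ingestion,
    colony_respiration,
    colony_sink,
    net_flux,
    seasonal_flux,
    species_totals,
    table1_report,
)
from gorgonian_carbon.parameters import (
    ConversionConstants,
    DepthZone,
    SinkMode,
    effective_parameters_from_totals,
)

from conftest import make_true_params


def identity_params(**overrides):
    """Length == height and AFDM 1 g at 100 cm: easy unit-chain checks."""
    return make_true_params(
        height_to_length=PowerLawModel(1.0, 1.0),
        afdm=LinearDensityFactor(10.0, 0.0, FactorUnits.MG_AFDM_PER_CM),
        **overrides,
    )


class TestColonyIngestion:
    def test_zooplankton_channel_arithmetic(self):
        # 1000 polyps at 2 ug C/polyp/day and no other channel
        p = identity_params(
            seston_ingestion_ug_c_per_g_afdm=None,
            polyp_factor=LinearDensityFactor(10.0, 0.0, FactorUnits.POLYPS_PER_CM),
        )
        # height 100 -> length 100 -> 1000 polyps
        assert colony_ingestion(100.0, p) == pytest.approx(0.002)

    def test_all_rates_zero_gives_zero(self):
        p = identity_params(
            zooplankton_ingestion_ug_c_per_polyp_per_day=0.0,
            seston_ingestion_ug_c_per_g_afdm=0.0,
        )
        assert colony_ingestion(50.0, p) == 0.0

    def test_hourly_seston_rate_scaled_to_day(self):
        from gorgonian_carbon.parameters import TimeBase
        daily = identity_params(zooplankton_ingestion_ug_c_per_polyp_per_day=None,
                                seston_ingestion_ug_c_per_g_afdm=240.0)
        hourly = identity_params(zooplankton_ingestion_ug_c_per_polyp_per_day=None,
                                 seston_ingestion_ug_c_per_g_afdm=10.0,
                                 seston_timebase=TimeBase.PER_HOUR)
        assert colony_ingestion(30.0, hourly) == pytest.approx(colony_ingestion(30.0, daily))

    def test_mixotroph_adds_autotrophic_channel(self):
        p = identity_params(
            zooplankton_ingestion_ug_c_per_polyp_per_day=None,
            seston_ingestion_ug_c_per_g_afdm=None,
            mixotrophic=True,
            autotrophic_ug_c_per_cm2_per_day=3.0,
            height_to_area=PowerLawModel(2.0, 1.0),
        )
        # area = 2 * 10 = 20 cm2 -> 60 ug C/d
        assert colony_ingestion(10.0, p) == pytest.approx(60e-6)

    def test_no_channel_configured_is_an_error(self):
        p = identity_params(zooplankton_ingestion_ug_c_per_polyp_per_day=None,
                            seston_ingestion_ug_c_per_g_afdm=None)
        with pytest.raises(KeyError):
            colony_ingestion(10.0, p)


class TestColonyRespiration:
    def test_unit_chain(self):
        # AFDM 1 g (height 100 -> length 100 cm x 10 mg/cm), rate 1 mg O2/g/h
        p = identity_params(respiration_mg_o2_per_g_afdm_per_hour=1.0)
        assert colony_respiration(100.0, p) == pytest.approx(24 * 0.281 / 1000)

    def test_zero_rate(self):
        p = identity_params(respiration_mg_o2_per_g_afdm_per_hour=0.0)
        assert colony_respiration(50.0, p) == 0.0

    def test_missing_rate_is_config_error(self):
        p = identity_params(respiration_mg_o2_per_g_afdm_per_hour=None)
        with pytest.raises(KeyError):
            colony_respiration(10.0, p)


class TestNetAndSeasonalFlux:
    @pytest.mark.parametrize(
        "ing,resp,expected",
        [(10.04, 5.14, 4.90), (3.3, 3.3, 0.0), (0.06, 0.02, 0.04)],
    )
    def test_net_is_ingestion_minus_respiration(self, ing, resp, expected):
        assert net_flux(ing, resp) == pytest.approx(expected)

    def test_negative_net_allowed_but_not_negative_inputs(self):
        assert net_flux(1.0, 2.0) == pytest.approx(-1.0)
        with pytest.raises(ValueError):
            net_flux(-1.0, 0.0)

    @pytest.mark.parametrize("daily,days,expected", [(4.90, 90, 441.0), (0.0, 90, 0.0), (1.0, 90, 90.0)])
    def test_seasonal_integration(self, daily, days, expected):
        assert seasonal_flux(daily, days) == pytest.approx(expected)

    def test_nonpositive_season_rejected(self):
        with pytest.raises(ValueError):
            seasonal_flux(1.0, 0)


class TestColonySink:
    def test_length_increment_route(self):
        # linear law: dlength = dh = 10 cm/yr; C content 5 mg/cm
        p = identity_params(growth_cm_height_per_year=10.0, c_content_mg_per_cm=5.0)
        assert colony_sink(20.0, p) == pytest.approx(0.05)

    def test_zero_growth_zero_sink(self):
        p = identity_params(growth_cm_height_per_year=0.0)
        assert colony_sink(20.0, p) == 0.0

    def test_per_size_class_table_route(self):
        table = SizeClassTable(edges=(0.0, 20.0, 50.0), values=(0.1, 0.4))
        p = identity_params(sink_mode=SinkMode.PER_SIZE_CLASS_TABLE,
                            sink_investment_table=table)
        assert colony_sink(10.0, p) == pytest.approx(0.1)
        assert colony_sink(30.0, p) == pytest.approx(0.4)

    def test_missing_growth_is_config_error(self):
        p = identity_params(growth_cm_height_per_year=None, growth_source_values=())
        with pytest.raises(KeyError):
            colony_sink(10.0, p)


def make_survey(heights, depths, species="Synthetica demo"):
    n = len(heights)
    return pd.DataFrame({
        "species": [species] * n,
        "height_cm": heights,
        "depth_m": depths,
        "transect": ["T1"] * n,
        "sampling_unit": [f"u{i}" for i in range(n)],
        "assemblage": ["rock"] * n,
    })


class TestAggregation:
    def params_both_zones(self):
        shallow = make_true_params()
        deep = make_true_params(zone=DepthZone.DEEP)
        return {shallow.key: shallow, deep.key: deep}

    def test_species_total_is_exact_sum_of_zones(self):
        params = self.params_both_zones()
        survey = make_survey([10.0, 20.0, 15.0], [10.0, 40.0, 50.0])
        budgets = aggregate_budget(survey, params)
        comps = [b for b in budgets if b.depth_zone is not None]
        total = [b for b in budgets if b.depth_zone is None][0]
        assert total.n_colonies == sum(b.n_colonies for b in comps) == 3
        for attr in ("biomass_g_afdm", "daily_ingestion_g_c", "daily_respiration_g_c",
                     "daily_net_g_c", "seasonal_net_g_c", "annual_sink_g_c"):
            assert getattr(total, attr) == pytest.approx(
                sum(getattr(b, attr) for b in comps), rel=1e-12
            )

    def test_internal_identities_hold_on_every_row(self):
        params = self.params_both_zones()
        rng = np.random.default_rng(11)
        survey = make_survey(rng.uniform(3, 50, 40).tolist(),
                             rng.uniform(0, 70, 40).tolist())
        for b in aggregate_budget(survey, params):
            assert b.daily_net_g_c == pytest.approx(
                b.daily_ingestion_g_c - b.daily_respiration_g_c, abs=1e-12)
            assert b.seasonal_net_g_c == pytest.approx(
                b.daily_net_g_c * b.season_days, rel=1e-12)

    def test_additive_over_disjoint_surveys(self):
        params = self.params_both_zones()
        rng = np.random.default_rng(5)
        survey = make_survey(rng.uniform(3, 50, 20).tolist(), [10.0] * 20)
        whole = aggregate_budget(survey, params)
        part_a = aggregate_budget(survey.iloc[:7], params)
        part_b = aggregate_budget(survey.iloc[7:], params)
        tot = [b for b in whole if b.depth_zone is None][0]
        ta = [b for b in part_a if b.depth_zone is None][0]
        tb = [b for b in part_b if b.depth_zone is None][0]
        assert tot.daily_ingestion_g_c == pytest.approx(
            ta.daily_ingestion_g_c + tb.daily_ingestion_g_c)
        assert tot.annual_sink_g_c == pytest.approx(
            ta.annual_sink_g_c + tb.annual_sink_g_c)

    def test_unconfigured_compartment_is_an_error(self):
        shallow = make_true_params()
        survey = make_survey([10.0], [50.0])  # deep colony
        with pytest.raises(KeyError, match="deep"):
            aggregate_budget(survey, {shallow.key: shallow})

    def test_report_rounds_only_at_serialization(self):
        params = self.params_both_zones()
        survey = make_survey([10.123, 20.456], [10.0, 40.0])
        budgets = aggregate_budget(survey, params)
        report = table1_report(budgets)
        assert len(report) == 1
        total = [b for b in budgets if b.depth_zone is None][0]
        assert report["biomass_g_afdm"][0] == round(total.biomass_g_afdm, 2)


class TestClosure:
    def test_regenerates_published_compartment_totals(self, packaged_params,
                                                      compartments_frame):
        """Effective rates back-solved from each published compartment,
        run through the budget unit chains against the same biomass,
        must return the published daily totals to within 0.01 g C/d."""
        for row in compartments_frame.itertuples(index=False):
            base = packaged_params[(row.species, DepthZone(row.depth_zone))]
            regen_ing, regen_resp = closure_check(
                base, row.biomass_g_afdm, row.daily_ingestion_g_c,
                row.daily_respiration_g_c)
            assert regen_ing == pytest.approx(row.daily_ingestion_g_c, abs=0.01)
            assert regen_resp == pytest.approx(row.daily_respiration_g_c, abs=0.01)

    def test_calibrated_rates_through_full_pipeline(self, true_params):
        """A population run under parameters calibrated to its own totals
        returns those totals (full per-colony route, not the shortcut)."""
        heights = [12.0, 25.0, 33.0]
        survey = make_survey(heights, [10.0] * 3, species=true_params.species)
        base = aggregate_budget(survey, {true_params.key: true_params})
        comp = [b for b in base if b.depth_zone is not None][0]
        eff = effective_parameters_from_totals(
            true_params, comp.biomass_g_afdm, comp.daily_ingestion_g_c,
            comp.daily_respiration_g_c)
        rerun = aggregate_budget(survey, {eff.key: eff}, include_sink=False)
        comp2 = [b for b in rerun if b.depth_zone is not None][0]
        assert comp2.biomass_g_afdm == pytest.approx(comp.biomass_g_afdm, rel=1e-12)
        assert comp2.daily_ingestion_g_c == pytest.approx(comp.daily_ingestion_g_c, rel=1e-9)
        assert comp2.daily_respiration_g_c == pytest.approx(comp.daily_respiration_g_c, rel=1e-9)


class TestPerAreaSummary:
    def test_denominator_convention_switches(self):
        from gorgonian_carbon.budget import per_area_summary
        p = make_true_params()
        survey = make_survey([10.0, 10.0], [10.0, 10.0], species=p.species)
        survey.loc[:, "transect"] = ["T1", "T1"]
        areas = {"T1": 2.0, "T2": 2.0}
        over_all = per_area_summary(survey, {p.key: p}, areas)
        over_occupied = per_area_summary(survey, {p.key: p}, areas,
                                         include_empty_transects=False)
        assert over_all["n_transects"][0] == 2
        assert over_occupied["n_transects"][0] == 1
        # empty transect contributes a zero, halving the mean
        assert over_all["biomass_g_afdm_m2_mean"][0] == pytest.approx(
            over_occupied["biomass_g_afdm_m2_mean"][0] / 2)

    def test_undeclared_transect_area_rejected(self):
        from gorgonian_carbon.budget import per_area_summary
        p = make_true_params()
        survey = make_survey([10.0], [10.0], species=p.species)
        with pytest.raises(KeyError):
            per_area_summary(survey, {p.key: p}, {"other": 1.0})


class TestBudgetFromTotals:
    def test_seasonal_precedence_and_identities(self):
        b = budget_from_totals("sp", DepthZone.SHALLOW, 10, 100.0, 10.04, 5.14,
                               annual_sink_g_c=57.42, seasonal_net_g_c=441.35)
        assert b.daily_net_g_c == pytest.approx(4.90)
        assert b.seasonal_net_g_c == 441.35

    def test_derived_seasonal_when_not_given(self):
        b = budget_from_totals("sp", DepthZone.DEEP, 5, 50.0, 2.0, 0.5, season_days=90)
        assert b.seasonal_net_g_c == pytest.approx(1.5 * 90)

    def test_species_totals_requires_single_species(self):
        a = budget_from_totals("sp1", DepthZone.SHALLOW, 1, 1.0, 1.0, 0.5)
        b = budget_from_totals("sp2", DepthZone.DEEP, 1, 1.0, 1.0, 0.5)
        with pytest.raises(ValueError):
            species_totals([a, b])
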