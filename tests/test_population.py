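"""Depth partition, size structures, density summaries, biomass."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gorgonian_carbon.parameters import DepthZone
from gorgonian_carbon.population import (
    DepthZoning,
    SamplingUnit,
    build_size_structure,
    density_summary,
    partition_by_depth,
    population_biomass,
    units_from_survey,
)

from conftest import make_true_params


def make_survey(depths, species="Synthetica demo", heights=None):
    n = len(depths)
    heights = heights if heights is not None else [10.0] * n
    return pd.DataFrame({
        "species": [species] * n,
        "height_cm": heights,
        "depth_m": depths,
        "transect": ["T1"] * n,
        "sampling_unit": [f"u{i}" for i in range(n)],
        "assemblage": ["rock"] * n,
    })


class TestPartitionByDepth:
    def test_boundary_depth_is_shallow(self):
        zones = partition_by_depth(make_survey([10.0, 35.0, 35.1]))
        assert sorted(zones[DepthZone.SHALLOW]["depth_m"]) == [10.0, 35.0]
        assert list(zones[DepthZone.DEEP]["depth_m"]) == [35.1]

    def test_empty_survey_gives_two_empty_zones(self):
        zones = partition_by_depth(make_survey([]))
        assert zones[DepthZone.SHALLOW].empty and zones[DepthZone.DEEP].empty

    def test_counts_conserved_and_zones_disjoint(self):
        rng = np.random.default_rng(7)
        depths = rng.uniform(0, 70, size=200)
        zones = partition_by_depth(make_survey(depths.tolist()))
        n_shallow = len(zones[DepthZone.SHALLOW])
        n_deep = len(zones[DepthZone.DEEP])
        assert n_shallow + n_deep == 200
        assert n_shallow == int((depths <= 35.0).sum())

    def test_missing_depth_reported_by_row(self):
        survey = make_survey([10.0, np.nan, 40.0])
        with pytest.raises(ValueError, match="missing depth"):
            partition_by_depth(survey)


class TestSizeStructure:
    def test_simple_histogram(self):
        s = build_size_structure([5.0, 15.0, 25.0], [0, 10, 20, 30])
        assert s.counts == (1, 1, 1)

    def test_empty_input_all_zero(self):
        s = build_size_structure([], [0, 10, 20])
        assert s.counts == (0, 0) and s.n_colonies == 0

    def test_matches_independent_recount(self):
        rng = np.random.default_rng(99)
        heights = rng.lognormal(2.5, 0.6, size=1000)
        edges = [0, 5, 10, 20, 40, 80, 200]
        s = build_size_structure(heights, edges)
        # brute-force recount per class, half-open bins
        expected = [
            sum(1 for h in np.clip(heights, edges[0], np.nextafter(edges[-1], 0))
                if lo <= h < hi)
            for lo, hi in zip(edges, edges[1:])
        ]
        assert list(s.counts) == expected
        assert s.n_colonies == 1000

    def test_out_of_range_heights_clamped_to_end_bins(self):
        s = build_size_structure([150.0, 0.5], [1, 10, 100])
        assert s.counts == (1, 1)

    def test_decreasing_edges_rejected(self):
        with pytest.raises(ValueError):
            build_size_structure([5.0], [10, 0])


class TestDensitySummary:
    @staticmethod
    def units(counts, area=1.0, assemblage="rock"):
        return [
            SamplingUnit(unit_id=f"u{i}", transect="T1", area_m2=area,
                         assemblage=assemblage, count=c)
            for i, c in enumerate(counts)
        ]

    def test_total_and_patch_means(self):
        d = density_summary(self.units([0, 0, 2, 2]), "sp", "rock")
        assert d.total_density == pytest.approx(1.0)
        assert d.patch_density == pytest.approx(2.0)
        assert d.n_units == 4 and d.n_occupied == 2

    def test_single_occupied_unit_has_no_patch_sd(self):
        d = density_summary(self.units([0, 0, 1]), "sp", "rock")
        assert d.patch_density == pytest.approx(1.0)
        assert d.patch_sd is None

    def test_all_empty_units_have_no_patch_density(self):
        d = density_summary(self.units([0, 0, 0]), "sp", "rock")
        assert d.total_density == 0.0 and d.patch_density is None

    def test_unit_area_scales_density(self):
        d = density_summary(self.units([2, 2], area=0.5), "sp", "rock")
        assert d.total_density == pytest.approx(4.0)

    def test_no_units_rejected(self):
        with pytest.raises(ValueError):
            density_summary(self.units([1]), "sp", "sand")

    @settings(max_examples=40, deadline=None)
    @given(counts=st.lists(st.integers(0, 20), min_size=1, max_size=30))
    def test_patch_density_never_below_total(self, counts):
        if not any(counts):
            return
        d = density_summary(self.units(counts), "sp", "rock")
        assert d.patch_density >= d.total_density - 1e-12
        if all(counts):
            assert d.patch_density == pytest.approx(d.total_density)


class TestPublishedDensityTable:
    def test_patch_exceeds_total_in_every_row(self, densities_frame):
        occupied = densities_frame.dropna(subset=["patch_density"])
        assert (occupied["patch_density"] >= occupied["total_density"]).all()

    def test_total_consistent_with_patch_times_occupancy(self, densities_frame):
        """Total density should equal on-patch density times occupancy
        fraction, within the rounding printed in the source table."""
        for row in densities_frame.itertuples(index=False):
            rederived = row.patch_density * row.n_patch / row.n_total
            assert rederived == pytest.approx(row.total_density, abs=0.005), row.assemblage


class TestPopulationBiomass:
    def test_single_colony_known_length(self):
        # linear law a=1, b=1 so length == height; afdm 18.35 mg/cm
        from gorgonian_carbon.allometry import (
            FactorUnits, LinearDensityFactor, PowerLawModel,
        )
        p = make_true_params(
            height_to_length=PowerLawModel(1.0, 1.0),
            afdm=LinearDensityFactor(18.35, 2.33, FactorUnits.MG_AFDM_PER_CM),
        )
        survey = make_survey([10.0], heights=[100.0])
        assert population_biomass(survey, {p.key: p}) == pytest.approx(1.835)

    def test_empty_survey_zero_biomass(self, true_params):
        survey = make_survey([])
        assert population_biomass(survey, {true_params.key: true_params}) == 0.0

    def test_additive_over_partition(self, true_params):
        rng = np.random.default_rng(3)
        heights = rng.uniform(5, 40, 30).tolist()
        survey = make_survey([10.0] * 30, heights=heights)
        whole = population_biomass(survey, {true_params.key: true_params})
        a = population_biomass(survey.iloc[:11], {true_params.key: true_params})
        b = population_biomass(survey.iloc[11:], {true_params.key: true_params})
        assert whole == pytest.approx(a + b)

    def test_missing_compartment_parameters_named(self, true_params):
        survey = make_survey([50.0])  # deep colony, only shallow configured
        with pytest.raises(KeyError, match="deep"):
            population_biomass(survey, {true_params.key: true_params})


class TestUnitsFromSurvey:
    def test_counts_include_empty_units(self):
        survey = make_survey([10.0, 10.0], heights=[5.0, 7.0])
        survey.loc[:, "sampling_unit"] = ["u0", "u0"]
        unit_table = pd.DataFrame({
            "sampling_unit": ["u0", "u1"],
            "transect": ["T1", "T1"],
            "area_m2": [1.0, 1.0],
            "assemblage": ["rock", "rock"],
        })
        units = units_from_survey(survey, "Synthetica demo", unit_table)
        assert [u.count for u in units] == [2, 0]
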