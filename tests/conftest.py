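import numpy as np
import pytest

from gorgonian_carbon.allometry import (
    FactorUnits,
    LinearDensityFactor,
    PowerLawModel,
    Response,
)
from gorgonian_carbon.io import (
    load_packaged_compartments,
    load_packaged_densities,
    load_packaged_parameters,
)
from gorgonian_carbon.parameters import DepthZone, SpeciesParameters
from gorgonian_carbon.synthetic import (
    AssemblageConfig,
    GeneratorConfig,
    HeightDistribution,
)


@pytest.fixture(scope="session")
def packaged_params():
    return load_packaged_parameters()


@pytest.fixture(scope="session")
def compartments_frame():
    return load_packaged_compartments()


@pytest.fixture(scope="session")
def densities_frame():
    return load_packaged_densities()


def make_true_params(species="Synthetica demo", zone=DepthZone.SHALLOW, **overrides):
    """A fully-specified parameter set with simple known rates."""
    defaults = dict(
        species=species,
        depth_zone=zone,
        afdm=LinearDensityFactor(mean=10.0, se=1.0, units=FactorUnits.MG_AFDM_PER_CM),
        height_to_length=PowerLawModel(0.5, 1.8),
        polyp_factor=LinearDensityFactor(mean=30.0, se=1.0, units=FactorUnits.POLYPS_PER_CM),
        zooplankton_ingestion_ug_c_per_polyp_per_day=2.0,
        seston_ingestion_ug_c_per_g_afdm=500.0,
        respiration_mg_o2_per_g_afdm_per_hour=0.5,
        growth_cm_height_per_year=1.5,
        c_content_mg_per_cm=5.0,
    )
    defaults.update(overrides)
    return SpeciesParameters(**defaults)


@pytest.fixture()
def true_params():
    return make_true_params()


@pytest.fixture()
def generator_config():
    shallow = make_true_params()
    deep = make_true_params(zone=DepthZone.DEEP)
    key_s = (shallow.species, DepthZone.SHALLOW)
    key_d = (deep.species, DepthZone.DEEP)
    return GeneratorConfig(
        seed=1234,
        true_params={key_s: shallow, key_d: deep},
        heights={
            key_s: HeightDistribution(median_cm=12.0, sigma_log=0.5, max_cm=60.0),
            key_d: HeightDistribution(median_cm=18.0, sigma_log=0.6, max_cm=90.0),
        },
        assemblages={
            key_s: [AssemblageConfig(assemblage="shallow-rock", zone=DepthZone.SHALLOW,
                                     n_units=60, occupancy=0.4, mean_count_occupied=3.0)],
            key_d: [AssemblageConfig(assemblage="deep-rock", zone=DepthZone.DEEP,
                                     n_units=40, occupancy=0.3, mean_count_occupied=2.0)],
        },
    )
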