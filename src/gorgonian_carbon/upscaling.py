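"""Habitat-based upscaling of observed densities to the study area.

Observed transects cover a tiny fraction of the coast.  To estimate
the species' study-area-wide role, the mean *total* density per
benthic assemblage (colonies m**-2, averaged over occupied and empty
sampling units alike) is multiplied by the mapped area of that
assemblage that is suitable for the species, giving a potential colony
number; mean per-colony flux and sink for the matching depth-zone
compartment then scale it into potential carbon totals.

Using the on-patch density here would be wrong — suitability maps do
not resolve patches — so :func:`potential_colonies` insists on the
total density.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .budget import CarbonBudget
from .parameters import DepthZone
from .population import AssemblageDensity

__all__ = [
    "HabitatArea",
    "PotentialEstimate",
    "M2_PER_HA",
    "potential_colonies",
    "potential_budget",
    "species_potential",
    "per_ha_sink_kg",
    "combined_per_ha_sink_t",
]

M2_PER_HA = 10_000.0
KG_PER_G = 1e-3
T_PER_KG = 1e-3


@dataclass(frozen=True)
class HabitatArea:
    """Mapped extent of one benthic assemblage suitable for a species."""

    assemblage: str
    area_ha: float
    zone: DepthZone
    suitable_for: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.area_ha <= 0:
            raise ValueError(f"habitat area must be > 0, got {self.area_ha}")


@dataclass(frozen=True)
class PotentialEstimate:
    """Potential stock of one species over one (or all) assemblages."""

    species: str
    assemblage: str
    potential_colonies: float
    potential_biomass_g_afdm: float
    potential_spring_flux_g_c: float
    potential_annual_sink_g_c: float
    area_ha: float

    @property
    def per_ha_sink_kg_c(self) -> float:
        return self.potential_annual_sink_g_c * KG_PER_G / self.area_ha


def potential_colonies(area: HabitatArea, density: AssemblageDensity) -> float:
    """Potential colony number: suitable area x mean total density.

    ``density`` must be an :class:`AssemblageDensity` so the total
    (not on-patch) density is used; passing a bare number is rejected
    to keep the two densities from being confused.
    """
    if not isinstance(density, AssemblageDensity):
        raise TypeError(
            "potential_colonies requires an AssemblageDensity (its total density "
            "is used); pass the summary object, not a bare density value"
        )
    return area.area_ha * M2_PER_HA * density.total_density


def potential_budget(
    area: HabitatArea,
    density: AssemblageDensity,
    compartment: CarbonBudget,
) -> PotentialEstimate:
    """Scale a compartment's mean per-colony budget to one assemblage.

    ``compartment`` must be the species x depth-zone budget matching
    the assemblage's zone; its per-colony means (biomass, spring flux,
    annual sink) multiply the potential colony number.
    """
    if compartment.depth_zone is not None and compartment.depth_zone is not area.zone:
        raise ValueError(
            f"assemblage {area.assemblage!r} is {area.zone.value} but compartment "
            f"{compartment.compartment} is {compartment.depth_zone.value}"
        )
    if compartment.species != density.species:
        raise ValueError(
            f"density is for {density.species!r} but compartment for {compartment.species!r}"
        )
    n_pot = potential_colonies(area, density)
    if compartment.n_colonies > 0:
        per_colony_biomass = compartment.biomass_g_afdm / compartment.n_colonies
        per_colony_flux = compartment.seasonal_net_g_c / compartment.n_colonies
        per_colony_sink = compartment.annual_sink_g_c / compartment.n_colonies
    else:
        per_colony_biomass = per_colony_flux = per_colony_sink = 0.0
    return PotentialEstimate(
        species=density.species,
        assemblage=area.assemblage,
        potential_colonies=n_pot,
        potential_biomass_g_afdm=n_pot * per_colony_biomass,
        potential_spring_flux_g_c=n_pot * per_colony_flux,
        potential_annual_sink_g_c=n_pot * per_colony_sink,
        area_ha=area.area_ha,
    )


def species_potential(estimates: Sequence[PotentialEstimate]) -> PotentialEstimate:
    """Exact sum of per-assemblage estimates for one species."""
    if not estimates:
        raise ValueError("no assemblage estimates to sum")
    species = {e.species for e in estimates}
    if len(species) != 1:
        raise ValueError(f"estimates mix species: {sorted(species)}")
    return PotentialEstimate(
        species=next(iter(species)),
        assemblage="all",
        potential_colonies=sum(e.potential_colonies for e in estimates),
        potential_biomass_g_afdm=sum(e.potential_biomass_g_afdm for e in estimates),
        potential_spring_flux_g_c=sum(e.potential_spring_flux_g_c for e in estimates),
        potential_annual_sink_g_c=sum(e.potential_annual_sink_g_c for e in estimates),
        area_ha=sum(e.area_ha for e in estimates),
    )


def per_ha_sink_kg(estimate: PotentialEstimate) -> float:
    """Annual C sink per suitable hectare (kg C ha**-1 yr**-1)."""
    return estimate.per_ha_sink_kg_c


def combined_per_ha_sink_t(per_species_kg_c_ha_yr: Mapping[str, float]) -> float:
    """Combine per-species per-ha sinks into one total (t C ha-1 yr-1).

    Each species' sink is already normalized by its own suitable area;
    the combined figure is their sum, converted from kg to tonnes.
    """
    if any(v < 0 for v in per_species_kg_c_ha_yr.values()):
        raise ValueError("per-ha sinks must be >= 0")
    return sum(per_species_kg_c_ha_yr.values()) * T_PER_KG


def potential_table(estimates: Iterable[PotentialEstimate]) -> pd.DataFrame:
    """Tidy per-assemblage (or per-species) potential-stock table."""
    return pd.DataFrame(
        [
            {
                "species": e.species,
                "assemblage": e.assemblage,
                "area_ha": e.area_ha,
                "potential_colonies": e.potential_colonies,
                "potential_biomass_g_afdm": e.potential_biomass_g_afdm,
                "potential_spring_flux_g_c": e.potential_spring_flux_g_c,
                "potential_annual_sink_g_c": e.potential_annual_sink_g_c,
                "per_ha_sink_kg_c": e.per_ha_sink_kg_c,
            }
            for e in estimates
        ]
    )
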