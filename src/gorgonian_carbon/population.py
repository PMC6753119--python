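"""Survey representation: colonies, sampling units, size structures,
densities.

A survey is a tidy table with one row per observed colony (species,
height, depth, transect, sampling unit, benthic assemblage).  Colonies
are partitioned into a shallow (depth <= 35 m, inclusive) and a deep
(> 35 m) zone, the depth at which Mediterranean precoralligenous and
shallow coralligenous assemblages give way to deep coralligenous ones.

Densities are summarized per benthic assemblage in two ways that
together capture patchiness: the *total* density averages colony
counts per m**2 over every sampling unit, while the *on-patch* density
averages only over units where the species occurs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .allometry import evaluate_power_law, length_to_afdm
from .parameters import DepthZone, SpeciesParameters

logger = logging.getLogger(__name__)

__all__ = [
    "SURVEY_COLUMNS",
    "ColonyRecord",
    "DepthZoning",
    "SizeStructure",
    "SamplingUnit",
    "AssemblageDensity",
    "partition_by_depth",
    "build_size_structure",
    "density_summary",
    "units_from_survey",
    "population_biomass",
]

SURVEY_COLUMNS = ("species", "height_cm", "depth_m", "transect", "sampling_unit", "assemblage")


@dataclass(frozen=True)
class ColonyRecord:
    species: str
    height_cm: float
    depth_m: float
    transect: str
    sampling_unit: str
    assemblage: str

    def __post_init__(self) -> None:
        if self.height_cm <= 0:
            raise ValueError(f"colony height must be > 0, got {self.height_cm}")
        if self.depth_m < 0:
            raise ValueError(f"colony depth must be >= 0, got {self.depth_m}")


@dataclass(frozen=True)
class DepthZoning:
    """Shallow/deep partition threshold; shallow is depth <= threshold."""

    threshold_m: float = 35.0


@dataclass(frozen=True)
class SizeStructure:
    """Height-class histogram for one species x depth-zone compartment."""

    edges: Tuple[float, ...]
    counts: Tuple[int, ...]
    species: str
    depth_zone: DepthZone

    def __post_init__(self) -> None:
        if len(self.counts) != len(self.edges) - 1:
            raise ValueError("need n+1 edges for n counts")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be >= 0")

    @property
    def n_colonies(self) -> int:
        return int(sum(self.counts))


@dataclass(frozen=True)
class SamplingUnit:
    """One video frame / quadrat with its area and per-species count."""

    unit_id: str
    transect: str
    area_m2: float
    assemblage: str
    count: int

    def __post_init__(self) -> None:
        if self.area_m2 <= 0:
            raise ValueError(f"sampling-unit area must be > 0, got {self.area_m2}")
        if self.count < 0:
            raise ValueError(f"count must be >= 0, got {self.count}")


@dataclass(frozen=True)
class AssemblageDensity:
    """Total and on-patch density (colonies m**-2) for one assemblage.

    ``patch_density`` (and its SD) cover only sampling units where the
    species occurs; with a single occupied unit the SD is undefined and
    stored as ``None``, and with no occupied unit the patch density
    itself is absent.
    """

    assemblage: str
    species: str
    total_density: float
    total_sd: Optional[float]
    patch_density: Optional[float]
    patch_sd: Optional[float]
    n_units: int
    n_occupied: int = 0

    def __post_init__(self) -> None:
        if self.total_density < 0:
            raise ValueError("total density must be >= 0")
        if self.patch_density is not None and self.patch_density < self.total_density - 1e-12:
            raise ValueError("on-patch density cannot be below total density")


def _require_survey_columns(survey: pd.DataFrame) -> None:
    missing = [c for c in SURVEY_COLUMNS if c not in survey.columns]
    if missing:
        raise KeyError(f"survey table missing columns: {missing}")


def partition_by_depth(
    survey: pd.DataFrame, zoning: DepthZoning = DepthZoning()
) -> Dict[DepthZone, pd.DataFrame]:
    """Split a survey into shallow (depth <= threshold) and deep zones.

    Every colony lands in exactly one zone; rows with missing depth are
    reported by index in the raised error rather than silently dropped.
    """
    _require_survey_columns(survey)
    depths = survey["depth_m"]
    bad = survey.index[depths.isna()].tolist()
    if bad:
        raise ValueError(f"colonies with missing depth at rows {bad}")
    shallow_mask = depths <= zoning.threshold_m
    return {
        DepthZone.SHALLOW: survey[shallow_mask],
        DepthZone.DEEP: survey[~shallow_mask],
    }


def build_size_structure(
    heights_cm: Sequence[float],
    edges: Sequence[float],
    species: str = "",
    depth_zone: DepthZone = DepthZone.SHALLOW,
) -> SizeStructure:
    """Histogram colony heights into half-open classes ``[lo, hi)``.

    Heights outside the edge range are assigned to the end classes with
    a warning, so counts always sum to the number of colonies.
    """
    edges_arr = np.asarray(edges, dtype=float)
    if edges_arr.ndim != 1 or len(edges_arr) < 2 or np.any(np.diff(edges_arr) <= 0):
        raise ValueError("edges must be a strictly increasing 1-D sequence")
    h = np.asarray(list(heights_cm), dtype=float)
    if h.size:
        out = (h < edges_arr[0]) | (h >= edges_arr[-1])
        if out.any():
            logger.warning(
                "%d colonies outside size-class range [%.1f, %.1f); assigned to end classes",
                int(out.sum()), edges_arr[0], edges_arr[-1],
            )
        h = np.clip(h, edges_arr[0], np.nextafter(edges_arr[-1], -np.inf))
    idx = np.searchsorted(edges_arr, h, side="right") - 1
    counts = np.bincount(idx, minlength=len(edges_arr) - 1)
    return SizeStructure(
        edges=tuple(edges_arr), counts=tuple(int(c) for c in counts),
        species=species, depth_zone=depth_zone,
    )


def density_summary(
    units: Sequence[SamplingUnit], species: str, assemblage: str
) -> AssemblageDensity:
    """Summarize total and on-patch density over sampling units.

    Total density is the mean of count/area over *all* units; on-patch
    density is the same mean restricted to occupied units.  SDs are
    sample standard deviations over the same unit sets (undefined, and
    reported absent, for fewer than two units).
    """
    relevant = [u for u in units if u.assemblage == assemblage]
    if not relevant:
        raise ValueError(f"no sampling units for assemblage {assemblage!r}")
    dens = np.array([u.count / u.area_m2 for u in relevant], dtype=float)
    occupied = dens[dens > 0]

    def _sd(values: np.ndarray) -> Optional[float]:
        return float(np.std(values, ddof=1)) if values.size >= 2 else None

    return AssemblageDensity(
        assemblage=assemblage,
        species=species,
        total_density=float(dens.mean()),
        total_sd=_sd(dens),
        patch_density=float(occupied.mean()) if occupied.size else None,
        patch_sd=_sd(occupied),
        n_units=len(relevant),
        n_occupied=int(occupied.size),
    )


def units_from_survey(
    survey: pd.DataFrame,
    species: str,
    unit_table: pd.DataFrame,
) -> list[SamplingUnit]:
    """Build per-species sampling units by counting survey colonies.

    ``unit_table`` lists every analyzed unit (columns ``sampling_unit``,
    ``transect``, ``area_m2``, ``assemblage``) including empty ones —
    the survey alone cannot reveal units where nothing was seen.
    """
    _require_survey_columns(survey)
    counts = (
        survey[survey["species"] == species]
        .groupby("sampling_unit")
        .size()
        .to_dict()
    )
    return [
        SamplingUnit(
            unit_id=str(row.sampling_unit),
            transect=str(row.transect),
            area_m2=float(row.area_m2),
            assemblage=str(row.assemblage),
            count=int(counts.get(row.sampling_unit, 0)),
        )
        for row in unit_table.itertuples(index=False)
    ]


def population_biomass(
    survey: pd.DataFrame,
    params_by_key: Mapping[Tuple[str, DepthZone], SpeciesParameters],
    zoning: DepthZoning = DepthZoning(),
) -> float:
    """Total biomass (g AFDM) of a set of colonies.

    Each colony's height is chained through its compartment's
    height-to-length allometry and AFDM per cm.  Additive over any
    partition of the colonies.
    """
    _require_survey_columns(survey)
    total = 0.0
    for row in survey.itertuples(index=False):
        zone = DepthZone.SHALLOW if row.depth_m <= zoning.threshold_m else DepthZone.DEEP
        key = (row.species, zone)
        if key not in params_by_key:
            raise KeyError(
                f"no parameters configured for species {row.species!r} in zone {zone.value}"
            )
        p = params_by_key[key]
        length = evaluate_power_law(p.height_to_length, float(row.height_cm))
        total += length_to_afdm(length, p.afdm)
    return total
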