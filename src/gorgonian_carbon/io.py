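"""Readers, writers, run configuration and the pipeline orchestrator.

All tabular interchange is plain CSV; parameter configs are YAML with
units encoded in field names.  Packaged reference data (the published
per-assemblage density table, the published compartment budget table,
the default species parameter config, and a clearly-labelled synthetic
habitat-area table) load through the ``load_packaged_*`` helpers.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import pandas as pd
import yaml

from . import __version__
from .allometry import (
    FactorUnits,
    LinearDensityFactor,
    PowerLawModel,
    Response,
    SizeClassTable,
)
from .budget import aggregate_budget, budget_table, table1_report
from .parameters import (
    ConversionConstants,
    DepthZone,
    SinkMode,
    SpeciesParameters,
    TimeBase,
    validate_parameters,
)
from .population import SURVEY_COLUMNS, AssemblageDensity, units_from_survey, density_summary
from .stats import compare_groups
from .upscaling import (
    HabitatArea,
    potential_budget,
    potential_table,
    species_potential,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SurveyFormatError",
    "RunConfig",
    "load_survey",
    "load_parameters",
    "load_habitat_areas",
    "load_packaged_densities",
    "load_packaged_compartments",
    "load_packaged_per_ha_sinks",
    "load_packaged_parameters",
    "load_packaged_habitat_areas",
    "densities_from_frame",
    "run_pipeline",
]

_DATA = resources.files("gorgonian_carbon") / "data"


class SurveyFormatError(ValueError):
    """A survey file failed schema or row-level validation."""


def load_survey(path: str | Path) -> pd.DataFrame:
    """Read and validate a colony survey CSV.

    Requires the columns ``species, height_cm, depth_m, transect,
    sampling_unit, assemblage``.  Row-level problems (unparsable or
    non-positive heights, negative depths) are collected and reported
    together with their line numbers.
    """
    frame = pd.read_csv(path, dtype={"species": str, "transect": str,
                                     "sampling_unit": str, "assemblage": str})
    missing = [c for c in SURVEY_COLUMNS if c not in frame.columns]
    if missing:
        raise SurveyFormatError(f"{path}: missing required columns {missing}")

    errors: List[str] = []
    heights = pd.to_numeric(frame["height_cm"], errors="coerce")
    depths = pd.to_numeric(frame["depth_m"], errors="coerce")
    for idx in frame.index:
        line = idx + 2  # header + 1-based
        if pd.isna(heights[idx]):
            errors.append(f"line {line}: unparsable height_cm {frame['height_cm'][idx]!r}")
        elif heights[idx] <= 0:
            errors.append(f"line {line}: height_cm must be > 0, got {heights[idx]}")
        if pd.isna(depths[idx]):
            errors.append(f"line {line}: unparsable depth_m {frame['depth_m'][idx]!r}")
        elif depths[idx] < 0:
            errors.append(f"line {line}: depth_m must be >= 0, got {depths[idx]}")
    if errors:
        raise SurveyFormatError(f"{path}: " + "; ".join(errors))
    frame["height_cm"] = heights
    frame["depth_m"] = depths
    return frame[list(SURVEY_COLUMNS)]


def _parse_power_law(spec: Mapping) -> PowerLawModel:
    return PowerLawModel(
        coefficient_a=float(spec["coefficient_a"]),
        exponent_b=float(spec["exponent_b"]),
        response=Response(spec.get("response", "linear_length_cm")),
        r_squared=spec.get("r_squared"),
        n_fit=spec.get("n_fit"),
    )


def _parse_size_class_table(spec: Optional[Mapping]) -> Optional[SizeClassTable]:
    if spec is None:
        return None
    return SizeClassTable(
        edges=tuple(float(e) for e in spec["edges"]),
        values=tuple(float(v) for v in spec["values"]),
        se=tuple(float(s) for s in spec["se"]) if spec.get("se") else None,
    )


def _parse_entry(entry: Mapping) -> SpeciesParameters:
    afdm_spec = entry["afdm_mg_per_cm"]
    polyp_spec = entry.get("polyps_per_cm")
    params = SpeciesParameters(
        species=entry["species"],
        depth_zone=DepthZone(entry["depth_zone"]),
        afdm=LinearDensityFactor(
            mean=float(afdm_spec["mean"]), se=float(afdm_spec.get("se", 0.0)),
            units=FactorUnits.MG_AFDM_PER_CM,
        ),
        height_to_length=_parse_power_law(entry["height_to_length"]),
        height_to_area=(
            _parse_power_law(entry["height_to_area"]) if entry.get("height_to_area") else None
        ),
        polyp_factor=(
            LinearDensityFactor(
                mean=float(polyp_spec["mean"]), se=float(polyp_spec.get("se", 0.0)),
                units=FactorUnits.POLYPS_PER_CM,
            )
            if polyp_spec else None
        ),
        polyp_table=_parse_size_class_table(entry.get("polyp_table")),
        zooplankton_ingestion_ug_c_per_polyp_per_day=entry.get(
            "zooplankton_ingestion_ug_c_per_polyp_per_day"),
        seston_ingestion_ug_c_per_g_afdm=entry.get("seston_ingestion_ug_c_per_g_afdm"),
        seston_timebase=TimeBase(entry.get("seston_timebase", "per_day")),
        autotrophic_ug_c_per_cm2_per_day=entry.get("autotrophic_ug_c_per_cm2_per_day"),
        respiration_mg_o2_per_g_afdm_per_hour=entry.get(
            "respiration_mg_o2_per_g_afdm_per_hour"),
        respiration_reference_temp_c=entry.get("respiration_reference_temp_c"),
        growth_cm_height_per_year=entry.get("growth_cm_height_per_year"),
        growth_source_values=tuple(entry.get("growth_source_values") or ()),
        c_content_mg_per_cm=entry.get("c_content_mg_per_cm"),
        sink_investment_table=_parse_size_class_table(entry.get("sink_investment_table")),
        mixotrophic=bool(entry.get("mixotrophic", False)),
        sink_mode=SinkMode(entry.get("sink_mode", "length_increment")),
        effective_rates=bool(entry.get("effective_rates", False)),
    )
    return params


def load_parameters(
    path: str | Path, strict: bool = False
) -> Dict[Tuple[str, DepthZone], SpeciesParameters]:
    """Load a species parameter YAML into a keyed dictionary.

    With ``strict=True`` any entry failing validation raises; the
    default logs issues and keeps going, since partially-specified
    configs (rates pending calibration) are a normal state.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    out: Dict[Tuple[str, DepthZone], SpeciesParameters] = {}
    for entry in doc["entries"]:
        params = _parse_entry(entry)
        issues = validate_parameters(params)
        if issues:
            msg = f"{params.species}/{params.depth_zone.value}: " + "; ".join(issues)
            if strict:
                raise ValueError(msg)
            logger.info("parameter issues (non-strict load): %s", msg)
        out[params.key] = params
    return out


def load_habitat_areas(path: str | Path) -> List[HabitatArea]:
    """Read a habitat-area CSV (assemblage, area_ha, zone, species_list)."""
    frame = pd.read_csv(path, comment="#")
    return [
        HabitatArea(
            assemblage=str(row.assemblage),
            area_ha=float(row.area_ha),
            zone=DepthZone(row.zone),
            suitable_for=tuple(str(row.species_list).split(";")),
        )
        for row in frame.itertuples(index=False)
    ]


def densities_from_frame(frame: pd.DataFrame) -> List[AssemblageDensity]:
    """Build density summaries from a published density table."""
    out = []
    for row in frame.itertuples(index=False):
        out.append(
            AssemblageDensity(
                assemblage=str(row.assemblage),
                species=str(row.species),
                total_density=float(row.total_density),
                total_sd=None if pd.isna(row.total_sd) else float(row.total_sd),
                patch_density=None if pd.isna(row.patch_density) else float(row.patch_density),
                patch_sd=None if pd.isna(row.patch_sd) else float(row.patch_sd),
                n_units=int(row.n_total),
                n_occupied=int(row.n_patch),
            )
        )
    return out


def load_packaged_densities() -> pd.DataFrame:
    """Published per-assemblage total and on-patch densities."""
    with resources.as_file(_DATA / "table3_densities.csv") as p:
        return pd.read_csv(p)


def load_packaged_compartments() -> pd.DataFrame:
    """Published per-compartment budget totals for the study area."""
    with resources.as_file(_DATA / "observed_compartments.csv") as p:
        return pd.read_csv(p)


def load_packaged_per_ha_sinks() -> pd.DataFrame:
    """Published per-species per-hectare annual C sinks (kg C ha-1 yr-1)."""
    with resources.as_file(_DATA / "reported_per_ha_sinks.csv") as p:
        return pd.read_csv(p)


def load_packaged_parameters() -> Dict[Tuple[str, DepthZone], SpeciesParameters]:
    """Default species parameter config (literature rates unset)."""
    with resources.as_file(_DATA / "species_params.yaml") as p:
        return load_parameters(p)


def load_packaged_habitat_areas() -> List[HabitatArea]:
    """Synthetic habitat-area table (placeholder hectares, for tests)."""
    with resources.as_file(_DATA / "synthetic_habitat_areas.csv") as p:
        return load_habitat_areas(p)


@dataclass
class RunConfig:
    """Paths and knobs for one end-to-end pipeline run."""

    survey_path: Path
    parameters_path: Path
    output_dir: Path
    densities_path: Optional[Path] = None
    areas_path: Optional[Path] = None
    unit_table_path: Optional[Path] = None
    season_days: int = 90
    seed: int = 0
    comparison_unit: str = "transect"

    def __post_init__(self) -> None:
        if self.season_days <= 0:
            raise ValueError("season_days must be > 0")
        for name in ("survey_path", "parameters_path", "densities_path",
                     "areas_path", "unit_table_path"):
            value = getattr(self, name)
            if value is not None:
                value = Path(value)
                setattr(self, name, value)
                if name != "output_dir" and not value.exists():
                    raise FileNotFoundError(f"{name}: {value} does not exist")
        self.output_dir = Path(self.output_dir)

    def manifest(self) -> dict:
        payload = {
            k: (str(v) if isinstance(v, Path) else v) for k, v in asdict(self).items()
        }
        digest = hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()
        return {"package_version": __version__, "config": payload, "config_sha256": digest}


def run_pipeline(config: RunConfig) -> dict:
    """Orchestrate budget -> upscale -> compare -> report.

    Writes the compartment budget table, the species summary, the
    upscaling table (when densities and areas are given), the species
    comparison (when >= 2 species present) and a JSON run manifest to
    the output directory; returns the manifest.  An empty survey
    produces an all-empty but valid report rather than an error.
    """
    config.output_dir.mkdir(parents=True, exist_ok=True)
    survey = load_survey(config.survey_path)
    params = load_parameters(config.parameters_path)
    constants = ConversionConstants(season_days=config.season_days)

    if survey.empty:
        logger.warning("survey %s contains no colonies; writing empty report",
                       config.survey_path)
        budgets = []
    else:
        budgets = aggregate_budget(survey, params, constants)

    full = budget_table(budgets)
    full.to_csv(config.output_dir / "budget_compartments.csv", index=False)
    table1_report(budgets).to_csv(config.output_dir / "budget_species_summary.csv", index=False)

    if config.densities_path is not None and config.areas_path is not None:
        dens = densities_from_frame(pd.read_csv(config.densities_path))
        areas = load_habitat_areas(config.areas_path)
        comps = {(b.species, b.depth_zone): b for b in budgets if b.depth_zone is not None}
        estimates = []
        for d in dens:
            for area in areas:
                if area.assemblage != d.assemblage or d.species not in area.suitable_for:
                    continue
                comp = comps.get((d.species, area.zone))
                if comp is None:
                    logger.warning("no observed compartment for %s/%s; skipping %s",
                                   d.species, area.zone.value, area.assemblage)
                    continue
                estimates.append(potential_budget(area, d, comp))
        per_species = [
            species_potential([e for e in estimates if e.species == sp])
            for sp in sorted({e.species for e in estimates})
        ]
        potential_table(estimates + per_species).to_csv(
            config.output_dir / "upscaling.csv", index=False
        )

    species_present = sorted(survey["species"].unique()) if not survey.empty else []
    if len(species_present) >= 2:
        rows = []
        for response, extractor in (
            ("biomass", "biomass_g_afdm"),
            ("spring_flux", "seasonal_net_g_c"),
            ("annual_sink", "annual_sink_g_c"),
        ):
            groups = _per_unit_values(survey, params, constants, extractor,
                                      config.comparison_unit)
            if all(len(v) >= 2 for v in groups.values()) and len(groups) >= 2:
                cmp_result = compare_groups(groups, response=response)
                for pair, pval in cmp_result.pairwise_p.items():
                    rows.append({
                        "response": response,
                        "f_statistic": cmp_result.f_statistic,
                        "p_value": cmp_result.p_value,
                        "species_a": pair[0], "species_b": pair[1],
                        "pairwise_p": pval,
                    })
        pd.DataFrame(rows).to_csv(config.output_dir / "species_comparison.csv", index=False)

    manifest = config.manifest()
    with open(config.output_dir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _per_unit_values(
    survey: pd.DataFrame,
    params: Mapping[Tuple[str, DepthZone], SpeciesParameters],
    constants: ConversionConstants,
    column: str,
    unit: str = "transect",
) -> Dict[str, List[float]]:
    """Per-observational-unit response values for the species comparison."""
    groups: Dict[str, List[float]] = {}
    for (species, unit_id), sub in survey.groupby(["species", unit]):
        try:
            budgets = aggregate_budget(sub, params, constants)
        except KeyError:
            continue
        total = [b for b in budgets if b.depth_zone is None][0]
        groups.setdefault(species, []).append(getattr(total, column))
    return groups
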