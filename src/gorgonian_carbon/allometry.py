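"""Allometric scaling of gorgonian colonies.

Gorgonian colonies are ramified: the ecologically relevant quantities
(total branch length, surface area, polyp number, biomass) grow faster
than the single measured dimension, colony height.  This module houses
the power laws ``y = a * h**b`` linking colony height (cm) to total
linear length (cm) or surface area (cm**2), the linear density factors
that convert length into ash-free dry mass (AFDM), polyp counts or
carbon content, and the per-size-class polyp lookup used for species
whose polyp number is published per height class rather than per cm.

Power laws are fitted by ordinary least squares on log-transformed
pairs (``log y = log a + b log x``), the standard estimator in
allometry; R-squared is reported in log space and 95% confidence
intervals are stored for both parameters.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence, Tuple

import numpy as np
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "Response",
    "FactorUnits",
    "PowerLawModel",
    "LinearDensityFactor",
    "SizeClassTable",
    "MeasurementPair",
    "UnitError",
    "FitError",
    "evaluate_power_law",
    "fit_power_law",
    "length_to_afdm",
    "length_to_polyps",
    "lookup_size_class",
    "height_to_polyps_by_class",
    "growth_to_length_increment",
]


class Response(str, Enum):
    """Response variable of a height-based power law."""

    LINEAR_LENGTH_CM = "linear_length_cm"
    SURFACE_AREA_CM2 = "surface_area_cm2"


class FactorUnits(str, Enum):
    """Units of a per-cm linear density factor."""

    MG_AFDM_PER_CM = "mg_AFDM_per_cm"
    POLYPS_PER_CM = "polyps_per_cm"
    MG_C_PER_CM = "mg_C_per_cm"


class UnitError(ValueError):
    """A factor with the wrong units was supplied to a conversion."""


class FitError(ValueError):
    """A power-law fit was requested on unusable data."""


@dataclass(frozen=True)
class PowerLawModel:
    """A fitted relationship ``response = a * height**b``.

    Parameters
    ----------
    coefficient_a
        Response value at height 1 cm; must be positive.
    exponent_b
        Scaling exponent.  Values > 1 indicate that ramification makes
        the response grow faster than height.
    response
        What the law predicts (total linear length or surface area).
    r_squared, n_fit
        Fit diagnostics, absent for literature relationships whose
        diagnostics were not reported.
    ci_a, ci_b
        Optional 95% confidence intervals for the parameters.
    """

    coefficient_a: float
    exponent_b: float
    response: Response = Response.LINEAR_LENGTH_CM
    predictor: str = "height_cm"
    r_squared: Optional[float] = None
    n_fit: Optional[int] = None
    ci_a: Optional[Tuple[float, float]] = None
    ci_b: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.coefficient_a <= 0:
            raise ValueError(f"coefficient_a must be > 0, got {self.coefficient_a}")
        if self.r_squared is not None and not (0.0 <= self.r_squared <= 1.0):
            raise ValueError(f"r_squared must lie in [0, 1], got {self.r_squared}")

    def __call__(self, height_cm: float) -> float:
        return evaluate_power_law(self, height_cm)


@dataclass(frozen=True)
class LinearDensityFactor:
    """A per-cm density (mean ± SE) converting colony length into
    biomass, polyps or carbon content."""

    mean: float
    se: float
    units: FactorUnits

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise ValueError(f"factor mean must be > 0, got {self.mean}")
        if self.se < 0:
            raise ValueError(f"factor se must be >= 0, got {self.se}")


@dataclass(frozen=True)
class SizeClassTable:
    """Values published per colony height class.

    ``edges`` are the strictly increasing class boundaries (cm) and
    ``values`` the per-class means, so ``len(values) == len(edges) - 1``.
    Classes are half-open ``[lower, upper)``; heights outside the table
    range are clamped to the end classes with a logged warning.
    """

    edges: Tuple[float, ...]
    values: Tuple[float, ...]
    se: Optional[Tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if len(self.edges) < 2 or len(self.values) != len(self.edges) - 1:
            raise ValueError("need n+1 edges for n class values")
        if any(b <= a for a, b in zip(self.edges, self.edges[1:])):
            raise ValueError("class edges must be strictly increasing")
        if any(b < a for a, b in zip(self.values, self.values[1:])):
            raise ValueError("per-class values must be non-decreasing with size")


@dataclass(frozen=True)
class MeasurementPair:
    """One digitized colony: measured height and the measured response."""

    height_cm: float
    response_value: float
    response: Response = Response.LINEAR_LENGTH_CM

    def __post_init__(self) -> None:
        if self.height_cm <= 0 or self.response_value <= 0:
            raise ValueError("measurement pairs must be strictly positive")


def evaluate_power_law(model: PowerLawModel, height_cm: float) -> float:
    """Evaluate ``a * height**b``; zero height maps to zero response.

    Raises a domain error for negative heights.
    """
    if height_cm < 0:
        raise ValueError(f"height must be >= 0, got {height_cm}")
    if height_cm == 0:
        return 0.0
    return model.coefficient_a * height_cm**model.exponent_b


def fit_power_law(
    pairs: Sequence[MeasurementPair],
    response: Optional[Response] = None,
) -> PowerLawModel:
    """Fit ``y = a * x**b`` by OLS on log-transformed pairs.

    At least three pairs are required.  R-squared is the coefficient of
    determination of the log-log regression; 95% confidence intervals
    for ``a`` (back-transformed) and ``b`` are stored on the model.
    """
    if len(pairs) < 3:
        raise FitError(f"power-law fit needs >= 3 pairs, got {len(pairs)}")
    responses = {p.response for p in pairs}
    if len(responses) > 1:
        raise FitError(f"pairs mix response types: {sorted(r.value for r in responses)}")
    if response is None:
        response = next(iter(responses))

    x = np.log(np.array([p.height_cm for p in pairs], dtype=float))
    y = np.log(np.array([p.response_value for p in pairs], dtype=float))
    design = sm.add_constant(x)
    result = sm.OLS(y, design).fit()
    log_a, b = result.params
    ci = result.conf_int(alpha=0.05)
    r2 = float(result.rsquared) if len(pairs) > 2 else 1.0
    # Guard against tiny negative rounding on perfectly collinear input.
    r2 = min(max(r2, 0.0), 1.0)
    return PowerLawModel(
        coefficient_a=float(math.exp(log_a)),
        exponent_b=float(b),
        response=response,
        r_squared=r2,
        n_fit=len(pairs),
        ci_a=(float(math.exp(ci[0][0])), float(math.exp(ci[0][1]))),
        ci_b=(float(ci[1][0]), float(ci[1][1])),
    )


def _require_units(factor: LinearDensityFactor, units: FactorUnits) -> None:
    if factor.units is not units:
        raise UnitError(f"expected factor in {units.value}, got {factor.units.value}")


def length_to_afdm(length_cm: float, factor: LinearDensityFactor) -> float:
    """Convert total colony length (cm) into ash-free dry mass (g).

    The factor carries mg AFDM per cm, so the product is divided by
    1000 to report grams.
    """
    if length_cm < 0:
        raise ValueError(f"length must be >= 0, got {length_cm}")
    _require_units(factor, FactorUnits.MG_AFDM_PER_CM)
    return length_cm * factor.mean / 1000.0


def length_to_polyps(length_cm: float, factor: LinearDensityFactor) -> float:
    """Convert total colony length (cm) into a (continuous) polyp count."""
    if length_cm < 0:
        raise ValueError(f"length must be >= 0, got {length_cm}")
    _require_units(factor, FactorUnits.POLYPS_PER_CM)
    return length_cm * factor.mean


def lookup_size_class(height_cm: float, table: SizeClassTable) -> float:
    """Look up the per-class value containing a given height.

    Classes are half-open ``[lower, upper)``; a height on a boundary
    falls in the upper class.  Heights outside the table range are
    clamped to the end classes with a warning.
    """
    if height_cm < 0:
        raise ValueError(f"height must be >= 0, got {height_cm}")
    edges = table.edges
    if height_cm < edges[0]:
        logger.warning(
            "height %.2f cm below first size class [%.1f, %.1f); clamping",
            height_cm, edges[0], edges[1],
        )
        return table.values[0]
    if height_cm >= edges[-1]:
        if height_cm > edges[-1]:
            logger.warning(
                "height %.2f cm above last size class edge %.1f; clamping",
                height_cm, edges[-1],
            )
        return table.values[-1]
    idx = int(np.searchsorted(np.asarray(edges), height_cm, side="right")) - 1
    return table.values[idx]


def height_to_polyps_by_class(height_cm: float, table: SizeClassTable) -> float:
    """Polyps per colony from a published per-size-class table."""
    return lookup_size_class(height_cm, table)


def growth_to_length_increment(
    model: PowerLawModel, height_cm: float, dheight_cm_per_year: float
) -> float:
    """Annual total-length increment from an annual height increment.

    Returns ``a*(h+dh)**b - a*h**b`` (cm yr**-1), the chain of the
    height growth rate through the allometric length relationship.
    """
    if height_cm < 0:
        raise ValueError(f"height must be >= 0, got {height_cm}")
    if dheight_cm_per_year < 0:
        raise ValueError(f"height increment must be >= 0, got {dheight_cm_per_year}")
    return evaluate_power_law(model, height_cm + dheight_cm_per_year) - evaluate_power_law(
        model, height_cm
    )
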