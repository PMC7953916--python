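"""Soil physical and chemical response metrics.

Implements the desk arithmetic downstream of the field and lab protocols:
loss-on-ignition organic matter, fine particulate organic matter (fPOM,
the organic share of the 53-500 um sieved fraction), core bulk density,
single-ring infiltration rate, the Haney soil-health score and
equivalent-soil-mass (ESM) element stocks.

Units: depths in cm, masses in g, bulk density in g/cm^3, element stocks
in Mg/ha.  One g/cm^3 over 1 cm of depth is 100 Mg/ha of soil, so the
default ESM reference mass of 6,000 Mg/ha corresponds to roughly 60 cm of
unit-density soil.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import CubicSpline, PchipInterpolator

from .errors import (
    InsufficientDepthError,
    MeasurementError,
    ValidationError,
)

#: Soil mass (Mg/ha) of a 1-cm layer at 1 g/cm^3.
MG_PER_HA_PER_CM_AT_UNIT_BD = 100.0

#: NRCS single-ring infiltration kit defaults.
DEFAULT_RING_DIAMETER_CM = 15.0
DEFAULT_WATER_VOLUME_ML = 444.0

#: Default ESM reference soil mass, Mg/ha.
DEFAULT_REFERENCE_MASS = 6000.0


@dataclass
class CoreMeasurement:
    """One soil core of known geometry, weighed before/after drying."""

    core_id: str
    depth_cm: float
    diameter_cm: float
    dry_mass_g: float
    wet_mass_g: Optional[float] = None
    ignited_mass_g: Optional[float] = None

    def __post_init__(self) -> None:
        if self.depth_cm <= 0 or self.diameter_cm <= 0:
            raise ValidationError(
                f"core {self.core_id}: dimensions must be positive"
            )
        if self.dry_mass_g <= 0:
            raise ValidationError(
                f"core {self.core_id}: dry mass must be positive"
            )
        if self.wet_mass_g is not None and self.dry_mass_g > self.wet_mass_g:
            raise MeasurementError(
                f"core {self.core_id}: dry mass exceeds wet mass"
            )
        if (
            self.ignited_mass_g is not None
            and self.ignited_mass_g > self.dry_mass_g
        ):
            raise MeasurementError(
                f"core {self.core_id}: ignited mass exceeds dry mass"
            )

    @property
    def volume_cm3(self) -> float:
        return math.pi * (self.diameter_cm / 2.0) ** 2 * self.depth_cm


@dataclass
class FpomMeasurement:
    """Sieved 53-500 um fraction masses from one fPOM assay."""

    initial_soil_mass_g: float
    fraction_dry_mass_g: float
    fraction_ash_mass_g: float

    def __post_init__(self) -> None:
        if self.initial_soil_mass_g <= 0:
            raise ValidationError("initial soil mass must be positive")
        if self.fraction_dry_mass_g < 0 or self.fraction_ash_mass_g < 0:
            raise ValidationError("fraction masses must be nonnegative")
        if self.fraction_ash_mass_g > self.fraction_dry_mass_g:
            raise MeasurementError("ash mass exceeds fraction dry mass")
        if self.fraction_dry_mass_g > self.initial_soil_mass_g:
            raise MeasurementError("fraction dry mass exceeds initial soil mass")


@dataclass
class SoilLayer:
    """One depth layer of a soil profile with bulk density and element
    concentrations (% of dry mass)."""

    top_cm: float
    bottom_cm: float
    bulk_density_g_cm3: float
    carbon_pct: float
    nitrogen_pct: float = 0.0

    def __post_init__(self) -> None:
        if self.top_cm < 0 or self.bottom_cm <= self.top_cm:
            raise ValidationError(
                f"layer [{self.top_cm}, {self.bottom_cm}]: top must be >= 0 "
                "and bottom > top"
            )
        if self.bulk_density_g_cm3 <= 0:
            raise ValidationError("bulk density must be positive")
        if self.carbon_pct < 0 or self.nitrogen_pct < 0:
            raise ValidationError("element percentages must be nonnegative")

    @property
    def thickness_cm(self) -> float:
        return self.bottom_cm - self.top_cm

    @property
    def soil_mass_mg_ha(self) -> float:
        return (
            MG_PER_HA_PER_CM_AT_UNIT_BD
            * self.bulk_density_g_cm3
            * self.thickness_cm
        )


@dataclass
class HaneyInput:
    """Inputs to the Haney soil-health score (all ppm)."""

    co2_c_ppm: float
    weoc_ppm: float
    weon_ppm: float

    def __post_init__(self) -> None:
        if min(self.co2_c_ppm, self.weoc_ppm, self.weon_ppm) < 0:
            raise ValidationError("Haney inputs must be nonnegative")


@dataclass
class InfiltrationTrial:
    """One pour of the NRCS single-ring infiltration kit."""

    time_to_saturation_s: float
    ring_diameter_cm: float = DEFAULT_RING_DIAMETER_CM
    water_volume_ml: float = DEFAULT_WATER_VOLUME_ML
    pour_index: int = 1

    def __post_init__(self) -> None:
        if self.time_to_saturation_s <= 0:
            raise ValidationError("time to saturation must be positive")
        if self.ring_diameter_cm <= 0 or self.water_volume_ml <= 0:
            raise ValidationError("ring diameter and volume must be positive")
        if self.pour_index not in (1, 2):
            raise ValidationError("pour_index must be 1 or 2")


def loi_som_percent(dry_mass_g: float, ignited_mass_g: float) -> float:
    """Soil organic matter (%) by weight loss on ignition:
    ``100 * (dry - ignited) / dry``."""
    if dry_mass_g <= 0:
        raise ValidationError("dry mass must be positive")
    if ignited_mass_g < 0:
        raise ValidationError("ignited mass must be nonnegative")
    if ignited_mass_g > dry_mass_g:
        raise MeasurementError("ignited mass exceeds dry mass")
    return 100.0 * (dry_mass_g - ignited_mass_g) / dry_mass_g


def fpom_percent(m: FpomMeasurement) -> float:
    """Fine particulate organic matter as % of initial soil mass: the
    mass lost on ignition of the 53-500 um fraction over the starting
    soil mass."""
    return (
        100.0
        * (m.fraction_dry_mass_g - m.fraction_ash_mass_g)
        / m.initial_soil_mass_g
    )


def bulk_density(core: CoreMeasurement) -> float:
    """Dry mass over core volume, g/cm^3."""
    return core.dry_mass_g / core.volume_cm3


def infiltration_rate(trial: InfiltrationTrial) -> dict:
    """Water depth applied (cm) and infiltration rate (cm/hr) for one
    pour.  The default kit (444 mL into a 15-cm ring) applies ~2.513 cm,
    the NRCS one-inch standard."""
    radius = trial.ring_diameter_cm / 2.0
    depth_cm = trial.water_volume_ml / (math.pi * radius**2)
    rate = depth_cm / trial.time_to_saturation_s * 3600.0
    return {"water_depth_cm": depth_cm, "rate_cm_per_hr": rate}


def infiltration_summary(trials: Sequence[InfiltrationTrial]) -> dict:
    """Rates for both pours of a kit run.  The second (wet-soil) pour is
    the headline rate; the first is retained."""
    out = {}
    for trial in trials:
        key = f"pour{trial.pour_index}_rate_cm_per_hr"
        out[key] = infiltration_rate(trial)["rate_cm_per_hr"]
    out["headline_rate_cm_per_hr"] = out.get(
        "pour2_rate_cm_per_hr", out.get("pour1_rate_cm_per_hr")
    )
    return out


def haney_score(h: HaneyInput) -> float:
    """Haney soil-health score: 1-day CO2-C/10 + WEOC/50 + WEON/10."""
    return h.co2_c_ppm / 10.0 + h.weoc_ppm / 50.0 + h.weon_ppm / 10.0


def _validate_profile(profile: Sequence[SoilLayer]) -> None:
    if not profile:
        raise ValidationError("soil profile must contain at least one layer")
    if profile[0].top_cm != 0:
        raise ValidationError("soil profile must start at 0 cm")
    for upper, lower in zip(profile[:-1], profile[1:]):
        if not math.isclose(upper.bottom_cm, lower.top_cm):
            raise ValidationError(
                "soil layers must be contiguous and ordered downward: "
                f"{upper.bottom_cm} cm -> {lower.top_cm} cm"
            )


def cumulative_mass_curves(
    profile: Sequence[SoilLayer], element: str = "C"
) -> tuple:
    """Cumulative soil mass and cumulative element mass (both Mg/ha) at
    the layer boundaries, starting from (0, 0)."""
    _validate_profile(profile)
    if element not in ("C", "N"):
        raise ValidationError("element must be 'C' or 'N'")
    soil = [0.0]
    elem = [0.0]
    for layer in profile:
        pct = layer.carbon_pct if element == "C" else layer.nitrogen_pct
        soil.append(soil[-1] + layer.soil_mass_mg_ha)
        elem.append(elem[-1] + layer.soil_mass_mg_ha * pct / 100.0)
    return np.array(soil), np.array(elem)


def esm_stock(
    profile: Sequence[SoilLayer],
    element: str = "C",
    reference_mass_mg_ha: float = DEFAULT_REFERENCE_MASS,
    spline: str = "monotone",
) -> float:
    """Element stock (Mg/ha) at a fixed cumulative soil mass.

    The equivalent-soil-mass method interpolates cumulative element mass
    against cumulative soil mass with a cubic spline and evaluates it at
    the reference mass (default 6,000 Mg/ha), removing the compaction
    bias of fixed-depth comparisons.  The default interpolant is the
    monotone (PCHIP) cubic, which is exact at the layer-boundary knots
    and cannot overshoot the physically monotone cumulative curve; set
    ``spline="natural"`` for a natural cubic spline sensitivity check.

    Raises :class:`InsufficientDepthError` if the profile holds less soil
    than the reference mass — stocks are never extrapolated.
    """
    soil, elem = cumulative_mass_curves(profile, element)
    if reference_mass_mg_ha <= 0:
        raise ValidationError("reference mass must be positive")
    if reference_mass_mg_ha > soil[-1] * (1 + 1e-12):
        raise InsufficientDepthError(
            f"profile holds {soil[-1]:.1f} Mg/ha of soil, less than the "
            f"reference mass {reference_mass_mg_ha:.1f} Mg/ha"
        )
    if spline == "monotone":
        interp = PchipInterpolator(soil, elem)
    elif spline == "natural":
        interp = CubicSpline(soil, elem, bc_type="natural")
    else:
        raise ValidationError("spline must be 'monotone' or 'natural'")
    return float(interp(min(reference_mass_mg_ha, soil[-1])))


def reference_depth_cm(
    profile: Sequence[SoilLayer],
    reference_mass_mg_ha: float = DEFAULT_REFERENCE_MASS,
) -> float:
    """Depth (cm) at which cumulative soil mass reaches the reference
    mass — a diagnostic for comparing against fixed-depth sampling."""
    _validate_profile(profile)
    cum = 0.0
    for layer in profile:
        layer_mass = layer.soil_mass_mg_ha
        if cum + layer_mass >= reference_mass_mg_ha:
            frac = (reference_mass_mg_ha - cum) / layer_mass
            return layer.top_cm + frac * layer.thickness_cm
        cum += layer_mass
    raise InsufficientDepthError(
        f"profile holds {cum:.1f} Mg/ha, less than {reference_mass_mg_ha:.1f}"
    )


def mean_of_cores(values: Sequence[float]) -> float:
    """Per-field value as the arithmetic mean of core replicates."""
    if len(values) == 0:
        raise ValidationError("no replicate values to average")
    return float(np.mean(values))
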