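"""MIRD absorbed-dose calculation and fractionated-activity planning.

The MIRD schema reduces internal dosimetry to

    D = Ã * S,

the time-integrated activity in a source region multiplied by the S value —
the mean absorbed dose rate per unit activity for that source/target pair.
Self-dose S values used here come from two mass power laws:

* whole body: S(m) = 1.34e-4 * m^-0.921 Gy/(MBq·h), m in kg, interpolating
  newborn to adult phantoms;
* spheres/organs (unit density): S(m) = a * m^b mGy/(MBq·s) with m in g,
  fitted log-log to tabulated sphere S values (the clinical example yields
  a = 0.031, b = -0.981).

Whole-body dose doubles as a red-marrow toxicity surrogate (ratio ~1.6),
and drives fractionated-activity planning: later fractions are scaled by
the first fraction's measured dose per unit activity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .units import MGY_MBQ_S_TO_GY_MBQ_H, S_UNIT_GY_MBQ_H, S_UNIT_MGY_MBQ_S, S_UNITS

#: Whole-body self-dose power law coefficients (mass in kg).
WB_S_COEFF = 1.34e-4
WB_S_EXPONENT = -0.921

#: Mass range (kg) spanned by the newborn-to-adult phantom interpolation.
WB_MASS_RANGE_KG = (1.0, 150.0)

#: Mean whole-body to red-marrow absorbed-dose ratio.
WB_TO_RM_RATIO = 1.6


@dataclass(frozen=True)
class SValue:
    """An S value with its unit tag, provenance and the mass it was built for."""

    value: float
    units: str
    source: str = "user_table"
    mass: float = None

    def __post_init__(self):
        if self.units not in S_UNITS:
            raise ValidationError(f"unknown S-value units {self.units!r}")
        if self.value <= 0:
            raise ValidationError("S value must be > 0")

    def in_gy_per_mbq_h(self) -> float:
        if self.units == S_UNIT_GY_MBQ_H:
            return self.value
        return self.value * MGY_MBQ_S_TO_GY_MBQ_H


@dataclass(frozen=True)
class PowerLawS:
    """Mass power law S(m) = a * m^b."""

    a: float
    b: float
    units: str
    mass_unit: str  # "kg" or "g"

    def __call__(self, mass: float) -> float:
        if mass <= 0:
            raise ValidationError("mass must be > 0")
        return self.a * mass ** self.b


#: The whole-body S power law (Gy/(MBq·h), mass in kg).
WB_POWER_LAW = PowerLawS(a=WB_S_COEFF, b=WB_S_EXPONENT,
                         units=S_UNIT_GY_MBQ_H, mass_unit="kg")


@dataclass
class DoseResult:
    """Absorbed dose for one region with first-order uncertainties."""

    region: str
    tia_MBq_h: float
    tia_sigma: float
    s_value: SValue
    s_sigma: float
    dose_Gy: float
    dose_sigma_Gy: float
    integration_period: str = "0-inf"


@dataclass
class TreatmentPlan:
    """Fractionated-activity plan derived from the first fraction's dose."""

    n_fractions: int
    target_dose_Gy: float
    A1_MBq: float
    D1_Gy: float
    planned_Ai_MBq: float

    @property
    def predicted_total_dose_Gy(self) -> float:
        return self.D1_Gy + (self.n_fractions - 1) * \
            self.planned_Ai_MBq * self.D1_Gy / self.A1_MBq


def s_wb_from_mass(mass_kg: float) -> SValue:
    """Whole-body self-dose S value from patient mass (kg).

    Valid over the newborn-to-adult interpolation range (1-150 kg); outside
    it the power law is still evaluated but a warning is raised.
    """
    if mass_kg <= 0:
        raise ValidationError("mass must be > 0")
    if not WB_MASS_RANGE_KG[0] <= mass_kg <= WB_MASS_RANGE_KG[1]:
        import warnings
        warnings.warn(f"mass {mass_kg} kg outside the phantom interpolation "
                      f"range {WB_MASS_RANGE_KG}", stacklevel=2)
    return SValue(value=WB_POWER_LAW(mass_kg), units=S_UNIT_GY_MBQ_H,
                  source="wb_power_law", mass=mass_kg)


def fit_s_power_law(masses_g, s_values,
                    units: str = S_UNIT_MGY_MBQ_S) -> PowerLawS:
    """Fit S(m) = a * m^b by ordinary least squares in log-log space.

    Used to interpolate sphere/organ self-dose S values at arbitrary
    lesion/organ masses (grams).
    """
    m = np.asarray(masses_g, dtype=float)
    s = np.asarray(s_values, dtype=float)
    if m.size < 3:
        raise ValidationError("need at least 3 (mass, S) points")
    if len(np.unique(m)) != m.size:
        raise ValidationError("masses must be distinct")
    if np.any(m <= 0) or np.any(s <= 0):
        raise ValidationError("masses and S values must be > 0")
    b, log_a = np.polyfit(np.log(m), np.log(s), 1)
    return PowerLawS(a=float(np.exp(log_a)), b=float(b), units=units,
                     mass_unit="g")


def s_from_power_law(law: PowerLawS, mass: float,
                     source: str = "sphere_power_law") -> SValue:
    """Evaluate a power law into a tagged SValue."""
    return SValue(value=law(mass), units=law.units, source=source, mass=mass)


def convert_s_units(s: SValue, target_units: str) -> SValue:
    """Exact conversion between Gy/(MBq·h) and mGy/(MBq·s)."""
    if target_units not in S_UNITS:
        raise ValidationError(f"unknown target units {target_units!r}")
    if s.units == target_units:
        return s
    if target_units == S_UNIT_GY_MBQ_H:
        value = s.value * MGY_MBQ_S_TO_GY_MBQ_H
    else:
        value = s.value / MGY_MBQ_S_TO_GY_MBQ_H
    return SValue(value=value, units=target_units, source=s.source, mass=s.mass)


def absorbed_dose(tia_MBq_h: float, s: SValue) -> float:
    """MIRD mean absorbed dose D = Ã * S, in Gy."""
    if tia_MBq_h < 0:
        raise ValidationError("time-integrated activity must be >= 0")
    if not isinstance(s, SValue):
        raise ValidationError("absorbed_dose requires a unit-tagged SValue")
    return tia_MBq_h * s.in_gy_per_mbq_h()


def dose_per_unit_activity(dose_Gy: float, activity_MBq: float) -> float:
    """Dose per administered activity in Gy/GBq."""
    if activity_MBq <= 0:
        raise ValidationError("activity must be > 0")
    return 1000.0 * dose_Gy / activity_MBq


def plan_next_fractions(A1_MBq: float, D1_Gy: float, target_Gy: float,
                        N: int) -> TreatmentPlan:
    """Activity per remaining fraction to reach a target whole-body dose.

        A_i = (A1 / D1) * (target - D1) / (N - 1)

    assuming the dose per unit activity observed in the first fraction holds
    for subsequent fractions.
    """
    if N < 2:
        raise ValidationError("planning requires N >= 2 fractions")
    if D1_Gy <= 0 or A1_MBq <= 0:
        raise ValidationError("A1 and D1 must be > 0")
    if D1_Gy >= target_Gy:
        raise ValidationError(
            f"first-fraction dose {D1_Gy} Gy already meets the target "
            f"{target_Gy} Gy")
    ai = (A1_MBq / D1_Gy) * (target_Gy - D1_Gy) / (N - 1)
    return TreatmentPlan(n_fractions=N, target_dose_Gy=target_Gy,
                         A1_MBq=A1_MBq, D1_Gy=D1_Gy, planned_Ai_MBq=ai)


def estimate_red_marrow_dose(wb_dose_Gy: float,
                             ratio: float = WB_TO_RM_RATIO) -> float:
    """Red-marrow dose surrogate: whole-body dose divided by ~1.6."""
    if ratio <= 0:
        raise ValidationError("ratio must be > 0")
    if wb_dose_Gy < 0:
        raise ValidationError("dose must be >= 0")
    return wb_dose_Gy / ratio


def weight_based_first_activity(mass_kg: float, MBq_per_kg: float) -> float:
    """Weight-based first-fraction activity prescription (e.g. 444 MBq/kg)."""
    if mass_kg <= 0 or MBq_per_kg <= 0:
        raise ValidationError("mass and MBq_per_kg must be > 0")
    return mass_kg * MBq_per_kg


def propagate_product_uncertainty(x: float, sx: float, y: float, sy: float,
                                  corr: float = 0.0) -> float:
    """First-order standard uncertainty of a product x*y.

    sigma^2 = (y*sx)^2 + (x*sy)^2 + 2*corr*x*y*sx*sy
    """
    if sx < 0 or sy < 0:
        raise ValidationError("sigmas must be >= 0")
    if not -1.0 <= corr <= 1.0:
        raise ValidationError("correlation must lie in [-1, 1]")
    var = (y * sx) ** 2 + (x * sy) ** 2 + 2.0 * corr * x * y * sx * sy
    return math.sqrt(max(var, 0.0))


def s_uncertainty_from_mass(law: PowerLawS, mass: float,
                            sigma_mass: float) -> float:
    """First-order S uncertainty from a mass uncertainty through a power law.

    sigma_S = |b| * (sigma_m / m) * S(m)
    """
    if mass <= 0 or sigma_mass < 0:
        raise ValidationError("mass must be > 0 and sigma_mass >= 0")
    return abs(law.b) * (sigma_mass / mass) * law(mass)


def dose_result(region: str, tia_MBq_h: float, s: SValue,
                tia_sigma: float = 0.0, s_sigma: float = 0.0,
                integration_period: str = "0-inf") -> DoseResult:
    """Assemble a DoseResult with first-order uncorrelated uncertainty."""
    s_gy = s.in_gy_per_mbq_h()
    scale = s_gy / s.value  # unit conversion applied to sigma too
    dose = absorbed_dose(tia_MBq_h, s)
    sigma = propagate_product_uncertainty(tia_MBq_h, tia_sigma,
                                          s_gy, s_sigma * scale)
    return DoseResult(region=region, tia_MBq_h=tia_MBq_h,
                      tia_sigma=tia_sigma, s_value=s, s_sigma=s_sigma,
                      dose_Gy=dose, dose_sigma_Gy=sigma,
                      integration_period=integration_period)
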