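"""Validated configuration and domain types shared across the pipeline.

The pipeline optimises four process factors of a continuous-flow lanolin
saponification: reaction temperature ``T`` (°C), reaction time ``t0`` (min),
mass fraction of the (diluted) lanolin solution ``wi`` and alkali dosage
``lam_a`` (kg alkali per kg lanolin). Everything else — stream densities,
reactor geometry, emission constants, risk settings — is explicit
configuration with documented defaults.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

#: Canonical factor order used for coded design columns everywhere.
FACTOR_ORDER = ("temperature", "time", "mass_fraction", "alkali")


class FactorSpec(BaseModel):
    """One design factor with its physical range."""

    name: str
    low: float
    high: float
    units: str = ""

    @model_validator(mode="after")
    def _range_ok(self) -> "FactorSpec":
        if not self.low < self.high:
            raise ValueError(f"factor {self.name!r}: low ({self.low}) must be < high ({self.high})")
        return self

    def decode(self, coded: float) -> float:
        """Map a coded level in [-1, 1] to physical units (0 -> midpoint).

        The three design levels map exactly onto low/midpoint/high, immune
        to float round-off at the range ends.
        """
        if coded == -1:
            return self.low
        if coded == 1:
            return self.high
        mid = 0.5 * (self.low + self.high)
        half = 0.5 * (self.high - self.low)
        return mid + coded * half

    def encode(self, physical: float) -> float:
        mid = 0.5 * (self.low + self.high)
        half = 0.5 * (self.high - self.low)
        return (physical - mid) / half


def default_factors() -> list[FactorSpec]:
    """The campaign's design ranges.

    Temperature 70-90 °C, time 5-15 min, lanolin solution mass fraction
    0.15-0.35 and alkali dosage 0.116-0.123 kg/kg lanolin (the experimental
    alkali range of the study; the wider 0.115-0.125 band is only used for
    sensitivity sampling, see :class:`SamplingRanges`).
    """
    return [
        FactorSpec(name="temperature", low=70.0, high=90.0, units="degC"),
        FactorSpec(name="time", low=5.0, high=15.0, units="min"),
        FactorSpec(name="mass_fraction", low=0.15, high=0.35, units="kg/kg"),
        FactorSpec(name="alkali", low=0.116, high=0.123, units="kg/kg lanolin"),
    ]


class ProcessConditions(BaseModel):
    """The four optimisation factors of a single run."""

    T: float = Field(description="reaction temperature, degC")
    t0: float = Field(gt=0, description="reaction time, min")
    wi: float = Field(gt=0, le=1, description="mass fraction of lanolin solution")
    lam_a: float = Field(ge=0, description="alkali dosage, kg alkali per kg lanolin")


class MaterialProperties(BaseModel):
    """Densities and mass fractions of the three feed streams.

    Defaults describe the virtual rig: unit densities and a 50 % lanolin
    feedstock solution neutralised by a 15 % alkali solution. Real campaigns
    override these with measured values.
    """

    rho1: float = Field(default=1.0, gt=0, description="density of lanolin feedstock solution, g/mL")
    rho2: float = Field(default=1.0, gt=0, description="density of alkali solution, g/mL")
    rho3: float = Field(default=1.0, gt=0, description="density of diluent, g/mL")
    w0: float = Field(default=0.5, gt=0, le=1, description="mass fraction of lanolin in feedstock solution")
    wj: float = Field(default=0.15, gt=0, le=1, description="mass fraction of the alkali solution")


class HardwareConfig(BaseModel):
    """Microreactor geometry and timing constants.

    ``Vr`` defaults to the volume of a 1 mm ID x 50 m PTFE coil
    (pi * (0.5 mm)^2 * 50 m = 39.27 mL).
    """

    coil_id: float = Field(default=1.0, gt=0, description="coil inner diameter, mm")
    coil_len: float = Field(default=50.0, gt=0, description="coil length, m")
    Vr: Optional[float] = Field(default=None, description="reactor coil volume, mL")
    V1: float = Field(default=10.0, ge=0, description="tubing volume pump -> second T-junction, mL")
    t3: float = Field(default=2.0, ge=0, description="equilibration time, min")

    @model_validator(mode="after")
    def _volume_consistent(self) -> "HardwareConfig":
        coil_volume = math.pi * (self.coil_id / 2.0) ** 2 * self.coil_len  # mm^2 * m = mL
        if self.Vr is None:
            self.Vr = coil_volume
        elif abs(self.Vr - coil_volume) > 1e-3 * coil_volume:
            raise ValueError(
                f"Vr = {self.Vr} mL inconsistent with coil dimensions "
                f"(pi*(id/2)^2*len = {coil_volume:.4f} mL, tolerance 0.1%)"
            )
        if self.Vr <= 0:
            raise ValueError("reactor volume must be positive")
        return self


class EmissionConstants(BaseModel):
    """Natural-gas heating emission constants.

    The fuel constants are the national chemical-industry accounting values:
    carbon content 15.3 t C per 10^4 Nm^3, oxidation rate 0.99 and lower
    heating value 389.9 GJ per 10^4 Nm^3. ``c_spec`` is the effective
    specific heat applied to the heated stream mass; its default is
    calibrated so the optimised validation conditions reproduce the
    reference emission of 0.072 kg CO2 per kg lanolin.
    """

    C_fuel: float = Field(default=15.3, gt=0, description="carbon content, t C / 1e4 Nm^3")
    eta: float = Field(default=0.99, ge=0, description="carbon oxidation rate")
    M_CO2: float = Field(default=44.0, gt=0, description="molar mass of CO2, g/mol")
    M_C: float = Field(default=12.0, gt=0, description="molar mass of carbon, g/mol")
    LHv: float = Field(default=389.9, gt=0, description="lower heating value, GJ / 1e4 Nm^3")
    c_spec: float = Field(default=2353.0, gt=0, description="effective specific heat, J/(kg*degC)")
    T_ref: float = Field(default=25.0, frozen=True, description="reference temperature, degC")

    @field_validator("T_ref")
    @classmethod
    def _ref_fixed(cls, v: float) -> float:
        if v != 25.0:
            raise ValueError("reference temperature is fixed at 25 degC")
        return v


class RiskSettings(BaseModel):
    """Design-space acceptance settings for the Monte-Carlo risk map."""

    yield_low: float = Field(default=0.55, description="lower lanosterol-yield bound")
    yield_high: float = Field(default=0.70, description="upper lanosterol-yield bound")
    n_sims: int = Field(default=500, ge=1, description="Monte Carlo coefficient draws")
    acceptable_risk: float = Field(default=0.2, gt=0, lt=1)
    significance: float = Field(default=0.05, gt=0, lt=1, description="CI level for optional risk intervals")
    seed: int = Field(default=0, ge=0)

    @model_validator(mode="after")
    def _bounds_ok(self) -> "RiskSettings":
        if not 0 <= self.yield_low < self.yield_high <= 1:
            raise ValueError("require 0 <= yield_low < yield_high <= 1")
        return self


class SamplingRanges(BaseModel):
    """Uniform sampling ranges for the emission sensitivity analysis.

    The alkali band here (0.115-0.125) is slightly wider than the design
    range; it is the stated sensitivity-study band.
    """

    temperature: tuple[float, float] = (70.0, 90.0)
    time: tuple[float, float] = (5.0, 15.0)
    mass_fraction: tuple[float, float] = (0.15, 0.35)
    alkali: tuple[float, float] = (0.115, 0.125)
    n_samples: int = Field(default=10_000, ge=2)
    seed: int = Field(default=0, ge=0)

    @model_validator(mode="after")
    def _ranges_ok(self) -> "SamplingRanges":
        for name in ("temperature", "time", "mass_fraction", "alkali"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"sampling range for {name}: low must be < high")
        return self


class CampaignConfig(BaseModel):
    """Aggregate configuration for the end-to-end pipeline."""

    factors: list[FactorSpec] = Field(default_factory=default_factors)
    materials: MaterialProperties = Field(default_factory=MaterialProperties)
    hardware: HardwareConfig = Field(default_factory=HardwareConfig)
    emission_constants: EmissionConstants = Field(default_factory=EmissionConstants)
    risk: RiskSettings = Field(default_factory=RiskSettings)
    sampling: SamplingRanges = Field(default_factory=SamplingRanges)
    seed: int = Field(default=0, ge=0, description="master seed; stage seeds derive from it")
    out_dir: Path = Path("campaign_out")

    @model_validator(mode="after")
    def _factors_ok(self) -> "CampaignConfig":
        if len(self.factors) != 4:
            raise ValueError("exactly four process factors are required")
        names = [f.name for f in self.factors]
        if len(set(names)) != 4:
            raise ValueError(f"factor names must be unique, got {names}")
        return self

    @classmethod
    def from_file(cls, path: str | Path) -> "CampaignConfig":
        """Load a YAML or JSON campaign configuration."""
        text = Path(path).read_text(encoding="utf-8")
        data = yaml.safe_load(text)  # YAML superset handles JSON too
        return cls.model_validate(data or {})
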