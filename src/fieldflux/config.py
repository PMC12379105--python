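"""Pipeline configuration.

A single configuration object collects every tunable constant of the
pipeline: chamber geometry, the flux QC thresholds, the trait validation
thresholds, the microclimate plausibility ranges and the folded-leaf
species list.  Defaults are the values used for the original field
campaign; a YAML file with the same structure can override any subset.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

#: Graminoid species whose tightly folded leaves are scanned folded, so the
#: scanned area must be doubled to obtain the true one-sided leaf area.
FOLDED_SPECIES = frozenset(
    {
        "Festuca rubra",
        "Festuca ovina",
        "Festuca vivipara",
        "Avenella flexuosa",
        "Nardus stricta",
    }
)


@dataclass(frozen=True)
class ChamberSpec:
    """Geometry and state of the closed chamber system.

    Attributes
    ----------
    pressure_atm:
        Air pressure inside the chamber, atm (assumed 1 atm in the field).
    volume_L:
        Volume of chamber plus tubing, litres.
    area_m2:
        Ground area enclosed by the chamber base, m^2.
    """

    pressure_atm: float = 1.0
    volume_L: float = 25.0
    area_m2: float = 0.0625

    #: Gas constant, L atm K^-1 mol^-1 (fixed; not configurable).
    R: float = dataclasses.field(default=0.082057, init=False)

    def __post_init__(self) -> None:
        if self.pressure_atm <= 0:
            raise ValueError(f"pressure_atm must be > 0, got {self.pressure_atm}")
        if self.volume_L <= 0:
            raise ValueError(f"volume_L must be > 0, got {self.volume_L}")
        if self.area_m2 <= 0:
            raise ValueError(f"area_m2 must be > 0, got {self.area_m2}")


@dataclass(frozen=True)
class FluxQCThresholds:
    """Thresholds of the flux-flag decision tree.

    ``start_center``/``start_halfwidth`` define the plausible starting
    concentration window (ppm); ``b_max`` is the upper bound on the
    exponential rate parameter beyond which the fit is an optimiser
    artefact; ``r_cut`` is the |Pearson r| cut separating *discard*
    (trend present) from *zero* (trendless noise) among bad fits.
    """

    start_center: float = 421.0
    start_halfwidth: float = 100.0
    b_max: float = 1.0
    r_cut: float = 0.5

    @property
    def start_min(self) -> float:
        return self.start_center - self.start_halfwidth

    @property
    def start_max(self) -> float:
        return self.start_center + self.start_halfwidth


@dataclass(frozen=True)
class TraitThresholds:
    """Plausibility limits for derived leaf traits (strict inequalities)."""

    ldmc_max: float = 1.0  # g g^-1
    sla_min: float = 5.0  # cm^2 g^-1
    sla_max: float = 500.0  # cm^2 g^-1
    nitrogen_max: float = 6.4  # percent dry mass


@dataclass(frozen=True)
class MicroclimateRanges:
    """Plausible value ranges per logger variable (inclusive bounds)."""

    air_min: float = -40.0
    air_max: float = 30.0
    ground_min: float = -40.0
    ground_max: float = 35.0
    soil_min: float = 5.0
    soil_max: float = 20.0
    moisture_min: float = 0.0


@dataclass(frozen=True)
class PipelineConfig:
    """Bundle of all pipeline constants, overridable from YAML."""

    chamber: ChamberSpec = field(default_factory=ChamberSpec)
    flux_qc: FluxQCThresholds = field(default_factory=FluxQCThresholds)
    traits: TraitThresholds = field(default_factory=TraitThresholds)
    microclimate: MicroclimateRanges = field(default_factory=MicroclimateRanges)
    folded_species: frozenset[str] = FOLDED_SPECIES
    #: Shift each site's diurnal GPP series so its most positive GPP is zero.
    night_correction: bool = True
    #: Trim length removed from each end of a chamber closure, seconds.
    trim_head_s: float = 10.0
    trim_tail_s: float = 10.0
    #: Length of the initial window used for the Cz intercept, seconds.
    cz_window_s: float = 15.0
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        kwargs: dict[str, Any] = {}
        sections = {
            "chamber": ChamberSpec,
            "flux_qc": FluxQCThresholds,
            "traits": TraitThresholds,
            "microclimate": MicroclimateRanges,
        }
        for key, value in d.items():
            if key in sections:
                if not isinstance(value, dict):
                    raise TypeError(f"config section {key!r} must be a mapping")
                kwargs[key] = sections[key](**value)
            elif key == "folded_species":
                kwargs[key] = frozenset(value)
            elif key in {f.name for f in dataclasses.fields(cls)}:
                kwargs[key] = value
            else:
                raise KeyError(f"unknown config key: {key!r}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {}
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if dataclasses.is_dataclass(value):
                section = {
                    sf.name: getattr(value, sf.name)
                    for sf in dataclasses.fields(value)
                    if sf.init
                }
                out[f.name] = section
            elif isinstance(value, frozenset):
                out[f.name] = sorted(value)
            else:
                out[f.name] = value
        return out

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


DEFAULT_CONFIG = PipelineConfig()
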