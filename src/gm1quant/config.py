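"""Validated pipeline configuration (YAML -> pydantic, versioned schema).

Unknown keys are rejected everywhere, so a typo in a config fails loudly at
load time rather than silently running with a default.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Mapping, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .chem import Adduct, MolecularFormula, SpeciesTarget
from .synthetic import (
    BaselineParams,
    RegionMap,
    RegionParams,
    SimulationConfig,
    build_phantom,
)

__all__ = ["PipelineConfig", "load_config", "config_hash"]

SCHEMA_VERSION = 1


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SpeciesSpec(_Model):
    name: str
    formula: str
    adduct: str = "[M-H]-"
    search_halfwidth: float = 0.5
    integration_halfwidth: float = 0.4

    def to_target(self) -> SpeciesTarget:
        return SpeciesTarget(
            name=self.name,
            formula=MolecularFormula.parse(self.formula),
            adduct=Adduct(self.adduct),
            search_halfwidth=self.search_halfwidth,
            integration_halfwidth=self.integration_halfwidth,
        )


class PhantomSpec(_Model):
    layout: Literal["single", "pair", "cortex3", "hippo6"] = "single"
    dims: tuple[int, int] = (8, 25)
    labels: Optional[list[str]] = None

    def to_phantom(self, pixel_pitch: float) -> RegionMap:
        return build_phantom(self.layout, self.dims, pixel_pitch, self.labels)


class RegionSpec(_Model):
    true_ratio: float
    total_intensity: float = 100.0


class BaselineSpec(_Model):
    constant: float = 2.0
    slope: float = -0.002
    bump_amplitude: float = 5.0
    bump_center: float = 1500.0
    bump_sigma: float = 120.0


class SimulationSpec(_Model):
    phantom: PhantomSpec = Field(default_factory=PhantomSpec)
    regions: dict[str, RegionSpec]
    mz_range: tuple[float, float] = (1000.0, 2000.0)
    mz_bin: float = 0.02
    peak_sigma: float = 0.15
    pixel_pitch: float = 70.0
    baseline: BaselineSpec = Field(default_factory=BaselineSpec)
    gain_sigma: float = 0.3
    noise_sigma: float = 1.0
    ratio_animal_cv: float = 0.08
    ratio_roi_cv: float = 0.08
    n_animals: int = 1
    sections_per_animal: int = 2
    roi_drop_rate: float = 0.0
    roi_max_pixels: Optional[int] = None


class QuantificationSpec(_Model):
    baseline_method: Literal["linear_median", "linear_minima", "tophat"] = "linear_median"
    flank_width_da: float = 1.0
    detection_snr: float = 3.0


class StatsSpec(_Model):
    normality_test: Literal["dagostino", "shapiro"] = "dagostino"
    alpha: float = 0.05


class PipelineConfig(_Model):
    schema_version: int = SCHEMA_VERSION
    seed: int = 0
    species: list[SpeciesSpec] = Field(
        default_factory=lambda: [
            SpeciesSpec(name="GM1d18:1", formula="C73H131N3O31"),
            SpeciesSpec(name="GM1d20:1", formula="C75H135N3O31"),
        ]
    )
    simulation: SimulationSpec
    quantification: QuantificationSpec = Field(default_factory=QuantificationSpec)
    stats: StatsSpec = Field(default_factory=StatsSpec)

    @field_validator("schema_version")
    @classmethod
    def _version(cls, v: int) -> int:
        if v != SCHEMA_VERSION:
            raise ValueError(f"unsupported schema_version {v}; expected {SCHEMA_VERSION}")
        return v

    @field_validator("species")
    @classmethod
    def _two_species(cls, v: list[SpeciesSpec]) -> list[SpeciesSpec]:
        if len(v) != 2:
            raise ValueError(
                "exactly two species are required: numerator first, denominator second"
            )
        return v

    def targets(self) -> tuple[SpeciesTarget, SpeciesTarget]:
        a, b = self.species
        return a.to_target(), b.to_target()

    def simulation_config(self, seed: int | None = None) -> SimulationConfig:
        s = self.simulation
        return SimulationConfig(
            regions={k: RegionParams(r.true_ratio, r.total_intensity)
                     for k, r in s.regions.items()},
            mz_range=s.mz_range,
            mz_bin=s.mz_bin,
            peak_sigma=s.peak_sigma,
            baseline=BaselineParams(**s.baseline.model_dump()),
            gain_sigma=s.gain_sigma,
            noise_sigma=s.noise_sigma,
            ratio_animal_cv=s.ratio_animal_cv,
            ratio_roi_cv=s.ratio_roi_cv,
            n_animals=s.n_animals,
            sections_per_animal=s.sections_per_animal,
            roi_drop_rate=s.roi_drop_rate,
            roi_max_pixels=s.roi_max_pixels,
            rng_seed=self.seed if seed is None else seed,
            targets=self.targets(),
        )

    def phantom(self) -> RegionMap:
        return self.simulation.phantom.to_phantom(self.simulation.pixel_pitch)


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, Mapping):
        raise ValueError(f"config file {path} is not a mapping")
    return PipelineConfig.model_validate(raw)


def config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()
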