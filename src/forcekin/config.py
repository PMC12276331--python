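"""YAML configuration with explicit units, validated by pydantic models."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

from .bond_physics import DEFAULT_KBT, BellParams
from .simulate import SimScenario


class BondConfig(BaseModel):
    k_off_per_s: float = 0.03
    x_beta_nm: float = 0.5
    kBT_pN_nm: float = DEFAULT_KBT
    temperature_K: float = 298.15

    def to_params(self) -> BellParams:
        return BellParams(k_off=self.k_off_per_s, x_beta=self.x_beta_nm,
                          kBT=self.kBT_pN_nm, temperature=self.temperature_K)


class ScenarioConfig(BaseModel):
    pulling_speeds_um_s: list[float] = [0.75, 1.5, 3.0, 5.0, 8.0, 12.0]
    cantilever_k_pN_nm: float = 10.0
    tether_contour_length_nm: float = 8.0
    tether_persistence_length_nm: float = 0.38
    surface_stiffness_pN_nm: float = 5.0
    bond: BondConfig = Field(default_factory=BondConfig)
    binding_A: float = 0.4
    binding_t0_s: float = 0.01
    binding_tau_s: float = 0.2
    second_bond_A: float = 0.3
    second_bond_tau_s: float = 0.25
    noise_sigma_range_pN: tuple[float, float] = (4.0, 6.0)
    sample_rate_per_nm: float = 10.0
    curves_per_condition: int = 600
    contact_times_s: list[float] = [0.25]
    seed: int = 0

    @field_validator("binding_A")
    @classmethod
    def _check_amplitude(cls, v):
        if not (0 < v <= 1):
            raise ValueError("binding_A must lie in (0, 1]")
        return v

    def to_scenario(self, seed: int | None = None) -> SimScenario:
        return SimScenario(
            pulling_speeds=tuple(self.pulling_speeds_um_s),
            cantilever_k=self.cantilever_k_pN_nm,
            tether_contour_length=self.tether_contour_length_nm,
            tether_persistence_length=self.tether_persistence_length_nm,
            surface_stiffness=self.surface_stiffness_pN_nm,
            bond=self.bond.to_params(),
            binding_A=self.binding_A, binding_t0=self.binding_t0_s,
            binding_tau=self.binding_tau_s,
            second_bond_A=self.second_bond_A,
            second_bond_tau=self.second_bond_tau_s,
            noise_sigma_range=tuple(self.noise_sigma_range_pN),
            sample_rate=self.sample_rate_per_nm,
            curves_per_condition=self.curves_per_condition,
            contact_times=tuple(self.contact_times_s),
            seed=self.seed if seed is None else seed,
        )


class DetectionConfig(BaseModel):
    min_drop_sigma: float = 4.0
    max_drop_width_nm: float = 2.0
    slope_window_nm: float = 10.0
    min_drop_abs_pN: float = 2.0


class KineticsConfig(BaseModel):
    tether_radius_nm: float = 12.0  # PEG contour + coupled-molecule size
    n_ligands: int = 1
    construct_name: str = "simulated"


class PipelineConfig(BaseModel):
    scenario: ScenarioConfig = Field(default_factory=ScenarioConfig)
    detection: DetectionConfig = Field(default_factory=DetectionConfig)
    kinetics: KineticsConfig = Field(default_factory=KineticsConfig)
    n_mixture_components: int = 2
    output_dir: str = "forcekin_results"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.model_validate(raw or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))


def quickstart_config_path() -> Path:
    """Path of the bundled quickstart configuration."""
    return Path(__file__).parent / "data" / "quickstart.yaml"
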