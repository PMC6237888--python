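"""Validated pipeline configuration.

One YAML file drives the whole pipeline; unknown keys are rejected so
typos fail loudly, and the effective configuration is echoed into every
output directory for provenance.
"""

from __future__ import annotations

from pathlib import Path
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .assignment import ElementBounds
from .synthetic import SimulationConfig


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulationSettings(_Strict):
    sugar: str = "ribose"
    amino_acids: tuple[str, ...] = (
        "glycine", "isoleucine", "lysine", "cysteine"
    )
    time_points_h: tuple[float, ...] = (2.0, 4.0, 6.0, 10.0)
    replicates: int = Field(3, ge=1)
    generations: int = Field(2, ge=0)
    delta_probability: float = Field(0.18, ge=0.0, le=1.0)
    delta_probabilities: dict[str, float] | None = None
    redox_probability: float = Field(0.8, ge=0.0, le=1.0)
    plant_scheme: bool = True
    degradation_branches: bool = True
    max_formulas_per_system: int = Field(160, ge=1)
    cleavage_depth: int = Field(4, ge=0)
    base_intensity: float = Field(1.0e8, gt=0)
    depth_decay: float = Field(0.45, gt=0, le=1.0)
    time_growth: float = Field(1.8, gt=0)
    intensity_sigma: float = Field(0.35, ge=0)
    replicate_sigma: float = Field(0.15, ge=0)
    noise_floor: float = Field(1.0e4, gt=0)
    min_truth_snr: float = Field(8.0, ge=0)
    mass_error_ppm_sd: float = Field(0.1, ge=0)
    isotopologues: bool = True
    noise_peaks: int = Field(40, ge=0)
    mz_range: tuple[float, float] = (100.0, 600.0)
    dropout_probability: float = Field(0.0, ge=0.0, le=1.0)
    resolution_floor_mda: float = Field(1.0, gt=0)


class BoundsSettings(_Strict):
    c: tuple[int, int] = (1, 40)
    h: tuple[int, int] = (1, 80)
    n: tuple[int, int] = (0, 6)
    o: tuple[int, int] = (0, 25)
    s: tuple[int, int] = (0, 4)
    ppm_tolerance: float = Field(0.2, gt=0)
    hard_ppm_cut: float = Field(0.5, gt=0)


class AssignmentSettings(_Strict):
    snr_floor: float = Field(4.0, ge=0)
    isotope_ppm_tol: float = Field(1.0, gt=0)
    isotope_rel_int_tol: float = Field(0.3, gt=0)


class SchemeSettings(_Strict):
    min_systems: int = Field(3, ge=1)
    min_snr: float = Field(8.0, ge=0)


class PipelineConfig(_Strict):
    seed: int = 0
    verbosity: int = Field(1, ge=0, le=2)
    simulation: SimulationSettings = SimulationSettings()
    bounds: BoundsSettings = BoundsSettings()
    assignment: AssignmentSettings = AssignmentSettings()
    scheme: SchemeSettings = SchemeSettings()

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)

    def simulation_config(self) -> SimulationConfig:
        return SimulationConfig(seed=self.seed, **self.simulation.model_dump())

    def element_bounds(self) -> ElementBounds:
        d = self.bounds.model_dump()
        return ElementBounds(
            c=tuple(d["c"]), h=tuple(d["h"]), n=tuple(d["n"]),
            o=tuple(d["o"]), s=tuple(d["s"]),
            ppm_tolerance=d["ppm_tolerance"], hard_ppm_cut=d["hard_ppm_cut"],
        )

    def echo(self, out_dir: str | Path) -> None:
        """Write the effective config and library version for provenance."""
        from . import __version__

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        payload = self.model_dump(mode="json")
        payload["maillardnet_version"] = __version__
        (out / "effective_config.yaml").write_text(
            yaml.safe_dump(payload, sort_keys=True)
        )
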